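&FCI NORB=4,NELEC=4,MS2=0,
 ORBSYM=1,1,1,1,
 ISYM=1,
/
  5.4686622972672339e-01    1    1    1    1
  2.0074884457498240e-16    2    1    1    1
  1.2341776729990389e-01    2    1    2    1
  4.8615551264339935e-01    2    2    1    1
 -2.4101949609518936e-16    2    2    2    1
  5.4523414539506221e-01    2    2    2    2
  7.4043943354756290e-03    3    1    2    1
  1.3988176982057340e-01    3    1    3    1
  1.6164298487605647e-02    3    2    1    1
  1.6175999214640500e-16    3    2    2    1
 -1.7963305361653734e-02    3    2    2    2
 -1.3284409249944095e-16    3    2    3    1
  2.2162954907683746e-02    3    2    3    2
  5.5507026461644871e-01    3    3    1    1
 -1.2791349791576202e-16    3    3    2    1
  4.4151234222030927e-01    3    3    2    2
 -3.1504311322724823e-16    3    3    3    1
  3.8156190782148242e-02    3    3    3    2
  6.2951046554876422e-01    3    3    3    3
  5.2331375919436658e-02    4    1    1    1
 -1.5594290674913083e-16    4    1    2    1
 -4.4933889494163021e-02    4    1    2    2
  1.5632282697188018e-16    4    1    3    1
  3.3050978773563500e-02    4    1    3    2
  1.0543851142269196e-01    4    1    3    3
  8.3721909430300570e-02    4    1    4    1
 -2.5287586067940057e-16    4    2    1    1
 -1.2902809731657985e-01    4    2    2    1
  2.6340116329927854e-16    4    2    2    2
  4.6851161151488567e-02    4    2    3    1
 -2.2090309777835059e-16    4    2    3    2
  2.5466689204936145e-16    4    2    4    1
  1.8020418424167076e-01    4    2    4    2
  2.6960099077513369e-16    4    3    1    1
  5.3187769821622329e-02    4    3    2    1
 -1.6268442764091425e-16    4    3    2    2
  1.0253329087597057e-01    4    3    3    1
 -1.1167474003169538e-16    4    3    3    2
  2.5312188741299191e-16    4    3    4    1
 -2.0625873943643631e-02    4    3    4    2
  1.0388424021663187e-01    4    3    4    3
  5.1762659399644384e-01    4    4    1    1
  3.0351856359247524e-16    4    4    2    1
  5.2882576330082520e-01    4    4    2    2
  3.6362424239653764e-16    4    4    3    1
 -3.3219600860032272e-03    4    4    3    2
  5.1287631744285067e-01    4    4    3    3
  7.0620556242693999e-04    4    4    4    1
  3.1554960229890535e-16    4    4    4    3
  5.4861529870676007e-01    4    4    4    4
 -2.1397725842040560e+00    1    1    0    0
  1.9929486234778132e-16    2    1    0    0
 -1.6186894158565246e+00    2    2    0    0
  3.3922468417313761e-16    3    1    0    0
 -6.9608972938920693e-03    3    2    0    0
 -1.5179250936571218e+00    3    3    0    0
 -9.1491694257244474e-02    4    1    0    0
  2.9160056165481151e-16    4    2    0    0
 -3.1729516558038487e-16    4    3    0    0
 -1.1594189576049412e+00    4    4    0    0
  2.8521633190509652e+00    0    0    0    0
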