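&FCI NORB=4,NELEC=4,MS2=0,
 ORBSYM=1,1,1,1,
 ISYM=1,
/
  5.4110926089675304e-01    1    1    1    1
  1.3545061570278139e-01    2    1    2    1
  5.0078529031624974e-01    2    2    1    1
  2.7713962220373286e-16    2    2    2    1
  5.3360901873347399e-01    2    2    2    2
  3.1572729194381939e-16    3    1    1    1
 -1.0620793680344394e-02    3    1    2    1
  1.3181053839732151e-01    3    1    3    1
 -2.3923886825376259e-02    3    2    1    1
 -2.8045779017903319e-16    3    2    2    1
  2.0504401632802684e-02    3    2    2    2
 -2.4047487295168435e-16    3    2    3    1
  5.1171443432014754e-02    3    2    3    2
  5.3780084948163254e-01    3    3    1    1
 -2.9808557710885701e-16    3    3    2    1
  4.7295139438617956e-01    3    3    2    2
  4.5982048380866301e-16    3    3    3    1
 -5.2094443109801651e-02    3    3    3    2
  5.8069758180782893e-01    3    3    3    3
  4.2751037802943995e-02    4    1    1    1
 -2.8413829745421736e-02    4    1    2    2
 -6.0409238222716953e-02    4    1    3    2
  7.9821891057191077e-02    4    1    3    3
  8.2702200799439865e-02    4    1    4    1
  1.0377913259625830e-16    4    2    1    1
 -9.8525799879851328e-02    4    2    2    1
 -1.8184379743821108e-16    4    2    2    2
 -8.7437824765943986e-02    4    2    3    1
  2.1782194543277851e-16    4    2    3    2
  3.2375268204225917e-16    4    2    3    3
  3.6424733772348389e-16    4    2    4    1
  1.6028620964789903e-01    4    2    4    2
  2.5041740554159833e-16    4    3    1    1
 -1.0273556110480619e-01    4    3    2    1
  7.5815873800430880e-02    4    3    3    1
  2.1909867608484738e-16    4    3    3    2
  4.4385050333178087e-16    4    3    3    3
 -1.5754107258590828e-16    4    3    4    1
  3.1577793476436050e-02    4    3    4    2
  1.2657245966188710e-01    4    3    4    3
  5.1966991827619047e-01    4    4    1    1
  4.5754215683191275e-16    4    4    2    1
  5.2850794325314998e-01    4    4    2    2
 -2.8084510893499519e-16    4    4    3    1
  4.6059935362010663e-03    4    4    3    2
  5.1905776656726810e-01    4    4    3    3
  4.6349732226449281e-04    4    4    4    1
 -4.4109764140944801e-16    4    4    4    3
  5.5003800947246473e-01    4    4    4    4
 -2.1339535012969919e+00    1    1    0    0
 -6.3666095944934265e-16    2    1    0    0
 -1.6517744831991270e+00    2    2    0    0
 -4.4703913100591492e-16    3    1    0    0
  1.6722578337637604e-02    3    2    0    0
 -1.5104614725400061e+00    3    3    0    0
 -8.4449178191958699e-02    4    1    0    0
  2.9610933073175272e-16    4    3    0    0
 -1.1273211003759129e+00    4    4    0    0
  2.8610860687238437e+00    0    0    0    0
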