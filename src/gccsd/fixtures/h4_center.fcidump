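&FCI NORB=4,NELEC=4,MS2=0,
 ORBSYM=1,1,1,1,
 ISYM=1,
/
  5.4090860036310973e-01    1    1    1    1
 -2.7231744139408305e-16    2    1    1    1
  1.2568285206202173e-01    2    1    2    1
  4.9197972707424903e-01    2    2    1    1
 -4.2495997942747819e-16    2    2    2    1
  5.6339833718193311e-01    2    2    2    2
  1.4238807241892296e-01    3    1    3    1
  1.8116395582910974e-16    3    2    1    1
 -1.9534302637811304e-16    3    2    2    2
  1.0354425937343099e-02    3    2    3    2
  5.4669207243340612e-01    3    3    1    1
 -3.0168800350759758e-16    3    3    2    1
  4.3321807508767091e-01    3    3    2    2
  3.0076635499470149e-16    3    3    3    1
  4.2464486126651761e-16    3    3    3    2
  6.3049425637934609e-01    3    3    3    3
  3.8574588854205671e-02    4    1    1    1
 -5.7343034140757039e-02    4    1    2    2
 -1.5659363711067839e-16    4    1    3    1
  3.3338571546649730e-16    4    1    3    2
  1.0247936905719641e-01    4    1    3    3
  8.0677396340230217e-02    4    1    4    1
  3.9690920084641222e-16    4    2    1    1
 -1.3940322176444209e-01    4    2    2    1
  6.7109228081030925e-16    4    2    2    2
  6.0241069000292858e-16    4    2    3    1
  1.5233051111733855e-16    4    2    3    3
 -1.6497456718668216e-16    4    2    4    1
  1.7725262144629333e-01    4    2    4    2
 -1.4542280686851220e-16    4    3    1    1
  5.9417282993076132e-16    4    3    2    1
  1.1991784677986499e-01    4    3    3    1
  2.7638330756067801e-16    4    3    3    3
 -1.4180167433204717e-16    4    3    4    1
 -1.3685168911027252e-16    4    3    4    2
  1.1138590688277986e-01    4    3    4    3
  5.1961226255333637e-01    4    4    1    1
 -4.4776207949175341e-16    4    4    2    1
  5.3259963531960886e-01    4    4    2    2
 -3.0636355775897846e-16    4    4    3    1
  5.1663079733094974e-01    4    4    3    3
 -1.7348795935724260e-03    4    4    4    1
  6.1679503901543265e-16    4    4    4    2
 -1.4616262744068250e-16    4    4    4    3
  5.5102265358895330e-01    4    4    4    4
 -2.1331726952526719e+00    1    1    0    0
  8.8693038294869583e-16    2    1    0    0
 -1.6208461703966590e+00    2    2    0    0
 -1.5624281512017595e+00    3    3    0    0
 -6.3291742330761055e-02    4    1    0    0
 -1.0870361872952477e-15    4    2    0    0
  2.5681403566080274e-16    4    3    0    0
 -1.1103596739156540e+00    4    4    0    0
  2.8559605242801647e+00    0    0    0    0
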