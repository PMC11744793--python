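&FCI NORB=4,NELEC=4,MS2=0,
 ORBSYM=1,1,1,1,
 ISYM=1,
/
  5.4110926089675293e-01    1    1    1    1
  1.3545061570278927e-01    2    1    2    1
  5.0078529031626795e-01    2    2    1    1
  5.3360901873344369e-01    2    2    2    2
  1.0620793680343138e-02    3    1    2    1
 -1.4008943460586150e-16    3    1    2    2
  1.3181053839731355e-01    3    1    3    1
  2.3923886825390272e-02    3    2    1    1
 -2.0504401632787005e-02    3    2    2    2
 -1.3363928368857344e-16    3    2    3    1
  5.1171443432069384e-02    3    2    3    2
  5.3780084948161444e-01    3    3    1    1
 -1.0021115103780598e-16    3    3    2    1
  4.7295139438623446e-01    3    3    2    2
 -1.7145340563310748e-16    3    3    3    1
  5.2094443109803552e-02    3    3    3    2
  5.8069758180775044e-01    3    3    3    3
  4.2751037802943870e-02    4    1    1    1
 -2.8413829745376405e-02    4    1    2    2
  1.5407195119893159e-16    4    1    3    1
  6.0409238222757733e-02    4    1    3    2
  7.9821891057145322e-02    4    1    3    3
  8.2702200799439823e-02    4    1    4    1
 -2.3946271783683691e-16    4    2    1    1
 -9.8525799879779719e-02    4    2    2    1
 -3.8764927334524990e-16    4    2    2    2
  8.7437824766009656e-02    4    2    3    1
 -3.7826322134415786e-16    4    2    3    3
  1.4149003350609784e-16    4    2    4    1
  1.6028620964787549e-01    4    2    4    2
  4.2367243545068229e-16    4    3    1    1
  1.0273556110487192e-01    4    3    2    1
  1.9043799702337945e-16    4    3    2    2
  7.5815873800359188e-02    4    3    3    1
 -1.1253361772378893e-16    4    3    3    2
  1.4429238328266570e-16    4    3    3    3
  2.3904675824793756e-16    4    3    4    1
 -3.1577793476449047e-02    4    3    4    2
  1.2657245966191105e-01    4    3    4    3
  5.1966991827619047e-01    4    4    1    1
  1.6383764885974028e-16    4    4    2    1
  5.2850794325314709e-01    4    4    2    2
 -4.6059935362045045e-03    4    4    3    2
  5.1905776656727143e-01    4    4    3    3
  4.6349732226419905e-04    4    4    4    1
 -1.5723931692487663e-16    4    4    4    2
  5.9726570340993865e-16    4    4    4    3
  5.5003800947246462e-01    4    4    4    4
 -2.1339535012969915e+00    1    1    0    0
 -1.6517744831991401e+00    2    2    0    0
  2.7181884154905146e-16    3    1    0    0
 -1.6722578337583772e-02    3    2    0    0
 -1.5104614725399939e+00    3    3    0    0
 -8.4449178191957130e-02    4    1    0    0
  5.4673855400897234e-16    4    2    0    0
 -1.1921275553786035e-15    4    3    0    0
 -1.1273211003759143e+00    4    4    0    0
  2.8610860687238437e+00    0    0    0    0
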