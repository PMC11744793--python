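&FCI NORB=4,NELEC=4,MS2=0,
 ORBSYM=1,1,1,1,
 ISYM=1,
/
  5.4402971732297833e-01    1    1    1    1
  1.5726081671593351e-16    2    1    1    1
  1.2985297100766549e-01    2    1    2    1
  4.9394251892042018e-01    2    2    1    1
 -4.1958371233834488e-16    2    2    2    1
  5.3729903604607654e-01    2    2    2    2
  1.0366377217373140e-02    3    1    2    1
  1.3523956120542749e-01    3    1    3    1
  2.2876333070550814e-02    3    2    1    1
 -2.1757231278184012e-02    3    2    2    2
  1.0448591170306645e-16    3    2    3    1
  3.9256315287628588e-02    3    2    3    2
  5.4595290124955720e-01    3    3    1    1
  1.5410767513783799e-16    3    3    2    1
  4.5964957506668258e-01    3    3    2    2
  3.2807607267712399e-16    3    3    3    1
  5.1179454009336593e-02    3    3    3    2
  6.0229117047842773e-01    3    3    3    3
  4.8254402335616169e-02    4    1    1    1
 -1.7916064465710804e-16    4    1    2    1
 -3.5525682753959523e-02    4    1    2    2
  5.0944727585852681e-02    4    1    3    2
  9.2426854475295986e-02    4    1    3    3
  8.3489587172195748e-02    4    1    4    1
 -1.1302563271644947e-01    4    2    2    1
  6.8642068538149451e-16    4    2    2    2
  7.2486718827707478e-02    4    2    3    1
  1.6937636802073108e-01    4    2    4    2
  8.4192148510130640e-02    4    3    2    1
 -1.2672730526034893e-16    4    3    2    2
  8.7978800911220789e-02    4    3    3    1
 -1.1427893282507642e-16    4    3    3    2
  3.2945726699401735e-16    4    3    3    3
 -2.4010769900737991e-16    4    3    4    1
 -2.9681081744514257e-02    4    3    4    2
  1.1575849724314799e-01    4    3    4    3
  5.1866098775196423e-01    4    4    1    1
  5.2829249486614338e-01    4    4    2    2
 -2.0474763178407099e-16    4    4    3    1
 -4.4456270535708116e-03    4    4    3    2
  5.1609073891708579e-01    4    4    3    3
  8.0381402345990787e-04    4    4    4    1
  2.5226302353095032e-16    4    4    4    2
 -2.0500485427355083e-16    4    4    4    3
  5.4922050430555602e-01    4    4    4    4
 -2.1369083150351580e+00    1    1    0    0
  4.4250862456650024e-16    2    1    0    0
 -1.6352210751268712e+00    2    2    0    0
 -1.6035847975867420e-16    3    1    0    0
 -1.3629057656185908e-02    3    2    0    0
 -1.5119380214011855e+00    3    3    0    0
 -9.0228669547121887e-02    4    1    0    0
 -4.8009203035855425e-16    4    2    0    0
  2.7441534275927292e-16    4    3    0    0
 -1.1464481860395477e+00    4    4    0    0
  2.8560024848553209e+00    0    0    0    0
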