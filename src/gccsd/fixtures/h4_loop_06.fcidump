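&FCI NORB=4,NELEC=4,MS2=0,
 ORBSYM=1,1,1,1,
 ISYM=1,
/
  5.4402971732334948e-01    1    1    1    1
 -4.0607261694101255e-16    2    1    1    1
  1.2985297101006155e-01    2    1    2    1
  4.9394251892653046e-01    2    2    1    1
  5.3729903603419205e-01    2    2    2    2
 -1.2229819333748862e-16    3    1    1    1
 -1.0366377218410027e-02    3    1    2    1
 -1.3841796617040419e-16    3    1    2    2
  1.3523956120293490e-01    3    1    3    1
 -2.2876333077848698e-02    3    2    1    1
  2.1757231278066114e-02    3    2    2    2
  3.9256315307547161e-02    3    2    3    2
  5.4595290124366513e-01    3    3    1    1
 -1.8051303108228065e-16    3    3    2    1
  4.5964957508660065e-01    3    3    2    2
 -1.9612249743582593e-16    3    3    3    1
 -5.1179454018093207e-02    3    3    3    2
  6.0229117045047409e-01    3    3    3    3
  4.8254402335888485e-02    4    1    1    1
  1.9715914035508761e-16    4    1    2    1
 -3.5525682739980774e-02    4    1    2    2
  1.1761222627687225e-16    4    1    3    1
 -5.0944727603271671e-02    4    1    3    2
  9.2426854461325716e-02    4    1    3    3
  8.3489587172013185e-02    4    1    4    1
  3.0357581448736516e-16    4    2    1    1
 -1.1302563269497928e-01    4    2    2    1
 -2.4118508018406820e-16    4    2    2    2
 -7.2486718855077042e-02    4    2    3    1
  2.2384099646935266e-16    4    2    3    3
 -2.0367436453431489e-16    4    2    4    1
  1.6937636801306033e-01    4    2    4    2
  1.2119595190738719e-16    4    3    1    1
 -8.4192148537500192e-02    4    3    2    1
  8.7978800889789224e-02    4    3    3    1
  1.7115217126678598e-16    4    3    3    2
 -2.5970181936551373e-16    4    3    4    1
  2.9681081752137194e-02    4    3    4    2
  1.1575849725091501e-01    4    3    4    3
  5.1866098775178193e-01    4    4    1    1
 -4.7699211735638432e-16    4    4    2    1
  5.2829249486506591e-01    4    4    2    2
 -1.9368281578805423e-16    4    4    3    1
  4.4456270554331110e-03    4    4    3    2
  5.1609073891794410e-01    4    4    3    3
  8.0381402319731400e-04    4    4    4    1
  2.3981933149647825e-16    4    4    4    2
  5.4922050430555069e-01    4    4    4    4
 -2.1369083150355048e+00    1    1    0    0
  3.8973617874218150e-16    2    1    0    0
 -1.6352210751305918e+00    2    2    0    0
  6.6873072326979413e-16    3    1    0    0
  1.3629057639351636e-02    3    2    0    0
 -1.5119380213974631e+00    3    3    0    0
 -9.0228669545216508e-02    4    1    0    0
 -3.3896751765844283e-16    4    2    0    0
 -2.0385161342803382e-16    4    3    0    0
 -1.1464481860392015e+00    4    4    0    0
  2.8560024848553214e+00    0    0    0    0
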