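&FCI NORB=6,NELEC=4,MS2=0,
 ORBSYM=1,1,1,1,1,1,
 ISYM=1,
/
  1.6591519949353712e+00    1    1    1    1
  1.0011818618946119e-01    2    1    1    1
  1.0535924848723972e-02    2    1    2    1
  3.2593114661335365e-01    2    2    1    1
 -3.4221102705139822e-03    2    2    2    1
  4.6027756616772164e-01    2    2    2    2
  1.4111712036633881e-01    3    1    1    1
  1.0604912394834994e-02    3    1    2    1
  1.2202577119241369e-02    3    1    2    2
  2.1988890573321221e-02    3    1    3    1
  2.3499385169918504e-02    3    2    1    1
  2.6664280656246474e-03    3    2    2    1
 -5.6319055874787062e-02    3    2    2    2
  9.7051942012987420e-05    3    2    3    1
  1.8620601421879837e-02    3    2    3    2
  3.9277087103263497e-01    3    3    1    1
  9.2698019200131935e-03    3    3    2    1
  2.1483546844691254e-01    3    3    2    2
 -1.1538369934558661e-03    3    3    3    1
  1.2749710723452485e-02    3    3    3    2
  3.3166318823214042e-01    3    3    3    3
  9.8107735551531232e-03    4    1    4    1
 -7.2813707072794534e-03    4    2    4    1
  2.1616982293176396e-02    4    2    4    2
 -1.0346070494949150e-02    4    3    4    1
  1.9938190669929450e-02    4    3    4    2
  4.1340311391452257e-02    4    3    4    3
  3.9633809268445425e-01    4    4    1    1
  3.7217759594280692e-03    4    4    2    1
  2.5125326791298713e-01    4    4    2    2
  5.0524945704689024e-03    4    4    3    1
  1.1183239150726545e-02    4    4    3    2
  2.8047757996587447e-01    4    4    3    3
  3.1294551115940933e-01    4    4    4    4
  9.8107735551531215e-03    5    1    5    1
 -7.2813707072794526e-03    5    2    5    1
  2.1616982293176393e-02    5    2    5    2
 -1.0346070494949148e-02    5    3    5    1
  1.9938190669929447e-02    5    3    5    2
  4.1340311391452250e-02    5    3    5    3
  1.6869139513691109e-02    5    4    5    4
  3.9633809268445419e-01    5    5    1    1
  3.7217759594280774e-03    5    5    2    1
  2.5125326791298713e-01    5    5    2    2
  5.0524945704689128e-03    5    5    3    1
  1.1183239150726545e-02    5    5    3    2
  2.8047757996587436e-01    5    5    3    3
  2.7920723213202714e-01    5    5    4    4
  3.1294551115940922e-01    5    5    5    5
  6.8342396628244290e-02    6    1    1    1
  9.3842288248692837e-03    6    1    2    1
 -7.5885702722022956e-03    6    1    2    2
  4.3320512105086756e-03    6    1    3    1
  2.5905019512659404e-03    6    1    3    2
  1.1734039330710924e-02    6    1    3    3
  1.4604830165929257e-03    6    1    4    4
  1.4604830165929257e-03    6    1    5    5
  1.0772598613269062e-02    6    1    6    1
  7.3177589435044169e-02    6    2    1    1
  2.0517336316133649e-03    6    2    2    1
 -1.1141496349213338e-01    6    2    2    2
  3.5672868198015325e-03    6    2    3    1
  4.1200664812757977e-02    6    2    3    2
  1.8379203738110958e-02    6    2    3    3
  3.2699063987472667e-02    6    2    4    4
  3.2699063987472660e-02    6    2    5    5
 -5.6474754736984486e-04    6    2    6    1
  1.2903417730422684e-01    6    2    6    2
 -2.1268367804091151e-02    6    3    1    1
 -2.4268653555542231e-03    6    3    2    1
  5.5471745970362502e-02    6    3    2    2
  4.0596818402042871e-03    6    3    3    1
 -1.4819766230253668e-02    6    3    3    2
 -3.6349300835598640e-02    6    3    3    3
 -6.3236623444868287e-03    6    3    4    4
 -6.3236623444868278e-03    6    3    5    5
 -4.3894156578326727e-03    6    3    6    1
 -3.7005667885783897e-02    6    3    6    2
  2.9234854418685233e-02    6    3    6    3
 -6.0121351750616657e-03    6    4    4    1
  1.8875002393760998e-02    6    4    4    2
  1.2527470199953875e-02    6    4    4    3
  1.9548329281579839e-02    6    4    6    4
 -6.0121351750616640e-03    6    5    5    1
  1.8875002393760994e-02    6    5    5    2
  1.2527470199953872e-02    6    5    5    3
  1.9548329281579836e-02    6    5    6    5
  3.5575972867814065e-01    6    6    1    1
 -1.1707061041140549e-03    6    6    2    1
  4.3238466231055467e-01    6    6    2    2
  1.0990390743867661e-02    6    6    3    1
 -4.7857722078205232e-02    6    6    3    2
  2.3897832553149431e-01    6    6    3    3
  2.6117050822794452e-01    6    6    4    4
  2.6117050822794452e-01    6    6    5    5
 -4.8742545309759843e-03    6    6    6    1
 -1.0756267985674334e-01    6    6    6    2
  4.5922312641892442e-02    6    6    6    3
  4.3006285920374204e-01    6    6    6    6
 -4.6616662448211894e+00    1    1    0    0
 -9.6696075918060079e-02    2    1    0    0
 -1.3517106046006828e+00    2    2    0    0
 -1.6285584653978788e-01    3    1    0    0
  1.9925197933803200e-02    3    2    0    0
 -1.1013241586727927e+00    3    3    0    0
 -1.1016492975732921e+00    4    4    0    0
 -1.5869753414066001e-16    5    2    0    0
 -1.6046006271712924e-16    5    4    0    0
 -1.1016492975732919e+00    5    5    0    0
 -5.1113522451032338e-02    6    1    0    0
 -2.5555986548317488e-02    6    2    0    0
 -2.2874040311634716e-02    6    3    0    0
  1.1852850549403341e-16    6    4    0    0
 -1.0038368443734378e+00    6    6    0    0
  7.9376581635449994e-01    0    0    0    0
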