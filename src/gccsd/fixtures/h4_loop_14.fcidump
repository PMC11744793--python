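&FCI NORB=4,NELEC=4,MS2=0,
 ORBSYM=1,1,1,1,
 ISYM=1,
/
  5.3606668066730434e-01    1    1    1    1
  1.3957469999885216e-01    2    1    2    1
  5.1076554154727727e-01    2    2    1    1
  2.8509261320686284e-16    2    2    2    1
  5.3374039305279852e-01    2    2    2    2
  6.4735743745539904e-03    3    1    2    1
 -2.4732816221768991e-16    3    1    2    2
  1.3194742638653184e-01    3    1    3    1
  1.6153067764493195e-02    3    2    1    1
 -2.7730901137286656e-16    3    2    2    1
 -1.8933769346804488e-02    3    2    2    2
  1.1432626079877091e-16    3    2    3    1
  6.2885624315189584e-02    3    2    3    2
  5.2565413039945552e-01    3    3    1    1
  2.4573499873536401e-16    3    3    2    1
  4.8786071358836181e-01    3    3    2    2
  2.4508460023273028e-16    3    3    3    1
  4.0684919679077017e-02    3    3    3    2
  5.5284083390446037e-01    3    3    3    3
  2.6021615569992860e-02    4    1    1    1
 -2.3364230001166789e-02    4    1    2    2
  6.8451128325772562e-02    4    1    3    2
  5.5483468135270449e-02    4    1    3    3
  7.9583054387295724e-02    4    1    4    1
 -3.5512026943940634e-16    4    2    1    1
 -7.3670774674204034e-02    4    2    2    1
 -6.4705900201033332e-16    4    2    2    2
  1.0853245776395345e-01    4    2    3    1
  1.1949468178652739e-16    4    2    3    2
 -3.3872134704293608e-16    4    2    3    3
 -2.1979938198914791e-16    4    2    4    1
  1.5097902487160456e-01    4    2    4    2
  1.2028784289832667e-01    4    3    2    1
  5.9627387201576232e-02    4    3    3    1
 -2.1668026448760253e-16    4    3    3    2
  3.1343040470553052e-16    4    3    3    3
 -2.1792244873196649e-02    4    3    4    2
  1.4088471611469655e-01    4    3    4    3
  5.2142957537150969e-01    4    4    1    1
 -2.9922766071823647e-16    4    4    2    1
  5.3005534815170796e-01    4    4    2    2
 -3.9799078784005402e-03    4    4    3    2
  5.2453323420360953e-01    4    4    3    3
 -1.1100200097717110e-03    4    4    4    1
  1.9351763128403163e-16    4    4    4    2
 -8.2563464311282701e-16    4    4    4    3
  5.5220051113562652e-01    4    4    4    4
 -2.1285852065133639e+00    1    1    0    0
 -1.6546267622539865e+00    2    2    0    0
 -2.0064115493411351e-16    3    1    0    0
 -6.8987918355489300e-03    3    2    0    0
 -1.5514968857313010e+00    3    3    0    0
 -5.2963930242261946e-02    4    1    0    0
  2.8954659936883590e-16    4    2    0    0
  3.7629575317702961e-16    4    3    0    0
 -1.0768055604177971e+00    4    4    0    0
  2.8652202093402011e+00    0    0    0    0
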