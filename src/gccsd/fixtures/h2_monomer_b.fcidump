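&FCI NORB=2,NELEC=2,MS2=0,
 ORBSYM=1,1,
 ISYM=1,
/
  6.7475592680991014e-01    1    1    1    1
  1.8121046201653132e-01    2    1    2    1
  6.6371140134667617e-01    2    2    1    1
 -1.6259117748842636e-16    2    2    2    1
  6.9765150448607194e-01    2    2    2    2
 -1.2533097866316092e+00    1    1    0    0
 -4.7506884878719929e-01    2    2    0    0
  7.1510433905810811e-01    0    0    0    0
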