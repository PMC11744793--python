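&FCI NORB=4,NELEC=4,MS2=0,
 ORBSYM=1,1,1,1,
 ISYM=1,
/
  6.6333014885873964e-01    1    1    1    1
  6.7475592680991014e-01    2    2    2    2
  1.0841128572991490e-16    3    1    1    1
  1.8462678355754503e-01    3    1    3    1
  6.5344137235957112e-01    3    3    1    1
  6.8679153568690698e-01    3    3    3    3
  1.8121046201653132e-01    4    2    4    2
  6.6371140134667617e-01    4    4    2    2
 -1.6259117748842636e-16    4    4    4    2
  6.9765150448607194e-01    4    4    4    4
 -1.2178260299802539e+00    1    1    0    0
 -1.2533097866316092e+00    2    2    0    0
 -5.0963787444998920e-01    3    3    0    0
 -4.7506884878719929e-01    4    4    0    0
  1.3765758526868581e+00    0    0    0    0
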