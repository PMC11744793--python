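&FCI NORB=2,NELEC=2,MS2=0,
 ORBSYM=1,1,
 ISYM=1,
/
  6.7448876635229171e-01    1    1    1    1
  1.8128880821283463e-01    2    1    2    1
  6.6346809641942484e-01    2    2    1    1
  6.9739376741862724e-01    2    2    2    2
 -1.2524635735505181e+00    1    1    0    0
 -4.7594871523595522e-01    2    2    0    0
  7.1375399366468839e-01    0    0    0    0
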