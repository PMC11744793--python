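&FCI NORB=2,NELEC=2,MS2=0,
 ORBSYM=1,1,
 ISYM=1,
/
  6.8238953314775241e-01    1    1    1    1
  1.7900057606263331e-01    2    1    2    1
  6.7073277830477485e-01    2    2    1    1
 -3.7951264231404788e-16    2    2    2    1
  7.0510563216855049e-01    2    2    2    2
 -1.2778530061428752e+00    1    1    0    0
 -4.4829969611759457e-01    2    2    0    0
  7.5596744414714279e-01    0    0    0    0
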