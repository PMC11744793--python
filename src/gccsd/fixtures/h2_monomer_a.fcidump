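&FCI NORB=2,NELEC=2,MS2=0,
 ORBSYM=1,1,
 ISYM=1,
/
  6.6333014885873964e-01    1    1    1    1
  1.0841128572991490e-16    2    1    1    1
  1.8462678355754503e-01    2    1    2    1
  6.5344137235957112e-01    2    2    1    1
  6.8679153568690698e-01    2    2    2    2
 -1.2178260299802539e+00    1    1    0    0
 -5.0963787444998920e-01    2    2    0    0
  6.6147151362875001e-01    0    0    0    0
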