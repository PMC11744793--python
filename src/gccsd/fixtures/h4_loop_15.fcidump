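&FCI NORB=4,NELEC=4,MS2=0,
 ORBSYM=1,1,1,1,
 ISYM=1,
/
  5.3704582852189886e-01    1    1    1    1
 -2.6718170113801865e-16    2    1    1    1
  1.4043471262464405e-01    2    1    2    1
  5.0924785900226477e-01    2    2    1    1
  5.3281607432545985e-01    2    2    2    2
  8.0225438246195914e-03    3    1    2    1
  1.3026155256272465e-01    3    1    3    1
  1.9169714307574692e-02    3    2    1    1
 -1.8001993104230545e-02    3    2    2    2
 -2.1944848489472969e-16    3    2    3    1
  6.2134744719405180e-02    3    2    3    2
  5.2758861952658043e-01    3    3    1    1
 -3.8692630049734262e-16    3    3    2    1
  4.8638879978321259e-01    3    3    2    2
 -2.0626182950169721e-16    3    3    3    1
  4.3964532823043356e-02    3    3    3    2
  5.5639956183774708e-01    3    3    3    3
  3.0826072830937874e-02    4    1    1    1
 -2.2309802684578450e-02    4    1    2    2
  6.7972953603720507e-02    4    1    3    2
  6.0309503440660689e-02    4    1    3    3
  8.0460248103794887e-02    4    1    4    1
  1.4050053455793415e-16    4    2    1    1
 -7.7608572026855130e-02    4    2    2    1
  1.0431343338317221e-01    4    2    3    1
  1.4048485692344469e-16    4    2    4    1
  1.5110214189932111e-01    4    2    4    2
  1.1965019442650124e-01    4    3    2    1
  6.0881417924418778e-02    4    3    3    1
 -3.6565423897434855e-16    4    3    3    3
  2.4805169937388213e-16    4    3    4    1
 -2.5896779693681322e-02    4    3    4    2
  1.3952265450067414e-01    4    3    4    3
  5.2107035424020920e-01    4    4    1    1
  5.2964986218369570e-01    4    4    2    2
  2.7636118582267952e-16    4    4    3    1
 -4.2278256141064239e-03    4    4    3    2
  5.2332721324484077e-01    4    4    3    3
 -6.9550177818097838e-04    4    4    4    1
  3.5827227560263494e-16    4    4    4    3
  5.5164551993292132e-01    4    4    4    4
 -2.1297846288742397e+00    1    1    0    0
  6.4521053594420496e-16    2    1    0    0
 -1.6635060303343392e+00    2    2    0    0
 -1.2314891706551893e-02    3    2    0    0
 -1.5307089715832225e+00    3    3    0    0
 -6.3815039491139425e-02    4    1    0    0
 -3.1922328507578926e-16    4    2    0    0
 -4.2013320255930247e-16    4    3    0    0
 -1.0887921709153023e+00    4    4    0    0
  2.8666771126204309e+00    0    0    0    0
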