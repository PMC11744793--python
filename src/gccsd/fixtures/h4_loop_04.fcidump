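&FCI NORB=4,NELEC=4,MS2=0,
 ORBSYM=1,1,1,1,
 ISYM=1,
/
  5.4828932465154800e-01    1    1    1    1
  1.1967192283739111e-01    2    1    2    1
  4.8142694412639969e-01    2    2    1    1
  2.4299030404246532e-16    2    2    2    1
  5.5231774122977950e-01    2    2    2    2
 -1.8288342499429915e-16    3    1    1    1
  1.4287100216854828e-01    3    1    3    1
  2.3012350259811358e-16    3    2    2    1
  9.6598122643130266e-03    3    2    3    2
  5.6049669280804748e-01    3    3    1    1
  4.2861968410719220e-01    3    3    2    2
 -4.5187254925168134e-16    3    3    3    1
  6.4776772521633108e-01    3    3    3    3
  5.3981252582478982e-02    4    1    1    1
 -5.1297121181156174e-02    4    1    2    2
 -1.3283199248034496e-16    4    1    3    2
  1.1304827351255754e-01    4    1    3    3
  8.3619500219236573e-02    4    1    4    1
 -1.3902751203455180e-01    4    2    2    1
 -2.3382661504409305e-16    4    2    2    2
 -2.0292267930027578e-16    4    2    3    1
 -3.2468288615513204e-16    4    2    3    2
 -1.1522835564423273e-16    4    2    4    1
  1.8684810749195677e-01    4    2    4    2
 -2.1923351166925299e-16    4    3    2    1
  1.1207061942560008e-01    4    3    3    1
  2.2013353596897128e-16    4    3    3    3
  2.9078001699467134e-16    4    3    4    1
  1.3458495384434523e-16    4    3    4    2
  9.6957478501891181e-02    4    3    4    3
  5.1706824358560499e-01    4    4    1    1
 -1.1501532547172925e-16    4    4    2    1
  5.2954451005406467e-01    4    4    2    2
  3.7951214104169160e-16    4    4    3    1
  5.1096672720016312e-01    4    4    3    3
  4.6122066706144870e-04    4    4    4    1
  3.5886167901138884e-16    4    4    4    2
  4.0206221987196173e-16    4    4    4    3
  5.4838889977137917e-01    4    4    4    4
 -2.1411617967825602e+00    1    1    0    0
 -2.2272618457035787e-16    2    1    0    0
 -1.6110429274339089e+00    2    2    0    0
 -1.3604803940304126e-16    3    1    0    0
 -1.5217817806683036e+00    3    3    0    0
 -9.0414522254031723e-02    4    1    0    0
 -2.7219982533221679e-16    4    2    0    0
 -3.3115504783081458e-16    4    3    0    0
 -1.1637795694113093e+00    4    4    0    0
  2.8507811686685698e+00    0    0    0    0
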