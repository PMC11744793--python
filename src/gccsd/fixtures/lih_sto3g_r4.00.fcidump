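&FCI NORB=6,NELEC=4,MS2=0,
 ORBSYM=1,1,1,1,1,1,
 ISYM=1,
/
  1.6603418216520156e+00    1    1    1    1
  1.1558138539274027e-01    2    1    1    1
  1.2575888284312997e-02    2    1    2    1
  2.4969221628117266e-01    2    2    1    1
  1.9129452247806239e-03    2    2    2    1
  3.6161863172960484e-01    2    2    2    2
  1.3948188358265282e-01    3    1    1    1
  1.4433644479170036e-02    3    1    2    1
  4.5424346967948290e-03    3    1    2    2
  1.8611819138597697e-02    3    1    3    1
  1.1852932589651199e-01    3    2    1    1
  3.1785645490126808e-03    3    2    2    1
 -1.2793371252533808e-01    3    2    2    2
  2.9055065079129729e-03    3    2    3    1
  1.5433306448628581e-01    3    2    3    2
  3.0653237712899450e-01    3    3    1    1
  4.6727046498850136e-03    3    3    2    1
  2.8901463977831698e-01    3    3    2    2
  3.6022585627547461e-03    3    3    3    1
 -5.0819373954171507e-02    3    3    3    2
  2.7840372550000336e-01    3    3    3    3
  9.7668962023661973e-03    4    1    4    1
 -8.6556377342413646e-03    4    2    4    1
  2.5365450577987655e-02    4    2    4    2
 -1.0376718103042422e-02    4    3    4    1
  2.8919056331274996e-02    4    3    4    2
  3.6642681671394707e-02    4    3    4    3
  3.9635905765488477e-01    4    4    1    1
  3.9861091628624161e-03    4    4    2    1
  1.9688710900295420e-01    4    4    2    2
  4.8203498826820774e-03    4    4    3    1
  7.0473857078463736e-02    4    4    3    2
  2.2979199249305277e-01    4    4    3    3
  3.1294551115940933e-01    4    4    4    4
  9.7668962023662008e-03    5    1    5    1
 -8.6556377342413681e-03    5    2    5    1
  2.5365450577987662e-02    5    2    5    2
  1.1255116704154142e-16    5    3    3    2
 -1.0376718103042427e-02    5    3    5    1
  2.8919056331275009e-02    5    3    5    2
  3.6642681671394721e-02    5    3    5    3
 -1.3645424102009665e-16    5    4    1    1
  1.6869139513691137e-02    5    4    5    4
  3.9635905765488494e-01    5    5    1    1
  3.9861091628624126e-03    5    5    2    1
  1.9688710900295428e-01    5    5    2    2
  4.8203498826820705e-03    5    5    3    1
  7.0473857078463764e-02    5    5    3    2
  2.2979199249305282e-01    5    5    3    3
  2.7920723213202736e-01    5    5    4    4
  3.1294551115940961e-01    5    5    5    5
 -1.5459588152443270e-02    6    1    1    1
 -3.2269757081467300e-03    6    1    2    1
  4.4239547645502477e-03    6    1    2    2
  4.1063752369146708e-04    6    1    3    1
 -2.3603817644920430e-03    6    1    3    2
 -4.4908649845426564e-03    6    1    3    3
 -3.2386610063999961e-04    6    1    4    4
 -3.2386610063999972e-04    6    1    5    5
  9.1036851331230476e-03    6    1    6    1
 -5.9946349436246653e-02    6    2    1    1
  2.5523805006690209e-04    6    2    2    1
  4.8356003688859249e-02    6    2    2    2
 -3.3374743488202561e-03    6    2    3    1
 -7.1911621245058330e-02    6    2    3    2
  3.6957335739243667e-02    6    2    3    3
 -3.5333780604804063e-02    6    2    4    4
 -3.5333780604804077e-02    6    2    5    5
 -7.2642985277768428e-03    6    2    6    1
  6.0531230731911752e-02    6    2    6    2
  4.6792680530100494e-02    6    3    1    1
  2.1246703121316508e-03    6    3    2    1
 -7.5791875459990804e-02    6    3    2    2
 -2.0716970251442599e-03    6    3    3    1
  7.6936370777897625e-02    6    3    3    2
 -1.2897265739739285e-02    6    3    3    3
  2.6782286815604572e-02    6    3    4    4
  2.6782286815604583e-02    6    3    5    5
 -9.6066180874736229e-03    6    3    6    1
 -1.1385515780593800e-02    6    3    6    2
  6.6616565648139933e-02    6    3    6    3
  1.3757620304587421e-03    6    4    4    1
 -6.7164853699277520e-03    6    4    4    2
 -4.9422017879748471e-04    6    4    4    3
  1.5895576793121625e-02    6    4    6    4
  1.3757620304587429e-03    6    5    5    1
 -6.7164853699277554e-03    6    5    5    2
 -4.9422017879748373e-04    6    5    5    3
  1.5895576793121636e-02    6    5    6    5
  3.7348738673739790e-01    6    6    1    1
  3.2265191281717924e-03    6    6    2    1
  2.4285243648392929e-01    6    6    2    2
  5.2226274800134202e-03    6    6    3    1
  2.3885902598459810e-02    6    6    3    2
  2.4808813705867680e-01    6    6    3    3
  2.6573441286333538e-01    6    6    4    4
  2.6573441286333549e-01    6    6    5    5
  2.3906484182390909e-03    6    6    6    1
 -2.5479140902328487e-02    6    6    6    2
  6.3810318279138587e-03    6    6    6    3
  2.9311280167475828e-01    6    6    6    6
 -4.5301480638372009e+00    1    1    0    0
 -1.1749433061759286e-01    2    1    0    0
 -9.7856997628208975e-01    2    2    0    0
 -1.4538818842732301e-01    3    1    0    0
 -9.4691294791222888e-02    3    2    0    0
 -9.8369538848689864e-01    3    3    0    0
 -1.0044353854686310e+00    4    4    0    0
  1.1257968987628300e-16    5    2    0    0
  2.2696873230148798e-16    5    4    0    0
 -1.0044353854686314e+00    5    5    0    0
  6.8669166734120152e-03    6    1    0    0
  6.8309719477002567e-02    6    2    0    0
 -1.3502593864486637e-02    6    3    0    0
 -1.0005683430165262e+00    6    6    0    0
  3.9688290817724997e-01    0    0    0    0
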