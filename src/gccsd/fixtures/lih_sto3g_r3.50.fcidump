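&FCI NORB=6,NELEC=4,MS2=0,
 ORBSYM=1,1,1,1,1,1,
 ISYM=1,
/
  1.6601936047869708e+00    1    1    1    1
  1.1002176667492770e-01    2    1    1    1
  1.1622312021784270e-02    2    1    2    1
  2.5781031629148060e-01    2    2    1    1
  1.0585440288045419e-03    2    2    2    1
  3.7811996928379404e-01    2    2    2    2
  1.4176648361306551e-01    3    1    1    1
  1.3514435450519210e-02    3    1    2    1
  5.7529163036812462e-03    3    1    2    2
  2.0029880138895780e-02    3    1    3    1
  9.4470648110252770e-02    3    2    1    1
  3.0062299296542707e-03    3    2    2    1
 -1.1182948791299496e-01    3    2    2    2
  2.0829775232044730e-03    3    2    3    1
  1.0778906958168573e-01    3    2    3    2
  3.3763586898435322e-01    3    3    1    1
  5.7608143844231586e-03    3    3    2    1
  2.5881939331693937e-01    3    3    2    2
  2.5057801873709495e-03    3    3    3    1
 -1.1341808792920472e-02    3    3    3    2
  2.7757971054013864e-01    3    3    3    3
  9.7722191931041043e-03    4    1    4    1
 -1.2329927653069634e-16    4    2    1    1
 -1.2103026653548853e-16    4    2    3    2
 -8.2637488338491993e-03    4    2    4    1
  2.3698734742303825e-02    4    2    4    2
 -1.1867736675280016e-16    4    3    2    2
  1.0152926978496967e-16    4    3    3    2
 -1.0490041865399757e-02    4    3    4    1
  2.7047181141434506e-02    4    3    4    2
  3.8770372937234843e-02    4    3    4    3
  3.9635651351997003e-01    4    4    1    1
  3.7981396540306507e-03    4    4    2    1
  2.0477865637272311e-01    4    4    2    2
  4.9398201816744291e-03    4    4    3    1
  5.4345299026795427e-02    4    4    3    2
  2.4905146459170577e-01    4    4    3    3
 -1.0191706109995673e-16    4    4    4    2
  3.1294551115940911e-01    4    4    4    4
  9.7722191931041077e-03    5    1    5    1
 -8.2637488338492028e-03    5    2    5    1
  2.3698734742303832e-02    5    2    5    2
 -1.0490041865399761e-02    5    3    5    1
  2.7047181141434517e-02    5    3    5    2
  3.8770372937234857e-02    5    3    5    3
  1.6869139513691119e-02    5    4    5    4
  3.9635651351997014e-01    5    5    1    1
  3.7981396540306585e-03    5    5    2    1
  2.0477865637272319e-01    5    5    2    2
  4.9398201816744326e-03    5    5    3    1
  5.4345299026795447e-02    5    5    3    2
  2.4905146459170588e-01    5    5    3    3
  2.7920723213202719e-01    5    5    4    4
  3.1294551115940938e-01    5    5    5    5
 -3.1774812357700570e-02    6    1    1    1
 -5.2185326547712204e-03    6    1    2    1
  5.2144059913577876e-03    6    1    2    2
 -7.5948201808662130e-04    6    1    3    1
 -3.0762567449433139e-03    6    1    3    2
 -7.4678276879737984e-03    6    1    3    3
 -8.0483619723877204e-04    6    1    4    4
 -8.0483619723877226e-04    6    1    5    5
  8.8767984117007672e-03    6    1    6    1
 -7.9825996781319172e-02    6    2    1    1
  4.6948078077283495e-05    6    2    2    1
  7.1828801542428489e-02    6    2    2    2
 -4.5733412441095814e-03    6    2    3    1
 -8.2641804297583304e-02    6    2    3    2
  2.8136129591740874e-02    6    2    3    3
 -4.5444053595329027e-02    6    2    4    4
 -4.5444053595329041e-02    6    2    5    5
 -5.5969654905487880e-03    6    2    6    1
  9.2404706117297522e-02    6    2    6    2
  5.1368667054055996e-02    6    3    1    1
  2.4028692211427718e-03    6    3    2    1
 -8.7775896594415412e-02    6    3    2    2
 -3.0949025532174173e-03    6    3    3    1
  7.4166906640388663e-02    6    3    3    2
  9.3711733375265189e-03    6    3    3    3
  2.8075751286046870e-02    6    3    4    4
  2.8075751286046880e-02    6    3    5    5
 -8.2915544012336188e-03    6    3    6    1
 -3.9355257640221727e-02    6    3    6    2
  7.3007491717021353e-02    6    3    6    3
  1.1566989081045805e-16    6    4    2    2
 -1.0155429903702219e-16    6    4    3    2
  2.6553256747844953e-03    6    4    4    1
 -1.0766300154133462e-02    6    4    4    2
 -3.1320708020101534e-03    6    4    4    3
  1.5745991224938673e-02    6    4    6    4
  2.6553256747844966e-03    6    5    5    1
 -1.0766300154133468e-02    6    5    5    2
 -3.1320708020101578e-03    6    5    5    3
  1.5745991224938676e-02    6    5    6    5
  3.5525847484968665e-01    6    6    1    1
  2.1692255566187770e-03    6    6    2    1
  2.9186923959543948e-01    6    6    2    2
  6.4069175976503596e-03    6    6    3    1
 -1.9399878674860989e-02    6    6    3    2
  2.6034550656756078e-01    6    6    3    3
  2.5574935975548541e-01    6    6    4    4
  2.5574935975548552e-01    6    6    5    5
  3.9737477593762352e-03    6    6    6    1
 -5.0639065066759434e-03    6    6    6    2
 -1.8447271190100784e-02    6    6    6    3
  3.0064319428017416e-01    6    6    6    6
 -4.5489524188947863e+00    1    1    0    0
 -1.1108031070377868e-01    2    1    0    0
 -1.0315937226987146e+00    2    2    0    0
 -1.5026608629079702e-01    3    1    0    0
 -6.3597372857454149e-02    3    2    0    0
 -1.0178138619758832e+00    3    3    0    0
  1.2975471353329064e-16    4    2    0    0
 -1.0206695571725830e+00    4    4    0    0
 -1.2191828942669071e-16    5    4    0    0
 -1.0206695571725835e+00    5    5    0    0
  2.1392948453112265e-02    6    1    0    0
  8.2604659365649619e-02    6    2    0    0
 -1.0586827235204628e-02    6    3    0    0
 -1.0140120686349975e-16    6    5    0    0
 -1.0069207523453927e+00    6    6    0    0
  4.5358046648828571e-01    0    0    0    0
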