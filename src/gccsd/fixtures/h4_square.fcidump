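&FCI NORB=4,NELEC=4,MS2=0,
 ORBSYM=1,1,1,1,
 ISYM=1,
/
  5.3337117226995001e-01    1    1    1    1
  1.3688824847162606e-01    2    1    2    1
  5.1763467518939144e-01    2    2    1    1
 -1.1883898527365840e-16    2    2    2    1
  5.2695331959585379e-01    2    2    2    2
 -1.1974890516924424e-16    3    1    1    1
  3.5291250375019394e-13    3    1    2    1
  4.0668088033494992e-16    3    1    2    2
  1.3688824847162609e-01    3    1    3    1
  2.0414934530798173e-13    3    2    1    1
  2.6147622435998122e-16    3    2    2    1
 -3.4711393279900427e-12    3    2    2    2
 -2.9404184231111969e-16    3    2    3    1
  7.7994611395000787e-02    3    2    3    2
  5.1763467518939155e-01    3    3    1    1
 -3.8140608564304730e-16    3    3    2    1
  5.0477032943435163e-01    3    3    2    2
  3.2118252638340591e-16    3    3    3    1
  3.4713298141948484e-12    3    3    3    2
  5.2695331959585412e-01    3    3    3    3
  1.8909706128858099e-13    4    1    1    1
 -1.9361450284401594e-16    4    1    2    1
 -4.0198567685108052e-12    4    1    2    2
  7.7770812243415505e-02    4    1    3    2
  4.0504006719571864e-12    4    1    3    3
  7.7596197833188690e-02    4    1    4    1
 -6.9626012506352846e-12    4    2    2    1
  4.0365306246140730e-16    4    2    2    2
  1.3446579353513374e-01    4    2    3    1
  4.0203291324024184e-16    4    2    3    3
  3.2117583033710747e-16    4    2    4    1
  1.4765793662636106e-01    4    2    4    2
  1.3446579353513374e-01    4    3    2    1
 -1.3591082634163980e-16    4    3    2    2
  6.9908286437449128e-12    4    3    3    1
  3.3768154572967949e-16    4    3    3    2
 -5.9653324450428381e-16    4    3    3    3
 -1.7853154285718247e-16    4    3    4    1
 -3.5281360933324813e-13    4    3    4    2
  1.4765793662636115e-01    4    3    4    3
  5.2239897465255114e-01    4    4    1    1
  4.0142456780278487e-16    4    4    2    1
  5.2937687480942663e-01    4    4    2    2
 -2.0372120476777714e-13    4    4    3    2
  5.2937687480942663e-01    4    4    3    3
 -1.6277145819935659e-13    4    4    4    1
  2.8537024347494772e-16    4    4    4    2
  6.6331119608498046e-16    4    4    4    3
  5.5348972901212079e-01    4    4    4    4
 -2.1254662276593064e+00    1    1    0    0
  6.3355381262797011e-16    2    1    0    0
 -1.6161538633394648e+00    2    2    0    0
 -6.5346453490878938e-16    3    1    0    0
 -2.6233500508464167e-16    3    2    0    0
 -1.6161538633394652e+00    3    3    0    0
  1.4184452021091174e-12    4    1    0    0
 -3.7400281271370252e-16    4    2    0    0
 -8.0361403861897762e-16    4    3    0    0
 -1.0448229147922974e+00    4    4    0    0
  2.8650784321697902e+00    0    0    0    0
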