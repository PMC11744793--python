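&FCI NORB=4,NELEC=4,MS2=0,
 ORBSYM=1,1,1,1,
 ISYM=1,
/
  5.3704582852163385e-01    1    1    1    1
 -2.4900623081013389e-16    2    1    1    1
  1.4043471262750210e-01    2    1    2    1
  5.0924785900838931e-01    2    2    1    1
 -1.5872847085956683e-16    2    2    2    1
  5.3281607431414102e-01    2    2    2    2
 -8.0225438225363221e-03    3    1    2    1
 -1.6460773370060724e-16    3    1    2    2
  1.3026155255993940e-01    3    1    3    1
 -1.9169714310164121e-02    3    2    1    1
 -2.0158626088666952e-16    3    2    2    1
  1.8001993091993778e-02    3    2    2    2
 -2.1160145134057867e-16    3    2    3    1
  6.2134744738887193e-02    3    2    3    2
  5.2758861952029368e-01    3    3    1    1
 -4.2404329895512605e-16    3    3    2    1
  4.8638879980269506e-01    3    3    2    2
 -4.3964532814514116e-02    3    3    3    2
  5.5639956181010264e-01    3    3    3    3
  3.0826072830624603e-02    4    1    1    1
 -2.2309802663252078e-02    4    1    2    2
 -6.7972953616758744e-02    4    1    3    2
  6.0309503419299505e-02    4    1    3    3
  8.0460248103931251e-02    4    1    4    1
  2.2648007436568624e-16    4    2    1    1
 -7.7608571991671593e-02    4    2    2    1
  1.5596726957372996e-16    4    2    2    2
 -1.0431343340501606e-01    4    2    3    1
  4.3946344606275856e-16    4    2    3    3
  1.9892452764510525e-16    4    2    4    1
  1.5110214189084376e-01    4    2    4    2
  1.5322124230152706e-16    4    3    1    1
 -1.1965019444834506e-01    4    3    2    1
  1.0818308013451962e-16    4    3    2    2
  6.0881417889192116e-02    4    3    3    1
  2.6969971967188783e-16    4    3    3    2
  2.3304461166250823e-16    4    3    3    3
 -1.0178534119712032e-16    4    3    4    1
  2.5896779695017139e-02    4    3    4    2
  1.3952265450907905e-01    4    3    4    3
  5.2107035424034587e-01    4    4    1    1
  1.7175078911025671e-16    4    4    2    1
  5.2964986218227028e-01    4    4    2    2
 -2.3873713428116217e-16    4    4    3    1
  4.2278256148064039e-03    4    4    3    2
  5.2332721324643050e-01    4    4    3    3
 -6.9550177789925592e-04    4    4    4    1
 -2.4321743344988206e-16    4    4    4    3
  5.5164551993291477e-01    4    4    4    4
 -2.1297846288739670e+00    1    1    0    0
  5.3272998705268301e-16    2    1    0    0
 -1.6635060303382123e+00    2    2    0    0
  3.3329288584607010e-16    3    1    0    0
  1.2314891685677171e-02    3    2    0    0
 -1.5307089715793507e+00    3    3    0    0
 -6.3815039493389958e-02    4    1    0    0
 -4.2062934629698314e-16    4    2    0    0
  3.6404787186745904e-16    4    3    0    0
 -1.0887921709155777e+00    4    4    0    0
  2.8666771126204309e+00    0    0    0    0
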