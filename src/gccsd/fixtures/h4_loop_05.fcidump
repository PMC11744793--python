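&FCI NORB=4,NELEC=4,MS2=0,
 ORBSYM=1,1,1,1,
 ISYM=1,
/
  5.4686622972840249e-01    1    1    1    1
  1.2341776729992604e-01    2    1    2    1
  4.8615551264724638e-01    2    2    1    1
  3.5640299268560910e-16    2    2    2    1
  5.4523414538490744e-01    2    2    2    2
 -7.4043943386048706e-03    3    1    2    1
  1.3988176982012587e-01    3    1    3    1
 -1.6164298497874721e-02    3    2    1    1
  1.7963305370047200e-02    3    2    2    2
  2.2162954923544798e-02    3    2    3    2
  5.5507026461357190e-01    3    3    1    1
  4.4151234223616992e-01    3    3    2    2
 -3.8156190802451327e-02    3    3    3    2
  6.2951046552719581e-01    3    3    3    3
  5.2331375920545500e-02    4    1    1    1
 -4.4933889484479385e-02    4    1    2    2
 -3.3050978794657009e-02    4    1    3    2
  1.0543851141301223e-01    4    1    3    3
  8.3721909429472080e-02    4    1    4    1
 -1.2902809730198708e-01    4    2    2    1
 -5.8819981258918182e-16    4    2    2    2
 -4.6851161183986766e-02    4    2    3    1
 -1.4917632111541213e-16    4    2    3    3
 -1.2403298944796221e-16    4    2    4    1
  1.8020418423791157e-01    4    2    4    2
 -5.3187769854120499e-02    4    3    2    1
 -1.1559511559693754e-16    4    3    2    2
  1.0253329086154472e-01    4    3    3    1
  1.2694861532742712e-16    4    3    3    2
 -2.0542505213278475e-16    4    3    3    3
  2.0625873955231491e-02    4    3    4    2
  1.0388424022081595e-01    4    3    4    3
  5.1762659399561495e-01    4    4    1    1
  5.2882576330060682e-01    4    4    2    2
  3.3219600887876189e-03    4    4    3    2
  5.1287631744209727e-01    4    4    3    3
  7.0620556133199608e-04    4    4    4    1
 -1.3729572429670917e-16    4    4    4    2
  5.4861529870673720e-01    4    4    4    4
 -2.1397725842055237e+00    1    1    0    0
 -3.0894541573113976e-16    2    1    0    0
 -1.6186894158584908e+00    2    2    0    0
  1.1500719125951266e-16    3    1    0    0
  6.9608972796528093e-03    3    2    0    0
 -1.5179250936551547e+00    3    3    0    0
 -9.1491694249378877e-02    4    1    0    0
  2.3496010487102273e-16    4    2    0    0
 -1.1594189576034721e+00    4    4    0    0
  2.8521633190509652e+00    0    0    0    0
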