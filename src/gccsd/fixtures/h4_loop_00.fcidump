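&FCI NORB=4,NELEC=4,MS2=0,
 ORBSYM=1,1,1,1,
 ISYM=1,
/
  5.3871377655613473e-01    1    1    1    1
  1.3909453835018998e-01    2    1    2    1
  5.0592767385364923e-01    2    2    1    1
  5.3260721168046288e-01    2    2    2    2
  9.5630008499789226e-03    3    1    2    1
  1.3015349682475402e-01    3    1    3    1
  2.2124881031741372e-02    3    2    1    1
 -1.8739521055421714e-02    3    2    2    2
  1.1957936219978412e-16    3    2    3    1
  5.8390742504125979e-02    3    2    3    2
  5.3161981701389138e-01    3    3    1    1
  1.6918726071979943e-16    3    3    2    1
  4.8154508653534189e-01    3    3    2    2
  4.8490357535813031e-02    3    3    3    2
  5.6560912447508682e-01    3    3    3    3
  3.6667221926976357e-02    4    1    1    1
 -2.4053590873217953e-02    4    1    2    2
  6.5489882647079847e-02    4    1    3    2
  6.8838752415597129e-02    4    1    3    3
  8.1582052834937982e-02    4    1    4    1
 -8.6465510333787923e-02    4    2    2    1
  9.7374195216641951e-02    4    2    3    1
 -1.2648783418132023e-16    4    2    4    1
  1.5414956143601161e-01    4    2    4    2
  1.1394940161622499e-01    4    3    2    1
  6.6678627945573707e-02    4    3    3    1
  1.4062879615033659e-16    4    3    3    3
 -1.1910333497347967e-16    4    3    4    1
 -2.9632126575409576e-02    4    3    4    2
  1.3470040252450563e-01    4    3    4    3
  5.2048723411656994e-01    4    4    1    1
  5.2908553343873599e-01    4    4    2    2
 -1.6158853154755971e-16    4    4    3    1
 -4.4651616468647471e-03    4    4    3    2
  5.2148944366333905e-01    4    4    3    3
 -1.2693297379385820e-04    4    4    4    1
  2.6868512333079599e-16    4    4    4    2
  5.5089387470742457e-01    4    4    4    4
 -2.1315447624609072e+00    1    1    0    0
 -1.6623267200297767e+00    2    2    0    0
 -1.5947240153407313e-02    3    2    0    0
 -1.5165545507965044e+00    3    3    0    0
 -7.5025550513612926e-02    4    1    0    0
 -3.2175096858878994e-16    4    2    0    0
  3.3425846624398238e-16    4    3    0    0
 -1.1065460271491034e+00    4    4    0    0
  2.8652707964523492e+00    0    0    0    0
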