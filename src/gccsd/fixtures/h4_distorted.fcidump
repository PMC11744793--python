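&FCI NORB=4,NELEC=4,MS2=0,
 ORBSYM=1,1,1,1,
 ISYM=1,
/
  5.8982199373550881e-01    1    1    1    1
 -1.3561178396204773e-16    2    1    1    1
  9.2866910416344567e-02    2    1    2    1
  4.4869223557784427e-01    2    2    1    1
  2.9093091771118779e-16    2    2    2    1
  5.2662073888804972e-01    2    2    2    2
 -9.5565070194460616e-02    3    1    1    1
 -1.3406033871515009e-15    3    1    2    1
  4.0983886601415748e-02    3    1    2    2
  8.8317061357005802e-02    3    1    3    1
 -1.9321483017846573e-15    3    2    1    1
  1.3077776999887414e-01    3    2    2    1
  9.4026597955850110e-16    3    2    2    2
 -5.2718609514874841e-16    3    2    3    1
  2.1689981619737039e-01    3    2    3    2
  5.0082345144458285e-01    3    3    1    1
  1.1097674399355965e-16    3    3    2    1
  5.1527498345207534e-01    3    3    2    2
 -4.6265044288194713e-03    3    3    3    1
  5.3395585939447332e-01    3    3    3    3
 -6.3192590157016486e-16    4    1    1    1
  3.8315083519940000e-16    4    1    2    1
  2.4530440876758717e-16    4    1    2    2
 -4.3058374031387272e-16    4    1    3    1
 -1.6369297455396674e-15    4    1    3    2
  1.2050532013880348e-15    4    1    3    3
  1.4547094251193182e-01    4    1    4    1
  1.1559860213111752e-15    4    2    1    1
  8.9317626786012302e-16    4    2    2    1
 -7.9653316852807792e-16    4    2    2    2
 -1.2870544390017392e-15    4    2    3    1
  1.4952115210936937e-15    4    2    3    2
 -3.2789870711273023e-16    4    2    3    3
  7.2652829835162771e-16    4    2    4    1
  7.1229499420149625e-03    4    2    4    2
 -7.3832194435907258e-16    4    3    1    1
 -1.5785813185473569e-15    4    3    2    1
  8.3607316054608977e-16    4    3    2    2
  1.5869502577093296e-15    4    3    3    1
 -1.1203761334209978e-15    4    3    3    2
 -4.9366531708413368e-16    4    3    3    3
 -8.8850843832258788e-02    4    3    4    1
 -4.3761724720209151e-16    4    3    4    2
  6.0683107816665180e-02    4    3    4    3
  6.1241372736382904e-01    4    4    1    1
  1.0370833168419002e-15    4    4    2    1
  4.0952912954040949e-01    4    4    2    2
 -1.3812196813862826e-01    4    4    3    1
 -6.6986146106004687e-16    4    4    3    2
  4.8763666749274243e-01    4    4    3    3
 -2.2834974054421686e-15    4    4    4    1
  2.2224427188630745e-15    4    4    4    2
 -3.7541164922349879e-16    4    4    4    3
  7.0092657992420482e-01    4    4    4    4
 -2.1903737919795794e+00    1    1    0    0
 -3.3412870999858435e-15    2    1    0    0
 -1.5580410813495054e+00    2    2    0    0
  1.4437506698521119e-01    3    1    0    0
  1.0758168674884848e-15    3    2    0    0
 -1.3030047818748300e+00    3    3    0    0
  1.3625440722285734e-15    4    1    0    0
  1.8867809286629601e-15    4    2    0    0
 -1.3314477028616654e+00    4    4    0    0
  2.8852226250162247e+00    0    0    0    0
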