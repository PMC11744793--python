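&FCI NORB=6,NELEC=4,MS2=0,
 ORBSYM=1,1,1,1,1,1,
 ISYM=1,
/
  1.6599423036223850e+00    1    1    1    1
  1.0296391927828959e-01    2    1    1    1
  1.0497571418772720e-02    2    1    2    1
  2.7032272306379795e-01    2    2    1    1
 -1.1987216872697980e-04    2    2    2    1
  4.0097952419166283e-01    2    2    2    2
 -1.4286472217828722e-01    3    1    1    1
 -1.2152137249361069e-02    3    1    2    1
 -7.3829358085924059e-03    3    1    2    2
  2.1292529258697596e-02    3    1    3    1
 -6.5681334062675914e-02    3    2    1    1
 -2.7220172707247067e-03    3    2    2    1
  8.9533375414467264e-02    3    2    2    2
  1.1669427918733536e-03    3    2    3    1
  6.1030303091046671e-02    3    2    3    2
  3.6719512230096335e-01    3    3    1    1
  6.9978870779577283e-03    3    3    2    1
  2.2737005333547156e-01    3    3    2    2
 -9.4976627330029581e-04    3    3    3    1
 -1.4653704857708196e-02    3    3    3    2
  2.9601121072632686e-01    3    3    3    3
  9.7815069362795718e-03    4    1    4    1
 -7.7590074722884471e-03    4    2    4    1
  2.1834587780227340e-02    4    2    4    2
  1.0505568384845327e-02    4    3    4    1
 -2.4242218681744351e-02    4    3    4    2
  4.0502884265892693e-02    4    3    4    3
  3.9635247700811344e-01    4    4    1    1
  3.5771482336189094e-03    4    4    2    1
  2.1559423796671379e-01    4    4    2    2
 -5.0305349146535054e-03    4    4    3    1
 -3.6159747693349155e-02    4    4    3    2
  2.6639744009325445e-01    4    4    3    3
  3.1294551115940933e-01    4    4    4    4
  9.7815069362795718e-03    5    1    5    1
 -7.7590074722884471e-03    5    2    5    1
  2.1834587780227340e-02    5    2    5    2
  1.0505568384845327e-02    5    3    5    1
 -2.4242218681744351e-02    5    3    5    2
  4.0502884265892693e-02    5    3    5    3
  1.6869139513691046e-02    5    4    5    4
  3.9635247700811338e-01    5    5    1    1
  3.5771482336189103e-03    5    5    2    1
  2.1559423796671379e-01    5    5    2    2
 -5.0305349146534933e-03    5    5    3    1
 -3.6159747693349113e-02    5    5    3    2
  2.6639744009325445e-01    5    5    3    3
  2.7920723213202697e-01    5    5    4    4
  3.1294551115940933e-01    5    5    5    5
 -5.0215365464436626e-02    6    1    1    1
 -7.1075408064077607e-03    6    1    2    1
  5.9020861567845775e-03    6    1    2    2
  2.5627372539483522e-03    6    1    3    1
  3.2499920921796933e-03    6    1    3    2
 -9.9551583697883896e-03    6    1    3    3
 -1.3278532629669615e-03    6    1    4    4
 -1.3278532629669613e-03    6    1    5    5
  9.2603997736498116e-03    6    1    6    1
 -9.1285404502354742e-02    6    2    1    1
 -2.5352248051989742e-04    6    2    2    1
  9.1113920247879385e-02    6    2    2    2
  5.1777927460562295e-03    6    2    3    1
  7.3399514960768450e-02    6    2    3    2
  3.3996742881104284e-03    6    2    3    3
 -4.9405839728591201e-02    6    2    4    4
 -4.9405839728591201e-02    6    2    5    5
 -3.6187513546148691e-03    6    2    6    1
  1.2159366013957226e-01    6    2    6    2
 -4.3310648540819695e-02    6    3    1    1
 -2.2781545855647622e-03    6    3    2    1
  8.1452942038938839e-02    6    3    2    2
 -3.6686329772350999e-03    6    3    3    1
  4.9984959238379020e-02    6    3    3    2
 -3.1224844663139587e-02    6    3    3    3
 -2.1882989555687848e-02    6    3    4    4
 -2.1882989555687845e-02    6    3    5    5
  6.3705119860532353e-03    6    3    6    1
  5.1853671505856548e-02    6    3    6    2
  5.8249365556699226e-02    6    3    6    3
  4.0950310147044458e-03    6    4    4    1
 -1.4555286325671110e-02    6    4    4    2
  6.8408512546653958e-03    6    4    4    3
  1.6585287890256289e-02    6    4    6    4
  4.0950310147044458e-03    6    5    5    1
 -1.4555286325671109e-02    6    5    5    2
  6.8408512546653923e-03    6    5    5    3
  1.6585287890256289e-02    6    5    6    5
  3.4233440128984127e-01    6    6    1    1
  9.2099356612846794e-04    6    6    2    1
  3.4816922189627647e-01    6    6    2    2
 -8.1617175242772698e-03    6    6    3    1
  4.6994181250047652e-02    6    6    3    2
  2.5210573435085815e-01    6    6    3    3
  2.4963150609268051e-01    6    6    4    4
  2.4963150609268051e-01    6    6    5    5
  5.0490141939646179e-03    6    6    6    1
  3.5558513570688025e-02    6    6    6    2
  4.1495038928066892e-02    6    6    6    3
  3.3772526101278427e-01    6    6    6    6
 -4.5739980498212613e+00    1    1    0    0
 -1.0284404710955773e-01    2    1    0    0
 -1.1066142943493136e+00    2    2    0    0
  1.5490857652474910e-01    3    1    0    0
  2.9677155461472499e-02    3    2    0    0
 -1.0495781480000592e+00    3    3    0    0
 -1.0411793562344827e+00    4    4    0    0
 -1.0411793562344827e+00    5    5    0    0
  3.8157670670342120e-02    6    1    0    0
  8.4349347950408993e-02    6    2    0    0
 -3.2233478150504971e-04    6    3    0    0
 -1.0351138652236647e-16    6    4    0    0
 -1.0158151836231528e+00    6    6    0    0
  5.2917721090300007e-01    0    0    0    0
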