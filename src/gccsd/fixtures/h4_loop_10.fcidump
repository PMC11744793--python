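&FCI NORB=4,NELEC=4,MS2=0,
 ORBSYM=1,1,1,1,
 ISYM=1,
/
  5.3606668066684215e-01    1    1    1    1
  3.4803932687155672e-16    2    1    1    1
  1.3957470000124214e-01    2    1    2    1
  5.1076554155181975e-01    2    2    1    1
  1.2464239988573256e-16    2    2    2    1
  5.3374039304263321e-01    2    2    2    2
  1.0435827399535054e-16    3    1    1    1
 -6.4735743725170720e-03    3    1    2    1
  1.3194742638426590e-01    3    1    3    1
 -1.6153067765885338e-02    3    2    1    1
  1.8933769336081343e-02    3    2    2    2
  6.2885624331194032e-02    3    2    3    2
  5.2565413039462761e-01    3    3    1    1
  1.7880236089379877e-16    3    3    2    1
  4.8786071360436656e-01    3    3    2    2
 -4.0684919670917342e-02    3    3    3    2
  5.5284083388261773e-01    3    3    3    3
  2.6021615569353219e-02    4    1    1    1
 -2.3364229982876399e-02    4    1    2    2
 -6.8451128336444941e-02    4    1    3    2
  5.5483468116900317e-02    4    1    3    3
  7.9583054387536004e-02    4    1    4    1
 -7.3670774643541312e-02    4    2    2    1
  1.6417221680594835e-16    4    2    2    2
 -1.0853245778197045e-01    4    2    3    1
  1.5774169867247298e-16    4    2    3    3
  1.5097902486510212e-01    4    2    4    2
  1.5121522389946160e-16    4    3    1    1
 -1.2028784291634362e-01    4    3    2    1
  1.5031103634817044e-16    4    3    2    2
  5.9627387170823665e-02    4    3    3    1
  3.4283195372440165e-16    4    3    3    3
  1.4676344858530397e-16    4    3    4    1
  2.1792244873538300e-02    4    3    4    2
  1.4088471612107531e-01    4    3    4    3
  5.2142957537174983e-01    4    4    1    1
  5.3005534815043309e-01    4    4    2    2
  1.2029511372909553e-16    4    4    3    1
  3.9799078785354488e-03    4    4    3    2
  5.2453323420517051e-01    4    4    3    3
 -1.1100200092026273e-03    4    4    4    1
  2.3964201225728073e-16    4    4    4    3
  5.5220051113560842e-01    4    4    4    4
 -2.1285852065128923e+00    1    1    0    0
 -6.6401769173024118e-16    2    1    0    0
 -1.6546267622558379e+00    2    2    0    0
 -3.1971345969125088e-16    3    1    0    0
  6.8987918217061081e-03    3    2    0    0
 -1.5514968857294507e+00    3    3    0    0
 -5.2963930246920095e-02    4    1    0    0
 -3.8462037021190442e-16    4    2    0    0
 -7.6806035345999662e-16    4    3    0    0
 -1.0768055604182667e+00    4    4    0    0
  2.8652202093402011e+00    0    0    0    0
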