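&FCI NORB=6,NELEC=4,MS2=0,
 ORBSYM=1,1,1,1,1,1,
 ISYM=1,
/
  1.6595785798293661e+00    1    1    1    1
  9.7960281974632496e-02    2    1    1    1
  9.8358495468784321e-03    2    1    2    1
  2.9152079455846186e-01    2    2    1    1
 -1.5152141410740556e-03    2    2    2    1
  4.2887795027474851e-01    2    2    2    2
 -1.4276352737390707e-01    3    1    1    1
 -1.0989689780681704e-02    3    1    2    1
 -9.3445074514517581e-03    3    1    2    2
  2.1951787578117929e-02    3    1    3    1
 -4.1180648637139709e-02    3    2    1    1
 -2.5068477341231598e-03    3    2    2    1
  6.9766051701261336e-02    3    2    2    2
  5.4797016249271487e-04    3    2    3    1
  3.2330343925062198e-02    3    2    3    2
  3.8465494090148528e-01    3    3    1    1
  8.0367983428741782e-03    3    3    2    1
  2.1301315784989000e-01    3    3    2    2
  2.5215640059863848e-04    3    3    3    1
 -1.8043627172373507e-02    3    3    3    2
  3.1775151456358769e-01    3    3    3    3
  9.7953389166572733e-03    4    1    4    1
 -7.3565706222143744e-03    4    2    4    1
  2.0849244657530807e-02    4    2    4    2
  1.0457370926606275e-02    4    3    4    1
 -2.1641090187326652e-02    4    3    4    2
  4.1317267388262795e-02    4    3    4    3
  3.9634675229875360e-01    4    4    1    1
  3.4752008249406786e-03    4    4    2    1
  2.3094764897307621e-01    4    4    2    2
 -5.0739291063158307e-03    4    4    3    1
 -2.1352708570206859e-02    4    4    3    2
  2.7617025624050273e-01    4    4    3    3
  3.1294551115940927e-01    4    4    4    4
  9.7953389166572785e-03    5    1    5    1
 -7.3565706222143779e-03    5    2    5    1
  2.0849244657530817e-02    5    2    5    2
  1.0457370926606278e-02    5    3    5    1
 -2.1641090187326659e-02    5    3    5    2
  4.1317267388262822e-02    5    3    5    3
  1.6869139513691084e-02    5    4    5    4
  3.9634675229875382e-01    5    5    1    1
  3.4752008249406951e-03    5    5    2    1
  2.3094764897307632e-01    5    5    2    2
 -5.0739291063158463e-03    5    5    3    1
 -2.1352708570206849e-02    5    5    3    2
  2.7617025624050284e-01    5    5    3    3
  2.7920723213202719e-01    5    5    4    4
  3.1294551115940961e-01    5    5    5    5
  6.3963359542803716e-02    6    1    1    1
  8.4369266952294998e-03    6    1    2    1
 -6.7458458453690312e-03    6    1    2    2
 -4.0588705274842785e-03    6    1    3    1
 -2.9962522400217438e-03    6    1    3    2
  1.1330478548002237e-02    6    1    3    3
  1.6204596592700453e-03    6    1    4    4
  1.6204596592700462e-03    6    1    5    5
  1.0236458887480235e-02    6    1    6    1
  8.9294717401884549e-02    6    2    1    1
  7.5227707824277389e-04    6    2    2    1
 -1.0169956826111405e-01    6    2    2    2
 -4.9155447002670388e-03    6    2    3    1
 -5.5249599903184544e-02    6    2    3    2
  1.4522801819235893e-02    6    2    3    3
  4.4805878391907937e-02    6    2    4    4
  4.4805878391907958e-02    6    2    5    5
 -1.9555721546901219e-03    6    2    6    1
  1.3211355173150913e-01    6    2    6    2
  3.0580401668685434e-02    6    3    1    1
  2.1137789716126928e-03    6    3    2    1
 -6.6608181642523426e-02    6    3    2    2
  3.8512357306951179e-03    6    3    3    1
 -2.7339516892203489e-02    6    3    3    2
  3.7193291288613269e-02    6    3    3    3
  1.3231522928976286e-02    6    3    4    4
  1.3231522928976291e-02    6    3    5    5
  4.9620374716021895e-03    6    3    6    1
  4.6085719940776884e-02    6    3    6    2
  3.9521824097251246e-02    6    3    6    3
 -5.2460415568892681e-03    6    4    4    1
  1.7101161978190216e-02    6    4    4    2
 -1.0144848603830981e-02    6    4    4    3
  1.8136544683531847e-02    6    4    6    4
 -5.2460415568892707e-03    6    5    5    1
  1.7101161978190227e-02    6    5    5    2
 -1.0144848603830990e-02    6    5    5    3
  1.8136544683531857e-02    6    5    6    5
  3.4434690729461986e-01    6    6    1    1
 -1.0256775873289447e-04    6    6    2    1
  3.9533132117325920e-01    6    6    2    2
 -9.7857505113604793e-03    6    6    3    1
  5.1635460979659216e-02    6    6    3    2
  2.4095876525460827e-01    6    6    3    3
  2.5245904595943153e-01    6    6    4    4
  2.5245904595943164e-01    6    6    5    5
 -5.3384629653782985e-03    6    6    6    1
 -7.4326650176497588e-02    6    6    6    2
 -4.7445841928277784e-02    6    6    6    3
  3.8622464092923908e-01    6    6    6    6
 -4.6090542598552293e+00    1    1    0    0
 -9.6445067833559800e-02    2    1    0    0
 -1.2113229059145989e+00    2    2    0    0
  1.5894569454268656e-01    3    1    0    0
  1.6055557923456195e-03    3    2    0    0
 -1.0757194263637166e+00    3    3    0    0
  1.0241321868760376e-16    4    2    0    0
 -1.0675203499530850e+00    4    4    0    0
 -1.0675203499530856e+00    5    5    0    0
 -4.9719390773824861e-02    6    1    0    0
 -6.8452939847433988e-02    6    2    0    0
  1.2747089517003653e-02    6    3    0    0
 -1.0222073052989518e+00    6    6    0    0
  6.3501265308360000e-01    0    0    0    0
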