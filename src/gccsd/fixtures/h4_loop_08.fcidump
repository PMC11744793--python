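&FCI NORB=4,NELEC=4,MS2=0,
 ORBSYM=1,1,1,1,
 ISYM=1,
/
  5.3871377655616037e-01    1    1    1    1
  1.3909453834971963e-01    2    1    2    1
  5.0592767385262138e-01    2    2    1    1
  5.3260721168218916e-01    2    2    2    2
 -9.5630008502211872e-03    3    1    2    1
  1.3015349682521754e-01    3    1    3    1
 -2.2124881031171932e-02    3    2    1    1
  1.4383028702728566e-16    3    2    2    1
  1.8739521056935774e-02    3    2    2    2
  1.6324039793970872e-16    3    2    3    1
  5.8390742501028069e-02    3    2    3    2
  5.3161981701493455e-01    3    3    1    1
  2.1153792741582379e-16    3    3    2    1
  4.8154508653224337e-01    3    3    2    2
 -4.1488759322791140e-16    3    3    3    1
 -4.8490357536566692e-02    3    3    3    2
  5.6560912447955525e-01    3    3    3    3
  3.6667221927000962e-02    4    1    1    1
 -2.4053590876231962e-02    4    1    2    2
 -6.5489882644935021e-02    4    1    3    2
  6.8838752418612925e-02    4    1    3    3
  8.1582052834925270e-02    4    1    4    1
 -8.6465510338654128e-02    4    2    2    1
  1.3214818974717084e-16    4    2    2    2
 -9.7374195213106737e-02    4    2    3    1
 -1.0266016042906435e-16    4    2    3    2
 -2.2951772328708537e-16    4    2    4    1
  1.5414956143740666e-01    4    2    4    2
 -1.1394940161268974e-01    4    3    2    1
  6.6678627950443270e-02    4    3    3    1
 -2.9695477057888941e-16    4    3    3    3
  1.2886860695178108e-16    4    3    4    1
  2.9632126574997784e-02    4    3    4    2
  1.3470040252311694e-01    4    3    4    3
  5.2048723411655706e-01    4    4    1    1
 -3.8687158990544291e-16    4    4    2    1
  5.2908553343894882e-01    4    4    2    2
  4.4651616467122667e-03    4    4    3    2
  5.2148944366310868e-01    4    4    3    3
 -1.2693297381693736e-04    4    4    4    1
  1.6711519252393813e-16    4    4    4    2
  3.1343277118342580e-16    4    4    4    3
  5.5089387470742257e-01    4    4    4    4
 -2.1315447624609338e+00    1    1    0    0
  2.4638854721840240e-16    2    1    0    0
 -1.6623267200290410e+00    2    2    0    0
  1.3347254783772364e-16    3    1    0    0
  1.5947240156766313e-02    3    2    0    0
 -1.5165545507972380e+00    3    3    0    0
 -7.5025550513435998e-02    4    1    0    0
 -1.0280172775296664e-16    4    2    0    0
  1.1226114784819385e-16    4    3    0    0
 -1.1065460271490759e+00    4    4    0    0
  2.8652707964523487e+00    0    0    0    0
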