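&FCI NORB=6,NELEC=4,MS2=0,
 ORBSYM=1,1,1,1,1,1,
 ISYM=1,
/
  1.6581667751115525e+00    1    1    1    1
  1.1685592256078434e-01    2    1    1    1
  1.4697825787431871e-02    2    1    2    1
  3.7946590389434059e-01    2    2    1    1
 -7.2543878524616856e-03    2    2    2    1
  4.9428349051091602e-01    2    2    2    2
 -1.3763566501591037e-01    3    1    1    1
 -1.1543566149706050e-02    3    1    2    1
 -1.7090257480863791e-02    3    1    2    2
  2.1512953760673331e-02    3    1    3    1
 -1.1429787658997510e-02    3    2    1    1
 -3.6595761857889974e-03    3    2    2    1
  4.6934492793586642e-02    3    2    2    2
 -2.3382292603071593e-04    3    2    3    1
  1.2138626084800935e-02    3    2    3    2
  3.9596306345246601e-01    3    3    1    1
  1.1673343544537047e-02    3    3    2    1
  2.2662426893598803e-01    3    3    2    2
  2.0007017341118608e-03    3    3    3    1
 -6.1626794412469174e-03    3    3    3    2
  3.3881567262287143e-01    3    3    3    3
  9.8192273157442552e-03    4    1    4    1
 -7.5765918400539558e-03    4    2    4    1
  2.3987043033349201e-02    4    2    4    2
  1.0243335293847546e-02    4    3    4    1
 -1.9210127747158426e-02    4    3    4    2
  4.1315277629299950e-02    4    3    4    3
  3.9630816432909494e-01    4    4    1    1
  4.5922500667888366e-03    4    4    2    1
  2.7514209705525361e-01    4    4    2    2
 -4.9398192989611976e-03    4    4    3    1
 -4.7291328356083859e-03    4    4    3    2
  2.8221728299090088e-01    4    4    3    3
  3.1294551115940922e-01    4    4    4    4
  9.8192273157442604e-03    5    1    5    1
 -7.5765918400539584e-03    5    2    5    1
  2.3987043033349212e-02    5    2    5    2
  1.0243335293847550e-02    5    3    5    1
 -1.9210127747158429e-02    5    3    5    2
  4.1315277629299964e-02    5    3    5    3
  1.6869139513691081e-02    5    4    5    4
  3.9630816432909505e-01    5    5    1    1
  4.5922500667888505e-03    5    5    2    1
  2.7514209705525372e-01    5    5    2    2
 -4.9398192989611985e-03    5    5    3    1
 -4.7291328356084041e-03    5    5    3    2
  2.8221728299090099e-01    5    5    3    3
  2.7920723213202719e-01    5    5    4    4
  3.1294551115940944e-01    5    5    5    5
 -4.3421123378467354e-02    6    1    1    1
 -8.1371593697870635e-03    6    1    2    1
  6.0030565506728030e-03    6    1    2    2
  1.2670329573075804e-03    6    1    3    1
  1.2390512618740872e-03    6    1    3    2
 -9.5984441736104015e-03    6    1    3    3
 -1.8737122077063642e-04    6    1    4    4
 -1.8737122077063645e-04    6    1    5    5
  7.2412417141280126e-03    6    1    6    1
 -2.8625074888886336e-02    6    2    1    1
 -5.7561802424106762e-03    6    2    2    1
  1.3223491548963498e-01    6    2    2    2
 -7.3725354781270091e-04    6    2    3    1
  3.3493444089519556e-02    6    2    3    2
 -9.4717488051516783e-03    6    2    3    3
 -1.0919531362905443e-02    6    2    4    4
 -1.0919531362905448e-02    6    2    5    5
 -4.2008754053619385e-04    6    2    6    1
  1.2295330946602923e-01    6    2    6    2
 -1.7403867713176598e-02    6    3    1    1
 -4.2655330492159076e-03    6    3    2    1
  5.0935654267483643e-02    6    3    2    2
 -4.5043511403662943e-03    6    3    3    1
  8.4445492689503455e-03    6    3    3    2
 -3.6048171164257362e-02    6    3    3    3
 -1.4075572781111721e-03    6    3    4    4
 -1.4075572781111726e-03    6    3    5    5
  4.1826837978428035e-03    6    3    6    1
  3.1057763490309233e-02    6    3    6    2
  2.6302978659623888e-02    6    3    6    3
  5.9928169752034915e-03    6    4    4    1
 -1.9518961828175616e-02    6    4    4    2
  1.3865567622364258e-02    6    4    4    3
  1.9473210204508026e-02    6    4    6    4
  5.9928169752034924e-03    6    5    5    1
 -1.9518961828175620e-02    6    5    5    2
  1.3865567622364261e-02    6    5    5    3
  1.9473210204508030e-02    6    5    6    5
  3.6167899467858122e-01    6    6    1    1
 -4.3217991790052840e-03    6    6    2    1
  4.5735818845159726e-01    6    6    2    2
 -1.1367636658917312e-02    6    6    3    1
  4.2160747197661635e-02    6    6    3    2
  2.4202242149879333e-01    6    6    3    3
  2.6929371108274391e-01    6    6    4    4
  2.6929371108274403e-01    6    6    5    5
  2.1227215970431698e-03    6    6    6    1
  1.4046708245118616e-01    6    6    6    2
  4.3557629185048213e-02    6    6    6    3
  4.5636654081935146e-01    6    6    6    6
 -4.7492364119327686e+00    1    1    0    0
 -1.0960153470839475e-01    2    1    0    0
 -1.5320787245503713e+00    2    2    0    0
  1.6815660379178912e-01    3    1    0    0
 -3.5618483625102351e-02    3    2    0    0
 -1.1325306564030877e+00    3    3    0    0
 -1.1453443386469278e+00    4    4    0    0
 -1.1453443386469280e+00    5    5    0    0
  2.5658830034775971e-02    6    1    0    0
 -8.3121925081349454e-02    6    2    0    0
 -3.2303096061614668e-02    6    3    0    0
 -9.3358249798869042e-01    6    6    0    0
  1.0583544218060001e+00    0    0    0    0
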