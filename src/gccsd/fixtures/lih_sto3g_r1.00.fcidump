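&FCI NORB=6,NELEC=4,MS2=0,
 ORBSYM=1,1,1,1,1,1,
 ISYM=1,
/
  1.6454044308370845e+00    1    1    1    1
 -1.6278429053302138e-01    2    1    1    1
  3.1693291258976269e-02    2    1    2    1
  4.6837494470040136e-01    2    2    1    1
  1.4857930403854596e-02    2    2    2    1
  5.2426312904988348e-01    2    2    2    2
  1.2588938684344209e-01    3    1    1    1
 -1.3658126088491854e-02    3    1    2    1
  2.5706308112459414e-02    3    1    2    2
  1.9459106097680274e-02    3    1    3    1
 -1.9498959155858726e-03    3    2    1    1
  6.5416261154250671e-03    3    2    2    1
  3.8811857131016633e-02    3    2    2    2
  6.2032197279940143e-04    3    2    3    1
  9.4659306948418707e-03    3    2    3    2
  3.9409244014379791e-01    3    3    1    1
 -1.6302313260332026e-02    3    3    2    1
  2.4664689844463075e-01    3    3    2    2
 -3.2578749904954053e-03    3    3    3    1
  1.3893951270643836e-03    3    3    3    2
  3.3900400935889119e-01    3    3    3    3
  9.8908246204368489e-03    4    1    4    1
  8.3115499304748913e-03    4    2    4    1
  2.7182115623006490e-02    4    2    4    2
 -1.0249559184741113e-02    4    3    4    1
 -1.9558158529180865e-02    4    3    4    2
  4.2362366266483327e-02    4    3    4    3
  3.9608902884487179e-01    4    4    1    1
 -6.0042074948731807e-03    4    4    2    1
  3.0049907803833587e-01    4    4    2    2
  4.3819419179127088e-03    4    4    3    1
 -8.1510620758458820e-04    4    4    3    2
  2.8275049370001337e-01    4    4    3    3
  3.1294551115940944e-01    4    4    4    4
  9.8908246204368507e-03    5    1    5    1
  8.3115499304748930e-03    5    2    5    1
  2.7182115623006497e-02    5    2    5    2
 -1.0249559184741115e-02    5    3    5    1
 -1.9558158529180868e-02    5    3    5    2
  4.2362366266483327e-02    5    3    5    3
  1.6869139513691064e-02    5    4    5    4
  3.9608902884487190e-01    5    5    1    1
 -6.0042074948731747e-03    5    5    2    1
  3.0049907803833598e-01    5    5    2    2
  4.3819419179127288e-03    5    5    3    1
 -8.1510620758458788e-04    5    5    3    2
  2.8275049370001337e-01    5    5    3    3
  2.7920723213202725e-01    5    5    4    4
  3.1294551115940955e-01    5    5    5    5
 -6.9054240511271431e-02    6    1    1    1
  1.0987447317828672e-02    6    1    2    1
  5.4238876899199793e-03    6    1    2    2
 -9.1852634992035873e-03    6    1    3    1
  4.1128615889305959e-03    6    1    3    2
 -3.2196465626984640e-04    6    1    3    3
 -3.2746097304819067e-03    6    1    4    4
 -3.2746097304819071e-03    6    1    5    5
  7.0977399789992884e-03    6    1    6    1
  8.8768310036122233e-02    6    2    1    1
  1.2547769299325530e-02    6    2    2    1
  1.5993535008355375e-01    6    2    2    2
  1.2961562644170617e-02    6    2    3    1
  2.8948402774070462e-02    6    2    3    2
  1.5385928094844147e-02    6    2    3    3
  2.2943366614424254e-02    6    2    4    4
  2.2943366614424261e-02    6    2    5    5
  8.4114630878430584e-03    6    2    6    1
  1.2241563147677113e-01    6    2    6    2
 -2.1068180411083742e-02    6    3    1    1
  1.0971053862814219e-02    6    3    2    1
  4.8578321614704982e-02    6    3    2    2
  5.1677824500142387e-03    6    3    3    1
  4.8367908649768858e-03    6    3    3    2
 -3.6333099164161595e-02    6    3    3    3
  4.0673163065673204e-04    6    3    4    4
  4.0673163065673215e-04    6    3    5    5
  1.5867970169548115e-03    6    3    6    1
  2.8987925495846535e-02    6    3    6    2
  2.6932138382538905e-02    6    3    6    3
 -3.6338758347959567e-03    6    4    4    1
 -1.6126606592798836e-02    6    4    4    2
  1.2199532098628016e-02    6    4    4    3
  1.5331945613200188e-02    6    4    6    4
 -3.6338758347959584e-03    6    5    5    1
 -1.6126606592798839e-02    6    5    5    2
  1.2199532098628021e-02    6    5    5    3
  1.5331945613200195e-02    6    5    6    5
  3.8377585199008252e-01    6    6    1    1
  1.4864160536851408e-02    6    6    2    1
  4.5939093066741588e-01    6    6    2    2
  1.6123099671020966e-02    6    6    3    1
  3.6131980646097024e-02    6    6    3    2
  2.4426136680592092e-01    6    6    3    3
  2.7247274215397821e-01    6    6    4    4
  2.7247274215397821e-01    6    6    5    5
  1.0076603250793873e-02    6    6    6    1
  1.5572011107207612e-01    6    6    6    2
  3.9863402442964095e-02    6    6    6    3
  4.3975875629103872e-01    6    6    6    6
 -4.9213604176571319e+00    1    1    0    0
  1.4792636013455046e-01    2    1    0    0
 -1.7459768446650656e+00    2    2    0    0
 -1.7076037695065216e-01    3    1    0    0
 -4.8570191383084070e-02    3    2    0    0
 -1.1757052150202185e+00    3    3    0    0
 -1.1981645481525518e+00    4    4    0    0
  1.0993840822325383e-16    5    2    0    0
 -1.1449084016215648e-16    5    4    0    0
 -1.1981645481525522e+00    5    5    0    0
  7.0754234432011343e-02    6    1    0    0
 -3.2648452283067614e-01    6    2    0    0
 -3.5257143127219309e-02    6    3    0    0
 -1.0477702322741827e-16    6    5    0    0
 -9.4382096233151713e-01    6    6    0    0
  1.5875316327089999e+00    0    0    0    0
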