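&FCI NORB=4,NELEC=4,MS2=0,
 ORBSYM=1,1,1,1,
 ISYM=1,
/
  5.3566729644167921e-01    1    1    1    1
  1.6953723554950200e-14    2    1    1    1
  1.3685773337452764e-01    2    1    2    1
  5.1033560105326736e-01    2    2    1    1
 -2.2937724191213359e-14    2    2    2    1
  5.3663151050545010e-01    2    2    2    2
 -1.4968379876954836e-14    3    1    1    1
  5.0781805986180092e-03    3    1    2    1
  7.2007599681643387e-15    3    1    2    2
  1.3499708243813899e-01    3    1    3    1
  1.3618477367938765e-02    3    2    1    1
  8.4995835926039755e-15    3    2    2    1
 -2.2317537015673836e-02    3    2    2    2
 -3.8457910410140739e-15    3    2    3    1
  5.9238263785768616e-02    3    2    3    2
  5.2592319015280076e-01    3    3    1    1
 -2.1041729088910102e-15    3    3    2    1
  4.8458792368397502e-01    3    3    2    2
  1.8809412878946302e-14    3    3    3    1
  4.0251946417027513e-02    3    3    3    2
  5.5657624331205258e-01    3    3    3    3
  2.2995278009431776e-02    4    1    1    1
 -2.2911390931011753e-14    4    1    2    1
 -2.8722917097964807e-02    4    1    2    2
  5.5963761313207886e-15    4    1    3    1
  6.6002002529594025e-02    4    1    3    2
  5.6865225739769341e-02    4    1    3    3
  7.9021008252979114e-02    4    1    4    1
 -2.6108013552677263e-14    4    2    1    1
 -7.8589600124457260e-02    4    2    2    1
  2.4430854993120919e-14    4    2    2    2
  1.0803603791104723e-01    4    2    3    1
 -1.7152175344451613e-14    4    2    3    2
  1.1265142725999307e-14    4    2    3    3
  9.8609271217808160e-15    4    2    4    1
  1.5378293100764609e-01    4    2    4    2
  8.7225415317218763e-15    4    3    1    1
  1.1440425638999462e-01    4    3    2    1
 -1.8252013934496378e-14    4    3    2    2
  6.6395784412092623e-02    4    3    3    1
  9.6845649855391600e-15    4    3    3    2
  1.1555548107190564e-14    4    3    3    3
 -1.1999039008548996e-14    4    3    4    1
 -1.8055123834667303e-02    4    3    4    2
  1.3875371869738320e-01    4    3    4    3
  5.2157657492260912e-01    4    4    1    1
  5.9130027242503849e-15    4    4    2    1
  5.3045200885652710e-01    4    4    2    2
 -8.6250401355083051e-15    4    4    3    1
 -3.8152714699576651e-03    4    4    3    2
  5.2496457235562055e-01    4    4    3    3
 -1.4509135583803106e-03    4    4    4    1
 -9.8520880077858677e-15    4    4    4    2
  7.6596011253939030e-16    4    4    4    3
  5.5253095146051634e-01    4    4    4    4
 -2.1279359727168545e+00    1    1    0    0
  3.2930779568443705e-14    2    1    0    0
 -1.6378090919517625e+00    2    2    0    0
 -3.5683632616954276e-14    3    1    0    0
  1.5876287806072147e-04    3    2    0    0
 -1.5756881837418926e+00    3    3    0    0
 -4.4139043937987184e-02    4    1    0    0
  2.3157218050929871e-14    4    2    0    0
 -1.8011927649820829e-15    4    3    0    0
 -1.0705645826279830e+00    4    4    0    0
  2.8627567866441783e+00    0    0    0    0
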