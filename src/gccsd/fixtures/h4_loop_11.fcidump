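&FCI NORB=4,NELEC=4,MS2=0,
 ORBSYM=1,1,1,1,
 ISYM=1,
/
  5.3566729644167443e-01    1    1    1    1
  1.3685773337455820e-01    2    1    2    1
  5.1033560105333031e-01    2    2    1    1
 -1.4664819849838954e-16    2    2    2    1
  5.3663151050525248e-01    2    2    2    2
 -5.0781805986022119e-03    3    1    2    1
  1.3499708243810965e-01    3    1    3    1
 -1.3618477367966180e-02    3    2    1    1
  2.2317537015527380e-02    3    2    2    2
  5.9238263786045159e-02    3    2    3    2
  5.2592319015273459e-01    3    3    1    1
  4.8458792368425091e-01    3    3    2    2
 -4.0251946416924797e-02    3    3    3    2
  5.5657624331169675e-01    3    3    3    3
  2.2995278009424101e-02    4    1    1    1
 -2.8722917097674525e-02    4    1    2    2
 -6.6002002529784123e-02    4    1    3    2
  5.6865225739477755e-02    4    1    3    3
  7.9021008252981778e-02    4    1    4    1
  1.6365812665550985e-16    4    2    1    1
 -7.8589600123966846e-02    4    2    2    1
  2.7317499341169961e-16    4    2    2    2
 -1.0803603791136877e-01    4    2    3    1
  2.6335072328350114e-16    4    2    3    3
  1.5378293100755860e-01    4    2    4    2
 -1.1440425639031583e-01    4    3    2    1
  1.0113667506250238e-16    4    3    2    2
  6.6395784411600975e-02    4    3    3    1
  1.8055123834688960e-02    4    3    4    2
  1.3875371869746939e-01    4    3    4    3
  5.2157657492261134e-01    4    4    1    1
 -1.2868575523891824e-16    4    4    2    1
  5.3045200885650667e-01    4    4    2    2
  3.8152714699631247e-03    4    4    3    2
  5.2496457235564298e-01    4    4    3    3
 -1.4509135583740105e-03    4    4    4    1
  2.6040239423439517e-16    4    4    4    2
  5.5253095146051490e-01    4    4    4    4
 -2.1279359727168501e+00    1    1    0    0
  2.0678417472028064e-16    2    1    0    0
 -1.6378090919517614e+00    2    2    0    0
 -1.4297661001049962e-16    3    1    0    0
 -1.5876287819851305e-04    3    2    0    0
 -1.5756881837418930e+00    3    3    0    0
 -4.4139043938041599e-02    4    1    0    0
 -3.6504799502890682e-16    4    2    0    0
 -3.0457877509032244e-16    4    3    0    0
 -1.0705645826279873e+00    4    4    0    0
  2.8627567866441783e+00    0    0    0    0
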