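&FCI NORB=4,NELEC=4,MS2=0,
 ORBSYM=1,1,1,1,
 ISYM=1,
/
  5.3633875398532371e-01    1    1    1    1
  3.1024120611708263e-16    2    1    1    1
  1.2974922670288833e-01    2    1    2    1
  5.0200041028286380e-01    2    2    1    1
  5.7552366829716228e-01    2    2    2    2
  1.4198722334218089e-01    3    1    3    1
 -1.2567096125722442e-16    3    2    2    1
 -2.3885430748832884e-16    3    2    2    2
  1.0839028510157420e-02    3    2    3    2
  5.3467719038032568e-01    3    3    1    1
  1.2730617776418362e-16    3    3    2    1
  4.3629987605277376e-01    3    3    2    2
  5.7719984233006045e-16    3    3    3    1
  4.1469744749477353e-16    3    3    3    2
  6.1426574195854111e-01    3    3    3    3
  2.3188430702516784e-02    4    1    1    1
 -6.4923703216479223e-02    4    1    2    2
  4.1019790009732865e-16    4    1    3    2
  9.1823872622472755e-02    4    1    3    3
  7.8410668886888829e-02    4    1    4    1
  1.1003936878893149e-16    4    2    1    1
 -1.3832206594991392e-01    4    2    2    1
  4.0829527582854432e-16    4    2    2    2
  6.8239150829781364e-16    4    2    3    1
  2.0886614983339537e-16    4    2    3    2
  2.4094837612198202e-16    4    2    3    3
  1.0938451445443056e-16    4    2    4    1
  1.6728089997544915e-01    4    2    4    2
  6.5366114483005456e-16    4    3    2    1
  2.6109610087695848e-16    4    3    2    2
  1.2696756934595971e-01    4    3    3    1
  1.6438221660960004e-16    4    3    3    3
 -3.1312395973497757e-16    4    3    4    1
 -1.6171241767442876e-16    4    3    4    2
  1.2565222913643662e-01    4    3    4    3
  5.2119186779494109e-01    4    4    1    1
  2.9160681339573632e-16    4    4    2    1
  5.3362235929524116e-01    4    4    2    2
 -2.0197874899791592e-16    4    4    3    1
  5.2158367612598344e-01    4    4    3    3
 -2.6614515512116354e-03    4    4    4    1
 -3.5375820079150633e-16    4    4    4    3
  5.5271203034900340e-01    4    4    4    4
 -2.1283413048981719e+00    1    1    0    0
 -2.5210138812056186e-16    2    1    0    0
 -1.6240732841130989e+00    2    2    0    0
 -1.4554759580836651e-16    3    1    0    0
 -1.5918994662354928e+00    3    3    0    0
 -3.1663090220246083e-02    4    1    0    0
 -4.2055700496466300e-16    4    2    0    0
  3.7717980801181885e-16    4    3    0    0
 -1.0681282583571596e+00    4    4    0    0
  2.8615984525537281e+00    0    0    0    0
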