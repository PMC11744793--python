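&FCI NORB=4,NELEC=2,MS2=0,
 ORBSYM=1,1,1,1,
 ISYM=1,
/
  6.4970272397380080e-01    1    1    1    1
  8.0146514833886073e-02    2    1    2    1
  4.3376450035090969e-01    2    2    1    1
  1.2726610673090717e-16    2    2    2    1
  3.8585581396620194e-01    2    2    2    2
 -1.6707334406080507e-01    3    1    1    1
 -5.0084802839121992e-02    3    1    2    2
  1.0930088578079909e-01    3    1    3    1
 -1.1071109929125248e-16    3    2    1    1
  1.9257352104610274e-02    3    2    2    1
  2.7195538112547745e-16    3    2    2    2
  3.5919305876364958e-02    3    2    3    2
  5.3182635063815642e-01    3    3    1    1
  2.1271706710925936e-16    3    3    2    1
  3.8138237486674498e-01    3    3    2    2
 -1.1985126748306416e-01    3    3    3    1
  4.6367428616715956e-01    3    3    3    3
  1.7789432192297584e-16    4    1    1    1
 -7.9376454623465723e-02    4    1    2    1
  2.1834680869513980e-02    4    1    3    2
 -3.4358527923582639e-16    4    1    3    3
  1.3755317508062892e-01    4    1    4    1
 -1.4334513079531330e-01    4    2    1    1
  2.9332710845642207e-16    4    2    2    1
 -5.4824139925592215e-02    4    2    2    2
  7.3315694045935131e-02    4    2    3    1
 -1.4660533780921610e-16    4    2    3    2
 -9.8414543610296001e-02    4    2    3    3
  6.7577190581280852e-02    4    2    4    2
  3.3345771902733398e-16    4    3    1    1
  8.3322683172879455e-02    4    3    2    1
 -6.5881213388220910e-16    4    3    2    2
 -4.4955266302696499e-16    4    3    3    1
 -2.7077125912856989e-03    4    3    3    2
  9.9373377725339911e-16    4    3    3    3
 -1.2311245073158622e-01    4    3    4    1
 -7.0621558729946404e-16    4    3    4    2
  1.2759409998564417e-01    4    3    4    3
  6.6282006455713427e-01    4    4    1    1
 -2.6313271931267136e-16    4    4    2    1
  4.4247425066637280e-01    4    4    2    2
 -2.0149481062549185e-01    4    4    3    1
  5.5221975701597814e-01    4    4    3    3
  2.2036812286495677e-16    4    4    4    1
 -1.6774815924467495e-01    4    4    4    2
  6.4553189420473711e-16    4    4    4    3
  7.4017035683824428e-01    4    4    4    4
 -1.2450953423773694e+00    1    1    0    0
 -5.4928422375877994e-01    2    2    0    0
  1.6707334406152397e-01    3    1    0    0
  3.7074705552671907e-16    3    2    0    0
 -1.7895301819463549e-01    3    3    0    0
  3.6236758290495139e-16    4    1    0    0
  2.0731380696716301e-01    4    2    0    0
  3.1088281046658157e-16    4    3    0    0
  2.1447916497282388e-01    4    4    0    0
  7.1375399366468839e-01    0    0    0    0
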