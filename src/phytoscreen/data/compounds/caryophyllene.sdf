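Caryophyllene
     RDKit          2D

 15 16  0  0  0  0  0  0  0  0999 V2000
   -3.9724    1.9301    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
   -2.7528    1.0568    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
   -3.1564   -0.3879    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
   -2.5370   -1.7540    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
   -1.1843   -2.4023    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    0.2686   -2.0295    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    1.1159   -3.2673    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    1.1420   -0.8100    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    2.6376   -0.6951    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    2.5227    0.8005    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    2.4078    2.2961    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    4.0183    0.9154    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    1.0271    0.6856    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
   -0.0222    1.7575    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
   -1.5150    1.9041    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
  1  2  1  0
  2  3  2  3
  3  4  1  0
  4  5  1  0
  5  6  1  0
  6  7  2  0
  6  8  1  0
  8  9  1  0
  9 10  1  0
 10 11  1  0
 10 12  1  0
 10 13  1  0
 13 14  1  0
 14 15  1  0
 15  2  1  0
 13  8  1  0
M  END
$$$$
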