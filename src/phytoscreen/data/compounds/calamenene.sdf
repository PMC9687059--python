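Calamenene
     RDKit          2D

 15 16  0  0  0  0  0  0  0  0999 V2000
    0.7500    3.7239    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
   -0.0000    2.4249    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
   -1.5000    2.4249    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
   -2.2500    1.1258    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
   -1.5000   -0.1732    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
   -2.2500   -1.4722    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
   -3.7500   -1.4722    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
   -1.5000   -2.7713    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    0.0000   -0.1732    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    0.7500   -1.4722    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    2.2500   -1.4722    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    3.0000   -2.7713    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    3.0000   -0.1732    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    2.2500    1.1258    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    0.7500    1.1258    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
  1  2  1  0
  2  3  1  0
  3  4  1  0
  4  5  1  0
  5  6  1  0
  6  7  1  0
  6  8  1  0
  5  9  1  0
  9 10  2  0
 10 11  1  0
 11 12  1  0
 11 13  2  0
 13 14  1  0
 14 15  2  0
 15  2  1  0
 15  9  1  0
M  END
$$$$
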