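14-Hydroxy-9-epi-(E)-caryophyllene
     RDKit          2D

 16 17  0  0  0  0  0  0  0  0999 V2000
   -4.3074    2.1468    0.0000 O   0  0  0  0  0  0  0  0  0  0  0  0
   -4.0541    0.6683    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
   -2.6471    0.1484    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
   -2.6544   -1.3516    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
   -1.6959   -2.5054    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
   -0.2200   -2.7731    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    1.0827   -2.0294    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    2.2271   -2.9992    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    1.6026   -0.6224    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    3.0147   -0.1163    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    2.5085    1.2958    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    2.0024    2.7078    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    3.9206    1.8019    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    1.0965    0.7896    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
   -0.1989    1.5460    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
   -1.6773    1.2927    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
  1  2  1  0
  2  3  1  0
  3  4  2  3
  4  5  1  0
  5  6  1  0
  6  7  1  0
  7  8  2  0
  7  9  1  0
  9 10  1  0
 10 11  1  0
 11 12  1  0
 11 13  1  0
 11 14  1  0
 14 15  1  0
 15 16  1  0
 16  3  1  0
 14  9  1  0
M  END
$$$$
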