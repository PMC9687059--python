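Humulene
     RDKit          2D

 15 15  0  0  0  0  0  0  0  0999 V2000
    1.0690   -4.0111    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    0.5780   -2.5937    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    1.7996   -1.7233    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    2.3567   -0.3306    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    2.0724    1.1423    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    2.7593    2.4757    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    3.5572    0.9292    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    1.0369    2.2275    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
   -0.4209    2.5807    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
   -1.8382    2.0897    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
   -2.7651    0.9104    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
   -4.1578    1.4674    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
   -2.9073   -0.5829    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
   -2.2195   -1.9159    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
   -0.9203   -2.6655    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
  1  2  1  0
  2  3  2  3
  3  4  1  0
  4  5  1  0
  5  6  1  0
  5  7  1  0
  5  8  1  0
  8  9  2  3
  9 10  1  0
 10 11  1  0
 11 12  1  0
 11 13  2  3
 13 14  1  0
 14 15  1  0
 15  2  1  0
M  END
$$$$
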