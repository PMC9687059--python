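Caryophyllene oxide
     RDKit          2D

 16 18  0  0  0  0  0  0  0  0999 V2000
    2.4864   -2.3857    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    2.6962   -0.9004    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    4.1815   -1.1103    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    2.9061    0.5848    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    1.4208    0.7947    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    1.2110   -0.6906    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    0.0955   -1.6935    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
   -1.4036   -1.7447    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
   -2.5849   -0.8203    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
   -3.2901   -2.1443    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
   -4.0112   -0.3558    0.0000 O   0  0  0  0  0  0  0  0  0  0  0  0
   -2.8957    0.6471    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
   -2.1906    1.9710    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
   -0.7994    2.5319    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    0.6269    2.0673    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    1.5512    3.2487    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
  1  2  1  0
  2  3  1  0
  2  4  1  0
  4  5  1  0
  5  6  1  0
  6  7  1  0
  7  8  1  0
  8  9  1  0
  9 10  1  0
  9 11  1  0
 11 12  1  0
 12 13  1  0
 13 14  1  0
 14 15  1  0
 15 16  2  0
  6  2  1  0
 15  5  1  0
 12  9  1  0
M  END
$$$$
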