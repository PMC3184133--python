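VV  emtcre convenience matrices (synthetic fixtures, not database reproductions)
XX
//
ID  SRY
XX
P0      A      C      G      T
01      9      1      1      1
02      9      1      1      1
03      1      9      1      1
04      9      1      1      1
05      9      1      1      1
06      1      1      1      9
07      1      1      9      1
XX
//
ID  FTS-1
XX
P0      A      C      G      T
01      1      1      1      9
02      1      1      9      1
03      9      1      1      1
04      1      1      1      9
05      1      1      1      9
06      1      1      9      1
07      9      1      1      1
08      1      1      1      9
09      1      9      1      1
10      1      9      1      1
11      1      1      1      9
XX
//
ID  Evi-1
XX
P0      A      C      G      T
01      1      1      9      1
02      9      1      1      1
03      1      9      1      1
04      9      1      1      1
05      9      1      1      1
06      1      1      9      1
07      9      1      1      1
08      1      1      1      9
09      9      1      1      1
10      9      1      1      1
XX
//
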