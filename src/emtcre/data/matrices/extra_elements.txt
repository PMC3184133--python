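# Simple-dialect matrices: >NAME then one "A C G T" count row per position.
# Synthetic convenience fixtures.
>GC-Box
1	2	8	1
1	1	9	1
1	1	9	1
1	2	8	1
2	8	1	1
1	1	9	1
1	1	9	1
1	2	8	1
1	1	9	1

>Elk-1
1	9	1	1
1	9	1	1
1	1	9	1
1	1	9	1
9	1	1	1
9	1	1	1
1	1	9	1
1	1	1	9

>CREB
1	1	1	9
1	1	9	1
9	1	1	1
1	9	1	1
1	1	9	1
1	1	1	9
1	9	1	1
9	1	1	1
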