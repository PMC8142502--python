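type	alphabet	k
T1	murphy4	2
T3A	murphy4	2
T3B	murphy4	2
T14	murphy4	2
T15	murphy4	2
T16	murphy4	2
T4	wang5	4
T5	murphy4	4
T6A	wang5	4
T6B	wang5	4
T7	wang5	4
T8	wang5	4
T9	wang5	4
T10	wang5	4
T11	wang5	4
T12	wang5	4
T13	murphy4	4
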