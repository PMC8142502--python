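name	groups
murphy2	LVIMCAGSTPFYW-EDNQKRH
murphy4	LVIMC-AGSTP-FYW-EDNQKRH
wang5	CMFILVWY-ATH-GP-DE-SNQRK
murphy8	LVIMC-AG-ST-P-FYW-EDNQ-KR-H
murphy10	LVIM-C-A-G-ST-P-FYW-EDNQ-KR-H
murphy15	LVIM-C-A-G-S-T-P-FY-W-E-D-N-Q-KR-H
identity20	A-C-D-E-F-G-H-I-K-L-M-N-P-Q-R-S-T-V-W-Y
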