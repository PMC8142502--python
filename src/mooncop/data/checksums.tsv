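file	sha256
codon_counts.tsv	2f065799464db31853f314093e2322032319746a5327939534d5fb92a06770fb
ctd_partitions.tsv	a02cca1e5420421a6772e97026e22c569fb6c214a86ea7ef105278b4d4d05ccc
grantham.tsv	172519b638196f283cad6eda5f942466f235b6ecb63472e46cb94fe1c8701f77
grouped_alphabets.tsv	24835fbc1c3213afb3328acc35915487f5b3f52d11317d43bd83641b66bf2ca6
psekraac_defaults.tsv	782f911ad4783d39fc4b92edc13816d4f4a9d47712b3f82e80523c09dc0200f0
schneider_wrede_synthetic.tsv	8f38b188c20fca68e7cd0dbcfdf2106078b0abe38accda7cad4cdd0f947d0966
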