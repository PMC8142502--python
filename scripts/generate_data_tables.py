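"""One-off generator for the plain-text data tables bundled with mooncop.

Writes TSV files into src/mooncop/data/ plus a checksums manifest.
"""
import hashlib
from pathlib import Path

AA = "ACDEFGHIKLMNPQRSTVWY"
OUT = Path(__file__).resolve().parents[1] / "src" / "mooncop" / "data"
OUT.mkdir(parents=True, exist_ok=True)

# ---------------------------------------------------------------- Grantham
# Grantham (1974) amino-acid difference matrix, lower-triangle pair list.
GRANTHAM_PAIRS = """
RS110 LS145 LR102 PS74 PR103 PL98 TS58 TR71 TL92 TP38
AS99 AR112 AL96 AP27 AT58 VS124 VR96 VL32 VP68 VT69 VA64
GS56 GR125 GL138 GP42 GT59 GA60 GV109
IS142 IR97 IL5 IP95 IT89 IA94 IV29 IG135
FS155 FR97 FL22 FP114 FT103 FA113 FV50 FG153 FI21
YS144 YR77 YL36 YP110 YT92 YA112 YV55 YG147 YI33 YF22
CS112 CR180 CL198 CP169 CT149 CA195 CV192 CG159 CI198 CF205 CY194
HS89 HR29 HL99 HP77 HT47 HA86 HV84 HG98 HI94 HF100 HY83 HC174
QS68 QR43 QL113 QP76 QT42 QA91 QV96 QG87 QI109 QF116 QY99 QC154 QH24
NS46 NR86 NL153 NP91 NT65 NA111 NV133 NG80 NI149 NF158 NY143 NC139 NH68 NQ46
KS121 KR26 KL107 KP103 KT78 KA106 KV97 KG127 KI102 KF102 KY85 KC202 KH32 KQ53 KN94
DS65 DR96 DL172 DP108 DT85 DA126 DV152 DG94 DI168 DF177 DY160 DC154 DH81 DQ61 DN23 DK101
ES80 ER54 EL138 EP93 ET65 EA107 EV121 EG98 EI134 EF140 EY122 EC170 EH40 EQ29 EN42 EK56 ED45
MS135 MR91 ML15 MP87 MT81 MA84 MV21 MG127 MI10 MF28 MY36 MC196 MH87 MQ101 MN142 MK95 MD160 ME126
WS177 WR101 WL61 WP147 WT128 WA148 WV88 WG184 WI61 WF40 WY37 WC215 WH115 WQ130 WN174 WK110 WD181 WE152 WM67
""".split()

gr = {(a, a): 0.0 for a in AA}
for tok in GRANTHAM_PAIRS:
    a, b, v = tok[0], tok[1], float(tok[2:])
    gr[(a, b)] = gr[(b, a)] = v
assert len(gr) == 400, len(gr)


def write_matrix(name, d):
    lines = ["\t" + "\t".join(AA)]
    for a in AA:
        lines.append(a + "\t" + "\t".join(f"{d[(a, b)]:g}" for b in AA))
    (OUT / name).write_text("\n".join(lines) + "\n")


write_matrix("grantham.tsv", gr)

# ---------------------------------------- synthetic Schneider-Wrede stand-in
# Physicochemical distance reconstructed from three residue scales
# (Kyte-Doolittle hydropathy, Hopp-Woods hydrophilicity, residue volume),
# z-scored over the 20 residues; Euclidean distance scaled to max 1.
KD = dict(A=1.8, R=-4.5, N=-3.5, D=-3.5, C=2.5, Q=-3.5, E=-3.5, G=-0.4,
          H=-3.2, I=4.5, L=3.8, K=-3.9, M=1.9, F=2.8, P=-1.6, S=-0.8,
          T=-0.7, W=-0.9, Y=-1.3, V=4.2)
HW = dict(A=-0.5, R=3.0, N=0.2, D=3.0, C=-1.0, Q=0.2, E=3.0, G=0.0,
          H=-0.5, I=-1.8, L=-1.8, K=3.0, M=-1.3, F=-2.5, P=0.0, S=0.3,
          T=-0.4, W=-3.4, Y=-2.3, V=-1.5)
VOL = dict(A=88.6, R=173.4, N=114.1, D=111.1, C=108.5, Q=143.8, E=138.4,
           G=60.1, H=153.2, I=166.7, L=166.7, K=168.6, M=162.9, F=189.9,
           P=112.7, S=89.0, T=116.1, W=227.8, Y=193.6, V=140.0)


def zscore(scale):
    vals = [scale[a] for a in AA]
    mu = sum(vals) / 20.0
    sd = (sum((v - mu) ** 2 for v in vals) / 20.0) ** 0.5
    return {a: (scale[a] - mu) / sd for a in AA}


z = [zscore(s) for s in (KD, HW, VOL)]
sw = {}
for a in AA:
    for b in AA:
        sw[(a, b)] = sum((s[a] - s[b]) ** 2 for s in z) ** 0.5
mx = max(sw.values())
sw = {k: round(v / mx, 6) for k, v in sw.items()}
write_matrix("schneider_wrede_synthetic.tsv", sw)

# --------------------------------------------------------- CTD partitions
# Three-class partitions of the 20 residues for 7 physicochemical
# properties (the standard Dubchak/PROFEAT groupings).
CTD = [
    ("hydrophobicity", "RKEDQN", "GASTPHY", "CLVIMFW"),
    ("normalized_vdw_volume", "GASTPDC", "NVEQIL", "MHKFRYW"),
    ("polarity", "LIFWCMVY", "PATGS", "HQRKNED"),
    ("polarizability", "GASDT", "CPNVEQIL", "KMHFRYW"),
    ("charge", "KR", "ANCQGHILMFPSTWYV", "DE"),
    ("secondary_structure", "EALMQKRH", "VIYCWFT", "GNPSD"),
    ("solvent_accessibility", "ALFCGIVW", "RKQEND", "MSPTHY"),
]
lines = ["property\tclass1\tclass2\tclass3"]
for name, c1, c2, c3 in CTD:
    assert sorted(c1 + c2 + c3) == sorted(AA), name
    lines.append(f"{name}\t{c1}\t{c2}\t{c3}")
(OUT / "ctd_partitions.tsv").write_text("\n".join(lines) + "\n")

# ------------------------------------------------------- grouped alphabets
# Murphy et al. (2000) reduced alphabets plus a 5-letter scheme; the
# 8-group scheme is the default for all grouped descriptor variants.
GROUPED = [
    ("murphy2", ["LVIMCAGSTPFYW", "EDNQKRH"]),
    ("murphy4", ["LVIMC", "AGSTP", "FYW", "EDNQKRH"]),
    ("wang5", ["CMFILVWY", "ATH", "GP", "DE", "SNQRK"]),
    ("murphy8", ["LVIMC", "AG", "ST", "P", "FYW", "EDNQ", "KR", "H"]),
    ("murphy10", ["LVIM", "C", "A", "G", "ST", "P", "FYW", "EDNQ", "KR", "H"]),
    ("murphy15", ["LVIM", "C", "A", "G", "S", "T", "P", "FY", "W", "E", "D",
                  "N", "Q", "KR", "H"]),
    ("identity20", list(AA)),
]
lines = ["name\tgroups"]
for name, groups in GROUPED:
    assert sorted("".join(groups)) == sorted(AA), name
    lines.append(f"{name}\t{'-'.join(groups)}")
(OUT / "grouped_alphabets.tsv").write_text("\n".join(lines) + "\n")

# ----------------------------------------------------------- codon counts
COD = dict(A=4, C=2, D=2, E=2, F=2, G=4, H=2, I=3, K=2, L=6, M=1, N=2,
           P=4, Q=2, R=6, S=6, T=4, V=4, W=1, Y=2)
assert sum(COD.values()) == 61
(OUT / "codon_counts.tsv").write_text(
    "residue\tcodons\n" + "\n".join(f"{a}\t{COD[a]}" for a in AA) + "\n")

# -------------------------------------- reduced k-tuple (PseKRAAC) defaults
# Per-type default (alphabet, k) reproducing the published vector lengths:
# g=4,k=2 -> 16; g=16... not bundled; g=4,k=4 -> 256; g=5,k=4 -> 625.
PSE = [
    ("T1", "murphy4", 2), ("T3A", "murphy4", 2), ("T3B", "murphy4", 2),
    ("T14", "murphy4", 2), ("T15", "murphy4", 2), ("T16", "murphy4", 2),
    ("T4", "wang5", 4), ("T5", "murphy4", 4), ("T6A", "wang5", 4),
    ("T6B", "wang5", 4), ("T7", "wang5", 4), ("T8", "wang5", 4),
    ("T9", "wang5", 4), ("T10", "wang5", 4), ("T11", "wang5", 4),
    ("T12", "wang5", 4), ("T13", "murphy4", 4),
]
(OUT / "psekraac_defaults.tsv").write_text(
    "type\talphabet\tk\n" + "\n".join(f"{t}\t{a}\t{k}" for t, a, k in PSE) + "\n")

# -------------------------------------------------------------- checksums
manifest = []
for f in sorted(OUT.glob("*.tsv")):
    if f.name == "checksums.tsv":
        continue
    manifest.append(f"{f.name}\t{hashlib.sha256(f.read_bytes()).hexdigest()}")
(OUT / "checksums.tsv").write_text("file\tsha256\n" + "\n".join(manifest) + "\n")
print("\n".join(manifest))
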