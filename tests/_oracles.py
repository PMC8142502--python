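"""Independent brute-force oracles used to cross-check the implementation.

Everything here is written as plain-Python enumeration over windows,
pairs and positions — deliberately naive and structurally unrelated to
the vectorized implementations under test.
"""
import math

ALPHABET = "ACDEFGHIKLMNPQRSTVWY"


def composition(seq, symbols=ALPHABET, mapping=None):
    counts = {s: 0 for s in symbols}
    for ch in seq:
        counts[mapping[ch] if mapping else ch] += 1
    return [counts[s] / len(seq) for s in symbols]


def kmer_freqs(seq, k, symbols=ALPHABET, mapping=None):
    from itertools import product
    windows = [seq[i:i + k] for i in range(len(seq) - k + 1)]
    if mapping:
        windows = ["".join(mapping[c] for c in w) for w in windows]
    out = []
    for tup in product(symbols, repeat=k):
        out.append(windows.count("".join(tup)) / len(windows))
    return out


def cks_pair_freqs(seq, gap, symbols=ALPHABET, mapping=None):
    pairs = [(seq[i], seq[i + gap + 1]) for i in range(len(seq) - gap - 1)]
    if mapping:
        pairs = [(mapping[a], mapping[b]) for a, b in pairs]
    out = []
    for x in symbols:
        for y in symbols:
            out.append(pairs.count((x, y)) / len(pairs))
    return out


def dde(seq, codon_counts, symbols=ALPHABET, mapping=None):
    cn = sum(codon_counts.values())
    if mapping:
        groups = {}
        for aa, g in mapping.items():
            groups.setdefault(g, 0)
            groups[g] += codon_counts[aa]
        codons = groups
    else:
        codons = codon_counts
    dc = cks_pair_freqs(seq, 0, symbols, mapping)
    out = []
    i = 0
    for x in symbols:
        for y in symbols:
            tm = (codons[x] / cn) * (codons[y] / cn)
            tv = tm * (1 - tm) / (len(seq) - 1)
            out.append((dc[i] - tm) / math.sqrt(tv))
            i += 1
    return out


def ctd_parts(seq, partitions):
    """Return (C, T, D) lists computed by direct position enumeration."""
    comp, trans, dist = [], [], []
    for _, classes in partitions:
        cls_of = {aa: ci for ci, group in enumerate(classes) for aa in group}
        codes = [cls_of[c] for c in seq]
        n = len(seq)
        for ci in range(3):
            comp.append(codes.count(ci) / n)
        if n >= 2:
            for a, b in ((0, 1), (0, 2), (1, 2)):
                t = sum(1 for i in range(n - 1)
                        if {codes[i], codes[i + 1]} == {a, b})
                trans.append(t / (n - 1))
        for ci in range(3):
            pos = [i + 1 for i, c in enumerate(codes) if c == ci]
            if not pos:
                dist.extend([0.0] * 5)
                continue
            for q in (0.0, 0.25, 0.5, 0.75, 1.0):
                idx = max(1, math.floor(q * len(pos) + 0.5))
                dist.append(100.0 * pos[idx - 1] / n)
    return comp, trans, dist


def socnumber(seq, nlag, matrices):
    """matrices: list of dicts (a, b) -> distance."""
    out = []
    for d_m in matrices:
        for d in range(1, nlag + 1):
            out.append(sum(d_m[(seq[i], seq[i + d])] ** 2
                           for i in range(len(seq) - d)))
    return out


def qsorder(seq, nlag, w, matrices):
    out = []
    for d_m in matrices:
        f = [seq.count(a) for a in ALPHABET]
        taus = [sum(d_m[(seq[i], seq[i + d])] ** 2
                    for i in range(len(seq) - d)) for d in range(1, nlag + 1)]
        z = sum(f) + w * sum(taus)
        out.extend(x / z for x in f)
        out.extend(w * t / z for t in taus)
    return out


def moreau_broto(seq, scale_by_aa, nlag):
    vals = [scale_by_aa[c] for c in seq]
    return [sum(vals[i] * vals[i + d] for i in range(len(seq) - d))
            / (len(seq) - d) for d in range(1, nlag + 1)]


# ---------------------------------------------------------------- metrics

def metrics_from_counts(tp, fp, tn, fn):
    n = tp + fp + tn + fn
    acc = (tp + tn) / n
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f = (2 * precision * recall / (precision + recall)
         if precision + recall else 0.0)
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / math.sqrt(denom) if denom else 0.0
    return acc, precision, recall, f, mcc


def pairwise_auc(scores, positive_flags):
    pos = [s for s, p in zip(scores, positive_flags) if p]
    neg = [s for s, p in zip(scores, positive_flags) if not p]
    total = 0.0
    for sp in pos:
        for sn in neg:
            total += 1.0 if sp > sn else (0.5 if sp == sn else 0.0)
    return total / (len(pos) * len(neg))


# ------------------------------------------------------------- outliers

def tally_from_rows(rows):
    """rows: iterable of (protein_id, repeat, correct_flag)."""
    misses = {}
    for pid, _, correct in rows:
        misses.setdefault(pid, 0)
        if not correct:
            misses[pid] += 1
    return misses


def filter_cops(misses, threshold, inclusive):
    if inclusive:
        return {p for p, c in misses.items() if c >= threshold}
    return {p for p, c in misses.items() if c > threshold}
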