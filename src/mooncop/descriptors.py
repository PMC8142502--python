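"""Sequence-derived feature vectors for protein classification.

Every descriptor maps one amino-acid sequence to a fixed-length numeric
vector with a deterministic feature order.  The catalogue covers the
composition family (whole-sequence, split, k-part, k-mer, k-spaced pairs,
each with an optional grouped-alphabet variant), dipeptide deviation from
the codon-usage expectation (DDE), composition/transition/distribution
over physicochemical classes (CTD), sequence-order coupling numbers and
the quasi-sequence-order descriptor built on two residue distance
matrices, a reduced-alphabet k-tuple engine, and lagged autocorrelation
statistics of residue property scales.

Descriptors are addressed through a registry (`extract`, `get_spec`,
`registry_names`) whose default parameters pin the published vector
lengths: SAAC 60, SGAAC 24, QSOrder 50, SOCNumber 60, DDE 400, CTD 147,
and so on.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from . import tables
from .seqio import ALPHABET, LabeledDataset

_IDX = {aa: i for i, aa in enumerate(ALPHABET)}


def _encode(seq: str, alphabet: tables.GroupedAlphabet | None = None) -> np.ndarray:
    """Encode a sequence as integer codes (residue or group indices)."""
    if alphabet is None:
        return np.fromiter((_IDX[c] for c in seq), dtype=np.intp, count=len(seq))
    m = alphabet.mapping
    return np.fromiter((m[c] for c in seq), dtype=np.intp, count=len(seq))


def _symbols(alphabet: tables.GroupedAlphabet | None) -> list[str]:
    if alphabet is None:
        return list(ALPHABET)
    return [f"G{i + 1}" for i in range(alphabet.g)]


def _size(alphabet: tables.GroupedAlphabet | None) -> int:
    return 20 if alphabet is None else alphabet.g


# --------------------------------------------------------------------------
# composition family
# --------------------------------------------------------------------------

def aac(seq: str, alphabet: tables.GroupedAlphabet | None = None) -> np.ndarray:
    """(Grouped) amino-acid composition: count(r) / L in fixed order."""
    if not seq:
        raise ValueError("empty sequence")
    codes = _encode(seq, alphabet)
    return np.bincount(codes, minlength=_size(alphabet)) / len(seq)


def aak_part_composition(seq: str, k: int = 3,
                         alphabet: tables.GroupedAlphabet | None = None) -> np.ndarray:
    """Composition of k contiguous near-equal parts, concatenated.

    The first ``len(seq) % k`` parts receive one extra residue, so part
    boundaries are deterministic and order-preserving.
    """
    if len(seq) < k:
        raise ValueError(f"sequence length {len(seq)} < {k} parts")
    base, extra = divmod(len(seq), k)
    out, start = [], 0
    for i in range(k):
        size = base + (1 if i < extra else 0)
        out.append(aac(seq[start:start + size], alphabet))
        start += size
    return np.concatenate(out)


def saac(seq: str, nt: int = 5, ct: int = 5,
         alphabet: tables.GroupedAlphabet | None = None) -> np.ndarray:
    """Split composition: N-terminal ``nt`` residues, middle, C-terminal ``ct``."""
    if len(seq) < nt + ct + 1:
        raise ValueError(
            f"sequence length {len(seq)} too short for termini {nt}+{ct}")
    return np.concatenate([aac(seq[:nt], alphabet),
                           aac(seq[nt:len(seq) - ct], alphabet),
                           aac(seq[len(seq) - ct:], alphabet)])


def kmer_composition(seq: str, k: int = 3,
                     alphabet: tables.GroupedAlphabet | None = None) -> np.ndarray:
    """Overlapping k-mer frequencies in lexicographic order, summing to 1."""
    if len(seq) < k:
        raise ValueError(f"sequence length {len(seq)} < k={k}")
    a = _size(alphabet)
    codes = _encode(seq, alphabet)
    n = len(seq) - k + 1
    idx = np.zeros(n, dtype=np.intp)
    for j in range(k):
        idx = idx * a + codes[j:j + n]
    return np.bincount(idx, minlength=a ** k) / n


def cks_pair(seq: str, gap: int = 1,
             alphabet: tables.GroupedAlphabet | None = None) -> np.ndarray:
    """Composition of k-spaced residue pairs (x, y) with ``gap`` residues between."""
    if len(seq) < gap + 2:
        raise ValueError(f"sequence length {len(seq)} too short for gap {gap}")
    a = _size(alphabet)
    codes = _encode(seq, alphabet)
    n = len(seq) - gap - 1
    idx = codes[:n] * a + codes[gap + 1:]
    return np.bincount(idx, minlength=a * a) / n


def reduced_ktuple(seq: str, alphabet: tables.GroupedAlphabet, k: int = 2) -> np.ndarray:
    """k-tuple composition over a reduced (clustered) alphabet: length g**k."""
    return kmer_composition(seq, k=k, alphabet=alphabet)


# --------------------------------------------------------------------------
# DDE
# --------------------------------------------------------------------------

def _codon_fractions(alphabet: tables.GroupedAlphabet | None) -> np.ndarray:
    counts = tables.codon_counts()
    if alphabet is None:
        c = np.array([counts[a] for a in ALPHABET], dtype=float)
    else:
        c = np.array([sum(counts[a] for a in grp) for grp in alphabet.groups],
                     dtype=float)
    return c / 61.0


def dde(seq: str, alphabet: tables.GroupedAlphabet | None = None) -> np.ndarray:
    """Dipeptide deviation from the expected mean.

    For each ordered dipeptide (i, j): the observed frequency
    Dc = N_ij / (L - 1) is standardized against the theoretical mean
    Tm = (C_i / C_N)(C_j / C_N) and variance Tv = Tm (1 - Tm) / (L - 1)
    implied by synonymous-codon usage, giving (Dc - Tm) / sqrt(Tv).
    """
    if len(seq) < 2:
        raise ValueError("DDE needs sequence length >= 2")
    dc = cks_pair(seq, gap=0, alphabet=alphabet)
    frac = _codon_fractions(alphabet)
    tm = np.outer(frac, frac).ravel()
    tv = tm * (1.0 - tm) / (len(seq) - 1)
    return (dc - tm) / np.sqrt(tv)


# --------------------------------------------------------------------------
# CTD
# --------------------------------------------------------------------------

def ctdc(seq: str) -> np.ndarray:
    """Composition: per property, fraction of residues in each of 3 classes."""
    if not seq:
        raise ValueError("empty sequence")
    out = []
    for part in tables.ctd_partitions():
        codes = np.asarray(part.encode(seq))
        out.append(np.bincount(codes, minlength=3) / len(seq))
    return np.concatenate(out)


def ctdt(seq: str) -> np.ndarray:
    """Transition: per property and unordered class pair, adjacent switches / (L-1)."""
    if len(seq) < 2:
        raise ValueError("CTD transition needs sequence length >= 2")
    out = []
    for part in tables.ctd_partitions():
        codes = np.asarray(part.encode(seq))
        a, b = codes[:-1], codes[1:]
        vals = []
        for x, y in ((0, 1), (0, 2), (1, 2)):
            vals.append(np.sum(((a == x) & (b == y)) | ((a == y) & (b == x))))
        out.append(np.asarray(vals, dtype=float) / (len(seq) - 1))
    return np.concatenate(out)


def _occurrence_index(q: float, n: int) -> int:
    # round-half-away-from-zero, floored at the first occurrence
    return max(1, int(np.floor(q * n + 0.5)))


def ctdd(seq: str, percent: bool = True) -> np.ndarray:
    """Distribution: per property and class, the sequence positions (as % of L)
    of the first, 25%, 50%, 75% and last occurrences of that class.

    A class absent from the sequence contributes five zeros.
    """
    if not seq:
        raise ValueError("empty sequence")
    scale = 100.0 if percent else 1.0
    out = []
    for part in tables.ctd_partitions():
        codes = np.asarray(part.encode(seq))
        for cls in range(3):
            pos = np.flatnonzero(codes == cls) + 1  # 1-based
            if pos.size == 0:
                out.extend([0.0] * 5)
                continue
            for q in (0.0, 0.25, 0.5, 0.75, 1.0):
                out.append(scale * pos[_occurrence_index(q, pos.size) - 1]
                           / len(seq))
    return np.asarray(out)


def ctd(seq: str) -> np.ndarray:
    """Concatenated composition + transition + distribution (7 properties)."""
    return np.concatenate([ctdc(seq), ctdt(seq), ctdd(seq)])


# --------------------------------------------------------------------------
# sequence-order descriptors
# --------------------------------------------------------------------------

def _tau(codes: np.ndarray, dist: np.ndarray, nlag: int) -> np.ndarray:
    taus = np.empty(nlag)
    for d in range(1, nlag + 1):
        taus[d - 1] = np.sum(dist[codes[:-d], codes[d:]] ** 2)
    return taus


def socnumber(seq: str, nlag: int = 30,
              matrices: Sequence[str] = tables.DISTANCE_MATRIX_NAMES) -> np.ndarray:
    """Sequence-order coupling numbers tau_d = sum_i d(s_i, s_{i+d})^2.

    One block of ``nlag`` lags per distance matrix, concatenated
    matrix-major; the two default matrices give the length 2 * nlag.
    """
    if len(seq) <= nlag:
        raise ValueError(f"sequence length {len(seq)} must exceed nlag={nlag}")
    codes = _encode(seq)
    return np.concatenate([
        _tau(codes, tables.distance_matrix(m).as_array(), nlag)
        for m in matrices])


def qsorder(seq: str, nlag: int = 5, w: float = 0.1,
            matrices: Sequence[str] = tables.DISTANCE_MATRIX_NAMES) -> np.ndarray:
    """Quasi-sequence-order descriptor.

    Per distance matrix: with residue counts f_r and coupling numbers
    tau_d, the joint normalizer is Z = sum_r f_r + w * sum_d tau_d; the
    block is [f_r / Z for the 20 residues] + [w * tau_d / Z for d=1..nlag].
    Each block therefore sums to 1.
    """
    if len(seq) <= nlag:
        raise ValueError(f"sequence length {len(seq)} must exceed nlag={nlag}")
    codes = _encode(seq)
    f = np.bincount(codes, minlength=20).astype(float)
    blocks = []
    for m in matrices:
        taus = _tau(codes, tables.distance_matrix(m).as_array(), nlag)
        z = f.sum() + w * taus.sum()
        blocks.append(np.concatenate([f / z, w * taus / z]))
    return np.concatenate(blocks)


# --------------------------------------------------------------------------
# autocorrelation
# --------------------------------------------------------------------------

#: residue property scales used by the autocorrelation descriptor:
#: Kyte-Doolittle hydropathy, Hopp-Woods hydrophilicity, residue volume,
#: residue mass, net charge at pH 7, aromaticity, Grantham polarity and
#: side-chain isoelectric point.  Scales are z-scored over the 20 residues
#: before use, so only relative differences matter.
AUTOCORR_SCALES: dict[str, dict[str, float]] = {
    "hydropathy": dict(A=1.8, R=-4.5, N=-3.5, D=-3.5, C=2.5, Q=-3.5, E=-3.5,
                       G=-0.4, H=-3.2, I=4.5, L=3.8, K=-3.9, M=1.9, F=2.8,
                       P=-1.6, S=-0.8, T=-0.7, W=-0.9, Y=-1.3, V=4.2),
    "hydrophilicity": dict(A=-0.5, R=3.0, N=0.2, D=3.0, C=-1.0, Q=0.2, E=3.0,
                           G=0.0, H=-0.5, I=-1.8, L=-1.8, K=3.0, M=-1.3,
                           F=-2.5, P=0.0, S=0.3, T=-0.4, W=-3.4, Y=-2.3,
                           V=-1.5),
    "volume": dict(A=88.6, R=173.4, N=114.1, D=111.1, C=108.5, Q=143.8,
                   E=138.4, G=60.1, H=153.2, I=166.7, L=166.7, K=168.6,
                   M=162.9, F=189.9, P=112.7, S=89.0, T=116.1, W=227.8,
                   Y=193.6, V=140.0),
    "mass": dict(A=71.08, R=156.19, N=114.10, D=115.09, C=103.14, Q=128.13,
                 E=129.12, G=57.05, H=137.14, I=113.16, L=113.16, K=128.17,
                 M=131.19, F=147.18, P=97.12, S=87.08, T=101.10, W=186.21,
                 Y=163.18, V=99.13),
    "charge": dict(A=0, R=1, N=0, D=-1, C=0, Q=0, E=-1, G=0, H=0.1, I=0,
                   L=0, K=1, M=0, F=0, P=0, S=0, T=0, W=0, Y=0, V=0),
    "aromaticity": dict(A=0, R=0, N=0, D=0, C=0, Q=0, E=0, G=0, H=1, I=0,
                        L=0, K=0, M=0, F=1, P=0, S=0, T=0, W=1, Y=1, V=0),
    "polarity": dict(A=8.1, R=10.5, N=11.6, D=13.0, C=5.5, Q=10.5, E=12.3,
                     G=9.0, H=10.4, I=5.2, L=4.9, K=11.3, M=5.7, F=5.2,
                     P=8.0, S=9.2, T=8.6, W=5.4, Y=6.2, V=5.9),
    "isoelectric": dict(A=6.00, R=10.76, N=5.41, D=2.77, C=5.07, Q=5.65,
                        E=3.22, G=5.97, H=7.59, I=6.02, L=5.98, K=9.74,
                        M=5.74, F=5.48, P=6.30, S=5.68, T=5.60, W=5.89,
                        Y=5.66, V=5.96),
}

AUTOCORR_KINDS = ("moreau_broto", "moran", "geary")


def _standardize(scale: dict[str, float]) -> np.ndarray:
    vals = np.array([scale[a] for a in ALPHABET], dtype=float)
    return (vals - vals.mean()) / vals.std()


def autocorrelation(seq: str,
                    properties: Sequence[str] = tuple(AUTOCORR_SCALES),
                    nlag: int = 19,
                    kinds: Sequence[str] = AUTOCORR_KINDS) -> np.ndarray:
    """Lagged autocorrelation statistics of property-encoded sequences.

    kind-major, then property-major, then lag order.  Moran and Geary
    statistics of a constant encoding (zero sample variance) are defined
    as 0 here rather than NaN.
    """
    if len(seq) <= nlag:
        raise ValueError(f"sequence length {len(seq)} must exceed nlag={nlag}")
    codes = _encode(seq)
    L = len(seq)
    out = []
    for kind in kinds:
        if kind not in AUTOCORR_KINDS:
            raise ValueError(f"unknown autocorrelation kind {kind!r}")
        for prop in properties:
            p = _standardize(AUTOCORR_SCALES[prop])[codes]
            pbar = p.mean()
            var = np.mean((p - pbar) ** 2)
            # constant encodings leave only round-off in the variance
            if var < 1e-15 * (np.abs(p).max() ** 2 + 1e-30):
                var = 0.0
            for d in range(1, nlag + 1):
                x, y = p[:-d], p[d:]
                if kind == "moreau_broto":
                    out.append(np.sum(x * y) / (L - d))
                elif kind == "moran":
                    if var == 0:
                        out.append(0.0)
                    else:
                        out.append((np.mean((x - pbar) * (y - pbar))) / var)
                else:  # geary
                    if var == 0:
                        out.append(0.0)
                    else:
                        denom = np.sum((p - pbar) ** 2) / (L - 1)
                        out.append(np.sum((x - y) ** 2) / (2 * (L - d)) / denom)
    return np.asarray(out)


# --------------------------------------------------------------------------
# registry
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class DescriptorSpec:
    """A named, parameterized descriptor with its expected vector length."""

    name: str
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.name not in _REGISTRY:
            raise KeyError(f"unknown descriptor {self.name!r}; "
                           f"registered: {registry_names()}")
        entry = _REGISTRY[self.name]
        unknown = set(self.params) - set(entry.defaults)
        if unknown:
            raise KeyError(f"{self.name}: unknown parameters {sorted(unknown)}; "
                           f"valid: {sorted(entry.defaults)}")

    @property
    def resolved(self) -> dict:
        return {**_REGISTRY[self.name].defaults, **self.params}

    @property
    def expected_length(self) -> int:
        return _REGISTRY[self.name].length(**self.resolved)

    def compute(self, seq: str) -> np.ndarray:
        vec = _REGISTRY[self.name].func(seq, **self.resolved)
        if vec.shape != (self.expected_length,):
            raise AssertionError(
                f"{self.name}: got length {vec.size}, expected "
                f"{self.expected_length}")
        return vec

    def feature_names(self) -> list[str]:
        entry = _REGISTRY[self.name]
        if entry.namer is not None:
            suffixes = entry.namer(**self.resolved)
        else:
            suffixes = [str(i + 1) for i in range(self.expected_length)]
        return [f"{self.name}.{s}" for s in suffixes]


@dataclass(frozen=True)
class _Entry:
    func: Callable
    defaults: dict
    length: Callable[..., int]
    namer: Callable[..., list[str]] | None = None


def _alph(name: str | None) -> tables.GroupedAlphabet | None:
    return None if name is None else tables.grouped_alphabet(name)


def _comp_names(alphabet=None, **_):
    return _symbols(_alph(alphabet))


def _part_names(k=3, alphabet=None, **_):
    syms = _symbols(_alph(alphabet))
    return [f"p{i + 1}.{s}" for i in range(k) for s in syms]


def _segment_names(alphabet=None, **_):
    syms = _symbols(_alph(alphabet))
    return [f"{seg}.{s}" for seg in ("nt", "mid", "ct") for s in syms]


def _kmer_names(k=3, alphabet=None, **_):
    syms = _symbols(_alph(alphabet))
    return ["".join(t) for t in product(syms, repeat=k)]


def _pair_names(alphabet=None, **_):
    syms = _symbols(_alph(alphabet))
    return [f"{x}{y}" for x in syms for y in syms]


def _ctd_suffixes(parts):
    names = []
    for part in tables.ctd_partitions():
        for suffix in parts(part):
            names.append(f"{part.name}.{suffix}")
    return names


def _ctdc_names(**_):
    return _ctd_suffixes(lambda p: ["c1", "c2", "c3"])


def _ctdt_names(**_):
    return _ctd_suffixes(lambda p: ["t12", "t13", "t23"])


def _ctdd_names(**_):
    return _ctd_suffixes(lambda p: [f"c{c}.q{q}" for c in (1, 2, 3)
                                    for q in (0, 25, 50, 75, 100)])


def _soc_names(nlag=30, matrices=tables.DISTANCE_MATRIX_NAMES, **_):
    return [f"{m}.lag{d}" for m in matrices for d in range(1, nlag + 1)]


def _qso_names(nlag=5, matrices=tables.DISTANCE_MATRIX_NAMES, **_):
    out = []
    for m in matrices:
        out.extend(f"{m}.{a}" for a in ALPHABET)
        out.extend(f"{m}.lag{d}" for d in range(1, nlag + 1))
    return out


def _autocorr_names(properties=tuple(AUTOCORR_SCALES), nlag=19,
                    kinds=AUTOCORR_KINDS, **_):
    return [f"{k}.{p}.lag{d}" for k in kinds for p in properties
            for d in range(1, nlag + 1)]


def _wrap_grouped(func):
    def inner(seq, alphabet=None, **kw):
        return func(seq, alphabet=_alph(alphabet), **kw)
    return inner


_REGISTRY: dict[str, _Entry] = {}


def _register(name, func, defaults, length, namer=None):
    _REGISTRY[name] = _Entry(func, defaults, length, namer)


def _alen(alphabet=None, **_):
    return 20 if alphabet is None else tables.grouped_alphabet(alphabet).g


_G8 = tables.DEFAULT_GROUPED

_register("AAC", _wrap_grouped(aac), dict(alphabet=None),
          lambda **kw: _alen(**kw), _comp_names)
_register("AAKpart", _wrap_grouped(aak_part_composition),
          dict(k=3, alphabet=None),
          lambda k=3, **kw: k * _alen(**kw), _part_names)
_register("SAAC", _wrap_grouped(saac), dict(nt=5, ct=5, alphabet=None),
          lambda **kw: 3 * _alen(**kw), _segment_names)
_register("SGAAC", _wrap_grouped(saac), dict(nt=5, ct=5, alphabet=_G8),
          lambda **kw: 3 * _alen(**kw), _segment_names)
_register("kAAComposition", _wrap_grouped(kmer_composition),
          dict(k=3, alphabet=None),
          lambda k=3, **kw: _alen(**kw) ** k, _kmer_names)
_register("kGAAComposition", _wrap_grouped(kmer_composition),
          dict(k=3, alphabet=_G8),
          lambda k=3, **kw: _alen(**kw) ** k, _kmer_names)
_register("CkSAApair", _wrap_grouped(cks_pair), dict(gap=1, alphabet=None),
          lambda **kw: _alen(**kw) ** 2, _pair_names)
_register("CkSGAApair", _wrap_grouped(cks_pair), dict(gap=1, alphabet=_G8),
          lambda **kw: _alen(**kw) ** 2, _pair_names)
_register("DDE", _wrap_grouped(dde), dict(alphabet=None),
          lambda **kw: _alen(**kw) ** 2, _pair_names)
_register("GrpDDE", _wrap_grouped(dde), dict(alphabet=_G8),
          lambda **kw: _alen(**kw) ** 2, _pair_names)
_register("CTDC", lambda seq: ctdc(seq), {}, lambda: 21, _ctdc_names)
_register("CTDT", lambda seq: ctdt(seq), {}, lambda: 21, _ctdt_names)
_register("CTDD", lambda seq: ctdd(seq), {}, lambda: 105, _ctdd_names)
_register("CTD", lambda seq: ctd(seq), {}, lambda: 147,
          lambda **kw: (_ctdc_names() + _ctdt_names() + _ctdd_names()))
_register("SOCNumber", socnumber,
          dict(nlag=30, matrices=tables.DISTANCE_MATRIX_NAMES),
          lambda nlag=30, matrices=tables.DISTANCE_MATRIX_NAMES, **_:
          len(matrices) * nlag, _soc_names)
_register("QSOrder", qsorder,
          dict(nlag=5, w=0.1, matrices=tables.DISTANCE_MATRIX_NAMES),
          lambda nlag=5, matrices=tables.DISTANCE_MATRIX_NAMES, **_:
          len(matrices) * (20 + nlag), _qso_names)
_register("AAutoCor", autocorrelation,
          dict(properties=tuple(AUTOCORR_SCALES), nlag=19,
               kinds=AUTOCORR_KINDS),
          lambda properties=tuple(AUTOCORR_SCALES), nlag=19,
          kinds=AUTOCORR_KINDS, **_: len(properties) * nlag * len(kinds),
          _autocorr_names)

for _typ, (_a, _k) in tables.psekraac_defaults().items():
    _register(f"PseKRAAC-{_typ}",
              lambda seq, alphabet, k: reduced_ktuple(
                  seq, tables.grouped_alphabet(alphabet), k),
              dict(alphabet=_a, k=_k),
              lambda alphabet, k: tables.grouped_alphabet(alphabet).g ** k,
              lambda alphabet, k: _kmer_names(k=k, alphabet=alphabet))


def registry_names() -> list[str]:
    return sorted(_REGISTRY)


def get_spec(name: str, **params) -> DescriptorSpec:
    """Look up a descriptor by registry name with parameter overrides."""
    return DescriptorSpec(name, params)


def extract(spec: DescriptorSpec | str, dataset: LabeledDataset) -> pd.DataFrame:
    """Compute one descriptor for every protein in a dataset.

    Returns a proteins x features DataFrame (index = protein id, in
    dataset order).  A sequence violating the descriptor's precondition
    aborts the extraction with the offending protein named — padded or
    partial rows would silently corrupt downstream cross-validation.
    """
    if isinstance(spec, str):
        spec = get_spec(spec)
    rows = np.empty((len(dataset), spec.expected_length))
    for i, rec in enumerate(dataset):
        try:
            rows[i] = spec.compute(rec.sequence)
        except ValueError as exc:
            raise ValueError(f"{spec.name}: protein {rec.id!r}: {exc}") from exc
    frame = pd.DataFrame(rows, index=pd.Index(dataset.ids, name="id"),
                         columns=spec.feature_names())
    if not np.isfinite(frame.to_numpy()).all():
        raise AssertionError(f"{spec.name}: non-finite feature values")
    return frame
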