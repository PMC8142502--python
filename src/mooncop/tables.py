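"""Loaders for the plain-text data tables bundled under ``mooncop/data``.

Bundled tables: two residue-pair distance matrices (the Grantham 1974
difference matrix, and a physicochemical distance reconstructed from
hydropathy/hydrophilicity/volume scales that stands in for the
Schneider-Wrede matrix — see ``schneider_wrede_synthetic.tsv``), the
seven three-class physicochemical partitions used by the CTD descriptor,
reduced (grouped) amino-acid alphabets, synonymous-codon counts for DDE,
and per-type defaults for the reduced k-tuple family.  Each file's sha256
is pinned in ``data/checksums.tsv`` and verified on first load.
"""
from __future__ import annotations

import hashlib
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources
from pathlib import Path

import numpy as np

from .seqio import ALPHABET

_DATA = resources.files("mooncop") / "data"


def _read(name: str) -> str:
    text = (_DATA / name).read_text()
    expected = _checksums().get(name)
    digest = hashlib.sha256(text.encode()).hexdigest()
    if expected is not None and digest != expected:
        raise RuntimeError(f"data table {name} is corrupted "
                           f"(sha256 {digest} != {expected})")
    return text


@lru_cache(maxsize=1)
def _checksums() -> dict[str, str]:
    out = {}
    for line in (_DATA / "checksums.tsv").read_text().splitlines()[1:]:
        name, digest = line.split("\t")
        out[name] = digest
    return out


@dataclass(frozen=True)
class DistanceMatrix:
    """A 20x20 residue-pair distance table with zero diagonal."""

    name: str
    values: tuple  # 20x20, row/col in ALPHABET order

    def __call__(self, a: str, b: str) -> float:
        return self.values[ALPHABET.index(a)][ALPHABET.index(b)]

    def as_array(self) -> np.ndarray:
        return np.asarray(self.values, dtype=float)


@lru_cache(maxsize=None)
def distance_matrix(name: str) -> DistanceMatrix:
    """Load a bundled distance matrix: ``schneider_wrede`` or ``grantham``."""
    files = {"grantham": "grantham.tsv",
             "schneider_wrede": "schneider_wrede_synthetic.tsv"}
    if name not in files:
        raise KeyError(f"unknown distance matrix {name!r}; "
                       f"available: {sorted(files)}")
    lines = _read(files[name]).splitlines()
    header = lines[0].split("\t")[1:]
    assert header == list(ALPHABET)
    rows = []
    for line in lines[1:]:
        parts = line.split("\t")
        rows.append(tuple(float(v) for v in parts[1:]))
    mat = DistanceMatrix(name, tuple(rows))
    arr = mat.as_array()
    if arr.shape != (20, 20) or np.diag(arr).any() or not np.isfinite(arr).all():
        raise RuntimeError(f"distance matrix {name} violates its invariants")
    return mat


#: matrix names in the canonical concatenation order used by QSOrder/SOCNumber
DISTANCE_MATRIX_NAMES = ("schneider_wrede", "grantham")


@dataclass(frozen=True)
class GroupedAlphabet:
    """A partition of the 20 residues into ``g`` physicochemical groups."""

    name: str
    groups: tuple[str, ...]

    @property
    def g(self) -> int:
        return len(self.groups)

    @property
    def mapping(self) -> dict[str, int]:
        return {aa: i for i, grp in enumerate(self.groups) for aa in grp}

    def encode(self, seq: str) -> list[int]:
        m = self.mapping
        return [m[ch] for ch in seq]

    #: one-letter symbol per group, for feature naming
    @property
    def symbols(self) -> list[str]:
        return [grp[0] for grp in self.groups]


@lru_cache(maxsize=None)
def grouped_alphabet(name: str) -> GroupedAlphabet:
    table = {}
    for line in _read("grouped_alphabets.tsv").splitlines()[1:]:
        nm, groups = line.split("\t")
        table[nm] = tuple(groups.split("-"))
    if name not in table:
        raise KeyError(f"unknown grouped alphabet {name!r}; "
                       f"available: {sorted(table)}")
    alph = GroupedAlphabet(name, table[name])
    if sorted("".join(alph.groups)) != sorted(ALPHABET):
        raise RuntimeError(f"alphabet {name} does not partition the residues")
    return alph


DEFAULT_GROUPED = "murphy8"


@dataclass(frozen=True)
class PropertyPartition:
    name: str
    classes: tuple[str, str, str]

    def encode(self, seq: str) -> list[int]:
        m = {aa: i for i, cls in enumerate(self.classes) for aa in cls}
        return [m[ch] for ch in seq]


@lru_cache(maxsize=1)
def ctd_partitions() -> tuple[PropertyPartition, ...]:
    """The 7 three-class physicochemical partitions for CTD."""
    out = []
    for line in _read("ctd_partitions.tsv").splitlines()[1:]:
        name, c1, c2, c3 = line.split("\t")
        if sorted(c1 + c2 + c3) != sorted(ALPHABET):
            raise RuntimeError(f"CTD partition {name} is not a partition")
        out.append(PropertyPartition(name, (c1, c2, c3)))
    if len(out) != 7:
        raise RuntimeError("expected 7 CTD properties")
    return tuple(out)


@lru_cache(maxsize=1)
def codon_counts() -> dict[str, int]:
    """Synonymous-codon counts per residue (standard genetic code, sum 61)."""
    out = {}
    for line in _read("codon_counts.tsv").splitlines()[1:]:
        aa, n = line.split("\t")
        out[aa] = int(n)
    if sum(out.values()) != 61:
        raise RuntimeError("codon counts must sum to 61")
    return out


@lru_cache(maxsize=1)
def psekraac_defaults() -> dict[str, tuple[str, int]]:
    """Per-type (reduced alphabet, k) defaults for the reduced k-tuple family."""
    out = {}
    for line in _read("psekraac_defaults.tsv").splitlines()[1:]:
        typ, alph, k = line.split("\t")
        out[typ] = (alph, int(k))
    return out


def data_path() -> Path:
    """Filesystem location of the bundled tables (for documentation)."""
    return Path(str(_DATA))
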