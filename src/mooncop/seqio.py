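"""Reading, validating and labelling protein sequences, plus tabular I/O.

Sequences are restricted to the 20 canonical residues; how non-canonical
characters are handled is an explicit, configurable policy because the
downstream descriptors are defined only on the 20-letter alphabet.
"""
from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Literal

import pandas as pd
from Bio import SeqIO as _BioSeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
_ALPHASET = frozenset(ALPHABET)

MP = "MP"
NONMP = "NONMP"
UNKNOWN = "UNKNOWN"
LABELS = (MP, NONMP, UNKNOWN)

#: replacements applied under the ``map_x`` sanitization policy
AMBIGUOUS_MAP = {"B": "N", "Z": "Q", "U": "C", "O": "K", "J": "L"}

Policy = Literal["strict", "drop", "map_x"]


class SequenceError(ValueError):
    """Raised for sequences that violate the 20-letter alphabet contract."""


def sanitize_sequence(raw: str, policy: Policy = "map_x", x_to: str = "A") -> str:
    """Normalize a raw sequence string to the canonical 20-letter alphabet.

    Case is folded and whitespace removed first.  Under ``strict`` any
    remaining non-canonical character is an error; ``drop`` removes such
    characters; ``map_x`` substitutes the conventional ambiguity codes
    (B->N, Z->Q, U->C, O->K, J->L) and maps X (and anything else) to
    ``x_to``.
    """
    if not isinstance(raw, str) or not raw:
        raise SequenceError("empty sequence")
    seq = "".join(raw.upper().split())
    if policy == "strict":
        for i, ch in enumerate(seq):
            if ch not in _ALPHASET:
                raise SequenceError(
                    f"non-canonical residue {ch!r} at position {i + 1}")
        out = seq
    elif policy == "drop":
        out = "".join(ch for ch in seq if ch in _ALPHASET)
    elif policy == "map_x":
        out = "".join(
            ch if ch in _ALPHASET else AMBIGUOUS_MAP.get(ch, x_to)
            for ch in seq)
    else:
        raise ValueError(f"unknown sanitization policy {policy!r}")
    if not out:
        raise SequenceError("sequence empty after sanitization")
    return out


@dataclass(frozen=True)
class ProteinRecord:
    """A single validated protein sequence with an optional class label."""

    id: str
    sequence: str
    label: str = UNKNOWN
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("protein id must be non-empty")
        if self.label not in LABELS:
            raise ValueError(f"label must be one of {LABELS}, got {self.label!r}")
        if not self.sequence or set(self.sequence) - _ALPHASET:
            bad = sorted(set(self.sequence) - _ALPHASET)
            raise SequenceError(
                f"record {self.id!r}: invalid sequence (offending: {bad})"
                if self.sequence else f"record {self.id!r}: empty sequence")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class LabeledDataset:
    """An ordered, id-unique collection of :class:`ProteinRecord`."""

    records: list[ProteinRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for rec in self.records:
            if rec.id in seen:
                raise ValueError(f"duplicate protein id {rec.id!r}")
            seen.add(rec.id)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[ProteinRecord]:
        return iter(self.records)

    def __getitem__(self, pid: str) -> ProteinRecord:
        for rec in self.records:
            if rec.id == pid:
                return rec
        raise KeyError(pid)

    @property
    def ids(self) -> list[str]:
        return [rec.id for rec in self.records]

    @property
    def labels(self) -> dict[str, str]:
        return {rec.id: rec.label for rec in self.records}

    @property
    def class_counts(self) -> dict[str, int]:
        return dict(Counter(rec.label for rec in self.records))

    def subset(self, ids: Iterable[str]) -> "LabeledDataset":
        keep = set(ids)
        missing = keep - set(self.ids)
        if missing:
            raise KeyError(f"ids not in dataset: {sorted(missing)}")
        return LabeledDataset([r for r in self.records if r.id in keep])

    def remove(self, ids: Iterable[str]) -> "LabeledDataset":
        drop = set(ids)
        return LabeledDataset([r for r in self.records if r.id not in drop])

    def require_trainable(self, min_per_class: int = 2) -> None:
        counts = self.class_counts
        for lab in (MP, NONMP):
            if counts.get(lab, 0) < min_per_class:
                raise ValueError(
                    f"need at least {min_per_class} {lab} records, "
                    f"got {counts.get(lab, 0)}")

    def __add__(self, other: "LabeledDataset") -> "LabeledDataset":
        return LabeledDataset(self.records + other.records)


def read_fasta(path: str | Path, label: str = UNKNOWN,
               policy: Policy = "map_x") -> LabeledDataset:
    """Read a FASTA file, assigning every record the given class label.

    The header token up to the first whitespace becomes the record id, the
    remainder the description.  Sequences are sanitized under ``policy``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records = []
    for rec in _BioSeqIO.parse(str(path), "fasta"):
        try:
            seq = sanitize_sequence(str(rec.seq), policy=policy)
        except SequenceError as exc:
            raise SequenceError(f"record {rec.id!r}: {exc}") from exc
        desc = rec.description[len(rec.id):].strip() if rec.description else ""
        records.append(ProteinRecord(rec.id, seq, label, desc))
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return LabeledDataset(records)


def read_labeled_fasta(mp_path: str | Path, nonmp_path: str | Path,
                       policy: Policy = "map_x") -> LabeledDataset:
    """Read the two-file layout: one FASTA per class."""
    return read_fasta(mp_path, MP, policy) + read_fasta(nonmp_path, NONMP, policy)


def write_fasta(dataset: LabeledDataset, path: str | Path) -> None:
    recs = [SeqRecord(Seq(r.sequence), id=r.id, description=r.description)
            for r in dataset]
    _BioSeqIO.write(recs, str(path), "fasta-2line")


def write_table(frame: pd.DataFrame, path: str | Path, sep: str = "\t") -> None:
    """Write a feature matrix or prediction log as delimited text.

    The index (protein ids) becomes the first column.  Non-finite values
    are refused: silently stored NaN/inf would corrupt downstream CV.
    """
    numeric = frame.select_dtypes("number")
    bad = ~numeric.apply(lambda c: c.map(lambda v: math.isfinite(v)))
    if bad.any().any():
        col = bad.any()[bad.any()].index[0]
        row = bad[col][bad[col]].index[0]
        raise ValueError(f"non-finite value at row {row!r}, column {col!r}")
    frame.to_csv(path, sep=sep, index=True, index_label=frame.index.name or "id")


def read_table(path: str | Path, sep: str = "\t") -> pd.DataFrame:
    frame = pd.read_csv(path, sep=sep, index_col=0)
    frame.index = frame.index.astype(str)
    return frame
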