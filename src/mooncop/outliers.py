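"""Candidate-outlier-protein (COP) detection from repeated-CV miss counts.

A protein that lands in the validation fold of every one of R repeated
cross-validation rounds and is misclassified in at least ``threshold``
of them (default 90 of 100) is flagged as a candidate outlier — either a
mislabelled record or a natural outlier lying far from its class.  The
module tallies per-protein miss counts from a prediction log, thresholds
them (inclusively by default, strictly as an option), summarizes a COP
set's class composition and always-missed fraction, combines COP sets
across descriptor x model cells, measures the effect of removing COPs,
and scores unlabelled candidate proteins by their average predicted
moonlighting probability over repeated refits.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import evalbench
from .descriptors import DescriptorSpec, extract, get_spec
from .evalbench import ClassifierConfig, FoldPlan, MetricSet, derive_seed
from .seqio import MP, NONMP, LabeledDataset, ProteinRecord


@dataclass(frozen=True)
class MisclassificationTally:
    """Per-protein count of repeats in which the protein was misclassified."""

    counts: dict[str, int]
    repeats: int

    def __post_init__(self) -> None:
        bad = {p: c for p, c in self.counts.items()
               if not 0 <= c <= self.repeats}
        if bad:
            raise ValueError(f"counts outside 0..{self.repeats}: {bad}")


def tally(log: pd.DataFrame) -> MisclassificationTally:
    """Count misclassified repeats per protein from a complete CV log."""
    per_protein = log.groupby("id", sort=False).size()
    repeats = log["repeat"].nunique()
    short = per_protein[per_protein != repeats]
    if len(short):
        raise ValueError(
            f"incomplete log: protein {short.index[0]!r} has "
            f"{short.iloc[0]} rows, expected {repeats}")
    misses = (~log["correct"]).groupby(log["id"], sort=False).sum()
    return MisclassificationTally(misses.to_dict(), repeats)


def detect_cops(t: MisclassificationTally, threshold: int = 90,
                inclusive: bool = True) -> set[str]:
    """Proteins misclassified at least (or, strictly, more than) ``threshold`` times."""
    if not 1 <= threshold <= t.repeats:
        raise ValueError(f"threshold must be in 1..{t.repeats}")
    if inclusive:
        return {p for p, c in t.counts.items() if c >= threshold}
    return {p for p, c in t.counts.items() if c > threshold}


@dataclass(frozen=True)
class COPReport:
    """Summary of one COP set: size, class composition, always-missed fraction."""

    descriptor: str
    model: str
    cops: frozenset[str]
    fraction_mp: float | None
    fraction_nonmp: float | None
    fm: float | None

    @property
    def frequency(self) -> int:
        return len(self.cops)

    def as_row(self) -> dict:
        return {"feature": self.descriptor, "classifier": self.model,
                "moonlight": self.fraction_mp, "non_mp": self.fraction_nonmp,
                "fm": self.fm, "frequency": self.frequency}


def cop_stats(cops, labels: dict[str, str], t: MisclassificationTally,
              descriptor: str = "", model: str = "") -> COPReport:
    """Class fractions of a COP set and the fraction missed in all R repeats."""
    cops = frozenset(cops)
    missing = cops - set(t.counts)
    if missing:
        raise KeyError(f"COPs not in tally: {sorted(missing)}")
    if not cops:
        return COPReport(descriptor, model, cops, None, None, None)
    n_mp = sum(1 for p in cops if labels[p] == MP)
    always = sum(1 for p in cops if t.counts[p] == t.repeats)
    n = len(cops)
    return COPReport(descriptor, model, cops, n_mp / n, (n - n_mp) / n,
                     always / n)


def combine_cops(sets, mode: str = "intersection") -> set[str]:
    """Combine COP sets across cells by exact intersection or union."""
    sets = [set(s) for s in sets]
    if not sets:
        raise ValueError("need at least one COP set")
    if mode == "intersection":
        return set.intersection(*sets)
    if mode == "union":
        return set.union(*sets)
    raise ValueError(f"mode must be intersection or union, got {mode!r}")


def cop_pipeline(dataset: LabeledDataset, spec: DescriptorSpec | str,
                 config: ClassifierConfig | str, repeats: int = 100,
                 folds: int = 10, seed: int = 0, threshold: int = 90,
                 inclusive: bool = True,
                 plan: FoldPlan | None = None
                 ) -> tuple[COPReport, MisclassificationTally, MetricSet]:
    """Run repeated CV on the full labelled dataset and flag COPs.

    Convenience wrapper chaining extract -> run_cv -> tally ->
    detect_cops -> cop_stats for one descriptor x model cell.
    """
    if isinstance(spec, str):
        spec = get_spec(spec)
    if isinstance(config, str):
        config = ClassifierConfig(config)
    dataset.require_trainable()
    feats = extract(spec, dataset)
    labels = dataset.labels
    if plan is None:
        plan = evalbench.make_fold_plan(dataset.ids, labels, repeats=repeats,
                                        folds=folds, seed=seed)
    log, metrics = evalbench.run_cv(feats, labels, config, plan, seed=seed)
    t = tally(log)
    cops = detect_cops(t, threshold=threshold, inclusive=inclusive)
    report = cop_stats(cops, labels, t, spec.name, config.family)
    return report, t, metrics


def remove_and_reevaluate(dataset: LabeledDataset, cops, spec, config,
                          repeats: int = 100, folds: int = 10,
                          seed: int = 0) -> tuple[MetricSet, MetricSet]:
    """Mean CV metrics before and after dropping the COPs from the dataset.

    Both runs use fresh fold plans built with the same repeat/fold/seed
    scheme.  Removal that leaves a class too small to stratify into
    ``folds`` folds is an error rather than a silently degenerate run.
    """
    cops = set(cops)
    unknown = cops - set(dataset.ids)
    if unknown:
        raise KeyError(f"COPs not in dataset: {sorted(unknown)}")
    reduced = dataset.remove(cops)
    counts = reduced.class_counts
    for lab in (MP, NONMP):
        if counts.get(lab, 0) < folds:
            raise ValueError(
                f"removing COPs leaves class {lab} with "
                f"{counts.get(lab, 0)} < {folds} proteins")
    def _cv(ds: LabeledDataset) -> MetricSet:
        s = get_spec(spec) if isinstance(spec, str) else spec
        c = ClassifierConfig(config) if isinstance(config, str) else config
        feats = extract(s, ds)
        plan = evalbench.make_fold_plan(ds.ids, ds.labels, repeats=repeats,
                                        folds=folds, seed=seed)
        return evalbench.run_cv(feats, ds.labels, c, plan, seed=seed)[1]

    return _cv(dataset), _cv(reduced)


def score_candidates(train: LabeledDataset, candidates, spec="QSOrder",
                     config: ClassifierConfig | str = "NB",
                     repeats: int = 100, seed: int = 0,
                     resample: bool = True) -> pd.DataFrame:
    """Average moonlighting probability of unlabelled candidates over R refits.

    Each repeat refits the classifier on a bootstrap resample of the
    training set (resampling supplies the repeat-to-repeat variability
    that deterministic families otherwise lack; disable with
    ``resample=False``) and predicts each candidate's positive-class
    probability.  Returns per-candidate mean and standard deviation.
    """
    if isinstance(spec, str):
        spec = get_spec(spec)
    if isinstance(config, str):
        config = ClassifierConfig(config)
    train.require_trainable()
    if isinstance(candidates, LabeledDataset):
        candidates = list(candidates.records)
    if not candidates:
        raise ValueError("no candidate proteins given")
    cand_ds = LabeledDataset([ProteinRecord(c.id, c.sequence)
                              for c in candidates])

    feats = extract(spec, train)
    Xc = extract(spec, cand_ds).to_numpy()
    y = np.array([train.labels[i] for i in feats.index])
    X = feats.to_numpy()

    probe = config.build(0)
    model = probe[-1] if hasattr(probe, "steps") else probe
    if not hasattr(model, "predict_proba"):
        raise ValueError(f"{config.family} does not produce class probabilities")

    probs = np.empty((repeats, len(cand_ds)))
    for r in range(repeats):
        rng = np.random.default_rng(derive_seed(seed, 4, r))
        if resample:
            while True:  # bootstrap must keep both classes
                idx = rng.integers(0, len(y), size=len(y))
                if len(np.unique(y[idx])) == 2:
                    break
        else:
            idx = np.arange(len(y))
        est = config.build(derive_seed(seed, 5, r))
        est.fit(X[idx], y[idx])
        pos_col = list(est.classes_).index(evalbench.POSITIVE)
        probs[r] = est.predict_proba(Xc)[:, pos_col]
    return pd.DataFrame(
        {"mean_probability": probs.mean(axis=0), "sd": probs.std(axis=0)},
        index=pd.Index(cand_ds.ids, name="id"))
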