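"""Evaluation statistics for community-profiling benchmarks.

L2 distance between estimated and expected abundance vectors, Bray-Curtis
dissimilarity, rarefaction of species richness, taxonomic entropy of a label
set, and correctly/mis/not-assigned read accounting against a ground truth.

L2 defaults to the root of the summed squared differences on percentage-
scale vectors; the plain sum of squares is available as a mode, since both
conventions circulate for abundance-vector comparisons.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .io import strip_gtdb_suffix
from .profiler import ReadAssignment

__all__ = [
    "AbundanceVector",
    "AssignmentEvaluation",
    "l2_distance",
    "bray_curtis",
    "rarefaction_curve",
    "taxonomic_entropy",
    "evaluate_assignments",
]


@dataclass(frozen=True)
class AbundanceVector:
    """Labelled non-negative abundance values (percent or fraction scale)."""

    taxa: tuple[str, ...]
    values: tuple[float, ...]
    percent_scale: bool = True

    def __post_init__(self) -> None:
        if len(self.taxa) != len(self.values):
            raise ValueError("taxa and values must have equal length")
        if any(not math.isfinite(v) for v in self.values):
            raise ValueError("abundance values must be finite")

    @classmethod
    def from_mapping(cls, m: Mapping[str, float], percent_scale: bool = True) -> "AbundanceVector":
        items = sorted(m.items())
        return cls(tuple(k for k, _ in items), tuple(float(v) for _, v in items), percent_scale)

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.taxa, self.values))


def _align(p: AbundanceVector, q: AbundanceVector) -> tuple[np.ndarray, np.ndarray]:
    """Align two vectors on the union of their taxa; missing taxa are 0."""
    taxa = sorted(set(p.taxa) | set(q.taxa))
    pd, qd = p.as_dict(), q.as_dict()
    return (
        np.array([pd.get(t, 0.0) for t in taxa]),
        np.array([qd.get(t, 0.0) for t in taxa]),
    )


def l2_distance(
    estimated: AbundanceVector, expected: AbundanceVector, mode: str = "root_sum_sq"
) -> float:
    """Distance between estimated and expected abundances.

    ``sum_sq`` is sum_i (estimated_i - expected_i)^2; ``root_sum_sq`` (the
    default) is its square root, i.e. the Euclidean norm of the difference.
    """
    if mode not in ("sum_sq", "root_sum_sq"):
        raise ValueError(f"unknown mode {mode!r}")
    a, b = _align(estimated, expected)
    if (a < 0).any() or (b < 0).any():
        raise ValueError("abundance values must be non-negative")
    ss = float(((a - b) ** 2).sum())
    return ss if mode == "sum_sq" else math.sqrt(ss)


def bray_curtis(p: AbundanceVector, q: AbundanceVector) -> float:
    """Bray-Curtis dissimilarity: sum|p - q| / sum(p + q) on the taxon union."""
    a, b = _align(p, q)
    if (a < 0).any() or (b < 0).any():
        raise ValueError("abundance values must be non-negative")
    denom = float((a + b).sum())
    if denom == 0:
        raise ValueError("both vectors are all-zero")
    return float(np.abs(a - b).sum()) / denom


def rarefaction_curve(
    read_taxa: Sequence[str],
    depths: Sequence[int],
    n_reps: int = 100,
    seed: int = 0,
    ci: float = 95.0,
) -> list[tuple[int, float, tuple[float, float]]]:
    """Mean distinct-species richness when subsampling reads without
    replacement, with a percentile confidence band per depth."""
    labels = np.asarray(read_taxa, dtype=object)
    n = labels.size
    rng = np.random.default_rng(seed)
    lo_pct, hi_pct = (100 - ci) / 2, 100 - (100 - ci) / 2
    out = []
    for depth in depths:
        if depth > n:
            raise ValueError(f"depth {depth} exceeds total reads {n}")
        rich = np.array(
            [len(set(rng.choice(labels, size=depth, replace=False))) for _ in range(n_reps)],
            dtype=float,
        )
        out.append(
            (int(depth), float(rich.mean()),
             (float(np.percentile(rich, lo_pct)), float(np.percentile(rich, hi_pct))))
        )
    return out


def taxonomic_entropy(labels: Iterable[str], base: float = math.e) -> float:
    """Shannon entropy -sum f log f of label frequencies (natural log by
    default), measuring richness and evenness jointly."""
    counts = Counter(labels)
    if not counts:
        raise ValueError("empty label set")
    total = sum(counts.values())
    h = -sum((c / total) * math.log(c / total) for c in counts.values())
    return h / math.log(base)


@dataclass(frozen=True)
class AssignmentEvaluation:
    correctly_assigned: int
    misassigned: int
    not_assigned: int

    @property
    def total(self) -> int:
        return self.correctly_assigned + self.misassigned + self.not_assigned

    def percentages(self) -> tuple[float, float, float]:
        t = self.total
        return tuple(100.0 * c / t for c in (self.correctly_assigned, self.misassigned, self.not_assigned))


def evaluate_assignments(
    truth: Mapping[str, str], predicted: Iterable[ReadAssignment]
) -> AssignmentEvaluation:
    """Score read assignments against true species labels.

    Species names are compared after GTDB suffix stripping and without rank
    prefixes. Any non-assigned status (filtered, no hit, length-removed)
    counts as not assigned.
    """
    correct = wrong = missing = 0
    for a in predicted:
        if a.read_id not in truth:
            raise KeyError(f"read {a.read_id!r} absent from truth table")
        if a.status != "assigned":
            missing += 1
            continue
        pred = strip_gtdb_suffix(a.lineage.species.removeprefix("s__"))
        true = strip_gtdb_suffix(truth[a.read_id].removeprefix("s__"))
        if pred == true:
            correct += 1
        else:
            wrong += 1
    return AssignmentEvaluation(correct, wrong, missing)
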