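"""Partitioning the observed proteome into aggregation fractions.

Five mutually exclusive labels, derived from the aggregate-fraction
differential results plus the whole-cell lysate (WCL) detection list:

- ``increased`` / ``decreased``: proteins called up / down by the
  differential-aggregation stage;
- ``baseline``: proteins detected in at least two replicates of both treated
  and untreated aggregate fractions whose abundance there is statistically
  unchanged (adjusted p > alpha) — the cell line's constitutive aggregome;
- ``other_aggregate``: proteins seen in the aggregate fraction that satisfy
  neither rule (e.g. single-replicate detections);
- ``nia`` ("not identified as aggregating"): proteins found only in the WCL
  and never in any aggregate fraction; the usual enrichment background.

A protein meeting both a call and the baseline criteria keeps the call.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .diffagg import CALL_DOWN, CALL_UP
from .errors import InternalError

LABEL_INCREASED = "increased"
LABEL_DECREASED = "decreased"
LABEL_BASELINE = "baseline"
LABEL_OTHER = "other_aggregate"
LABEL_NIA = "nia"
ALL_LABELS = (LABEL_INCREASED, LABEL_DECREASED, LABEL_BASELINE, LABEL_OTHER, LABEL_NIA)


@dataclass
class FractionLabels:
    """id -> label map plus the experiments it was derived from."""

    labels: pd.Series
    provenance: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        bad = set(self.labels.unique()) - set(ALL_LABELS)
        if bad:
            raise InternalError(f"unknown fraction labels: {sorted(bad)}")
        if self.labels.index.duplicated().any():
            raise InternalError("a protein was assigned more than one label")

    def ids(self, label: str) -> frozenset[str]:
        return frozenset(self.labels.index[self.labels == label])

    def counts(self) -> dict[str, int]:
        return {label: int((self.labels == label).sum()) for label in ALL_LABELS}


@dataclass(frozen=True)
class OverlapSummary:
    size_a: int
    size_b: int
    intersection_size: int

    def __post_init__(self) -> None:
        if self.intersection_size > min(self.size_a, self.size_b):
            raise InternalError("intersection larger than a constituent set")

    @property
    def fraction_of_a(self) -> float:
        return self.intersection_size / self.size_a if self.size_a else 0.0

    @property
    def fraction_of_b(self) -> float:
        return self.intersection_size / self.size_b if self.size_b else 0.0


def define_nia(wcl_ids: Iterable[str], aggregate_ids_all_experiments: Iterable[str]) -> frozenset[str]:
    """Proteins identified only in the WCL, never in any aggregate fraction."""
    wcl = frozenset(wcl_ids)
    if not wcl:
        raise ValueError("WCL identifier set is empty")
    nia = wcl - frozenset(aggregate_ids_all_experiments)
    if not nia:
        warnings.warn("every WCL protein also appears in an aggregate fraction", stacklevel=2)
    return nia


def define_baseline(
    results: pd.DataFrame, min_reps: int = 2, alpha: float = 0.05
) -> frozenset[str]:
    """Constitutively aggregating proteins: detected in >= min_reps replicates
    of both conditions with adjusted p > alpha."""
    ok = (
        (results["n_detected_case"] >= min_reps)
        & (results["n_detected_control"] >= min_reps)
        & (results["p_adj"] > alpha)
    )
    return frozenset(results.index[ok])


def classify_fractions(
    results: pd.DataFrame,
    wcl_ids: Iterable[str],
    min_reps: int = 2,
    alpha: float = 0.05,
    provenance: Sequence[str] = (),
) -> FractionLabels:
    """Assign every WCL- or aggregate-detected protein exactly one label."""
    aggregate_detected = frozenset(
        results.index[(results["n_detected_case"] + results["n_detected_control"]) >= 1]
    )
    increased = frozenset(results.index[results["call"] == CALL_UP])
    decreased = frozenset(results.index[results["call"] == CALL_DOWN])
    baseline = define_baseline(results, min_reps=min_reps, alpha=alpha) - increased - decreased
    other = aggregate_detected - increased - decreased - baseline
    nia = define_nia(wcl_ids, aggregate_detected | increased | decreased)

    labels: dict[str, str] = {}
    for ids, label in (
        (increased, LABEL_INCREASED),
        (decreased, LABEL_DECREASED),
        (baseline, LABEL_BASELINE),
        (other, LABEL_OTHER),
        (nia, LABEL_NIA),
    ):
        for pid in ids:
            if pid in labels:
                raise InternalError(f"protein {pid!r} assigned two labels")
            labels[pid] = label
    series = pd.Series(labels, name="label")
    series.index.name = "id"
    return FractionLabels(labels=series.sort_index(), provenance=tuple(provenance))


def set_overlap(a: Iterable[str], b: Iterable[str]) -> OverlapSummary:
    """Exact intersection counts between two reconciled identifier sets."""
    sa, sb = frozenset(a), frozenset(b)
    return OverlapSummary(size_a=len(sa), size_b=len(sb), intersection_size=len(sa & sb))


def consistency_metric(replicate_sets: Sequence[Iterable[str]]) -> float:
    """Mean over ordered pairs (A, B), A != B, of |A n B| / |A|.

    A directional overlap measure for "how consistently do independent
    experiments recover the same aggregating proteins".
    """
    sets = [frozenset(s) for s in replicate_sets]
    if len(sets) < 2:
        raise ValueError("need >= 2 replicate sets")
    if any(not s for s in sets):
        raise ValueError("replicate sets must be nonempty")
    fractions = [
        len(a & b) / len(a) for i, a in enumerate(sets) for j, b in enumerate(sets) if i != j
    ]
    return float(sum(fractions) / len(fractions))


def overlap_report(named_sets: Mapping[str, Iterable[str]]) -> pd.DataFrame:
    """All pairwise overlap summaries as a tidy frame."""
    names = list(named_sets)
    rows = []
    for i, na in enumerate(names):
        for nb in names[i + 1 :]:
            ov = set_overlap(named_sets[na], named_sets[nb])
            rows.append(
                {
                    "set_a": na,
                    "set_b": nb,
                    "size_a": ov.size_a,
                    "size_b": ov.size_b,
                    "intersection": ov.intersection_size,
                    "fraction_of_a": ov.fraction_of_a,
                    "fraction_of_b": ov.fraction_of_b,
                }
            )
    return pd.DataFrame(rows)
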