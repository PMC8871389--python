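"""Supersaturation and phase-separation propensity scoring.

Supersaturation captures the idea that a protein's aggregation risk grows
with both its cellular concentration and its intrinsic aggregation
propensity.  We score it as

    sigma = log10(abundance + pseudocount) + z

where ``abundance`` is a normalized transcript (or protein) abundance such
as CPM and ``z`` is the aggregation-propensity score standardized against a
designated reference proteome (the whole-cell lysate).  The proteome-median
sigma of that reference defines the iso-sigma "diagonal"; proteins above it
are relatively supersaturated.

Propensity scores can be imported from dedicated predictors (TANGO, CamSol,
catGRANULE, PScore) via score tables, which are authoritative when present.
Two deliberately simple built-in windowed predictors are shipped as labelled
approximations for when no external scores are available: an aggregation
scale that rewards hydrophobic/beta-prone stretches and penalizes charge,
and an LLPS scale that rewards disorder-promoting composition and the
R/G/Y/F residues typical of condensate-forming low-complexity regions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .fractions import FractionLabels

DEFAULT_WINDOW = 7
PSCORE_THRESHOLD = 4.0  # conventional cutoff for high pi-pi LLPS propensity


def _load_scale(name: str) -> dict[str, float]:
    with resources.files("aggregome.data").joinpath(name).open("r") as fh:
        frame = pd.read_csv(fh, sep="\t")
    return dict(zip(frame["residue"], frame["value"].astype(float)))


def aggregation_scale() -> dict[str, float]:
    """Shipped per-residue aggregation-propensity scale."""
    return _load_scale("aggregation_scale.tsv")


def llps_scale() -> dict[str, float]:
    """Shipped per-residue LLPS-propensity scale."""
    return _load_scale("llps_scale.tsv")


@dataclass(frozen=True)
class PropensityProfile:
    identifier: str
    window_scores: np.ndarray  # one score per sequence window
    summary: float
    source: str
    window: int


def windowed_propensity(
    seq: str,
    scale: Mapping[str, float],
    window: int = DEFAULT_WINDOW,
    identifier: str = "",
    source: str = "builtin",
) -> PropensityProfile:
    """Sliding-window mean of per-residue scale values.

    The per-protein summary rewards both the intensity and the extent of
    high-scoring regions: mean of the positive window scores multiplied by
    the fraction of windows that are positive (0 if no window is positive).
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    if len(seq) < window:
        raise ValueError(f"sequence length {len(seq)} shorter than window {window}")
    unknown = {ch for ch in seq if ch not in scale}
    if unknown:
        warnings.warn(f"residues {sorted(unknown)} not in scale; scored 0", stacklevel=2)
    values = np.array([scale.get(ch, 0.0) for ch in seq], dtype=float)
    kernel = np.ones(window) / window
    scores = np.convolve(values, kernel, mode="valid")
    positive = scores[scores > 0]
    if positive.size:
        summary = float(positive.mean() * (positive.size / scores.size))
    else:
        summary = 0.0
    return PropensityProfile(
        identifier=identifier, window_scores=scores, summary=summary, source=source, window=window
    )


def aggregation_propensity_builtin(seq: str, window: int = DEFAULT_WINDOW) -> float:
    """Summary aggregation propensity under the shipped scale."""
    return windowed_propensity(seq, aggregation_scale(), window, source="builtin_agg").summary


def llps_propensity_builtin(seq: str, window: int = DEFAULT_WINDOW) -> float:
    """Summary LLPS propensity under the shipped scale."""
    return windowed_propensity(seq, llps_scale(), window, source="builtin_llps").summary


def zscore_normalize(
    scores: Mapping[str, float], reference_ids: Iterable[str]
) -> dict[str, float]:
    """Standardize all scores by the mean/SD of the reference subset."""
    ref = [scores[i] for i in reference_ids if i in scores]
    if len(ref) < 2:
        raise ValueError("reference set must contain >= 2 scored proteins")
    mean = float(np.mean(ref))
    sd = float(np.std(ref, ddof=1))
    if sd == 0:
        raise ValueError("reference scores have zero variance")
    return {i: (v - mean) / sd for i, v in scores.items()}


def supersaturation(z_propensity: float, transcript_abundance: float, pseudocount: float = 1.0) -> float:
    """sigma = log10(abundance + pseudocount) + z."""
    if transcript_abundance < 0:
        raise ValueError("abundance must be >= 0")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    return float(np.log10(transcript_abundance + pseudocount) + z_propensity)


def saturation_threshold(sigma_values_of_reference) -> float:
    """Median sigma of the reference proteome (ties by midpoint)."""
    values = np.asarray(list(sigma_values_of_reference), dtype=float)
    values = values[np.isfinite(values)]
    if values.size == 0:
        raise ValueError("no finite reference sigma values")
    return float(np.median(values))


def compute_supersaturation(
    propensity: Mapping[str, float],
    abundance: Mapping[str, float],
    reference_ids: Iterable[str],
    pseudocount: float = 1.0,
) -> tuple[pd.DataFrame, float]:
    """Per-protein sigma with the reference-median threshold tau.

    Only proteins with both a propensity score and an abundance are scored.
    Returns (frame indexed by id with columns z, log10_abundance, sigma,
    supersaturated) and tau.  ``supersaturated`` is sigma > tau, with tau the
    median sigma over the reference (WCL) subset.
    """
    reference_ids = frozenset(reference_ids)
    z = zscore_normalize(propensity, reference_ids)
    common = [i for i in z if i in abundance]
    if not common:
        raise ValueError("no proteins have both propensity and abundance")
    rows = {
        i: (z[i], float(np.log10(abundance[i] + pseudocount))) for i in common
    }
    frame = pd.DataFrame.from_dict(rows, orient="index", columns=["z", "log10_abundance"])
    frame.index.name = "id"
    frame["sigma"] = frame["z"] + frame["log10_abundance"]
    ref_sigma = frame.loc[frame.index.isin(reference_ids), "sigma"]
    tau = saturation_threshold(ref_sigma)
    frame["supersaturated"] = frame["sigma"] > tau
    return frame.sort_index(), tau


def fraction_score_summary(
    scores: Mapping[str, float],
    labels: FractionLabels,
    threshold: float | None = None,
) -> pd.DataFrame:
    """Per-fraction mean/median score (and share above a cutoff, e.g. the
    PScore > 4 convention).  Fractions with no scored protein are omitted
    with a warning."""
    rows = []
    for label in sorted(set(labels.labels)):
        ids = [i for i in labels.ids(label) if i in scores]
        if not ids:
            warnings.warn(f"fraction {label!r} has no scored proteins; omitted", stacklevel=2)
            continue
        vals = np.array([scores[i] for i in ids], dtype=float)
        row = {
            "fraction": label,
            "n": len(ids),
            "mean": float(vals.mean()),
            "median": float(np.median(vals)),
        }
        if threshold is not None:
            row["fraction_above_threshold"] = float(np.mean(vals > threshold))
            row["threshold"] = threshold
        rows.append(row)
    return pd.DataFrame(rows).set_index("fraction")
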