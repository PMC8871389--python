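"""Differential-aggregation calling from label-free intensities.

The stage mirrors the common post-processing of MaxQuant LFQ output for
SDS-insoluble (aggregate) fractions:

1. log2-transform present intensities, keeping non-detections as missing;
2. keep proteins identified in more than one replicate of either condition;
3. impute missing values from a downshifted Gaussian per sample column
   (missing-not-at-random model: non-detections sit in the low-intensity
   tail), repeating the draw ``n_draws`` times (default 100) and averaging
   the completed matrices cell-wise;
4. per-protein two-sided t-test on the averaged matrix (Student's pooled
   variance by default: with four replicates a side, per-group variance
   estimates are too noisy to be worth Welch's reduced degrees of freedom;
   Welch is available by flag), with Benjamini-Hochberg adjustment;
5. call a protein "up" when p_adj <= alpha, log2 fold change >= threshold
   and it was *detected* (not imputed) in at least ``min_nonimputed`` case
   replicates; "down" is the mirror image on the control side.

The fold change is mean(case) - mean(control) in log2 units.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import DesignError, FormatError, InternalError
from .io import ProteinGroupTable, SampleDesign

CALL_UP = "up"
CALL_DOWN = "down"
CALL_NS = "ns"


@dataclass(frozen=True)
class ImputationConfig:
    """Downshifted-Gaussian imputation parameters (sigma units are the
    observed per-sample standard deviation of log2 intensities)."""

    n_draws: int = 100
    downshift: float = 1.8
    width: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_draws < 1:
            raise ValueError("n_draws must be >= 1")
        if self.width <= 0:
            raise ValueError("width must be > 0")


@dataclass(frozen=True)
class DifferentialCallConfig:
    alpha: float = 0.05           # applied to BH-adjusted p
    lfc_threshold: float = 1.0    # log2 units
    min_nonimputed: int = 2       # detected replicates required on the called side
    min_identified_repeats: int = 2  # ">1 repeats" prefilter

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.lfc_threshold < 0 or self.min_nonimputed < 0:
            raise ValueError("thresholds must be >= 0")


@dataclass
class LogIntensityMatrix:
    """log2 intensities (NaN = missing) plus per-condition detection counts."""

    values: pd.DataFrame
    design: SampleDesign

    def __post_init__(self) -> None:
        if list(self.values.columns) != self.design.labels:
            raise DesignError("matrix columns must match design labels exactly")

    @property
    def mask(self) -> pd.DataFrame:
        """True where a value was observed."""
        return self.values.notna()

    def detection_counts(self) -> pd.DataFrame:
        """Per-protein counts of detected replicates per condition."""
        mask = self.mask
        return pd.DataFrame(
            {
                "n_detected_case": mask[self.design.case_labels].sum(axis=1).astype(int),
                "n_detected_control": mask[self.design.control_labels].sum(axis=1).astype(int),
            }
        )

    @property
    def is_complete(self) -> bool:
        return bool(self.mask.all().all())


def log2_transform(table: ProteinGroupTable, design: SampleDesign) -> LogIntensityMatrix:
    """log2-transform LFQ intensities for the samples in ``design``.

    A literal zero reaching this stage is an internal error: upstream
    ingestion stores non-detections as missing.
    """
    sub = table.intensities[design.labels]
    values = sub.to_numpy(dtype=float)
    if np.any(values == 0):
        raise InternalError("zero intensity reached log2_transform; zeros must be missing")
    out = pd.DataFrame(np.log2(values), index=sub.index, columns=sub.columns)
    return LogIntensityMatrix(values=out, design=design)


def prefilter_identified(matrix: LogIntensityMatrix, min_repeats: int = 2) -> LogIntensityMatrix:
    """Keep proteins detected in >= min_repeats replicates of either condition."""
    counts = matrix.detection_counts()
    keep = (counts["n_detected_case"] >= min_repeats) | (
        counts["n_detected_control"] >= min_repeats
    )
    return LogIntensityMatrix(values=matrix.values.loc[keep].copy(), design=matrix.design)


def impute_missing(matrix: LogIntensityMatrix, cfg: ImputationConfig) -> LogIntensityMatrix:
    """Averaged downshifted-Gaussian imputation.

    For draw ``d`` every missing cell in sample ``j`` is replaced by a draw
    from ``Normal(mu_j - downshift * sd_j, (width * sd_j)^2)`` where ``mu_j``
    and ``sd_j`` are the mean and SD of the *observed* log2 intensities in
    that sample.  The ``n_draws`` completed matrices are averaged cell-wise;
    observed cells are untouched.  The standard-normal deviate used for cell
    (i, j) in draw d is a pure function of (seed, d, i, j), so the result
    does not depend on which cells happen to be missing.

    Samples with fewer than two observed values fall back to the global mean
    and SD across all observed cells, with a warning.
    """
    values = matrix.values.to_numpy(dtype=float).copy()
    mask_missing = np.isnan(values)
    n, p = values.shape
    if not mask_missing.any() or n == 0:
        return LogIntensityMatrix(values=matrix.values.copy(), design=matrix.design)

    observed = np.where(mask_missing, np.nan, values)
    global_mu = float(np.nanmean(observed))
    global_sd = float(np.nanstd(observed, ddof=1))
    mu = np.empty(p)
    sd = np.empty(p)
    for j in range(p):
        col = observed[:, j]
        n_obs = int(np.sum(~np.isnan(col)))
        if n_obs < 2:
            warnings.warn(
                f"sample {matrix.values.columns[j]!r} has {n_obs} observed values; "
                "falling back to global statistics for imputation",
                stacklevel=2,
            )
            mu[j], sd[j] = global_mu, global_sd
        else:
            mu[j] = np.nanmean(col)
            sd[j] = np.nanstd(col, ddof=1)

    rng = np.random.default_rng(cfg.seed)
    # One deviate per (draw, row, column): averaging n_draws completions is
    # equivalent to imputing each cell with the mean of its n_draws draws.
    z = rng.standard_normal((cfg.n_draws, n, p)).mean(axis=0)
    imputed = mu - cfg.downshift * sd + cfg.width * sd * z
    values[mask_missing] = imputed[mask_missing]
    out = pd.DataFrame(values, index=matrix.values.index, columns=matrix.values.columns)
    return LogIntensityMatrix(values=out, design=matrix.design)


def differential_test(
    matrix: LogIntensityMatrix, design: SampleDesign | None = None, equal_var: bool = False
) -> pd.DataFrame:
    """Per-protein two-sided t-test of case vs control on a complete matrix.

    Welch's unequal-variance test by default; ``equal_var=True`` gives the
    classical Student test.  Returns mean_case, mean_control, log2fc
    (= mean_case - mean_control), t and p per protein.
    """
    design = design or matrix.design
    if not matrix.is_complete:
        raise InternalError("differential_test requires a complete (imputed) matrix")
    case = matrix.values[design.case_labels].to_numpy(dtype=float)
    ctrl = matrix.values[design.control_labels].to_numpy(dtype=float)
    if case.shape[1] < 2 or ctrl.shape[1] < 2:
        raise DesignError("need >= 2 replicates per condition for t-tests")
    with np.errstate(invalid="ignore", divide="ignore"):
        t, p = stats.ttest_ind(case, ctrl, axis=1, equal_var=equal_var)
    mean_case = case.mean(axis=1)
    mean_ctrl = ctrl.mean(axis=1)
    # Degenerate rows: zero variance on both sides.
    degenerate = np.isnan(t)
    same = degenerate & np.isclose(mean_case, mean_ctrl)
    diff = degenerate & ~np.isclose(mean_case, mean_ctrl)
    with np.errstate(invalid="ignore"):
        t = np.where(same, 0.0, t)
        p = np.where(same, 1.0, p)
        t = np.where(diff, np.sign(mean_case - mean_ctrl) * np.inf, t)
        p = np.where(diff, 0.0, p)
    return pd.DataFrame(
        {
            "mean_case": mean_case,
            "mean_control": mean_ctrl,
            "log2fc": mean_case - mean_ctrl,
            "t": t,
            "p": p,
        },
        index=matrix.values.index,
    )


def adjust_bh(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (clipped to 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_differential(
    results: pd.DataFrame,
    detection: pd.DataFrame,
    cfg: DifferentialCallConfig = DifferentialCallConfig(),
) -> pd.DataFrame:
    """Apply the replicate-gated up/down call rule.

    up:   p_adj <= alpha AND log2fc >= lfc_threshold AND detected in >=
          min_nonimputed case replicates.
    down: p_adj <= alpha AND log2fc <= -lfc_threshold AND detected in >=
          min_nonimputed control replicates.
    """
    if not results.index.equals(detection.index):
        raise InternalError("results and detection counts must be index-aligned")
    out = results.copy()
    out["n_detected_case"] = detection["n_detected_case"].to_numpy()
    out["n_detected_control"] = detection["n_detected_control"].to_numpy()
    sig = out["p_adj"] <= cfg.alpha
    up = sig & (out["log2fc"] >= cfg.lfc_threshold) & (out["n_detected_case"] >= cfg.min_nonimputed)
    down = (
        sig
        & (out["log2fc"] <= -cfg.lfc_threshold)
        & (out["n_detected_control"] >= cfg.min_nonimputed)
    )
    call = np.full(len(out), CALL_NS, dtype=object)
    call[up.to_numpy()] = CALL_UP
    call[down.to_numpy()] = CALL_DOWN
    out["call"] = call
    return out


def run_differential(
    table: ProteinGroupTable,
    design: SampleDesign,
    imputation: ImputationConfig = ImputationConfig(),
    calls: DifferentialCallConfig = DifferentialCallConfig(),
    equal_var: bool = True,
) -> pd.DataFrame:
    """End-to-end differential-aggregation analysis of one fraction.

    Returns one row per retained protein with columns mean_case,
    mean_control, log2fc, t, p, p_adj, n_detected_case, n_detected_control
    and call.
    """
    design.require_replicates(2)
    matrix = log2_transform(table, design)
    matrix = prefilter_identified(matrix, calls.min_identified_repeats)
    detection = matrix.detection_counts()
    complete = impute_missing(matrix, imputation)
    results = differential_test(complete, design, equal_var=equal_var)
    results["p_adj"] = adjust_bh(results["p"].to_numpy())
    return call_differential(results, detection, calls)
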