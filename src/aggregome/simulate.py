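"""Ground-truth proteome simulator with a threshold model of aggregation.

The generator operationalizes the view that genotoxic stress lowers a
cell-intrinsic aggregation threshold: each protein carries a supersaturation
score sigma = log10(abundance + 1) + z (abundance in CPM, z a standardized
intrinsic aggregation propensity), and aggregates in a condition with
probability logistic((sigma - tau) / steepness), where the treated
threshold tau_treated sits below the control threshold tau_control.  A
single latent uniform per protein couples the two conditions, so the
treated aggregator set contains the control set and "treatment gainers" are
exactly the proteins between the two thresholds that the lowered threshold
tips over.

Observation layers:

- LFQ intensity matrices for an aggregate fraction (case and control, n
  replicates each) and a whole-cell lysate (WCL) fraction.  log2 intensity
  is an affine function of log10 abundance plus replicate noise; proteins
  aggregating in a condition gain ``effect_size`` log2 units in that
  condition's aggregate fraction.  Each cell is detected with probability
  logistic((log2 intensity - midpoint) / slope) — the missing-not-at-random
  mechanism the imputation stage models.  The aggregate-fraction offset is
  set low so that non-aggregators sit below the detection midpoint and are
  mostly missing there, reproducing the presence/absence structure of real
  SDS-insoluble fractions, while the WCL offset keeps most proteins
  detected.
- Negative-binomial transcript counts with mean proportional to abundance
  times library size (expression is unaffected by treatment, matching the
  observation that the induced aggregation is not transcription-driven).
- Annotation sets with a planted odds multiplier for treatment gainers.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit

from .io import (
    CONDITION_CASE,
    CONDITION_CONTROL,
    FRACTION_AGGREGATE,
    FRACTION_WCL,
    GeneSet,
    GeneSetCollection,
    ProteinGroupTable,
    SampleDesign,
    SampleInfo,
    write_count_matrix,
    write_gene_sets_gmt,
    write_protein_groups,
    write_sample_design,
    write_score_table,
)

LOG2_10 = float(np.log2(10.0))


@dataclass(frozen=True)
class SimulationConfig:
    n_proteins: int = 2000
    n_replicates: int = 4
    # log10-CPM abundance distribution
    abundance_logmean: float = 1.5
    abundance_logsd: float = 1.0
    # intrinsic propensity z
    propensity_mean: float = 0.0
    propensity_sd: float = 1.0
    # aggregation threshold model (sigma units)
    tau_control: float = 3.5
    tau_treated: float = 2.8
    aggregation_steepness: float = 0.25
    # exact number of planted treatment gainers; None = purely probabilistic
    n_gainers: int | None = None
    # observation model: log2 intensity = offset + log2(10) * log10(ab + 1) + noise
    effect_size: float = 2.0
    wcl_log2_offset: float = 19.0
    aggregate_log2_offset: float = 15.0
    replicate_sd: float = 0.3
    missing_logistic_midpoint: float = 20.0
    missing_logistic_slope: float = 0.25
    # transcript counts
    nb_dispersion: float = 0.05
    library_size: int = 5_000_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_proteins < 1:
            raise ValueError("n_proteins must be >= 1")
        if self.aggregation_steepness <= 0:
            raise ValueError("steepness must be > 0")
        if min(self.abundance_logsd, self.propensity_sd, self.replicate_sd) <= 0:
            raise ValueError("standard deviations must be > 0")


def null_config(seed: int = 0, **overrides) -> SimulationConfig:
    """No treatment effect: equal thresholds and zero intensity shift."""
    base = SimulationConfig(seed=seed)
    return replace(base, tau_treated=base.tau_control, effect_size=0.0, n_gainers=None, **overrides)


def planted_config(seed: int = 0, n_gainers: int = 150, **overrides) -> SimulationConfig:
    """The planted-recovery scenario: a fixed number of treatment gainers."""
    return replace(SimulationConfig(seed=seed), n_gainers=n_gainers, **overrides)


def _protein_ids(n: int) -> pd.Index:
    return pd.Index([f"P{i:05d}" for i in range(1, n + 1)], name="id")


def simulate_proteome(cfg: SimulationConfig, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Draw the ground-truth proteome.

    Returns a frame indexed by protein id with columns abundance (CPM),
    propensity_z, sigma, aggregates_control, aggregates_treated.  A shared
    latent uniform per protein makes the aggregator sets nested whenever
    tau_treated <= tau_control.  With ``n_gainers`` set, exactly that many
    non-control-aggregators are tipped over in the treated condition,
    sampled with probability proportional to their logistic gain
    probability.
    """
    rng = rng or np.random.default_rng(cfg.seed)
    n = cfg.n_proteins
    log_ab = rng.normal(cfg.abundance_logmean, cfg.abundance_logsd, n)
    abundance = 10.0**log_ab
    z = rng.normal(cfg.propensity_mean, cfg.propensity_sd, n)
    sigma = np.log10(abundance + 1.0) + z
    p_control = expit((sigma - cfg.tau_control) / cfg.aggregation_steepness)
    p_treated = expit((sigma - cfg.tau_treated) / cfg.aggregation_steepness)
    u = rng.uniform(size=n)
    agg_control = u < p_control
    if cfg.n_gainers is None:
        agg_treated = u < p_treated
    else:
        candidates = np.flatnonzero(~agg_control)
        if cfg.n_gainers > candidates.size:
            raise ValueError("n_gainers exceeds the number of non-aggregating proteins")
        weights = np.clip(p_treated[candidates] - p_control[candidates], 0.0, None)
        if weights.sum() == 0:
            weights = np.ones_like(weights)
        chosen = rng.choice(
            candidates, size=cfg.n_gainers, replace=False, p=weights / weights.sum()
        )
        agg_treated = agg_control.copy()
        agg_treated[chosen] = True
    return pd.DataFrame(
        {
            "abundance": abundance,
            "propensity_z": z,
            "sigma": sigma,
            "aggregates_control": agg_control,
            "aggregates_treated": agg_treated,
        },
        index=_protein_ids(n),
    )


def treatment_gainers(truth: pd.DataFrame) -> frozenset[str]:
    gain = truth["aggregates_treated"] & ~truth["aggregates_control"]
    return frozenset(truth.index[gain])


def _detected(rng: np.random.Generator, log2_intensity: np.ndarray, cfg: SimulationConfig) -> np.ndarray:
    p = expit((log2_intensity - cfg.missing_logistic_midpoint) / cfg.missing_logistic_slope)
    return rng.uniform(size=log2_intensity.shape) < p


def simulate_lfq(
    truth: pd.DataFrame, cfg: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[ProteinGroupTable, SampleDesign]:
    """Simulate proteinGroups-style LFQ intensities for the aggregate
    (case + control) and WCL fractions, with MNAR missingness."""
    rng = rng or np.random.default_rng(cfg.seed + 1)
    n = len(truth)
    log_ab1 = np.log10(truth["abundance"].to_numpy() + 1.0)

    samples: list[SampleInfo] = []
    columns: dict[str, np.ndarray] = {}

    def add_samples(prefix: str, condition: str, fraction: str, base_log2: np.ndarray) -> None:
        for rep in range(1, cfg.n_replicates + 1):
            label = f"{prefix}_{rep}"
            noisy = base_log2 + rng.normal(0.0, cfg.replicate_sd, n)
            det = _detected(rng, noisy, cfg)
            linear = np.where(det, 2.0**noisy, np.nan)
            samples.append(
                SampleInfo(label=label, condition=condition, replicate=rep, fraction=fraction)
            )
            columns[label] = linear

    agg_base = cfg.aggregate_log2_offset + LOG2_10 * log_ab1
    case_shift = cfg.effect_size * truth["aggregates_treated"].to_numpy()
    ctrl_shift = cfg.effect_size * truth["aggregates_control"].to_numpy()
    add_samples("Agg_case", CONDITION_CASE, FRACTION_AGGREGATE, agg_base + case_shift)
    add_samples("Agg_ctrl", CONDITION_CONTROL, FRACTION_AGGREGATE, agg_base + ctrl_shift)
    wcl_base = cfg.wcl_log2_offset + LOG2_10 * log_ab1
    add_samples("WCL", CONDITION_CONTROL, FRACTION_WCL, wcl_base)

    meta = pd.DataFrame(index=truth.index.copy())
    meta.index.name = "group_id"
    meta["gene_symbols"] = [(f"G{pid[1:]}",) for pid in truth.index]
    meta["is_contaminant"] = False
    meta["is_reverse"] = False
    meta["razor_unique_peptides"] = 2
    intensities = pd.DataFrame(columns, index=meta.index)
    return ProteinGroupTable(meta=meta, intensities=intensities), SampleDesign(samples)


def simulate_counts(
    truth: pd.DataFrame,
    cfg: SimulationConfig,
    rng: np.random.Generator | None = None,
    n_samples: int | None = None,
) -> pd.DataFrame:
    """Negative-binomial transcript counts, mean = CPM / 1e6 * library size.

    Expression does not depend on treatment; columns are rna_1..rna_k
    (k defaults to n_replicates).
    """
    rng = rng or np.random.default_rng(cfg.seed + 2)
    k = n_samples if n_samples is not None else cfg.n_replicates
    mu = truth["abundance"].to_numpy() / 1e6 * cfg.library_size
    out = {}
    for j in range(1, k + 1):
        if cfg.nb_dispersion == 0:
            draws = rng.poisson(mu)
        else:
            r = 1.0 / cfg.nb_dispersion
            lam = rng.gamma(shape=r, scale=mu / r)
            draws = rng.poisson(lam)
        out[f"rna_{j}"] = draws
    frame = pd.DataFrame(out, index=truth.index.copy())
    frame.index.name = "gene"
    return frame


def simulate_annotations(
    truth: pd.DataFrame,
    enrichment_odds: float,
    set_size: int,
    rng: np.random.Generator | None = None,
    name: str = "planted_set",
    seed: int = 0,
) -> tuple[GeneSetCollection, float]:
    """Sample an annotation set with weight ``enrichment_odds`` on treatment
    gainers.  Returns the collection and the realized odds ratio
    (gainers vs the rest)."""
    if enrichment_odds <= 0:
        raise ValueError("enrichment_odds must be > 0")
    if set_size > len(truth):
        raise ValueError("set_size exceeds the number of proteins")
    rng = rng or np.random.default_rng(seed)
    gainers = truth["aggregates_treated"].to_numpy() & ~truth["aggregates_control"].to_numpy()
    weights = np.where(gainers, enrichment_odds, 1.0)
    idx = rng.choice(len(truth), size=set_size, replace=False, p=weights / weights.sum())
    member_mask = np.zeros(len(truth), dtype=bool)
    member_mask[idx] = True
    a = int(np.sum(member_mask & gainers))
    b = int(np.sum(~member_mask & gainers))
    c = int(np.sum(member_mask & ~gainers))
    d = int(np.sum(~member_mask & ~gainers))
    realized_or = (a * d) / (b * c) if b * c else float("inf")
    members = frozenset(truth.index[member_mask])
    collection = GeneSetCollection(
        [GeneSet(name=name, members=members, provenance=f"simulated, odds={enrichment_odds}")]
    )
    return collection, realized_or


def evaluate_recovery(calls: pd.DataFrame, truth: pd.DataFrame) -> dict[str, float]:
    """Score up-calls against the planted treatment gainers.

    sensitivity = true gainers called up / true gainers;
    empirical_fdr = false up-calls / up-calls (0 when nothing is called).
    Truth proteins absent from ``calls`` (e.g. prefiltered) count as missed.
    """
    gainers = treatment_gainers(truth)
    called_up = frozenset(calls.index[calls["call"] == "up"])
    n_true = len(gainers)
    n_called = len(called_up)
    tp = len(called_up & gainers)
    return {
        "sensitivity": tp / n_true if n_true else 0.0,
        "empirical_fdr": (n_called - tp) / n_called if n_called else 0.0,
        "n_true": n_true,
        "n_called": n_called,
    }


def simulate_dataset(cfg: SimulationConfig, outdir: str | Path) -> dict[str, str]:
    """Write a complete synthetic dataset (proteinGroups TSV, design TSV,
    counts TSV, imported-score TSV, GMT annotation, truth TSV and a JSON
    manifest).  Returns the path map."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    truth = simulate_proteome(cfg)
    table, design = simulate_lfq(truth, cfg)
    counts = simulate_counts(truth, cfg)
    annotations, realized_or = simulate_annotations(
        truth, enrichment_odds=5.0, set_size=max(10, cfg.n_proteins // 10),
        seed=cfg.seed + 3,
    )
    scores = pd.DataFrame({"tango": truth["propensity_z"]}, index=truth.index)

    paths = {
        "protein_groups": outdir / "proteinGroups.tsv",
        "design": outdir / "design.tsv",
        "counts": outdir / "counts.tsv",
        "scores": outdir / "scores.tsv",
        "gene_sets": outdir / "annotations.gmt",
        "truth": outdir / "truth.tsv",
        "manifest": outdir / "simulation.json",
    }
    write_protein_groups(table, paths["protein_groups"])
    write_sample_design(design, paths["design"])
    write_count_matrix(counts, paths["counts"])
    write_score_table(scores, paths["scores"])
    write_gene_sets_gmt(annotations, paths["gene_sets"])
    truth.to_csv(paths["truth"], sep="\t")
    manifest = {
        "config": asdict(cfg),
        "realized_annotation_odds_ratio": realized_or,
        "n_treatment_gainers": len(treatment_gainers(truth)),
        "files": {k: str(v.name) for k, v in paths.items() if k != "manifest"},
    }
    paths["manifest"].write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return {k: str(v) for k, v in paths.items()}
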