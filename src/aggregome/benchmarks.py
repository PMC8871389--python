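"""Synthetic benchmark scenarios used for validation and reporting.

Each function runs the pipeline end to end on generated data under a fixed
scenario — the null (no treatment effect), the planted-recovery scenario
(150 of 2000 proteins gain aggregation by 2 log2 units), NB-test
calibration, annotation-enrichment calibration, and a byte-identity check
of two full runs — and returns the summary numbers.  Seeds are derived from
a single entry seed so every scenario is reproducible.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import diffagg, enrichment, fractions, metastability, rnaseq, simulate
from .io import FRACTION_AGGREGATE, FRACTION_WCL


def subseeds(seed: int, n: int) -> list[int]:
    """n reproducible child seeds below 2**31."""
    ss = np.random.SeedSequence(seed)
    return [int(s) % (2**31) for s in ss.generate_state(n, dtype=np.uint32)]


def _run_caller(cfg: simulate.SimulationConfig, seed: int):
    truth = simulate.simulate_proteome(cfg)
    table, design = simulate.simulate_lfq(truth, cfg)
    results = diffagg.run_differential(
        table,
        design.subset(FRACTION_AGGREGATE),
        imputation=diffagg.ImputationConfig(seed=seed),
    )
    return truth, table, design, results


def null_fdr_scenario(seed: int, n_proteins: int = 2000) -> dict[str, float]:
    """No planted effect, MNAR missingness on: fraction of proteins called
    and a KS test of raw p-values against uniformity."""
    cfg = simulate.null_config(seed=seed, n_proteins=n_proteins)
    _, _, _, results = _run_caller(cfg, seed)
    called = (results["call"] != "ns").mean()
    ks = stats.kstest(results["p"].to_numpy(), "uniform")
    return {
        "fraction_called": float(called),
        "ks_p": float(ks.pvalue),
        "n_tested": int(len(results)),
    }


def planted_recovery_scenario(
    seed: int, n_seeds: int = 5, n_proteins: int = 2000, n_gainers: int = 150
) -> dict[str, float]:
    """Recovery of planted treatment gainers (2 log2-unit effect) across
    independent seeded runs: mean sensitivity and empirical FDR."""
    sens, fdrs = [], []
    for s in subseeds(seed, n_seeds):
        cfg = simulate.planted_config(seed=s, n_proteins=n_proteins, n_gainers=n_gainers)
        truth, _, _, results = _run_caller(cfg, s)
        rec = simulate.evaluate_recovery(results, truth)
        sens.append(rec["sensitivity"])
        fdrs.append(rec["empirical_fdr"])
    return {
        "sensitivity": float(np.mean(sens)),
        "empirical_fdr": float(np.mean(fdrs)),
        "sensitivity_min": float(np.min(sens)),
        "empirical_fdr_max": float(np.max(fdrs)),
        "n_seeds": n_seeds,
    }


def classified_run(seed: int, n_proteins: int = 2000, n_gainers: int = 150):
    """Planted scenario through classification: returns (truth, results,
    labels, counts matrix)."""
    cfg = simulate.planted_config(seed=seed, n_proteins=n_proteins, n_gainers=n_gainers)
    truth, table, design, results = _run_caller(cfg, seed)
    wcl_labels = design.labels_for(fraction=FRACTION_WCL)
    wcl_ids = frozenset(
        table.intensities.index[table.intensities[wcl_labels].notna().any(axis=1)]
    )
    labels = fractions.classify_fractions(results, wcl_ids)
    counts = simulate.simulate_counts(truth, cfg)
    return truth, results, labels, counts, wcl_ids


def metastability_scenario(seed: int, n_proteins: int = 2000, n_gainers: int = 150) -> dict:
    """Supersaturation separation between the increased and NIA fractions in
    the planted scenario, with the Kruskal-Wallis omnibus p across
    {increased, baseline, nia}."""
    truth, _, labels, counts, wcl_ids = classified_run(seed, n_proteins, n_gainers)
    abundance = rnaseq.cpm(counts).mean(axis=1)
    frame, tau = metastability.compute_supersaturation(
        truth["propensity_z"].to_dict(), abundance.to_dict(), wcl_ids
    )
    groups = {}
    for name in (fractions.LABEL_INCREASED, fractions.LABEL_BASELINE, fractions.LABEL_NIA):
        ids = [i for i in labels.ids(name) if i in frame.index]
        groups[name] = frame.loc[ids, "sigma"].to_numpy()
    kw = enrichment.kruskal_wallis(groups)
    return {
        "median_sigma_increased": float(np.median(groups[fractions.LABEL_INCREASED])),
        "median_sigma_baseline": float(np.median(groups[fractions.LABEL_BASELINE])),
        "median_sigma_nia": float(np.median(groups[fractions.LABEL_NIA])),
        "tau": float(tau),
        "kruskal_p": float(kw["p"]),
        "n_per_fraction": {k: int(v.size) for k, v in groups.items()},
    }


def nb_calibration_scenario(seed: int, n_genes: int = 5000, dispersion: float = 0.1) -> dict:
    """Type-I error of the NB LRT on a matched-dispersion null, plus the
    maximum discrepancy of the dispersion-0 path against an independent
    Poisson-LRT oracle."""
    rng = np.random.default_rng(seed)
    mu = 10 ** rng.normal(1.5, 1.0, n_genes) / 1e6 * 5e6
    lam = rng.gamma(1.0 / dispersion, np.tile(mu[:, None], (1, 8)) * dispersion)
    counts = pd.DataFrame(
        rng.poisson(lam),
        columns=[f"s{i}" for i in range(8)],
        index=[f"g{i}" for i in range(n_genes)],
    )
    groups = {f"s{i}": ("case" if i < 4 else "control") for i in range(8)}
    res = rnaseq.nb_lrt(counts, groups, dispersion)
    type1 = float((res["p"] < 0.05).mean())

    pois = rnaseq.nb_lrt(counts, groups, 0.0)
    y = counts.to_numpy(float)
    libs = y.sum(axis=0)
    mask = np.array([groups[c] == "control" for c in counts.columns])

    def ll(y, mu):
        mu = np.clip(mu, 1e-12, None)
        return (y * np.log(mu) - mu).sum(axis=1)

    q0 = y.sum(1) / libs.sum()
    qa = y[:, mask].sum(1) / libs[mask].sum()
    qr = y[:, ~mask].sum(1) / libs[~mask].sum()
    mu1 = np.where(mask[None, :], qa[:, None], qr[:, None]) * libs[None, :]
    oracle = np.clip(2 * (ll(y, mu1) - ll(y, q0[:, None] * libs[None, :])), 0, None)
    max_diff = float(np.max(np.abs(oracle - pois["lr_statistic"].to_numpy())))
    return {"type1_error": type1, "poisson_oracle_max_abs_diff": max_diff, "n_genes": n_genes}


def enrichment_scenario(seed: int, n_replicates: int = 200) -> dict:
    """Planted annotation enrichment (odds 5) through the chi-square stage,
    and calibration of the null (odds 1) p-values over replicate sets."""
    _, _, labels, _, _ = classified_run(seed)
    increased = labels.ids(fractions.LABEL_INCREASED)
    nia = labels.ids(fractions.LABEL_NIA)
    cfg = simulate.planted_config(seed=seed)
    truth = simulate.simulate_proteome(cfg)
    seeds = subseeds(seed + 1, n_replicates + 1)

    sets, _ = simulate.simulate_annotations(truth, 5.0, 200, seed=seeds[0])
    planted_table = enrichment.build_membership_table(
        increased, sets.members("planted_set"), nia
    )
    planted_p = enrichment.chi_square(planted_table)["p"]

    null_ps = []
    for s in seeds[1:]:
        null_sets, _ = simulate.simulate_annotations(truth, 1.0, 200, seed=s)
        table = enrichment.build_membership_table(
            increased, null_sets.members("planted_set"), nia
        )
        null_ps.append(enrichment.chi_square(table)["p"])
    ks = stats.kstest(null_ps, "uniform")
    return {
        "planted_p": float(planted_p),
        "null_ks_p": float(ks.pvalue),
        "n_null_replicates": n_replicates,
    }


def determinism_scenario(seed: int, workdir: str | Path, n_proteins: int = 600) -> dict:
    """Two full pipeline runs from one simulated dataset: byte-identity of
    every result table."""
    from .pipeline import run_full_analysis

    workdir = Path(workdir)
    cfg = simulate.planted_config(seed=seed, n_proteins=n_proteins, n_gainers=40)
    paths = simulate.simulate_dataset(cfg, workdir / "data")
    config = {
        "inputs": {
            "protein_groups": paths["protein_groups"],
            "design": paths["design"],
            "counts": paths["counts"],
            "gene_sets": paths["gene_sets"],
            "scores": paths["scores"],
        },
        "seed": seed,
    }
    m1 = run_full_analysis(config, workdir / "run1", reuse=False)
    m2 = run_full_analysis(config, workdir / "run2", reuse=False)
    by_name = lambda m: {Path(p).name: h for p, h in sorted(m.outputs.items())}
    identical = by_name(m1) == by_name(m2)
    return {"identical": bool(identical), "n_outputs": len(m1.outputs)}
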