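"""Simplified RNA-seq differential expression for 3'-end count data.

Gene-level counts are filtered (a gene needs count > 1 in at least two
samples), normalized to prior-damped log2 counts-per-million (logCPM), and
tested between two groups with a negative-binomial likelihood-ratio test
under a single common dispersion estimated by method of moments.  Library
sizes enter as offsets; no between-sample scale normalization is applied
(3'-end protocols produce one fragment per transcript, so neither length
nor composition normalization is attempted here).

Calling uses strict cutoffs: |logFC| > 1 and BH-adjusted p < 0.05.

This stage deliberately trades edgeR's gene-wise empirical-Bayes dispersion
machinery for a self-contained common-dispersion fit; an externally
computed DE table can be used as a drop-in wherever a DEResult frame is
accepted.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

from .diffagg import adjust_bh

CALL_UP = "up"
CALL_DOWN = "down"
CALL_NS = "ns"


def library_sizes(counts: pd.DataFrame) -> pd.Series:
    libs = counts.sum(axis=0)
    if (libs <= 0).any():
        raise ValueError("every sample must have a positive library size")
    return libs


def filter_min_counts(
    counts: pd.DataFrame, min_count: int = 2, min_samples: int = 2
) -> pd.DataFrame:
    """Keep genes with count >= min_count in >= min_samples samples."""
    keep = (counts >= min_count).sum(axis=1) >= min_samples
    if not keep.any():
        raise ValueError("no genes pass the minimum-count filter")
    return counts.loc[keep]


def logcpm(counts: pd.DataFrame, prior_count: float = 2.0) -> pd.DataFrame:
    """Prior-damped log2 counts per million.

    Following the standard convention, the prior is scaled proportionally to
    each library: with library sizes L_j and mean library L-bar, sample j
    gets prior pc_j = prior_count * L_j / L-bar and

        logCPM_ij = log2( (y_ij + pc_j) / (L_j + 2 * pc_j) * 1e6 ).

    With prior_count = 0 this is plain log2(CPM).
    """
    libs = library_sizes(counts).to_numpy(dtype=float)
    pc = prior_count * libs / libs.mean()
    denom = libs + 2.0 * pc
    values = np.log2((counts.to_numpy(dtype=float) + pc) / denom * 1e6)
    return pd.DataFrame(values, index=counts.index, columns=counts.columns)


def cpm(counts: pd.DataFrame) -> pd.DataFrame:
    """Plain counts per million."""
    libs = library_sizes(counts).to_numpy(dtype=float)
    return pd.DataFrame(
        counts.to_numpy(dtype=float) / libs * 1e6, index=counts.index, columns=counts.columns
    )


def _group_arrays(counts: pd.DataFrame, groups) -> tuple[np.ndarray, np.ndarray, list]:
    labels = pd.Series(groups)
    if not set(labels.index) >= set(counts.columns):
        labels = pd.Series(list(groups), index=counts.columns)
    levels = sorted(set(labels[c] for c in counts.columns))
    return (
        counts.to_numpy(dtype=float),
        np.array([labels[c] for c in counts.columns]),
        levels,
    )


def estimate_common_dispersion(counts: pd.DataFrame, groups) -> float:
    """Method-of-moments common NB dispersion.

    Per gene, with m the pooled (grand) mean and s^2 the within-group
    variance pooled across groups, the NB relation var = m + phi * m^2 gives
    phi_g = (s^2 - m) / m^2; the estimate is the average of max(0, phi_g)
    over genes with m > 0.  Requires >= 2 samples per group.
    """
    y, labels, levels = _group_arrays(counts, groups)
    for lev in levels:
        if np.sum(labels == lev) < 2:
            raise ValueError(f"group {lev!r} has < 2 replicates")
    n = y.shape[1]
    ss = np.zeros(y.shape[0])
    for lev in levels:
        sub = y[:, labels == lev]
        ss += sub.shape[1] * np.var(sub, axis=1, ddof=0)  # within-group SS
    s2 = ss / (n - len(levels))
    m = y.mean(axis=1)
    ok = m > 0
    if not ok.any():
        return 0.0
    phi = (s2[ok] - m[ok]) / m[ok] ** 2
    return float(np.mean(np.clip(phi, 0.0, None)))


def _nb_loglik(y: np.ndarray, mu: np.ndarray, dispersion: float) -> np.ndarray:
    """Row-wise NB2 log-likelihood (Poisson when dispersion == 0); constant
    terms in y are kept so absolute values are comparable across models."""
    mu = np.clip(mu, 1e-12, None)
    if dispersion == 0:
        return np.sum(y * np.log(mu) - mu - gammaln(y + 1.0), axis=-1)
    r = 1.0 / dispersion
    return np.sum(
        gammaln(y + r) - gammaln(r) - gammaln(y + 1.0)
        + r * np.log(r / (r + mu))
        + y * np.log(mu / (r + mu)),
        axis=-1,
    )


def _nb_mle_rate(y: np.ndarray, libs: np.ndarray, dispersion: float) -> np.ndarray:
    """Per-gene MLE of the common rate q in mean_ij = q * L_j.

    Newton iteration on the score Sum_j [ y_j/q - (y_j + r) L_j/(r + q L_j) ];
    the Poisson estimate Sum y / Sum L is the starting point and is exact for
    dispersion 0 (and for equal library sizes).
    """
    total = y.sum(axis=1)
    q = total / libs.sum()
    if dispersion == 0:
        return q
    r = 1.0 / dispersion
    positive = q > 0
    qp = q[positive]
    yp = y[positive]
    for _ in range(100):
        denom = r + qp[:, None] * libs[None, :]
        score = yp.sum(axis=1) / qp - np.sum((yp + r) * libs[None, :] / denom, axis=1)
        fisher = yp.sum(axis=1) / qp**2 - np.sum(
            (yp + r) * libs[None, :] ** 2 / denom**2, axis=1
        )
        step = np.where(fisher > 0, score / fisher, 0.0)
        q_new = np.clip(qp + step, qp * 0.1, qp * 10.0)
        if np.max(np.abs(q_new - qp) / np.maximum(qp, 1e-300)) < 1e-10:
            qp = q_new
            break
        qp = q_new
    q[positive] = qp
    return q


def nb_lrt(
    counts: pd.DataFrame,
    groups,
    dispersion: float,
    lib_sizes: pd.Series | None = None,
) -> pd.DataFrame:
    """Common-dispersion NB likelihood-ratio test between two groups.

    Null: one rate per gene (library-size offsets); alternative: one rate
    per group.  LR = 2 * delta logL, p from chi-square with 1 df.  logFC is
    the unshrunk log2 ratio of fitted group rates, oriented over the
    reference group: a group named "control" serves as reference when
    present, otherwise the lexicographically later level.  Genes with
    all-zero counts get p = 1 and logFC = 0.
    """
    if dispersion < 0:
        raise ValueError("dispersion must be >= 0")
    y, labels, levels = _group_arrays(counts, groups)
    if len(levels) != 2:
        raise ValueError(f"need exactly two groups, got {levels}")
    libs = (
        lib_sizes.reindex(counts.columns).to_numpy(dtype=float)
        if lib_sizes is not None
        else library_sizes(counts).to_numpy(dtype=float)
    )
    ref = "control" if "control" in levels else levels[1]
    alt = next(lev for lev in levels if lev != ref)
    mask_alt = labels == alt
    q0 = _nb_mle_rate(y, libs, dispersion)
    q_ref = _nb_mle_rate(y[:, ~mask_alt], libs[~mask_alt], dispersion)
    q_alt = _nb_mle_rate(y[:, mask_alt], libs[mask_alt], dispersion)

    ll0 = _nb_loglik(y, q0[:, None] * libs[None, :], dispersion)
    mu1 = np.where(mask_alt[None, :], q_alt[:, None], q_ref[:, None]) * libs[None, :]
    ll1 = _nb_loglik(y, mu1, dispersion)
    lr = np.clip(2.0 * (ll1 - ll0), 0.0, None)
    p = stats.chi2.sf(lr, df=1)

    with np.errstate(divide="ignore", invalid="ignore"):
        logfc = np.log2(q_alt) - np.log2(q_ref)
    all_zero = y.sum(axis=1) == 0
    logfc = np.where(all_zero, 0.0, logfc)
    logfc = np.where(np.isnan(logfc), 0.0, logfc)  # both groups zero
    p = np.where(all_zero, 1.0, p)
    lr = np.where(all_zero, 0.0, lr)

    mean_logcpm = logcpm(counts).mean(axis=1).to_numpy()
    return pd.DataFrame(
        {
            "logFC": logfc,
            "lr_statistic": lr,
            "p": p,
            "mean_logcpm": mean_logcpm,
        },
        index=counts.index,
    )


def call_de(result: pd.DataFrame, lfc_cut: float = 1.0, fdr_cut: float = 0.05) -> pd.DataFrame:
    """Strict-cutoff calls: up iff logFC > lfc_cut and fdr < fdr_cut
    (down mirrored).  Adds the ``fdr`` column via BH if absent."""
    out = result.copy()
    if "fdr" not in out.columns:
        out["fdr"] = adjust_bh(out["p"].to_numpy())
    call = np.full(len(out), CALL_NS, dtype=object)
    sig = out["fdr"] < fdr_cut
    call[(sig & (out["logFC"] > lfc_cut)).to_numpy()] = CALL_UP
    call[(sig & (out["logFC"] < -lfc_cut)).to_numpy()] = CALL_DOWN
    out["call"] = call
    return out


def annotate_gene_set_de(result: pd.DataFrame, gene_set) -> dict:
    """Counts of set members called up/down, with their identifiers."""
    members = frozenset(gene_set)
    sub = result.loc[result.index.isin(members)]
    up = sorted(sub.index[sub["call"] == CALL_UP])
    down = sorted(sub.index[sub["call"] == CALL_DOWN])
    return {"n_up": len(up), "n_down": len(down), "members_up": up, "members_down": down}


def run_de(
    counts: pd.DataFrame,
    groups,
    min_count: int = 2,
    min_samples: int = 2,
    lfc_cut: float = 1.0,
    fdr_cut: float = 0.05,
    dispersion: float | None = None,
) -> pd.DataFrame:
    """Filter, estimate common dispersion (unless given), test and call."""
    libs = library_sizes(counts)  # offsets from the unfiltered matrix
    filtered = filter_min_counts(counts, min_count=min_count, min_samples=min_samples)
    if dispersion is None:
        dispersion = estimate_common_dispersion(filtered, groups)
    result = nb_lrt(filtered, groups, dispersion, lib_sizes=libs)
    result.attrs["dispersion"] = dispersion
    return call_de(result, lfc_cut=lfc_cut, fdr_cut=fdr_cut)
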