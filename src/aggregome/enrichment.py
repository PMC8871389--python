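"""Figure-level statistics: membership enrichment and group comparisons.

Annotation-set enrichment of a proteome fraction against a background (the
NIA fraction by default) is tested on a 2x2 contingency table with Pearson's
chi-square (no continuity correction).  Score distributions across fractions
are compared with Kruskal-Wallis followed by Dunn's post-hoc z-tests;
matched pairs with the Wilcoxon signed-rank test (exact for small n); and
planned pairwise comparisons with Student t-tests under Bonferroni
correction.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts: a = fraction & set, b = fraction - set, c = background & set,
    d = background - set."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency counts must be nonnegative")
        if self.n == 0:
            raise ValueError("empty contingency table")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=float)


def build_membership_table(
    fraction: Iterable[str], annotation: Iterable[str], background: Iterable[str]
) -> ContingencyTable2x2:
    """Cross-tabulate annotation membership in a fraction vs a background.

    Fraction and background must be disjoint (the background is typically
    the NIA set)."""
    f, ann, bg = frozenset(fraction), frozenset(annotation), frozenset(background)
    if f & bg:
        raise ValueError("fraction and background overlap")
    return ContingencyTable2x2(
        a=len(f & ann), b=len(f - ann), c=len(bg & ann), d=len(bg - ann)
    )


def chi_square(table: ContingencyTable2x2) -> dict[str, float]:
    """Pearson chi-square on a 2x2 table, df = 1, no Yates correction."""
    arr = table.as_array()
    if np.any(arr.sum(axis=0) == 0) or np.any(arr.sum(axis=1) == 0):
        raise ValueError(
            "a margin of the table is zero (expected count 0); use an exact test"
        )
    statistic, p, df, _ = stats.chi2_contingency(arr, correction=False)
    return {"statistic": float(statistic), "df": int(df), "p": float(p)}


def _validated_groups(groups: Mapping[str, Sequence[float]]) -> dict[str, np.ndarray]:
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    out = {}
    for name, values in groups.items():
        arr = np.asarray(values, dtype=float)
        if arr.size == 0:
            raise ValueError(f"group {name!r} is empty")
        out[name] = arr
    return out


def kruskal_wallis(groups: Mapping[str, Sequence[float]]) -> dict[str, float]:
    """Rank-based omnibus test with tie correction; chi-square p, df = k-1."""
    g = _validated_groups(groups)
    if sum(a.size for a in g.values()) < 3:
        raise ValueError("need >= 3 observations in total")
    pooled = np.concatenate(list(g.values()))
    if np.all(pooled == pooled[0]):
        # every observation identical: zero statistic by convention
        return {"H": 0.0, "df": len(g) - 1, "p": 1.0}
    h, p = stats.kruskal(*g.values())
    return {"H": float(h), "df": len(g) - 1, "p": float(p)}


def dunn_posthoc(
    groups: Mapping[str, Sequence[float]], method: str = "bonferroni"
) -> pd.DataFrame:
    """Dunn's pairwise z-tests on pooled ranks with tie correction.

    Family-wise adjustment over all pairs by Bonferroni (default) or Sidak.
    """
    if method not in ("bonferroni", "sidak"):
        raise ValueError("method must be 'bonferroni' or 'sidak'")
    g = _validated_groups(groups)
    names = list(g)
    pooled = np.concatenate([g[n] for n in names])
    n_total = pooled.size
    ranks = stats.rankdata(pooled)
    mean_ranks = {}
    start = 0
    for name in names:
        size = g[name].size
        mean_ranks[name] = ranks[start : start + size].mean()
        start += size
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    pairs = list(itertools.combinations(names, 2))
    m = len(pairs)
    rows = []
    for na, nb in pairs:
        ni, nj = g[na].size, g[nb].size
        var = (n_total * (n_total + 1) / 12.0 - tie_term / (12.0 * (n_total - 1))) * (
            1.0 / ni + 1.0 / nj
        )
        z = (mean_ranks[na] - mean_ranks[nb]) / np.sqrt(var) if var > 0 else 0.0
        p_raw = float(2.0 * stats.norm.sf(abs(z)))
        if method == "bonferroni":
            p_adj = min(1.0, p_raw * m)
        else:
            p_adj = float(1.0 - (1.0 - p_raw) ** m)
        rows.append({"group_a": na, "group_b": nb, "z": float(z), "p_raw": p_raw, "p_adjusted": p_adj})
    return pd.DataFrame(rows)


def _signed_rank_exact_p(w2: float, doubled_ranks: np.ndarray) -> float:
    """Exact two-sided p for the signed-rank statistic via the distribution of
    the positive-rank sum over all 2^n equiprobable sign assignments (dynamic
    program over doubled ranks, which are integers even with average-rank
    ties)."""
    total = int(doubled_ranks.sum())
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in doubled_ranks.astype(int):
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: counts.size - r]
        counts = counts + shifted
    counts /= counts.sum()
    w2 = int(round(w2))
    p_le = counts[: w2 + 1].sum()
    p_ge = counts[w2:].sum()
    return float(min(1.0, 2.0 * min(p_le, p_ge)))


def wilcoxon_signed_rank(
    paired_a: Sequence[float], paired_b: Sequence[float], exact_limit: int = 25
) -> dict[str, float]:
    """Two-sided Wilcoxon matched-pairs signed-rank test.

    Zero differences are dropped.  For n <= exact_limit the p-value is exact
    (enumeration of sign assignments); above that a normal approximation
    with tie correction is used.  Statistic = sum of ranks of positive
    differences.
    """
    a = np.asarray(paired_a, dtype=float)
    b = np.asarray(paired_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired vectors must have equal length")
    d = a - b
    d = d[d != 0]
    n = d.size
    if n == 0:
        warnings.warn("all paired differences are zero", stacklevel=2)
        return {"statistic": 0.0, "n": 0, "p": 1.0}
    ranks = stats.rankdata(np.abs(d))
    w_pos = float(ranks[d > 0].sum())
    if n <= exact_limit:
        p = _signed_rank_exact_p(2.0 * w_pos, np.round(2.0 * ranks))
    else:
        mean = n * (n + 1) / 4.0
        _, tie_counts = np.unique(np.abs(d), return_counts=True)
        tie_term = float(np.sum(tie_counts**3 - tie_counts))
        var = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term / 48.0
        z = (w_pos - mean) / np.sqrt(var)
        p = float(2.0 * stats.norm.sf(abs(z)))
    return {"statistic": w_pos, "n": int(n), "p": float(min(1.0, p))}


def ttest_bonferroni(
    groups: Mapping[str, Sequence[float]],
    comparisons: Sequence[tuple[str, str]],
) -> pd.DataFrame:
    """Two-sided two-sample Student t-tests with Bonferroni adjustment
    (p_adjusted = min(1, p_raw * number of comparisons))."""
    g = _validated_groups(groups)
    for name, arr in g.items():
        if arr.size < 2:
            raise ValueError(f"group {name!r} needs >= 2 observations")
    m = len(comparisons)
    rows = []
    for na, nb in comparisons:
        x, y = g[na], g[nb]
        with np.errstate(invalid="ignore", divide="ignore"):
            t, p = stats.ttest_ind(x, y, equal_var=True)
        if np.isnan(t):  # zero variance in both groups
            if np.isclose(x.mean(), y.mean()):
                t, p = 0.0, 1.0
            else:
                t, p = np.sign(x.mean() - y.mean()) * np.inf, 0.0
        rows.append(
            {
                "group_a": na,
                "group_b": nb,
                "t": float(t),
                "p_raw": float(p),
                "p_adjusted": float(min(1.0, p * m)),
            }
        )
    return pd.DataFrame(rows)


def enrichment_report(
    fractions: Mapping[str, Iterable[str]],
    annotations: Mapping[str, Iterable[str]],
    background: Iterable[str],
) -> pd.DataFrame:
    """Chi-square enrichment of every (fraction, annotation set) pair against
    a shared background."""
    bg = frozenset(background)
    rows = []
    for fname, fids in fractions.items():
        for aname, aids in annotations.items():
            table = build_membership_table(fids, aids, bg)
            try:
                res = chi_square(table)
            except ValueError:
                warnings.warn(
                    f"zero margin for fraction {fname!r} x set {aname!r}; skipped",
                    stacklevel=2,
                )
                continue
            rows.append(
                {
                    "fraction": fname,
                    "set": aname,
                    "a": table.a,
                    "b": table.b,
                    "c": table.c,
                    "d": table.d,
                    "odds_ratio": (table.a * table.d) / (table.b * table.c)
                    if table.b * table.c
                    else np.inf,
                    "statistic": res["statistic"],
                    "p": res["p"],
                }
            )
    return pd.DataFrame(rows)
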