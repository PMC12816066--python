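"""Cohort-level statistical validation of the IG score.

Nonparametric group comparisons (Mann–Whitney U, Fisher's exact),
Spearman correlation matrix with strength bands, ROC analysis over the
integer score range with Youden cut-off selection, the *P. gingivalis* /
total-bacteria ratio, and Table-1-style group summaries.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.stats.contingency import odds_ratio as _odds_ratio

ALPHA_TIERS = (0.05, 0.01, 0.001, 0.0001)

BAND_SLIGHT = "slight"
BAND_MODERATE = "moderate"
BAND_STRONG = "strong"
BAND_VERY_STRONG = "very strong"


class DomainError(ValueError):
    pass


class UndefinedCorrelationError(ValueError):
    pass


def significance_stars(p: float, alpha_tiers: Sequence[float] = ALPHA_TIERS) -> str:
    """Star annotation: * p<0.05, ** p<0.01, *** p<0.001, **** p<0.0001."""
    stars = sum(p < a for a in alpha_tiers)
    return "*" * stars if stars else "ns"


def mann_whitney_u(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Two-sided Mann–Whitney U test (U statistic of the first sample, from
    average ranks).

    Uses the exact permutation null when both samples have ≤ 12 observations
    and there are no ties, and the tie-corrected normal approximation (with
    continuity correction) otherwise.
    """
    xa, ya = np.asarray(x, float), np.asarray(y, float)
    if xa.size == 0 or ya.size == 0:
        raise DomainError("both samples must be non-empty")
    pooled = np.concatenate([xa, ya])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (not has_ties and max(xa.size, ya.size) <= 12) else "asymptotic"
    res = sps.mannwhitneyu(xa, ya, alternative="two-sided", method=method)
    return float(res.statistic), float(min(res.pvalue, 1.0))


def fisher_exact_2x2(table) -> tuple[float, float]:
    """Fisher's exact test for a 2×2 table.

    Two-sided p by the probability-mass rule (sum of hypergeometric
    probabilities of tables, at fixed margins, no more probable than the
    observed one); the conditional maximum-likelihood odds ratio is reported.
    """
    t = np.asarray(table, dtype=int)
    if t.shape != (2, 2) or (t < 0).any():
        raise DomainError("table must be 2x2 with nonnegative integer counts")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise DomainError("all margins must be positive")
    p = float(sps.fisher_exact(t, alternative="two-sided").pvalue)
    orat = float(_odds_ratio(t, kind="conditional").statistic)
    return orat, min(p, 1.0)


def spearman(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Spearman rank correlation (Pearson on average ranks, tie-safe) with a
    two-sided p from the t-distribution approximation."""
    xa, ya = np.asarray(x, float), np.asarray(y, float)
    if xa.size != ya.size or xa.size < 3:
        raise DomainError("samples must have equal length >= 3")
    if np.unique(xa).size < 2 or np.unique(ya).size < 2:
        raise UndefinedCorrelationError("correlation undefined for a constant vector")
    rho, p = sps.spearmanr(xa, ya)
    return float(rho), float(p)


def band_strength(rho: float) -> str:
    """Correlation-strength band on |rho|: < 0.4 slight, [0.4, 0.6) moderate,
    [0.6, 0.8) strong, ≥ 0.8 very strong."""
    if not -1.0 <= rho <= 1.0:
        raise DomainError("rho must lie in [-1, 1]")
    a = abs(rho)
    if a < 0.4:
        return BAND_SLIGHT
    if a < 0.6:
        return BAND_MODERATE
    if a < 0.8:
        return BAND_STRONG
    return BAND_VERY_STRONG


@dataclass(frozen=True)
class CorrelationEntry:
    var_x: str
    var_y: str
    rho: float | None
    p: float | None
    band: str | None
    stars: str | None
    computable: bool = True


def correlation_matrix(
    table: pd.DataFrame,
    variables: Sequence[str],
    alpha: float = 0.05,
    bh_correction: bool = False,
) -> list[CorrelationEntry]:
    """All pairwise Spearman correlations among ``variables`` (upper
    triangle, diagonal omitted), with strength bands and significance stars.

    Pairs with fewer than 3 complete cases or a constant column are flagged
    not-computable and the run continues.  p-values are unadjusted by
    default, matching the reported analysis; Benjamini–Hochberg is opt-in.
    """
    entries: list[CorrelationEntry] = []
    raw_ps: list[float] = []
    slots: list[int] = []
    for i, vx in enumerate(variables):
        for vy in variables[i + 1 :]:
            pair = table[[vx, vy]].dropna()
            try:
                if len(pair) < 3:
                    raise DomainError("fewer than 3 complete cases")
                rho, p = spearman(pair[vx].to_numpy(), pair[vy].to_numpy())
            except (DomainError, UndefinedCorrelationError):
                entries.append(CorrelationEntry(vx, vy, None, None, None, None, False))
                continue
            slots.append(len(entries))
            raw_ps.append(p)
            entries.append(
                CorrelationEntry(vx, vy, rho, p, band_strength(rho), significance_stars(p))
            )
    if bh_correction and raw_ps:
        adj = _benjamini_hochberg(np.array(raw_ps))
        for slot, p_adj in zip(slots, adj):
            e = entries[slot]
            entries[slot] = CorrelationEntry(
                e.var_x, e.var_y, e.rho, float(p_adj), e.band, significance_stars(p_adj)
            )
    return entries


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    order = np.argsort(p)
    m = len(p)
    adj = np.empty(m)
    running = 1.0
    for rank_idx in range(m - 1, -1, -1):
        idx = order[rank_idx]
        running = min(running, p[idx] * m / (rank_idx + 1))
        adj[idx] = running
    return adj


def correlation_frame(entries: Sequence[CorrelationEntry]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "var_x": [e.var_x for e in entries],
            "var_y": [e.var_y for e in entries],
            "rho": [e.rho for e in entries],
            "p": [e.p for e in entries],
            "band": [e.band for e in entries],
            "stars": [e.stars for e in entries],
            "computable": [e.computable for e in entries],
        }
    )


@dataclass(frozen=True)
class ROCResult:
    """ROC sweep over all integer IG cut-offs 0–16 with rule score ≥ cut-off
    ⇒ disease-positive."""

    thresholds: np.ndarray  # (17,)
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float

    def youden(self) -> np.ndarray:
        return self.sensitivity + self.specificity - 1.0


def roc(scores: Sequence[float], labels: Sequence[int]) -> ROCResult:
    """ROC analysis of IG totals against binary disease labels (1 = disease).

    Sensitivity/specificity are computed at every integer cut-off 0..16;
    AUC by the trapezoid rule over (1 − specificity, sensitivity).
    """
    s = np.asarray(scores, float)
    y = np.asarray(labels, int)
    if s.size != y.size or s.size == 0:
        raise DomainError("scores and labels must be equal-length and non-empty")
    if len(np.unique(y)) < 2:
        raise DomainError("both classes must be present")
    pos, neg = s[y == 1], s[y == 0]
    thresholds = np.arange(17)
    sens = np.array([(pos >= c).mean() for c in thresholds])
    spec = np.array([(neg < c).mean() for c in thresholds])
    # integrate in decreasing-cutoff order: sens and FPR both nondecreasing,
    # so vertical segments (tied FPR) contribute zero area correctly
    fpr = 1.0 - spec
    auc = float(np.trapezoid(sens[::-1], fpr[::-1]))
    return ROCResult(thresholds=thresholds, sensitivity=sens, specificity=spec, auc=auc)


def select_cutoff(result: ROCResult) -> int:
    """Best cut-off: among the maximizers of Youden's J = sens + spec − 1,
    the smallest (fewest false negatives); deterministic."""
    j = result.youden()
    best = np.flatnonzero(np.isclose(j, j.max()))
    return int(result.thresholds[best[0]])


def roc_frame(result: ROCResult) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "cutoff": result.thresholds,
            "sensitivity": result.sensitivity,
            "specificity": result.specificity,
            "youden_j": result.youden(),
        }
    )


def pg_ratio(pg_ng: float, total_ng: float) -> float:
    """*P. gingivalis* / total bacteria ratio, as a percentage."""
    if total_ng <= 0:
        raise DomainError("total_ng must be > 0")
    if pg_ng < 0:
        raise DomainError("pg_ng must be >= 0")
    return 100.0 * pg_ng / total_ng


@dataclass(frozen=True)
class GroupSummary:
    median: float
    q1: float
    q3: float
    mean: float

    def format(self, digits: int = 4) -> str:
        """Render in the ``median (Q1–Q3)–mean`` table dialect."""
        f = lambda v: f"{round(v, digits):g}"
        return f"{f(self.median)} ({f(self.q1)}–{f(self.q3)})–{f(self.mean)}"


def summarize_group(values: Sequence[float], method: str = "linear") -> GroupSummary:
    """Median, quartiles (linear interpolation between order statistics by
    default; numpy method name, config-switchable) and mean."""
    v = np.asarray(values, float)
    if v.size == 0:
        raise DomainError("cannot summarize an empty sample")
    q1, med, q3 = np.quantile(v, [0.25, 0.5, 0.75], method=method)
    return GroupSummary(float(med), float(q1), float(q3), float(v.mean()))


@dataclass(frozen=True)
class GroupComparison:
    variable: str
    summary_a: str
    summary_b: str
    test: str  # "mann-whitney" | "fisher"
    statistic: float
    p: float
    stars: str


def compare_groups(
    cohort: pd.DataFrame,
    group_col: str = "group",
    groups: tuple[str, str] = ("healthy", "periodontitis"),
    quantitative: Sequence[str] = (),
    qualitative: Sequence[str] = (),
    quartile_method: str = "linear",
) -> list[GroupComparison]:
    """Table-1-style comparisons: Mann–Whitney U for quantitative variables,
    Fisher's exact test for binary qualitative ones."""
    a = cohort[cohort[group_col] == groups[0]]
    b = cohort[cohort[group_col] == groups[1]]
    out = []
    for var in quantitative:
        xa = a[var].dropna().to_numpy(float)
        xb = b[var].dropna().to_numpy(float)
        u, p = mann_whitney_u(xa, xb)
        out.append(
            GroupComparison(
                var,
                summarize_group(xa, quartile_method).format(),
                summarize_group(xb, quartile_method).format(),
                "mann-whitney",
                u,
                p,
                significance_stars(p),
            )
        )
    for var in qualitative:
        xa = a[var].dropna().astype(bool)
        xb = b[var].dropna().astype(bool)
        table = [
            [int(xa.sum()), int((~xa).sum())],
            [int(xb.sum()), int((~xb).sum())],
        ]
        orat, p = fisher_exact_2x2(table)
        out.append(
            GroupComparison(
                var,
                f"{table[0][0]}/{table[0][1]}",
                f"{table[1][0]}/{table[1][1]}",
                "fisher",
                orat,
                p,
                significance_stars(p),
            )
        )
    return out


def comparisons_frame(comparisons: Sequence[GroupComparison]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "variable": [c.variable for c in comparisons],
            "healthy": [c.summary_a for c in comparisons],
            "periodontitis": [c.summary_b for c in comparisons],
            "test": [c.test for c in comparisons],
            "statistic": [c.statistic for c in comparisons],
            "p": [c.p for c in comparisons],
            "stars": [c.stars for c in comparisons],
        }
    )
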