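"""Paired cross-period trait comparison and community-weighted means.

Per-site trait values (usually community-weighted means of the standardized
traits) are compared between the two survey periods with a paired design.
Method choice is gated on parametric assumptions: a paired t-test is used
when the site-level differences pass Shapiro-Wilk normality and the two
periods pass a Brown-Forsythe (median-centered Levene) homogeneity check,
both at alpha = 0.05; otherwise the Wilcoxon signed-rank test is used.
Cohen's d for the paired design is mean(diff) / sd(diff) and is reported
for both paths (the method label stays honest).

Differences are defined as second period minus first (2020 - 1990), so a
trait that declined carries a negative d.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

#: |d| bands: very_small < 0.2 <= small < 0.5 <= medium < 0.8 <= large
EFFECT_THRESHOLDS = (0.2, 0.5, 0.8)
EFFECT_LABELS = ("very_small", "small", "medium", "large")


def effect_label(d: float) -> str:
    a = abs(d)
    if a < EFFECT_THRESHOLDS[0]:
        return "very_small"
    if a < EFFECT_THRESHOLDS[1]:
        return "small"
    if a < EFFECT_THRESHOLDS[2]:
        return "medium"
    return "large"


@dataclass
class PairedTestResult:
    trait: str
    method: str  # "paired_t" | "wilcoxon_signed_rank"
    statistic: float
    p_value: float
    cohens_d: float
    effect_label: str
    n_pairs: int


def cohens_d_paired(diff: np.ndarray) -> float:
    sd = float(np.std(diff, ddof=1))
    m = float(np.mean(diff))
    if sd == 0.0:
        return 0.0 if m == 0.0 else float(np.sign(m)) * np.inf
    return m / sd


def paired_trait_test(
    x_1990: np.ndarray,
    x_2020: np.ndarray,
    trait: str = "",
    alpha: float = 0.05,
) -> PairedTestResult:
    """Assumption-gated paired comparison of per-site values across periods."""
    a = np.asarray(x_1990, dtype=float)
    b = np.asarray(x_2020, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired vectors must be 1-D and equal length")
    n = len(a)
    if n < 3:
        raise ValueError(f"need at least 3 pairs, got {n}")
    diff = b - a
    d = cohens_d_paired(diff)
    if np.all(diff == 0.0):
        return PairedTestResult(trait, "paired_t", 0.0, 1.0, 0.0, "very_small", n)
    if np.std(diff, ddof=1) == 0.0:
        # constant non-zero shift: t statistic diverges
        return PairedTestResult(trait, "paired_t", float(np.sign(np.mean(diff))) * np.inf,
                                0.0, d, effect_label(d), n)

    normal_ok = stats.shapiro(diff).pvalue > alpha
    if np.std(a, ddof=1) == 0.0 and np.std(b, ddof=1) == 0.0:
        variance_ok = True
    else:
        variance_ok = stats.levene(a, b, center="median").pvalue > alpha

    if normal_ok and variance_ok:
        res = stats.ttest_rel(b, a)
        return PairedTestResult(trait, "paired_t", float(res.statistic),
                                float(res.pvalue), d, effect_label(d), n)
    nz = diff[diff != 0.0]
    has_ties = len(np.unique(np.abs(nz))) < len(nz)
    use_exact = n <= 25 and not np.any(diff == 0.0) and not has_ties
    res = stats.wilcoxon(
        diff,
        zero_method="pratt",
        correction=not use_exact,
        method="exact" if use_exact else "approx",
    )
    return PairedTestResult(trait, "wilcoxon_signed_rank", float(res.statistic),
                            float(res.pvalue), d, effect_label(d), n)


def community_weighted_mean(
    abund_row: np.ndarray,
    trait_col: np.ndarray,
    tol: float = 1e-3,
) -> float:
    """CWM = sum_i P_i X_i over the species of one site.

    ``abund_row`` must sum to 1 within 1e-9; sums off by up to ``tol`` are
    renormalized, anything worse is an error.
    """
    p = np.asarray(abund_row, dtype=float)
    x = np.asarray(trait_col, dtype=float)
    if p.shape != x.shape:
        raise ValueError("abundance and trait vectors must align")
    if np.any(p < 0):
        raise ValueError("negative relative abundance")
    s = p.sum()
    if abs(s - 1.0) > tol:
        raise ValueError(f"relative abundances sum to {s:.6f}, not 1")
    if abs(s - 1.0) > 1e-9:
        p = p / s
    return float(p @ x)


def cwm_table(community, trait_values: pd.DataFrame) -> pd.DataFrame:
    """Per-site CWM of every trait column for one period.

    ``trait_values`` is indexed by species_id (e.g. standardized traits for
    the community's period); only species present in both objects enter,
    with abundances renormalized over that subset.
    """
    common = [sp for sp in community.species if sp in trait_values.index]
    if not common:
        raise ValueError("no species shared between community and trait values")
    A = community.abundance[common].to_numpy(dtype=float)
    A = A / A.sum(axis=1, keepdims=True)
    X = trait_values.loc[common].to_numpy(dtype=float)
    out = A @ X
    return pd.DataFrame(out, index=community.abundance.index,
                        columns=trait_values.columns)


def paired_cwm_tests(
    cwm_1990: pd.DataFrame,
    cwm_2020: pd.DataFrame,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Tidy per-trait paired test table (trait, method, statistic, p, d, label, n)."""
    if list(cwm_1990.index) != list(cwm_2020.index):
        raise ValueError("site lists differ between periods")
    rows = []
    for trait in cwm_1990.columns:
        r = paired_trait_test(cwm_1990[trait].to_numpy(),
                              cwm_2020[trait].to_numpy(), trait=trait, alpha=alpha)
        rows.append({"trait": r.trait, "method": r.method, "statistic": r.statistic,
                     "p": r.p_value, "d": r.cohens_d, "label": r.effect_label,
                     "n": r.n_pairs})
    return pd.DataFrame(rows)
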