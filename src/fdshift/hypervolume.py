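"""Kernel-density hypervolumes and Sorensen overlap in full trait space.

A group of species is summarised by a Gaussian-mixture density: one
axis-aligned Gaussian kernel per species, with a per-dimension Silverman
bandwidth.  The occupied "hypervolume" is the Lebesgue measure of the
superlevel set of that density enclosing a fixed fraction (default 95%)
of its probability mass.  Both the threshold and the measure are obtained
by Monte-Carlo sampling from the mixture itself: for samples x ~ f,

    P(f(X) >= t)                 estimates the enclosed mass above t,
    (1/m) sum_{f(x_i)>=t} 1/f(x_i)  estimates Leb{x : f(x) >= t},

which is an unbiased importance-sampling estimate of the superlevel-set
volume.  All estimates are deterministic given the seed.

Overlap between two hypervolumes uses cross-inclusion of the retained
clouds: each group's retained samples are tested against the other
group's superlevel set, giving two importance-sampling estimates of the
intersection volume that are averaged.  Sorensen = 2 V(A^B) / (V_A + V_B).

The permutation null shuffles group labels over the pooled species and
asks whether the observed overlap is lower than expected under label
exchangeability; the bootstrap resamples species within groups.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp


def silverman_bandwidth(points: np.ndarray) -> np.ndarray:
    """Per-dimension Silverman rule for a k-variate Gaussian kernel."""
    X = np.asarray(points, dtype=float)
    n, k = X.shape
    sd = X.std(axis=0, ddof=1)
    factor = (4.0 / ((k + 2.0) * n)) ** (1.0 / (k + 4.0))
    bw = factor * sd
    if np.any(bw <= 0):
        # degenerate dimension: fall back to a small positive width so the
        # mixture stays a proper density
        bw = np.where(bw > 0, bw, 1e-6)
    return bw


@dataclass
class HypervolumeEstimate:
    dimension: int
    bandwidth: np.ndarray
    data: np.ndarray  # n x k kernel centres
    n_samples: int  # total Monte-Carlo draws m
    random_points: np.ndarray  # retained cloud (above threshold)
    log_densities: np.ndarray  # mixture log-density at retained points
    log_threshold: float
    threshold_quantile: float
    volume: float
    rng_seed: int

    def log_density(self, X: np.ndarray) -> np.ndarray:
        """Mixture log-density at arbitrary points (vectorized, chunked)."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        # bound the (chunk x n_kernels) work matrix to ~4e6 entries
        max_chunk = max(int(4e6 / max(len(self.data), 1)), 1)
        if len(X) > max_chunk:
            return np.concatenate([
                self.log_density(X[i:i + max_chunk])
                for i in range(0, len(X), max_chunk)
            ])
        bw = self.bandwidth
        # squared Mahalanobis-to-centre distances via one GEMM:
        # ||(x-c)/bw||^2 = |x/bw|^2 + |c/bw|^2 - 2 (x/bw).(c/bw)
        Xs = X / bw
        Cs = self.data / bw
        sq = (
            (Xs * Xs).sum(axis=1)[:, None]
            + (Cs * Cs).sum(axis=1)[None, :]
            - 2.0 * (Xs @ Cs.T)
        )
        np.maximum(sq, 0.0, out=sq)
        log_kern = -0.5 * sq - (
            0.5 * self.dimension * np.log(2 * np.pi) + np.log(bw).sum()
        )
        return logsumexp(log_kern, axis=1) - np.log(len(self.data))

    def contains(self, X: np.ndarray) -> np.ndarray:
        return self.log_density(X) >= self.log_threshold


def estimate_hypervolume(
    points: np.ndarray,
    samples_per_point: int = 500,
    quantile: float = 0.95,
    seed: int | np.random.Generator = 0,
) -> HypervolumeEstimate:
    """Kernel hypervolume of one species cloud (no dimensionality reduction)."""
    X = np.asarray(points, dtype=float)
    if X.ndim != 2 or len(X) < 2:
        raise ValueError("need at least 2 points (n x k array)")
    if not (0.0 < quantile < 1.0):
        raise ValueError("quantile must be in (0, 1)")
    n, k = X.shape
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    bw = silverman_bandwidth(X)
    m = n * samples_per_point
    centres = rng.integers(0, n, size=m)
    samples = X[centres] + rng.standard_normal((m, k)) * bw

    est = HypervolumeEstimate(
        dimension=k, bandwidth=bw, data=X, n_samples=m,
        random_points=samples, log_densities=np.empty(0),
        log_threshold=-np.inf, threshold_quantile=quantile,
        volume=np.nan, rng_seed=-1,
    )
    logf = est.log_density(samples)
    # threshold so that the superlevel set holds `quantile` of the mass
    log_t = float(np.quantile(logf, 1.0 - quantile))
    keep = logf >= log_t
    volume = float(np.exp(-logf[keep]).sum() / m)
    est.random_points = samples[keep]
    est.log_densities = logf[keep]
    est.log_threshold = log_t
    est.volume = volume
    est.rng_seed = -1 if isinstance(seed, np.random.Generator) else int(seed)
    return est


@dataclass
class OverlapResult:
    sorensen: float
    v_a: float
    v_b: float
    v_intersection: float
    null_distribution: np.ndarray | None = None
    p_value: float | None = None
    ci: tuple[float, float] | None = None
    n_perm: int = 0
    n_boot: int = 0


def sorensen_overlap(A: HypervolumeEstimate, B: HypervolumeEstimate) -> OverlapResult:
    """Point estimate of the Sorensen overlap of two hypervolumes."""
    if A.dimension != B.dimension:
        raise ValueError("hypervolume dimensions differ")

    def inter_from(src: HypervolumeEstimate, other: HypervolumeEstimate) -> float:
        if len(src.random_points) == 0:
            return 0.0
        inside = other.log_density(src.random_points) >= other.log_threshold
        return float(np.exp(-src.log_densities[inside]).sum() / src.n_samples)

    v_int = 0.5 * (inter_from(A, B) + inter_from(B, A))
    denom = A.volume + B.volume
    s = 2.0 * v_int / denom if denom > 0 else 0.0
    return OverlapResult(sorensen=s, v_a=A.volume, v_b=B.volume, v_intersection=v_int)


def _group_points(values: pd.DataFrame | np.ndarray, labels: np.ndarray):
    X = values.to_numpy(dtype=float) if hasattr(values, "to_numpy") else np.asarray(values, float)
    labels = np.asarray(labels)
    groups = pd.unique(labels)
    if len(groups) != 2:
        raise ValueError(f"need exactly 2 group labels, got {list(groups)}")
    a, b = groups
    return X, labels, a, b


def overlap_between_groups(
    values, labels, samples_per_point: int = 500, quantile: float = 0.95,
    rng: np.random.Generator | None = None,
) -> OverlapResult:
    X, labels, a, b = _group_points(values, labels)
    rng = rng or np.random.default_rng(0)
    A = estimate_hypervolume(X[labels == a], samples_per_point, quantile, rng)
    B = estimate_hypervolume(X[labels == b], samples_per_point, quantile, rng)
    return sorensen_overlap(A, B)


def overlap_null_test(
    values,
    labels,
    n_perm: int = 999,
    seed: int = 0,
    samples_per_point: int = 500,
    quantile: float = 0.95,
    perm_samples_per_point: int | None = None,
    alternative: str = "lower",
) -> OverlapResult:
    """Permutation test of the observed overlap against label exchangeability.

    p = (1 + #{null <= observed}) / (n_perm + 1) for the default "lower"
    alternative (observed overlap smaller than random); "two_sided" doubles
    the smaller tail.  ``perm_samples_per_point`` lets replicates run at a
    lighter sampling effort than the observed estimate.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    X, labels, a, b = _group_points(values, labels)
    if (labels == a).sum() < 2 or (labels == b).sum() < 2:
        raise ValueError("each group needs at least 2 species")
    root = np.random.default_rng(seed)
    obs = overlap_between_groups(X, labels, samples_per_point, quantile, rng=root)
    spp = perm_samples_per_point or samples_per_point
    null = np.empty(n_perm)
    for i in range(n_perm):
        perm = root.permutation(labels)
        null[i] = overlap_between_groups(X, perm, spp, quantile, rng=root).sorensen
    lower = (1 + np.sum(null <= obs.sorensen)) / (n_perm + 1)
    upper = (1 + np.sum(null >= obs.sorensen)) / (n_perm + 1)
    if alternative == "lower":
        p = lower
    elif alternative == "upper":
        p = upper
    elif alternative == "two_sided":
        p = min(1.0, 2.0 * min(lower, upper))
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    obs.null_distribution = null
    obs.p_value = float(p)
    obs.n_perm = n_perm
    return obs


def bootstrap_overlap(
    values,
    labels,
    n_boot: int = 999,
    seed: int = 0,
    samples_per_point: int = 500,
    quantile: float = 0.95,
    boot_samples_per_point: int | None = None,
    ci_level: float = 0.95,
) -> OverlapResult:
    """Percentile bootstrap CI for the Sorensen overlap (resampling species
    with replacement within each group; degenerate all-duplicate resamples
    are redrawn and counted)."""
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    X, labels, a, b = _group_points(values, labels)
    root = np.random.default_rng(seed)
    obs = overlap_between_groups(X, labels, samples_per_point, quantile, rng=root)
    spp = boot_samples_per_point or samples_per_point
    ia, ib = np.where(labels == a)[0], np.where(labels == b)[0]
    vals = np.empty(n_boot)
    redraws = 0
    for i in range(n_boot):
        for _ in range(100):
            ra = root.choice(ia, size=len(ia), replace=True)
            rb = root.choice(ib, size=len(ib), replace=True)
            pts = np.vstack([X[ra], X[rb]])
            lab = np.array([0] * len(ra) + [1] * len(rb))
            if len(np.unique(X[ra], axis=0)) > 1 and len(np.unique(X[rb], axis=0)) > 1:
                break
            redraws += 1
        vals[i] = overlap_between_groups(pts, lab, spp, quantile, rng=root).sorensen
    alpha = 1.0 - ci_level
    obs.ci = (float(np.quantile(vals, alpha / 2)),
              float(np.quantile(vals, 1 - alpha / 2)))
    obs.n_boot = n_boot
    obs.null_distribution = None
    if redraws:
        import logging
        logging.getLogger(__name__).info("bootstrap: %d degenerate resamples redrawn", redraws)
    return obs


#: the four group comparisons of the study design
SURVEY_COMPARISONS = (
    ("native_1990_vs_2020", ("P1990", "native"), ("P2020", "native")),
    ("nonnative_1990_vs_2020", ("P1990", "non_native"), ("P2020", "non_native")),
    ("native_vs_nonnative_1990", ("P1990", "native"), ("P1990", "non_native")),
    ("native_vs_nonnative_2020", ("P2020", "native"), ("P2020", "non_native")),
)


def survey_overlap_table(
    st,
    n_perm: int = 999,
    n_boot: int = 999,
    seed: int = 0,
    samples_per_point: int = 500,
    quantile: float = 0.95,
    resample_samples_per_point: int | None = None,
    include_total: bool = False,
) -> pd.DataFrame:
    """Driver for the standard status/period comparisons on pooled-standardized
    traits (rows keyed by (period, species_id); ``st.status`` aligned).

    Comparisons whose groups are too small (< 2 species) are reported with
    NaN and a note.  ``include_total`` adds the all-species cross-period row.
    """
    values = st.values
    status = st.status
    periods = values.index.get_level_values("period").to_numpy()
    stat = status.to_numpy()
    comparisons = list(SURVEY_COMPARISONS)
    if include_total:
        comparisons = [("total_1990_vs_2020", ("P1990", None), ("P2020", None))] + comparisons

    rows = []
    ss = np.random.SeedSequence(seed)
    for (name, (pa, sa), (pb, sb)), child in zip(
        comparisons, ss.spawn(len(comparisons))
    ):
        mask_a = (periods == pa) & ((stat == sa) if sa else True)
        mask_b = (periods == pb) & ((stat == sb) if sb else True)
        sub = values[mask_a | mask_b]
        lab = np.where(mask_a[mask_a | mask_b], "A", "B")
        base = {"comparison": name, "n_A": int(mask_a.sum()), "n_B": int(mask_b.sum())}
        if mask_a.sum() < 2 or mask_b.sum() < 2:
            rows.append({**base, "V_A": np.nan, "V_B": np.nan,
                         "V_intersection": np.nan, "sorensen": np.nan,
                         "p_null": np.nan, "ci_lo": np.nan, "ci_hi": np.nan,
                         "note": "group too small"})
            continue
        s1, s2 = child.spawn(2)
        res = overlap_null_test(sub, lab, n_perm=n_perm,
                                seed=s1.generate_state(1)[0] % (2**31),
                                samples_per_point=samples_per_point,
                                quantile=quantile,
                                perm_samples_per_point=resample_samples_per_point)
        ci = bootstrap_overlap(sub, lab, n_boot=n_boot,
                               seed=s2.generate_state(1)[0] % (2**31),
                               samples_per_point=samples_per_point,
                               quantile=quantile,
                               boot_samples_per_point=resample_samples_per_point).ci
        rows.append({**base, "V_A": res.v_a, "V_B": res.v_b,
                     "V_intersection": res.v_intersection,
                     "sorensen": res.sorensen, "p_null": res.p_value,
                     "ci_lo": ci[0], "ci_hi": ci[1], "note": ""})
    return pd.DataFrame(rows)
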