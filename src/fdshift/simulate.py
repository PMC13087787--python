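"""Synthetic two-period fish surveys with known ground truth.

The generator emulates the structure of a 30-year resurvey of a tropical
river basin: a large historical native pool of which only a fraction
persists, a small set of non-native species appearing (mostly) in the
second period, ten correlated positive morphological traits with a
period-specific mean shift for surviving natives, lognormal site
abundances, and environment-linked, spatially autocorrelated community
composition.

Traits are drawn as exp(MVN) so the downstream log + Z-score pipeline
recovers the exact multivariate-normal structure.  A single site-occupancy
draw is shared by both periods, so in a null scenario (full survival, zero
shift, no non-natives) the two periods differ only in abundance noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Literal

import numpy as np
import pandas as pd

from .data import (
    PREDICTOR_NAMES,
    TRAIT_NAMES,
    CommunityMatrix,
    SiteTable,
    SurveyPair,
    TraitTable,
    ValidationError,
)


def _default_covariance() -> np.ndarray:
    # AR(1)-correlated log-traits, sd 0.5, neighbour correlation 0.5
    k = len(TRAIT_NAMES)
    idx = np.arange(k)
    return 0.25 * 0.5 ** np.abs(idx[:, None] - idx[None, :])


def _default_shift() -> np.ndarray:
    # Sign pattern of the observed decadal shifts: most shape ratios shrink,
    # caudal throttling and eye position rise, body mass roughly stable.
    return np.array([0.0, -0.3, -0.6, 0.6, -0.25, 0.15, -0.3, -0.55, 0.45, -0.4])


def _default_offset() -> np.ndarray:
    # Non-native centroid displaced on the log scale (larger, deeper-bodied).
    return np.array([1.0, 0.5, 0.4, -0.3, 0.3, 0.0, -0.3, 0.3, -0.3, 0.2])


def _default_env_beta() -> np.ndarray:
    # predictors x traits; sparse paper-motivated links:
    # MAP -> CFd/CPd (+), DO -> BodyMass (-), Dam -> HL/SL (+), Intro -> BD/SL (+)
    beta = np.zeros((len(PREDICTOR_NAMES), len(TRAIT_NAMES)))
    beta[PREDICTOR_NAMES.index("MAP"), TRAIT_NAMES.index("CFd/CPd")] = 0.5
    beta[PREDICTOR_NAMES.index("DO"), TRAIT_NAMES.index("BodyMass")] = -0.5
    beta[PREDICTOR_NAMES.index("Dam"), TRAIT_NAMES.index("HL/SL")] = 0.5
    beta[PREDICTOR_NAMES.index("Intro"), TRAIT_NAMES.index("BD/SL")] = 0.5
    return beta


@dataclass
class SyntheticScenario:
    """Parameters of a synthetic two-period survey.

    Defaults mirror the motivating study's design: 19 sites, ~90 historical
    native species of which ~35% persist, 7 non-native species by the second
    period (2 already present, rare, in the first), 10 correlated traits.
    """

    n_sites: int = 19
    n_native_1990: int = 90
    native_survival_prob: float = 0.35
    n_nonnative_2020: int = 7
    n_nonnative_1990: int = 2
    trait_mean: np.ndarray = field(
        default_factory=lambda: np.array([3.0] + [-0.7] * 9)
    )
    trait_covariance: np.ndarray = field(default_factory=_default_covariance)
    native_trait_shift: np.ndarray = field(default_factory=_default_shift)
    nonnative_offset: np.ndarray = field(default_factory=_default_offset)
    nonnative_trait_shift: np.ndarray = field(
        default_factory=lambda: np.zeros(len(TRAIT_NAMES))
    )
    # per-species scatter of the decadal shift (species are re-measured,
    # so their individual shifts differ around the mean); on the log scale
    native_trait_shift_sd: float = 0.15
    nonnative_trait_shift_sd: float = 0.15
    env_beta: np.ndarray = field(default_factory=_default_env_beta)
    spatial_range: float = 30.0  # km, exponential correlation length
    error_sd: float = 0.3
    abundance_lognormal_sigma: float = 1.0
    occupancy_prob: float = 0.6
    extent_km: float = 100.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        k = len(TRAIT_NAMES)
        self.trait_mean = np.asarray(self.trait_mean, dtype=float)
        self.trait_covariance = np.asarray(self.trait_covariance, dtype=float)
        self.native_trait_shift = np.asarray(self.native_trait_shift, dtype=float)
        self.nonnative_offset = np.asarray(self.nonnative_offset, dtype=float)
        self.nonnative_trait_shift = np.asarray(self.nonnative_trait_shift, dtype=float)
        self.env_beta = np.asarray(self.env_beta, dtype=float)
        if self.trait_covariance.shape != (k, k):
            raise ValidationError(f"trait_covariance must be {k}x{k}")
        try:
            np.linalg.cholesky(self.trait_covariance)
        except np.linalg.LinAlgError as e:
            raise ValidationError("trait_covariance is not SPD") from e
        if not (0.0 < self.native_survival_prob <= 1.0):
            raise ValidationError("native_survival_prob must be in (0, 1]")
        if self.n_nonnative_1990 > self.n_nonnative_2020:
            raise ValidationError("n_nonnative_1990 cannot exceed n_nonnative_2020")


@dataclass
class GroundTruth:
    """What the generator actually did; targets for parameter recovery."""

    survivors: list[str]
    lost_natives: list[str]
    nonnative_1990: list[str]
    nonnative_2020: list[str]
    native_trait_shift: np.ndarray
    nonnative_trait_shift: np.ndarray
    native_trait_shift_sd: float
    nonnative_trait_shift_sd: float
    nonnative_offset: np.ndarray
    env_beta: np.ndarray
    spatial_range: float
    error_sd: float
    rng_seed: int

    def to_jsonable(self) -> dict:
        d = asdict(self)
        for key in ("native_trait_shift", "nonnative_trait_shift",
                    "nonnative_offset", "env_beta"):
            d[key] = np.asarray(d[key]).tolist()
        return d


def spatial_correlation(
    coords: np.ndarray,
    rho: float,
    structure: Literal["exponential", "gaussian", "spherical"] = "exponential",
) -> np.ndarray:
    """Distance-decay correlation matrix used for simulation and GLS."""
    from scipy.spatial.distance import pdist, squareform

    d = squareform(pdist(coords))
    if structure == "exponential":
        return np.exp(-d / rho)
    if structure == "gaussian":
        return np.exp(-((d / rho) ** 2))
    if structure == "spherical":
        C = np.where(d < rho, 1.0 - 1.5 * (d / rho) + 0.5 * (d / rho) ** 3, 0.0)
        return C
    raise ValueError(f"unknown structure {structure!r}")


def simulate_spatial_response(
    coords: np.ndarray,
    X: np.ndarray,
    beta: np.ndarray,
    rho: float,
    sigma: float,
    structure: Literal["exponential", "gaussian", "spherical"] = "exponential",
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """y = X beta + eps with eps ~ MVN(0, sigma^2 C(rho)); for GLS testing."""
    rng = rng or np.random.default_rng()
    C = spatial_correlation(coords, rho, structure)
    # small jitter keeps the Cholesky stable for near-singular structures
    L = np.linalg.cholesky(C + 1e-10 * np.eye(len(C)))
    eps = sigma * (L @ rng.standard_normal(len(C)))
    return np.asarray(X, dtype=float) @ np.asarray(beta, dtype=float) + eps


def generate_scenario(
    scenario: SyntheticScenario | None = None,
) -> tuple[SurveyPair, SiteTable, GroundTruth]:
    """Draw one synthetic survey; fixed seed gives byte-identical output."""
    s = scenario or SyntheticScenario()
    rng = np.random.default_rng(s.rng_seed)
    k = len(TRAIT_NAMES)

    natives = [f"nat{i:03d}" for i in range(s.n_native_1990)]
    nonnat = [f"inv{i:02d}" for i in range(s.n_nonnative_2020)]
    nonnat_1990 = nonnat[: s.n_nonnative_1990]

    log_nat = rng.multivariate_normal(s.trait_mean, s.trait_covariance,
                                      size=s.n_native_1990, method="cholesky")
    log_inv = rng.multivariate_normal(s.trait_mean + s.nonnative_offset,
                                      s.trait_covariance,
                                      size=s.n_nonnative_2020, method="cholesky")

    survive = rng.random(s.n_native_1990) < s.native_survival_prob
    # decomposition needs enough survivors for a hull in a few dimensions
    if survive.sum() < 6:
        survive[rng.choice(s.n_native_1990, 6, replace=False)] = True
    survivors = [sp for sp, keep in zip(natives, survive) if keep]
    lost = [sp for sp, keep in zip(natives, survive) if not keep]

    def trait_table(ids: list[str], logvals: np.ndarray, status: list[str],
                    period: str) -> TraitTable:
        df = pd.DataFrame(np.exp(logvals), index=pd.Index(ids, name="species_id"),
                          columns=list(TRAIT_NAMES))
        st = pd.Series(status, index=df.index, name="status")
        return TraitTable(df, st, period)

    t90 = trait_table(
        natives + nonnat_1990,
        np.vstack([log_nat, log_inv[: s.n_nonnative_1990]]),
        ["native"] * len(natives) + ["non_native"] * len(nonnat_1990),
        "P1990",
    )
    log_surv_2020 = (
        log_nat[survive] + s.native_trait_shift
        + s.native_trait_shift_sd * rng.standard_normal((int(survive.sum()), k))
    )
    log_inv_2020 = (
        log_inv + s.nonnative_trait_shift
        + s.nonnative_trait_shift_sd * rng.standard_normal((s.n_nonnative_2020, k))
    )
    t20 = trait_table(
        survivors + nonnat,
        np.vstack([log_surv_2020, log_inv_2020]),
        ["native"] * len(survivors) + ["non_native"] * len(nonnat),
        "P2020",
    )

    # sites: uniform on a square basin; scaled iid N(0,1) predictors
    site_ids = [f"S{i:02d}" for i in range(s.n_sites)]
    coords = rng.uniform(0.0, s.extent_km, size=(s.n_sites, 2))
    preds = rng.standard_normal((s.n_sites, len(PREDICTOR_NAMES)))
    site_df = pd.DataFrame(
        np.column_stack([coords, preds]),
        index=pd.Index(site_ids, name="site_id"),
        columns=["x", "y", *PREDICTOR_NAMES],
    )
    sites = SiteTable(site_df)

    # one occupancy draw shared by both periods: turnover comes only from
    # global losses/gains, matching the null-scenario contract
    pool = natives + nonnat
    occupancy = rng.random((s.n_sites, len(pool))) < s.occupancy_prob
    for r in range(s.n_sites):  # every site hosts at least one native
        if not occupancy[r, : s.n_native_1990].any():
            occupancy[r, rng.integers(0, s.n_native_1990)] = True

    # environment -> trait-weighted abundance tilt, with spatially
    # correlated noise shared across both periods' expectations
    Xs = (preds - preds.mean(0)) / preds.std(0, ddof=1)
    C = spatial_correlation(coords, s.spatial_range, "exponential")
    L = np.linalg.cholesky(C + 1e-10 * np.eye(s.n_sites))
    E = s.error_sd * (L @ rng.standard_normal((s.n_sites, k)))
    u = Xs @ s.env_beta + E  # n_sites x n_traits
    z_pool = np.vstack([log_nat, log_inv])
    z_std = (z_pool - s.trait_mean) / np.sqrt(np.diag(s.trait_covariance))
    tilt = u @ z_std.T  # n_sites x n_pool

    def community(period: str, keep_ids: list[str]) -> CommunityMatrix:
        keep = np.array([sp in set(keep_ids) for sp in pool])
        noise = s.abundance_lognormal_sigma * rng.standard_normal(
            (s.n_sites, len(pool))
        )
        ab = np.exp(tilt + noise) * occupancy * keep
        if period == "P1990":  # pre-period non-natives are rare
            for j, sp in enumerate(pool):
                if sp in set(nonnat_1990):
                    ab[:, j] *= 0.1
        df = pd.DataFrame(ab, index=pd.Index(site_ids, name="site_id"),
                          columns=pool)
        df = df.loc[:, df.columns.isin(keep_ids)]
        empty = df.sum(axis=1) <= 0
        if empty.any():  # degenerate draw: seed one present species
            for r in df.index[empty]:
                df.loc[r, keep_ids[0]] = 1e-6
        return CommunityMatrix(df, period)

    c90 = community("P1990", natives + nonnat_1990)
    c20 = community("P2020", survivors + nonnat)

    pair = SurveyPair(t90, t20, c90, c20)
    truth = GroundTruth(
        survivors=survivors,
        lost_natives=lost,
        nonnative_1990=nonnat_1990,
        nonnative_2020=nonnat,
        native_trait_shift=s.native_trait_shift.copy(),
        nonnative_trait_shift=s.nonnative_trait_shift.copy(),
        native_trait_shift_sd=s.native_trait_shift_sd,
        nonnative_trait_shift_sd=s.nonnative_trait_shift_sd,
        nonnative_offset=s.nonnative_offset.copy(),
        env_beta=s.env_beta.copy(),
        spatial_range=s.spatial_range,
        error_sd=s.error_sd,
        rng_seed=s.rng_seed,
    )
    return pair, sites, truth


def null_scenario(seed: int = 0, **overrides) -> SyntheticScenario:
    """No loss, no shift, no non-natives: periods differ only in abundance noise."""
    base = dict(
        native_survival_prob=1.0,
        n_nonnative_2020=0,
        n_nonnative_1990=0,
        native_trait_shift=np.zeros(len(TRAIT_NAMES)),
        nonnative_trait_shift=np.zeros(len(TRAIT_NAMES)),
        native_trait_shift_sd=0.0,
        nonnative_trait_shift_sd=0.0,
        env_beta=np.zeros((len(PREDICTOR_NAMES), len(TRAIT_NAMES))),
        rng_seed=seed,
    )
    base.update(overrides)
    return SyntheticScenario(**base)
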