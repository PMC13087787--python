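"""Counterfactual decomposition of functional-richness change.

The 30-year change in per-site functional richness (FRic) is split into
four additive-by-construction components by re-computing FRic under
counterfactual communities in the shared functional space:

* X1 (native turnover)          — native presence/absence switched to the
  second survey, traits held at first-survey values;
* X2 (native trait shift)       — native composition held, native trait
  coordinates switched to second-survey measurements;
* X3 (non-native turnover)      — as X1 for non-natives;
* X4 (non-native trait shift)   — as X2 for non-natives.

Each component is counterfactual FRic minus baseline FRic (baseline:
first-survey composition with first-survey traits); the response Y is the
fully-observed change, FRic(2020 community, 2020 traits) - baseline.
Species entering through a composition swap use their second-survey trait
coordinates (the only measurement available); species measured in both
surveys keep the non-swapped survey's coordinates.

Variation partitioning then attributes the variance of Y across sites to
the four components: adjusted R-squared is recorded for all 15 non-empty
predictor subsets and the 15 exclusive (unique + shared) fractions are
recovered by inclusion-exclusion; unique + shared + residual sums to 1
exactly.  Negative fractions are reported, never silently clamped.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .data import StandardizedTraits, SurveyPair, standardize_traits
from .fspace import FunctionalSpace, functional_richness, pcoa, trait_distance_matrix

COMPONENTS = ("X1", "X2", "X3", "X4")
COMPONENT_MEANING = {
    "X1": "native turnover",
    "X2": "native trait shift",
    "X3": "non-native turnover",
    "X4": "non-native trait shift",
}
SWAPS = ("native_comp", "native_traits", "nonnative_comp", "nonnative_traits")
_SWAP_TO_COMPONENT = dict(zip(SWAPS, COMPONENTS))


def build_shared_space(
    sp: SurveyPair, k_use: int = 4, pool_periods: bool = True
) -> tuple[FunctionalSpace, StandardizedTraits]:
    """PCoA space holding both periods' trait rows (pooled scale by default)."""
    st = standardize_traits([sp.traits_1990, sp.traits_2020],
                            pool_periods=pool_periods)
    fs = pcoa(trait_distance_matrix(st), k=k_use)
    return fs, st


def _coord_lookup(fs: FunctionalSpace, k_use: int) -> dict:
    return {key: fs.coordinates[i, :k_use] for i, key in enumerate(fs.species)}


def _site_keys(sp: SurveyPair, site: str, swap: str | None) -> list[tuple[str, str]]:
    """(period, species) coordinate keys for one site under one counterfactual."""
    c90, c20 = sp.community_1990, sp.community_2020
    stat90, stat20 = sp.traits_1990.status, sp.traits_2020.status
    has90 = set(sp.traits_1990.species)
    has20 = set(sp.traits_2020.species)
    present90 = c90.present(site)
    present20 = c20.present(site)

    def status(spc: str) -> str:
        return stat90.get(spc, stat20.get(spc))

    if swap in (None, "native_traits", "nonnative_traits"):
        group = {"native_traits": "native", "nonnative_traits": "non_native"}.get(swap)
        keys = []
        for spc in present90:
            if group is not None and status(spc) == group and spc in has20:
                keys.append(("P2020", spc))
            else:
                keys.append(("P1990", spc))
        return keys
    if swap in ("native_comp", "nonnative_comp"):
        group = "native" if swap == "native_comp" else "non_native"
        keys = []
        for spc in present90:  # untouched group keeps baseline composition
            if status(spc) != group:
                keys.append(("P1990", spc))
        for spc in present20:  # swapped group takes second-survey composition
            if status(spc) == group:
                keys.append(("P1990", spc) if spc in has90 else ("P2020", spc))
        return keys
    if swap == "full_2020":
        return [("P2020", spc) if spc in has20 else ("P1990", spc)
                for spc in present20]
    raise ValueError(f"unknown swap {swap!r}")


def counterfactual_frich(
    sp: SurveyPair,
    swap: str | None,
    fs: FunctionalSpace,
    k_use: int = 4,
) -> pd.Series:
    """Per-site FRic under one counterfactual (None = baseline); NaN if undefined."""
    lookup = _coord_lookup(fs, k_use)
    vals = {}
    for site in sp.sites:
        keys = _site_keys(sp, site, swap)
        pts = np.array([lookup[k] for k in keys])
        v = functional_richness(pts) if len(pts) >= k_use + 1 else None
        vals[site] = np.nan if v is None else v
    return pd.Series(vals, name=swap or "baseline")


@dataclass
class ComponentVectors:
    table: pd.DataFrame  # sites x (Y, X1..X4)
    excluded_sites: list[str]

    @property
    def Y(self) -> np.ndarray:
        return self.table["Y"].to_numpy()

    def X(self, name: str) -> np.ndarray:
        return self.table[name].to_numpy()


def build_components(sp: SurveyPair, k_use: int = 4,
                     fs: FunctionalSpace | None = None) -> ComponentVectors:
    """Per-site Y = observed delta-FRic and the four counterfactual components."""
    if fs is None:
        fs, _ = build_shared_space(sp, k_use=k_use)
    base = counterfactual_frich(sp, None, fs, k_use)
    full = counterfactual_frich(sp, "full_2020", fs, k_use)
    cols = {"Y": full - base}
    for swap in SWAPS:
        cols[_SWAP_TO_COMPONENT[swap]] = counterfactual_frich(sp, swap, fs, k_use) - base
    df = pd.DataFrame(cols)
    excluded = df.index[df.isna().any(axis=1)].tolist()
    df = df.dropna()
    if len(df) < 4:
        raise ValueError(
            f"only {len(df)} usable sites after exclusions {excluded}; "
            "variation partitioning is ill-posed"
        )
    return ComponentVectors(table=df, excluded_sites=excluded)


def _adjusted_r2(y: np.ndarray, X: np.ndarray) -> float:
    """Adjusted R2 = 1 - (1-R2)(n-1)/(n-p-1), p = number of columns.

    Constant (zero-variance) columns contribute nothing to the fit but
    still spend their degree of freedom; genuine collinearity among
    non-constant columns makes the attribution ambiguous and yields NaN.
    """
    n, p = X.shape
    if n - p - 1 <= 0:
        return float("nan")
    scale = np.abs(X).max(axis=0)
    live = X.std(axis=0) > 1e-12 * (1.0 + scale)
    Xl = X[:, live]
    if Xl.shape[1] and np.linalg.matrix_rank(Xl) < Xl.shape[1]:
        return float("nan")
    model = sm.OLS(y, sm.add_constant(Xl, has_constant="add")).fit()
    r2 = model.rsquared
    return float(1.0 - (1.0 - r2) * (n - 1) / (n - p - 1))


@dataclass
class DecompositionResult:
    marginal_r2: dict[str, float]
    subset_r2: dict[frozenset, float]
    fractions: dict[frozenset, float]  # exclusive unique/shared fractions
    residual: float
    vif: dict[str, float]
    negative_fractions: dict[str, float]
    n_sites: int
    excluded_sites: list[str] = field(default_factory=list)

    def fraction(self, *components: str) -> float:
        return self.fractions[frozenset(components)]

    @property
    def unique(self) -> dict[str, float]:
        return {c: self.fractions[frozenset([c])] for c in COMPONENTS}

    def summary(self) -> dict:
        key = lambda s: "&".join(sorted(s))
        return {
            "marginal_adjusted_R2": self.marginal_r2,
            "fractions": {key(s): v for s, v in self.fractions.items()},
            "residual": self.residual,
            "vif": self.vif,
            "negative_fractions": self.negative_fractions,
            "n_sites": self.n_sites,
            "excluded_sites": self.excluded_sites,
        }


def _component_vifs(X: pd.DataFrame) -> dict[str, float]:
    out = {}
    for c in X.columns:
        if X[c].std() <= 1e-12 * (1.0 + X[c].abs().max()):
            out[c] = float("nan")  # constant component: collinearity moot
            continue
        others = X.drop(columns=c)
        r2 = sm.OLS(X[c], sm.add_constant(others)).fit().rsquared
        out[c] = float(np.inf) if r2 >= 1.0 else float(1.0 / (1.0 - r2))
    return out


def variation_partition(cv: ComponentVectors) -> DecompositionResult:
    """Adjusted-R2 variation partitioning of Y over X1..X4.

    Marginal values are single-predictor adjusted R2 (these may well sum to
    more than 1); the exclusive fractions solve the inclusion-exclusion
    system over all 15 subset models and sum with the residual to exactly 1.
    """
    df = cv.table
    y = df["Y"].to_numpy()
    n = len(df)
    subsets = []
    for r in range(1, len(COMPONENTS) + 1):
        subsets.extend(frozenset(c) for c in combinations(COMPONENTS, r))
    subset_r2 = {}
    for S in subsets:
        subset_r2[S] = _adjusted_r2(y, df[sorted(S)].to_numpy())

    # inclusion-exclusion: A(S) = sum over T with T&S nonempty of b(T)
    A = np.array([[1.0 if S & T else 0.0 for T in subsets] for S in subsets])
    rhs = np.array([subset_r2[S] for S in subsets])
    if np.any(np.isnan(rhs)):
        fractions = {S: np.nan for S in subsets}
        residual = np.nan
    else:
        b = np.linalg.solve(A, rhs)
        fractions = dict(zip(subsets, map(float, b)))
        residual = float(1.0 - subset_r2[frozenset(COMPONENTS)])

    key = lambda s: "&".join(sorted(s))
    neg = {key(S): v for S, v in fractions.items()
           if np.isfinite(v) and v < 0}
    return DecompositionResult(
        marginal_r2={c: subset_r2[frozenset([c])] for c in COMPONENTS},
        subset_r2=subset_r2,
        fractions=fractions,
        residual=residual,
        vif=_component_vifs(df[list(COMPONENTS)]),
        negative_fractions=neg,
        n_sites=n,
        excluded_sites=cv.excluded_sites,
    )
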