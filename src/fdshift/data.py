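"""Core domain types for two-period fish community surveys.

The analysis compares fish assemblages surveyed in two periods (``P1990``
and ``P2020``) at a shared set of sites.  Each period carries a species x
trait table (10 continuous morphological traits, e.g. body mass and nine
shape ratios such as body depth / standard length) plus a site x species
abundance matrix.  Sites additionally carry projected coordinates and nine
scaled environmental predictors.

Traits enter every downstream computation log-transformed (natural log)
and Z-scored; by default the two periods' species are pooled into a single
fitting set so that both periods live in one commensurable functional
space.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: Canonical trait names, fixed order. '/' maps to '_' in CSV headers.
TRAIT_NAMES: tuple[str, ...] = (
    "BodyMass",
    "BD/SL",
    "BD/BW",
    "CFd/CPd",
    "HL/SL",
    "HD/BD",
    "SnL/HD",
    "Mo/HD",
    "EH/HD",
    "ED/HD",
)

#: Environmental predictor names, fixed order (site table columns).
PREDICTOR_NAMES: tuple[str, ...] = (
    "MAP",
    "MAT",
    "ChlA",
    "DO",
    "EC",
    "Forest",
    "Dam",
    "POP",
    "Intro",
)

PERIODS = ("P1990", "P2020")
STATUSES = ("native", "non_native")


class ValidationError(ValueError):
    """Raised when survey data violates a domain invariant."""


class FormatError(ValueError):
    """Raised when an input file does not match the expected schema."""


def trait_to_header(name: str) -> str:
    return name.replace("/", "_")


def header_to_trait(header: str) -> str:
    mapping = {trait_to_header(t): t for t in TRAIT_NAMES}
    return mapping.get(header, header)


@dataclass
class TraitTable:
    """Species x trait values for one survey period.

    ``traits`` is indexed by species_id with the 10 canonical trait columns;
    all raw values must be strictly positive so the log transform is defined.
    """

    traits: pd.DataFrame
    status: pd.Series
    period: str

    def __post_init__(self) -> None:
        if self.period not in PERIODS:
            raise ValidationError(f"unknown period {self.period!r}")
        if list(self.traits.columns) != list(TRAIT_NAMES):
            missing = set(TRAIT_NAMES) - set(self.traits.columns)
            extra = set(self.traits.columns) - set(TRAIT_NAMES)
            raise FormatError(
                f"trait columns must be exactly the 10 canonical names; "
                f"missing={sorted(missing)}, unexpected={sorted(extra)}"
            )
        if self.traits.index.has_duplicates:
            dups = self.traits.index[self.traits.index.duplicated()].tolist()
            raise ValidationError(f"duplicate species_id within period: {dups}")
        bad = set(self.status.unique()) - set(STATUSES)
        if bad:
            raise ValidationError(f"unknown status values: {sorted(bad)}")
        if not self.status.index.equals(self.traits.index):
            raise ValidationError("status index must match trait table index")
        vals = self.traits.to_numpy(dtype=float)
        if not np.all(np.isfinite(vals)):
            raise ValidationError(f"non-finite trait values in period {self.period}")
        if np.any(vals <= 0):
            r, c = np.argwhere(vals <= 0)[0]
            raise ValidationError(
                f"non-positive trait value: species {self.traits.index[r]!r}, "
                f"trait {TRAIT_NAMES[c]!r} = {vals[r, c]} (log-transform undefined)"
            )

    @property
    def species(self) -> list[str]:
        return list(self.traits.index)

    def subset(self, species: Iterable[str]) -> "TraitTable":
        idx = [s for s in self.traits.index if s in set(species)]
        return TraitTable(self.traits.loc[idx], self.status.loc[idx], self.period)


@dataclass
class StandardizedTraits:
    """Log + Z-score standardized traits with the transform parameters.

    Rows are keyed by (period, species_id) so a species measured in both
    periods contributes two distinct points to the functional space.
    ``mean`` / ``sd`` are the per-trait moments of the log values over the
    fitting pool; ``transform`` reapplies them to held-out species.
    """

    values: pd.DataFrame  # MultiIndex (period, species_id) x traits
    mean: pd.Series | dict
    sd: pd.Series | dict
    status: pd.Series

    def params_for(self, period: str) -> tuple[pd.Series, pd.Series]:
        if isinstance(self.mean, dict):  # per-period standardization
            return self.mean[period], self.sd[period]
        return self.mean, self.sd

    def transform(self, table: TraitTable) -> pd.DataFrame:
        mean, sd = self.params_for(table.period)
        logs = np.log(table.traits)
        return (logs - mean) / sd

    def rows_for(self, period: str) -> pd.DataFrame:
        return self.values.xs(period, level="period")


def standardize_traits(
    tables: Sequence[TraitTable] | TraitTable,
    pool: Iterable[str] | None = None,
    pool_periods: bool = True,
) -> StandardizedTraits:
    """Natural-log transform then Z-score (sample sd, n-1 denominator).

    The fitting set is the concatenation of all rows of ``tables`` (optionally
    restricted to species ids in ``pool``); each trait column of the fitting
    set ends up with mean 0 and sd 1.  With ``pool_periods=False`` each
    table is standardized against its own moments instead — the periods
    then no longer share a scale, which makes cross-period volume
    comparisons meaningless; off by default for that reason.
    """
    if isinstance(tables, TraitTable):
        tables = [tables]
    if not pool_periods:
        parts = [standardize_traits(t, pool=pool) for t in tables]
        return StandardizedTraits(
            values=pd.concat([p.values for p in parts]),
            mean={t.period: p.mean for t, p in zip(tables, parts)},
            sd={t.period: p.sd for t, p in zip(tables, parts)},
            status=pd.concat([p.status for p in parts]),
        )
    frames, statuses = [], []
    for t in tables:
        df = t.traits
        st = t.status
        if pool is not None:
            keep = [s for s in df.index if s in set(pool)]
            df, st = df.loc[keep], st.loc[keep]
        df = df.copy()
        df.index = pd.MultiIndex.from_product(
            [[t.period], df.index], names=["period", "species_id"]
        )
        st = st.copy()
        st.index = df.index
        frames.append(df)
        statuses.append(st)
    pooled = pd.concat(frames)
    status = pd.concat(statuses)
    if pooled.empty:
        raise ValidationError("empty fitting pool for standardization")
    logs = np.log(pooled)
    mean = logs.mean(axis=0)
    sd = logs.std(axis=0, ddof=1)
    zero_var = sd[~(sd > 0)].index.tolist()
    if zero_var:
        raise ValidationError(f"zero variance in trait column(s) {zero_var}; cannot Z-score")
    z = (logs - mean) / sd
    return StandardizedTraits(values=z, mean=mean, sd=sd, status=status)


@dataclass
class CommunityMatrix:
    """Site x species relative abundances for one period.

    Rows are renormalized to sum to 1 at construction (abundances are
    interpreted as relative abundance P_i throughout).
    """

    abundance: pd.DataFrame  # site_id x species_id
    period: str
    renormalize: bool = True

    def __post_init__(self) -> None:
        if self.period not in PERIODS:
            raise ValidationError(f"unknown period {self.period!r}")
        vals = self.abundance.to_numpy(dtype=float)
        if not np.all(np.isfinite(vals)):
            raise ValidationError("non-finite abundance values")
        if np.any(vals < 0):
            r, c = np.argwhere(vals < 0)[0]
            raise ValidationError(
                f"negative abundance at site {self.abundance.index[r]!r}, "
                f"species {self.abundance.columns[c]!r}"
            )
        rowsum = vals.sum(axis=1)
        if np.any(rowsum <= 0):
            bad = self.abundance.index[rowsum <= 0].tolist()
            raise ValidationError(f"site(s) with zero total abundance: {bad}")
        if self.renormalize:
            sums = self.abundance.sum(axis=1)
            # rows already normalized stay untouched so round-trips are stable
            self.abundance = self.abundance.div(sums.where((sums - 1.0).abs() > 1e-9, 1.0), axis=0)

    @property
    def sites(self) -> list[str]:
        return list(self.abundance.index)

    @property
    def species(self) -> list[str]:
        return list(self.abundance.columns)

    def present(self, site: str, tol: float = 0.0) -> list[str]:
        row = self.abundance.loc[site]
        return list(row.index[row > tol])


@dataclass
class SurveyPair:
    """Matched two-period survey: trait tables plus community matrices.

    Site lists must be identical and identically ordered in both periods
    (19 sites in the motivating study; any n >= 4 accepted).  Community
    species must be a subset of the same period's trait table.
    """

    traits_1990: TraitTable
    traits_2020: TraitTable
    community_1990: CommunityMatrix
    community_2020: CommunityMatrix

    def __post_init__(self) -> None:
        if self.traits_1990.period != "P1990" or self.community_1990.period != "P1990":
            raise ValidationError("first-period objects must be labelled P1990")
        if self.traits_2020.period != "P2020" or self.community_2020.period != "P2020":
            raise ValidationError("second-period objects must be labelled P2020")
        if self.community_1990.sites != self.community_2020.sites:
            raise ValidationError("site lists differ between periods (order matters)")
        if len(self.sites) < 4:
            raise ValidationError(f"need at least 4 sites, got {len(self.sites)}")
        for comm, tt in ((self.community_1990, self.traits_1990),
                         (self.community_2020, self.traits_2020)):
            orphan = set(comm.species) - set(tt.species)
            if orphan:
                raise ValidationError(
                    f"species in {comm.period} community but not in its trait "
                    f"table: {sorted(orphan)}"
                )

    @property
    def sites(self) -> list[str]:
        return self.community_1990.sites

    def traits(self, period: str) -> TraitTable:
        return self.traits_1990 if period == "P1990" else self.traits_2020

    def community(self, period: str) -> CommunityMatrix:
        return self.community_1990 if period == "P1990" else self.community_2020


@dataclass
class SiteTable:
    """Site coordinates (projected, shared length unit) plus 9 predictors."""

    table: pd.DataFrame  # site_id x (x, y, predictors)

    def __post_init__(self) -> None:
        needed = ["x", "y", *PREDICTOR_NAMES]
        missing = [c for c in needed if c not in self.table.columns]
        if missing:
            raise FormatError(f"site table missing column(s): {missing}")
        self.table = self.table[needed]
        coords = self.table[["x", "y"]].to_numpy(dtype=float)
        if not np.all(np.isfinite(coords)):
            raise ValidationError("non-finite site coordinates")
        if len(np.unique(coords, axis=0)) != len(coords):
            raise ValidationError("duplicated site coordinates")
        preds = self.table[list(PREDICTOR_NAMES)].to_numpy(dtype=float)
        if not np.all(np.isfinite(preds)):
            raise ValidationError("missing/non-finite predictor values")

    @property
    def sites(self) -> list[str]:
        return list(self.table.index)

    @property
    def coords(self) -> np.ndarray:
        return self.table[["x", "y"]].to_numpy(dtype=float)

    def predictors(self, scaled: bool = True) -> pd.DataFrame:
        X = self.table[list(PREDICTOR_NAMES)].astype(float)
        if scaled:
            X = (X - X.mean()) / X.std(ddof=1)
        return X
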