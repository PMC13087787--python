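"""CSV readers/writers for the survey file schemas.

Schemas (UTF-8, '/' in trait names mapped to '_' in headers):

* ``traits_<period>.csv``  — ``species_id,status,BodyMass,BD_SL,...,ED_HD``
* ``community_<period>.csv`` — ``site_id`` plus one column per species_id
* ``sites.csv`` — ``site_id,x,y,MAP,MAT,ChlA,DO,EC,Forest,Dam,POP,Intro``
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Mapping

import pandas as pd

from .data import (
    PREDICTOR_NAMES,
    TRAIT_NAMES,
    CommunityMatrix,
    FormatError,
    SiteTable,
    SurveyPair,
    TraitTable,
    ValidationError,
    header_to_trait,
    trait_to_header,
)

log = logging.getLogger(__name__)

TRAIT_HEADERS = [trait_to_header(t) for t in TRAIT_NAMES]


def read_trait_table(path: str | Path, period: str) -> TraitTable:
    df = pd.read_csv(path)
    expected = ["species_id", "status", *TRAIT_HEADERS]
    if list(df.columns) != expected:
        missing = [c for c in expected if c not in df.columns]
        extra = [c for c in df.columns if c not in expected]
        raise FormatError(
            f"{path}: bad trait header; missing={missing}, unexpected={extra}"
        )
    df = df.set_index("species_id")
    status = df["status"].astype(str)
    traits = df[TRAIT_HEADERS].astype(float)
    traits.columns = [header_to_trait(c) for c in traits.columns]
    return TraitTable(traits=traits, status=status, period=period)


def read_community(path: str | Path, period: str) -> CommunityMatrix:
    df = pd.read_csv(path)
    if df.columns[0] != "site_id":
        raise FormatError(f"{path}: first column must be 'site_id'")
    df = df.set_index("site_id").astype(float)
    return CommunityMatrix(abundance=df, period=period)


def read_sites(path: str | Path) -> SiteTable:
    df = pd.read_csv(path)
    if df.columns[0] != "site_id":
        raise FormatError(f"{path}: first column must be 'site_id'")
    return SiteTable(table=df.set_index("site_id"))


def read_survey(
    paths: Mapping[str, str | Path],
    drop_unknown_species: bool = False,
) -> tuple[SurveyPair, SiteTable]:
    """Load and validate a full two-period survey.

    ``paths`` needs keys ``traits_1990, traits_2020, community_1990,
    community_2020, sites``.  Community species missing from the matching
    trait table are a hard error unless ``drop_unknown_species`` is set, in
    which case they are dropped with a logged warning (rows renormalize).
    """
    needed = {"traits_1990", "traits_2020", "community_1990", "community_2020", "sites"}
    missing = needed - set(paths)
    if missing:
        raise FormatError(f"read_survey: missing path(s) for {sorted(missing)}")
    t90 = read_trait_table(paths["traits_1990"], "P1990")
    t20 = read_trait_table(paths["traits_2020"], "P2020")
    c90 = read_community(paths["community_1990"], "P1990")
    c20 = read_community(paths["community_2020"], "P2020")
    if drop_unknown_species:
        for comm, tt in ((c90, t90), (c20, t20)):
            orphan = sorted(set(comm.species) - set(tt.species))
            if orphan:
                log.warning(
                    "%s community: dropping %d species absent from trait table: %s",
                    comm.period, len(orphan), orphan,
                )
                comm.abundance = comm.abundance.drop(columns=orphan)
                comm.abundance = comm.abundance.div(comm.abundance.sum(axis=1), axis=0)
    pair = SurveyPair(t90, t20, c90, c20)
    sites = read_sites(paths["sites"])
    if sites.sites != pair.sites:
        raise ValidationError("site table and community matrices disagree on site list")
    return pair, sites


def _fmt(df: pd.DataFrame) -> pd.DataFrame:
    return df.map(lambda v: float(f"{v:.10g}") if isinstance(v, float) else v)


def write_trait_table(table: TraitTable, path: str | Path) -> None:
    out = table.traits.copy()
    out.columns = [trait_to_header(c) for c in out.columns]
    out.insert(0, "status", table.status)
    _fmt(out).to_csv(path, index_label="species_id", float_format="%.10g")


def write_community(comm: CommunityMatrix, path: str | Path) -> None:
    comm.abundance.to_csv(path, index_label="site_id", float_format="%.10g")


def write_sites(sites: SiteTable, path: str | Path) -> None:
    sites.table.to_csv(path, index_label="site_id", float_format="%.10g")


def write_survey(pair: SurveyPair, sites: SiteTable, outdir: str | Path) -> dict[str, Path]:
    """Write the five CSVs into ``outdir``; returns the path map read_survey expects."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "traits_1990": outdir / "traits_1990.csv",
        "traits_2020": outdir / "traits_2020.csv",
        "community_1990": outdir / "community_1990.csv",
        "community_2020": outdir / "community_2020.csv",
        "sites": outdir / "sites.csv",
    }
    write_trait_table(pair.traits_1990, paths["traits_1990"])
    write_trait_table(pair.traits_2020, paths["traits_2020"])
    write_community(pair.community_1990, paths["community_1990"])
    write_community(pair.community_2020, paths["community_2020"])
    write_sites(sites, paths["sites"])
    return paths
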