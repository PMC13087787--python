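"""Functional space construction and the FRic / FEve / FDiv index family.

Species are embedded by principal coordinates analysis (PCoA) of their
Euclidean distances in standardized trait space.  Should the distance
matrix be non-Euclidean (it is not for purely continuous traits, but the
interface accepts arbitrary metric input), the Lingoes correction — an
additive constant on the squared distances — is applied before the
embedding whenever the smallest eigenvalue falls below -1e-8.

Per-site indices follow the classic geometric definitions: FRic is the
convex-hull volume of the species present, FEve the evenness of abundance
along the community's minimum spanning tree, and FDiv the degree to which
abundance sits at extreme distances from the hull-vertex centroid.  By
default indices use the first four PCoA axes; a site whose richness S is
too small for a hull in that many dimensions falls back to S - 1 axes.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import minimum_spanning_tree
from scipy.spatial import ConvexHull, QhullError
from scipy.spatial.distance import pdist, squareform
from scipy import stats
from skbio import DistanceMatrix
from skbio.stats.ordination import pcoa as _skbio_pcoa

from .data import StandardizedTraits

log = logging.getLogger(__name__)


@dataclass
class FunctionalSpace:
    """Species coordinates on PCoA axes plus the eigenvalue spectrum."""

    species: list
    coordinates: np.ndarray  # n_species x k_axes, column-centered
    eigenvalues: np.ndarray  # non-increasing, all retained >= 0
    proportion_explained: np.ndarray
    correction: str  # "none" | "lingoes"

    def coords_for(self, species) -> np.ndarray:
        idx = pd.Index(self.species)
        pos = idx.get_indexer(list(species))
        if np.any(pos < 0):
            missing = [s for s, p in zip(species, pos) if p < 0]
            raise KeyError(f"species not in functional space: {missing}")
        return self.coordinates[pos]


def trait_distance_matrix(st: StandardizedTraits | pd.DataFrame) -> pd.DataFrame:
    """Pairwise Euclidean distances between species in standardized trait space."""
    df = st.values if isinstance(st, StandardizedTraits) else st
    X = df.to_numpy(dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValueError("missing values in standardized traits")
    D = squareform(pdist(X, metric="euclidean"))
    return pd.DataFrame(D, index=df.index, columns=df.index)


def _gower_eigenvalues(D: np.ndarray) -> np.ndarray:
    n = len(D)
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D ** 2) @ J
    return np.linalg.eigvalsh((B + B.T) / 2)


def pcoa(distances: pd.DataFrame, k: int = 4) -> FunctionalSpace:
    """PCoA with automatic Lingoes correction for negative eigenvalues.

    Proportions explained are computed on the corrected positive spectrum.
    Requesting more axes than there are positive eigenvalues truncates with
    a warning.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    D = np.asarray(distances, dtype=float)
    ids = [str(i) if not isinstance(i, tuple) else i for i in distances.index]
    eig = _gower_eigenvalues(D)
    correction = "none"
    if eig.min() < -1e-8:
        # Lingoes: d'^2 = d^2 + 2c off-diagonal, c = -lambda_min
        c = -eig.min()
        D = np.sqrt(D ** 2 + 2 * c * (1 - np.eye(len(D))))
        correction = "lingoes"
    dm = DistanceMatrix(D, ids=[repr(i) for i in ids])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ord_res = _skbio_pcoa(dm, method="eigh")
    eigvals = ord_res.eigvals.to_numpy()
    pos = eigvals > max(1e-8 * eigvals.max(), 0.0)
    n_pos = int(pos.sum())
    if k > n_pos:
        log.warning("requested %d axes but only %d positive eigenvalues; truncating",
                    k, n_pos)
        k = n_pos
    coords = ord_res.samples.to_numpy()[:, :k]
    total = eigvals[pos].sum()
    prop = eigvals[:k] / total
    return FunctionalSpace(
        species=list(distances.index),
        coordinates=coords - coords.mean(axis=0, keepdims=True),
        eigenvalues=eigvals[:n_pos],
        proportion_explained=prop,
        correction=correction,
    )


def axis_trait_correlation(
    fs: FunctionalSpace, st: StandardizedTraits | pd.DataFrame
) -> pd.DataFrame:
    """Pearson r (and two-sided p) between each PCoA axis and each trait."""
    df = st.values if isinstance(st, StandardizedTraits) else st
    df = df.loc[fs.species]
    rows = []
    for a in range(fs.coordinates.shape[1]):
        axis = fs.coordinates[:, a]
        for trait in df.columns:
            x = df[trait].to_numpy(dtype=float)
            if np.std(axis) == 0.0 or np.std(x) == 0.0:
                rows.append({"axis": a + 1, "trait": trait,
                             "r": np.nan, "p": np.nan, "defined": False})
                continue
            r, p = stats.pearsonr(axis, x)
            rows.append({"axis": a + 1, "trait": trait, "r": float(r),
                         "p": float(p), "defined": True})
    return pd.DataFrame(rows)


def convex_hull_volume(points: np.ndarray) -> float:
    """Exact convex-hull volume; raises QhullError on degenerate input."""
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2:
        raise ValueError("points must be 2-D (n x k)")
    hull = ConvexHull(pts)
    return float(hull.volume)


def functional_richness(points: np.ndarray) -> float | None:
    """Hull volume of the present species; None when undefined (flagged).

    Degenerate configurations (too few points, coplanarity) are flagged
    rather than jittered, so results are exactly reproducible.
    """
    pts = np.asarray(points, dtype=float)
    k = pts.shape[1]
    if len(pts) < k + 1:
        return None
    try:
        return convex_hull_volume(pts)
    except QhullError:
        return None


def functional_evenness(points: np.ndarray, weights: np.ndarray) -> float | None:
    """Villeger's FEve: abundance evenness along the minimum spanning tree.

    EW_l = dist(i,j)/(w_i + w_j) per MST branch; PEW_l = EW_l / sum EW;
    FEve = (sum min(PEW_l, 1/(S-1)) - 1/(S-1)) / (1 - 1/(S-1)).
    """
    pts = np.asarray(points, dtype=float)
    w = np.asarray(weights, dtype=float)
    S = len(pts)
    if S < 3:
        return None
    w = w / w.sum()
    D = squareform(pdist(pts))
    mst = minimum_spanning_tree(D).tocoo()
    ew = np.array([D[i, j] / (w[i] + w[j]) for i, j in zip(mst.row, mst.col)])
    if ew.sum() == 0.0:
        return None  # all species coincide
    pew = ew / ew.sum()
    thr = 1.0 / (S - 1)
    return float((np.minimum(pew, thr).sum() - thr) / (1.0 - thr))


def functional_divergence(points: np.ndarray, weights: np.ndarray) -> float | None:
    """Villeger's FDiv: abundance-weighted deviation from the hull centroid.

    The centre of gravity uses hull-vertex species only; dG_i are species
    distances to it; FDiv = (dd + mean dG) / (d|d| + mean dG) with
    dd = sum w_i (dG_i - mean dG) and d|d| = sum w_i |dG_i - mean dG|.
    """
    pts = np.asarray(points, dtype=float)
    w = np.asarray(weights, dtype=float)
    k = pts.shape[1]
    if len(pts) < k + 1:
        return None
    try:
        hull = ConvexHull(pts)
    except QhullError:
        return None
    w = w / w.sum()
    G = pts[hull.vertices].mean(axis=0)
    dG = np.linalg.norm(pts - G, axis=1)
    mean_dG = dG.mean()
    dev = dG - mean_dG
    dd = float(w @ dev)
    dabs = float(w @ np.abs(dev))
    denom = dabs + mean_dG
    if denom == 0.0:
        return None
    return float((dd + mean_dG) / denom)


@dataclass
class SiteIndices:
    site_id: str
    SR: int
    FRic: float | None
    FEve: float | None
    FDiv: float | None
    k_used: int
    notes: list[str] = field(default_factory=list)


def site_indices(
    fs: FunctionalSpace,
    community,
    period_key,
    k_use: int = 4,
) -> pd.DataFrame:
    """Per-site SR / FRic / FEve / FDiv in the shared functional space.

    ``period_key`` maps a species_id to its row key in ``fs.species`` (e.g.
    ``lambda sp: ("P1990", sp)`` when the space is built on pooled
    period-tagged rows).  Sites with SR <= k_use fall back to k = SR - 1,
    mirroring the usual dimensionality reduction of hull-based indices on
    species-poor sites; indices that remain undefined are NaN with a note.
    """
    rows = []
    for site in community.sites:
        present = community.present(site)
        ab = community.abundance.loc[site, present].to_numpy(dtype=float)
        ab = ab / ab.sum()
        S = len(present)
        notes = []
        k_site = min(k_use, max(S - 1, 1))
        if k_site < k_use:
            notes.append(f"k reduced to {k_site} (SR={S})")
        coords = fs.coords_for([period_key(sp) for sp in present])[:, :k_site]
        fric = functional_richness(coords) if S >= k_site + 1 else None
        feve = functional_evenness(coords, ab)
        fdiv = functional_divergence(coords, ab)
        for name, v in (("FRic", fric), ("FEve", feve), ("FDiv", fdiv)):
            if v is None:
                notes.append(f"{name} undefined")
        rows.append({"site_id": site, "SR": S,
                     "FRic": np.nan if fric is None else fric,
                     "FEve": np.nan if feve is None else feve,
                     "FDiv": np.nan if fdiv is None else fdiv,
                     "k_used": k_site, "notes": "; ".join(notes)})
    return pd.DataFrame(rows).set_index("site_id")
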