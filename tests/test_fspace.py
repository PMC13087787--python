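"""Functional space (PCoA) and the FRic / FEve / FDiv geometry.

Each index is checked against an independently coded brute-force oracle:
2-D hull areas against a monotone-chain + shoelace implementation, FEve
against a hand-rolled Prim MST plus the branch-weight formula, FDiv
against a direct formula evaluation.
"""

import time

import numpy as np
import pytest

from fdshift.data import standardize_traits
from fdshift.fspace import (
    axis_trait_correlation,
    functional_divergence,
    functional_evenness,
    functional_richness,
    pcoa,
    site_indices,
    trait_distance_matrix,
)
from fdshift.simulate import SyntheticScenario, generate_scenario

from conftest import make_trait_table, make_community


# --------------------------------------------------------------- oracles

def shoelace_hull_area(pts: np.ndarray) -> float:
    """2-D convex hull area: Andrew monotone chain + shoelace, no scipy."""
    P = sorted(map(tuple, pts))

    def cross(o, a, b):
        return (a[0] - o[0]) * (b[1] - o[1]) - (a[1] - o[1]) * (b[0] - o[0])

    lower, upper = [], []
    for p in P:
        while len(lower) >= 2 and cross(lower[-2], lower[-1], p) <= 0:
            lower.pop()
        lower.append(p)
    for p in reversed(P):
        while len(upper) >= 2 and cross(upper[-2], upper[-1], p) <= 0:
            upper.pop()
        upper.append(p)
    hull = lower[:-1] + upper[:-1]
    area = 0.0
    for i in range(len(hull)):
        x1, y1 = hull[i]
        x2, y2 = hull[(i + 1) % len(hull)]
        area += x1 * y2 - x2 * y1
    return abs(area) / 2.0


def prim_mst_edges(D: np.ndarray) -> list[tuple[int, int]]:
    """O(n^2) Prim minimum spanning tree, independent of scipy.csgraph."""
    n = len(D)
    in_tree = [0]
    edges = []
    while len(in_tree) < n:
        best = None
        for i in in_tree:
            for j in range(n):
                if j in in_tree:
                    continue
                if best is None or D[i, j] < best[2]:
                    best = (i, j, D[i, j])
        edges.append((best[0], best[1]))
        in_tree.append(best[1])
    return edges


def feve_oracle(pts: np.ndarray, w: np.ndarray) -> float:
    S = len(pts)
    w = w / w.sum()
    D = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
    ew = [D[i, j] / (w[i] + w[j]) for i, j in prim_mst_edges(D)]
    pew = np.array(ew) / np.sum(ew)
    thr = 1.0 / (S - 1)
    return (np.minimum(pew, thr).sum() - thr) / (1 - thr)


def fdiv_oracle(pts: np.ndarray, w: np.ndarray, vertices: np.ndarray) -> float:
    w = w / w.sum()
    G = pts[vertices].mean(axis=0)
    dG = np.sqrt(((pts - G) ** 2).sum(axis=1))
    dev = dG - dG.mean()
    return (w @ dev + dG.mean()) / (w @ np.abs(dev) + dG.mean())


# ------------------------------------------------------- distance + PCoA

def test_distance_matrix_against_loop(default_survey):
    pair, _, _ = default_survey
    st = standardize_traits(pair.traits_2020)
    D = trait_distance_matrix(st).to_numpy()
    X = st.values.to_numpy()
    for i in range(0, 5):
        for j in range(0, 5):
            assert np.isclose(D[i, j], np.sqrt(((X[i] - X[j]) ** 2).sum()))
    assert np.allclose(D, D.T) and np.allclose(np.diag(D), 0.0)


def test_distance_simple_cases():
    import pandas as pd
    # identical species -> 0; species differing by 3 in one trait only -> 3
    z = pd.DataFrame(np.zeros((3, 4)), columns=list("abcd"))
    z.iloc[2, 0] = 3.0
    D = trait_distance_matrix(z)
    assert D.iloc[0, 1] == 0.0
    assert np.isclose(D.iloc[0, 2], 3.0)


def test_pcoa_recovers_euclidean_configuration():
    """PCoA of Euclidean distances reproduces all pairwise distances."""
    rng = np.random.default_rng(0)
    pts = rng.normal(size=(15, 2))
    import pandas as pd
    from scipy.spatial.distance import pdist, squareform
    D = pd.DataFrame(squareform(pdist(pts)))
    fs = pcoa(D, k=2)
    got = squareform(pdist(fs.coordinates))
    np.testing.assert_allclose(got, squareform(pdist(pts)), atol=1e-8)
    assert fs.correction == "none"
    assert np.all(np.abs(fs.coordinates.mean(axis=0)) < 1e-9)


def test_pcoa_proportions_match_pca_variance_ratios(default_survey):
    pair, _, _ = default_survey
    st = standardize_traits(pair.traits_2020)
    fs = pcoa(trait_distance_matrix(st), k=4)
    X = st.values.to_numpy()
    Xc = X - X.mean(0)
    sv = np.linalg.svd(Xc, compute_uv=False)
    ratios = sv ** 2 / (sv ** 2).sum()
    np.testing.assert_allclose(fs.proportion_explained, ratios[:4], rtol=1e-8)


def test_pcoa_collinear_points_have_one_axis():
    import pandas as pd
    pts = np.array([[0.0], [1.0], [3.0]])
    D = pd.DataFrame(np.abs(pts - pts.T))
    fs = pcoa(D, k=2)  # truncates to the single positive axis with a warning
    assert len(fs.eigenvalues) == 1
    assert fs.coordinates.shape[1] == 1


def test_axis_trait_correlation_extremes_and_oracle(default_survey):
    pair, _, _ = default_survey
    st = standardize_traits(pair.traits_2020)
    fs = pcoa(trait_distance_matrix(st), k=2)
    z = st.values.copy()
    ax1 = fs.coordinates[:, 0]
    z.iloc[:, 0] = ax1  # trait equal to the first axis
    # trait orthogonalized against both axes
    A = fs.coordinates[:, :2]
    y = z.iloc[:, 1].to_numpy()
    z.iloc[:, 1] = y - A @ np.linalg.lstsq(A, y, rcond=None)[0]
    tab = axis_trait_correlation(fs, z)
    r11 = tab[(tab.axis == 1) & (tab.trait == "BodyMass")].r.iloc[0]
    assert np.isclose(r11, 1.0)
    r_orth = tab[(tab.axis == 1) & (tab.trait == "BD/SL")].r.iloc[0]
    assert abs(r_orth) < 1e-8
    # textbook r formula on a random pair
    x = fs.coordinates[:, 1]
    yv = z.iloc[:, 2].to_numpy()
    r_manual = ((x - x.mean()) @ (yv - yv.mean())) / (
        np.sqrt(((x - x.mean()) ** 2).sum() * ((yv - yv.mean()) ** 2).sum())
    )
    r21 = tab[(tab.axis == 2) & (tab.trait == "BD/BW")].r.iloc[0]
    assert np.isclose(r21, r_manual, rtol=1e-10)


# ------------------------------------------------------------------ FRic

class TestFRic:
    def test_unit_square(self):
        sq = np.array([[0, 0], [1, 0], [0, 1], [1, 1.0]])
        assert np.isclose(functional_richness(sq), 1.0)

    def test_unit_simplex_3d(self):
        simplex = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1.0]])
        assert np.isclose(functional_richness(simplex), 1.0 / 6.0)

    @pytest.mark.parametrize("seed", range(20))
    def test_random_2d_matches_shoelace(self, seed):
        pts = np.random.default_rng(seed).normal(size=(12, 2))
        assert np.isclose(functional_richness(pts), shoelace_hull_area(pts),
                          rtol=1e-10)

    def test_monotone_under_additions(self):
        rng = np.random.default_rng(7)
        pts = rng.normal(size=(6, 3))
        v = functional_richness(pts)
        for _ in range(15):
            pts = np.vstack([pts, rng.normal(size=3)])
            v2 = functional_richness(pts)
            assert v2 >= v - 1e-12
            v = v2

    def test_degenerate_flagged_not_jittered(self):
        line = np.column_stack([np.arange(5.0), np.arange(5.0)])
        assert functional_richness(line) is None
        assert functional_richness(np.zeros((3, 2))) is None  # too few

    def test_scaling_power_law(self):
        rng = np.random.default_rng(9)
        pts = rng.normal(size=(10, 3))
        v = functional_richness(pts)
        assert np.isclose(functional_richness(2.5 * pts), 2.5 ** 3 * v, rtol=1e-9)


# ------------------------------------------------------------------ FEve

class TestFEve:
    def test_equidistant_equal_abundance_is_one(self):
        pts = np.column_stack([np.arange(6.0), np.zeros(6)])
        w = np.full(6, 1 / 6)
        assert np.isclose(functional_evenness(pts, w), 1.0)

    def test_extreme_clumping_low(self):
        # one species far away carries nearly all weight on one branch
        pts = np.array([[0, 0], [0.01, 0], [0.02, 0], [10.0, 0]])
        w = np.array([0.97, 0.01, 0.01, 0.01])
        assert functional_evenness(pts, w) < 0.2

    @pytest.mark.parametrize("seed", range(10))
    def test_random_matches_prim_oracle(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.normal(size=(9, 3))
        w = rng.dirichlet(np.ones(9))
        assert np.isclose(functional_evenness(pts, w), feve_oracle(pts, w),
                          rtol=1e-9)

    def test_scale_invariant(self):
        rng = np.random.default_rng(3)
        pts = rng.normal(size=(8, 2))
        w = rng.dirichlet(np.ones(8))
        assert np.isclose(functional_evenness(pts, w),
                          functional_evenness(7.3 * pts, w), rtol=1e-9)

    def test_too_few_species_undefined(self):
        assert functional_evenness(np.zeros((2, 2)), np.array([0.5, 0.5])) is None


# ------------------------------------------------------------------ FDiv

class TestFDiv:
    def test_equidistant_from_centroid_is_one(self):
        ang = np.linspace(0, 2 * np.pi, 7, endpoint=False)
        pts = np.column_stack([np.cos(ang), np.sin(ang)])
        w = np.random.default_rng(0).dirichlet(np.ones(7))
        assert np.isclose(functional_divergence(pts, w), 1.0)

    def test_abundant_centre_low(self):
        # rim square plus a dominant species at the centre
        pts = np.array([[0, 0], [1, 0], [0, 1], [1, 1], [0.5, 0.5]])
        w = np.array([0.01, 0.01, 0.01, 0.01, 0.96])
        assert functional_divergence(pts, w) < 0.5

    @pytest.mark.parametrize("seed", range(10))
    def test_random_matches_formula_oracle(self, seed):
        from scipy.spatial import ConvexHull
        rng = np.random.default_rng(seed)
        pts = rng.normal(size=(10, 2))
        w = rng.dirichlet(np.ones(10))
        vertices = ConvexHull(pts).vertices
        assert np.isclose(functional_divergence(pts, w),
                          fdiv_oracle(pts, w, vertices), rtol=1e-9)

    def test_scale_invariant(self):
        rng = np.random.default_rng(4)
        pts = rng.normal(size=(9, 3))
        w = rng.dirichlet(np.ones(9))
        assert np.isclose(functional_divergence(pts, w),
                          functional_divergence(0.2 * pts, w), rtol=1e-9)


# ------------------------------------------------------------- site level

def test_site_indices_study_design_fast(shared_space, default_survey):
    """All per-site indices for both periods complete well under a second."""
    pair, _, _ = default_survey
    fs, _ = shared_space
    t0 = time.perf_counter()
    for period in ("P1990", "P2020"):
        idx = site_indices(fs, pair.community(period),
                           period_key=lambda s, p=period: (p, s), k_use=4)
        assert (idx["SR"] > 0).all()
        defined = idx["FRic"].dropna()
        assert (defined >= 0).all()
        for col in ("FEve", "FDiv"):
            vals = idx[col].dropna()
            assert ((vals >= 0) & (vals <= 1 + 1e-9)).all()
    assert time.perf_counter() - t0 < 1.0


def test_site_indices_fallback_for_poor_sites(shared_space):
    """A 3-species site cannot support a 4-D hull: k falls back to SR - 1."""
    fs, st = shared_space
    species = [sp for (per, sp) in fs.species if per == "P1990"][:3]
    comm = make_community(np.array([[0.2, 0.3, 0.5]]), species)
    idx = site_indices(fs, comm, period_key=lambda s: ("P1990", s), k_use=4)
    assert idx["k_used"].iloc[0] == 2
    assert np.isfinite(idx["FRic"].iloc[0])
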