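"""Counterfactual FRic decomposition and variation partitioning.

The partitioning arithmetic is cross-checked against vegan::varpart
(R / Rscript), an independent implementation of adjusted-R2 variation
partitioning for four explanatory tables.
"""

import json
import subprocess

import numpy as np
import pandas as pd
import pytest

from fdshift.data import TRAIT_NAMES
from fdshift.decomposition import (
    COMPONENTS,
    ComponentVectors,
    build_components,
    build_shared_space,
    counterfactual_frich,
    variation_partition,
)
from fdshift.fspace import convex_hull_volume
from fdshift.simulate import SyntheticScenario, generate_scenario, null_scenario


def pure_loss_scenario(seed=0):
    """Native losses only: no trait shifts, no non-natives."""
    return null_scenario(seed=seed, native_survival_prob=0.5)


class TestCounterfactuals:
    def test_identical_inputs_reproduce_baseline(self):
        pair, _, _ = generate_scenario(null_scenario(seed=1))
        fs, _ = build_shared_space(pair)
        base = counterfactual_frich(pair, None, fs)
        for swap in ("native_comp", "native_traits", "nonnative_comp",
                     "nonnative_traits"):
            cf = counterfactual_frich(pair, swap, fs)
            np.testing.assert_allclose(cf.to_numpy(), base.to_numpy(),
                                       rtol=1e-9, atol=1e-12)

    def test_pure_native_loss_structure(self):
        """Only native turnover acts: the composition counterfactual equals
        the full second-survey FRic and the other three equal baseline."""
        pair, _, _ = generate_scenario(pure_loss_scenario(seed=2))
        fs, _ = build_shared_space(pair)
        base = counterfactual_frich(pair, None, fs)
        full = counterfactual_frich(pair, "full_2020", fs)
        nc = counterfactual_frich(pair, "native_comp", fs)
        np.testing.assert_allclose(nc.to_numpy(), full.to_numpy(),
                                   rtol=1e-8, atol=1e-10)
        for swap in ("native_traits", "nonnative_comp", "nonnative_traits"):
            cf = counterfactual_frich(pair, swap, fs)
            np.testing.assert_allclose(cf.to_numpy(), base.to_numpy(),
                                       rtol=1e-8, atol=1e-10)

    def test_counterfactual_matches_manual_assembly(self):
        """Site-by-site oracle: assemble the swapped point sets explicitly
        and take hull volumes directly."""
        pair, _, _ = generate_scenario(SyntheticScenario(rng_seed=3))
        k_use = 4
        fs, _ = build_shared_space(pair, k_use=k_use)
        coords = {key: fs.coordinates[i, :k_use] for i, key in enumerate(fs.species)}
        status90 = pair.traits_1990.status
        status20 = pair.traits_2020.status
        in20 = set(pair.traits_2020.species)
        got = counterfactual_frich(pair, "native_traits", fs, k_use)
        for site in pair.sites[:6]:
            pts = []
            for sp in pair.community_1990.present(site):
                stt = status90.get(sp, status20.get(sp))
                if stt == "native" and sp in in20:
                    pts.append(coords[("P2020", sp)])
                else:
                    pts.append(coords[("P1990", sp)])
            expect = convex_hull_volume(np.array(pts))
            assert np.isclose(got[site], expect, rtol=1e-10)


class TestComponents:
    def test_null_scenario_all_zero(self):
        pair, _, _ = generate_scenario(null_scenario(seed=4))
        cv = build_components(pair)
        for c in COMPONENTS:
            np.testing.assert_allclose(cv.X(c), 0.0, atol=1e-9)
        np.testing.assert_allclose(cv.Y, 0.0, atol=1e-9)

    def test_pure_native_loss_x1_equals_y(self):
        pair, _, _ = generate_scenario(pure_loss_scenario(seed=5))
        cv = build_components(pair)
        np.testing.assert_allclose(cv.X("X1"), cv.Y, rtol=1e-8, atol=1e-9)
        for c in ("X2", "X3", "X4"):
            np.testing.assert_allclose(cv.X(c), 0.0, atol=1e-9)

    def test_study_scale_decomposition_is_fast(self):
        """19 sites x ~120 species: components + partitioning in seconds."""
        import time
        pair, _, _ = generate_scenario(SyntheticScenario(rng_seed=13,
                                                         n_native_1990=113))
        t0 = time.perf_counter()
        vp = variation_partition(build_components(pair))
        assert time.perf_counter() - t0 < 10.0
        assert np.isfinite(vp.residual)

    def test_too_few_sites_rejected(self):
        pair, _, _ = generate_scenario(SyntheticScenario(rng_seed=6, n_sites=4,
                                                         occupancy_prob=0.05))
        with pytest.raises(ValueError):
            build_components(pair)


class TestVariationPartition:
    def test_adjusted_r2_closed_form(self):
        """R2 = 0.5, n = 19, p = 1 gives 1 - 0.5 * 18/17 = 0.4706."""
        from fdshift.decomposition import _adjusted_r2
        rng = np.random.default_rng(7)
        # build y with R^2 exactly 0.5 against x
        x = rng.normal(size=19)
        x = (x - x.mean()) / np.linalg.norm(x - x.mean())
        e = rng.normal(size=19)
        e = e - e.mean()
        e -= (e @ x) * x
        e /= np.linalg.norm(e)
        y = x + e  # |proj|^2 = 1, residual 1 -> R2 = 0.5
        got = _adjusted_r2(y, x.reshape(-1, 1))
        assert np.isclose(got, 1 - 0.5 * 18 / 17, atol=1e-9)
        assert np.isclose(got, 0.4706, atol=1e-4)

    def _cv_from(self, Y, X):
        df = pd.DataFrame(X, columns=list(COMPONENTS))
        df.insert(0, "Y", Y)
        df.index = [f"S{i}" for i in range(len(df))]
        return ComponentVectors(table=df, excluded_sites=[])

    def test_exact_single_component(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(100, 4))
        Y = X[:, 0].copy()  # Y identical to X1
        vp = variation_partition(self._cv_from(Y, X))
        assert np.isclose(vp.marginal_r2["X1"], 1.0, atol=1e-9)
        # the adjusted-R2 penalty of the noise-only complement model leaks
        # into the unique fraction (vegan behaves identically), so ~1 only
        assert np.isclose(vp.unique["X1"], 1.0, atol=0.1)
        assert abs(vp.residual) < 1e-9

    def test_two_orthogonal_predictors_split_evenly(self):
        rng = np.random.default_rng(9)
        n = 200
        a = rng.normal(size=n)
        a = (a - a.mean()) / np.linalg.norm(a - a.mean())
        b = rng.normal(size=n)
        b = b - b.mean()
        b -= (b @ a) * a
        b /= np.linalg.norm(b)
        X = np.column_stack([a, b, rng.normal(size=n), rng.normal(size=n)])
        Y = a + b
        vp = variation_partition(self._cv_from(Y, X))
        assert np.isclose(vp.unique["X1"], vp.unique["X2"], atol=0.02)
        assert abs(vp.fraction("X1", "X2")) < 0.05  # shared ~ 0
        # inclusion-exclusion oracle for the unique fraction:
        # unique(X1) = adjR2(full) - adjR2(X2,X3,X4)
        from fdshift.decomposition import _adjusted_r2
        full = _adjusted_r2(Y, X)
        wo1 = _adjusted_r2(Y, X[:, 1:])
        assert np.isclose(vp.unique["X1"], full - wo1, atol=1e-9)

    def test_fraction_identity_and_marginals_can_exceed_one(self):
        """Unique + shared + residual is exactly 1 even when the four
        marginal adjusted R2 values sum to more than 1."""
        rng = np.random.default_rng(10)
        base = rng.normal(size=19)
        X = np.column_stack([base + 0.3 * rng.normal(size=19) for _ in range(4)])
        Y = base + 0.2 * rng.normal(size=19)
        vp = variation_partition(self._cv_from(Y, X))
        assert sum(vp.marginal_r2.values()) > 1.0
        total = sum(vp.fractions.values()) + vp.residual
        assert np.isclose(total, 1.0, atol=1e-9)

    def test_duplicated_component_flagged_undefined(self):
        rng = np.random.default_rng(11)
        x = rng.normal(size=19)
        X = np.column_stack([x, x, rng.normal(size=19), rng.normal(size=19)])
        Y = x + rng.normal(size=19)
        vp = variation_partition(self._cv_from(Y, X))
        assert np.isnan(vp.subset_r2[frozenset(["X1", "X2"])])
        assert np.isinf(vp.vif["X1"])

    def test_matches_vegan_varpart(self, tmp_path):
        """Unique fractions and residual agree with R vegan::varpart."""
        # non-zero non-native trait shift so all four components carry
        # genuine variation (degenerate columns are handled differently
        # by design: float dust is not allowed to explain variance here)
        pair, _, _ = generate_scenario(SyntheticScenario(
            rng_seed=12, nonnative_trait_shift=np.full(len(TRAIT_NAMES), 0.3)))
        cv = build_components(pair)
        vp = variation_partition(cv)
        csv = tmp_path / "cv.csv"
        cv.table.to_csv(csv, index=False)
        script = tmp_path / "vp.R"
        script.write_text(
            'd <- read.csv("%s")\n'
            "suppressMessages(library(vegan))\n"
            "v <- varpart(d$Y, ~X1, ~X2, ~X3, ~X4, data=d)\n"
            "f <- v$part$indfract\n"
            'cat(f$Adj.R.square[c(1, 2, 3, 4, 16)], sep="\\n")\n' % csv
        )
        out = subprocess.run(["Rscript", str(script)], capture_output=True,
                             text=True, check=True).stdout.split()
        ua, ub, uc, ud, resid = map(float, out)
        assert np.isclose(vp.unique["X1"], ua, atol=1e-6)
        assert np.isclose(vp.unique["X2"], ub, atol=1e-6)
        assert np.isclose(vp.unique["X3"], uc, atol=1e-6)
        assert np.isclose(vp.unique["X4"], ud, atol=1e-6)
        assert np.isclose(vp.residual, resid, atol=1e-6)
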