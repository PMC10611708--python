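"""Presence/background SDM: AUC oracle, collinearity filter, fitting,
contributions and cross-scenario projection."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vegshift.grid_io import GridStack, OccurrenceSet
from vegshift.sdm import SdmConfig, auc, contributions, fit, project, select_variables

from conftest import make_grid


def brute_force_auc(pos, neg):
    """Independent oracle: enumerate every (pos, neg) pair."""
    wins = sum(1.0 for p in pos for n in neg if p > n)
    ties = sum(1.0 for p in pos for n in neg if p == n)
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


class TestAuc:
    @pytest.mark.parametrize(
        "pos, neg, expected",
        [
            ([3, 4], [1, 2], 1.0),        # perfect separation
            ([1, 1], [1, 1], 0.5),        # all ties
            ([2, 3], [1, 3], 0.625),      # 2 wins + 1 tie over 4 pairs
            ([1, 2], [3, 4], 0.0),        # perfect inversion
        ],
    )
    def test_known_values(self, pos, neg, expected):
        assert auc(pos, neg) == pytest.approx(expected)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            auc([], [1.0])
        with pytest.raises(ValueError):
            auc([1.0], [])

    @settings(max_examples=200, derandomize=True, deadline=None)
    @given(
        pos=st.lists(st.integers(-5, 5), min_size=1, max_size=50),
        neg=st.lists(st.integers(-5, 5), min_size=1, max_size=50),
    )
    def test_matches_pairwise_oracle(self, pos, neg):
        """Rank-based AUC equals brute-force Mann-Whitney on tied data."""
        assert auc(pos, neg) == pytest.approx(brute_force_auc(pos, neg))


def _stack_from(arrays: dict) -> GridStack:
    return GridStack({k: make_grid(v) for k, v in arrays.items()})


class TestSelectVariables:
    def test_identical_layers_keep_one(self):
        rng = np.random.default_rng(0)
        a = rng.standard_normal((20, 20))
        kept = select_variables(_stack_from({"A": a, "B": a.copy()}))
        assert len(kept) == 1

    def test_independent_fields_all_kept(self):
        rng = np.random.default_rng(1)
        arrays = {n: rng.standard_normal((40, 40)) for n in "ABC"}
        data = np.column_stack([a.ravel() for a in arrays.values()])
        corr = np.abs(np.corrcoef(data, rowvar=False))
        np.fill_diagonal(corr, 0)
        assert corr.max() < 0.8  # construction check
        assert select_variables(_stack_from(arrays)) == ["A", "B", "C"]

    def test_correlated_pair_reduced_to_valid_subset(self):
        """One of a rho=0.9 pair is dropped; result matches the brute-force
        enumeration of maximal subsets with all pairwise |r| below 0.8."""
        rng = np.random.default_rng(2)
        a = rng.standard_normal((50, 50))
        b = 0.9 * a + np.sqrt(1 - 0.81) * rng.standard_normal((50, 50))
        c = rng.standard_normal((50, 50))
        stack = _stack_from({"A": a, "B": b, "C": c})
        kept = set(select_variables(stack))

        data = {"A": a.ravel(), "B": b.ravel(), "C": c.ravel()}
        from itertools import combinations

        def valid(subset):
            return all(
                abs(np.corrcoef(data[u], data[v])[0, 1]) < 0.8
                for u, v in combinations(subset, 2)
            )

        maximal = [
            set(s)
            for k in (3, 2, 1)
            for s in combinations(data, k)
            if valid(s)
        ]
        max_size = max(len(s) for s in maximal)
        assert len(kept) == max_size == 2
        assert kept in [s for s in maximal if len(s) == max_size]
        assert "C" in kept

    def test_single_layer_rejected(self):
        with pytest.raises(ValueError):
            select_variables(_stack_from({"A": np.zeros((4, 4))}))


def _signal_setup(seed, n_pres=120, shape=(60, 60), top_decile=True):
    """Presences on a landscape where variable v1 carries the signal."""
    rng = np.random.default_rng(seed)
    from scipy.ndimage import gaussian_filter

    def grf():
        z = gaussian_filter(rng.standard_normal(shape), sigma=5)
        return (z - z.mean()) / z.std()

    v1, v2 = grf(), grf()
    stack = _stack_from({"v1": v1, "v2": v2})
    if top_decile:
        pool = np.flatnonzero(v1.ravel() >= np.quantile(v1, 0.9))
    else:
        pool = np.arange(v1.size)
    flat = rng.choice(pool, size=n_pres, replace=False)
    r, c = np.unravel_index(flat, shape)
    x, y = stack.transform.cell_center(r, c)
    occ = OccurrenceSet(
        points=pd.DataFrame({"x": x, "y": y, "taxon": "t"}), role="forest"
    )
    return occ, stack


class TestFit:
    def test_strong_signal_recovers_driver_and_passes_gate(self):
        """Presences restricted to the driver's top decile: positive linear
        coefficient on the driver, test AUC above 0.9 and above the 0.75 gate."""
        occ, stack = _signal_setup(seed=5)
        cfg = SdmConfig(seed=5, n_background=2000)
        res = fit(occ, stack, cfg, variables=["v1", "v2"])
        assert res.coefficients["v1:linear"] > 0
        assert res.mean_auc > 0.9
        assert res.passes_gate

    def test_uniform_presences_give_chance_auc(self):
        occ, stack = _signal_setup(seed=6, top_decile=False)
        cfg = SdmConfig(seed=6, n_background=2000)
        res = fit(occ, stack, cfg, variables=["v1", "v2"])
        assert 0.35 <= res.mean_auc <= 0.65

    def test_insufficient_presences_rejected(self):
        occ, stack = _signal_setup(seed=7, n_pres=12)
        with pytest.raises(ValueError, match="insufficient"):
            fit(occ, stack, SdmConfig(seed=7, n_replicates=10), variables=["v1", "v2"])

    def test_fixed_seed_is_bit_reproducible(self):
        occ, stack = _signal_setup(seed=8)
        cfg = SdmConfig(seed=8, n_background=1500)
        a = fit(occ, stack, cfg, variables=["v1", "v2"])
        b = fit(occ, stack, cfg, variables=["v1", "v2"])
        assert a.replicate_aucs == b.replicate_aucs
        assert a.coefficients == b.coefficients
        np.testing.assert_array_equal(a.suitability.values, b.suitability.values)

    def test_replicate_count_and_suitability_range(self):
        occ, stack = _signal_setup(seed=9)
        cfg = SdmConfig(seed=9, n_background=1000, n_replicates=5)
        res = fit(occ, stack, cfg, variables=["v1", "v2"])
        assert len(res.replicate_aucs) == 5
        vals = res.suitability.valid_values()
        assert vals.min() >= 0 and vals.max() <= 1

    def test_stronger_l1_never_adds_coefficients(self):
        """Sparsity is monotone in the penalty on a fixed seeded instance
        (coarse penalty ladder: L1 path cardinality is only broadly, not
        pointwise, decreasing)."""
        occ, stack = _signal_setup(seed=10)
        counts = []
        for pen in (1.0, 4.0, 16.0, 64.0):
            cfg = SdmConfig(seed=10, n_background=1000, l1_penalty=pen)
            res = fit(occ, stack, cfg, variables=["v1", "v2"])
            counts.append(sum(1 for v in res.coefficients.values() if v != 0))
        assert counts == sorted(counts, reverse=True)


class TestContributions:
    def test_single_variable_gets_everything(self):
        occ, stack = _signal_setup(seed=11)
        cfg = SdmConfig(seed=11, n_background=1000)
        res = fit(occ, stack.subset(["v1"]), cfg, variables=["v1"])
        assert res.contributions == {"v1": pytest.approx(100.0)}

    def test_contributions_sum_to_100(self):
        occ, stack = _signal_setup(seed=12)
        res = fit(occ, stack, SdmConfig(seed=12, n_background=1000), variables=["v1", "v2"])
        assert sum(res.contributions.values()) == pytest.approx(100.0, abs=1e-6)
        assert contributions(res) == res.contributions

    @pytest.mark.parametrize("seed", range(5))
    def test_driver_variable_outranks_noise(self, seed):
        occ, stack = _signal_setup(seed=100 + seed)
        res = fit(occ, stack, SdmConfig(seed=seed, n_background=1000), variables=["v1", "v2"])
        assert res.contributions["v1"] > res.contributions["v2"]


class TestProject:
    def _fitted(self, seed=20):
        occ, stack = _signal_setup(seed=seed)
        res = fit(occ, stack, SdmConfig(seed=seed, n_background=1000), variables=["v1", "v2"])
        return res, stack

    def test_projection_onto_training_stack_is_identity(self):
        res, stack = self._fitted()
        proj = project(res, stack)
        np.testing.assert_allclose(proj.values, res.suitability.values, rtol=0, atol=1e-12)

    def test_flat_target_gives_flat_surface(self):
        res, stack = self._fitted()
        flat = _stack_from({
            "v1": np.full((60, 60), float(res.feature_map.means["v1"])),
            "v2": np.full((60, 60), float(res.feature_map.means["v2"])),
        })
        proj = project(res, flat)
        assert np.ptp(proj.valid_values()) == pytest.approx(0.0, abs=1e-12)

    def test_offset_in_driver_shifts_suitability_monotonically(self):
        """With a linear-only response, shifting the driver layer by a constant
        moves the projected surface cellwise in the direction of the offset."""
        occ, stack = _signal_setup(seed=21)
        cfg = SdmConfig(seed=21, n_background=1000, feature_classes=("linear",))
        res = fit(occ, stack, cfg, variables=["v1", "v2"])
        beta = res.coefficients["v1:linear"]
        assert beta > 0
        base = project(res, stack).values
        sd = res.feature_map.sds["v1"]
        for sign in (+1.0, -1.0):
            target = _stack_from({"v1": stack.layers["v1"].values + sign * 0.5 * sd,
                                  "v2": stack.layers["v2"].values})
            shifted = project(res, target).values
            assert np.all(sign * (shifted - base) > 0)

    def test_missing_variable_named_in_error(self):
        res, _ = self._fitted()
        with pytest.raises(ValueError, match="v2"):
            project(res, _stack_from({"v1": np.zeros((60, 60))}))
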