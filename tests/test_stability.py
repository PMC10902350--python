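import numpy as np
import pytest

import _oracles as naive
from conftest import random_matrix, random_tensor
from reefstab import stability as st
from reefstab.datamodel import CommunityMatrix, MetacommunityTensor


def mat(cols, site="s"):
    """Matrix from per-species columns."""
    a = np.column_stack([np.asarray(c, dtype=float) for c in cols])
    return CommunityMatrix(site, np.arange(2000, 2000 + a.shape[0]),
                           [f"sp{j}" for j in range(a.shape[1])], a)


class TestSiteMeasures:
    def test_alpha_stability_hand_example(self):
        # totals 3, 6, 9: mean 6, sd 3
        assert st.alpha_stability(mat([[1, 2, 3], [2, 4, 6]])) == pytest.approx(2.0)

    def test_alpha_stability_totals_2_4_6(self):
        assert st.alpha_stability(mat([[2, 4, 6]])) == pytest.approx(2.0)

    def test_constant_totals_flagged_undefined(self):
        m = mat([[5, 5, 5, 5, 5]])
        assert np.isnan(st.alpha_stability(m))
        summary = st.community_summary(m)
        assert "zero-variance" in summary.degenerate_flags

    def test_species_stability_closed_form(self):
        # mu_total = 9, sigma_A + sigma_B = 1 + 2
        assert st.species_stability(mat([[1, 2, 3], [2, 4, 6]])) == pytest.approx(2.0)

    def test_single_species_collapses_to_alpha(self):
        m = mat([[1, 3, 2, 5, 4]])
        assert st.species_stability(m) == pytest.approx(st.alpha_stability(m))

    def test_adding_constant_species_increases_species_stability(self):
        base = mat([[1, 2, 3], [2, 4, 6]])
        more = mat([[1, 2, 3], [2, 4, 6], [5, 5, 5]])
        assert st.species_stability(more) > st.species_stability(base)

    @pytest.mark.parametrize("cols,expected", [
        ([[1, 2, 3], [3, 2, 1]], 1.0),   # perfect compensation
        ([[1, 2, 3], [2, 4, 6]], -1.0),  # perfect synchrony
        ([[1, 2, 3], [6, 4, 2]], 1.0),   # weights 1/3, 2/3, both r = -1
    ])
    def test_gross_asynchrony_examples(self, cols, expected):
        assert st.gross_asynchrony(mat(cols)) == pytest.approx(expected)

    def test_gross_single_species_undefined(self):
        assert np.isnan(st.gross_asynchrony(mat([[1, 2, 3]])))

    def test_gross_drops_constant_species_and_renormalises(self):
        val, flags = st.gross_asynchrony_flagged(mat([[1, 2, 3], [3, 2, 1], [7, 7, 7]]))
        assert "zero-variance-component" in flags
        assert val == pytest.approx(1.0)

    @pytest.mark.parametrize("cols,expected", [
        ([[1, 2, 3], [3, 2, 1]], 1.0),   # sd_total = 0
        ([[1, 2, 3], [2, 4, 6]], 0.0),   # sd_total = 3 = 1 + 2
    ])
    def test_ldm_asynchrony_examples(self, cols, expected):
        assert st.ldm_asynchrony(mat(cols)) == pytest.approx(expected)

    def test_ldm_single_species_is_zero_asynchrony(self):
        assert st.ldm_asynchrony(mat([[1, 3, 2, 5]])) == pytest.approx(0.0)


class TestDetrend:
    def test_linear_series_becomes_constant(self):
        m = mat([[1, 2, 3, 4, 5]])
        d = st.detrend(m)
        np.testing.assert_allclose(d.abundance[:, 0], 3.0, atol=1e-9)

    def test_mean_preserved_sd_reduced_for_trended_series(self, rng):
        t = 30
        trend = 0.5 * np.arange(t)
        noise = rng.normal(0, 1, t)
        m = mat([10 + trend + noise])
        d = st.detrend(m)
        assert d.abundance[:, 0].mean() == pytest.approx(m.abundance[:, 0].mean())
        assert d.abundance[:, 0].std() < m.abundance[:, 0].std()

    def test_trendless_noise_nearly_unchanged(self, rng):
        m = mat([20 + rng.normal(0, 1, 200)])
        d = st.detrend(m)
        assert np.corrcoef(m.abundance[:, 0], d.abundance[:, 0])[0, 1] > 0.99

    def test_idempotent(self, rng):
        m = random_matrix(rng, t=12, s=3)
        once = st.detrend(m)
        twice = st.detrend(once)
        np.testing.assert_allclose(once.abundance, twice.abundance, atol=1e-9)


def tensor(data):
    a = np.asarray(data, dtype=float)
    n, s, t = a.shape
    return MetacommunityTensor("eco", [f"s{i}" for i in range(n)],
                               [f"sp{j}" for j in range(s)],
                               np.arange(2000, 2000 + t), a)


class TestMetacommunity:
    def test_single_site_single_species_all_collapse_to_alpha(self):
        series = [2.0, 4.0, 3.0, 6.0]
        t = tensor([[series]])
        alpha = st.alpha_stability(mat([series]))
        vals = st.metacommunity_stability(t)
        for k in ("GAS", "AAS", "ASS", "MPS"):
            assert vals[k] == pytest.approx(alpha)

    def test_hand_example_site_totals(self):
        # site totals [2,3,4] and [4,3,3] -> metacommunity [6,6,7]
        t = tensor([[[2, 3, 4]], [[4, 3, 3]]])
        gas = st.metacommunity_stability(t)["GAS"]
        assert gas == pytest.approx((19 / 3) / np.std([6, 6, 7], ddof=1), rel=1e-9)
        assert gas == pytest.approx(10.9697, abs=1e-3)

    def test_scale_invariance_of_all_measures(self, rng):
        t = random_tensor(rng, n=3, s=4, t=8)
        t10 = MetacommunityTensor(t.ecoregion, t.site_ids, t.species_ids, t.years,
                                  10.0 * t.abundance)
        for family in ("gross", "ldm"):
            a = st.metacommunity_measures(t, family).values
            b = st.metacommunity_measures(t10, family).values
            for k in a:
                assert a[k] == pytest.approx(b[k], abs=1e-12)

    def test_identical_site_totals_are_perfectly_synchronous(self):
        t = tensor([[[1, 2, 3]], [[1, 2, 3]]])
        assert st.metacommunity_asynchrony(t, "gross")["SCA"] == pytest.approx(-1.0)

    def test_compensating_site_totals_max_asynchrony_both_families(self):
        t = tensor([[[1, 2, 3]], [[3, 2, 1]]])
        assert st.metacommunity_asynchrony(t, "gross")["SCA"] == pytest.approx(1.0)
        assert st.metacommunity_asynchrony(t, "ldm")["SCA"] == pytest.approx(1.0)

    def test_ldm_identity_links_gas_aas(self, rng):
        for _ in range(20):
            t = random_tensor(rng)
            vals = st.metacommunity_stability(t)
            site_tot = t.abundance.sum(axis=1)
            phi_spatial = np.var(site_tot.sum(axis=0), ddof=1) / (
                sum(np.std(site_tot[i], ddof=1) for i in range(t.n_sites)) ** 2
            )
            assert vals["GAS"] == pytest.approx(vals["AAS"] / np.sqrt(phi_spatial), rel=1e-10)

    def test_naive_oracle_agreement_all_measures(self, rng):
        for _ in range(25):
            t = random_tensor(rng, n=3, s=3, t=6)
            data = t.abundance.tolist()
            vals = st.metacommunity_stability(t)
            asy = st.metacommunity_asynchrony(t, "gross")
            assert vals["GAS"] == pytest.approx(naive.gamma_stability(data), rel=1e-12)
            assert vals["AAS"] == pytest.approx(naive.average_alpha_stability(data), rel=1e-12)
            assert vals["ASS"] == pytest.approx(naive.average_species_stability(data), rel=1e-12)
            assert vals["MPS"] == pytest.approx(naive.metapopulation_stability(data), rel=1e-12)
            assert asy["SCA"] == pytest.approx(naive.spatial_community_asynchrony(data), rel=1e-12)
            assert asy["SSA"] == pytest.approx(naive.spatial_species_asynchrony(data), rel=1e-12)
            assert asy["ASA"] == pytest.approx(naive.average_species_asynchrony(data), rel=1e-12)
            assert asy["MPAS"] == pytest.approx(naive.metapopulation_asynchrony(data), rel=1e-12)

    def test_literal_inverted_average_reading_breaks_collapse(self):
        """The alternative reading that inverts a weighted sum of per-site
        species stabilities turns average species stability into a
        variability: on one site with one species it returns 1/alpha, not
        alpha, contradicting the collapse identity the hierarchy requires."""
        series = [2.0, 4.0, 3.0, 6.0]
        data = [[series]]
        alpha = st.alpha_stability(mat([series]))
        literal = naive.ass_literal_printed(data)
        assert literal == pytest.approx(1.0 / alpha)
        assert st.metacommunity_stability(tensor(data))["ASS"] == pytest.approx(alpha)


class TestCyclicShiftNull:
    def test_every_shifted_series_is_a_rotation(self, rng):
        m = random_matrix(rng, t=9, s=4)
        shifted = st.cyclic_shift(m, rng)
        for j in range(m.n_species):
            orig = m.abundance[:, j]
            got = shifted.abundance[:, j]
            assert any(
                np.array_equal(np.roll(orig, k), got) for k in range(m.n_years)
            )

    def test_constant_community_p_one_flagged(self):
        m = mat([[5, 5, 5, 5, 5], [2, 2, 2, 2, 2]])
        res = st.cyclic_shift_null(m, lambda x: x.totals().sum(), n_iter=49, seed=1)
        assert res.p_value == 1.0
        assert np.isnan(res.ses)
        assert "degenerate-null" in res.flags

    def test_minimum_p_is_one_over_iterations_plus_one(self):
        # five spiky series aligned at t=0: the total cross-product is
        # maximised only when every relative shift is zero, which a random
        # joint rotation essentially never reproduces
        t_len, s_len = 12, 5
        cols = []
        for j in range(s_len):
            c = np.ones(t_len)
            c[0] = 50 + j
            cols.append(c)
        m = mat(cols)

        def cross(x):
            a = x.abundance
            return float((a.sum(axis=1) ** 2).sum())

        res = st.cyclic_shift_null(m, cross, n_iter=999, seed=3)
        assert res.p_value == pytest.approx(1 / 1000)

    def test_same_seed_reproducible(self, rng):
        m = random_matrix(rng, t=10, s=3)
        a = st.cyclic_shift_null(m, st.gross_asynchrony, n_iter=99, seed=11)
        b = st.cyclic_shift_null(m, st.gross_asynchrony, n_iter=99, seed=11)
        assert a.p_value == b.p_value
        np.testing.assert_array_equal(a.null_values, b.null_values)
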