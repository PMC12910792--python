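"""Area histograms, t-tests, Holm-Šídák adjustment, group comparison."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import integrate
from scipy.special import gammaln

import specklepipe as sp
from specklepipe import Plane, RegionOfInterest


class TestHistogram:
    def test_direct_counting_with_sub_threshold_tally(self):
        h = sp.histogram_areas([0.5, 1.5, 1.7, 2.5], (1, 2, 3, 4, 5))
        assert h.counts == (2, 1, 0, 0, 0)
        assert h.sub_threshold_count == 1
        assert h.total_count == 3
        assert h.bin_labels[-1] == "[5,inf)"

    def test_empty_records(self):
        h = sp.histogram_areas([], (1, 2, 3))
        assert h.counts == (0, 0, 0)
        assert h.total_count == 0

    def test_only_accepted_records_counted(self):
        recs = [
            sp.CondensateRecord(1, 1.5, (0, 0), 0, 0, 0, 1.0, 10, accepted=True),
            sp.CondensateRecord(2, 1.6, (0, 0), 0, 0, 0, 1.0, 10, accepted=False),
        ]
        h = sp.histogram_areas(recs, (1, 2))
        assert h.counts == (1, 0)

    def test_lognormal_counts_match_analytic_probabilities(self, rng):
        # joint goodness-of-fit of all bins (incl. the sub-threshold mass)
        # against the closed-form log-normal bin probabilities
        from scipy.stats import chisquare, norm

        mu, s, n = np.log(2.0), 0.5, 1000
        areas = rng.lognormal(mu, s, n)
        edges = (1.0, 2.0, 3.0, 4.0, 5.0)
        h = sp.histogram_areas(areas, edges)
        zs = [(np.log(e) - mu) / s for e in edges]
        cdf = [0.0] + [norm.cdf(z) for z in zs] + [1.0]
        probs = np.diff(cdf)
        observed = np.array([h.sub_threshold_count, *h.counts])
        assert observed.sum() == n
        res = chisquare(observed, n * probs)
        assert res.pvalue > 1e-3

    def test_non_increasing_edges_rejected(self):
        with pytest.raises(ValueError):
            sp.histogram_areas([1.0], (2, 2, 3))

    def test_csv_round_trip(self):
        h1 = sp.histogram_areas([1.5, 2.5], (1, 2, 3), subject_id="s1", group="WT")
        h2 = sp.histogram_areas([0.5, 4.0], (1, 2, 3), subject_id="s2", group="KO")
        frame = sp.histograms_to_frame([h1, h2])
        back = sp.frame_to_histograms(frame)
        assert back == [h1, h2]


class TestMeanIntensity:
    def test_three_pixel_mean(self):
        img = np.zeros((4, 4))
        mask = np.zeros((4, 4), bool)
        img[0, :3] = [10, 20, 30]
        mask[0, :3] = True
        assert sp.mean_intensity(Plane(img), RegionOfInterest("r", mask)) == 20.0

    def test_constant_plane(self):
        plane = Plane(np.full((8, 8), 7.25))
        assert sp.mean_intensity(plane, RegionOfInterest.full_field((8, 8))) == 7.25

    def test_empty_roi_rejected(self):
        with pytest.raises(ValueError):
            sp.mean_intensity(
                Plane(np.zeros((4, 4))), RegionOfInterest("e", np.zeros((4, 4), bool))
            )

    def test_matches_ground_truth_flux_on_clean_field(self, clean_field):
        # Gaussian blur conserves flux, so the full-field mean equals the
        # background mean plus the analytic per-pixel object contribution
        spec, plane, truth = clean_field
        h, w = spec.field_size_px
        gy, gx = spec.background_gradient
        bg_mean = spec.background_level + gy * (h - 1) / 2 + gx * (w - 1) / 2
        n_px = h * w
        contribution = (
            spec.nucleus_intensity * truth.nucleus_mask.sum()
            + spec.condensate_peak_intensity * (truth.label_map > 0).sum()
        ) / n_px
        got = sp.mean_intensity(plane, RegionOfInterest.full_field((h, w)))
        assert got == pytest.approx(bg_mean + contribution, rel=1e-3)


class TestTTest:
    def test_identical_groups_null(self):
        res = sp.two_sample_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.t == 0.0
        assert res.p == pytest.approx(1.0)

    def test_pooled_hand_case(self):
        # mean diff -3, pooled sd 1, se = sqrt(2/3), t = -3.674, df = 4
        res = sp.two_sample_t_test([1, 2, 3], [4, 5, 6])
        assert res.t == pytest.approx(-3.674, abs=1e-3)
        assert res.df == 4
        assert res.p == pytest.approx(0.0213, abs=1e-3)

    def test_p_matches_t_density_quadrature(self):
        def t_pdf(x, df):
            lognorm = gammaln((df + 1) / 2) - gammaln(df / 2) - 0.5 * np.log(df * np.pi)
            return np.exp(lognorm) * (1 + x * x / df) ** (-(df + 1) / 2)

        cases = [([1, 2, 3], [4, 5, 6]), ([1.0, 3.0, 2.5, 4.0], [2.0, 2.2, 5.0])]
        for a, b in cases:
            res = sp.two_sample_t_test(a, b)
            tail, _ = integrate.quad(t_pdf, abs(res.t), np.inf, args=(res.df,))
            assert res.p == pytest.approx(2 * tail, rel=1e-6)

    def test_constant_unequal_groups_give_infinite_t(self):
        res = sp.two_sample_t_test([1.0, 1.0], [2.0, 2.0])
        assert np.isinf(res.t)
        assert res.p == 0.0

    def test_degenerate_sizes_rejected(self):
        with pytest.raises(ValueError):
            sp.two_sample_t_test([1.0], [2.0, 3.0])


class TestHolmSidak:
    def test_single_p_unchanged(self):
        np.testing.assert_allclose(sp.holm_sidak_adjust([0.04]), [0.04])

    def test_three_sorted_example(self):
        adj = sp.holm_sidak_adjust([0.01, 0.02, 0.20])
        np.testing.assert_allclose(adj, [0.029701, 0.039600, 0.200000], atol=1e-6)

    def test_equal_ps_stay_equal(self):
        adj = sp.holm_sidak_adjust([0.03, 0.03, 0.03])
        assert np.allclose(adj, adj[0])

    def test_matches_direct_formula_on_random_vectors(self, rng):
        for m in (2, 5, 11, 20):
            p = rng.uniform(0, 1, m)
            adj = sp.holm_sidak_adjust(p)
            order = np.argsort(p, kind="stable")
            expected = np.empty(m)
            running = 0.0
            for rank, idx in enumerate(order):
                running = max(running, 1 - (1 - p[idx]) ** (m - rank))
                expected[idx] = min(running, 1.0)
            np.testing.assert_allclose(adj, expected, atol=1e-12)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=12), st.randoms())
    def test_permutation_invariance_and_dominance(self, ps, shuffler):
        adj = sp.holm_sidak_adjust(ps)
        assert np.all(adj >= np.asarray(ps) - 1e-12)
        perm = list(range(len(ps)))
        shuffler.shuffle(perm)
        adj_perm = sp.holm_sidak_adjust([ps[i] for i in perm])
        np.testing.assert_allclose([adj[i] for i in perm], adj_perm, atol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            sp.holm_sidak_adjust([0.5, 1.5])


class TestCompareGroups:
    def make_hists(self, counts_by_subject):
        hists = []
        for subject, (group, areas) in counts_by_subject.items():
            hists.append(
                sp.histogram_areas(areas, (1, 2, 3), subject_id=subject, group=group)
            )
        return hists

    def test_identical_per_subject_counts_give_zero_t(self):
        hists = self.make_hists(
            {
                "a1": ("WT", [1.5, 2.5]),
                "a2": ("WT", [1.5, 2.5]),
                "b1": ("KO", [1.5, 2.5]),
                "b2": ("KO", [1.5, 2.5]),
            }
        )
        comp = sp.compare_groups(hists)
        assert (comp.per_bin["t"] == 0.0).all()
        assert comp.total["t"] == 0.0

    def test_adjusted_never_below_raw(self):
        rng = np.random.default_rng(3)
        hists = self.make_hists(
            {
                f"{g}{i}": (g, rng.lognormal(0.7, 0.5, 30))
                for g in ("WT", "KO")
                for i in range(4)
            }
        )
        comp = sp.compare_groups(hists)
        assert (comp.per_bin["p_adj"] >= comp.per_bin["p_raw"] - 1e-12).all()

    def test_count_conservation_through_aggregation(self):
        areas = {"a1": ("WT", [1.1, 1.2, 2.5]), "a2": ("WT", [1.3]),
                 "b1": ("KO", [2.1, 2.2]), "b2": ("KO", [4.5])}
        hists = self.make_hists(areas)
        comp = sp.compare_groups(hists)
        ga, gb = comp.group_names
        total_mean_a = comp.total[f"mean_{ga}"]
        total_mean_b = comp.total[f"mean_{gb}"]
        assert total_mean_a * 2 == sum(len(v[1]) for k, v in areas.items() if v[0] == ga)
        assert total_mean_b * 2 == sum(len(v[1]) for k, v in areas.items() if v[0] == gb)

    def test_single_group_rejected(self):
        hists = self.make_hists({"a1": ("WT", [1.5]), "a2": ("WT", [2.5])})
        with pytest.raises(ValueError):
            sp.compare_groups(hists)
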