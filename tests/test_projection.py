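"""Projection curve construction, MPV/LSS statistics and the closed form."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from projana.projection import (
    ProjectionCurve,
    closed_form_projection,
    compute_projection,
    constant_curve,
    lss,
    mpv,
    rebin_projection,
    summarize,
)
from projana.siteio import PanelSite, SiteObservation


def obs(i, n, call, chrom="1", pos=1):
    site = PanelSite(chrom, pos, "A", "C", "A", i, n)
    return SiteObservation(site, call, coverage=5, filter_reasons=frozenset())


class TestComputeProjection:
    def test_hand_tally(self):
        # n=4: category i=1 has 1/2 derived -> 0.5/0.25 = 2; i=2 has 2/2 -> 1/0.5 = 2
        observations = [
            obs(1, 4, "derived"),
            obs(1, 4, "ancestral"),
            obs(2, 4, "derived"),
            obs(2, 4, "derived"),
        ]
        curve = compute_projection(observations)
        assert curve.panel_size == 4
        np.testing.assert_allclose(curve.w[:2], [2.0, 2.0])
        assert not curve.defined[2]

    def test_all_ancestral_gives_zero(self):
        curve = compute_projection([obs(i % 3 + 1, 4, "ancestral") for i in range(30)])
        assert np.all(curve.w[curve.defined] == 0.0)

    def test_matches_brute_force_tally(self, rng):
        n = 8
        counts = rng.integers(0, n + 1, size=50)
        calls = rng.random(50) < 0.5
        observations = [
            obs(int(c), n, "derived" if d else "ancestral")
            for c, d in zip(counts, calls)
        ]
        curve = compute_projection(observations)
        # independent brute-force loop over sites
        for i in range(1, n):
            tot = sum(1 for c in counts if c == i)
            der = sum(1 for c, d in zip(counts, calls) if c == i and d)
            if tot == 0:
                assert not curve.defined[i - 1]
            else:
                assert curve.sites[i - 1] == tot
                np.testing.assert_allclose(curve.w[i - 1], (der / tot) / (i / n))

    def test_panel_member_scores_one(self, rng):
        # copying a uniformly chosen panel chromosome: derived with prob i/n
        n = 20
        counts = rng.integers(1, n, size=100_000)
        calls = rng.random(100_000) < counts / n
        curve = ProjectionCurve.from_site_counts(counts, calls, n)
        # chi-square-style bound: sum of squared z-scores over categories
        sel = curve.defined
        var = (1 - curve.x[sel]) / (curve.x[sel] * curve.sites[sel])
        z2 = (curve.w[sel] - 1.0) ** 2 / var
        from scipy.stats import chi2

        assert z2.sum() < chi2.ppf(0.999, sel.sum())

    def test_scaling_in_expectation(self, rng):
        # derived probability c*x scales the whole curve by c
        n, c = 20, 0.6
        counts = rng.integers(1, n, size=200_000)
        calls = rng.random(200_000) < c * counts / n
        curve = ProjectionCurve.from_site_counts(counts, calls, n)
        np.testing.assert_allclose(np.nanmean(curve.w), c, atol=0.02)

    def test_errors(self):
        with pytest.raises(ValueError, match="no usable"):
            compute_projection([])
        mixed = [obs(1, 4, "derived"), obs(1, 6, "derived")]
        with pytest.raises(ValueError, match="mixed panel sizes"):
            compute_projection(mixed)


class TestMPV:
    def test_constant_curve(self):
        assert mpv(constant_curve(0.9, 50)) == pytest.approx(0.9)

    def test_single_category_above_half(self):
        c = ProjectionCurve.from_category_weights(4, [0, 0, 10], [0, 0, 0.8 * 0.75 * 10])
        assert mpv(c) == pytest.approx(0.8)

    def test_mean_over_defined_only(self):
        # n=10: defined only at x=0.6 (w=0.6) and x=0.7 (w=0.8)
        sites = np.zeros(9)
        der = np.zeros(9)
        sites[5], der[5] = 100, 0.6 * 0.6 * 100
        sites[6], der[6] = 100, 0.8 * 0.7 * 100
        c = ProjectionCurve.from_category_weights(10, sites, der)
        assert mpv(c) == pytest.approx(0.7)

    def test_error_without_upper_categories(self):
        c = ProjectionCurve.from_category_weights(4, [5, 0, 0], [1, 0, 0])
        with pytest.raises(ValueError):
            mpv(c)


class TestLSS:
    def test_identity_is_zero(self):
        c = constant_curve(0.7, 30)
        assert lss(c, c) == 0.0

    def test_constant_closed_form(self):
        # flat 0.8 vs the w=1 line over 100 categories: 100 * 0.04
        c = constant_curve(0.8, 101)
        assert lss(c, 1.0) == pytest.approx(4.0)
        assert lss(c) == pytest.approx(4.0)  # default comparator is the 1-line

    @settings(deadline=None, max_examples=25)
    @given(st.integers(0, 2**31 - 1))
    def test_symmetry(self, seed):
        r = np.random.default_rng(seed)
        n = 12
        a = ProjectionCurve.from_site_counts(
            r.integers(1, n, 500), r.random(500) < 0.5, n
        )
        b = ProjectionCurve.from_site_counts(
            r.integers(1, n, 500), r.random(500) < 0.5, n
        )
        assert lss(a, b) == pytest.approx(lss(b, a))

    def test_disjoint_categories_error(self):
        a = ProjectionCurve.from_category_weights(4, [10, 0, 0], [5, 0, 0])
        b = ProjectionCurve.from_category_weights(4, [0, 0, 10], [0, 0, 5])
        with pytest.raises(ValueError, match="no defined"):
            lss(a, b)

    def test_mismatched_grids_rebinned(self):
        a = constant_curve(0.8, 200)
        b = constant_curve(1.0, 100)
        assert lss(a, b) == pytest.approx(25 * 0.04, rel=1e-6)


class TestClosedForm:
    def test_values(self):
        assert closed_form_projection(0, 5000) == pytest.approx(1.0)
        assert closed_form_projection(1000, 5000) == pytest.approx(0.904837, abs=1e-6)

    def test_monotone_decay(self):
        times = np.linspace(0, 10_000, 25)
        vals = [closed_form_projection(t, 5000) for t in times]
        assert np.all(np.diff(vals) < 0)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            closed_form_projection(100, 0)
        with pytest.raises(ValueError):
            closed_form_projection(-1, 100)

    def test_mpv_of_closed_form_curve_is_exact(self):
        v = closed_form_projection(1000, 5000)
        assert mpv(constant_curve(v, 200)) == pytest.approx(v)


class TestRebin:
    def test_identity_rebin(self):
        c = ProjectionCurve.from_category_weights(6, [3, 1, 4, 1, 5], [1, 0, 2, 1, 3])
        r = rebin_projection(c, 5)
        np.testing.assert_allclose(r.x, c.x)
        np.testing.assert_allclose(np.nan_to_num(r.w), np.nan_to_num(c.w))

    def test_pooling_hand_example(self):
        # n=4: (i=1, 10 sites, 2 derived) + (i=2, 10 sites, 8 derived) into 1 bin:
        # pooled fraction 0.5, weighted x 0.375 -> w = 1.3333
        c = ProjectionCurve.from_category_weights(4, [10, 10, 0], [2, 8, 0])
        r = rebin_projection(c, 1)
        assert r.w[0] == pytest.approx(10 / 20 / 0.375)

    @settings(deadline=None, max_examples=25)
    @given(st.integers(0, 2**31 - 1), st.integers(2, 20))
    def test_site_conservation(self, seed, num_bins):
        r = np.random.default_rng(seed)
        n = 25
        c = ProjectionCurve.from_site_counts(
            r.integers(1, n, 400), r.random(400) < 0.5, n
        )
        assert rebin_projection(c, num_bins).total_sites == pytest.approx(c.total_sites)

    def test_bin_count_limits(self):
        with pytest.raises(ValueError):
            rebin_projection(constant_curve(1.0, 5), 10)
        with pytest.raises(ValueError):
            rebin_projection(constant_curve(1.0, 5), 0)


def test_summary_and_tsv_roundtrip(tmp_path):
    c = constant_curve(0.8, 50, sites_per_category=10)
    s = summarize(c)
    assert s.mpv == pytest.approx(0.8)
    assert s.total_sites == pytest.approx(490)
    path = tmp_path / "curve.tsv"
    c.to_tsv(path)
    back = ProjectionCurve.read_tsv(path)
    np.testing.assert_allclose(back.x, c.x)
    np.testing.assert_allclose(back.w, c.w)
    assert back.panel_size == 50
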