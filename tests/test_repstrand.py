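"""Replication timing, fork directionality and the window regression."""

import numpy as np
import pandas as pd
import pytest

from lesionseg.core import WindowTrack
from lesionseg.repstrand import (
    leading_lagging,
    okseq_rfd,
    quantile_bin_and_concord,
    quantile_bins,
    regression_design,
    replication_timing,
    rescale_re,
    rfd_from_rt,
    rsb_orient,
    window_regression,
)


def _track(values, chrom="chr1", step=10_000):
    n = len(values)
    return WindowTrack(
        np.array([chrom] * n, dtype=object),
        np.arange(n, dtype=np.int64) * step,
        (np.arange(n, dtype=np.int64) + 1) * step,
        np.asarray(values, dtype=float),
    )


class TestReplicationTiming:
    def test_equal_counts_zero(self):
        e = _track([10, 10, 10, 10, 10])
        l = _track([10, 10, 10, 10, 10])
        rt = replication_timing(e, l)
        assert np.allclose(rt.values, 0.0)

    def test_zero_late_is_one(self):
        e = _track([5, 5, 5])
        l = _track([0, 0, 0])
        rt = replication_timing(e, l)
        assert np.allclose(rt.values, 1.0)

    def test_step_profile_matches_hand_smoothing(self):
        # library sizes equal, so TPM normalisation cancels; the value
        # at index i is the 5-window mean relative enrichment
        e = np.array([0, 0, 10, 10, 10, 10, 10], dtype=float)
        l = np.array([10, 10, 0, 0, 0, 0, 0], dtype=float)
        rt = replication_timing(_track(e), _track(l))
        # at index 2: windows 0..4 -> E=30,L=20 (after equal-size TPM,
        # e-library sum 50, l-library sum 20: E'=30/50, L'=20/20)
        e_t = e * 1e6 / e.sum()
        l_t = l * 1e6 / l.sum()
        exp = []
        for i in range(7):
            lo, hi = max(0, i - 2), min(7, i + 3)
            ee, ll = e_t[lo:hi].mean(), l_t[lo:hi].mean()
            exp.append((ee - ll) / (ee + ll))
        assert np.allclose(rt.values, exp)

    def test_mismatched_grids_rejected(self):
        with pytest.raises(ValueError):
            replication_timing(_track([1, 2]), _track([1, 2, 3]))


class TestRfdFromRt:
    def test_constant_rt_zero(self):
        rfd = rfd_from_rt(_track([0.3] * 6))
        assert np.allclose(rfd.values[1:-1], 0.0)
        assert np.isnan(rfd.values[0]) and np.isnan(rfd.values[-1])

    def test_linear_rt_constant_slope(self):
        s = 0.07
        rfd = rfd_from_rt(_track(np.arange(8) * s))
        assert np.allclose(rfd.values[1:-1], s)

    def test_matches_central_difference(self):
        rng = np.random.default_rng(0)
        v = rng.uniform(-1, 1, 50)
        rfd = rfd_from_rt(_track(v))
        assert np.allclose(rfd.values[1:-1], (v[2:] - v[:-2]) / 2)

    def test_per_chromosome_edges(self):
        n = 5
        track = WindowTrack(
            np.array(["chr1"] * n + ["chr2"] * n, dtype=object),
            np.tile(np.arange(n) * 10_000, 2),
            np.tile((np.arange(n) + 1) * 10_000, 2),
            np.arange(2 * n, dtype=float),
        )
        rfd = rfd_from_rt(track)
        assert np.isnan(rfd.values[[0, n - 1, n, 2 * n - 1]]).all()


class TestOkseqRfd:
    @pytest.mark.parametrize("f,r,expected", [
        (10, 10, 0.0),
        (0, 5, 1.0),
        (10, 30, 0.5),
    ])
    def test_examples(self, f, r, expected):
        rfd = okseq_rfd(_track([f]), _track([r]))
        assert rfd.values[0] == pytest.approx(expected)

    def test_both_zero_missing(self):
        rfd = okseq_rfd(_track([0]), _track([0]))
        assert np.isnan(rfd.values[0])

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            okseq_rfd(_track([-1]), _track([2]))


class TestQuantileBins:
    def test_near_equal_occupancy(self):
        rng = np.random.default_rng(1)
        v = rng.random(21 * 100 + 13)
        bins = quantile_bins(v, 21)
        counts = np.bincount(bins)[1:]
        assert counts.max() - counts.min() <= 1

    def test_monotone(self):
        rng = np.random.default_rng(2)
        v = rng.random(500)
        bins = quantile_bins(v, 21)
        order = np.argsort(v, kind="stable")
        assert (np.diff(bins[order]) >= 0).all()

    def test_concordance_flags(self):
        rng = np.random.default_rng(3)
        v = rng.random(210)
        a, b = _track(v), _track(v)
        bins_ok, bins_repli, conc = quantile_bin_and_concord(a, b)
        assert np.array_equal(bins_ok, bins_repli)
        assert conc.all()

    def test_extreme_bins_discordant(self):
        v1 = np.concatenate([[0.0], np.full(20, 0.5) +
                             np.arange(20) * 1e-3])
        v2 = np.concatenate([[1.0], np.full(20, 0.5) +
                             np.arange(20) * 1e-3])
        bins1, bins2, conc = quantile_bin_and_concord(
            _track(v1), _track(v2))
        assert bins1[0] == 1 and bins2[0] == 21
        assert not conc[0]

    def test_all_missing_rejected(self):
        with pytest.raises(ValueError):
            quantile_bins(np.full(5, np.nan))


class TestLeadingLagging:
    @pytest.mark.parametrize("cls,rfd,expected", [
        ("F", 0.4, "lagging"),
        ("R", 0.4, "leading"),
        ("F", -0.4, "leading"),
        ("R", -0.4, "lagging"),
    ])
    def test_truth_table(self, cls, rfd, expected):
        assert leading_lagging(cls, rfd) == expected

    def test_exhaustive_balance(self):
        calls = [leading_lagging(c, r) for c in "FR" for r in (0.4, -0.4)]
        assert calls.count("leading") == 2 and calls.count("lagging") == 2

    def test_strand_swap_flips(self):
        for rfd in (0.7, -0.7):
            assert leading_lagging("F", rfd) != leading_lagging("R", rfd)

    def test_zero_rfd_unassigned(self):
        assert leading_lagging("F", 0.0) == "unassigned"

    def test_errors(self):
        with pytest.raises(ValueError):
            leading_lagging("unresolved", 0.5)
        with pytest.raises(ValueError):
            leading_lagging("F", float("nan"))

    def test_rsb_orientation(self):
        # RSB makes the lesion strand the reverse strand: positive RSB
        # is lagging synthesis over the lesions for both classes
        assert rsb_orient(0.5, "R") == 0.5
        assert rsb_orient(0.5, "F") == -0.5
        assert leading_lagging("R", 0.5) == leading_lagging("F", -0.5)


class TestRescale:
    @pytest.mark.parametrize("r,f", [(0.0, 0.5), (-1.0, 0.0),
                                     (1.0, 1.0), (0.5, 0.75)])
    def test_examples(self, r, f):
        assert rescale_re(r) == pytest.approx(f)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            rescale_re(1.5)


class TestWindowRegression:
    def _design(self, n=5000, seed=0):
        rng = np.random.default_rng(seed)
        return pd.DataFrame({
            "rt_rescaled": rng.random(n),
            "rsb_rescaled": rng.random(n),
            "frac_template_expressed": rng.random(n) * 0.5,
        })

    def test_recovers_injected_coefficient(self):
        df = self._design()
        rng = np.random.default_rng(1)
        df["rate"] = 2.0 * df.rt_rescaled + 0.02 * rng.standard_normal(
            len(df))
        coefs, _ = window_regression(
            df, "rate",
            ["rt_rescaled", "rsb_rescaled", "frac_template_expressed"])
        assert coefs.loc["rt_rescaled", "coef"] == pytest.approx(2.0,
                                                                 rel=0.05)
        assert abs(coefs.loc["rsb_rescaled", "coef"]) < 0.01

    def test_permuted_outcome_null(self):
        df = self._design(seed=2)
        rng = np.random.default_rng(3)
        df["rate"] = rng.standard_normal(len(df))
        coefs, _ = window_regression(
            df, "rate",
            ["rt_rescaled", "rsb_rescaled", "frac_template_expressed"])
        assert (coefs.drop(index="intercept").p > 0.001).all()

    def test_collinear_design_rejected(self):
        df = self._design(n=200, seed=4)
        df["dup"] = df.rt_rescaled * 2.0
        df["rate"] = df.rt_rescaled
        with pytest.raises(ValueError, match="dup"):
            window_regression(df, "rate", ["rt_rescaled", "dup"])

    def test_simulated_tcr_signature(self, cohort, asym_phased):
        """With TCR on, the expressed-template fraction carries the
        strongest (negative) association with window mutation rate."""
        ann = cohort.annotation
        rt = replication_timing(ann.early_counts, ann.late_counts)
        rfd = rfd_from_rt(rt)
        design = regression_design(asym_phased, ann.genome, ann.genes,
                                   rt, rfd)
        predictors = ["frac_template_expressed",
                      "frac_nontemplate_expressed",
                      "frac_residual_genic", "rt_rescaled",
                      "rsb_rescaled"]
        coefs, _ = window_regression(design, "rate", predictors)
        tcoef = coefs.loc["frac_template_expressed"]
        assert tcoef.coef < 0
        assert abs(tcoef.t) == coefs.drop(index="intercept").t.abs().max()
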