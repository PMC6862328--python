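"""pDMP selection, cutpoint estimation, DMP calling, Fisher comparator."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from methsignal.dist_fit import CriticalValue, FittedModel
from methsignal.signal_detect import (
    CutpointResult,
    call_dmps,
    classifier_posterior_cutpoint,
    fisher_comparator,
    gamma_mixture_cutpoint,
    select_potential_dmps,
    tv_quantile_cutoff,
    youden_cutpoint,
)
from .conftest import make_sample


def _unit_model():
    return FittedModel("weibull2", 1.0, 1.0, 0.0, 1.0, 0.0, 0.0, 100)


def _cv(sample_id, h_crit):
    return CriticalValue(sample_id, 0.05, h_crit, _unit_model())


def _pdmps(hdivs, groups, **extra):
    n = len(hdivs)
    base = {
        "sample_id": extra.get("sample_id", ["s"] * n),
        "group": groups,
        "chrom": ["chr1"] * n,
        "pos": np.arange(1, n + 1) * 10,
        "tv": np.full(n, 0.5),
        "tv_abs": np.full(n, 0.5),
        "hdiv": np.asarray(hdivs, dtype=float),
        "weight": np.full(n, 10.0),
        "log2_tailp": -np.asarray(hdivs, dtype=float),
    }
    base.update({k: v for k, v in extra.items() if k != "sample_id"})
    return pd.DataFrame(base)


class TestTvQuantileCutoff:
    def test_matches_order_statistics_oracle(self, rng):
        vals = np.concatenate([np.full(95, 0.1), np.full(5, 0.9)])
        rng.shuffle(vals)
        track = pd.DataFrame({"tv_abs": vals})
        got = tv_quantile_cutoff([track], q=0.95)
        assert got == pytest.approx(np.quantile(vals, 0.95))

    def test_constant_distribution(self):
        track = pd.DataFrame({"tv_abs": np.full(10, 0.3)})
        assert tv_quantile_cutoff([track], 0.95) == pytest.approx(0.3)

    def test_median_small(self):
        track = pd.DataFrame({"tv_abs": [0.1, 0.2, 0.3]})
        assert tv_quantile_cutoff([track], 0.5) == pytest.approx(0.2)

    def test_pools_over_tracks(self, rng):
        a = pd.DataFrame({"tv_abs": rng.uniform(size=50)})
        b = pd.DataFrame({"tv_abs": rng.uniform(size=70)})
        pooled = np.concatenate([a["tv_abs"], b["tv_abs"]])
        assert tv_quantile_cutoff([a, b], 0.9) == pytest.approx(np.quantile(pooled, 0.9))


class TestSelectPotentialDmps:
    def _tracks(self):
        track = pd.DataFrame(
            {
                "chrom": ["chr1"] * 4,
                "pos": [10, 20, 30, 40],
                "tv": [0.5, 0.5, 0.1, 0.5],
                "tv_abs": [0.5, 0.5, 0.1, 0.5],
                "hdiv": [2.0, 1.0, 2.0, 0.5],
                "weight": [10.0] * 4,
            }
        )
        return {"s1": track}, {"s1": "control"}

    def test_boundary_is_strict_on_hdiv(self):
        tracks, groups = self._tracks()
        out = select_potential_dmps(tracks, groups, {"s1": _cv("s1", 1.0)}, tv_cut=0.0)
        assert out["pos"].tolist() == [10, 30]  # hdiv == 1.0 excluded

    def test_vacuous_filters_keep_all(self):
        tracks, groups = self._tracks()
        out = select_potential_dmps(tracks, groups, {"s1": _cv("s1", 0.0)}, tv_cut=0.0)
        assert len(out) == 4

    def test_joint_filter_matches_brute_force(self, rng):
        track = pd.DataFrame(
            {
                "chrom": ["chr1"] * 10,
                "pos": np.arange(1, 11),
                "tv": rng.uniform(-1, 1, 10),
                "hdiv": rng.gamma(2, 1, 10),
                "weight": np.full(10, 8.0),
            }
        )
        track["tv_abs"] = track["tv"].abs()
        h_crit, tv_cut = 1.5, 0.4
        out = select_potential_dmps(
            {"s": track}, {"s": "treatment"}, {"s": _cv("s", h_crit)}, tv_cut
        )
        expected = {
            int(r.pos)
            for r in track.itertuples()
            if r.hdiv > h_crit and r.tv_abs >= tv_cut
        }
        assert set(out["pos"]) == expected

    def test_tailp_attached_per_sample_model(self):
        tracks, groups = self._tracks()
        out = select_potential_dmps(tracks, groups, {"s1": _cv("s1", 0.0)}, 0.0)
        # unit-exponential model: log2 sf(h) = -h/ln 2
        assert out["log2_tailp"].to_numpy() == pytest.approx(
            -tracks["s1"]["hdiv"].to_numpy() / np.log(2)
        )


def _brute_force_youden(hdiv, is_trt):
    best = (-np.inf, None)
    for t in np.unique(hdiv):
        pred = hdiv > t
        sens = (pred & is_trt).sum() / is_trt.sum()
        spec = (~pred & ~is_trt).sum() / (~is_trt).sum()
        j = sens + spec - 1
        if j > best[0] + 1e-9:
            best = (j, t)
    return best


class TestYoudenCutpoint:
    def test_separable_groups(self):
        p = _pdmps([1, 2, 3, 10, 11, 12], ["control"] * 3 + ["treatment"] * 3)
        cp = youden_cutpoint(p)
        assert cp.diagnostics["youden_j"] == pytest.approx(1.0)
        assert 3 <= cp.h_cutoff < 10

    def test_identical_distributions_uninformative(self, rng):
        h = rng.gamma(2, 1, 400)
        p = _pdmps(h, ["control", "treatment"] * 200)
        cp = youden_cutpoint(p)
        assert cp.diagnostics["youden_j"] < 0.2

    def test_single_group_rejected(self):
        with pytest.raises(ValueError, match="both groups"):
            youden_cutpoint(_pdmps([1, 2], ["control", "control"]))

    @settings(max_examples=50, deadline=None)
    @given(st.data())
    def test_equals_brute_force_maximizer(self, data):
        n = data.draw(st.integers(5, 200))
        seed = data.draw(st.integers(0, 2**16))
        rng = np.random.default_rng(seed)
        hdiv = rng.gamma(2, 1, n).round(2)  # rounding creates ties
        is_trt = rng.uniform(size=n) < 0.5
        if is_trt.all() or not is_trt.any():
            is_trt[0] = True
            is_trt[-1] = False
        groups = np.where(is_trt, "treatment", "control")
        cp = youden_cutpoint(_pdmps(hdiv, groups))
        j_brute, t_brute = _brute_force_youden(hdiv, is_trt)
        assert cp.diagnostics["youden_j"] == pytest.approx(j_brute)
        assert cp.h_cutoff == pytest.approx(t_brute)


class TestClassifierPosteriorCutpoint:
    LENGTHS = {"chr1": 100_000}

    def _separable(self, rng, n=120):
        # control pdmps low-H cluster, treatment high-H cluster
        h = np.concatenate([rng.uniform(1, 2, n // 2), rng.uniform(8, 12, n // 2)])
        groups = ["control"] * (n // 2) + ["treatment"] * (n // 2)
        p = _pdmps(h, groups)
        p["log2_tailp"] = -h
        return p

    def test_separable_accuracy_one(self, rng):
        p = self._separable(rng)
        cp = classifier_posterior_cutpoint(p, self.LENGTHS, cv_resamples=10, seed=3)
        assert cp.diagnostics["cv_summary"]["accuracy"] == pytest.approx(1.0)
        # chosen cutoff keeps both classes => below the separating gap
        assert cp.h_cutoff < 8

    def test_degenerate_grid_of_one(self, rng):
        p = self._separable(rng)
        cp = classifier_posterior_cutpoint(
            p, self.LENGTHS, n_candidates=1, cv_resamples=10, seed=3
        )
        grid = cp.diagnostics["grid"]
        assert len(grid) == 1
        assert cp.h_cutoff == pytest.approx(grid["threshold"].iloc[0])

    def test_agrees_with_exhaustive_grid(self, rng):
        p = self._separable(rng, n=60)
        cp = classifier_posterior_cutpoint(
            p, self.LENGTHS, n_candidates=8, cv_resamples=10, seed=5
        )
        grid = cp.diagnostics["grid"].dropna()
        best = grid.sort_values(
            ["cv_accuracy", "cv_kappa", "threshold"], ascending=[False, False, True]
        ).iloc[0]
        assert cp.h_cutoff == pytest.approx(best["threshold"])

    def test_determinism(self, rng):
        p = self._separable(rng)
        a = classifier_posterior_cutpoint(p, self.LENGTHS, cv_resamples=10, seed=9)
        b = classifier_posterior_cutpoint(p, self.LENGTHS, cv_resamples=10, seed=9)
        assert a.h_cutoff == b.h_cutoff
        pd.testing.assert_frame_equal(a.diagnostics["grid"], b.diagnostics["grid"])


class TestGammaMixtureCutpoint:
    def test_recovers_separated_mixture(self, rng):
        x = np.concatenate(
            [rng.gamma(2.0, 1 / 4.0, 5000), rng.gamma(20.0, 1 / 2.0, 5000)]
        )
        cp = gamma_mixture_cutpoint(x, seed=0)
        means = sorted(cp.diagnostics["component_means"])
        assert means[0] == pytest.approx(0.5, rel=0.1)
        assert means[1] == pytest.approx(10.0, rel=0.1)
        assert 0.5 < cp.h_cutoff < 10.0

    def test_posterior_half_at_cutoff(self, rng):
        x = np.concatenate([rng.gamma(2.0, 0.25, 3000), rng.gamma(20.0, 0.5, 3000)])
        cp = gamma_mixture_cutpoint(x, seed=0)
        w = np.asarray(cp.diagnostics["weights"])
        shapes = cp.diagnostics["shapes"]
        rates = cp.diagnostics["rates"]
        hi = cp.diagnostics["signal_component"]
        logp = [
            np.log(w[c]) + stats.gamma.logpdf(cp.h_cutoff, shapes[c], scale=1 / rates[c])
            for c in (0, 1)
        ]
        post = np.exp(logp[hi]) / (np.exp(logp[0]) + np.exp(logp[1]))
        assert post == pytest.approx(0.5, abs=1e-6)

    def test_identical_components_flagged_degenerate(self, rng):
        x = rng.gamma(3.0, 1.0, 2000)
        cp = gamma_mixture_cutpoint(x, seed=1)
        # single-population input: heavily overlapping components are
        # reported but flagged as a degenerate mixture
        assert cp.diagnostics["degenerate"]

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="n >= 100"):
            gamma_mixture_cutpoint(np.ones(50) + np.arange(50) * 0.01)


class TestCallDmps:
    def test_cutoff_above_max_empty(self):
        p = _pdmps([1, 2, 3], ["control", "treatment", "treatment"])
        assert len(call_dmps(p, CutpointResult("youden", 99.0))) == 0

    def test_cutoff_zero_keeps_all(self):
        p = _pdmps([1, 2, 3], ["control", "treatment", "treatment"])
        assert len(call_dmps(p, CutpointResult("youden", 0.0))) == 3

    def test_exact_membership(self):
        h = [0.5, 1.5, 2.5, 3.5, 4.5, 5.5, 6.5, 7.5, 8.5, 9.5]
        p = _pdmps(h, ["control", "treatment"] * 5)
        out = call_dmps(p, CutpointResult("youden", 5.0))
        assert out.members["hdiv"].tolist() == [5.5, 6.5, 7.5, 8.5, 9.5]
        assert set(out.members["group"]) == {"control", "treatment"}

    def test_monotone_in_cutoff(self, rng):
        p = _pdmps(rng.gamma(2, 1, 100), ["control", "treatment"] * 50)
        sizes = [
            len(call_dmps(p, CutpointResult("youden", c)))
            for c in np.linspace(0, 10, 20)
        ]
        assert (np.diff(sizes) <= 0).all()


class TestFisherComparator:
    def test_identical_pooled_counts_p_one(self):
        c = [make_sample([("chr1", 1, 10, 10)], "c1")]
        t = [make_sample([("chr1", 1, 10, 10)], "t1", "treatment")]
        out = fisher_comparator(c, t)
        assert out["pvalue"].iloc[0] == pytest.approx(1.0)

    def test_matches_hypergeometric_enumeration(self):
        # table [[10, 90], [50, 50]]: enumerate all tables with fixed margins
        c = [make_sample([("chr1", 1, 10, 90)], "c1")]
        t = [make_sample([("chr1", 1, 50, 50)], "t1", "treatment")]
        out = fisher_comparator(c, t, adjust="none")
        m, n_, big_n = 60, 140, 200  # margins: mC total, uC total, grand
        row1 = 100
        probs = [
            stats.hypergeom.pmf(k, big_n, m, row1) for k in range(0, min(m, row1) + 1)
        ]
        p_obs = stats.hypergeom.pmf(10, big_n, m, row1)
        expected = sum(p for p in probs if p <= p_obs * (1 + 1e-9))
        assert out["pvalue"].iloc[0] == pytest.approx(expected, rel=1e-6)

    def test_bh_step_up(self):
        # p-values {~0.01,~0.02,~0.03,~0.5}: BH at alpha 0.05 keeps the first 3
        reject, padj, _, _ = __import__(
            "statsmodels.stats.multitest", fromlist=["multipletests"]
        ).multipletests([0.01, 0.02, 0.03, 0.5], alpha=0.05, method="fdr_bh")
        assert reject.tolist() == [True, True, True, False]
        # step-up oracle: padj_i = min_j>=i (m * p_j / j)
        p = np.array([0.01, 0.02, 0.03, 0.5])
        m = 4
        oracle = np.minimum.accumulate((m * p / np.arange(1, 5))[::-1])[::-1]
        assert np.allclose(padj, np.minimum(oracle, 1))

    def test_pools_replicates_per_group(self):
        c = [
            make_sample([("chr1", 1, 5, 45)], "c1"),
            make_sample([("chr1", 1, 5, 45)], "c2"),
        ]
        t = [make_sample([("chr1", 1, 50, 50)], "t1", "treatment")]
        out = fisher_comparator(c, t, adjust="none")
        _, expected = stats.fisher_exact([[10, 90], [50, 50]])
        assert out["pvalue"].iloc[0] == pytest.approx(expected)
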