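import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize_scalar
from scipy.stats import norm

from clutchsig import (
    BimodalityError,
    ProbeMatrix,
    call_expression,
    call_transcripts,
    classify_probe_variance,
    collapse_genes,
    find_valley_threshold,
    posterior_expressed,
    probe_log_variance,
)
from clutchsig.expression import VarianceSplit


def _pm(values: np.ndarray) -> ProbeMatrix:
    n = values.shape[1]
    cols = [f"s{i}" for i in range(n)]
    return ProbeMatrix(
        pd.DataFrame(values, index=[f"p{i}" for i in range(values.shape[0])], columns=cols),
        {c: "M0" for c in cols},
    )


class TestProbeLogVariance:
    def test_hand_value(self):
        # values [1, 3]: unbiased variance 2, ln(2) ~ 0.693
        lv = probe_log_variance(_pm(np.array([[1.0, 3.0], [0.0, 1.0]])))
        assert lv["p0"] == pytest.approx(np.log(2), abs=1e-12)

    def test_constant_probe_gets_sentinel(self):
        lv = probe_log_variance(_pm(np.array([[1.0, 3.0], [2.0, 2.0]])))
        assert lv["p1"] == pytest.approx(lv["p0"] - 1.0)

    def test_sd_ratio_separates_log_variances(self):
        # sd 0.1 vs 1.0 -> log-variance distributions ~2 ln(10) ~ 4.6 apart
        rng = np.random.default_rng(0)
        quiet = rng.normal(0, 0.1, (10_000, 24))
        loud = rng.normal(0, 1.0, (10_000, 24))
        lv = probe_log_variance(_pm(np.vstack([quiet, loud])))
        gap = lv[10_000:].mean() - lv[:10_000].mean()
        assert gap == pytest.approx(2 * np.log(10), abs=0.05)


def analytic_valley(w_high, m_low, m_high, s_low, s_high):
    """Numeric minimum of the true two-Gaussian mixture density."""
    dens = lambda x: (1 - w_high) * norm.pdf(x, m_low, s_low) + w_high * norm.pdf(
        x, m_high, s_high
    )
    return minimize_scalar(dens, bounds=(m_low, m_high), method="bounded").x


class TestValleyThreshold:
    @pytest.mark.parametrize("w_high", [0.5, 0.34])
    def test_matches_analytic_mixture_minimum(self, w_high):
        rng = np.random.default_rng(42)
        n = 40_000
        comp = rng.random(n) < w_high
        x = np.where(comp, rng.normal(-2, 0.5, n), rng.normal(-6, 0.5, n))
        valley = find_valley_threshold(x)
        expected = analytic_valley(w_high, -6, -2, 0.5, 0.5)
        assert valley == pytest.approx(expected, abs=0.1)
        if w_high == 0.5:
            assert valley == pytest.approx(-4.0, abs=0.1)
        else:
            # the valley shifts toward the smaller (high-variance) mode
            assert expected > -4.0

    def test_unimodal_raises(self):
        rng = np.random.default_rng(1)
        with pytest.raises(BimodalityError):
            find_valley_threshold(rng.normal(0, 1, 5000))


class TestClassifyProbeVariance:
    def test_boundary_probe_goes_high(self):
        lv = pd.Series([-5.0, -3.74, -2.0], index=["a", "b", "c"])
        split = classify_probe_variance(lv, valley=-3.74)
        assert "b" in split.high_probes and "c" in split.high_probes
        assert split.low_probes == ["a"]

    def test_all_below_valley_high_empty(self):
        lv = pd.Series([-5.0, -6.0], index=["a", "b"])
        split = classify_probe_variance(lv, valley=0.0)
        assert split.high_probes == []

    def test_mixture_proportions_recovered(self):
        rng = np.random.default_rng(2)
        n = 30_000
        w = 0.34
        comp = rng.random(n) < w
        x = np.where(comp, rng.normal(-2, 0.5, n), rng.normal(-6, 0.5, n))
        split = classify_probe_variance(pd.Series(x), find_valley_threshold(x))
        assert split.prior_high == pytest.approx(w, abs=0.02)


class TestPosteriorExpressed:
    def _two_class_matrix(self, rng, n=20_000, extra=()):
        """One-column matrix of n low-class N(2,1) and n high-class N(8,1)
        probes, with optional extra query probes appended to the high class."""
        low = rng.normal(2, 1, n)
        high = rng.normal(8, 1, n)
        col = np.concatenate([low, high, list(extra)])
        vals = col[:, None]
        m = _pm(vals)
        lv = pd.Series(0.0, index=m.values.index)
        split = VarianceSplit(
            log_variance=lv,
            valley=0.0,
            low_probes=list(m.values.index[:n]),
            high_probes=list(m.values.index[n:]),
        )
        return m, split

    def test_closed_form_gaussian_oracle(self):
        # equal priors, classes N(2,1) and N(8,1): posterior(x) =
        # 1 / (1 + exp(-(x - 5) * 6)) in closed form; x = 5 and 6 sit 3-4 sd
        # into the class tails, so the KDE needs a large sample there
        rng = np.random.default_rng(3)
        m, split = self._two_class_matrix(rng, n=1_000_000, extra=[5.0, 6.0])
        post = posterior_expressed(m, split).to_numpy().ravel()
        closed = lambda x: 1 / (1 + np.exp(-(x - 5.0) * 6.0))
        assert post[-2] == pytest.approx(closed(5.0), abs=0.02)
        assert post[-1] == pytest.approx(closed(6.0), abs=0.02)

    def test_degenerate_prior_all_high(self):
        m = _pm(np.array([[1.0], [2.0]]))
        split = VarianceSplit(
            log_variance=pd.Series(0.0, index=m.values.index),
            valley=0.0,
            low_probes=[],
            high_probes=list(m.values.index),
        )
        assert (posterior_expressed(m, split).to_numpy() == 1.0).all()

    def test_posterior_in_unit_interval(self):
        rng = np.random.default_rng(4)
        m, split = self._two_class_matrix(rng, n=2000)
        post = posterior_expressed(m, split).to_numpy()
        assert np.all((post >= 0) & (post <= 1))

    def test_monotone_for_equal_variance_gaussians(self):
        rng = np.random.default_rng(5)
        m, split = self._two_class_matrix(rng, n=5000)
        grid = np.linspace(0.0, 10.0, 101)
        m2 = _pm(np.concatenate([m.values.to_numpy().ravel(), grid])[:, None])
        split2 = VarianceSplit(
            log_variance=pd.Series(0.0, index=m2.values.index),
            valley=0.0,
            low_probes=list(m2.values.index[:5000]),
            high_probes=list(m2.values.index[5000:]),
        )
        post = posterior_expressed(m2, split2, density="gaussian").to_numpy().ravel()
        tail = post[-101:]
        assert np.all(np.diff(tail) >= -1e-9)


class TestTranscriptAndGeneCalls:
    def test_min_arrays_boundary(self):
        expressed = pd.DataFrame(
            [[True] * 3 + [False] * 3, [True] * 4 + [False] * 2],
            index=["p3", "p4"],
            columns=[f"s{i}" for i in range(6)],
        )
        mapping = {"p3": "t3", "p4": "t4"}
        called, unmapped = call_transcripts(expressed, mapping, min_arrays=4)
        assert called == {"t4"}
        assert unmapped == []

    def test_unmapped_probe_reported(self):
        expressed = pd.DataFrame([[True] * 5], index=["orphan"], columns=list("abcde"))
        called, unmapped = call_transcripts(expressed, {}, min_arrays=4)
        assert called == set() and unmapped == ["orphan"]

    def test_gene_any_rule_and_representative(self):
        vals = np.array([[5.0] * 4, [7.0] * 4])
        m = _pm(vals)
        ann = pd.DataFrame(
            {
                "probe_id": ["p0", "p1"],
                "transcript_id": ["t0", "t1"],
                "gene_id": ["g", "g"],
            }
        )
        genes, nongenes, rep = collapse_genes({"t0"}, ann, m)
        assert genes == {"g"} and nongenes == set()
        assert rep["g"] == "p1"  # highest mean intensity wins

    def test_representative_tie_lexicographic(self):
        vals = np.array([[6.0] * 4, [6.0] * 4])
        m = _pm(vals)
        ann = pd.DataFrame(
            {
                "probe_id": ["p1", "p0"],
                "transcript_id": ["t1", "t0"],
                "gene_id": ["g", "g"],
            }
        )
        _, _, rep = collapse_genes(set(), ann, m)
        assert rep["g"] == "p0"


class TestFullCaller:
    def test_gene_universe_partitioned(self, small_dataset, small_pipeline):
        _, annotation, _, _ = small_dataset
        result, _ = small_pipeline
        calls = result.calls
        assert calls.expressed_genes.isdisjoint(calls.nonexpressed_genes)
        assert calls.expressed_genes | calls.nonexpressed_genes == set(annotation["gene_id"])

    def test_raising_threshold_shrinks_expressed_set(self, small_dataset):
        matrix, annotation, _, _ = small_dataset
        lenient = call_expression(matrix, annotation, posterior_threshold=0.5)
        strict = call_expression(matrix, annotation, posterior_threshold=0.99)
        assert strict.expressed_genes <= lenient.expressed_genes

    def test_recovery_against_truth(self, small_dataset, small_pipeline):
        _, annotation, _, truth = small_dataset
        result, _ = small_pipeline
        called = result.calls.expressed_genes
        tp = len(called & truth.expressed_genes)
        assert tp / len(truth.expressed_genes) >= 0.95
        universe = set(annotation["gene_id"])
        tn = len((universe - truth.expressed_genes) - called)
        assert tn / len(universe - truth.expressed_genes) >= 0.95


class TestStraightLineOracle:
    def test_toy_pipeline_equals_straight_line_reimplementation(self):
        """20 probes x 6 samples: package output vs direct brute-force code.

        The oracle recomputes every step inline with exact (unbinned)
        Gaussian-kernel densities; with a fixed valley and well-separated
        classes the boolean calls and gene sets must coincide.
        """
        rng = np.random.default_rng(9)
        low = rng.normal(2, 0.1, (12, 6))
        high = rng.normal(8, 1.0, (8, 6))
        vals = np.vstack([low, high])
        m = _pm(vals)
        ann = pd.DataFrame(
            {
                "probe_id": [f"p{i}" for i in range(20)],
                "transcript_id": [f"t{i}" for i in range(20)],
                "gene_id": [f"g{i // 2}" for i in range(20)],
            }
        )
        valley = np.log(0.25)  # between var 0.01 and var ~1
        calls = call_expression(m, ann, valley=valley)

        # --- straight-line re-implementation ---
        var = vals.var(axis=1, ddof=1)
        logv = np.log(var)
        is_high = logv >= valley
        pi_high = is_high.mean()
        expressed = np.zeros((20, 6), dtype=bool)
        for j in range(6):
            xl, xh = vals[~is_high, j], vals[is_high, j]
            def kde(pts, data):
                sd = data.std(ddof=1)
                iqr = np.subtract(*np.percentile(data, [75, 25]))
                h = 0.9 * min(sd, iqr / 1.34 if iqr > 0 else sd) * len(data) ** -0.2
                return norm.pdf((pts[:, None] - data[None, :]) / h).sum(axis=1) / (len(data) * h)
            fl, fh = kde(vals[:, j], xl), kde(vals[:, j], xh)
            post = pi_high * fh / (pi_high * fh + (1 - pi_high) * fl)
            expressed[:, j] = post > 0.95
        transcripts = {f"t{i}" for i in range(20) if expressed[i].sum() >= 4}
        genes = {f"g{i // 2}" for i in range(20) if f"t{i}" in transcripts}
        rep = {}
        means = vals.mean(axis=1)
        for g in range(10):
            a, b = 2 * g, 2 * g + 1
            rep[f"g{g}"] = f"p{a}" if means[a] >= means[b] else f"p{b}"
        # ---------------------------------------

        assert calls.expressed_transcripts == transcripts
        assert calls.expressed_genes == genes
        assert calls.representative_probe == rep
        np.testing.assert_array_equal(
            calls.probe_sample_expressed.to_numpy(), expressed
        )
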