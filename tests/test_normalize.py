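import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest

from parallelpy.datatypes import CountMatrix, ValidationError
from parallelpy.normalize import (
    NormFactors,
    cpm,
    estimate_bcv2,
    filter_low_expression,
    tmm_factors,
)

from conftest import nb_counts


def oracle_tmm_pair(obs, ref, lib_obs, lib_ref):
    """Step-by-step trim-and-weight reference, written independently:
    plain loops over scipy-free arithmetic."""
    m_vals, a_vals, w_vals = [], [], []
    for o, r in zip(obs, ref):
        if o > 0 and r > 0:
            po, pr = o / lib_obs, r / lib_ref
            m_vals.append(np.log2(po / pr))
            a_vals.append(0.5 * np.log2(po * pr))
            w_vals.append((lib_obs - o) / (lib_obs * o)
                          + (lib_ref - r) / (lib_ref * r))
    m_vals, a_vals, w_vals = map(np.array, (m_vals, a_vals, w_vals))
    n = len(m_vals)
    rank_m = pd.Series(m_vals).rank().to_numpy()
    rank_a = pd.Series(a_vals).rank().to_numpy()
    lo_m = np.floor(n * 0.3) + 1
    hi_m = n + 1 - lo_m
    lo_a = np.floor(n * 0.05) + 1
    hi_a = n + 1 - lo_a
    keep = ((rank_m >= lo_m) & (rank_m <= hi_m)
            & (rank_a >= lo_a) & (rank_a <= hi_a))
    return 2.0 ** (np.sum(m_vals[keep] / w_vals[keep])
                   / np.sum(1.0 / w_vals[keep]))


def composition_fixture():
    """1000 equal genes plus 100 genes 10x up in sample B only."""
    rng = np.random.default_rng(0)
    base = rng.integers(50, 500, 1100)
    a = base.copy()
    b = base.copy()
    b[1000:] *= 10
    counts = np.column_stack([a, b])
    return CountMatrix([f"g{i}" for i in range(1100)], ["A", "B"], counts)


class TestTMM:
    def test_identical_samples_unit_factors(self):
        counts = np.tile(np.arange(1, 101)[:, None], (1, 4))
        m = CountMatrix([f"g{i}" for i in range(100)],
                        ["a", "b", "c", "d"], counts)
        np.testing.assert_allclose(tmm_factors(m).factors, 1.0, atol=1e-9)

    def test_pure_depth_scaling_unit_factors(self):
        rng = np.random.default_rng(1)
        base = rng.integers(10, 1000, 500)
        m = CountMatrix([f"g{i}" for i in range(500)], ["a", "b"],
                        np.column_stack([base, base * 3]))
        np.testing.assert_allclose(tmm_factors(m).factors, 1.0, atol=1e-9)

    def test_composition_fixture_matches_step_oracle(self):
        m = composition_fixture()
        f = tmm_factors(m)
        raw = oracle_tmm_pair(m.counts[:, 1], m.counts[:, 0],
                              m.lib_size[1], m.lib_size[0])
        expected = np.array([1.0, raw])
        expected /= np.exp(np.mean(np.log(expected)))
        np.testing.assert_allclose(f.factors, expected, rtol=1e-10)

    def test_matches_edger_reference(self, tmp_path):
        """Cross-check against the canonical implementation via Rscript."""
        m = composition_fixture()
        counts_file = tmp_path / "counts.tsv"
        pd.DataFrame(m.counts, columns=["A", "B"]).to_csv(
            counts_file, sep="\t", index=False
        )
        script = tmp_path / "tmm.R"
        script.write_text(textwrap.dedent(f"""
            suppressMessages(library(edgeR))
            x <- read.delim("{counts_file}")
            f <- calcNormFactors(as.matrix(x), method="TMM")
            cat(sprintf("%.10f %.10f", f[1], f[2]))
        """))
        try:
            out = subprocess.run(
                ["Rscript", "--vanilla", str(script)],
                capture_output=True, text=True, timeout=120,
            )
        except (FileNotFoundError, subprocess.TimeoutExpired):
            pytest.skip("Rscript unavailable")
        if out.returncode != 0:
            pytest.skip(f"edgeR unavailable: {out.stderr[-200:]}")
        expected = np.array([float(v) for v in out.stdout.split()])
        np.testing.assert_allclose(tmm_factors(m).factors, expected, rtol=1e-6)

    def test_scale_invariance(self):
        m = composition_fixture()
        f1 = tmm_factors(m).factors
        scaled = CountMatrix(m.gene_ids, m.sample_ids,
                             np.column_stack([m.counts[:, 0] * 7,
                                              m.counts[:, 1]]))
        f2 = tmm_factors(scaled).factors
        np.testing.assert_allclose(f1, f2, rtol=1e-9)

    def test_disjoint_support_rejected(self):
        counts = np.array([[5, 0], [0, 5]])
        m = CountMatrix(["g1", "g2"], ["a", "b"], counts)
        with pytest.raises(ValidationError, match="co-expressed"):
            tmm_factors(m)


class TestCPM:
    def test_basic_scaling(self):
        m = CountMatrix(["g1", "g2"], ["s1"], np.array([[100], [999_900]]))
        f = NormFactors(["s1"], np.array([1.0]), np.array([1e6]))
        table = cpm(m, f, prior_count=0.0)
        assert table.loc["g1", "s1"] == pytest.approx(100.0)

    def test_zero_count_zero_cpm(self):
        m = CountMatrix(["g1", "g2"], ["s1"], np.array([[0], [10]]))
        assert cpm(m, prior_count=0.0).loc["g1", "s1"] == 0.0

    def test_prior_count_hand_formula(self):
        """Single sample, lib 1e6: CPM = (count + prior) / lib * 1e6."""
        m = CountMatrix(["g1", "g2"], ["s1"], np.array([[10], [999_990]]))
        f = NormFactors(["s1"], np.array([1.0]), np.array([1e6]))
        got = cpm(m, f, prior_count=0.5).loc["g1", "s1"]
        assert got == pytest.approx((10 + 0.5) / 1e6 * 1e6)

    def test_columns_sum_to_million_without_prior(self, tiny_counts):
        table = cpm(tiny_counts, prior_count=0.0)
        np.testing.assert_allclose(table.sum(axis=0), 1e6)


class TestExpressionFilter:
    def test_boundary_inclusive(self):
        table = pd.DataFrame({"s1": [0.1, 0.09], "s2": [5.0, 5.0]},
                             index=["keep", "drop"])
        assert filter_low_expression(table, 0.1) == ["keep"]

    def test_hand_fixture(self):
        table = pd.DataFrame(
            {"s1": [1.0, 0.0, 0.2, 50.0, 0.1],
             "s2": [1.0, 1.0, 0.05, 50.0, 0.1]},
            index=list("abcde"),
        )
        assert filter_low_expression(table, 0.1) == ["a", "d", "e"]

    def test_empty_result_warns(self):
        table = pd.DataFrame({"s1": [0.01]}, index=["a"])
        with pytest.warns(UserWarning, match="no genes"):
            assert filter_low_expression(table, 0.1) == []


class TestBCV2:
    def test_poisson_limit_near_zero(self):
        rng = np.random.default_rng(0)
        counts = rng.poisson(1000.0, (500, 20))
        m = CountMatrix([f"g{i}" for i in range(500)],
                        [f"i{j}" for j in range(20)], counts)
        est = estimate_bcv2(m)
        assert np.nanmedian(est.dispersion) < 0.01

    def test_phi_recovery_within_bootstrap_band(self):
        rng = np.random.default_rng(5)
        counts = nb_counts(rng, 1000.0, 0.09, (2000, 20))
        m = CountMatrix([f"g{i}" for i in range(2000)],
                        [f"i{j}" for j in range(20)], counts)
        est = estimate_bcv2(m)
        boots = [np.nanmean(rng.choice(est.dispersion, 2000))
                 for _ in range(500)]
        lo, hi = np.percentile(boots, [2.5, 97.5])
        assert lo <= 0.09 <= hi

    def test_cross_panel_concordance(self):
        """Two independent panels from identical parameters rank genes
        alike, mirroring the replicate-set concordance check."""
        rng = np.random.default_rng(6)
        phi = rng.lognormal(np.log(0.09), 0.8, 1000)
        ests = []
        for _ in range(2):
            counts = nb_counts(rng, 800.0, phi[:, None], (1000, 20))
            m = CountMatrix([f"g{i}" for i in range(1000)],
                            [f"i{j}" for j in range(20)], counts)
            ests.append(estimate_bcv2(m).dispersion)
        from scipy.stats import spearmanr
        rho = spearmanr(ests[0], ests[1]).statistic
        assert rho > 0.5

    def test_consistency_with_panel_size(self):
        """|bias| of the mean estimate shrinks as the panel grows."""
        rng = np.random.default_rng(7)
        biases = []
        for n in (10, 40, 160):
            counts = nb_counts(rng, 500.0, 0.09, (400, n))
            m = CountMatrix([f"g{i}" for i in range(400)],
                            [f"i{j}" for j in range(n)], counts)
            est = estimate_bcv2(m)
            biases.append(abs(np.nanmean(est.per_gene_mle) - 0.09))
        assert biases[2] < biases[0]

    def test_all_zero_gene_flagged(self):
        rng = np.random.default_rng(8)
        counts = rng.poisson(100.0, (50, 10))
        counts[0, :] = 0
        m = CountMatrix([f"g{i}" for i in range(50)],
                        [f"i{j}" for j in range(10)], counts)
        est = estimate_bcv2(m)
        assert np.isnan(est.dispersion[0])
        assert np.all(np.isfinite(est.dispersion[1:]))

    def test_too_few_individuals_rejected(self):
        m = CountMatrix(["g1"], [f"i{j}" for j in range(4)],
                        np.ones((1, 4), dtype=int))
        with pytest.raises(ValidationError, match=">=5"):
            estimate_bcv2(m)
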