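import numpy as np
import pandas as pd
import pytest

from parallelpy.datatypes import ValidationError
from parallelpy.sim import (
    Architecture,
    SimConfig,
    evaluate_parallelism,
    run_experiment,
    run_replicate,
    run_replicate_set,
)
from parallelpy.synthetic import gen_founder_haplotypes


def small_cfg(**kw):
    defaults = dict(n_diploid=100, n_replicates=3, generations=20,
                    n_runs=20, seed=0,
                    architecture=Architecture(loci_per_gene=(5, 15)))
    defaults.update(kw)
    return SimConfig(**defaults)


class TestArchitecture:
    def test_equal_per_locus_effects(self):
        arch = Architecture()
        eff = arch.effects
        assert eff.size == 100
        assert np.all(eff == eff[0])

    def test_gene_slices_partition_loci(self):
        arch = Architecture()
        covered = np.zeros(arch.n_loci, dtype=int)
        for s in arch.gene_slices:
            covered[s] += 1
        assert np.all(covered == 1)

    def test_ancestral_variance_scales_with_locus_count(self):
        """More loci of equal effect = more standing variation."""
        rng = np.random.default_rng(0)
        cfg = small_cfg(architecture=Architecture(loci_per_gene=(5, 50)))
        founders = gen_founder_haplotypes(189, 55, seed=1)
        run = run_replicate_set(founders, cfg, rng)
        assert run["ancestral_gene_var"][1] > run["ancestral_gene_var"][0]


class TestNeutralLimit:
    def test_heterozygosity_decay_matches_wright_fisher(self):
        """No selection: expected heterozygosity decays by (1 - 1/2N)
        per generation; check the mean over loci and replicates against
        the diffusion prediction within 3 SE."""
        n, gens, reps = 50, 30, 30
        founders = gen_founder_haplotypes(100, 40, seed=2)
        arch = Architecture(loci_per_gene=(40,))
        cfg = SimConfig(n_diploid=n, n_replicates=1, generations=gens,
                        optimum_shift=0.0, selection_width=1e9, seed=0,
                        architecture=arch)
        rng = np.random.default_rng(3)
        ratios = []
        for _ in range(reps):
            hap0 = founders[rng.integers(0, 100, 2 * n), :]
            h0 = 2 * hap0.mean(0) * (1 - hap0.mean(0))
            out = run_replicate(founders, arch, cfg, rng, optimum=0.0,
                                omega=1e9)
            f1 = out["final_hap"].mean(0)
            h1 = 2 * f1 * (1 - f1)
            ratios.append(h1.mean() / h0.mean())
        expected = (1 - 1 / (2 * n)) ** gens
        se = np.std(ratios, ddof=1) / np.sqrt(reps)
        assert abs(np.mean(ratios) - expected) < 3 * se

    def test_neutral_frequency_change_within_drift_band(self):
        n = 100
        founders = gen_founder_haplotypes(150, 30, seed=4)
        arch = Architecture(loci_per_gene=(30,))
        cfg = SimConfig(n_diploid=n, n_replicates=1, generations=10,
                        optimum_shift=0.0, selection_width=1e9, seed=0,
                        architecture=arch)
        rng = np.random.default_rng(5)
        deltas = []
        for _ in range(20):
            out = run_replicate(founders, arch, cfg, rng, optimum=0.0,
                                omega=1e9)
            deltas.append(out["final_hap"].mean(0) - out["initial_hap"].mean(0))
        mean_delta = np.concatenate(deltas).mean()
        # drift SD per locus after t generations ~ sqrt(t * p q / 2N)
        band = 3 * np.sqrt(10 * 0.25 / (2 * n) / (20 * 30))
        assert abs(mean_delta) < band


class TestSelectionResponse:
    def test_trait_moves_toward_shifted_optimum(self):
        founders = gen_founder_haplotypes(189, 20, seed=6)
        cfg = SimConfig(n_diploid=150, n_replicates=10, generations=40,
                        optimum_shift=1.0, selection_width=0.5, seed=0,
                        architecture=Architecture(loci_per_gene=(5, 15)))
        rng = np.random.default_rng(7)
        run = run_replicate_set(founders, cfg, rng)
        gap0 = abs(run["optimum"] - run["ancestral_trait_mean"])
        gaps = np.abs(run["optimum"] - run["final_trait_means"])
        assert np.mean(gaps < gap0) >= 0.95

    def test_single_locus_matches_deterministic_recursion(self):
        """One locus, weak Gaussian selection: mean trajectory over many
        replicates tracks the deterministic allele-frequency recursion."""
        n = 500
        arch = Architecture(loci_per_gene=(1,), per_locus_effect=1.0)
        law = lambda r, size: np.full(size, 0.3)  # noqa: E731
        founders = gen_founder_haplotypes(400, 1, freq_law=law, seed=8)
        p0 = founders.mean()
        gens = 15
        opt, omega = 2.0, 2.0  # optimum at homozygote-rich side
        cfg = SimConfig(n_diploid=n, n_replicates=1, generations=gens,
                        seed=0, architecture=arch)
        rng = np.random.default_rng(9)
        finals = []
        for _ in range(40):
            out = run_replicate(founders, arch, cfg, rng, optimum=opt,
                                omega=omega)
            finals.append(out["final_hap"].mean())
        # deterministic recursion under the same Gaussian fitness on
        # genotype value g in {0,1,2}
        w = {g: np.exp(-((g - opt) ** 2) / (2 * omega**2)) for g in (0, 1, 2)}
        p = p0
        for _ in range(gens):
            freqs = {0: (1 - p) ** 2, 1: 2 * p * (1 - p), 2: p**2}
            wbar = sum(freqs[g] * w[g] for g in (0, 1, 2))
            p = (freqs[2] * w[2] + 0.5 * freqs[1] * w[1]) / wbar
        se = np.std(finals, ddof=1) / np.sqrt(len(finals))
        assert np.mean(finals) == pytest.approx(p, abs=4 * se + 0.01)


class TestEvaluateParallelism:
    def fake_run(self, pop_means, anc_var, anc_mean=None):
        pop_means = np.asarray(pop_means, dtype=float)
        g = pop_means.shape[1]
        return {
            "ancestral_gene_mean": np.zeros(g) if anc_mean is None else anc_mean,
            "ancestral_gene_var": np.asarray(anc_var, dtype=float),
            "ancestral_trait_sd": 1.0,
            "final_gene_means": pop_means,
        }

    def test_identical_populations_f_near_null(self):
        """All populations identical: only measurement noise remains and
        the scaled statistic R*F has mean ~ F(9,20) expectation."""
        cfg = SimConfig(measurement_noise_sd=1.0,
                        architecture=Architecture(loci_per_gene=(5,)))
        rng = np.random.default_rng(10)
        fs = []
        for _ in range(300):
            run = self.fake_run(np.zeros((10, 1)), [1.0])
            tab = evaluate_parallelism(run, cfg, rng)
            fs.append(tab["f"].iloc[0])
        assert 3 * np.mean(fs) == pytest.approx(20 / 18, rel=0.1)

    def test_distinct_fixed_phenotypes_low_parallelism(self):
        cfg = SimConfig(measurement_noise_sd=0.01,
                        architecture=Architecture(loci_per_gene=(5,)))
        rng = np.random.default_rng(11)
        run = self.fake_run(np.arange(10, dtype=float)[:, None], [1.0])
        tab = evaluate_parallelism(run, cfg, rng)
        assert tab["f"].iloc[0] > 100
        assert tab["parallelism"].iloc[0] < 0.01

    def test_more_loci_more_parallel_under_selection(self):
        """The headline mechanism: genes with more standing variation
        (more equal-effect loci) respond less in parallel.  Founders are
        redrawn each run so the comparison averages over founder pools,
        and measurement noise is kept low to expose the signal."""
        cfg = SimConfig(n_diploid=150, n_replicates=10, generations=50,
                        n_runs=20, seed=1, measurement_noise_sd=0.2,
                        architecture=Architecture(loci_per_gene=(5, 50)))
        rng = np.random.default_rng(12)
        ln_par = {5: [], 50: []}
        for rep in range(20):
            founders = gen_founder_haplotypes(189, 55, seed=1000 + rep)
            run = run_replicate_set(founders, cfg, rng)
            tab = evaluate_parallelism(run, cfg, rng)
            for n_loci, v in zip(tab["n_loci"], tab["ln_parallelism"]):
                ln_par[n_loci].append(v)
        assert np.mean(ln_par[5]) > np.mean(ln_par[50])


class TestExperiment:
    def test_seed_determinism(self):
        cfg = small_cfg(n_runs=20, seed=42)
        r1 = run_experiment(cfg)
        r2 = run_experiment(small_cfg(n_runs=20, seed=42))
        assert r1["rho"] == r2["rho"]
        pd.testing.assert_frame_equal(r1["sampled"], r2["sampled"])

    def test_huge_noise_destroys_signal(self):
        cfg = small_cfg(n_runs=30, seed=2, measurement_noise_sd=100.0,
                        architecture=Architecture(loci_per_gene=(5, 15, 30, 50)))
        res = run_experiment(cfg)
        assert abs(res["rho"]) < 3.0 / np.sqrt(30)

    def test_too_few_runs_rejected(self):
        with pytest.raises(ValidationError, match=">= 20"):
            run_experiment(small_cfg(n_runs=5))
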