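"""Synthetic inputs with known ground truth for every pipeline stage.

The generator emulates the structure of the study design it is built
for: 5 pooled ancestral RNA-seq samples plus 10 evolved populations x 3
biological replicates, two 20-individual ancestral panels, a
FlyAtlas2-like tissue table, and a weighted regulatory network.  Gene
level ground truth is a triple of latents — pleiotropy Pl, ancestral
variation A and parallelism Pa — drawn from one of the five candidate
causal graphs, and every observable is a declared monotone link of a
latent:

* individual-panel counts are negative binomial with dispersion
  ``exp(A + log_dispersion_offset)``;
* the across-population spread of the true log2 fold change is
  ``lfc_sd_scale * exp(-Pa / 2)`` (more parallelism = less spread);
* the tissue profile realizes ``1 - tau = Phi(Pl)`` exactly and the
  network realizes per-gene connectivity ``exp(Pl)``.

Pooled-sample counts use a small constant dispersion: pooling ~50
individuals averages away individual-level biological variance, and a
constant value keeps measurement error independent of A by design.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.stats import norm

from .datatypes import (
    CountMatrix,
    NetworkEdges,
    SampleDesign,
    TissueProfile,
    ValidationError,
)

__all__ = [
    "DEFAULT_COEFFICIENTS",
    "make_study_design",
    "gen_causal_truth",
    "gen_counts_from_truth",
    "gen_individual_panels",
    "gen_tissue_profile",
    "gen_network",
    "gen_founder_haplotypes",
    "simulate_dataset",
]

#: default causal link strengths: a = Pl->A, b = A->Pa, c = Pl->Pa.
#: Signs follow the biology the generator emulates (pleiotropy depletes
#: ancestral variation, ancestral variation reduces parallelism,
#: pleiotropy sharpens the selection response).
DEFAULT_COEFFICIENTS = {"a": -0.5, "b": -0.4, "c": 0.3}


def make_study_design(n_pops: int = 10, n_reps: int = 3,
                      n_ancestral: int = 5) -> SampleDesign:
    """Sample table mirroring the evolve-and-resequence layout."""
    rows = [
        {"sample_id": f"anc_{j + 1}", "role": "ancestral",
         "population_id": 0, "replicate_id": j + 1}
        for j in range(n_ancestral)
    ]
    rows += [
        {"sample_id": f"evo_{p + 1}_{r + 1}", "role": "evolved",
         "population_id": p + 1, "replicate_id": r + 1}
        for p in range(n_pops)
        for r in range(n_reps)
    ]
    return SampleDesign(pd.DataFrame(rows))


def gen_causal_truth(
    model: str,
    n_genes: int,
    coefficients: dict | None = None,
    noise_sd: float = 1.0,
    seed: int | None = 0,
) -> pd.DataFrame:
    """Draw (Pl, A, Pa) latents under one of the five causal graphs.

    Pl is always standard normal; structural residuals have SD
    ``noise_sd``.  Under model V the three latents are mutually
    independent; models I-III give A the stated slope on Pl.
    """
    if model not in ("I", "II", "III", "IV", "V"):
        raise ValidationError(f"unknown model {model!r}")
    if n_genes < 10:
        raise ValidationError("n_genes must be >= 10")
    coef = dict(DEFAULT_COEFFICIENTS)
    if coefficients:
        coef.update(coefficients)
    if not all(np.isfinite(v) for v in coef.values()):
        raise ValidationError("coefficients must be finite")
    a, b, c = coef["a"], coef["b"], coef["c"]
    rng = np.random.default_rng(seed)
    pl = rng.normal(0.0, 1.0, n_genes)
    e_a = rng.normal(0.0, noise_sd, n_genes)
    e_pa = rng.normal(0.0, noise_sd, n_genes)
    if model in ("I", "II", "III"):
        av = a * pl + e_a
    else:
        av = e_a
    if model == "I":
        pa = b * av + e_pa
    elif model == "II":
        pa = c * pl + e_pa
    elif model in ("III", "IV"):
        pa = b * av + c * pl + e_pa
    else:
        pa = e_pa
    return pd.DataFrame(
        {
            "gene_id": [f"g{i:05d}" for i in range(n_genes)],
            "Pl": pl,
            "A": av,
            "Pa": pa,
            "generating_model": model,
            "a": a,
            "b": b,
            "c": c,
        }
    )


def _nb_draw(rng: np.random.Generator, mu: np.ndarray,
             phi: np.ndarray | float) -> np.ndarray:
    """Gamma-Poisson NB sampler; phi = 0 degenerates to Poisson."""
    mu = np.asarray(mu, dtype=float)
    phi = np.broadcast_to(np.asarray(phi, dtype=float), mu.shape)
    out = np.empty(mu.shape, dtype=np.int64)
    pois = phi <= 0
    if np.any(pois):
        out[pois] = rng.poisson(mu[pois])
    if np.any(~pois):
        shape = 1.0 / phi[~pois]
        lam = rng.gamma(shape, phi[~pois] * mu[~pois])
        out[~pois] = rng.poisson(lam)
    return out


def gen_counts_from_truth(
    truth: pd.DataFrame,
    design: SampleDesign,
    mean_expression: np.ndarray | None = None,
    seed: int | None = 0,
    lfc_base: float = 1.0,
    lfc_extra_sd: float = 0.5,
    lfc_sd_scale: float = 1.0,
    pool_dispersion: float = 0.01,
    depth_sd: float = 0.15,
) -> tuple[CountMatrix, pd.DataFrame]:
    """Pooled-sample count matrix for the ancestral + evolved design.

    Every gene receives an adaptive shift ``sign * (lfc_base +
    |N(0, lfc_extra_sd)|)`` (log2 units) shared across populations;
    each population's true log2FC deviates from it with SD
    ``lfc_sd_scale * exp(-Pa/2)``, shared by that population's
    replicates.  Counts are NB with dispersion ``pool_dispersion``
    around ``mean_expression * depth_factor * 2**log2FC``.

    Returns ``(CountMatrix, per-population true log2FC table)``.
    """
    rng = np.random.default_rng(seed)
    n_genes = len(truth)
    if mean_expression is None:
        mean_expression = rng.lognormal(np.log(200.0), 1.0, n_genes)
    mean_expression = np.asarray(mean_expression, dtype=float)
    if np.any(mean_expression <= 0):
        raise ValidationError("mean_expression must be positive")

    pops = design.populations
    sign = rng.choice([-1.0, 1.0], n_genes)
    delta = sign * (lfc_base + np.abs(rng.normal(0.0, lfc_extra_sd, n_genes)))
    sd_pop = lfc_sd_scale * np.exp(-truth["Pa"].to_numpy() / 2.0)
    true_lfc = delta[:, None] + rng.normal(0.0, 1.0, (n_genes, len(pops))) * sd_pop[:, None]

    sample_ids = list(design.table["sample_id"])
    depth = rng.lognormal(0.0, depth_sd, len(sample_ids))
    counts = np.empty((n_genes, len(sample_ids)), dtype=np.int64)
    pop_col = {p: i for i, p in enumerate(pops)}
    for j, (sid, role, pop) in enumerate(
        zip(design.table["sample_id"], design.table["role"],
            design.table["population_id"])
    ):
        mu = mean_expression * depth[j]
        if role == "evolved":
            mu = mu * 2.0 ** true_lfc[:, pop_col[pop]]
        counts[:, j] = _nb_draw(rng, mu, pool_dispersion)

    m = CountMatrix(list(truth["gene_id"]), sample_ids, counts)
    lfc_table = pd.DataFrame(
        true_lfc, index=truth["gene_id"], columns=[f"pop_{p}" for p in pops]
    )
    return m, lfc_table


def gen_individual_panels(
    truth: pd.DataFrame,
    mean_expression: np.ndarray,
    n_panels: int = 2,
    n_individuals: int = 20,
    log_dispersion_offset: float = float(np.log(0.09)),
    depth_sd: float = 0.15,
    seed: int | None = 0,
) -> list[CountMatrix]:
    """Individual-level ancestral panels with dispersion exp(A + offset).

    The offset centers BCV^2 on a realistic scale (default 0.09) while
    A carries the gene-to-gene variation; two independent panels mirror
    the study's replicate-concordance check.
    """
    rng = np.random.default_rng(seed)
    phi = np.exp(truth["A"].to_numpy() + log_dispersion_offset)
    mean_expression = np.asarray(mean_expression, dtype=float)
    panels = []
    for p in range(n_panels):
        depth = rng.lognormal(0.0, depth_sd, n_individuals)
        mu = mean_expression[:, None] * depth[None, :]
        counts = _nb_draw(rng, mu, phi[:, None])
        panels.append(
            CountMatrix(
                list(truth["gene_id"]),
                [f"panel{p + 1}_ind{i + 1}" for i in range(n_individuals)],
                counts,
            )
        )
    return panels


def gen_tissue_profile(
    target_tau: np.ndarray,
    n_tissues: int = 20,
    gene_ids=None,
    seed: int | None = 0,
) -> TissueProfile:
    """Profile whose tau equals ``target_tau`` exactly.

    One tissue (random position) is set to 1.0 and all others to
    ``1 - target_tau``, which plugs into the tau formula as
    (N-1)(1 - (1-tau)) / (N-1) = tau.
    """
    target_tau = np.asarray(target_tau, dtype=float)
    if np.any((target_tau < 0) | (target_tau > 1)):
        raise ValidationError("target tau must lie in [0, 1]")
    if n_tissues < 2:
        raise ValidationError("need >= 2 tissues")
    rng = np.random.default_rng(seed)
    n = len(target_tau)
    expr = np.repeat((1.0 - target_tau)[:, None], n_tissues, axis=1)
    max_pos = rng.integers(0, n_tissues, n)
    expr[np.arange(n), max_pos] = 1.0
    if gene_ids is None:
        gene_ids = [f"g{i:05d}" for i in range(n)]
    tissues = [f"tissue_{t + 1}" for t in range(n_tissues)]
    return TissueProfile(list(gene_ids), tissues, expr)


def gen_network(
    target_connectivity: np.ndarray,
    gene_ids=None,
    seed: int | None = 0,
    tol: float = 1e-9,
) -> NetworkEdges:
    """Edge list whose per-gene weight sums hit the targets.

    Greedy construction on a max-heap of unmet targets: the two largest
    remainders r1 >= r2 receive an edge of weight min(r2, r1/2) (the
    full min(r1, r2) once only two genes remain), so every step either
    retires a gene or halves the front-runner.  This realizes the
    targets exactly whenever the sequence is feasible (no gene demands
    more than all others combined); any infeasible excess is left unmet
    with a warning.
    """
    import heapq

    rem = np.asarray(target_connectivity, dtype=float).copy()
    if np.any(rem < 0):
        raise ValidationError("connectivity targets must be >= 0")
    if gene_ids is None:
        gene_ids = [f"g{i:05d}" for i in range(len(rem))]
    gene_ids = list(gene_ids)
    heap = [(-r, i) for i, r in enumerate(rem) if r > tol]
    heapq.heapify(heap)
    records = []
    while len(heap) >= 2:
        r1, g1 = heapq.heappop(heap)
        r2, g2 = heapq.heappop(heap)
        r1, r2 = -r1, -r2
        w = min(r1, r2) if len(heap) == 0 else min(r2, r1 / 2.0)
        records.append((gene_ids[g1], gene_ids[g2], w))
        for r, g in ((r1 - w, g1), (r2 - w, g2)):
            if r > tol:
                heapq.heappush(heap, (-r, g))
    if heap and -heap[0][0] > max(1e-6, 10 * tol):
        r, g = heap[0]
        warnings.warn(
            f"connectivity target of {gene_ids[g]} unmet by {-r:.3g}",
            stacklevel=2,
        )
    return NetworkEdges.from_records(records)


def gen_founder_haplotypes(
    n_haplotypes: int,
    n_loci: int,
    freq_law=None,
    seed: int | None = 0,
    max_retries: int = 1000,
) -> np.ndarray:
    """0/1 founder haplotypes at linkage equilibrium.

    Per locus, the founder allele frequency is drawn from ``freq_law``
    (default Beta(0.2, 0.2), a U-shaped spectrum mimicking a natural
    SFS) and haplotype alleles are i.i.d. Bernoulli draws conditioned
    on the locus being polymorphic among the founders (bounded
    redraws).
    """
    if n_haplotypes < 2:
        raise ValidationError("need >= 2 haplotypes")
    rng = np.random.default_rng(seed)
    if freq_law is None:
        freq_law = lambda r, size: r.beta(0.2, 0.2, size)  # noqa: E731
    hap = np.empty((n_haplotypes, n_loci), dtype=np.int8)
    for locus in range(n_loci):
        for _ in range(max_retries):
            p = float(freq_law(rng, 1)[0])
            col = (rng.random(n_haplotypes) < p).astype(np.int8)
            if 0 < col.sum() < n_haplotypes:
                hap[:, locus] = col
                break
        else:
            raise ValidationError(
                f"locus {locus}: no polymorphic draw in {max_retries} retries"
            )
    return hap


def simulate_dataset(
    model: str = "III",
    n_genes: int = 2000,
    seed: int | None = 0,
    coefficients: dict | None = None,
    noise_sd: float = 1.0,
    design: SampleDesign | None = None,
    n_tissues: int = 20,
    **count_kwargs,
) -> dict:
    """All pipeline inputs from a single causal ground truth.

    Returns a dict with keys ``truth``, ``design``, ``counts``,
    ``true_lfc``, ``panels`` (two 20-individual ancestral panels),
    ``tissues`` (realizing 1 - tau = Phi(Pl)), ``network`` (realizing
    connectivity = exp(Pl)) and ``mean_expression``.
    """
    rng = np.random.default_rng(seed)
    child = lambda: int(rng.integers(0, 2**31 - 1))  # noqa: E731
    truth = gen_causal_truth(model, n_genes, coefficients, noise_sd, seed=child())
    if design is None:
        design = make_study_design()
    mean_expression = np.random.default_rng(child()).lognormal(
        np.log(200.0), 1.0, n_genes
    )
    counts, true_lfc = gen_counts_from_truth(
        truth, design, mean_expression, seed=child(), **count_kwargs
    )
    panels = gen_individual_panels(truth, mean_expression, seed=child())
    pl = truth["Pl"].to_numpy()
    tissues = gen_tissue_profile(
        1.0 - norm.cdf(pl), n_tissues=n_tissues,
        gene_ids=list(truth["gene_id"]), seed=child(),
    )
    network = gen_network(np.exp(pl), gene_ids=list(truth["gene_id"]), seed=child())
    return {
        "truth": truth,
        "design": design,
        "counts": counts,
        "true_lfc": true_lfc,
        "panels": panels,
        "tissues": tissues,
        "network": network,
        "mean_expression": mean_expression,
    }
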