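"""Differential expression of each evolved population against the ancestor.

One NB GLM per gene with a two-level evolution factor (ancestral vs the
focal evolved population), offset = log effective library size and a
fixed per-gene dispersion; the evolution effect is tested by a 1-df
likelihood-ratio test against chi-square(1), and p-values are adjusted
by Benjamini-Hochberg within each population's test.  Each evolved
population is tested separately against the common ancestral samples;
no cross-population multiplicity correction is applied beyond that.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import chi2

from ._nb import (
    dispersion_grid,
    estimate_dispersion,
    fit_group_means,
    group_mu,
    nb_loglik,
)
from .datatypes import CountMatrix, SampleDesign, ValidationError
from .normalize import DispersionEstimate, NormFactors

__all__ = ["bh_adjust", "de_test_population", "de_all_populations"]

CALL_UP = "up"
CALL_DOWN = "down"
CALL_NS = "ns"


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values; NaN propagated."""
    p = np.asarray(p, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    vals = p[ok]
    if np.any((vals < 0) | (vals > 1)):
        raise ValidationError("p-values must lie in [0, 1]")
    m = vals.size
    if m == 0:
        return out
    order = np.argsort(vals, kind="mergesort")
    ranked = vals[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    res = np.empty(m)
    res[order] = adj
    out[ok] = res
    return out


def de_test_population(
    m: CountMatrix,
    design: SampleDesign,
    pop: int,
    f: NormFactors | None = None,
    dispersion: DispersionEstimate | None = None,
    fdr_level: float = 0.05,
    prior_n: float = 20.0,
) -> pd.DataFrame:
    """DE table (gene, population, log2fc, pvalue, padj, call) for one population.

    If ``dispersion`` is None, a tagwise dispersion is estimated from
    the contrast's own samples (ancestral + focal population) under the
    two-group model, shrunk toward their common dispersion.
    """
    anc = design.ancestral_samples
    evo = design.population_samples(pop)
    if len(evo) < 2 or len(anc) < 2:
        raise ValidationError(
            f"population {pop}: need >=2 replicates and >=2 ancestral samples"
        )
    samples = anc + evo
    sub = m.subset_samples(samples)
    if f is None:
        eff = sub.lib_size.astype(float)
    else:
        keep = [f.sample_ids.index(s) for s in samples]
        eff = f.effective_lib_size[keep]
    offsets = np.log(eff)
    groups = np.array([0] * len(anc) + [1] * len(evo))

    if dispersion is None:
        phi, _, _ = estimate_dispersion(
            sub.counts, offsets, groups, prior_n=prior_n, grid=dispersion_grid()
        )
    else:
        lut = dict(zip(dispersion.gene_ids, dispersion.dispersion))
        phi = np.array([lut.get(g, np.nan) for g in sub.gene_ids])

    counts = sub.counts.astype(float)
    expressed = (counts.sum(axis=1) > 0) & np.isfinite(phi)
    phi_fit = np.where(expressed, phi, 0.0)

    betas_full = fit_group_means(counts, offsets, groups, phi_fit)
    mu_full = group_mu(betas_full, offsets, groups)
    ll_full = nb_loglik(counts, mu_full, phi_fit[:, None]).sum(axis=1)

    betas_null = fit_group_means(counts, offsets, np.zeros_like(groups), phi_fit)
    mu_null = group_mu(betas_null, offsets, np.zeros_like(groups))
    ll_null = nb_loglik(counts, mu_null, phi_fit[:, None]).sum(axis=1)

    lrt = np.maximum(2.0 * (ll_full - ll_null), 0.0)
    pvals = chi2.sf(lrt, df=1)
    with np.errstate(invalid="ignore"):  # -inf betas for all-zero groups
        log2fc = (betas_full[:, 1] - betas_full[:, 0]) / np.log(2.0)

    pvals = np.where(expressed, pvals, np.nan)
    log2fc = np.where(expressed, log2fc, np.nan)
    padj = bh_adjust(pvals)

    call = np.full(len(sub.gene_ids), CALL_NS, dtype=object)
    sig = np.isfinite(padj) & (padj <= fdr_level) & np.isfinite(log2fc)
    call[sig & (log2fc > 0)] = CALL_UP
    call[sig & (log2fc < 0)] = CALL_DOWN
    return pd.DataFrame(
        {
            "gene_id": sub.gene_ids,
            "population_id": pop,
            "log2fc": log2fc,
            "pvalue": pvals,
            "padj": padj,
            "call": call,
        }
    )


def de_all_populations(
    m: CountMatrix,
    design: SampleDesign,
    f: NormFactors | None = None,
    dispersion: DispersionEstimate | None = None,
    fdr_level: float = 0.05,
    prior_n: float = 20.0,
) -> pd.DataFrame:
    """Concatenated DE calls over every evolved population."""
    tables = [
        de_test_population(m, design, pop, f=f, dispersion=dispersion,
                           fdr_level=fdr_level, prior_n=prior_n)
        for pop in design.populations
    ]
    return pd.concat(tables, ignore_index=True)
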