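"""Per-gene parallelism of the evolutionary expression response.

The response of a gene in evolved sample j of population i is the log2
fold change against the mean ancestral expression,

    X_ij = log2( CPM_evolved_ij / mean(CPM_ancestral) ).

Heterogeneity of the response across populations is summarized by the
ratio F = MS_pop / MS_e with

    MS_pop = sum_i (Xbar_i - Xbar)^2 / (P - 1)
    MS_e   = sum_ij (X_ij - Xbar_i)^2 / (N - P),

and parallelism is its reciprocal 1/F: replicate populations that moved
alike have small between-population spread relative to measurement
error, hence small F and large 1/F.  Note that MS_pop averages squared
deviations of the population *means* without the usual replicate-count
multiplier, so for a balanced design F equals the textbook one-way
ANOVA statistic divided by R and its null distribution is
F(P-1, N-P) / R.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import CountMatrix, SampleDesign, ValidationError
from .de import CALL_DOWN, CALL_UP

__all__ = [
    "GeneEvoStats",
    "log2fc_per_sample",
    "f_statistic",
    "f_statistic_batch",
    "gene_evo_stats",
    "build_rfs",
    "select_adaptive",
]


@dataclass
class GeneEvoStats:
    """Per-gene parallelism summary over a P x R log2FC matrix."""

    gene_ids: list[str]
    x: np.ndarray  # (n_genes, P, R) log2FC per population x replicate
    ms_pop: np.ndarray
    ms_e: np.ndarray
    f: np.ndarray
    parallelism: np.ndarray  # 1/F
    ln_parallelism: np.ndarray  # ln(1/F) = -ln(F)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene_id": self.gene_ids,
                "ms_pop": self.ms_pop,
                "ms_e": self.ms_e,
                "f": self.f,
                "parallelism": self.parallelism,
                "ln_parallelism": self.ln_parallelism,
            }
        )


def log2fc_per_sample(
    cpm_table: pd.DataFrame, design: SampleDesign
) -> tuple[np.ndarray, list[int], list[list[str]]]:
    """Per-gene log2FC of each evolved sample against the ancestral mean.

    Returns ``(x, populations, sample_layout)`` where x has shape
    (n_genes, P, R).  Requires a balanced design (equal replicates per
    population).  Genes whose ancestral mean CPM is zero are returned
    as NaN rows (flagged, not dropped).
    """
    anc = design.ancestral_samples
    pops = design.populations
    layout = [design.population_samples(p) for p in pops]
    n_rep = {len(s) for s in layout}
    if len(n_rep) != 1:
        raise ValidationError("unbalanced replicate numbers across populations")
    r = n_rep.pop()
    anc_mean = cpm_table[anc].to_numpy().mean(axis=1)
    x = np.full((len(cpm_table), len(pops), r), np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        for i, samples in enumerate(layout):
            evo = cpm_table[samples].to_numpy()
            x[:, i, :] = np.log2(evo / anc_mean[:, None])
    x[~np.isfinite(x)] = np.nan
    return x, pops, layout


def f_statistic(x: np.ndarray) -> tuple[float, float, float, float]:
    """(MS_pop, MS_e, F, 1/F) of one P x R log2FC matrix.

    MS_e = 0 leaves F undefined (NaN); MS_pop = 0 with positive MS_e
    gives F = 0 and parallelism = +inf.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValidationError("need a P x R matrix with P >= 2 and R >= 2")
    if np.any(~np.isfinite(x)):
        raise ValidationError("non-finite log2FC entries")
    ms_pop, ms_e, f, par, _ = f_statistic_batch(x[None, :, :])
    return float(ms_pop[0]), float(ms_e[0]), float(f[0]), float(par[0])


def f_statistic_batch(x: np.ndarray):
    """Vectorized (n_genes, P, R) version of :func:`f_statistic`."""
    n_genes, p, r = x.shape
    pop_means = np.nanmean(x, axis=2)
    grand = np.nanmean(pop_means, axis=1)
    ms_pop = np.nansum((pop_means - grand[:, None]) ** 2, axis=1) / (p - 1)
    resid = x - pop_means[:, :, None]
    n_obs = np.isfinite(x).reshape(n_genes, -1).sum(axis=1)
    ms_e = np.nansum(resid**2, axis=(1, 2)) / np.maximum(n_obs - p, 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = np.where(ms_e > 0, ms_pop / ms_e, np.nan)
        par = np.where(np.isnan(f), np.nan, np.where(f > 0, 1.0 / f, np.inf))
        lnpar = np.where(np.isfinite(par) & (par > 0), -np.log(f), np.nan)
    return ms_pop, ms_e, f, par, lnpar


def gene_evo_stats(cpm_table: pd.DataFrame, design: SampleDesign,
                   genes=None) -> GeneEvoStats:
    """Full parallelism summary for (a subset of) the CPM table."""
    if genes is not None:
        cpm_table = cpm_table.loc[list(genes)]
    x, _, _ = log2fc_per_sample(cpm_table, design)
    ms_pop, ms_e, f, par, lnpar = f_statistic_batch(x)
    n_degenerate = int(np.sum(~np.isfinite(lnpar)))
    if n_degenerate:
        warnings.warn(
            f"{n_degenerate} gene(s) with degenerate F excluded from log-scale "
            "analyses",
            stacklevel=2,
        )
    return GeneEvoStats(list(cpm_table.index), x, ms_pop, ms_e, f, par, lnpar)


def _direction_counts(calls: pd.DataFrame) -> pd.DataFrame:
    """Per gene: number of populations significant up and down."""
    up = (
        calls.assign(is_up=calls["call"] == CALL_UP)
        .groupby("gene_id", sort=False)["is_up"]
        .sum()
    )
    down = (
        calls.assign(is_down=calls["call"] == CALL_DOWN)
        .groupby("gene_id", sort=False)["is_down"]
        .sum()
    )
    return pd.DataFrame({"n_up": up, "n_down": down})


def build_rfs(calls: pd.DataFrame) -> pd.DataFrame:
    """Replicate frequency spectrum.

    For each gene, k is the larger of (populations significant up,
    populations significant down); the spectrum counts genes with
    k = 1..P.  Genes significant nowhere are not part of the spectrum.
    """
    n_pops = calls["population_id"].nunique()
    d = _direction_counts(calls)
    k = d[["n_up", "n_down"]].max(axis=1)
    spectrum = [int((k == i).sum()) for i in range(1, n_pops + 1)]
    return pd.DataFrame({"n_populations": range(1, n_pops + 1), "n_genes": spectrum})


def select_adaptive(calls: pd.DataFrame, min_populations: int = 3) -> pd.DataFrame:
    """Putatively adaptive genes: significant in the same direction in at
    least ``min_populations`` evolved populations (inclusive threshold).

    Returns a table (gene_id, direction, n_populations) in input gene
    order; ties between directions keep both counts but a gene
    qualifies on its majority direction.
    """
    if min_populations < 1:
        raise ValidationError("min_populations must be >= 1")
    d = _direction_counts(calls)
    best = d[["n_up", "n_down"]].max(axis=1)
    sel = d[best >= min_populations]
    direction = np.where(sel["n_up"] >= sel["n_down"], CALL_UP, CALL_DOWN)
    return pd.DataFrame(
        {
            "gene_id": sel.index,
            "direction": direction,
            "n_populations": best[best >= min_populations].to_numpy(),
        }
    ).reset_index(drop=True)
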