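"""Library-size normalization and biological-variance estimation.

Implements trimmed-mean-of-M-values (TMM) scaling factors, counts per
million (CPM), the minimum-expression filter, and per-gene negative
binomial dispersion (BCV^2) for individual-level count panels.

The TMM procedure follows the published defaults: the reference sample
is the one whose 75th-percentile count fraction is closest to the mean
across samples; per-sample factors are precision-weighted means of
gene-wise log2 ratios (M-values) after trimming the 30% most extreme
M-values on each tail and the 5% most extreme A-values on each tail;
factors are renormalized to geometric mean 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._nb import dispersion_grid, estimate_dispersion
from .datatypes import CountMatrix, ValidationError

__all__ = [
    "NormFactors",
    "DispersionEstimate",
    "tmm_factors",
    "cpm",
    "filter_low_expression",
    "estimate_bcv2",
]


@dataclass
class NormFactors:
    sample_ids: list[str]
    factors: np.ndarray  # geometric mean 1
    lib_size: np.ndarray

    def __post_init__(self) -> None:
        self.factors = np.asarray(self.factors, dtype=float)
        if np.any(~np.isfinite(self.factors)) or np.any(self.factors <= 0):
            raise ValidationError("normalization factors must be finite and positive")

    @property
    def effective_lib_size(self) -> np.ndarray:
        return self.lib_size * self.factors

    @classmethod
    def unit(cls, m: CountMatrix) -> "NormFactors":
        return cls(list(m.sample_ids), np.ones(m.n_samples), m.lib_size.copy())


@dataclass
class DispersionEstimate:
    """Per-gene NB dispersion phi; BCV^2 is phi itself."""

    gene_ids: list[str]
    dispersion: np.ndarray  # tagwise (shrunk) phi, NaN where undefined
    common_dispersion: float
    per_gene_mle: np.ndarray
    shrinkage_weight: float

    @property
    def bcv2(self) -> np.ndarray:
        return self.dispersion

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene_id": self.gene_ids,
                "bcv2": self.dispersion,
                "per_gene_mle": self.per_gene_mle,
                "common": self.common_dispersion,
            }
        )


def _tmm_pair(obs: np.ndarray, ref: np.ndarray, lib_obs: float, lib_ref: float,
              logratio_trim: float = 0.3, abs_trim: float = 0.05) -> float:
    """TMM factor of one sample against the reference (log2 scale)."""
    keep = (obs > 0) & (ref > 0)
    if not np.any(keep):
        raise ValidationError("sample shares no co-expressed genes with the reference")
    o = obs[keep] / lib_obs
    r = ref[keep] / lib_ref
    m = np.log2(o / r)
    a = 0.5 * np.log2(o * r)
    # asymptotic (delta-method) variance of M as precision weight
    w = (lib_obs - obs[keep]) / (lib_obs * obs[keep]) + (
        lib_ref - ref[keep]
    ) / (lib_ref * ref[keep])
    if np.max(np.abs(m)) < 1e-6:
        return 0.0
    n = m.size
    m_rank = pd.Series(m).rank().to_numpy()
    a_rank = pd.Series(a).rank().to_numpy()
    lo_m, hi_m = np.floor(n * logratio_trim) + 1, n + 1 - (np.floor(n * logratio_trim) + 1)
    lo_a, hi_a = np.floor(n * abs_trim) + 1, n + 1 - (np.floor(n * abs_trim) + 1)
    keep2 = (m_rank >= lo_m) & (m_rank <= hi_m) & (a_rank >= lo_a) & (a_rank <= hi_a)
    if not np.any(keep2):
        return 0.0
    return float(np.sum(m[keep2] / w[keep2]) / np.sum(1.0 / w[keep2]))


def tmm_factors(m: CountMatrix) -> NormFactors:
    """Trimmed-mean-of-M-values scaling factors for a count matrix."""
    if m.n_samples < 2:
        raise ValidationError("TMM needs >=2 samples")
    if np.any(m.lib_size <= 0):
        raise ValidationError("TMM needs nonzero library sizes")
    counts = m.counts.astype(float)
    frac75 = np.quantile(counts / m.lib_size[None, :], 0.75, axis=0)
    ref_idx = int(np.argmin(np.abs(frac75 - frac75.mean())))
    ref = counts[:, ref_idx]
    log_factors = np.array(
        [
            _tmm_pair(counts[:, j], ref, m.lib_size[j], m.lib_size[ref_idx])
            if j != ref_idx
            else 0.0
            for j in range(m.n_samples)
        ]
    )
    factors = 2.0 ** log_factors
    factors /= np.exp(np.mean(np.log(factors)))
    return NormFactors(list(m.sample_ids), factors, m.lib_size.copy())


def cpm(m: CountMatrix, f: NormFactors | None = None,
        prior_count: float = 0.0) -> pd.DataFrame:
    """Counts per million on effective library sizes.

    ``prior_count`` is scaled per sample by library size relative to the
    mean library size before being added, so a constant prior means the
    same prior *fraction* in every sample:
    CPM_ij = (y_ij + prior * L_j / mean(L)) / (L_j * f_j) * 1e6.
    """
    if prior_count < 0:
        raise ValidationError("prior_count must be >= 0")
    if f is None:
        f = NormFactors.unit(m)
    eff = f.effective_lib_size
    prior = prior_count * m.lib_size / np.mean(m.lib_size)
    vals = (m.counts + prior[None, :]) / eff[None, :] * 1e6
    return pd.DataFrame(vals, index=m.gene_ids, columns=m.sample_ids)


def filter_low_expression(cpm_table: pd.DataFrame, threshold: float = 0.1) -> list[str]:
    """Genes with CPM >= threshold in *every* sample (inclusive bound)."""
    if threshold <= 0:
        raise ValidationError("threshold must be positive")
    keep = (cpm_table.to_numpy() >= threshold).all(axis=1)
    retained = [g for g, k in zip(cpm_table.index, keep) if k]
    if not retained:
        warnings.warn("expression filter retained no genes", stacklevel=2)
    return retained


def estimate_bcv2(panel: CountMatrix, f: NormFactors | None = None,
                  prior_n: float = 10.0) -> DispersionEstimate:
    """Per-gene biological variance (BCV^2) from an individual-level panel.

    Fits a one-group NB model per gene with offsets = log effective
    library size, maximizing the Cox-Reid adjusted profile likelihood
    over dispersion, then shrinks each per-gene maximum toward the
    common dispersion with weight n/(n + prior_n).  All-zero genes are
    flagged with NaN.
    """
    if panel.n_samples < 5:
        raise ValidationError("BCV^2 estimation needs >=5 individuals")
    if f is None:
        f = tmm_factors(panel)
    offsets = np.log(f.effective_lib_size)
    groups = np.zeros(panel.n_samples, dtype=int)
    tagwise, common, mle = estimate_dispersion(
        panel.counts, offsets, groups, prior_n=prior_n, grid=dispersion_grid()
    )
    w = panel.n_samples / (panel.n_samples + prior_n)
    return DispersionEstimate(list(panel.gene_ids), tagwise, common, mle, w)
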