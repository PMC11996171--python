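"""Pleiotropy proxies: tissue specificity (tau) and network connectivity.

tau = sum_i (1 - x_i / x_max) / (N - 1) over N tissues: 1 for a gene
expressed in a single tissue, 0 for uniform expression.  Broadly
expressed genes are presumed to affect more traits, so 1 - tau is used
as the tissue-based pleiotropy score.  Connectivity is the sum of
adjacency weights incident to the gene in a regulatory network
(self-loops excluded).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .datatypes import NetworkEdges, TissueProfile, ValidationError

__all__ = [
    "tau",
    "tau_all",
    "connectivity",
    "connectivity_all",
    "pleiotropy_table",
    "pleiotropy_concordance",
]


def tau(profile: TissueProfile, gene: str) -> float:
    """Tissue-specificity index of one gene; NaN if the profile is all zero."""
    i = profile.gene_ids.index(gene)
    x = profile.expression[i]
    return _tau_row(x)


def _tau_row(x: np.ndarray) -> float:
    xmax = x.max()
    if xmax <= 0:
        return float("nan")
    n = x.size
    return float(np.sum(1.0 - x / xmax) / (n - 1))


def tau_all(profile: TissueProfile) -> pd.Series:
    xmax = profile.expression.max(axis=1)
    n = len(profile.tissue_ids)
    with np.errstate(invalid="ignore", divide="ignore"):
        vals = np.sum(1.0 - profile.expression / xmax[:, None], axis=1) / (n - 1)
    vals = np.where(xmax > 0, vals, np.nan)
    return pd.Series(vals, index=profile.gene_ids, name="tau")


def connectivity(net: NetworkEdges, gene: str) -> float:
    """Sum of incident edge weights; 0 for a gene absent from the network."""
    e = net.edges
    mask = (e["gene_a"] == gene) | (e["gene_b"] == gene)
    return float(e.loc[mask, "weight"].sum())


def connectivity_all(net: NetworkEdges, genes) -> pd.Series:
    e = net.edges
    acc: dict[str, float] = {g: 0.0 for g in genes}
    for a, b, w in zip(e["gene_a"], e["gene_b"], e["weight"]):
        if a in acc:
            acc[a] += w
        if b in acc:
            acc[b] += w
    return pd.Series(acc, name="connectivity")


def _standardize(v: np.ndarray) -> np.ndarray:
    ok = np.isfinite(v)
    sd = np.std(v[ok])
    if sd == 0:
        raise ValidationError("cannot standardize a constant column")
    out = np.full_like(v, np.nan, dtype=float)
    out[ok] = (v[ok] - np.mean(v[ok])) / sd
    return out


def pleiotropy_table(profile: TissueProfile | None = None,
                     net: NetworkEdges | None = None,
                     genes=None) -> pd.DataFrame:
    """Per-gene table of tau, 1-tau, connectivity and standardized copies.

    Genes missing from one source keep NaN in that column and are
    excluded pairwise by downstream analyses, never listwise.
    """
    if profile is None and net is None:
        raise ValidationError("need a tissue profile and/or a network")
    if genes is None:
        genes = profile.gene_ids if profile is not None else sorted(net.nodes)
    df = pd.DataFrame(index=pd.Index(genes, name="gene_id"))
    if profile is not None:
        t = tau_all(profile).reindex(genes)
        df["tau"] = t
        df["pleiotropy_tissue"] = 1.0 - t
        df["pleiotropy_tissue_std"] = _standardize(df["pleiotropy_tissue"].to_numpy())
    if net is not None:
        df["connectivity"] = connectivity_all(net, genes)
        df["connectivity_std"] = _standardize(df["connectivity"].to_numpy())
    return df


def pleiotropy_concordance(table: pd.DataFrame) -> tuple[float, float]:
    """Spearman correlation between 1-tau and connectivity (diagnostic).

    Average ranks for ties; pairwise-complete genes only.
    """
    sub = table[["pleiotropy_tissue", "connectivity"]].dropna()
    if len(sub) < 3:
        raise ValidationError("need >=3 genes scored on both proxies")
    for col in sub:
        if sub[col].nunique() == 1:
            warnings.warn(f"constant column {col}; rho undefined", stacklevel=2)
            return float("nan"), float("nan")
    rho, p = spearmanr(sub["pleiotropy_tissue"], sub["connectivity"])
    return float(rho), float(p)
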