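"""End-to-end orchestration: counts -> parallelism -> causal inference.

The canonical order of operations is the one the statistic definitions
assume: TMM factors from the full count matrix; the 0.1-CPM filter on
prior-free CPM; per-population DE with tagwise dispersion; the adaptive
gene set (same-direction significance in >= min_populations
populations); per-sample log2FC on prior-0.5 CPM and the 1/F statistic
over adaptive genes; BCV^2 from the individual-level ancestral panel;
and finally BIC model selection plus path analysis on
(Pa, A, Pl) = (ln 1/F, ln BCV^2, pleiotropy proxy).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import causal, de, normalize, parallelism, pleiotropy
from .datatypes import Config, CountMatrix, NetworkEdges, SampleDesign, TissueProfile

__all__ = ["run_pipeline"]


def run_pipeline(
    counts: CountMatrix,
    design: SampleDesign,
    panel: CountMatrix,
    tissues: TissueProfile | None = None,
    network: NetworkEdges | None = None,
    config: Config | None = None,
    pleiotropy_proxy: str = "tissue",
    n_boot: int = 1000,
) -> dict:
    """Run the full analysis; returns a dict of intermediate and final results."""
    cfg = config or Config()
    design.validate_against(counts)

    factors = normalize.tmm_factors(counts)
    cpm_raw = normalize.cpm(counts, factors, prior_count=0.0)
    retained = normalize.filter_low_expression(cpm_raw, cfg.cpm_min)
    expressed = counts.subset_genes(retained)

    calls = de.de_all_populations(
        expressed, design, f=factors, fdr_level=cfg.fdr_level,
    )
    rfs = parallelism.build_rfs(calls)
    adaptive = parallelism.select_adaptive(calls, cfg.min_populations)
    adaptive_genes = list(adaptive["gene_id"])

    cpm_prior = normalize.cpm(expressed, factors, prior_count=cfg.log2fc_prior_count)
    stats = parallelism.gene_evo_stats(cpm_prior, design, genes=adaptive_genes)

    disp = normalize.estimate_bcv2(panel, prior_n=cfg.dispersion_prior_n)
    bcv2 = pd.Series(disp.bcv2, index=disp.gene_ids, name="bcv2")

    pl_table = pleiotropy.pleiotropy_table(tissues, network)
    if pleiotropy_proxy == "tissue":
        pl = pl_table["pleiotropy_tissue"]
    elif pleiotropy_proxy == "connectivity":
        pl = pl_table["connectivity"]
    else:
        raise ValueError(f"unknown pleiotropy proxy {pleiotropy_proxy!r}")

    causal_data = causal.build_causal_data(
        stats.to_frame(), bcv2, pl, genes=adaptive_genes
    )
    selected, fits = causal.select_causal_model(causal_data)
    paths = causal.path_analysis(causal_data, n_boot=n_boot, seed=cfg.seed)

    return {
        "config": cfg,
        "norm_factors": factors,
        "retained_genes": retained,
        "de_calls": calls,
        "rfs": rfs,
        "adaptive": adaptive,
        "gene_stats": stats,
        "bcv2": bcv2,
        "pleiotropy": pl_table,
        "causal_data": causal_data,
        "causal_fits": fits,
        "selected_model": selected.model,
        "path_fit": paths,
    }
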