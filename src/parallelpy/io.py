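"""Readers and writers for the pipeline's TSV tables.

TSV is the canonical dialect (tab-separated, ``.`` decimal, one header
row); gzip is handled transparently by extension.  All writers prepend a
commented header recording the package version, seed and config hash so
every output is traceable to its run.
"""

from __future__ import annotations

import gzip
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import (
    Config,
    CountMatrix,
    NetworkEdges,
    SampleDesign,
    TissueProfile,
    ValidationError,
)

__all__ = [
    "read_count_matrix",
    "read_design",
    "read_tissue_profile",
    "read_network",
    "write_count_matrix",
    "write_tissue_profile",
    "write_network",
    "write_table",
]


def _read_tsv(path, **kw) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", **kw)


def read_design(design_path) -> SampleDesign:
    df = _read_tsv(design_path)
    return SampleDesign(df)


def read_count_matrix(path, design_path=None):
    """Read a gene x sample count TSV (first column = gene ids).

    Returns ``CountMatrix`` alone, or ``(CountMatrix, SampleDesign)``
    when ``design_path`` is given; the pair is cross-referenced so that
    every sample appears in both files.
    """
    df = _read_tsv(path, index_col=0)
    counts = df.to_numpy()
    if not np.issubdtype(counts.dtype, np.number):
        raise ValidationError(f"non-numeric counts in {path}")
    if np.any(counts != np.floor(counts)):
        raise ValidationError(f"non-integer counts in {path}")
    m = CountMatrix(
        [str(g) for g in df.index], [str(s) for s in df.columns], counts.astype(np.int64)
    )
    if design_path is None:
        return m
    design = read_design(design_path)
    design.validate_against(m)
    return m, design


def read_tissue_profile(path) -> TissueProfile:
    df = _read_tsv(path, index_col=0)
    if df.shape[1] < 2:
        raise ValidationError(
            f"{path}: tau needs >=2 tissue columns, found {df.shape[1]}"
        )
    return TissueProfile(
        [str(g) for g in df.index],
        [str(t) for t in df.columns],
        df.to_numpy(dtype=float),
    )


def read_network(path) -> NetworkEdges:
    df = _read_tsv(path)
    df.columns = ["gene_a", "gene_b", "weight"][: len(df.columns)]
    if df.shape[1] != 3:
        raise ValidationError(f"{path}: expected 3 columns (gene, gene, weight)")
    return NetworkEdges.from_records(
        list(zip(df["gene_a"].astype(str), df["gene_b"].astype(str),
                 df["weight"].astype(float)))
    )


def _open_text(path, mode="wt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def _header_lines(config: Config | None) -> str:
    from . import __version__

    if config is None:
        return f"# parallelpy v{__version__}\n"
    return (
        f"# parallelpy v{__version__} seed={config.seed} "
        f"config={config.hash()}\n"
    )


def write_table(df: pd.DataFrame, path, config: Config | None = None,
                index: bool = False) -> None:
    """Write any result DataFrame as TSV with a provenance header."""
    with _open_text(path) as fh:
        fh.write(_header_lines(config))
        df.to_csv(fh, sep="\t", index=index)


def write_count_matrix(m: CountMatrix, path, config: Config | None = None) -> None:
    df = m.to_frame()
    df.index.name = "gene_id"
    write_table(df, path, config, index=True)


def write_design(design: SampleDesign, path, config: Config | None = None) -> None:
    write_table(design.table, path, config)


def write_tissue_profile(p: TissueProfile, path, config: Config | None = None) -> None:
    df = p.to_frame()
    df.index.name = "gene_id"
    write_table(df, path, config, index=True)


def write_network(net: NetworkEdges, path, config: Config | None = None) -> None:
    write_table(net.edges, path, config)
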