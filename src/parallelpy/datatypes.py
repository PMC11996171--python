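"""Typed containers for every table the pipeline touches.

All containers are thin, validated wrappers around numpy arrays /
pandas objects.  Validation happens once, at construction; downstream
code may assume the invariants hold.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ValidationError",
    "CountMatrix",
    "SampleDesign",
    "TissueProfile",
    "NetworkEdges",
    "Config",
]


class ValidationError(ValueError):
    """Raised when an input table violates a structural invariant."""


def _check_unique(ids, what: str) -> None:
    ids = list(ids)
    if len(set(ids)) != len(ids):
        seen, dups = set(), []
        for i in ids:
            if i in seen:
                dups.append(i)
            seen.add(i)
        raise ValidationError(f"duplicate {what}: {sorted(set(dups))}")


@dataclass
class CountMatrix:
    """Gene x sample matrix of non-negative integer read counts.

    ``lib_size`` defaults to the per-sample column sum; it may be
    overridden explicitly (e.g. to carry the pre-filtering totals
    through a gene subset).
    """

    gene_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray  # shape (n_genes, n_samples)
    lib_size: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        _check_unique(self.gene_ids, "gene ids")
        _check_unique(self.sample_ids, "sample ids")
        if self.counts.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValidationError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if self.counts.size and np.any(self.counts < 0):
            g, s = np.argwhere(self.counts < 0)[0]
            raise ValidationError(
                f"negative count for gene {self.gene_ids[g]!r} "
                f"in sample {self.sample_ids[s]!r}"
            )
        if self.lib_size is None:
            self.lib_size = self.counts.sum(axis=0).astype(float)
        else:
            self.lib_size = np.asarray(self.lib_size, dtype=float)
            if self.lib_size.shape != (len(self.sample_ids),):
                raise ValidationError("lib_size length does not match samples")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.gene_ids, columns=self.sample_ids)

    def subset_genes(self, genes) -> "CountMatrix":
        """Row subset; library sizes of the full matrix are retained."""
        idx = [self.gene_ids.index(g) if isinstance(g, str) else g for g in genes]
        return CountMatrix(
            [self.gene_ids[i] for i in idx],
            list(self.sample_ids),
            self.counts[idx, :],
            lib_size=self.lib_size.copy(),
        )

    def subset_samples(self, samples) -> "CountMatrix":
        idx = [self.sample_ids.index(s) for s in samples]
        return CountMatrix(
            list(self.gene_ids),
            [self.sample_ids[i] for i in idx],
            self.counts[:, idx],
            lib_size=self.lib_size[idx],
        )


ROLE_ANCESTRAL = "ancestral"
ROLE_EVOLVED = "evolved"


@dataclass
class SampleDesign:
    """Maps each sample to its role, population and biological replicate.

    Ancestral samples share ``population_id`` 0; evolved populations are
    numbered 1..P so that grouping for the one-way parallelism ANOVA is
    unambiguous.
    """

    table: pd.DataFrame  # columns: sample_id, role, population_id, replicate_id

    def __post_init__(self) -> None:
        required = {"sample_id", "role", "population_id", "replicate_id"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValidationError(f"design table missing columns: {sorted(missing)}")
        _check_unique(self.table["sample_id"], "design sample ids")
        bad_roles = set(self.table["role"]) - {ROLE_ANCESTRAL, ROLE_EVOLVED}
        if bad_roles:
            raise ValidationError(f"unknown roles: {sorted(bad_roles)}")
        anc = self.table[self.table["role"] == ROLE_ANCESTRAL]
        if len(anc) < 1:
            raise ValidationError("design has no ancestral sample")
        if np.any(anc["population_id"].to_numpy() != 0):
            raise ValidationError("ancestral samples must have population_id 0")
        evo = self.table[self.table["role"] == ROLE_EVOLVED]
        if len(evo) and np.any(evo["population_id"].to_numpy() < 1):
            raise ValidationError("evolved populations must be numbered 1..P")

    @property
    def ancestral_samples(self) -> list[str]:
        t = self.table
        return list(t.loc[t["role"] == ROLE_ANCESTRAL, "sample_id"])

    @property
    def populations(self) -> list[int]:
        t = self.table
        return sorted(set(t.loc[t["role"] == ROLE_EVOLVED, "population_id"]))

    def population_samples(self, pop: int) -> list[str]:
        t = self.table
        sub = t[(t["role"] == ROLE_EVOLVED) & (t["population_id"] == pop)]
        return list(sub.sort_values("replicate_id")["sample_id"])

    def validate_against(self, m: CountMatrix) -> None:
        """Cross-reference: samples must agree one-to-one with the matrix."""
        design_ids = set(self.table["sample_id"])
        matrix_ids = set(m.sample_ids)
        only_design = design_ids - matrix_ids
        only_matrix = matrix_ids - design_ids
        if only_design:
            raise ValidationError(
                f"design references unknown samples: {sorted(only_design)}"
            )
        if only_matrix:
            raise ValidationError(
                f"samples missing from design: {sorted(only_matrix)}"
            )


@dataclass
class TissueProfile:
    """Gene x tissue expression table used for the tau specificity index."""

    gene_ids: list[str]
    tissue_ids: list[str]
    expression: np.ndarray  # (n_genes, n_tissues), non-negative

    def __post_init__(self) -> None:
        self.expression = np.asarray(self.expression, dtype=float)
        _check_unique(self.gene_ids, "gene ids")
        _check_unique(self.tissue_ids, "tissue ids")
        if len(self.tissue_ids) < 2:
            raise ValidationError(
                "tissue profile needs >=2 tissues (tau denominator is N-1)"
            )
        if self.expression.shape != (len(self.gene_ids), len(self.tissue_ids)):
            raise ValidationError("expression shape mismatch")
        if self.expression.size and np.any(self.expression < 0):
            raise ValidationError("negative tissue expression")

    @property
    def unscorable_genes(self) -> list[str]:
        """Genes whose profile is all zero: tau is undefined for them."""
        zero = self.expression.max(axis=1) == 0
        return [g for g, z in zip(self.gene_ids, zero) if z]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.expression, index=self.gene_ids, columns=self.tissue_ids
        )


@dataclass
class NetworkEdges:
    """Undirected weighted edge list; weights are regulatory adjacencies.

    Duplicate (a,b)/(b,a) rows are merged by summing their weights once;
    self-loops are dropped (with a count kept) because they never count
    toward connectivity.
    """

    edges: pd.DataFrame  # columns: gene_a, gene_b, weight
    n_self_loops_dropped: int = 0

    def __post_init__(self) -> None:
        required = {"gene_a", "gene_b", "weight"}
        if not required.issubset(self.edges.columns):
            raise ValidationError("edge table missing columns")
        if len(self.edges) and np.any(self.edges["weight"].to_numpy() < 0):
            raise ValidationError("negative edge weight")

    @classmethod
    def from_records(cls, records) -> "NetworkEdges":
        df = pd.DataFrame(records, columns=["gene_a", "gene_b", "weight"])
        if len(df) and np.any(df["weight"].to_numpy(dtype=float) < 0):
            raise ValidationError("negative edge weight")
        loops = df["gene_a"] == df["gene_b"]
        n_loops = int(loops.sum())
        df = df[~loops].copy()
        # canonical unordered key, then merge duplicates by summing
        a = df["gene_a"].astype(str).to_numpy()
        b = df["gene_b"].astype(str).to_numpy()
        swap = a > b
        df["gene_a"] = np.where(swap, b, a)
        df["gene_b"] = np.where(swap, a, b)
        df = (
            df.groupby(["gene_a", "gene_b"], as_index=False)["weight"]
            .sum()
            .astype({"weight": float})
        )
        return cls(df.reset_index(drop=True), n_self_loops_dropped=n_loops)

    @property
    def nodes(self) -> set[str]:
        return set(self.edges["gene_a"]) | set(self.edges["gene_b"])


@dataclass
class Config:
    """Pipeline thresholds and options; hashed into output headers."""

    cpm_min: float = 0.1
    fdr_level: float = 0.05
    min_populations: int = 3
    log2fc_prior_count: float = 0.5
    dispersion_prior_n: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cpm_min <= 0 or self.fdr_level <= 0 or self.min_populations <= 0:
            raise ValidationError("thresholds must be positive")

    def hash(self) -> str:
        payload = json.dumps(self.__dict__, sort_keys=True, default=str)
        return hashlib.sha1(payload.encode()).hexdigest()[:10]
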