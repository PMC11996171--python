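"""Causal structure among pleiotropy, ancestral variation and parallelism.

Three per-gene quantities — pleiotropy Pl, ancestral expression
variation A = ln(BCV^2) and parallelism Pa = ln(1/F) — are related by
one of five candidate causal graphs:

    I   Pl -> A -> Pa                 L = p(Pa|A) p(A|Pl) p(Pl)
    II  A <- Pl -> Pa                 L = p(Pa|Pl) p(A|Pl) p(Pl)
    III Pl -> A -> Pa and Pl -> Pa    L = p(Pa|A,Pl) p(A|Pl) p(Pl)
    IV  A -> Pa <- Pl, A indep Pl     L = p(Pa|A,Pl) p(A) p(Pl)
    V   all independent               L = p(Pa) p(A) p(Pl)

Each factor is Gaussian: marginals by mean/variance MLE, conditionals
by OLS with MLE residual variance (RSS/n), so every factor's maximized
log-likelihood is -(n/2) (ln(2 pi s^2) + 1).  Models are compared by
BIC = -2 ln L + k ln n with k counting every mean, slope, intercept and
variance: k = {I: 8, II: 8, III: 9, IV: 8, V: 6}.

Path analysis on standardized variables decomposes the pleiotropy
effect into direct (beta2, from Pa ~ A + Pl) and indirect via ancestral
variation (beta1 * beta3, with beta3 from A ~ Pl); on standardized
data cor(Pl, Pa) = beta2 + beta1*beta3 exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .datatypes import ValidationError

__all__ = [
    "MODELS",
    "MODEL_K",
    "build_causal_data",
    "fit_causal_model",
    "select_causal_model",
    "path_analysis",
    "CausalFit",
    "PathFit",
]

MODELS = ("I", "II", "III", "IV", "V")
MODEL_K = {"I": 8, "II": 8, "III": 9, "IV": 8, "V": 6}

# factorization of each model: (response, regressors) with None = marginal
_FACTORS = {
    "I": [("Pa", ("A",)), ("A", ("Pl",)), ("Pl", ())],
    "II": [("Pa", ("Pl",)), ("A", ("Pl",)), ("Pl", ())],
    "III": [("Pa", ("A", "Pl")), ("A", ("Pl",)), ("Pl", ())],
    "IV": [("Pa", ("A", "Pl")), ("A", ()), ("Pl", ())],
    "V": [("Pa", ()), ("A", ()), ("Pl", ())],
}


@dataclass
class CausalFit:
    model: str
    loglik: float
    k: int
    bic: float
    coefficients: dict = field(default_factory=dict)
    residual_variances: dict = field(default_factory=dict)


@dataclass
class PathFit:
    beta1: float  # Pa on A
    beta2: float  # Pa on Pl (direct effect)
    beta3: float  # A on Pl
    se: dict
    direct: float
    indirect: float  # beta1 * beta3
    indirect_ci: tuple[float, float]
    n_boot: int


def build_causal_data(
    stats_table: pd.DataFrame,
    bcv2: pd.Series,
    pleiotropy: pd.Series,
    genes=None,
    min_genes: int = 30,
) -> pd.DataFrame:
    """Assemble the per-gene (Pa, A, Pl) table over the adaptive gene set.

    ``stats_table`` must carry ``ln_parallelism`` indexed by gene (as
    produced by :func:`parallelpy.parallelism.gene_evo_stats`);
    ``bcv2`` and ``pleiotropy`` are gene-indexed Series.  Pa and A are
    natural-log transformed upstream/here; genes with any non-finite
    value are dropped with a logged count.  Standardized copies
    (suffix ``_std``) are added for the path analysis.
    """
    if "gene_id" in stats_table.columns:
        stats_table = stats_table.set_index("gene_id")
    if genes is None:
        genes = list(stats_table.index)
    genes = [g for g in genes if g in stats_table.index]
    pa = stats_table["ln_parallelism"].reindex(genes)
    with np.errstate(divide="ignore", invalid="ignore"):
        a = np.log(bcv2.reindex(genes).astype(float))
    pl = pleiotropy.reindex(genes).astype(float)
    df = pd.DataFrame({"Pa": pa, "A": a, "Pl": pl})
    n0 = len(df)
    df = df.replace([np.inf, -np.inf], np.nan).dropna()
    dropped = n0 - len(df)
    if dropped:
        warnings.warn(
            f"dropped {dropped} gene(s) with non-finite Pa/A/Pl", stacklevel=2
        )
    if len(df) < min_genes:
        raise ValidationError(
            f"only {len(df)} usable genes (<{min_genes}); model fitting unreliable"
        )
    for col in ("Pa", "A", "Pl"):
        sd = df[col].std(ddof=0)
        if sd == 0:
            raise ValidationError(f"constant column {col}; cannot standardize")
        df[col + "_std"] = (df[col] - df[col].mean()) / sd
    return df


def _gauss_factor_loglik(y: np.ndarray, x_cols: tuple, data: pd.DataFrame):
    """Maximized Gaussian log-likelihood of one factor, with coefficients.

    Marginal: mean + variance (MLE, /n).  Conditional: OLS intercept +
    slopes, residual variance RSS/n.  Either way the profile
    log-likelihood is -(n/2)(ln(2 pi s2) + 1).
    """
    n = len(y)
    if not x_cols:
        s2 = float(np.var(y))
        coefs = {"mean": float(np.mean(y))}
    else:
        design = np.column_stack([np.ones(n)] + [data[c].to_numpy() for c in x_cols])
        if np.linalg.matrix_rank(design) < design.shape[1]:
            raise ValidationError(f"singular design for regressors {x_cols}")
        beta, *_ = np.linalg.lstsq(design, y, rcond=None)
        resid = y - design @ beta
        s2 = float(np.mean(resid**2))
        coefs = {"intercept": float(beta[0])}
        coefs.update({c: float(b) for c, b in zip(x_cols, beta[1:])})
    if s2 <= 0:
        raise ValidationError("zero residual variance in a Gaussian factor")
    ll = -(n / 2.0) * (np.log(2.0 * np.pi * s2) + 1.0)
    return ll, coefs, s2


def fit_causal_model(model: str, data: pd.DataFrame,
                     standardized: bool = False) -> CausalFit:
    """Fit one causal graph by Gaussian ML and return its BIC entry."""
    if model not in MODELS:
        raise ValidationError(f"unknown model {model!r}")
    suffix = "_std" if standardized else ""
    n = len(data)
    loglik = 0.0
    coefs: dict = {}
    rvars: dict = {}
    for resp, xs in _FACTORS[model]:
        y = data[resp + suffix].to_numpy(dtype=float)
        cols = tuple(c + suffix for c in xs)
        ll, c, s2 = _gauss_factor_loglik(y, cols, data)
        loglik += ll
        key = f"{resp}|{','.join(xs)}" if xs else resp
        coefs[key] = c
        rvars[key] = s2
    k = MODEL_K[model]
    bic = -2.0 * loglik + k * np.log(n)
    return CausalFit(model, float(loglik), k, float(bic), coefs, rvars)


def select_causal_model(data: pd.DataFrame, standardized: bool = False,
                        tie_tol: float = 1e-9):
    """Fit all five models and pick the smallest BIC.

    Ties within ``tie_tol`` resolve toward the model with fewer
    parameters (and are logged).  Returns ``(selected, fits)`` with
    fits keyed by model id.
    """
    fits = {m: fit_causal_model(m, data, standardized=standardized) for m in MODELS}
    best_bic = min(f.bic for f in fits.values())
    tied = [m for m in MODELS if fits[m].bic <= best_bic + tie_tol]
    if len(tied) > 1:
        warnings.warn(f"BIC tie among models {tied}; choosing smallest k",
                      stacklevel=2)
    selected = min(tied, key=lambda m: (fits[m].k, MODELS.index(m)))
    return fits[selected], fits


def path_analysis(data: pd.DataFrame, n_boot: int = 1000,
                  seed: int | None = 0) -> PathFit:
    """Direct/indirect decomposition of the pleiotropy effect.

    Two OLS fits on the standardized columns: Pa ~ A + Pl gives beta1,
    beta2; A ~ Pl gives beta3.  Direct effect = beta2, indirect =
    beta1*beta3 with a seeded nonparametric bootstrap percentile CI.
    """
    if n_boot < 100:
        warnings.warn("n_boot < 100: indirect-effect CI will be unstable",
                      stacklevel=2)
    pa = data["Pa_std"].to_numpy(dtype=float)
    a = data["A_std"].to_numpy(dtype=float)
    pl = data["Pl_std"].to_numpy(dtype=float)
    n = len(pa)

    m1 = sm.OLS(pa, sm.add_constant(np.column_stack([a, pl]))).fit()
    m2 = sm.OLS(a, sm.add_constant(pl)).fit()
    beta1, beta2 = float(m1.params[1]), float(m1.params[2])
    beta3 = float(m2.params[1])
    se = {
        "beta1": float(m1.bse[1]),
        "beta2": float(m1.bse[2]),
        "beta3": float(m2.bse[1]),
    }

    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, n, n)
        xa, xpl, ypa = a[idx], pl[idx], pa[idx]
        d1 = np.column_stack([np.ones(n), xa, xpl])
        c1, *_ = np.linalg.lstsq(d1, ypa, rcond=None)
        d2 = np.column_stack([np.ones(n), xpl])
        c2, *_ = np.linalg.lstsq(d2, xa, rcond=None)
        boots[b] = c1[1] * c2[1]
    ci = (float(np.percentile(boots, 2.5)), float(np.percentile(boots, 97.5)))
    return PathFit(beta1, beta2, beta3, se, beta2, beta1 * beta3, ci, n_boot)
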