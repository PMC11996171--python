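"""Vectorized negative-binomial GLM primitives.

Everything here operates on a whole gene x sample count matrix at once:
group means are fitted by Newton iterations on arrays of per-gene
intercepts, and dispersion is profiled on a log-spaced grid with a
Cox-Reid adjustment.  This keeps a 2000-gene x 35-sample dataset in the
tens of milliseconds per fit instead of looping scalar GLMs.

Parametrization: Var(Y) = mu + phi * mu^2, i.e. ``phi`` is the squared
biological coefficient of variation (BCV^2).  ``phi = 0`` is the
Poisson limit and is handled explicitly.
"""

from __future__ import annotations

import numpy as np
from scipy.special import gammaln

_POISSON_EPS = 1e-8
_MIN_MU = 1e-10


def nb_loglik(y: np.ndarray, mu: np.ndarray, phi: np.ndarray | float) -> np.ndarray:
    """Elementwise NB log-likelihood; Poisson limit for tiny phi."""
    y = np.asarray(y, dtype=float)
    mu = np.maximum(mu, _MIN_MU)
    phi = np.asarray(phi, dtype=float)
    out = np.empty(np.broadcast(y, mu, phi).shape, dtype=float)
    pois = np.broadcast_to(phi <= _POISSON_EPS, out.shape)
    yb, mub, phib = np.broadcast_arrays(y, mu, phi)
    if np.any(pois):
        out[pois] = (
            yb[pois] * np.log(mub[pois]) - mub[pois] - gammaln(yb[pois] + 1.0)
        )
    nb = ~pois
    if np.any(nb):
        r = 1.0 / phib[nb]
        m = mub[nb]
        yy = yb[nb]
        out[nb] = (
            gammaln(yy + r)
            - gammaln(r)
            - gammaln(yy + 1.0)
            + r * np.log(r / (r + m))
            + yy * np.log(m / (r + m))
        )
    return out


def fit_group_means(
    counts: np.ndarray,
    offsets: np.ndarray,
    groups: np.ndarray,
    phi: np.ndarray | float,
    n_iter: int = 30,
    tol: float = 1e-10,
) -> np.ndarray:
    """Fit per-gene, per-group log-means of a NB GLM with log link.

    Model: mu_gj = exp(beta_{g, group(j)} + offsets_j).  Returns the
    beta array of shape (n_genes, n_groups).  Genes with an all-zero
    group get beta = -inf (mu -> 0).
    """
    counts = np.asarray(counts, dtype=float)
    offsets = np.asarray(offsets, dtype=float)
    groups = np.asarray(groups)
    group_ids = np.unique(groups)
    n_genes = counts.shape[0]
    phi_col = np.broadcast_to(np.asarray(phi, dtype=float), (n_genes,))[:, None]

    betas = np.full((n_genes, len(group_ids)), -np.inf)
    for gi, g in enumerate(group_ids):
        cols = groups == g
        y = counts[:, cols]
        o = offsets[cols]
        tot = y.sum(axis=1)
        nonzero = tot > 0
        if not np.any(nonzero):
            continue
        # moment start: beta = log(sum y / sum exp(o))
        beta = np.log(tot[nonzero] / np.exp(o).sum())
        yv = y[nonzero]
        ph = phi_col[nonzero]
        for _ in range(n_iter):
            mu = np.exp(beta[:, None] + o[None, :])
            denom = 1.0 + ph * mu
            score = ((yv - mu) / denom).sum(axis=1)
            info = (mu / denom).sum(axis=1)
            step = score / np.maximum(info, 1e-12)
            step = np.clip(step, -5.0, 5.0)
            beta = beta + step
            if np.max(np.abs(step)) < tol:
                break
        full = np.full(n_genes, -np.inf)
        full[nonzero] = beta
        betas[:, gi] = full
    return betas


def group_mu(betas: np.ndarray, offsets: np.ndarray, groups: np.ndarray) -> np.ndarray:
    """Expand fitted group betas into the full (n_genes, n_samples) mu."""
    groups = np.asarray(groups)
    group_ids = np.unique(groups)
    col_of = {g: i for i, g in enumerate(group_ids)}
    beta_per_sample = betas[:, [col_of[g] for g in groups]]
    return np.exp(beta_per_sample + offsets[None, :])


def profile_loglik(
    counts: np.ndarray,
    offsets: np.ndarray,
    groups: np.ndarray,
    phi: np.ndarray | float,
    adjusted: bool = True,
) -> np.ndarray:
    """Per-gene profile log-likelihood at dispersion phi.

    With ``adjusted=True`` the Cox-Reid term -0.5*log|I(beta)| is
    subtracted (one information term per fitted group mean), which
    removes most of the downward bias of the dispersion MLE caused by
    estimating the means.
    """
    counts = np.asarray(counts, dtype=float)
    groups = np.asarray(groups)
    n_genes = counts.shape[0]
    phi_col = np.broadcast_to(np.asarray(phi, dtype=float), (n_genes,))[:, None]
    betas = fit_group_means(counts, offsets, groups, phi)
    mu = group_mu(betas, offsets, groups)
    ll = nb_loglik(counts, mu, phi_col).sum(axis=1)
    if adjusted:
        w = mu / (1.0 + phi_col * mu)
        for g in np.unique(groups):
            cols = groups == g
            info = w[:, cols].sum(axis=1)
            ok = info > 0
            ll[ok] -= 0.5 * np.log(info[ok])
    return ll


def _quadratic_peak(x: np.ndarray, y0: float, y1: float, y2: float, i: int) -> float:
    """Vertex of the parabola through three grid points around index i."""
    denom = y0 - 2.0 * y1 + y2
    if denom >= 0 or not np.isfinite(denom):
        return x[i]
    delta = 0.5 * (y0 - y2) / denom
    delta = float(np.clip(delta, -1.0, 1.0))
    # grid is uniform in log space
    step = x[1] - x[0]
    return x[i] + delta * step


def dispersion_grid(lo: float = 1e-4, hi: float = 10.0, n: int = 61) -> np.ndarray:
    return np.logspace(np.log10(lo), np.log10(hi), n)


def estimate_dispersion(
    counts: np.ndarray,
    offsets: np.ndarray,
    groups: np.ndarray,
    prior_n: float = 10.0,
    grid: np.ndarray | None = None,
):
    """Cox-Reid dispersion estimation with shrinkage toward the common value.

    Returns ``(tagwise, common, per_gene_mle)``.  The common dispersion
    maximizes the summed adjusted profile likelihood; per-gene maxima
    are then shrunk by a simple weighted average with weight
    ``n / (n + prior_n)`` on the per-gene estimate, where n is the
    number of samples.  All-zero genes get NaN.
    """
    counts = np.asarray(counts, dtype=float)
    if grid is None:
        grid = dispersion_grid()
    log_grid = np.log(grid)
    n_genes, n_samples = counts.shape
    apl = np.empty((n_genes, len(grid)))
    for k, phi in enumerate(grid):
        apl[:, k] = profile_loglik(counts, offsets, groups, phi)

    expressed = counts.sum(axis=1) > 0
    # common: maximize the summed APL over expressed genes
    total = apl[expressed].sum(axis=0)
    i = int(np.argmax(total))
    if 0 < i < len(grid) - 1:
        common = float(
            np.exp(_quadratic_peak(log_grid, total[i - 1], total[i], total[i + 1], i))
        )
    else:
        common = float(grid[i])

    # per-gene maxima with quadratic refinement in log space
    idx = np.argmax(apl, axis=1)
    mle = grid[idx].astype(float)
    interior = (idx > 0) & (idx < len(grid) - 1)
    for g in np.where(interior & expressed)[0]:
        i = idx[g]
        mle[g] = np.exp(
            _quadratic_peak(log_grid, apl[g, i - 1], apl[g, i], apl[g, i + 1], i)
        )
    w = n_samples / (n_samples + prior_n)
    tagwise = w * mle + (1.0 - w) * common
    tagwise[~expressed] = np.nan
    mle[~expressed] = np.nan
    return tagwise, common, mle
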