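"""Per-subject FC matrices, ComBat site harmonization, network aggregation."""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from ._types import NETWORKS

__all__ = [
    "compute_fc",
    "combat_harmonize",
    "network_average",
    "vectorize_upper",
    "unvectorize_upper",
]

_R_CLIP = 1.0 - 1e-7


def compute_fc(timeseries: np.ndarray) -> np.ndarray:
    """Fisher-z transformed Pearson correlation matrix of a T x R time series.

    Correlations are clipped to +/-(1 - 1e-7) before atanh so every entry is
    finite; the diagonal is zeroed. Constant columns produce zero edges with
    a warning.
    """
    ts = np.asarray(timeseries, dtype=float)
    if ts.ndim != 2:
        raise ValueError("timeseries must be 2-D (T x R)")
    T = ts.shape[0]
    if T < 3:
        raise ValueError(f"need at least 3 timepoints, got {T}")
    sd = ts.std(axis=0)
    const = sd == 0
    if const.any():
        warnings.warn(
            f"{const.sum()} constant column(s); their edges are set to 0",
            stacklevel=2,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(ts, rowvar=False)
    if const.any():
        r[const, :] = 0.0
        r[:, const] = 0.0
    r = np.nan_to_num(r, nan=0.0)
    r = np.clip(r, -_R_CLIP, _R_CLIP)
    z = np.arctanh(r)
    np.fill_diagonal(z, 0.0)
    return z


def vectorize_upper(stack: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """n x R x R stack -> (n x E matrix of upper-triangle edges, iu, ju)."""
    stack = np.asarray(stack)
    R = stack.shape[-1]
    iu, ju = np.triu_indices(R, k=1)
    return stack[..., iu, ju], iu, ju


def unvectorize_upper(edges: np.ndarray, R: int) -> np.ndarray:
    """n x E edge matrix -> symmetric n x R x R stack with zero diagonal."""
    iu, ju = np.triu_indices(R, k=1)
    out = np.zeros(edges.shape[:-1] + (R, R))
    out[..., iu, ju] = edges
    out[..., ju, iu] = edges
    return out


def _combat_design(site_labels: pd.Series, covariates: pd.DataFrame | None):
    sites = pd.Categorical(site_labels)
    batch = pd.get_dummies(sites, dtype=float).to_numpy()
    if covariates is not None and covariates.shape[1] > 0:
        cov = covariates.to_numpy(dtype=float)
        design = np.column_stack([batch, cov])
        # Name collinear columns up front; a rank-deficient design breaks
        # the standardization step silently otherwise.
        if np.linalg.matrix_rank(design) < design.shape[1]:
            for j, name in enumerate(covariates.columns):
                sub = np.column_stack([batch, np.delete(cov, j, axis=1)])
                if np.linalg.matrix_rank(sub) == np.linalg.matrix_rank(design):
                    raise ValueError(f"covariate {name!r} is collinear with the design")
            raise ValueError("design matrix is rank deficient")
    else:
        design = batch
    return batch, design, list(sites.categories)


def _aprior(delta_hat: np.ndarray) -> tuple[float, float]:
    m, s2 = delta_hat.mean(), delta_hat.var()
    return (2 * s2 + m**2) / s2, (m * s2 + m**3) / s2


def _postmean(g_hat, g_bar, n, d_star, t2):
    return (t2 * n * g_hat + d_star * g_bar) / (t2 * n + d_star)


def _postvar(sum2, n, a, b):
    return (0.5 * sum2 + b) / (n / 2.0 + a - 1.0)


def _it_sol(sdat, g_hat, d_hat, g_bar, t2, a, b, conv=1e-4):
    n = (1 - np.isnan(sdat)).sum(axis=1)
    g_old, d_old = g_hat.copy(), d_hat.copy()
    change = 1.0
    while change > conv:
        g_new = _postmean(g_hat, g_bar, n, d_old, t2)
        sum2 = ((sdat - g_new[:, None]) ** 2).sum(axis=1)
        d_new = _postvar(sum2, n, a, b)
        change = max(
            np.abs(g_new - g_old).max() / np.abs(g_old).max() if np.abs(g_old).max() > 0 else 0,
            np.abs(d_new - d_old).max() / np.abs(d_old).max(),
        )
        g_old, d_old = g_new, d_new
    return g_old, d_old


def combat_harmonize(
    fc_stack: np.ndarray,
    site_labels,
    protected_covariates: pd.DataFrame | None = None,
) -> np.ndarray:
    """Empirical-Bayes location/scale harmonization of FC edges across sites.

    ``fc_stack`` is n_subjects x R x R; edges are harmonized on the upper
    triangle and mirrored back. Protected covariates (e.g. clinical scores,
    age, sex) enter the design matrix so their effects are restored after
    site location/scale removal. With a single site the input is returned
    unchanged.
    """
    fc_stack = np.asarray(fc_stack, dtype=float)
    site_labels = pd.Series(list(site_labels))
    n = fc_stack.shape[0]
    if len(site_labels) != n:
        raise ValueError("site_labels length must match number of subjects")
    counts = site_labels.value_counts()
    if (counts < 2).any():
        bad = counts[counts < 2].index.tolist()
        raise ValueError(f"site(s) with fewer than 2 subjects: {bad}")
    if counts.size == 1:
        return fc_stack.copy()

    edges, iu, ju = vectorize_upper(fc_stack)
    Y = edges.T  # features (edges) x subjects
    batch, design, site_names = _combat_design(site_labels, protected_covariates)
    n_sites = batch.shape[1]
    n_per_site = batch.sum(axis=0)

    beta, *_ = np.linalg.lstsq(design, Y.T, rcond=None)
    grand_mean = (n_per_site / n) @ beta[:n_sites]
    resid = Y.T - design @ beta
    var_pooled = (resid**2).mean(axis=0)
    var_pooled = np.where(var_pooled <= 0, 1e-12, var_pooled)

    stand_mean = np.outer(np.ones(n), grand_mean)
    if design.shape[1] > n_sites:
        stand_mean = stand_mean + design[:, n_sites:] @ beta[n_sites:]
    Z = (Y.T - stand_mean) / np.sqrt(var_pooled)  # subjects x edges

    gamma_star = np.empty((n_sites, Y.shape[0]))
    delta_star = np.empty((n_sites, Y.shape[0]))
    for i in range(n_sites):
        mask = batch[:, i] == 1
        zi = Z[mask].T  # edges x subjects-in-site
        g_hat = zi.mean(axis=1)
        d_hat = zi.var(axis=1, ddof=1)
        d_hat = np.where(d_hat <= 0, 1e-12, d_hat)
        g_bar, t2 = g_hat.mean(), g_hat.var()
        a, b = _aprior(d_hat)
        g_star, d_star = _it_sol(zi, g_hat, d_hat, g_bar, t2, a, b)
        gamma_star[i] = g_star
        delta_star[i] = np.where(d_star <= 0, 1e-12, d_star)

    adj = Z.copy()
    for i in range(n_sites):
        mask = batch[:, i] == 1
        adj[mask] = (Z[mask] - gamma_star[i]) / np.sqrt(delta_star[i])
    out_edges = adj * np.sqrt(var_pooled) + stand_mean  # subjects x edges
    return unvectorize_upper(out_edges, fc_stack.shape[-1])


def network_average(fc: np.ndarray, atlas: pd.DataFrame) -> pd.DataFrame:
    """Average an R x R FC matrix into the fixed-order 7 x 7 network matrix.

    Cell (a, b) is the mean z over all region pairs (i in a, j in b, i != j);
    a within-network cell with fewer than 2 regions is NaN (flagged), the
    between-network cells are still computed.
    """
    fc = np.asarray(fc, dtype=float)
    if fc.shape[0] != len(atlas):
        raise ValueError("atlas does not cover the FC matrix rows")
    nets = atlas["network"].to_numpy()
    out = np.full((len(NETWORKS), len(NETWORKS)), np.nan)
    for ai, a in enumerate(NETWORKS):
        ia = np.where(nets == a)[0]
        for bi in range(ai, len(NETWORKS)):
            b = NETWORKS[bi]
            ib = np.where(nets == b)[0]
            if ai == bi:
                if len(ia) < 2:
                    continue
                sub = fc[np.ix_(ia, ia)]
                iu = np.triu_indices(len(ia), k=1)
                val = sub[iu].mean()
            else:
                if len(ia) == 0 or len(ib) == 0:
                    continue
                val = fc[np.ix_(ia, ib)].mean()
            out[ai, bi] = out[bi, ai] = val
    return pd.DataFrame(out, index=list(NETWORKS), columns=list(NETWORKS))
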