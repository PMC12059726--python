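"""Inclusion filtering, group contrasts, NBS correction, net t-values,
and the propensity-matched paired validation.

All edge-wise statistics are computed with a vectorized OLS over the upper
triangle; permutation nulls use the Freedman-Lane scheme (permute residuals
of the reduced, covariate-only model) so covariates are respected. With no
covariates this reduces to plain label permutation.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from ._types import EdgeStatMap, NBSComponent, NBSResult, NETWORKS, SubjectRecord
from .connectome import unvectorize_upper, vectorize_upper

__all__ = [
    "apply_inclusion_criteria",
    "assign_groups",
    "edge_glm_ttest",
    "nbs_correct",
    "network_ttest",
    "net_t_value",
    "propensity_match",
    "paired_edge_ttest",
]


def _is_missing(v) -> bool:
    return v is None or (isinstance(v, float) and np.isnan(v))


def apply_inclusion_criteria(
    subjects: list[SubjectRecord],
    fd_max: float = 0.2,
    hamd_min_exclusive: int = 7,
    quality_min: int = 4,
) -> tuple[list[SubjectRecord], list[tuple[SubjectRecord, list[str]]]]:
    """Split subjects into included and excluded-with-reasons.

    Exclusion rules: FD strictly above ``fd_max``; HAMD at or below
    ``hamd_min_exclusive`` (remission); quality score below ``quality_min``;
    missing HAMD or HAMA. All applicable reasons are recorded.
    """
    included, excluded = [], []
    for s in subjects:
        reasons = []
        if _is_missing(s.hamd) or _is_missing(s.hama):
            reasons.append("missing HAMD or HAMA")
        if s.fd > fd_max:
            reasons.append(f"head motion (FD {s.fd:.3f} > {fd_max})")
        if not _is_missing(s.hamd) and s.hamd <= hamd_min_exclusive:
            reasons.append(f"remission (HAMD {s.hamd} <= {hamd_min_exclusive})")
        if s.quality_score < quality_min:
            reasons.append(f"quality score {s.quality_score} < {quality_min}")
        if reasons:
            excluded.append((s, reasons))
        else:
            included.append(s)
    return included, excluded


def assign_groups(subjects: list[SubjectRecord], hama_cut: int = 18) -> np.ndarray:
    """Label subjects 'ANX+' (HAMA > cut) or 'ANX-' (HAMA <= cut)."""
    labels = []
    for s in subjects:
        if _is_missing(s.hama):
            raise ValueError(
                f"subject {s.subject_id} has no HAMA score; it should have been "
                "excluded upstream"
            )
        labels.append("ANX+" if s.hama > hama_cut else "ANX-")
    return np.array(labels)


def _design_matrix(group: np.ndarray, covariates: pd.DataFrame | None) -> tuple[np.ndarray, list[str]]:
    g = np.asarray(group)
    if g.dtype.kind in "UOS":
        uniq = np.unique(g)
        if len(uniq) != 2:
            raise ValueError(f"need exactly 2 groups, got {list(uniq)}")
        g = (g == uniq[1]).astype(float)
    else:
        g = g.astype(float)
    if len(np.unique(g)) < 2:
        raise ValueError("group indicator is constant")
    cols = [np.ones_like(g), g]
    names = ["intercept", "group"]
    if covariates is not None and covariates.shape[1] > 0:
        for name in covariates.columns:
            cols.append(covariates[name].to_numpy(dtype=float))
            names.append(str(name))
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        # identify the offending column for the error message
        for j in range(2, X.shape[1]):
            if np.linalg.matrix_rank(np.delete(X, j, axis=1)) == np.linalg.matrix_rank(X):
                raise ValueError(f"design is rank deficient: column {names[j]!r} is collinear")
        raise ValueError("design is rank deficient")
    return X, names


def _glm_group_t(Y: np.ndarray, X: np.ndarray, coef_idx: int = 1) -> tuple[np.ndarray, int]:
    """t statistic for one coefficient, vectorized over columns of Y (n x E)."""
    n, p = X.shape
    if n <= p:
        raise ValueError(f"need n > number of design columns ({p}), got n={n}")
    XtX_inv = np.linalg.inv(X.T @ X)
    H = XtX_inv @ X.T
    beta = H @ Y                       # p x E
    resid = Y - X @ beta
    df = n - p
    sigma2 = (resid**2).sum(axis=0) / df
    se = np.sqrt(np.maximum(sigma2 * XtX_inv[coef_idx, coef_idx], 1e-300))
    t = beta[coef_idx] / se
    # degenerate edges: zero residual variance and zero effect -> t = 0
    t[(sigma2 <= 1e-30) & (np.abs(beta[coef_idx]) < 1e-12)] = 0.0
    return t, df


def edge_glm_ttest(
    fc_stack: np.ndarray,
    group: np.ndarray,
    covariates: pd.DataFrame | None = None,
) -> EdgeStatMap:
    """Per-edge OLS of FC on [intercept, group, covariates]; group t and p.

    With no covariates the t equals the classical pooled-variance two-sample
    t statistic.
    """
    edges, iu, ju = vectorize_upper(np.asarray(fc_stack, dtype=float))
    X, _ = _design_matrix(group, covariates)
    t, df = _glm_group_t(edges, X)
    p = 2.0 * stats.t.sf(np.abs(t), df)
    R = fc_stack.shape[-1]
    t_mat = unvectorize_upper(t, R)
    p_mat = unvectorize_upper(p, R)
    p_mat[np.eye(R, dtype=bool)] = 1.0
    return EdgeStatMap(t=t_mat, p=p_mat, df=df, contrast="group2 - group1")


def _components_from_edges(t_abs: np.ndarray, thresh: float, R: int, iu, ju):
    """Connected components of the suprathreshold graph; sizes in edge counts."""
    supra = t_abs > thresh
    if not supra.any():
        return [], supra
    rows, cols = iu[supra], ju[supra]
    adj = csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(R, R))
    adj = adj + adj.T
    n_comp, labels = connected_components(adj, directed=False)
    comps = []
    for c in range(n_comp):
        nodes = np.where(labels == c)[0]
        if len(nodes) < 2:
            continue
        in_comp = np.isin(rows, nodes)
        edges = list(zip(rows[in_comp].tolist(), cols[in_comp].tolist()))
        if edges:
            comps.append(edges)
    return comps, supra


def _freedman_lane_null(
    Y: np.ndarray,
    X_full: np.ndarray,
    reduced_cols: list[int],
    n_perm: int,
    rng: np.random.Generator,
    stat_fn,
) -> np.ndarray:
    """Permutation null via Freedman-Lane: permute reduced-model residuals."""
    Xr = X_full[:, reduced_cols]
    beta_r, *_ = np.linalg.lstsq(Xr, Y, rcond=None)
    fitted = Xr @ beta_r
    resid = Y - fitted
    n = Y.shape[0]
    null = np.empty(n_perm)
    for b in range(n_perm):
        perm = rng.permutation(n)
        Y_star = fitted + resid[perm]
        t_star, _ = _glm_group_t(Y_star, X_full)
        null[b] = stat_fn(t_star)
    return null


def nbs_correct(
    fc_stack: np.ndarray,
    group: np.ndarray,
    covariates: pd.DataFrame | None = None,
    edge_p: float = 0.001,
    alpha: float = 0.05,
    n_perm: int = 1000,
    seed: int | None = None,
) -> NBSResult:
    """Network-based statistics correction of the edge-wise group contrast.

    Edges with two-tailed |t| above the ``edge_p`` critical value form a
    graph; the component statistic is the edge count. The null distribution
    of the maximum component size comes from Freedman-Lane permutations;
    component p-values use the (1 + exceedances) / (1 + n_perm) estimator.
    """
    if n_perm < 100:
        warnings.warn(f"n_perm={n_perm} is low; p-value resolution will be poor", stacklevel=2)
    rng = np.random.default_rng(seed)
    edges, iu, ju = vectorize_upper(np.asarray(fc_stack, dtype=float))
    X, _ = _design_matrix(group, covariates)
    t_obs, df = _glm_group_t(edges, X)
    t_crit = stats.t.isf(edge_p / 2.0, df)
    R = fc_stack.shape[-1]

    comps, _ = _components_from_edges(np.abs(t_obs), t_crit, R, iu, ju)

    def max_comp_size(t_star: np.ndarray) -> float:
        c, _ = _components_from_edges(np.abs(t_star), t_crit, R, iu, ju)
        return max((len(e) for e in c), default=0)

    null = _freedman_lane_null(edges, X, [0] + list(range(2, X.shape[1])), n_perm, rng, max_comp_size)

    components = []
    for edge_list in sorted(comps, key=len, reverse=True):
        size = len(edge_list)
        p_comp = (1.0 + np.sum(null >= size)) / (1.0 + n_perm)
        components.append(NBSComponent(edges=edge_list, size=size, p_value=p_comp))
    return NBSResult(
        components=components,
        null_max_size=null,
        edge_p=edge_p,
        alpha=alpha,
        n_perm=n_perm,
        t_threshold=t_crit,
    )


def network_ttest(
    network_matrices: np.ndarray,
    group: np.ndarray,
    covariates: pd.DataFrame | None = None,
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Group contrast on the 28 unique network cells with max-|t| correction.

    Returns (t, p_corrected) as 7x7 DataFrames in the fixed network order;
    corrected p = (1 + #{max-null |t| >= |t_obs|}) / (1 + n_perm).
    """
    rng = np.random.default_rng(seed)
    stack = np.asarray(network_matrices, dtype=float)
    K = stack.shape[-1]
    iu, ju = np.triu_indices(K, k=0)  # include within-network diagonal cells
    Y = stack[:, iu, ju]
    X, _ = _design_matrix(group, covariates)
    t_obs, df = _glm_group_t(Y, X)

    null = _freedman_lane_null(
        Y, X, [0] + list(range(2, X.shape[1])), n_perm, rng,
        lambda t_star: np.abs(t_star).max(),
    )
    p_corr = (1.0 + (null[:, None] >= np.abs(t_obs)[None, :]).sum(axis=0)) / (1.0 + n_perm)

    t_mat = np.zeros((K, K))
    p_mat = np.ones((K, K))
    t_mat[iu, ju] = t_obs
    t_mat[ju, iu] = t_obs
    p_mat[iu, ju] = p_corr
    p_mat[ju, iu] = p_corr
    names = list(NETWORKS)[:K]
    return (
        pd.DataFrame(t_mat, index=names, columns=names),
        pd.DataFrame(p_mat, index=names, columns=names),
    )


def net_t_value(
    edge_stats: EdgeStatMap,
    region_subset: np.ndarray | list[int] | None = None,
) -> pd.Series:
    """Per-region sum of positive t-values minus the sum of |negative| ones.

    Algebraically this is the plain row sum of the t matrix over j != i.
    ``region_subset`` restricts which regions are reported (e.g. the left
    hemisphere for the PLS path); the sum itself always runs over all edges.
    """
    t = np.asarray(edge_stats.t, dtype=float).copy()
    np.fill_diagonal(t, 0.0)
    scores = t.sum(axis=1)
    idx = np.arange(t.shape[0]) if region_subset is None else np.asarray(region_subset)
    return pd.Series(scores[idx], index=idx, name="net_t")


def propensity_match(
    subjects: list[SubjectRecord],
    group: np.ndarray,
    covariates: list[str] = ("age", "sex"),
    caliper_sd: float = 0.2,
    seed: int | None = None,
) -> list[tuple[int, int]]:
    """Greedy 1:1 nearest-neighbor propensity matching on the logit scale.

    Propensity comes from a logistic regression of group on the covariates;
    the caliper is ``caliper_sd`` times the SD of the logit over everyone.
    Returns index pairs (treated_idx, control_idx) into ``subjects``;
    unmatched subjects are dropped. Treated processing order is randomized
    by ``seed``.
    """
    import statsmodels.api as sm

    g = np.asarray(group)
    uniq = np.unique(g)
    if len(uniq) != 2:
        raise ValueError("need exactly two groups")
    y = (g == uniq[1]).astype(float)
    if y.sum() == 0 or y.sum() == len(y):
        raise ValueError("one group is empty")

    cols = []
    for c in covariates:
        vals = [getattr(s, c) for s in subjects]
        if c == "sex":
            vals = [1.0 if v == "F" else 0.0 for v in vals]
        cols.append(np.asarray(vals, dtype=float))
    X = sm.add_constant(np.column_stack(cols))
    # Complete separation leaves the logits at +/-huge values: every pair then
    # falls outside the caliper, which is the right downstream behavior, so
    # only a fit that fails to produce finite parameters is an error.
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
            params = fit.params
        except Exception as exc:
            raise ValueError(f"propensity model failed: {exc}") from exc
    if not np.all(np.isfinite(params)):
        raise ValueError("propensity model failed: non-finite coefficients (complete separation)")
    logit = X @ params
    caliper = caliper_sd * logit.std()

    treated = np.where(y == 1)[0]
    control = np.where(y == 0)[0]
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(treated))
    available = set(control.tolist())
    pairs = []
    for ti in treated[order]:
        if not available:
            break
        cands = np.array(sorted(available))
        d = np.abs(logit[cands] - logit[ti])
        j = int(np.argmin(d))
        if d[j] <= caliper:
            pairs.append((int(ti), int(cands[j])))
            available.remove(int(cands[j]))
    return pairs


def paired_edge_ttest(
    fc_stack: np.ndarray,
    pairs: list[tuple[int, int]],
    fd: np.ndarray | None = None,
    n_perm: int = 1000,
    edge_p: float = 0.001,
    alpha: float = 0.05,
    seed: int | None = None,
) -> NBSResult:
    """Paired edge contrast with FD control and sign-flip NBS correction.

    Within-pair FC differences are regressed on the within-pair FD
    difference; the tested term is the intercept (the mean paired effect).
    The null flips the signs of the reduced-model residuals per pair
    (Freedman-Lane analogue for the one-sample case).
    """
    if len(pairs) < 3:
        raise ValueError("need at least 3 matched pairs")
    rng = np.random.default_rng(seed)
    stack = np.asarray(fc_stack, dtype=float)
    ti = np.array([p[0] for p in pairs])
    ci = np.array([p[1] for p in pairs])
    edges, iu, ju = vectorize_upper(stack)
    D = edges[ti] - edges[ci]  # n_pairs x E
    n = len(pairs)
    if fd is not None:
        fd = np.asarray(fd, dtype=float)
        fd_diff = fd[ti] - fd[ci]
        X = np.column_stack([np.ones(n), fd_diff - fd_diff.mean()])
        reduced = X[:, 1:]
    else:
        X = np.ones((n, 1))
        reduced = None

    def intercept_t(Y: np.ndarray) -> tuple[np.ndarray, int]:
        return _glm_group_t(Y, X, coef_idx=0)

    t_obs, df = intercept_t(D)
    t_crit = stats.t.isf(edge_p / 2.0, df)
    R = stack.shape[-1]
    comps, _ = _components_from_edges(np.abs(t_obs), t_crit, R, iu, ju)

    if reduced is not None:
        beta_r, *_ = np.linalg.lstsq(reduced, D, rcond=None)
        fitted = reduced @ beta_r
    else:
        fitted = np.zeros_like(D)
    resid = D - fitted

    null = np.empty(n_perm)
    for b in range(n_perm):
        signs = rng.choice([-1.0, 1.0], size=n)
        D_star = fitted + signs[:, None] * resid
        t_star, _ = intercept_t(D_star)
        c, _ = _components_from_edges(np.abs(t_star), t_crit, R, iu, ju)
        null[b] = max((len(e) for e in c), default=0)

    components = []
    for edge_list in sorted(comps, key=len, reverse=True):
        size = len(edge_list)
        p_comp = (1.0 + np.sum(null >= size)) / (1.0 + n_perm)
        components.append(NBSComponent(edges=edge_list, size=size, p_value=p_comp))
    return NBSResult(
        components=components,
        null_max_size=null,
        edge_p=edge_p,
        alpha=alpha,
        n_perm=n_perm,
        t_threshold=t_crit,
    )
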