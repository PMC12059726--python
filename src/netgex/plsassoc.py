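"""SIMPLS PLS of a regional response map on gene expression, with
variogram-matched surrogate permutation significance and bootstrap z-scored
gene weights.

The SIMPLS algorithm (de Jong) deflates the predictor-response cross-product
directly; for a univariate response the first weight vector is proportional
to X'y. The permutation null is selection-aware: each surrogate response is
refit and the best component re-selected, mirroring the observed procedure.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from ._types import PLSModel, SurrogateEnsemble

__all__ = [
    "zscore_columns",
    "simpls_fit",
    "select_component",
    "surrogate_maps",
    "permutation_test",
    "bootstrap_gene_weights",
    "select_genes",
]

log = logging.getLogger(__name__)


def zscore_columns(a: np.ndarray, ddof: int = 1) -> np.ndarray:
    a = np.asarray(a, dtype=float)
    mu = a.mean(axis=0)
    sd = a.std(axis=0, ddof=ddof)
    sd = np.where(sd == 0, 1.0, sd)
    return (a - mu) / sd


def simpls_fit(X: np.ndarray, y: np.ndarray, n_components: int = 5) -> PLSModel:
    """Fit SIMPLS with a univariate response.

    Columns of X and y are z-scored internally. Scores are orthonormal;
    ``var_y``/``var_x`` hold the fraction of response/predictor variance
    explained per component. K is truncated (with a warning) if it exceeds
    the available rank.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if y.shape[0] != n:
        raise ValueError("X rows and y length differ")
    if np.std(y) == 0:
        raise ValueError("response is constant")
    Xz = zscore_columns(X)
    yz = (y - y.mean()) / y.std(ddof=1)

    max_k = min(n - 1, p)
    K = int(n_components)
    if K > max_k:
        log.warning("n_components=%d exceeds rank bound %d; truncated", K, max_k)
        K = max_k
    if K < 1:
        raise ValueError("need at least one component")

    ss_y = float(yz @ yz)
    ss_x = float((Xz**2).sum())

    s = Xz.T @ yz  # cross-product vector, p
    W = np.zeros((p, K))
    T = np.zeros((n, K))
    P = np.zeros((p, K))
    Q = np.zeros(K)
    V = np.zeros((p, K))
    var_y = np.zeros(K)
    var_x = np.zeros(K)
    for a in range(K):
        r = s.copy()
        t = Xz @ r
        t = t - t.mean()
        normt = np.linalg.norm(t)
        if normt < 1e-12:
            K = a
            break
        t /= normt
        r /= normt
        p_load = Xz.T @ t
        q = float(yz @ t)
        v = p_load.copy()
        if a > 0:
            v -= V[:, :a] @ (V[:, :a].T @ p_load)
        nv = np.linalg.norm(v)
        if nv < 1e-12:
            K = a
            break
        v /= nv
        s = s - v * (v @ s)
        W[:, a] = r
        T[:, a] = t
        P[:, a] = p_load
        Q[a] = q
        V[:, a] = v
        var_y[a] = q**2 / ss_y
        var_x[a] = (p_load @ p_load) / ss_x
    return PLSModel(
        weights=W[:, :K],
        scores=T[:, :K],
        x_loadings=P[:, :K],
        y_loadings=Q[:K],
        var_y=var_y[:K],
        var_x=var_x[:K],
        y=yz,
        n_components=K,
    )


def select_component(model: PLSModel) -> int:
    """Pick the component explaining the most response variance (0-based).

    Ties break to the smallest index. The chosen component's sign is fixed
    in place so its score correlates positively with the response.
    """
    idx = int(np.argmax(model.var_y))
    score = model.scores[:, idx]
    if np.corrcoef(score, model.y)[0, 1] < 0:
        model.scores[:, idx] = -score
        model.weights[:, idx] = -model.weights[:, idx]
        model.x_loadings[:, idx] = -model.x_loadings[:, idx]
        model.y_loadings[idx] = -model.y_loadings[idx]
    model.selected = idx
    return idx


def _bin_pairs(dist: np.ndarray, bin_edges: np.ndarray):
    iu, ju = np.triu_indices(dist.shape[0], k=1)
    which = np.digitize(dist[iu, ju], bin_edges) - 1
    n_bins = len(bin_edges) - 1
    inside = (which >= 0) & (which < n_bins)
    counts = np.bincount(which[inside], minlength=n_bins).astype(float)
    counts[counts == 0] = np.nan
    return iu, ju, which, inside, counts


def _binned_variogram(values, iu, ju, which, inside, counts, n_bins) -> np.ndarray:
    sq = 0.5 * (values[iu] - values[ju]) ** 2
    sums = np.bincount(which[inside], weights=sq[inside], minlength=n_bins)
    return sums / counts


def _variogram(values: np.ndarray, dist: np.ndarray, bin_edges: np.ndarray) -> np.ndarray:
    iu, ju, which, inside, counts = _bin_pairs(dist, bin_edges)
    return _binned_variogram(values, iu, ju, which, inside, counts, len(bin_edges) - 1)


def surrogate_maps(
    y: np.ndarray,
    centroids: np.ndarray,
    n_surrogates: int,
    seed: int | None = None,
    kernel_grid: tuple[float, ...] = (10.0, 20.0, 40.0, 80.0),
    n_bins: int = 15,
    k_grid: tuple[int, ...] | None = None,
    n_candidates: int = 3,
    max_dist_percentile: float = 75.0,
) -> SurrogateEnsemble:
    """Variogram-matched surrogate response maps over region centroids.

    Each surrogate draws ``n_candidates`` random permutations of ``y``,
    smooths each with an exponential distance-decay kernel over the k
    nearest regions for every (k, length-scale) combination in
    ``k_grid`` x ``kernel_grid``, and keeps the candidate whose variogram
    best matches the empirical one after an affine recalibration
    (white noise is mixed in to realize the fitted nugget). The winning map
    is affinely rescaled to the mean/variance of ``y``. Distances beyond
    ``max_dist_percentile`` of the pair distribution are ignored: the
    long-range variogram bins are noisy and dominated by the map-wide trend.
    """
    y = np.asarray(y, dtype=float).ravel()
    R = len(y)
    if R < 10:
        raise ValueError("need at least 10 regions for a stable variogram")
    cents = np.asarray(centroids, dtype=float)
    if cents.shape[0] != R:
        raise ValueError("centroids must cover every region of y")
    rng = np.random.default_rng(seed)

    dist = np.sqrt(((cents[:, None, :] - cents[None, :, :]) ** 2).sum(axis=2))
    iu0, ju0 = np.triu_indices(R, k=1)
    dmax = np.percentile(dist[iu0, ju0], max_dist_percentile)
    bin_edges = np.linspace(0.0, dmax, n_bins + 1)
    iu, ju, which, inside, counts = _bin_pairs(dist, bin_edges)
    nb = n_bins
    gamma_emp = _binned_variogram(y, iu, ju, which, inside, counts, nb)
    valid = ~np.isnan(gamma_emp)

    if k_grid is None:
        k_grid = tuple(sorted({max(3, R // 6), max(4, R // 3), max(5, R // 2), R - 1}))
    # Precompute neighbor weights per (k, length scale) candidate.
    order = np.argsort(dist, axis=1)
    smoothers = []
    for k in k_grid:
        nn = order[:, 1 : k + 1]
        nn_d = np.take_along_axis(dist, nn, axis=1)
        for ell in kernel_grid:
            w = np.exp(-nn_d / ell)
            w /= w.sum(axis=1, keepdims=True)
            smoothers.append((k, ell, nn, w))

    maps = np.empty((n_surrogates, R))
    fit_rows = []
    y_mean, y_var = y.mean(), y.var()
    for si in range(n_surrogates):
        best = None
        for _ in range(n_candidates):
            y_perm = y[rng.permutation(R)]
            for k, ell, nn, w in smoothers:
                smooth = (w * y_perm[nn]).sum(axis=1)
                gamma_s = _binned_variogram(smooth, iu, ju, which, inside, counts, nb)
                ok = valid & ~np.isnan(gamma_s)
                A = np.column_stack([np.ones(ok.sum()), gamma_s[ok]])
                coef, *_ = np.linalg.lstsq(A, gamma_emp[ok], rcond=None)
                alpha, beta = coef
                sse = float(((A @ coef - gamma_emp[ok]) ** 2).sum())
                if best is None or sse < best[0]:
                    best = (sse, k, ell, alpha, beta, smooth, y_perm)
        sse, k, ell, alpha, beta, smooth, y_perm = best
        noise = rng.standard_normal(R)
        cand = np.sqrt(max(beta, 0.0)) * smooth + np.sqrt(max(alpha, 0.0)) * noise
        cv = cand.var()
        if cv <= 0:
            cand = y_perm.copy()
            cv = cand.var()
        cand = (cand - cand.mean()) / np.sqrt(cv) * np.sqrt(y_var) + y_mean
        maps[si] = cand
        fit_rows.append({"surrogate": si, "k": k, "kernel_scale": ell, "sse": sse})
    return SurrogateEnsemble(
        maps=maps,
        variogram_fit=pd.DataFrame(fit_rows),
        distance_bins=bin_edges,
        empirical_variogram=gamma_emp,
    )


def permutation_test(
    X: np.ndarray,
    y: np.ndarray,
    surrogates: SurrogateEnsemble | np.ndarray,
    n_components: int = 5,
) -> tuple[float, float, np.ndarray]:
    """Selection-aware permutation p for the selected component's variance.

    Observed statistic: response variance explained by the best component of
    a SIMPLS fit on (X, y). For each surrogate response the model is refit
    and the best component re-selected. Returns (p, observed, null).
    """
    maps = surrogates.maps if isinstance(surrogates, SurrogateEnsemble) else np.asarray(surrogates)
    model = simpls_fit(X, y, n_components)
    sel = select_component(model)
    observed = float(model.var_y[sel])
    null = np.empty(maps.shape[0])
    for i in range(maps.shape[0]):
        m = simpls_fit(X, maps[i], n_components)
        null[i] = float(m.var_y.max())
    p = (1.0 + np.sum(null >= observed)) / (1.0 + len(null))
    return p, observed, null


def bootstrap_gene_weights(
    X: np.ndarray,
    y: np.ndarray,
    n_components: int = 5,
    selected: int | None = None,
    n_boot: int = 1000,
    seed: int | None = None,
    gene_names: list[str] | None = None,
    rescale: str = "projection",
) -> pd.DataFrame:
    """Bootstrap (regions resampled with replacement) z-scores of gene weights.

    Each refit's components are matched to the original selected component by
    maximal |correlation| of weight vectors and sign-aligned before the SE is
    taken, so component reordering and the global PLS sign indeterminacy do
    not inflate the error. With ``rescale='projection'`` (default) each
    matched bootstrap weight vector is divided by its projection coefficient
    onto the reference vector before the SD: refits share a global scale
    wobble (the component normalization varies with the draw) that otherwise
    deflates the SE and makes null-map z-scores anti-conservative.
    z = original weight / bootstrap SD; genes are ranked by z descending.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    rng = np.random.default_rng(seed)
    model = simpls_fit(X, y, n_components)
    if selected is None:
        selected = select_component(model)
    w_ref = model.weights[:, selected]

    boots = np.empty((n_boot, p))
    b = 0
    while b < n_boot:
        idx = rng.integers(0, n, size=n)
        if len(np.unique(idx)) <= model.n_components:
            log.info("bootstrap draw with too few distinct regions; redrawn")
            continue
        try:
            m = simpls_fit(X[idx], y[idx], n_components)
        except ValueError:
            continue  # e.g. constant resampled response; redraw
        cors = np.array(
            [abs(_safe_corr(m.weights[:, a], w_ref)) for a in range(m.n_components)]
        )
        a = int(np.argmax(cors))
        w = m.weights[:, a].copy()
        if _safe_corr(w, w_ref) < 0:
            w = -w
        if rescale == "projection":
            g = (w @ w_ref) / (w_ref @ w_ref)
            if abs(g) > 1e-12:
                w = w / g
        elif rescale != "none":
            raise ValueError(f"unknown rescale mode {rescale!r}")
        boots[b] = w
        b += 1

    se = boots.std(axis=0, ddof=1)
    se = np.where(se == 0, np.nan, se)
    z = w_ref / se
    names = gene_names if gene_names is not None else [f"g{j}" for j in range(p)]
    table = pd.DataFrame(
        {"gene": names, "weight": w_ref, "se": se, "z": z, "sign": np.sign(z)}
    )
    table["rank"] = (-table["z"]).rank(method="first").astype(int)
    return table.sort_values("rank").reset_index(drop=True)


def _safe_corr(a: np.ndarray, b: np.ndarray) -> float:
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def select_genes(table: pd.DataFrame, z_thresh: float = 3.0) -> tuple[list[str], list[str]]:
    """Split genes with |z| strictly above the threshold by weight sign.

    Both lists are sorted by |z| descending.
    """
    if table.empty:
        return [], []
    sel = table[np.abs(table["z"]) > z_thresh].copy()
    sel["absz"] = np.abs(sel["z"])
    sel = sel.sort_values("absz", ascending=False)
    pos = sel.loc[sel["z"] > 0, "gene"].tolist()
    neg = sel.loc[sel["z"] < 0, "gene"].tolist()
    return pos, neg
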