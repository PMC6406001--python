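"""Pairwise Granger-Geweke feedback estimation with AIC lag adaptation.

For an ordered node pair (i, j) the directed feedback in nats is

    F_{i->j} = ln(T1 / T2)

where T1 is the innovation variance of the restricted autoregression of j on
its own past and T2 the innovation variance of the j-equation of the full
bivariate autoregression on the past of both i and j, both fit by ordinary
least squares at the same lag on the same effective sample.  Because the
restricted design is a column subset of the full design evaluated on
identical rows, the estimated F is non-negative by construction.

The model order is chosen per pair by minimising the AIC of the full
bivariate fit over lags 1..lag_max, with all candidates scored on the common
sample t > lag_max so the criteria are comparable.  Significance comes from
the large-sample likelihood-ratio equivalence: n_effective * F is chi-square
with `lag` degrees of freedom under the null of no directed influence.

Concatenated runs are respected throughout: lagged design rows that would
reach across a run boundary are dropped, and each series is demeaned within
run before fitting (the feedback measure itself is invariant to affine
rescaling of either series).
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
import scipy.linalg
from joblib import Parallel, delayed
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin

from .atlas_io import FlowMatrix, TimeSeriesPanel
from .errors import DegenerateInputError, FlowgcError, InsufficientDataError

_RSS_FLOOR = 1e-300


@dataclasses.dataclass(frozen=True)
class ArFitRestricted:
    """OLS fit of a series on its own past: lag-l autoregression with intercept."""

    lag: int
    coefficients: np.ndarray       # l autoregressive weights, lag 1 first
    intercept: float
    residual_variance: float       # RSS / n_effective (ML scaling)
    n_effective: int


@dataclasses.dataclass(frozen=True)
class VarFitFull:
    """Per-equation OLS fit of the full bivariate autoregression.

    ``coef_x`` stacks (a_1..a_l, b_1..b_l): own-past then cross-past weights
    of the x equation; ``coef_y`` stacks (c_1..c_l, d_1..d_l): cross-past then
    own-past weights of the y equation.
    """

    lag: int
    coef_x: np.ndarray
    coef_y: np.ndarray
    intercept_x: float
    intercept_y: float
    residual_variance_x: float     # Sigma2
    residual_variance_y: float     # T2
    residual_covariance: float     # gamma2
    n_effective: int


@dataclasses.dataclass(frozen=True)
class EdgeResult:
    """Directed feedback for one node pair, both directions."""

    f_forward: float
    f_reverse: float
    p_forward: float
    p_reverse: float
    lag_forward: int
    lag_reverse: int


# ---------------------------------------------------------------------------
# design-matrix plumbing
# ---------------------------------------------------------------------------

def demean_per_run(data: np.ndarray, boundaries: Sequence[int]) -> np.ndarray:
    """Subtract each run segment's mean, per column."""
    out = np.array(data, dtype=float, copy=True)
    edges = list(boundaries) + [out.shape[0]]
    for s, e in zip(edges[:-1], edges[1:]):
        out[s:e] = out[s:e] - out[s:e].mean(axis=0)
    return out


def _lagged(x: np.ndarray, boundaries: Sequence[int], lag_max: int
            ) -> tuple[np.ndarray, np.ndarray]:
    """Lagged copies of ``x`` plus the per-row count of within-run lags available.

    Returns ``L`` of shape [T, lag_max] with ``L[t, l-1] = x[t-l]`` wherever
    t-l stays inside the same run (other cells are zero and masked out via
    ``avail``), and ``avail[t]`` = number of valid lags at row t, capped at
    lag_max.  A row enters a lag-l fit iff ``avail[t] >= l``.
    """
    T = x.shape[0]
    L = np.zeros((T, lag_max))
    avail = np.zeros(T, dtype=int)
    edges = list(boundaries) + [T]
    for s, e in zip(edges[:-1], edges[1:]):
        seg = x[s:e]
        n = e - s
        for l in range(1, min(lag_max, n - 1) + 1):
            L[s + l:e, l - 1] = seg[: n - l]
        avail[s:e] = np.arange(n)
    np.minimum(avail, lag_max, out=avail)
    return L, avail


def _cho_solve(G: np.ndarray, rhs: np.ndarray) -> np.ndarray:
    try:
        c = scipy.linalg.cho_factor(G, lower=True, check_finite=False)
    except scipy.linalg.LinAlgError as exc:
        raise DegenerateInputError(
            "singular regression design (constant or collinear series)"
        ) from exc
    return scipy.linalg.cho_solve(c, rhs, check_finite=False)


def _validate_pair_input(x: np.ndarray, y: np.ndarray | None, lag: int) -> None:
    if lag < 1:
        raise ValueError("lag must be >= 1")
    if y is not None and x.shape != y.shape:
        raise InsufficientDataError("paired series must share length and run boundaries")


# ---------------------------------------------------------------------------
# single-pair fits (reference implementations used by the matrix engine too)
# ---------------------------------------------------------------------------

def fit_ar_restricted(y: np.ndarray, lag: int, run_boundaries: Sequence[int] = (0,),
                      demean: bool = True) -> ArFitRestricted:
    """Restricted model: OLS of y_t on its own l past values with intercept.

    The residual variance uses maximum-likelihood scaling (RSS / n_effective).
    """
    y = np.asarray(y, dtype=float)
    _validate_pair_input(y, None, lag)
    if demean:
        y = demean_per_run(y[:, None], run_boundaries)[:, 0]
    L, avail = _lagged(y, run_boundaries, lag)
    rows = avail >= lag
    n = int(rows.sum())
    if n <= lag + 1:
        raise InsufficientDataError(
            f"lag {lag} leaves only {n} usable rows; need more than lag+1"
        )
    D = np.column_stack([np.ones(n), L[rows, :lag]])
    t = y[rows]
    G = D.T @ D
    g = D.T @ t
    beta = _cho_solve(G, g)
    rss = max(float(t @ t - beta @ g), 0.0)
    return ArFitRestricted(
        lag=lag, coefficients=beta[1:], intercept=float(beta[0]),
        residual_variance=rss / n, n_effective=n,
    )


def fit_var_full(x: np.ndarray, y: np.ndarray, lag: int,
                 run_boundaries: Sequence[int] = (0,), demean: bool = True) -> VarFitFull:
    """Full bivariate model: each series regressed on l past values of both."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    _validate_pair_input(x, y, lag)
    if demean:
        xy = demean_per_run(np.column_stack([x, y]), run_boundaries)
        x, y = xy[:, 0], xy[:, 1]
    Lx, avail = _lagged(x, run_boundaries, lag)
    Ly, _ = _lagged(y, run_boundaries, lag)
    rows = avail >= lag
    n = int(rows.sum())
    ncol = 2 * lag + 1
    if n <= ncol:
        raise InsufficientDataError(f"lag {lag} leaves only {n} usable rows for {ncol} parameters")
    D = np.column_stack([np.ones(n), Lx[rows, :lag], Ly[rows, :lag]])
    tx, ty = x[rows], y[rows]
    G = D.T @ D
    gx, gy = D.T @ tx, D.T @ ty
    bx = _cho_solve(G, gx)
    by = _cho_solve(G, gy)
    rss_x = max(float(tx @ tx - bx @ gx), 0.0)
    rss_y = max(float(ty @ ty - by @ gy), 0.0)
    cross = float(tx @ ty - bx @ gy - by @ gx + bx @ (G @ by))
    return VarFitFull(
        lag=lag,
        coef_x=np.concatenate([bx[1:lag + 1], bx[lag + 1:]]),
        coef_y=np.concatenate([by[1:lag + 1], by[lag + 1:]]),
        intercept_x=float(bx[0]), intercept_y=float(by[0]),
        residual_variance_x=rss_x / n, residual_variance_y=rss_y / n,
        residual_covariance=cross / n, n_effective=n,
    )


def geweke_f(x: np.ndarray, y: np.ndarray, lag: int,
             run_boundaries: Sequence[int] = (0,), demean: bool = True
             ) -> tuple[float, float]:
    """Directed Geweke feedback (F_{x->y}, F_{y->x}) in nats at a fixed lag.

    Restricted and full fits share the effective sample (rows with ``lag``
    within-run past values), so each F is >= 0 exactly.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    _validate_pair_input(x, y, lag)
    if demean:
        xy = demean_per_run(np.column_stack([x, y]), run_boundaries)
        x, y = xy[:, 0], xy[:, 1]
    Lx, avail = _lagged(x, run_boundaries, lag)
    Ly, _ = _lagged(y, run_boundaries, lag)
    f_xy, f_yx, _ = _geweke_from_designs(Lx, Ly, x, y, avail, lag)
    return f_xy, f_yx


def lr_pvalue(f_value: float, n_effective: int, lag: int) -> float:
    """Upper-tail chi-square(lag) probability at statistic n_effective * F.

    Negative feedback estimates are clipped to zero first, giving p = 1.
    """
    if n_effective <= lag:
        raise InsufficientDataError("n_effective must exceed the lag")
    f = max(float(f_value), 0.0)
    return float(stats.chi2.sf(n_effective * f, df=lag))


def select_lag_aic(x: np.ndarray, y: np.ndarray, lag_max: int = 10,
                   run_boundaries: Sequence[int] = (0,), demean: bool = True) -> int:
    """AIC-optimal order of the full bivariate model over lags 1..lag_max.

    All candidates are refit on the common sample with ``lag_max`` within-run
    past values so their criteria are comparable; ties go to the smallest lag.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    _validate_pair_input(x, y, 1 if lag_max >= 1 else lag_max)
    if lag_max < 1:
        raise ValueError("lag_max must be >= 1")
    if demean:
        xy = demean_per_run(np.column_stack([x, y]), run_boundaries)
        x, y = xy[:, 0], xy[:, 1]
    Lx, avail = _lagged(x, run_boundaries, lag_max)
    Ly, _ = _lagged(y, run_boundaries, lag_max)
    return _select_lag_from_designs(Lx, Ly, x, y, avail, lag_max)


def _select_lag_from_designs(Lx: np.ndarray, Ly: np.ndarray, x: np.ndarray,
                             y: np.ndarray, avail: np.ndarray, lag_max: int) -> int:
    rows = avail >= lag_max
    n = int(rows.sum())
    if n <= 2 * lag_max + 1:
        raise InsufficientDataError(
            f"lag_max {lag_max} leaves only {n} usable rows on the common support"
        )
    D = np.column_stack([np.ones(n), Lx[rows, :lag_max], Ly[rows, :lag_max]])
    tx, ty = x[rows], y[rows]
    G = D.T @ D
    gx, gy = D.T @ tx, D.T @ ty
    sxx, syy, sxy = float(tx @ tx), float(ty @ ty), float(tx @ ty)
    best_l, best_aic = 1, np.inf
    for l in range(1, lag_max + 1):
        cols = np.r_[0, 1:l + 1, lag_max + 1:lag_max + l + 1]
        Gs = G[np.ix_(cols, cols)]
        bx = _cho_solve(Gs, gx[cols])
        by = _cho_solve(Gs, gy[cols])
        rss_x = max(sxx - bx @ gx[cols], _RSS_FLOOR)
        rss_y = max(syy - by @ gy[cols], _RSS_FLOOR)
        cross = sxy - bx @ gy[cols] - by @ gx[cols] + bx @ (Gs @ by)
        det = (rss_x / n) * (rss_y / n) - (cross / n) ** 2
        if det <= 0:
            continue
        k = 2 * (2 * l + 1)
        aic = n * np.log(det) + 2 * k
        if aic < best_aic:           # first minimum: ties keep the smaller lag
            best_aic, best_l = aic, l
    return best_l


# ---------------------------------------------------------------------------
# whole-panel engine
# ---------------------------------------------------------------------------

def _pair_edge(Lx, Ly, x, y, avail, lag_max: int) -> EdgeResult:
    l = _select_lag_from_designs(Lx, Ly, x, y, avail, lag_max)
    f_xy, f_yx, n = _geweke_from_designs(Lx, Ly, x, y, avail, l)
    p_xy = lr_pvalue(f_xy, n, l)
    p_yx = lr_pvalue(f_yx, n, l)
    return EdgeResult(f_forward=f_xy, f_reverse=f_yx,
                      p_forward=p_xy, p_reverse=p_yx,
                      lag_forward=l, lag_reverse=l)


def _geweke_from_designs(Lx, Ly, x, y, avail, lag: int) -> tuple[float, float, int]:
    """Same algebra as :func:`_geweke_on_design` but on precomputed lag stacks."""
    rows = avail >= lag
    n = int(rows.sum())
    if n <= 2 * lag + 1:
        raise InsufficientDataError(f"lag {lag} leaves only {n} usable rows")
    D = np.column_stack([np.ones(n), Lx[rows, :lag], Ly[rows, :lag]])
    tx, ty = x[rows], y[rows]
    G = D.T @ D
    gx, gy = D.T @ tx, D.T @ ty
    idx_x = np.r_[0, 1:lag + 1]
    idx_y = np.r_[0, lag + 1:2 * lag + 1]
    full = np.arange(2 * lag + 1)
    sxx, syy = float(tx @ tx), float(ty @ ty)

    def _rss(cols, g, s2):
        b = _cho_solve(G[np.ix_(cols, cols)], g[cols])
        return max(float(s2 - b @ g[cols]), 0.0)

    rx_r, rx_f = _rss(idx_x, gx, sxx), _rss(full, gx, sxx)
    ry_r, ry_f = _rss(idx_y, gy, syy), _rss(full, gy, syy)
    if rx_f <= _RSS_FLOOR or ry_f <= _RSS_FLOOR:
        raise DegenerateInputError("full-model residual variance is zero")
    return float(np.log(ry_r / ry_f)), float(np.log(rx_r / rx_f)), n


def _support_pyramid(data: np.ndarray, boundaries: Sequence[int], lag_max: int):
    """Cross-products of the all-node lag design at every trim level.

    Level l keeps rows with at least l within-run past samples.  Returns
    dicts keyed by level: Gram ``G[l]`` of the stacked design
    [1, lags of node 0, ..., lags of node N-1], target cross-products
    ``C[l] = Z' X`` and ``S[l] = X' X``, and row counts — computed once at
    level 1 and downdated row-by-row (only a handful of rows separate
    consecutive levels, one per run per level).
    """
    T, N = data.shape
    L_all = np.empty((T, N * lag_max))
    avail = None
    for n in range(N):
        L_all[:, n * lag_max:(n + 1) * lag_max], avail = _lagged(
            data[:, n], boundaries, lag_max)
    Z = np.column_stack([np.ones(T), L_all])
    rows = avail >= 1
    Z1, X1 = Z[rows], data[rows]
    G = {1: Z1.T @ Z1}
    C = {1: Z1.T @ X1}
    S = {1: X1.T @ X1}
    counts = {1: int(rows.sum())}
    for l in range(2, lag_max + 1):
        drop = avail == l - 1
        Zd, Xd = Z[drop], data[drop]
        G[l] = G[l - 1] - Zd.T @ Zd
        C[l] = C[l - 1] - Zd.T @ Xd
        S[l] = S[l - 1] - Xd.T @ Xd
        counts[l] = counts[l - 1] - int(drop.sum())
    return G, C, S, counts


def _batched_rss(G_level: np.ndarray, C_level: np.ndarray, orders: np.ndarray,
                 targets: np.ndarray) -> np.ndarray:
    """Partial-model RSS profiles for a batch of column orderings.

    For each batch member the columns listed in ``orders`` are brought into
    that order; the Cholesky factor of a Gram matrix restricted to a leading
    block is the leading block of the full factor, so one factorization and
    one triangular solve give the residual sum of squares of every nested
    leading-column model at once: rss(d) = s2 - sum of the first d squared
    forward-substituted entries.  Returns z, the forward-substituted vectors
    [batch, d]; callers combine cumulative sums of its squares.
    """
    Gs = G_level[orders[:, :, None], orders[:, None, :]]
    g = np.take_along_axis(C_level[:, targets].T, orders, axis=1)
    Lc = np.linalg.cholesky(Gs)
    z = np.linalg.solve(Lc, g[:, :, None])[:, :, 0]
    return z


def compute_flow_matrix(panel: TimeSeriesPanel, lag_max: int = 10,
                        demean: bool = True, n_jobs: int = 1) -> FlowMatrix:
    """Directed flow, significance and lag layers for every ordered node pair.

    The lag is selected per pair by AIC on the common support (rows with
    ``lag_max`` within-run past values); F and p are then computed at that
    lag on the largest sample it permits.  The diagonal is fixed at F = 0,
    p = 1.  Results are deterministic and identical to calling
    :func:`select_lag_aic` / :func:`geweke_f` pair by pair; the batched path
    shares one Gram-matrix pyramid across all pairs and falls back to the
    pairwise loop when any design is singular.
    """
    N = panel.n_nodes
    if N < 2:
        raise InsufficientDataError("need at least two nodes")
    data = demean_per_run(panel.data, panel.run_boundaries) if demean else np.asarray(
        panel.data, dtype=float)
    try:
        return _compute_flow_batched(panel.subject_id, data, panel.run_boundaries, lag_max)
    except np.linalg.LinAlgError:
        return _compute_flow_loop(panel, data, lag_max, n_jobs)


def _compute_flow_batched(subject_id: str, data: np.ndarray,
                          boundaries: Sequence[int], lag_max: int) -> FlowMatrix:
    N = data.shape[1]
    G, C, S, counts = _support_pyramid(data, boundaries, lag_max)
    n_common = counts[lag_max]
    if n_common <= 2 * lag_max + 1:
        raise InsufficientDataError(
            f"lag_max {lag_max} leaves only {n_common} usable rows on the common support"
        )
    iu = np.triu_indices(N, k=1)
    pi, pj = iu[0], iu[1]
    P = pi.size

    def col(nodes: np.ndarray, l: int) -> np.ndarray:
        return 1 + nodes * lag_max + (l - 1)

    # AIC stage: interleaved ordering [1, x_1, y_1, x_2, y_2, ...] makes the
    # lag-l model the leading (2l+1)-column block.
    order = np.empty((P, 2 * lag_max + 1), dtype=int)
    order[:, 0] = 0
    for l in range(1, lag_max + 1):
        order[:, 2 * l - 1] = col(pi, l)
        order[:, 2 * l] = col(pj, l)
    GL, CL = G[lag_max], C[lag_max]
    zx = _batched_rss(GL, CL, order, pi)
    zy = _batched_rss(GL, CL, order, pj)
    cx = np.cumsum(zx ** 2, axis=1)
    cy = np.cumsum(zy ** 2, axis=1)
    cxy = np.cumsum(zx * zy, axis=1)
    sxx, syy, sxy = S[lag_max][pi, pi], S[lag_max][pj, pj], S[lag_max][pi, pj]
    aic = np.full((P, lag_max), np.inf)
    for l in range(1, lag_max + 1):
        d = 2 * l
        rss_x = np.maximum(sxx - cx[:, d], _RSS_FLOOR)
        rss_y = np.maximum(syy - cy[:, d], _RSS_FLOOR)
        cross = sxy - cxy[:, d]
        det = (rss_x / n_common) * (rss_y / n_common) - (cross / n_common) ** 2
        ok = det > 0
        aic[ok, l - 1] = n_common * np.log(det[ok]) + 2 * (2 * (2 * l + 1))
    l_opt = np.argmin(aic, axis=1) + 1     # first minimum: ties keep smaller lag

    # F stage at the selected lag, on the largest support that lag permits.
    f = np.zeros((N, N))
    p = np.ones((N, N))
    lag_layer = np.zeros((N, N))
    for l in np.unique(l_opt):
        sel = np.flatnonzero(l_opt == l)
        gi, gj = pi[sel], pj[sel]
        n_l = counts[int(l)]
        # ordering [1, own past of target, cross past]: the restricted model
        # is the leading l+1 block, the full model the whole 2l+1 block.
        ord_y = np.concatenate(
            [np.zeros((sel.size, 1), int)]
            + [col(gj, ll)[:, None] for ll in range(1, l + 1)]
            + [col(gi, ll)[:, None] for ll in range(1, l + 1)], axis=1)
        ord_x = np.concatenate(
            [np.zeros((sel.size, 1), int)]
            + [col(gi, ll)[:, None] for ll in range(1, l + 1)]
            + [col(gj, ll)[:, None] for ll in range(1, l + 1)], axis=1)
        z_y = _batched_rss(G[int(l)], C[int(l)], ord_y, gj)
        z_x = _batched_rss(G[int(l)], C[int(l)], ord_x, gi)
        syy_l = S[int(l)][gj, gj]
        sxx_l = S[int(l)][gi, gi]
        cyc = np.cumsum(z_y ** 2, axis=1)
        cxc = np.cumsum(z_x ** 2, axis=1)
        ry_r = np.maximum(syy_l - cyc[:, l], _RSS_FLOOR)
        ry_f = syy_l - cyc[:, 2 * l]
        rx_r = np.maximum(sxx_l - cxc[:, l], _RSS_FLOOR)
        rx_f = sxx_l - cxc[:, 2 * l]
        if np.any(ry_f <= _RSS_FLOOR) or np.any(rx_f <= _RSS_FLOOR):
            raise np.linalg.LinAlgError("zero full-model residual variance")
        f_ij = np.log(ry_r / ry_f)
        f_ji = np.log(rx_r / rx_f)
        f[gi, gj] = np.maximum(f_ij, 0.0)
        f[gj, gi] = np.maximum(f_ji, 0.0)
        p[gi, gj] = stats.chi2.sf(n_l * np.maximum(f_ij, 0.0), df=int(l))
        p[gj, gi] = stats.chi2.sf(n_l * np.maximum(f_ji, 0.0), df=int(l))
        lag_layer[gi, gj] = lag_layer[gj, gi] = l
    return FlowMatrix(subject_id=subject_id, f=f, p=p, lag=lag_layer)


def _compute_flow_loop(panel: TimeSeriesPanel, data: np.ndarray, lag_max: int,
                       n_jobs: int = 1) -> FlowMatrix:
    """Pairwise reference path; collects per-pair failures into one report."""
    N = panel.n_nodes
    lags_all = [None] * N
    avail = None
    for node in range(N):
        lags_all[node], avail = _lagged(data[:, node], panel.run_boundaries, lag_max)

    pairs = [(i, j) for i in range(N) for j in range(i + 1, N)]

    def _one(i, j):
        return _pair_edge(lags_all[i], lags_all[j], data[:, i], data[:, j], avail, lag_max)

    if n_jobs == 1:
        results = []
        failures = []
        for i, j in pairs:
            try:
                results.append(_one(i, j))
            except FlowgcError as exc:
                results.append(None)
                failures.append((i + 1, j + 1, str(exc)))
    else:
        raw = Parallel(n_jobs=n_jobs, prefer="threads")(
            delayed(_safe_pair)(_one, i, j) for i, j in pairs
        )
        results = [r if not isinstance(r, tuple) else None for r in raw]
        failures = [(i + 1, j + 1, r[1]) for (i, j), r in zip(pairs, raw)
                    if isinstance(r, tuple)]

    if failures:
        listing = "; ".join(f"({i},{j}): {msg}" for i, j, msg in failures[:10])
        more = "" if len(failures) <= 10 else f" (+{len(failures) - 10} more)"
        raise FlowgcError(f"{len(failures)} node pairs failed: {listing}{more}")

    f = np.zeros((N, N))
    p = np.ones((N, N))
    lag = np.zeros((N, N))
    for (i, j), edge in zip(pairs, results):
        f[i, j], f[j, i] = max(edge.f_forward, 0.0), max(edge.f_reverse, 0.0)
        p[i, j], p[j, i] = edge.p_forward, edge.p_reverse
        lag[i, j], lag[j, i] = edge.lag_forward, edge.lag_reverse
    return FlowMatrix(subject_id=panel.subject_id, f=f, p=p, lag=lag)


def _safe_pair(fn, i, j):
    try:
        return fn(i, j)
    except FlowgcError as exc:
        return ("error", str(exc))


class GrangerGewekeFlow(TransformerMixin, BaseEstimator):
    """Transformer mapping time-series panels to per-subject flow matrices.

    Parameters
    ----------
    lag_max : int
        Largest autoregressive order searched by AIC, in samples.
    demean_per_run : bool
        Remove each run segment's mean before fitting.  The feedback measure
        is invariant to affine rescaling either way; demeaning removes
        between-run offset artifacts introduced by concatenation.
    n_jobs : int
        Parallelism over node pairs (joblib threads).
    """

    def __init__(self, lag_max: int = 10, demean_per_run: bool = True, n_jobs: int = 1):
        self.lag_max = lag_max
        self.demean_per_run = demean_per_run
        self.n_jobs = n_jobs

    def fit(self, X, y=None):
        """Validate parameters; the transformer is stateless."""
        if self.lag_max < 1:
            raise ValueError("lag_max must be >= 1")
        self.n_features_in_ = None
        return self

    def transform(self, X):
        """Compute flow matrices for one panel, a list or a mapping of panels."""
        self.fit(X)
        if isinstance(X, TimeSeriesPanel):
            return self._compute(X)
        if isinstance(X, Mapping):
            return {k: self._compute(v) for k, v in X.items()}
        return [self._compute(p) for p in X]

    def _compute(self, panel: TimeSeriesPanel) -> FlowMatrix:
        return compute_flow_matrix(panel, lag_max=self.lag_max,
                                   demean=self.demean_per_run, n_jobs=self.n_jobs)
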