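"""Ground-truth vector-autoregressive testbed for the flow pipeline.

Panels are stationary VAR realizations over a planted sparse directed graph:
each directed edge carries its own lag and coefficient, every node has an
AR(1) self-decay, and each subject receives an independent Gaussian jitter of
the edge coefficients (the between-subject variability the predictive stage
exploits).  Behavioral scores are a noisy linear function of a planted subset
of the subject-specific edge coefficients plus age and sex effects.

The default testbed uses a bipartite driver-to-receiver topology: drivers are
autonomous AR(1) nodes and receivers never feed back.  A pairwise feedback
measure reports total (direct plus mediated) influence, so chained edges
would make genuinely non-zero flows appear on non-planted pairs; the
bipartite layout keeps the planted adjacency a meaningful ground truth for
edge-recovery benchmarks.

The module also carries the closed-form population oracle: the exact
autocovariance function of a stationary VAR (companion-form Lyapunov
equation) and the implied population pairwise Geweke feedback at any finite
lag, obtained from Yule-Walker projections.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.linalg

from .atlas_io import Atlas, TimeSeriesPanel
from .errors import ValidationError

Edge = tuple[int, int, int, float]     # (source, target, lag, coefficient); nodes 0-based

_BURN_IN = 200
_JITTER_RETRIES = 50


@dataclasses.dataclass(frozen=True)
class NetworkSpec:
    """Planted directed network generating a stationary VAR panel.

    ``edges`` holds (source, target, lag, coefficient) with 0-based nodes;
    ``self_decay`` is each node's own AR(1) coefficient; ``noise_sd`` the
    innovation scale.  Between-subject variability has two components: an
    independent Gaussian jitter per edge (``coefficient_jitter_sd``) and
    subject-level multiplicative coupling gains (``coupling_gain_sd``)
    emulating trait-like modulators of circuit strength.  ``gain_groups``
    assigns each edge to one latent gain factor (default: a single global
    factor); edges sharing a factor have mutually correlated strengths
    across subjects, which is what makes an edge set behaviorally coherent
    and individually detectable by edge-wise screening at modest sample
    sizes.
    """

    n_nodes: int
    edges: tuple[Edge, ...]
    self_decay: float = 0.3
    noise_sd: float = 1.0
    coefficient_jitter_sd: float = 0.05
    coupling_gain_sd: float = 0.25
    gain_groups: tuple[int, ...] | None = None

    def __post_init__(self):
        for (s, t, l, c) in self.edges:
            if not (0 <= s < self.n_nodes and 0 <= t < self.n_nodes):
                raise ValidationError(f"edge ({s},{t}) outside node range")
            if l < 1:
                raise ValidationError("edge lags must be >= 1")
        if not np.all(np.abs(self.self_decay) < 1):
            raise ValidationError("self_decay must lie in (-1, 1)")
        if self.gain_groups is not None and len(self.gain_groups) != len(self.edges):
            raise ValidationError("gain_groups must assign one factor per edge")
        if not is_stationary(self.coefficient_matrices()):
            raise ValidationError("planted network is not stationary (companion radius >= 1)")

    @property
    def max_lag(self) -> int:
        return max((l for (_, _, l, _) in self.edges), default=1)

    def coefficient_matrices(self, coefficients: Sequence[float] | None = None
                             ) -> list[np.ndarray]:
        """VAR coefficient matrices A_1..A_p with A_l[target, source] = coefficient."""
        coefs = [c for (_, _, _, c) in self.edges] if coefficients is None else list(coefficients)
        A = [np.zeros((self.n_nodes, self.n_nodes)) for _ in range(self.max_lag)]
        np.fill_diagonal(A[0], self.self_decay)
        for (s, t, l, _), c in zip(self.edges, coefs):
            A[l - 1][t, s] += c
        return A

    @property
    def adjacency(self) -> np.ndarray:
        """Boolean planted adjacency: entry (i, j) true iff an edge i -> j exists."""
        adj = np.zeros((self.n_nodes, self.n_nodes), dtype=bool)
        for (s, t, _, _) in self.edges:
            adj[s, t] = True
        return adj


@dataclasses.dataclass(frozen=True)
class ScoreSpec:
    """Behavioral score model: linear in planted edge strengths plus covariates.

    score = intercept + sum_e weight_e * coefficient_e(subject)
            + age_effect * (age - 29) + sex_effect * sex + N(0, noise_sd^2)
    """

    predictive_edges: tuple[Edge, ...]
    weights: tuple[float, ...]
    intercept: float = 100.0
    age_effect: float = 0.2
    sex_effect: float = 1.0
    noise_sd: float = 1.0

    def __post_init__(self):
        if len(self.predictive_edges) != len(self.weights):
            raise ValidationError("one weight per predictive edge required")


def is_stationary(coeff_matrices: Sequence[np.ndarray]) -> bool:
    return _spectral_radius(coeff_matrices) < 1.0


def _spectral_radius(coeff_matrices: Sequence[np.ndarray]) -> float:
    return float(np.abs(np.linalg.eigvals(_companion(coeff_matrices))).max())


def _companion(coeff_matrices: Sequence[np.ndarray]) -> np.ndarray:
    p = len(coeff_matrices)
    N = coeff_matrices[0].shape[0]
    C = np.zeros((N * p, N * p))
    C[:N] = np.hstack(coeff_matrices)
    if p > 1:
        C[N:, :N * (p - 1)] = np.eye(N * (p - 1))
    return C


# ---------------------------------------------------------------------------
# panel and score simulation
# ---------------------------------------------------------------------------

def _simulate_var(coeffs: list[np.ndarray], noise_sd: float, T: int,
                  rng: np.random.Generator) -> np.ndarray:
    p = len(coeffs)
    N = coeffs[0].shape[0]
    total = T + _BURN_IN
    x = np.zeros((total, N))
    e = rng.normal(scale=noise_sd, size=(total, N))
    for t in range(p, total):
        acc = e[t]
        for l, A in enumerate(coeffs, start=1):
            acc = acc + A @ x[t - l]
        x[t] = acc
    return x[_BURN_IN:]


def simulate_panel(spec: NetworkSpec, n_subjects: int, T: int = 1200, n_runs: int = 4,
                   seed: int | np.random.Generator = 0
                   ) -> tuple[dict[str, TimeSeriesPanel], pd.DataFrame]:
    """Simulate per-subject VAR panels with jittered edge coefficients.

    Each run is an independent stationary realization of length ``T`` (after
    burn-in); runs are concatenated with recorded boundaries.  Returns the
    panels keyed by subject id and a table of each subject's realized edge
    coefficients (one row per subject, one column per planted edge).
    """
    rng = np.random.default_rng(seed)
    panels: dict[str, TimeSeriesPanel] = {}
    base = np.array([c for (_, _, _, c) in spec.edges])
    rows = []
    groups = np.asarray(spec.gain_groups if spec.gain_groups is not None
                        else np.zeros(len(spec.edges), dtype=int))
    n_groups = int(groups.max()) + 1 if groups.size else 1
    for k in range(n_subjects):
        sid = f"sub{k:04d}"
        for attempt in range(_JITTER_RETRIES):
            gains = np.maximum(1.0 + rng.normal(scale=spec.coupling_gain_sd,
                                                size=n_groups), 0.05)
            coefs = gains[groups] * (base + rng.normal(scale=spec.coefficient_jitter_sd,
                                                       size=base.shape))
            A = spec.coefficient_matrices(coefs)
            if is_stationary(A):
                break
        else:
            raise ValidationError(
                f"subject {sid}: no stationary coefficient draw in {_JITTER_RETRIES} tries"
            )
        runs = [_simulate_var(A, spec.noise_sd, T, rng) for _ in range(n_runs)]
        boundaries = tuple(np.arange(n_runs) * T)
        panels[sid] = TimeSeriesPanel(subject_id=sid, data=np.vstack(runs),
                                      run_boundaries=boundaries)
        rows.append(coefs)
    columns = [f"e{s}_{t}_l{l}" for (s, t, l, _) in spec.edges]
    truth = pd.DataFrame(rows, index=list(panels), columns=columns)
    truth.index.name = "subject_id"
    return panels, truth


def simulate_scores(score_spec: ScoreSpec, network: NetworkSpec, truth: pd.DataFrame,
                    seed: int | np.random.Generator = 0) -> pd.DataFrame:
    """Generate the behavioral table from the subjects' true edge strengths.

    Age is drawn uniformly on 22..36 years, sex Bernoulli(0.5), and head
    motion from a small positive lognormal so the motion-exclusion rule has
    something to act on.  With ``noise_sd`` zero the score is an exact linear
    function of the planted strengths and covariates.
    """
    rng = np.random.default_rng(seed)
    edge_cols = []
    for e in score_spec.predictive_edges:
        if e not in network.edges:
            raise ValidationError(f"predictive edge {e} is not a planted network edge")
        s, t, l, _ = e
        edge_cols.append(f"e{s}_{t}_l{l}")
    K = len(truth)
    age = rng.integers(22, 37, size=K).astype(float)
    sex = rng.integers(0, 2, size=K)
    strengths = truth[edge_cols].to_numpy()
    w = np.asarray(score_spec.weights)
    score = (
        score_spec.intercept
        + strengths @ w
        + score_spec.age_effect * (age - 29.0)
        + score_spec.sex_effect * sex
        + rng.normal(scale=score_spec.noise_sd, size=K)
    )
    head_motion = rng.lognormal(mean=np.log(0.06), sigma=0.4, size=K)
    return pd.DataFrame(
        {
            "subject_id": truth.index,
            "score": score,
            "age": age,
            "sex": np.where(sex == 1, "male", "female"),
            "head_motion": head_motion,
        }
    ).reset_index(drop=True)


# ---------------------------------------------------------------------------
# default testbed
# ---------------------------------------------------------------------------

def default_network(n_nodes: int = 20, n_edges: int = 30, seed: int = 12345,
                    coef_range: tuple[float, float] = (0.2, 0.5),
                    lags: Sequence[int] = (1, 2, 3)) -> NetworkSpec:
    """Desk-scale testbed: bipartite driver->receiver graph, 20 nodes, 30 edges.

    The first half of the nodes are drivers (autonomous AR(1) sources), the
    second half receivers; edges run only from drivers to receivers, so the
    planted adjacency coincides with the set of non-zero pairwise flows.
    Edges are split round-robin into three latent gain groups; a score model
    built on one group (see :func:`default_score_spec`) then has coherent,
    individually detectable predictive edges while the other groups vary
    independently of the score.
    """
    rng = np.random.default_rng(seed)
    drivers = np.arange(n_nodes // 2)
    receivers = np.arange(n_nodes // 2, n_nodes)
    pairs = [(int(s), int(t)) for s in drivers for t in receivers]
    chosen = rng.choice(len(pairs), size=n_edges, replace=False)
    edges = []
    for idx in chosen:
        s, t = pairs[idx]
        l = int(rng.choice(lags))
        c = float(rng.uniform(*coef_range)) * float(rng.choice([-1.0, 1.0]))
        edges.append((s, t, l, c))
    groups = tuple(int(i % 3) for i in range(n_edges))
    return NetworkSpec(n_nodes=n_nodes, edges=tuple(edges), gain_groups=groups)


def default_score_spec(network: NetworkSpec, n_predictive: int = 10,
                       population_r2: float = 0.3, seed: int = 12345) -> ScoreSpec:
    """Score model on a planted subset of edges, noise set for a target R².

    The predictive set is drawn from the network's first gain group, so its
    edges co-vary across subjects (a behaviorally coherent circuit) while
    edges of other groups stay score-independent.  Weights are
    sign(coefficient): every predictive edge contributes its absolute
    strength.  With gain sd g, jitter sd s and C the summed absolute base
    coefficients of the predictive set, the explainable score variance is
    g^2 C^2 + (1 + g^2) n s^2; the noise standard deviation is fixed so the
    population strength-level R^2 equals ``population_r2``.
    """
    rng = np.random.default_rng(seed)
    if network.gain_groups is not None:
        pool = [i for i, g in enumerate(network.gain_groups) if g == 0]
    else:
        pool = list(range(len(network.edges)))
    if n_predictive > len(pool):
        raise ValidationError("n_predictive exceeds the coherent edge pool")
    chosen = rng.choice(pool, size=n_predictive, replace=False)
    edges = tuple(network.edges[i] for i in chosen)
    weights = tuple(np.sign(e[3]) * 1.0 for e in edges)
    c_sum = float(sum(abs(e[3]) for e in edges))
    g2 = network.coupling_gain_sd ** 2
    s2 = network.coefficient_jitter_sd ** 2
    signal_var = g2 * c_sum ** 2 + (1 + g2) * n_predictive * s2
    noise_sd = float(np.sqrt(signal_var * (1 - population_r2) / population_r2))
    return ScoreSpec(predictive_edges=edges, weights=weights, noise_sd=noise_sd)


def mock_atlas(n_nodes: int, n_regions: int = 18, n_networks: int = 8) -> Atlas:
    """Round-robin assignment of nodes to mock regions, networks, hemispheres."""
    regions = np.array([f"region{(i % n_regions) + 1:02d}" for i in range(n_nodes)])
    networks = np.array([f"network{(i % n_networks) + 1}" for i in range(n_nodes)])
    hemis = np.array(["L" if i % 2 == 0 else "R" for i in range(n_nodes)])
    return Atlas(node_id=np.arange(1, n_nodes + 1), region=regions,
                 network=networks, hemisphere=hemis)


# ---------------------------------------------------------------------------
# population (Yule-Walker) oracle
# ---------------------------------------------------------------------------

def var_autocovariance(coeff_matrices: Sequence[np.ndarray], sigma: np.ndarray,
                       max_lag: int) -> np.ndarray:
    """Exact autocovariances Gamma_h = Cov(x_t, x_{t-h}) of a stationary VAR.

    Solves the companion-form discrete Lyapunov equation for Gamma_0..p-1 and
    extends with the Yule-Walker recursion Gamma_h = sum_i A_i Gamma_{h-i}.
    """
    if not is_stationary(coeff_matrices):
        raise ValidationError("autocovariance undefined: process is not stationary")
    p = len(coeff_matrices)
    N = sigma.shape[0]
    C = _companion(coeff_matrices)
    Q = np.zeros_like(C)
    Q[:N, :N] = sigma
    P = scipy.linalg.solve_discrete_lyapunov(C, Q)
    gammas = [P[:N, k * N:(k + 1) * N] for k in range(p)]
    for h in range(p, max_lag + 1):
        gammas.append(sum(A @ gammas[h - i] for i, A in enumerate(coeff_matrices, start=1)))
    return np.stack(gammas[: max_lag + 1])


def _pair_cov(gammas: np.ndarray, i: int, j: int, h: int) -> float:
    """Cov(node_i at time t, node_j at time t-h) for signed h."""
    if h >= 0:
        return float(gammas[h][i, j])
    return float(gammas[-h][j, i])


def population_pairwise_f(gammas: np.ndarray, source: int, target: int, lag: int
                          ) -> float:
    """Population Geweke feedback source -> target at a finite lag, in nats.

    Computes the linear projection of the target on its own ``lag`` past
    values (restricted) and on the joint past of both series (full) directly
    from the exact autocovariances; the feedback is the log ratio of the two
    projection error variances.  This is the quantity the OLS estimator
    converges to as T grows.
    """
    c0 = _pair_cov(gammas, target, target, 0)
    # restricted: Toeplitz Yule-Walker system in the target's own autocovariances
    auto = np.array([_pair_cov(gammas, target, target, h) for h in range(lag + 1)])
    R = scipy.linalg.toeplitz(auto[:lag])
    r = auto[1:lag + 1]
    t1 = c0 - r @ np.linalg.solve(R, r)
    # full: predictors are lags 1..lag of source then target
    m = 2 * lag
    M = np.empty((m, m))
    g = np.empty(m)
    nodes = [source] * lag + [target] * lag
    offsets = list(range(1, lag + 1)) * 2
    for a in range(m):
        g[a] = _pair_cov(gammas, target, nodes[a], offsets[a])
        for b in range(m):
            M[a, b] = _pair_cov(gammas, nodes[a], nodes[b], offsets[b] - offsets[a])
    t2 = c0 - g @ np.linalg.solve(M, g)
    if t1 <= 0 or t2 <= 0:
        raise ValidationError("non-positive projection variance: degenerate process")
    return float(np.log(t1 / t2))


def population_flow_matrix(spec: NetworkSpec, lag: int = 1) -> np.ndarray:
    """Population pairwise feedback for every ordered node pair of a network."""
    A = spec.coefficient_matrices()
    sigma = spec.noise_sd ** 2 * np.eye(spec.n_nodes)
    gammas = var_autocovariance(A, sigma, max_lag=lag + len(A))
    N = spec.n_nodes
    out = np.zeros((N, N))
    for i in range(N):
        for j in range(N):
            if i != j:
                out[i, j] = population_pairwise_f(gammas, i, j, lag)
    return out
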