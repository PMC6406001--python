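"""Group-level aggregation of subject flow matrices.

Stacks per-subject F/p matrices, performs the average-p edge selection
(select i -> j when the mean p-value across subjects is at or below alpha),
collapses flow and variance maps onto anatomic-region or functional-network
partitions, and tests directionality and variability contrasts with
family-wise error control (Holm step-down).

The diagonal is excluded from every statistic; all aggregation operators are
permutation-equivariant in both subjects and nodes.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .atlas_io import Atlas, FlowMatrix
from .errors import DimensionError, ValidationError


@dataclasses.dataclass
class GroupFlowStack:
    """Stacked subject flow matrices with elementwise group statistics.

    ``mean_p`` is the edge-selection feature: the average of each directed
    edge's p-value across subjects.  ``var_f`` is the unbiased (K-1 divisor)
    between-subject variance of F.
    """

    subjects: list[str]
    f_stack: np.ndarray       # [K, N, N]
    p_stack: np.ndarray       # [K, N, N]

    def __post_init__(self):
        if self.f_stack.shape != self.p_stack.shape:
            raise DimensionError("F and p stacks must share one shape")
        if self.f_stack.ndim != 3 or self.f_stack.shape[1] != self.f_stack.shape[2]:
            raise DimensionError("stacks must be [subjects, N, N]")
        if len(self.subjects) != self.f_stack.shape[0]:
            raise DimensionError("subject list does not match stack depth")
        if len(set(self.subjects)) != len(self.subjects):
            raise ValidationError("duplicate subject_id in group stack")
        if self.n_subjects < 2:
            raise ValidationError("need at least two subjects")

    @property
    def n_subjects(self) -> int:
        return self.f_stack.shape[0]

    @property
    def n_nodes(self) -> int:
        return self.f_stack.shape[1]

    @property
    def _off(self) -> np.ndarray:
        return ~np.eye(self.n_nodes, dtype=bool)

    @property
    def mean_p(self) -> np.ndarray:
        m = self.p_stack.mean(axis=0)
        np.fill_diagonal(m, 1.0)
        return m

    @property
    def mean_f(self) -> np.ndarray:
        m = self.f_stack.mean(axis=0)
        np.fill_diagonal(m, 0.0)
        return m

    @property
    def var_f(self) -> np.ndarray:
        v = self.f_stack.var(axis=0, ddof=1)
        np.fill_diagonal(v, 0.0)
        return v


@dataclasses.dataclass
class PartitionSummary:
    """Flow matrix collapsed onto partition units (regions or networks).

    ``total_flow[a, b]`` sums entries from nodes of unit a to nodes of unit b
    (within-unit cells count ordered node pairs i != j); ``average_flow``
    divides each cell by its contributing ordered-pair count.  ``net`` is
    afferent minus efferent between-unit total flow and sums to zero exactly.
    """

    units: list[str]
    total_flow: np.ndarray
    average_flow: np.ndarray
    pair_counts: np.ndarray
    afferent: np.ndarray
    efferent: np.ndarray
    net: np.ndarray
    edge_count: np.ndarray | None = None     # selected edges per cell, if a mask was given


@dataclasses.dataclass
class VariabilityReport:
    """Between-subject variability aggregates per partition unit.

    ``unit_table`` has one row per unit with afferent/efferent variability
    ratios against the whole-brain average and Holm-adjusted significance;
    ``logratio`` is the antisymmetric matrix ln(mean var A->B) - ln(mean var
    B->A) with Holm-adjusted p-values in ``p_fwe``.
    """

    unit_table: pd.DataFrame
    logratio: np.ndarray
    p_fwe: np.ndarray
    units: list[str]


# ---------------------------------------------------------------------------


def stack_group(flows: Mapping[str, FlowMatrix] | Iterable[FlowMatrix]) -> GroupFlowStack:
    """Stack subject flow matrices (same N, same node order) into a group object."""
    if isinstance(flows, Mapping):
        items = list(flows.values())
    else:
        items = list(flows)
    if not items:
        raise ValidationError("empty flow collection")
    n = items[0].n_nodes
    for fm in items:
        if fm.n_nodes != n:
            raise DimensionError(
                f"subject {fm.subject_id}: {fm.n_nodes} nodes, expected {n}"
            )
    return GroupFlowStack(
        subjects=[fm.subject_id for fm in items],
        f_stack=np.stack([fm.f for fm in items]),
        p_stack=np.stack([fm.p for fm in items]),
    )


def step1_select(stack: GroupFlowStack, alpha: float = 0.05) -> np.ndarray:
    """Boolean mask of edges whose average p-value is at or below alpha.

    The threshold is inclusive (mean p exactly alpha selects the edge); the
    diagonal is always false.
    """
    if not (0 <= alpha < 1):
        raise ValidationError("alpha must lie in [0, 1)")
    mask = stack.mean_p <= alpha
    np.fill_diagonal(mask, False)
    return mask


def _unit_membership(atlas: Atlas, partition: str) -> tuple[list[str], list[np.ndarray]]:
    labels = atlas.labels(partition)
    units = list(dict.fromkeys(labels.tolist()))
    return units, [np.flatnonzero(labels == u) for u in units]


def summarize_partition(matrix: np.ndarray, atlas: Atlas, partition: str = "network",
                        mask: np.ndarray | None = None) -> PartitionSummary:
    """Collapse an N x N directed matrix onto partition units.

    ``matrix`` is any per-edge map (mean F, selected mean F, variance...).
    When ``mask`` is given, ``edge_count`` reports selected edges per cell.
    """
    matrix = np.asarray(matrix, dtype=float)
    if matrix.shape[0] != atlas.n_nodes:
        raise DimensionError("matrix does not match atlas node count")
    units, members = _unit_membership(atlas, partition)
    P = len(units)
    total = np.zeros((P, P))
    counts = np.zeros((P, P), dtype=int)
    edge_count = np.zeros((P, P), dtype=int) if mask is not None else None
    off = ~np.eye(atlas.n_nodes, dtype=bool)
    for a, rows in enumerate(members):
        for b, cols in enumerate(members):
            cell = matrix[np.ix_(rows, cols)]
            valid = off[np.ix_(rows, cols)]
            total[a, b] = cell[valid].sum()
            counts[a, b] = int(valid.sum())
            if edge_count is not None:
                edge_count[a, b] = int(mask[np.ix_(rows, cols)][valid].sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        average = np.where(counts > 0, total / np.maximum(counts, 1), 0.0)
    between = total.copy()
    np.fill_diagonal(between, 0.0)
    afferent = between.sum(axis=0)
    efferent = between.sum(axis=1)
    return PartitionSummary(
        units=units, total_flow=total, average_flow=average, pair_counts=counts,
        afferent=afferent, efferent=efferent, net=afferent - efferent,
        edge_count=edge_count,
    )


def directionality_anova(stack: GroupFlowStack, atlas: Atlas, partition: str = "network",
                         mask: np.ndarray | None = None) -> pd.DataFrame:
    """Directionality test per unordered unit pair {A, B}.

    Compares each subject's mean A->B flow against the subjects' mean B->A
    flows with a one-way ANOVA (two groups, so equivalent to a two-sample
    t-test); p-values are Holm-adjusted across all unit pairs.  Subjects are
    the independent replicates.  When a selection ``mask`` is given, only
    selected edges contribute to the per-subject means; a pair with no
    selected edge in either direction is excluded from the family.
    """
    if stack.n_subjects < 3:
        raise ValidationError("directionality test needs at least three subjects")
    units, members = _unit_membership(atlas, partition)
    use = mask if mask is not None else stack._off
    rows = []
    for a in range(len(units)):
        for b in range(a + 1, len(units)):
            ab = np.zeros_like(use)
            ab[np.ix_(members[a], members[b])] = True
            ab &= use
            ba = np.zeros_like(use)
            ba[np.ix_(members[b], members[a])] = True
            ba &= use
            if not ab.any() and not ba.any():
                continue
            flows_ab = stack.f_stack[:, ab].mean(axis=1) if ab.any() else np.zeros(stack.n_subjects)
            flows_ba = stack.f_stack[:, ba].mean(axis=1) if ba.any() else np.zeros(stack.n_subjects)
            _, p = stats.f_oneway(flows_ab, flows_ba)
            rows.append(
                {
                    "unit_a": units[a], "unit_b": units[b],
                    "mean_diff": float(flows_ab.mean() - flows_ba.mean()),
                    "p": float(p) if np.isfinite(p) else 1.0,
                }
            )
    df = pd.DataFrame(rows)
    if not df.empty:
        df["p_fwe"] = multipletests(df["p"], method="holm")[1]
    return df


def variability_ratios(stack: GroupFlowStack, atlas: Atlas, partition: str = "network",
                       mask: np.ndarray | None = None) -> VariabilityReport:
    """Variability of directed flow per unit against the whole brain.

    The afferent (efferent) ratio of a unit is the mean between-subject
    variance of edges into (out of) the unit divided by the mean variance
    over all off-diagonal edges; the whole-brain denominator includes the
    unit's own edges.  The between-unit log-ratio is ln(mean var A->B) -
    ln(mean var B->A), exactly antisymmetric.  Per-comparison significance
    is a one-way ANOVA on the per-edge variances, Holm-adjusted.
    """
    var = stack.var_f
    use = mask if mask is not None else stack._off
    units, members = _unit_membership(atlas, partition)
    P = len(units)
    global_vals = var[use]
    global_mean = float(global_vals.mean())
    if global_mean <= 0:
        raise ValidationError("zero whole-brain variance: ratios undefined")
    node_in_unit = np.zeros(atlas.n_nodes, dtype=int)
    for u, rows in enumerate(members):
        node_in_unit[rows] = u

    rows_out = []
    ps = []
    for u in range(P):
        into = np.zeros_like(use)
        into[:, members[u]] = True
        into &= use
        outof = np.zeros_like(use)
        outof[members[u], :] = True
        outof &= use
        aff_vals, eff_vals = var[into], var[outof]
        aff_ratio = float(aff_vals.mean() / global_mean) if aff_vals.size else np.nan
        eff_ratio = float(eff_vals.mean() / global_mean) if eff_vals.size else np.nan
        p_aff = stats.f_oneway(aff_vals, global_vals)[1] if aff_vals.size > 1 else np.nan
        p_eff = stats.f_oneway(eff_vals, global_vals)[1] if eff_vals.size > 1 else np.nan
        rows_out.append({"unit": units[u], "afferent_ratio": aff_ratio,
                         "efferent_ratio": eff_ratio,
                         "p_afferent": float(p_aff), "p_efferent": float(p_eff)})
    unit_table = pd.DataFrame(rows_out)
    for col in ("p_afferent", "p_efferent"):
        ok = unit_table[col].notna()
        adj = np.full(len(unit_table), np.nan)
        if ok.any():
            adj[ok.to_numpy()] = multipletests(unit_table.loc[ok, col], method="holm")[1]
        unit_table[col + "_fwe"] = adj

    logratio = np.zeros((P, P))
    praw = np.full((P, P), np.nan)
    for a in range(P):
        for b in range(a + 1, P):
            ab = np.zeros_like(use)
            ab[np.ix_(members[a], members[b])] = True
            ab &= use
            ba = np.zeros_like(use)
            ba[np.ix_(members[b], members[a])] = True
            ba &= use
            va, vb = var[ab], var[ba]
            if va.size == 0 or vb.size == 0 or va.mean() <= 0 or vb.mean() <= 0:
                continue     # not-applicable cell
            lr = float(np.log(va.mean()) - np.log(vb.mean()))
            logratio[a, b], logratio[b, a] = lr, -lr
            if va.size > 1 and vb.size > 1:
                praw[a, b] = praw[b, a] = stats.f_oneway(va, vb)[1]
    p_fwe = np.full((P, P), np.nan)
    iu = np.triu_indices(P, k=1)
    flat = praw[iu]
    ok = np.isfinite(flat)
    if ok.any():
        adj = np.full(flat.shape, np.nan)
        adj[ok] = multipletests(flat[ok], method="holm")[1]
        p_fwe[iu] = adj
        p_fwe.T[iu] = adj
    return VariabilityReport(unit_table=unit_table, logratio=logratio,
                             p_fwe=p_fwe, units=units)
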