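"""Undirected functional-connectivity baseline and its comparison to flow.

Functional connectivity (FC) is the plain Pearson correlation matrix of the
node time courses; it is symmetric and carries no directionality.  The
module quantifies how much of the directed-flow geography FC already
captures (correlating a per-node FC connectedness profile with the
afferent/efferent/net flow profiles) and runs the identical prediction
pipeline on FC edges so directed and undirected features can be compared
head to head.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import stats

from .atlas_io import Atlas, TimeSeriesPanel
from .cpm import CpmRegressor
from .errors import DimensionError, ValidationError
from .ggc import demean_per_run
from .group import GroupFlowStack


@dataclasses.dataclass
class FcMatrix:
    """Symmetric Pearson correlation matrix of one subject's node signals."""

    subject_id: str
    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise DimensionError("FC matrix must be square")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValidationError("FC matrix must be symmetric")
        self.values = v

    @property
    def n_nodes(self) -> int:
        return self.values.shape[0]


def fc_matrix(panel: TimeSeriesPanel) -> FcMatrix:
    """Pearson correlation over the per-run demeaned, concatenated samples."""
    data = demean_per_run(panel.data, panel.run_boundaries)
    sd = data.std(axis=0)
    dead = np.flatnonzero(sd == 0)
    if dead.size:
        raise ValidationError(
            f"panel {panel.subject_id}: constant node(s) {(dead + 1).tolist()} "
            "have undefined correlation"
        )
    c = np.corrcoef(data, rowvar=False)
    c = (c + c.T) / 2
    np.fill_diagonal(c, 1.0)
    return FcMatrix(subject_id=panel.subject_id, values=c)


def node_connectedness(mean_fc: np.ndarray, signed: bool = False) -> np.ndarray:
    """Per-node summary of FC: mean (absolute) off-diagonal correlation.

    The absolute value avoids cancellation between positive and negative
    correlations; set ``signed=True`` for the plain mean.
    """
    m = np.asarray(mean_fc, dtype=float)
    off = ~np.eye(m.shape[0], dtype=bool)
    vals = m if signed else np.abs(m)
    return np.array([vals[i, off[i]].mean() for i in range(m.shape[0])])


def compare_fc_flow(mean_fc: np.ndarray, stack: GroupFlowStack, atlas: Atlas,
                    signed: bool = False) -> dict[str, float]:
    """Correlate the FC connectedness profile with the flow profiles.

    Collapses the group-mean flow matrix to per-node afferent, efferent and
    net vectors (single-node units of the trivial partition) and returns the
    Pearson r of each against the per-node FC connectedness, plus r^2.
    """
    if mean_fc.shape[0] != stack.n_nodes or atlas.n_nodes != stack.n_nodes:
        raise DimensionError("FC, flow stack and atlas must share the node set")
    fc_vec = node_connectedness(mean_fc, signed=signed)
    mean_f = stack.mean_f
    afferent = mean_f.sum(axis=0)
    efferent = mean_f.sum(axis=1)
    out = {}
    for name, vec in (("afferent", afferent), ("efferent", efferent),
                      ("net", afferent - efferent)):
        r = float(stats.pearsonr(fc_vec, vec)[0]) if np.ptp(vec) > 0 else 0.0
        out[f"r_{name}"] = r
        out[f"r2_{name}"] = r ** 2
    return out


def fc_features(fcs: list[FcMatrix] | dict[str, FcMatrix]
                ) -> tuple[np.ndarray, np.ndarray]:
    """Subjects x edges matrix of upper-triangle FC values.

    Returns the features and an [E, 2] array of (i, j) node indices, i < j.
    """
    items = list(fcs.values()) if isinstance(fcs, dict) else list(fcs)
    n = items[0].n_nodes
    iu = np.triu_indices(n, k=1)
    feats = np.stack([fm.values[iu] for fm in items])
    return feats, np.column_stack(iu)


def fc_predict(features: np.ndarray, behavior: pd.DataFrame,
               p_step2: float = 0.005, sign: str = "positive") -> CpmRegressor:
    """Run the unchanged prediction pipeline on FC edge features."""
    est = CpmRegressor(p_step2=p_step2, sign=sign)
    est.fit(np.asarray(features, float), behavior=behavior)
    return est


def asymmetry_index(f: np.ndarray) -> float:
    """Relative asymmetry ||F - F^T|| / ||F|| (Frobenius); 0 for symmetric maps."""
    f = np.asarray(f, dtype=float)
    denom = np.linalg.norm(f)
    return float(np.linalg.norm(f - f.T) / denom) if denom > 0 else 0.0
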