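"""Input/output and indexing conventions for the information-flow pipeline.

All on-disk interfaces use 1-based node indices, matching the node numbering
of functional parcellation atlases.  Internally arrays are 0-based numpy.
Flow matrices follow the convention row = source, column = target:
entry (i, j) is the flow i -> j.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import DimensionError, ParseError, ValidationError

log = logging.getLogger(__name__)

HEMISPHERES = ("L", "R", "midline")


@dataclasses.dataclass(frozen=True)
class Atlas:
    """Node partition: anatomic region, functional network and hemisphere per node.

    ``node_id`` is a contiguous 1..N integer range.  Region and network label
    sets are closed: they are enumerated from the file that defined them.
    """

    node_id: np.ndarray          # int, 1..N
    region: np.ndarray           # str labels, hemisphere-tagged
    network: np.ndarray          # str labels
    hemisphere: np.ndarray       # "L" | "R" | "midline"

    def __post_init__(self):
        n = len(self.node_id)
        if sorted(self.node_id.tolist()) != list(range(1, n + 1)):
            raise ValidationError("node_ids must be the contiguous set 1..N without duplicates")
        for name in ("region", "network", "hemisphere"):
            if len(getattr(self, name)) != n:
                raise DimensionError(f"atlas column {name!r} has wrong length")
        bad = set(self.hemisphere) - set(HEMISPHERES)
        if bad:
            raise ValidationError(f"unknown hemisphere codes: {sorted(bad)}")

    @property
    def n_nodes(self) -> int:
        return len(self.node_id)

    @property
    def regions(self) -> list[str]:
        """Region labels in first-appearance order (closed set)."""
        return list(dict.fromkeys(self.region.tolist()))

    @property
    def networks(self) -> list[str]:
        return list(dict.fromkeys(self.network.tolist()))

    def labels(self, partition: str) -> np.ndarray:
        if partition == "region":
            return self.region
        if partition == "network":
            return self.network
        raise ValidationError(f"unknown partition {partition!r}; expected 'region' or 'network'")


@dataclasses.dataclass
class TimeSeriesPanel:
    """One subject's concatenated multivariate time series.

    ``run_boundaries`` holds 0-based start indices of each concatenated run,
    always beginning with 0 (files store them 1-based).
    """

    subject_id: str
    data: np.ndarray                     # [T_total, N]
    run_boundaries: tuple[int, ...] = (0,)
    sampling_interval: float = 0.72      # seconds per sample

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise DimensionError(f"panel {self.subject_id}: data must be 2-D (time x node)")
        if np.isnan(self.data).any():
            raise ValidationError(f"panel {self.subject_id}: NaN values present")
        rb = tuple(int(b) for b in self.run_boundaries)
        if not rb or rb[0] != 0 or list(rb) != sorted(set(rb)):
            raise ValidationError(
                f"panel {self.subject_id}: run boundaries must start at the first sample "
                "and be strictly increasing"
            )
        if rb[-1] >= self.n_times:
            raise ValidationError(f"panel {self.subject_id}: run boundary beyond end of data")
        self.run_boundaries = rb

    @property
    def n_times(self) -> int:
        return self.data.shape[0]

    @property
    def n_nodes(self) -> int:
        return self.data.shape[1]

    def run_slices(self) -> list[slice]:
        edges = list(self.run_boundaries) + [self.n_times]
        return [slice(s, e) for s, e in zip(edges[:-1], edges[1:])]


@dataclasses.dataclass
class FlowMatrix:
    """Asymmetric directed-flow result for one subject.

    ``f[i, j]`` is the Geweke feedback from node i to node j in nats;
    ``p`` the matching significance and ``lag`` the selected model order.
    """

    subject_id: str
    f: np.ndarray
    p: np.ndarray
    lag: np.ndarray

    def __post_init__(self):
        for name in ("f", "p", "lag"):
            a = np.asarray(getattr(self, name), dtype=float)
            if a.ndim != 2 or a.shape[0] != a.shape[1]:
                raise DimensionError(f"{name} layer must be square")
            setattr(self, name, a)
        if self.f.shape != self.p.shape or self.f.shape != self.lag.shape:
            raise DimensionError("f/p/lag layers must share one shape")

    @property
    def n_nodes(self) -> int:
        return self.f.shape[0]


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_atlas(path: str | Path) -> Atlas:
    """Read an atlas CSV with header ``node_id,region,network,hemisphere``."""
    df = pd.read_csv(path)
    required = {"node_id", "region", "network", "hemisphere"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: atlas file missing columns {sorted(missing)}")
    df = df.sort_values("node_id")
    return Atlas(
        node_id=df["node_id"].to_numpy(int),
        region=df["region"].to_numpy(str),
        network=df["network"].to_numpy(str),
        hemisphere=df["hemisphere"].to_numpy(str),
    )


def write_atlas(atlas: Atlas, path: str | Path) -> None:
    pd.DataFrame(
        {
            "node_id": atlas.node_id,
            "region": atlas.region,
            "network": atlas.network,
            "hemisphere": atlas.hemisphere,
        }
    ).to_csv(path, index=False)


def _read_matrix(path: Path) -> np.ndarray:
    rows: list[list[float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.split()
            try:
                rows.append([float(v) for v in fields])
            except ValueError as exc:
                raise ParseError(f"{path}: non-numeric value at row {lineno}") from exc
            if len(rows[-1]) != len(rows[0]):
                raise ParseError(f"{path}: row {lineno} has {len(rows[-1])} columns, expected {len(rows[0])}")
    if not rows:
        raise ParseError(f"{path}: empty matrix")
    return np.asarray(rows, dtype=float)


def read_panel(path: str | Path, atlas: Atlas, sampling_interval: float = 0.72
               ) -> dict[str, TimeSeriesPanel]:
    """Read all per-subject TSV matrices in a directory.

    Each ``<subject>.tsv`` is a header-less whitespace-delimited matrix with
    time down the rows and one column per atlas node.  An optional sidecar
    ``<subject>.runs.txt`` lists 1-based run start indices, one per line.
    """
    path = Path(path)
    panels: dict[str, TimeSeriesPanel] = {}
    for f in sorted(path.glob("*.tsv")):
        if f.name.endswith((".pvals.tsv", ".lags.tsv")):
            continue
        subject = f.stem
        data = _read_matrix(f)
        if data.shape[1] != atlas.n_nodes:
            raise DimensionError(
                f"{f}: {data.shape[1]} columns but atlas defines {atlas.n_nodes} nodes"
            )
        sidecar = f.with_suffix("").with_suffix(".runs.txt")
        if sidecar.exists():
            starts = [int(v) - 1 for v in sidecar.read_text().split()]
        else:
            starts = [0]
        panels[subject] = TimeSeriesPanel(
            subject_id=subject, data=data,
            run_boundaries=tuple(starts), sampling_interval=sampling_interval,
        )
        log.info("read panel %s: T_total=%d", subject, data.shape[0])
    return panels


def write_panel(panel: TimeSeriesPanel, directory: str | Path, fmt: str = "%.10g") -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    out = directory / f"{panel.subject_id}.tsv"
    np.savetxt(out, panel.data, fmt=fmt, delimiter="\t")
    if len(panel.run_boundaries) > 1:
        sidecar = directory / f"{panel.subject_id}.runs.txt"
        sidecar.write_text("\n".join(str(b + 1) for b in panel.run_boundaries) + "\n")
    return out


def read_behavior(path: str | Path) -> pd.DataFrame:
    """Read the behavioral table: ``subject_id,score,age,sex,head_motion``."""
    df = pd.read_csv(path, dtype={"subject_id": str})
    required = {"subject_id", "score", "age", "sex", "head_motion"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: behavior file missing columns {sorted(missing)}")
    validate_behavior(df)
    return df


def validate_behavior(df: pd.DataFrame) -> None:
    if df["subject_id"].duplicated().any():
        raise ValidationError("behavioral table has duplicate subject_ids")
    if (df["head_motion"] < 0).any():
        raise ValidationError("head_motion must be non-negative")


def write_behavior(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)


def write_flow(flow: FlowMatrix, directory: str | Path) -> None:
    """Write a subject's flow matrix as three TSV layers (F, p-values, lags)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    np.savetxt(directory / f"{flow.subject_id}.tsv", flow.f, fmt="%.17g", delimiter="\t")
    np.savetxt(directory / f"{flow.subject_id}.pvals.tsv", flow.p, fmt="%.17g", delimiter="\t")
    np.savetxt(directory / f"{flow.subject_id}.lags.tsv", flow.lag, fmt="%d", delimiter="\t")


def read_flow(directory: str | Path, subject_id: str) -> FlowMatrix:
    directory = Path(directory)
    return FlowMatrix(
        subject_id=subject_id,
        f=_read_matrix(directory / f"{subject_id}.tsv"),
        p=_read_matrix(directory / f"{subject_id}.pvals.tsv"),
        lag=_read_matrix(directory / f"{subject_id}.lags.tsv"),
    )


def read_flows(directory: str | Path) -> dict[str, FlowMatrix]:
    directory = Path(directory)
    subjects = sorted(
        f.stem for f in directory.glob("*.tsv")
        if not f.name.endswith((".pvals.tsv", ".lags.tsv"))
    )
    return {s: read_flow(directory, s) for s in subjects}


# ---------------------------------------------------------------------------
# subject exclusion
# ---------------------------------------------------------------------------

def exclude_by_motion(behavior: pd.DataFrame, threshold: float = 1.0) -> pd.DataFrame:
    """Drop subjects whose motion-to-score ratio exceeds the cutoff.

    A subject is excluded when ``(head_motion / score) * 1e3 > threshold``.
    Scores must be strictly positive, otherwise the ratio is undefined.
    The boundary case (ratio exactly equal to the threshold) is retained.
    """
    if (behavior["score"] <= 0).any():
        raise ValidationError("score must be > 0 for all subjects (motion ratio is undefined)")
    ratio = behavior["head_motion"] / behavior["score"] * 1e3
    kept = behavior.loc[ratio <= threshold].reset_index(drop=True)
    log.info("excluded %d of %d subjects by motion ratio", len(behavior) - len(kept), len(behavior))
    return kept


def check_expected_length(panels: Mapping[str, TimeSeriesPanel], expected: int | None
                          ) -> dict[str, TimeSeriesPanel]:
    """Drop subjects whose total sample count differs from the configured expectation."""
    if expected is None:
        return dict(panels)
    kept = {s: p for s, p in panels.items() if p.n_times == expected}
    dropped = sorted(set(panels) - set(kept))
    if dropped:
        log.info("dropped %d subjects with unexpected T_total: %s", len(dropped), dropped)
    return kept
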