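"""Core in-memory containers shared across the pipeline.

The pipeline operates on region-of-interest (ROI) time series: one
``nodes x scans`` matrix per subject, with every node assigned to exactly
one a-priori functional network by a :class:`NetworkAtlas`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["NetworkAtlas", "RoiTimeSeries", "QCReport"]


@dataclass(frozen=True)
class NetworkAtlas:
    """Assignment of every node to exactly one functional network.

    Parameters
    ----------
    node_ids
        Ordered node identifiers.
    network_of_node
        Mapping ``node_id -> network_name`` covering every node exactly once.
    """

    node_ids: tuple[str, ...]
    network_of_node: dict[str, str]

    def __post_init__(self) -> None:
        missing = [n for n in self.node_ids if n not in self.network_of_node]
        if missing:
            raise ValueError(f"nodes without a network assignment: {missing[:5]}")
        if len(set(self.node_ids)) != len(self.node_ids):
            raise ValueError("duplicate node ids in atlas")
        if len(self.networks) < 2:
            raise ValueError("atlas must define at least 2 networks")

    @property
    def networks(self) -> tuple[str, ...]:
        """Network names in order of first appearance."""
        seen: dict[str, None] = {}
        for n in self.node_ids:
            seen.setdefault(self.network_of_node[n], None)
        return tuple(seen)

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    def labels(self) -> np.ndarray:
        """Integer network label per node (index into :attr:`networks`)."""
        order = {name: i for i, name in enumerate(self.networks)}
        return np.array([order[self.network_of_node[n]] for n in self.node_ids])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"node_id": self.node_ids,
             "network_name": [self.network_of_node[n] for n in self.node_ids]}
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "NetworkAtlas":
        return cls(tuple(df["node_id"].astype(str)),
                   dict(zip(df["node_id"].astype(str), df["network_name"].astype(str))))

    def write(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def read(cls, path: str | Path) -> "NetworkAtlas":
        return cls.from_frame(pd.read_csv(path, sep="\t", dtype=str))


@dataclass
class RoiTimeSeries:
    """A subject's node-by-scan signal matrix with trial-onset annotations."""

    subject_id: str
    node_ids: tuple[str, ...]
    data: np.ndarray  # nodes x scans
    tr_seconds: float = 2.0
    repetition_onsets: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.repetition_onsets = np.asarray(self.repetition_onsets, dtype=int)
        if self.data.ndim != 2 or self.data.shape[0] != len(self.node_ids):
            raise ValueError("data must be nodes x scans matching node_ids")
        if self.data.shape[1] < 2:
            raise ValueError("need at least 2 scans")
        if np.isnan(self.data).any():
            raise ValueError("time series contains missing values")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")

    @property
    def n_nodes(self) -> int:
        return self.data.shape[0]

    @property
    def n_scans(self) -> int:
        return self.data.shape[1]

    def write(self, path: str | Path) -> None:
        """Tab-delimited: node ids in first column, scans as columns."""
        df = pd.DataFrame(self.data, index=list(self.node_ids))
        df.index.name = "node_id"
        df.to_csv(path, sep="\t", float_format="%.8g")

    @classmethod
    def read(cls, path: str | Path, subject_id: str | None = None,
             tr_seconds: float = 2.0,
             repetition_onsets: np.ndarray | None = None) -> "RoiTimeSeries":
        df = pd.read_csv(path, sep="\t", index_col="node_id")
        sid = subject_id if subject_id is not None else Path(path).stem
        onsets = repetition_onsets if repetition_onsets is not None else np.array([], dtype=int)
        return cls(sid, tuple(str(i) for i in df.index), df.to_numpy(float),
                   tr_seconds=tr_seconds, repetition_onsets=onsets)


@dataclass(frozen=True)
class QCReport:
    """Motion quality-control verdict for one subject."""

    subject_id: str
    fd_trace: np.ndarray
    spike_fraction: float
    excluded: bool

    def __post_init__(self) -> None:
        if not 0.0 <= self.spike_fraction <= 1.0:
            raise ValueError("spike_fraction must lie in [0, 1]")
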