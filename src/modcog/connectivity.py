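"""Weighted functional-connectivity graphs from censored node time series."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DegenerateInputError, FormatError, ParameterError
from .preprocess import NodeTimeSeries, TemporalMask

__all__ = ["ConnectivityMatrix", "correlation_matrix", "prepare_for_modularity"]

NEGATIVE_POLICIES = ("zeroed", "retained", "absolute")


@dataclass
class ConnectivityMatrix:
    """Symmetric weighted adjacency over nodes with zero diagonal.

    ``negative_policy`` records how negative correlations were handled
    (``raw`` until :func:`prepare_for_modularity` is applied).
    """

    weights: np.ndarray
    node_ids: list[str] = field(default=None)  # type: ignore[assignment]
    negative_policy: str = "raw"

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.ndim != 2 or self.weights.shape[0] != self.weights.shape[1]:
            raise FormatError("weights must be a square matrix")
        if not np.allclose(self.weights, self.weights.T, atol=1e-12):
            raise FormatError("weights must be symmetric (tolerance 1e-12)")
        self.weights = 0.5 * (self.weights + self.weights.T)
        if np.abs(np.diag(self.weights)).max(initial=0.0) > 0:
            raise FormatError("diagonal must be exactly zero")
        if self.node_ids is None:
            self.node_ids = [f"n{i:03d}" for i in range(self.weights.shape[0])]
        else:
            self.node_ids = [str(n) for n in self.node_ids]
        if len(self.node_ids) != self.weights.shape[0]:
            raise FormatError("node_ids length does not match matrix size")

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]

    @property
    def total_weight(self) -> float:
        """Sum over all ordered node pairs (2m in modularity notation)."""
        return float(self.weights.sum())


def correlation_matrix(
    ts: NodeTimeSeries, mask: TemporalMask | None = None
) -> ConnectivityMatrix:
    """Pearson correlation over kept frames, diagonal zeroed.

    Invariant to affine rescaling of any node's signal. Requires at least
    3 surviving frames and nonzero variance on every node.
    """
    if mask is not None:
        if mask.n_frames != ts.n_frames:
            raise FormatError("mask and time series frame counts differ")
        values = ts.values[mask.kept]
    else:
        values = ts.values
    if values.shape[0] < 3:
        raise DegenerateInputError(
            f"only {values.shape[0]} frames survive censoring; need >= 3"
        )
    sd = values.std(axis=0)
    dead = np.flatnonzero(sd == 0)
    if dead.size:
        names = [ts.node_ids[i] for i in dead]
        raise DegenerateInputError(f"zero-variance node(s) on kept frames: {names}")
    if values.shape[1] == 1:
        w = np.zeros((1, 1))
    else:
        w = np.corrcoef(values, rowvar=False)
        w = np.clip(0.5 * (w + w.T), -1.0, 1.0)
        np.fill_diagonal(w, 0.0)
    return ConnectivityMatrix(w, list(ts.node_ids), negative_policy="raw")


def prepare_for_modularity(
    cm: ConnectivityMatrix, negative_policy: str = "zeroed"
) -> ConnectivityMatrix:
    """Apply a negative-weight policy ahead of modularity maximization.

    The configuration null model is defined for non-negative weights, so the
    default zeroes negative correlations; ``absolute`` takes magnitudes, and
    ``retained`` keeps signed weights (non-standard: the null term downstream
    then uses positive weights only).
    """
    if negative_policy not in NEGATIVE_POLICIES:
        raise ParameterError(
            f"negative_policy must be one of {NEGATIVE_POLICIES}, got {negative_policy!r}"
        )
    w = cm.weights.copy()
    if negative_policy == "zeroed":
        w[w < 0] = 0.0
    elif negative_policy == "absolute":
        w = np.abs(w)
    if np.maximum(w, 0).sum() <= 0:
        raise DegenerateInputError(
            f"matrix has no positive weight after '{negative_policy}' policy; no graph"
        )
    return ConnectivityMatrix(w, list(cm.node_ids), negative_policy=negative_policy)
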