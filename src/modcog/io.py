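"""Plain-text interchange formats (TSV/JSON) for every pipeline stage.

Column layouts are documented in docs/FORMATS.md; frames are 0-based.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .community import QProfile
from .connectivity import ConnectivityMatrix
from .errors import FormatError
from .preprocess import MotionParams, NodeTimeSeries, TemporalMask
from .synthetic_data import MOTION_COLUMNS

__all__ = [
    "read_timeseries_tsv",
    "read_motion_tsv",
    "read_cohort_table",
    "write_mask_tsv",
    "write_matrix_tsv",
    "read_matrix_tsv",
    "write_qprofile_tsv",
    "read_q_median_tsv",
]


def read_timeseries_tsv(path, tr_seconds: float) -> NodeTimeSeries:
    """Frames x nodes TSV with a header row of node ids."""
    df = pd.read_csv(path, sep="\t")
    return NodeTimeSeries(df.to_numpy(dtype=float), tr_seconds, list(df.columns))


def read_motion_tsv(path) -> MotionParams:
    """Frames x 6 TSV (trans_*_mm, rot_*_rad)."""
    df = pd.read_csv(path, sep="\t")
    if list(df.columns) != MOTION_COLUMNS:
        raise FormatError(
            f"{path}: expected motion columns {MOTION_COLUMNS}, got {list(df.columns)}"
        )
    return MotionParams(df.to_numpy(dtype=float))


def read_cohort_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if not {"subject", "group"}.issubset(df.columns):
        raise FormatError(f"{path}: cohort table needs subject and group columns")
    return df


def write_mask_tsv(path, mask: TemporalMask) -> None:
    """Per-frame mask: frame, kept, flagged_fd, flagged_dvars (0/1 flags)."""
    n = mask.n_frames
    df = pd.DataFrame(
        {
            "frame": np.arange(n),
            "kept": mask.kept.astype(int),
            "flagged_fd": [int(i in mask.flagged_fd) for i in range(n)],
            "flagged_dvars": [int(i in mask.flagged_dvars) for i in range(n)],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def write_matrix_tsv(path, cm: ConnectivityMatrix) -> None:
    """Square matrix with node ids as header row and index column."""
    df = pd.DataFrame(cm.weights, index=cm.node_ids, columns=cm.node_ids)
    df.to_csv(path, sep="\t", float_format="%.8f")


def read_matrix_tsv(path) -> ConnectivityMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return ConnectivityMatrix(df.to_numpy(dtype=float), list(df.columns))


def write_qprofile_tsv(runs_path, median_path, profile: QProfile) -> None:
    """Long run table (gamma, run, q) and the per-gamma medians."""
    rows = [
        {"gamma": g, "run": r, "q": q}
        for g in profile.gammas
        for r, q in enumerate(profile.q_runs[g])
    ]
    # full precision so cached reloads reproduce downstream fits exactly
    pd.DataFrame(rows).to_csv(runs_path, sep="\t", index=False, float_format="%.17g")
    med = pd.DataFrame(
        {"gamma": profile.gammas, "median_q": [profile.medians[g] for g in profile.gammas]}
    )
    med.to_csv(median_path, sep="\t", index=False, float_format="%.17g")


def read_q_median_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if not {"gamma", "median_q"}.issubset(df.columns):
        raise FormatError(f"{path}: expected columns gamma, median_q")
    return df


def write_partition_tsv(path, node_ids, partition) -> None:
    pd.DataFrame({"node_id": node_ids, "community": partition.assignment}).to_csv(
        path, sep="\t", index=False
    )


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
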