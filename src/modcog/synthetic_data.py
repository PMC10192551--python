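"""Synthetic two-arm pre/post cohorts with planted modular structure.

Generates everything the analysis pipeline consumes: per-subject,
per-session node time series drawn from a block-modular Gaussian whose
within-module correlation increases at post for the intervention (AE) arm
only; six-parameter motion traces with Bernoulli displacement spikes; and a
correlated seven-task executive-function battery with configurable
group-by-time effects and pre-to-post autocorrelation.

The generator's defaults mirror the design it emulates: two arms of 90
subjects, 264 nodes, 180 frames at TR = 2 s, and task means/SDs on the raw
scale (reaction-time-like units) so that downstream studentization is
nontrivial. Ground truth (module assignment, spike frames, planted effects)
is stored for recovery tests.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ParameterError
from .preprocess import MotionParams, NodeTimeSeries

__all__ = [
    "TASK_NAMES",
    "TASK_BASELINES",
    "CohortSpec",
    "SyntheticCohort",
    "module_assignment",
    "block_covariance",
    "simulate_timeseries",
    "simulate_motion",
    "simulate_task_scores",
    "make_cohort",
    "write_cohort",
]

#: The seven executive-function measures, in battery order.
TASK_NAMES = (
    "spatial_wm_rt",
    "two_back_rt",
    "task_switch_cost",
    "trails_b_time",
    "flanker_incongruent_rt",
    "digit_symbol_count",
    "meps_steps",
)

#: Raw-scale (mean, SD) per task, calibrated to typical older-adult values
#: (control-arm pre-intervention descriptives).
TASK_BASELINES = {
    "spatial_wm_rt": (998.9, 163.2),
    "two_back_rt": (859.5, 197.0),
    "task_switch_cost": (504.5, 280.3),
    "trails_b_time": (76.68, 36.6),
    "flanker_incongruent_rt": (813.0, 111.7),
    "digit_symbol_count": (64.5, 12.8),
    "meps_steps": (9.8, 4.9),
}

GROUPS = ("AE", "UAA")
SESSIONS = ("pre", "post")


def _substream_seed(master_seed: int, *tags) -> int:
    """Stable child seed below 2**31 from a master seed and string tags.

    Uses CRC32 of the joined tags so each (subject, session) keeps its
    stream when the cohort is resized.
    """
    h = zlib.crc32(":".join(str(t) for t in tags).encode())
    ss = np.random.SeedSequence([int(master_seed), h])
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class CohortSpec:
    """Parameters of a synthetic cohort; validated at construction.

    ``task_effect_sizes`` are standardized group-by-time shifts (in units of
    each task's raw SD) applied to the AE arm at post; the default plants a
    modest effect on the three updating tasks (spatial working memory,
    2-back, means-end problem solving).
    """

    n_per_group: int = 90
    n_nodes: int = 264
    n_modules: int = 10
    n_frames: int = 180
    tr_seconds: float = 2.0
    r_within_pre: float = 0.35
    r_between_pre: float = 0.10
    delta_r_within_post_AE: float = 0.10
    task_effect_sizes: tuple = (0.3, 0.3, 0.0, 0.0, 0.0, 0.0, 0.3)
    task_intercorrelation: float = 0.3
    prepost_autocorrelation: float = 0.7
    motion_spike_rate: float = 0.02
    spike_magnitude_mm: float = 2.0
    ar1: float = 0.0
    baseline_mean: float = 1000.0
    seed: int = 0

    def __post_init__(self):
        if self.n_per_group < 1 or self.n_nodes < 1 or self.n_frames < 2:
            raise ParameterError("cohort sizes must be positive (and n_frames >= 2)")
        if not (1 <= self.n_modules <= self.n_nodes):
            raise ParameterError("n_modules must be in [1, n_nodes]")
        if not (-1 < self.r_between_pre <= self.r_within_pre < 1):
            raise ParameterError(
                "need -1 < r_between_pre <= r_within_pre < 1 "
                f"(got r_between_pre={self.r_between_pre}, r_within_pre={self.r_within_pre})"
            )
        if len(self.task_effect_sizes) != len(TASK_NAMES):
            raise ParameterError("task_effect_sizes must have 7 entries")
        if not (0 <= self.task_intercorrelation < 1):
            raise ParameterError("task_intercorrelation must be in [0, 1)")
        if not (0 <= self.prepost_autocorrelation <= 1):
            raise ParameterError("prepost_autocorrelation must be in [0, 1]")
        if not (0 <= self.motion_spike_rate <= 1):
            raise ParameterError("motion_spike_rate must be a probability")
        if self.spike_magnitude_mm < 0:
            raise ParameterError("spike_magnitude_mm must be non-negative")
        if not (0 <= self.ar1 < 1):
            raise ParameterError("ar1 must be in [0, 1)")
        # the block covariance (pre and AE-post) must be positive definite
        assign = module_assignment(self.n_nodes, self.n_modules)
        for rw in (self.r_within_pre, self.r_within_pre + self.delta_r_within_post_AE):
            block_covariance(assign, rw, self.r_between_pre)

    @property
    def subject_ids(self) -> list[str]:
        return [
            f"sub-{g}-{i:03d}" for g in GROUPS for i in range(1, self.n_per_group + 1)
        ]

    @property
    def groups(self) -> pd.Series:
        return pd.Series(
            {s: ("AE" if "-AE-" in s else "UAA") for s in self.subject_ids},
            name="group",
        )


def module_assignment(n_nodes: int, n_modules: int) -> np.ndarray:
    """Node -> module map; equal blocks, remainder nodes go to the last module."""
    if not (1 <= n_modules <= n_nodes):
        raise ParameterError("n_modules must be in [1, n_nodes]")
    size = n_nodes // n_modules
    assign = np.repeat(np.arange(n_modules), size)
    remainder = n_nodes - assign.size
    if remainder:
        assign = np.concatenate([assign, np.full(remainder, n_modules - 1)])
    return assign


def block_covariance(
    assignment: np.ndarray, r_within: float, r_between: float
) -> np.ndarray:
    """Block-constant correlation matrix; raises if not positive definite."""
    assignment = np.asarray(assignment)
    same = assignment[:, None] == assignment[None, :]
    cov = np.where(same, r_within, r_between).astype(float)
    np.fill_diagonal(cov, 1.0)
    if cov.shape[0] > 1:
        min_eig = float(np.linalg.eigvalsh(cov)[0])
        if min_eig <= 1e-10:
            sizes = np.bincount(assignment).tolist()
            raise ParameterError(
                "block covariance is not positive definite "
                f"(r_within={r_within}, r_between={r_between}, "
                f"module sizes={sizes}, min eigenvalue={min_eig:.3e})"
            )
    return cov


def simulate_timeseries(
    assignment: np.ndarray,
    n_frames: int,
    r_within: float,
    r_between: float,
    seed: int,
    tr_seconds: float = 2.0,
    ar1: float = 0.0,
    baseline_mean: float = 1000.0,
) -> NodeTimeSeries:
    """Draw a frames x nodes series from a block-modular Gaussian.

    Fluctuations are zero-mean with unit variance, correlation ``r_within``
    inside modules and ``r_between`` across modules, optionally AR(1) in
    time, then shifted by a constant ``baseline_mean`` (a scanner-units
    offset, so DVARS rescaling is well defined; correlations are unaffected).
    """
    assignment = np.asarray(assignment)
    cov = block_covariance(assignment, r_within, r_between)
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((n_frames, assignment.size))
    if assignment.size > 1:
        L = np.linalg.cholesky(cov)
        z = z @ L.T
    if ar1 > 0:
        # innovations scaled so the marginal variance stays 1
        out = np.empty_like(z)
        out[0] = z[0]
        c = np.sqrt(1 - ar1**2)
        for t in range(1, n_frames):
            out[t] = ar1 * out[t - 1] + c * z[t]
        z = out
    return NodeTimeSeries(z + baseline_mean, tr_seconds)


def simulate_motion(
    n_frames: int,
    spike_rate: float,
    spike_magnitude_mm: float = 2.0,
    seed: int = 0,
    baseline_amplitude_mm: float = 0.01,
    baseline_amplitude_rad: float = 1e-4,
) -> tuple[MotionParams, np.ndarray]:
    """Smooth six-parameter motion trace plus displacement spikes.

    The baseline is a sum of two slow sinusoids per axis (translations in mm,
    rotations in radians) with amplitudes far below the censoring threshold.
    Spikes are step displacements of +/- ``spike_magnitude_mm`` applied to the
    x translation at Bernoulli(``spike_rate``) interior frames, so framewise
    displacement at a spike frame is the spike magnitude plus a negligible
    baseline term. Returns the trace and the ground-truth spike frames.
    """
    if not (0 <= spike_rate <= 1):
        raise ParameterError("spike_rate must be a probability in [0, 1]")
    if spike_magnitude_mm < 0:
        raise ParameterError("spike_magnitude_mm must be non-negative")
    rng = np.random.default_rng(seed)
    t = np.arange(n_frames)
    values = np.zeros((n_frames, 6))
    for ax in range(6):
        amp = baseline_amplitude_mm if ax < 3 else baseline_amplitude_rad
        for freq in (0.008, 0.013):
            phase = rng.uniform(0, 2 * np.pi)
            values[:, ax] += 0.5 * amp * np.sin(2 * np.pi * freq * t + phase)
    spikes = np.flatnonzero(rng.random(n_frames - 1) < spike_rate) + 1
    if spikes.size:
        steps = np.zeros(n_frames)
        steps[spikes] = rng.choice([-1.0, 1.0], size=spikes.size) * spike_magnitude_mm
        values[:, 0] += np.cumsum(steps)
    return MotionParams(values), spikes


def simulate_task_scores(
    spec: CohortSpec, seed: int | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Correlated seven-task battery at pre and post.

    Pre scores are multivariate normal on the raw scale with compound-
    symmetric intercorrelation; post scores follow

        post = mean + ac * (pre - mean) + delta * SD * [AE] + sqrt(1-ac^2) * SD * eps

    with ``eps`` drawn with the same intercorrelation, so the marginal SD is
    preserved and the pre-post correlation equals ``prepost_autocorrelation``.
    Returns (pre, post) DataFrames indexed by subject id.
    """
    p = len(TASK_NAMES)
    rho = spec.task_intercorrelation
    R = np.full((p, p), rho)
    np.fill_diagonal(R, 1.0)
    if np.linalg.eigvalsh(R)[0] <= 1e-10:
        raise ParameterError(f"task intercorrelation {rho} gives a singular matrix")
    L = np.linalg.cholesky(R)
    seed = spec.seed if seed is None else seed
    rng = np.random.default_rng(_substream_seed(seed, "tasks"))
    subjects = spec.subject_ids
    n = len(subjects)
    means = np.array([TASK_BASELINES[t][0] for t in TASK_NAMES])
    sds = np.array([TASK_BASELINES[t][1] for t in TASK_NAMES])
    u_pre = rng.standard_normal((n, p)) @ L.T
    eps = rng.standard_normal((n, p)) @ L.T
    is_ae = np.array([s.startswith("sub-AE-") for s in subjects], dtype=float)
    ac = spec.prepost_autocorrelation
    delta = np.asarray(spec.task_effect_sizes, dtype=float)
    pre = means + sds * u_pre
    post = (
        means
        + ac * (pre - means)
        + is_ae[:, None] * delta * sds
        + np.sqrt(1 - ac**2) * sds * eps
    )
    pre_df = pd.DataFrame(pre, index=subjects, columns=TASK_NAMES)
    post_df = pd.DataFrame(post, index=subjects, columns=TASK_NAMES)
    pre_df.index.name = post_df.index.name = "subject"
    return pre_df, post_df


@dataclass
class SyntheticCohort:
    """A fully materialized synthetic cohort with its ground truth."""

    spec: CohortSpec
    cohort: pd.DataFrame  # subject, group
    assignment: np.ndarray  # planted node -> module map
    timeseries: dict  # (subject, session) -> NodeTimeSeries
    motion: dict  # (subject, session) -> MotionParams
    spike_frames: dict  # (subject, session) -> ndarray of ground-truth spikes
    tasks_pre: pd.DataFrame
    tasks_post: pd.DataFrame
    ground_truth: dict = field(default_factory=dict)


def make_cohort(spec: CohortSpec) -> SyntheticCohort:
    """Assemble time series, motion and task scores for every subject/session.

    The AE arm's post-session covariance uses
    ``r_within_pre + delta_r_within_post_AE``; everything else uses the pre
    parameters. Fully reproducible: each (subject, session) draws from its
    own seed substream derived from ``spec.seed``.
    """
    assign = module_assignment(spec.n_nodes, spec.n_modules)
    cohort = spec.groups.rename_axis("subject").reset_index()
    timeseries: dict = {}
    motion: dict = {}
    spikes: dict = {}
    for subject in spec.subject_ids:
        is_ae = subject.startswith("sub-AE-")
        for session in SESSIONS:
            r_within = spec.r_within_pre
            if is_ae and session == "post":
                r_within += spec.delta_r_within_post_AE
            ts = simulate_timeseries(
                assign,
                spec.n_frames,
                r_within,
                spec.r_between_pre,
                seed=_substream_seed(spec.seed, subject, session, "ts"),
                tr_seconds=spec.tr_seconds,
                ar1=spec.ar1,
                baseline_mean=spec.baseline_mean,
            )
            mot, sp = simulate_motion(
                spec.n_frames,
                spec.motion_spike_rate,
                spec.spike_magnitude_mm,
                seed=_substream_seed(spec.seed, subject, session, "motion"),
            )
            timeseries[(subject, session)] = ts
            motion[(subject, session)] = mot
            spikes[(subject, session)] = sp
    tasks_pre, tasks_post = simulate_task_scores(spec)
    ground_truth = {
        "module_assignment": assign.tolist(),
        "task_effect_sizes": list(map(float, spec.task_effect_sizes)),
        "delta_r_within_post_AE": spec.delta_r_within_post_AE,
        "spike_frames": {
            f"{s}_{ses}": sp.tolist() for (s, ses), sp in spikes.items()
        },
        "seed": spec.seed,
    }
    return SyntheticCohort(
        spec=spec,
        cohort=cohort,
        assignment=assign,
        timeseries=timeseries,
        motion=motion,
        spike_frames=spikes,
        tasks_pre=tasks_pre,
        tasks_post=tasks_post,
        ground_truth=ground_truth,
    )


MOTION_COLUMNS = [
    "trans_x_mm",
    "trans_y_mm",
    "trans_z_mm",
    "rot_x_rad",
    "rot_y_rad",
    "rot_z_rad",
]


def write_cohort(cohort: SyntheticCohort, outdir) -> Path:
    """Write the on-disk cohort layout (all plain TSV/JSON, 0-based frames).

    ``cohort.tsv``, ``tasks_pre.tsv``/``tasks_post.tsv``, per-session
    ``ts/<subject>_<session>.tsv`` (header row of node ids) and
    ``motion/<subject>_<session>.tsv``, plus ``ground_truth.json``.
    """
    outdir = Path(outdir)
    (outdir / "ts").mkdir(parents=True, exist_ok=True)
    (outdir / "motion").mkdir(parents=True, exist_ok=True)
    cohort.cohort.to_csv(outdir / "cohort.tsv", sep="\t", index=False)
    cohort.tasks_pre.to_csv(outdir / "tasks_pre.tsv", sep="\t", float_format="%.6f")
    cohort.tasks_post.to_csv(outdir / "tasks_post.tsv", sep="\t", float_format="%.6f")
    for (subject, session), ts in cohort.timeseries.items():
        df = pd.DataFrame(ts.values, columns=ts.node_ids)
        df.to_csv(
            outdir / "ts" / f"{subject}_{session}.tsv",
            sep="\t",
            index=False,
            float_format="%.6f",
        )
    for (subject, session), mot in cohort.motion.items():
        df = pd.DataFrame(mot.values, columns=MOTION_COLUMNS)
        df.to_csv(
            outdir / "motion" / f"{subject}_{session}.tsv",
            sep="\t",
            index=False,
            float_format="%.8f",
        )
    with open(outdir / "ground_truth.json", "w") as fh:
        json.dump(cohort.ground_truth, fh, indent=1, sort_keys=True)
    return outdir
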