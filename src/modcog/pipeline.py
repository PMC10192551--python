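"""Config-driven orchestration of the three-hypothesis analysis workflow.

``run_pipeline`` ties the stages together — (optional) cohort simulation,
frame censoring and filtering, connectivity, the Louvain resolution sweep,
the log-link mixed model of median Q, and the residualize / PLS-DA / VIP /
logistic discriminant chain — writing plain-text stage outputs and a single
JSON report. Given the same config and seed the run is fully reproducible;
expensive stage outputs are cached on disk keyed by a hash of the config.

``verify_paper_numbers`` recomputes the bundled printed-table check values
(two-sample t statistics from published group descriptives and the
one-component VIP identity on a published loading vector).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import community, connectivity, discriminant, io, mixed_model, preprocess
from .errors import ModcogError, ParameterError
from .synthetic_data import (
    SESSIONS,
    TASK_NAMES,
    CohortSpec,
    _substream_seed,
    make_cohort,
    write_cohort,
)

__all__ = ["PipelineConfig", "run_pipeline", "verify_paper_numbers"]

logger = logging.getLogger("modcog.pipeline")

#: Published per-task group descriptives (n, mean, SD) for the acting (AE)
#: and control (UAA) arms at each time point, with the published |t|.
PRINTED_TASK_DESCRIPTIVES = {
    ("spatial_wm_rt", "pre"): (83, 1021.4, 183.7, 81, 998.9, 163.2, 0.83),
    ("spatial_wm_rt", "post"): (81, 1036.4, 187.2, 79, 992.5, 171.8, 1.55),
    ("two_back_rt", "pre"): (84, 911.5, 199.6, 81, 859.5, 197.0, 1.68),
    ("two_back_rt", "post"): (81, 902.6, 162.7, 79, 858.2, 169.2, 1.69),
    ("task_switch_cost", "pre"): (83, 478.6, 271.8, 77, 504.5, 280.3, 0.59),
    ("task_switch_cost", "post"): (75, 406.2, 283.6, 77, 467.7, 282.4, 1.34),
    ("trails_b_time", "pre"): (84, 85.99, 35.1, 80, 76.68, 36.6, 1.66),
    ("trails_b_time", "post"): (75, 79.2, 33.6, 77, 75.0, 29.1, 0.84),
    ("flanker_incongruent_rt", "pre"): (75, 866.6, 124.7, 73, 813.0, 111.7, 2.76),
    ("flanker_incongruent_rt", "post"): (79, 838.8, 119.1, 73, 792.1, 99.1, 2.63),
    ("digit_symbol_count", "pre"): (83, 60.9, 13.3, 81, 64.5, 12.8, 1.78),
    ("digit_symbol_count", "post"): (81, 64.0, 13.4, 80, 68.1, 14.2, 1.89),
    ("meps_steps", "pre"): (84, 8.4, 4.0, 81, 9.8, 4.9, 2.06),
    ("meps_steps", "post"): (77, 11.3, 4.6, 80, 10.3, 4.3, 1.42),
}

#: Published one-component loading vector (battery order) with published VIPs.
PRINTED_LOADINGS = (0.47, 0.58, -0.17, -0.04, 0.00, -0.21, 0.60)
PRINTED_VIPS = (1.24, 1.55, 0.45, 0.12, 0.00, 0.56, 1.59)


@dataclass
class PipelineConfig:
    """Validated settings for a full pipeline run.

    Either ``input_dir`` points at an existing cohort directory, or
    ``simulate`` carries :class:`~modcog.synthetic_data.CohortSpec` keyword
    arguments and the cohort is generated under ``out_dir``.
    """

    out_dir: str = "modcog_out"
    input_dir: str | None = None
    simulate: dict | None = None
    tr_seconds: float = 2.0
    # preprocessing
    fd_thresh_mm: float = 0.5
    dvars_thresh_pct: float = 0.5
    augment_back: int = 1
    augment_fwd: int = 2
    combine: str = "intersection"
    low_hz: float = 0.008
    high_hz: float = 0.1
    # connectivity / community
    negative_policy: str = "zeroed"
    gammas: tuple = community.DEFAULT_GAMMA_GRID
    n_runs: int = 100
    # statistics
    model_mode: str = "pooled"  # pooled gamma rows | per_gamma fits
    n_components: int = 1
    error_method: str = "loocv_centroid"
    vip_threshold: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.input_dir is None and self.simulate is None:
            raise ParameterError("config needs either input_dir or a simulate stanza")
        if self.combine not in ("intersection", "union"):
            raise ParameterError("combine must be intersection or union")
        if self.model_mode not in ("pooled", "per_gamma"):
            raise ParameterError("model_mode must be pooled or per_gamma")
        if self.negative_policy not in connectivity.NEGATIVE_POLICIES:
            raise ParameterError(f"unknown negative_policy {self.negative_policy!r}")
        self.gammas = tuple(float(g) for g in self.gammas)
        if self.input_dir is not None:
            inp = Path(self.input_dir).resolve()
            out = Path(self.out_dir).resolve()
            if inp == out or out in inp.parents or inp in out.parents:
                raise ParameterError(
                    f"input_dir {inp} and out_dir {out} overlap; refusing to run"
                )
        if self.simulate is not None:
            CohortSpec(**{**self.simulate, "seed": self.seed})  # validate eagerly

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = sorted(set(d) - known)
        if unknown:
            raise ParameterError(f"unknown config key(s): {unknown}")
        return cls(**d)

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)  # YAML is a superset of JSON
        if not isinstance(data, dict):
            raise ParameterError(f"{path}: config must be a mapping")
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["gammas"] = list(self.gammas)
        return d

    @property
    def config_hash(self) -> str:
        # out_dir is where results land, not what they depend on
        d = {k: v for k, v in self.to_dict().items() if k != "out_dir"}
        return hashlib.sha256(
            json.dumps(d, sort_keys=True).encode()
        ).hexdigest()[:16]


def _preprocess_session(ts, motion, cfg: PipelineConfig):
    """FD/DVARS -> filter -> nuisance regression -> mask. Returns
    (censored NodeTimeSeries, TemporalMask, per-session log record)."""
    fd = preprocess.compute_fd(motion)
    dvars = preprocess.compute_dvars(ts)
    filtered = preprocess.bandpass(ts, cfg.low_hz, cfg.high_hz)
    motion_f = preprocess.bandpass_array(
        motion.values, ts.tr_seconds, cfg.low_hz, cfg.high_hz
    )
    resid = preprocess.nuisance_regress(filtered, motion_f)
    mask = preprocess.build_temporal_mask(
        fd,
        dvars,
        cfg.fd_thresh_mm,
        cfg.dvars_thresh_pct,
        cfg.augment_back,
        cfg.augment_fwd,
        combine=cfg.combine,
    )
    censored = preprocess.censor(resid, mask)
    record = {
        "n_frames": ts.n_frames,
        "n_censored": int(mask.n_frames - mask.n_kept),
        "n_flagged_fd": len(mask.flagged_fd),
        "n_flagged_dvars": len(mask.flagged_dvars),
    }
    return censored, mask, record


def _load_cohort_inputs(cohort_dir: Path, cfg: PipelineConfig):
    cohort = io.read_cohort_table(cohort_dir / "cohort.tsv")
    tasks_pre = pd.read_csv(cohort_dir / "tasks_pre.tsv", sep="\t", index_col="subject")
    tasks_post = pd.read_csv(cohort_dir / "tasks_post.tsv", sep="\t", index_col="subject")
    ts, motion = {}, {}
    for subject in cohort["subject"]:
        for session in SESSIONS:
            stem = f"{subject}_{session}"
            ts[(subject, session)] = io.read_timeseries_tsv(
                cohort_dir / "ts" / f"{stem}.tsv", cfg.tr_seconds
            )
            motion[(subject, session)] = io.read_motion_tsv(
                cohort_dir / "motion" / f"{stem}.tsv"
            )
    return cohort, tasks_pre, tasks_post, ts, motion


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages and return the analysis report (also written to
    ``<out_dir>/report.json``). Deterministic given (config, seed, inputs)."""
    out = io.ensure_dir(config.out_dir)
    provenance_path = out / "provenance.json"
    cached_hash = None
    if provenance_path.exists():
        cached_hash = json.loads(provenance_path.read_text()).get("config_hash")
    cache_ok = cached_hash == config.config_hash
    warnings_log: list[str] = []

    # --- stage: simulate (optional) -------------------------------------
    if config.simulate is not None:
        cohort_dir = out / "cohort"
        if not (cache_ok and (cohort_dir / "ground_truth.json").exists()):
            spec = CohortSpec(**{**config.simulate, "seed": config.seed})
            logger.info("simulating cohort: %d subjects/group", spec.n_per_group)
            write_cohort(make_cohort(spec), cohort_dir)
        else:
            logger.info("reusing cached simulated cohort")
    else:
        cohort_dir = Path(config.input_dir)

    cohort, tasks_pre, tasks_post, ts_all, motion_all = _load_cohort_inputs(
        cohort_dir, config
    )
    logger.info("cohort: %d subjects, %d sessions each", len(cohort), len(SESSIONS))

    # --- stages: preprocess -> connectivity -> community ----------------
    for sub in ("mask", "conn", "q", "q_median"):
        io.ensure_dir(out / sub)
    profiles: dict = {}
    preprocess_log: dict = {}
    for subject in sorted(cohort["subject"]):
        for session in SESSIONS:
            key = f"{subject}_{session}"
            median_path = out / "q_median" / f"{key}.tsv"
            if cache_ok and median_path.exists():
                med = io.read_q_median_tsv(median_path)
                profiles[(subject, session)] = community.QProfile(
                    gammas=tuple(med["gamma"]),
                    q_runs={g: [q] for g, q in zip(med["gamma"], med["median_q"])},
                    medians=dict(zip(med["gamma"], med["median_q"])),
                    best_partitions={},
                    n_runs=config.n_runs,
                    seed=config.seed,
                )
                continue
            try:
                censored, mask, record = _preprocess_session(
                    ts_all[(subject, session)], motion_all[(subject, session)], config
                )
                preprocess_log[key] = record
                logger.info(
                    "%s: %d/%d frames censored",
                    key,
                    record["n_censored"],
                    record["n_frames"],
                )
                io.write_mask_tsv(out / "mask" / f"{key}.tsv", mask)
                cm = connectivity.correlation_matrix(censored, mask=None)
                cm = connectivity.prepare_for_modularity(cm, config.negative_policy)
                io.write_matrix_tsv(out / "conn" / f"{key}.tsv", cm)
                prof = community.gamma_sweep(
                    cm,
                    config.gammas,
                    n_runs=config.n_runs,
                    seed=_substream_seed(config.seed, subject, session, "louvain"),
                )
                profiles[(subject, session)] = prof
                io.write_qprofile_tsv(
                    out / "q" / f"{key}.tsv", median_path, prof
                )
            except ModcogError as exc:
                raise type(exc)(
                    f"stage failed for {subject}/{session}: {exc}"
                ) from exc

    # --- stage: mixed model ---------------------------------------------
    table = mixed_model.build_long_table(profiles, cohort)
    # the log link requires a positive outcome; at high resolution the best
    # attainable Q on dense graphs can be <= 0, so those rows cannot enter
    nonpos = int((table["median_q"] <= 0).sum())
    if nonpos:
        msg = (
            f"dropped {nonpos}/{len(table)} rows with median_q <= 0 "
            "(log link requires a positive outcome; typically high-gamma rows)"
        )
        logger.warning(msg)
        warnings_log.append(msg)
        table = table[table["median_q"] > 0]
    glmm_block = {}
    if config.model_mode == "pooled":
        fit = mixed_model.fit_glmm_log_link(table)
        glmm_block["pooled"] = _fit_to_dict(fit)
    else:
        for gamma in config.gammas:
            fit = mixed_model.fit_glmm_log_link(table[table["gamma"] == gamma])
            glmm_block[f"gamma={gamma}"] = _fit_to_dict(fit)
    (out / "glmm_fit.json").write_text(json.dumps(glmm_block, indent=1, sort_keys=True))

    # --- stage: discriminant --------------------------------------------
    groups = pd.Series(
        cohort.set_index("subject")["group"], name="group"
    ).reindex(tasks_pre.index)
    task_table = discriminant.TaskTable(groups=groups, pre=tasks_pre, post=tasks_post)
    resid = discriminant.studentize(discriminant.control_residualize(task_table))
    stud = discriminant.complete_cases(resid.studentized)
    model = discriminant.fit_plsda(
        stud, task_table.groups.loc[stud.index], config.n_components
    )
    vip_scores = discriminant.vip(model)
    selected = discriminant.select_discriminant_tasks(model, config.vip_threshold)
    err_loocv = discriminant.classification_error(
        model, stud, task_table.groups.loc[stud.index], method=config.error_method
    )
    err_resub = discriminant.classification_error(
        model, stud, task_table.groups.loc[stud.index], method="resubstitution"
    )
    plsda_block = {
        "weights": model.weights[:, 0].round(10).tolist(),
        "x_loadings": model.x_loadings[:, 0].round(10).tolist(),
        "vip": {t: round(float(v), 10) for t, v in vip_scores.items()},
        "selected_tasks": selected,
        "explained_x_variance": model.explained_x_variance.round(10).tolist(),
        "explained_y_variance": model.explained_y_variance.round(10).tolist(),
        "error_rate": {config.error_method: err_loocv, "resubstitution": err_resub},
        "n_complete": int(len(stud)),
    }
    (out / "plsda.json").write_text(json.dumps(plsda_block, indent=1, sort_keys=True))

    # per-subject change in median Q averaged over the resolution grid
    wide = table.pivot_table(index="participant", columns="time", values="median_q")
    delta_q = (wide[1] - wide[0]).rename("delta_q")
    logistic_block = {}
    for task in selected:
        sub = pd.DataFrame(
            {
                "delta_q": delta_q,
                "task": resid.studentized[task],
                "group": task_table.groups,
            }
        ).dropna()
        lf = discriminant.fit_logistic_interaction(
            sub["delta_q"], sub["task"], sub["group"]
        )
        logistic_block[task] = {
            "coef": dict(zip(lf.coef_names, lf.coef.round(10))),
            "se": dict(zip(lf.coef_names, lf.se.round(10))),
            "p": dict(zip(lf.coef_names, lf.p.round(10))),
            "converged": bool(lf.converged),
            "separation": bool(lf.separation),
            "n": int(lf.n_obs),
        }
    (out / "logistic.json").write_text(
        json.dumps(logistic_block, indent=1, sort_keys=True, default=float)
    )

    _write_table2_replica(out / "table2_replica.tsv", task_table)

    report = {
        "provenance": {
            "config_hash": config.config_hash,
            "seed": config.seed,
            "modcog_version": _version(),
        },
        "hypothesis1_glmm": glmm_block,
        "hypothesis2_plsda": plsda_block,
        "hypothesis3_logistic": logistic_block,
        "preprocess_log": preprocess_log,
        "warnings": warnings_log,
    }
    (out / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True))
    provenance_path.write_text(
        json.dumps({"config_hash": config.config_hash}, indent=1)
    )
    return report


def _version() -> str:
    from . import __version__

    return __version__


def _fit_to_dict(fit) -> dict:
    tests = mixed_model.wald_tests(fit)
    return {
        "coefficients": {
            row.coef: {
                "estimate": round(float(row.estimate), 10),
                "se": round(float(row.se), 10),
                "z": round(float(row.z), 10),
                "p": round(float(row.p), 10),
            }
            for row in tests.itertuples()
        },
        "sigma_b": round(float(fit.sigma_b), 10),
        "sigma_e": round(float(fit.sigma_e), 10),
        "loglik": round(float(fit.loglik), 8),
        "converged": bool(fit.converged),
        "message": fit.message,
        "n_obs": fit.n_obs,
        "n_participants": fit.n_participants,
    }


def _write_table2_replica(path, task_table) -> None:
    """Group descriptives and two-sample t tests on the cohort's own tasks."""
    rows = []
    for session, df in (("pre", task_table.pre), ("post", task_table.post)):
        ae = df[task_table.is_ae]
        ctrl = df[~task_table.is_ae]
        for task in TASK_NAMES:
            a, c = ae[task].dropna(), ctrl[task].dropna()
            t_pooled, _, p_pooled = discriminant.pooled_t_test(
                len(a), a.mean(), a.std(ddof=1), len(c), c.mean(), c.std(ddof=1)
            )
            t_welch, _, p_welch = discriminant.pooled_t_test(
                len(a), a.mean(), a.std(ddof=1), len(c), c.mean(), c.std(ddof=1),
                welch=True,
            )
            rows.append(
                {
                    "task": task,
                    "time": session,
                    "n_acting": len(a),
                    "mean_acting": round(a.mean(), 4),
                    "sd_acting": round(a.std(ddof=1), 4),
                    "n_control": len(c),
                    "mean_control": round(c.mean(), 4),
                    "sd_control": round(c.std(ddof=1), 4),
                    "t_pooled": round(t_pooled, 4),
                    "p_pooled": round(p_pooled, 4),
                    "t_welch": round(t_welch, 4),
                    "p_welch": round(p_welch, 4),
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def verify_paper_numbers() -> pd.DataFrame:
    """Recompute each bundled printed-table quantity and report pass/fail
    at 2-decimal rounding (both t-test variants are shown; the published
    analysis environment's default was the Welch form)."""
    rows = []
    for (task, session), (n1, m1, s1, n2, m2, s2, t_printed) in sorted(
        PRINTED_TASK_DESCRIPTIVES.items()
    ):
        t_pooled = abs(discriminant.pooled_t_test(n1, m1, s1, n2, m2, s2)[0])
        t_welch = abs(
            discriminant.pooled_t_test(n1, m1, s1, n2, m2, s2, welch=True)[0]
        )
        rows.append(
            {
                "check": f"t|{task}|{session}",
                "printed": t_printed,
                "computed_pooled": round(t_pooled, 2),
                "computed_welch": round(t_welch, 2),
                "pass": round(t_welch, 2) == t_printed
                or round(t_pooled, 2) == t_printed,
            }
        )
    vips = discriminant.vip_from_loadings(PRINTED_LOADINGS)
    for task, vip_printed, vip_computed in zip(TASK_NAMES, PRINTED_VIPS, vips):
        rows.append(
            {
                "check": f"vip|{task}",
                "printed": vip_printed,
                "computed_pooled": round(float(vip_computed), 2),
                "computed_welch": round(float(vip_computed), 2),
                "pass": round(float(vip_computed), 2) == vip_printed,
            }
        )
    rows.append(
        {
            "check": "vip|sum_of_squares",
            "printed": 7.0,
            "computed_pooled": round(float((vips**2).sum()), 2),
            "computed_welch": round(float((vips**2).sum()), 2),
            "pass": abs(float((vips**2).sum()) - 7.0) < 1e-8,
        }
    )
    return pd.DataFrame(rows)
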