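"""End-to-end experiment runner: simulate, preprocess, extract, evaluate, compare.

``run_experiment`` reproduces the full study grid on a synthetic cohort:
for each task (EC, VS), each session set (session 1, session 2, combined)
and each decomposition strategy (OVO, OVA) it runs 5-fold cross-validated
identification — 12 reports with the default two-session configuration —
then applies the normality-gated EC-vs-VS comparison per session set and
strategy.  A single top-level seed drives every random draw.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np

from eegauth._version import __version__ as _version
from eegauth.classify import PolyKernel
from eegauth.config import ExperimentConfig
from eegauth.evaluate import EvalReport, StatTestReport, compare_protocols, kfold_evaluate
from eegauth.features import FeatureMatrix, build_matrix, concat_matrices
from eegauth.io import save_recording
from eegauth.preprocess import (
    FilterSpec,
    bandpass_fir,
    epoch_vs,
    reject_epochs,
    remove_ocular,
    segment_ec,
)
from eegauth.simulate import (
    SubjectGenParams,
    build_schedule,
    inject_blinks,
    make_cohort,
    session_params,
    simulate_ec,
    simulate_vs,
)

logger = logging.getLogger(__name__)

TASKS = ("EC", "VS")


def _cohort(config: ExperimentConfig) -> list[SubjectGenParams]:
    return make_cohort(
        config.n_subjects,
        seed=config.seed,
        separation=config.separation,
        alpha_amplitude_uv=config.alpha_amplitude_uv,
        background_amplitude_uv=config.background_amplitude_uv,
        sensor_noise_uv=config.sensor_noise_uv,
        blink_rate_hz=config.blink_rate_hz,
        blink_amplitude_uv=config.blink_amplitude_uv,
        erp_trial_jitter=config.intra_subject_var,
    )


def subject_session_features(
    params: SubjectGenParams, session: int, config: ExperimentConfig
) -> dict[str, FeatureMatrix]:
    """Simulate one subject-session and run both task branches to features."""
    sp = session_params(params, session, config.intra_subject_var)
    session_id = f"S{session}"
    spec = FilterSpec(low_hz=config.low_hz, high_hz=config.high_hz)

    # eyes-closed branch: filter -> segment (no ocular correction: resting
    # state, eyes shut, so no blink artifacts to remove)
    ec = simulate_ec(sp, config.ec_duration_s, config.fs, session_id=session_id)
    ec_trials = segment_ec(bandpass_fir(ec, spec), config.discard_s, config.frame_s)

    # visual-stimulation branch: filter -> ocular regression -> epoch -> reject
    schedule = build_schedule(config.vs_n_stimuli)
    vs = simulate_vs(sp, schedule, config.fs, session_id=session_id)
    vs = inject_blinks(vs, sp)
    vs = bandpass_fir(vs, spec)
    vs = remove_ocular(vs, config.ocular_method)
    vs_trials = reject_epochs(
        epoch_vs(vs, config.pre_s, config.post_s), config.amp_thresh_uv
    )

    return {"EC": build_matrix(ec_trials), "VS": build_matrix(vs_trials)}


def run_experiment(config: ExperimentConfig | None = None) -> dict:
    """Run the full grid; returns {"reports": ..., "comparisons": ...}.

    ``reports`` maps "<task>_<session_set>_<strategy>" to an
    :class:`~eegauth.evaluate.EvalReport`; ``comparisons`` maps
    "<session_set>_<strategy>" to the EC-vs-VS
    :class:`~eegauth.evaluate.StatTestReport`.
    """
    config = config or ExperimentConfig()
    cohort = _cohort(config)
    kernel = PolyKernel(
        degree=config.degree, coef0=config.coef0, gamma=config.gamma, C=config.C
    )

    per_session: dict[tuple[str, int], list[FeatureMatrix]] = {
        (task, s): []
        for task in TASKS
        for s in range(1, config.sessions + 1)
    }
    for params in cohort:
        for session in range(1, config.sessions + 1):
            features = subject_session_features(params, session, config)
            for task in TASKS:
                per_session[(task, session)].append(features[task])

    session_sets: dict[str, list[int]] = {
        f"S{s}": [s] for s in range(1, config.sessions + 1)
    }
    if config.sessions > 1:
        combined = "+".join(f"S{s}" for s in range(1, config.sessions + 1))
        session_sets[combined] = list(range(1, config.sessions + 1))

    reports: dict[str, EvalReport] = {}
    seed_rng = np.random.default_rng([config.seed, 7])
    for task in TASKS:
        for set_name, session_ids in session_sets.items():
            matrix = concat_matrices(
                [m for s in session_ids for m in per_session[(task, s)]]
            )
            for strategy in config.strategies:
                eval_seed = int(seed_rng.integers(2**31))
                report = kfold_evaluate(
                    matrix.X,
                    matrix.labels,
                    strategy=strategy,
                    k=config.k,
                    seed=eval_seed,
                    kernel=kernel,
                    f1_mode=config.f1_mode,
                    stratify=config.stratify,
                    averaging=config.averaging,
                    task=task,
                    session=set_name,
                )
                reports[f"{task}_{set_name}_{strategy}"] = report
                logger.info("%s", report.summary())

    comparisons: dict[str, StatTestReport] = {}
    for set_name in session_sets:
        for strategy in config.strategies:
            a = reports[f"EC_{set_name}_{strategy}"]
            b = reports[f"VS_{set_name}_{strategy}"]
            comparisons[f"{set_name}_{strategy}"] = compare_protocols(
                {m: a.fold_samples(m) for m in a.mean},
                {m: b.fold_samples(m) for m in b.mean},
                alpha=config.alpha,
                nonparametric=config.nonparametric,
            )

    return {"reports": reports, "comparisons": comparisons, "config": config}


def results_to_json(results: dict) -> str:
    """Deterministic JSON rendering of a run (embeds config hash + version)."""
    config: ExperimentConfig = results["config"]
    payload = {
        "version": _version,
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "reports": {k: r.to_dict() for k, r in results["reports"].items()},
        "comparisons": {
            k: c.to_dict() for k, c in results["comparisons"].items()
        },
    }
    return json.dumps(payload, sort_keys=True, indent=2)


def make_fixtures(seed: int, out_dir: str | Path, n_stimuli: int = 10) -> list[Path]:
    """Write a miniature 2-subject, 1-session dataset (EDF + events CSV).

    Produces 4 EDF files (2 subjects x 2 protocols); the EC recordings are
    full 30 s so they segment into the standard 25 trials.
    """
    out_dir = Path(out_dir)
    cohort = make_cohort(2, seed=seed, separation=1.0)
    written: list[Path] = []
    schedule = build_schedule(n_stimuli)
    for params in cohort:
        sp = session_params(params, 1)
        ec = simulate_ec(sp, 30.0, 256.0, session_id="S1")
        vs = inject_blinks(simulate_vs(sp, schedule, 256.0, session_id="S1"), sp)
        written.extend(save_recording(ec, out_dir))
        written.extend(save_recording(vs, out_dir))
    return written
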