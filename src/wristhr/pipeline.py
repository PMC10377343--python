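"""End-to-end orchestration used by the CLI, the tests and the report script."""

from __future__ import annotations

import logging
import time

import numpy as np
import pandas as pd

from . import simulate as sim
from .features import WindowTable, apply_norm, featurize, fit_norm
from .models import TrainedBundle, split_dataset, train_classifier, train_regressors
from .preprocess import process_session, window_session
from .select import nca_weights, relieff_weights
from .session_io import PipelineConfig

log = logging.getLogger(__name__)

__all__ = ["simulate_users", "featurize_sessions", "train_bundle", "stack_tables"]


def simulate_users(
    n_users: int,
    seed: int,
    schedule: sim.ProtocolSchedule | None = None,
    artifact: sim.ArtifactModel | None = None,
) -> list[sim.RawSession]:
    """Simulate one session per user with independent seeded physiologies."""
    if schedule is None:
        schedule = sim.make_schedule()
    rng = np.random.default_rng(seed)
    sessions = []
    for u in range(n_users):
        phys = sim.sample_physiology(rng)
        t0 = time.perf_counter()
        sessions.append(sim.simulate_session(schedule, phys, artifact))
        log.info("simulated user %d (resting HR %.1f bpm) in %.2f s",
                 u, phys.resting_hr, time.perf_counter() - t0)
    return sessions


def featurize_sessions(
    sessions: list[sim.RawSession],
    cfg: PipelineConfig,
    hr_source: str = "reference",
) -> WindowTable:
    """Process, window and featurize a list of sessions into one table."""
    tables = []
    for u, raw in enumerate(sessions):
        t0 = time.perf_counter()
        proc = process_session(raw, cfg, hr_source=hr_source)
        windows = window_session(proc, cfg)
        tables.append(featurize(windows, band=cfg.bandpass, user=u).df)
        log.info("featurized user %d: %d windows in %.2f s",
                 u, len(tables[-1]), time.perf_counter() - t0)
    return WindowTable(pd.concat(tables, ignore_index=True))


def stack_tables(tables: list[WindowTable]) -> WindowTable:
    return WindowTable(
        pd.concat([t.df for t in tables], ignore_index=True), tables[0].catalogue
    )


def train_bundle(train_table: WindowTable, cfg: PipelineConfig, *, cv: bool = False) -> TrainedBundle:
    """Fit normalization, both feature selections and all three models."""
    stats = fit_norm(train_table)
    normed = apply_norm(train_table, stats)
    X = normed.features

    t0 = time.perf_counter()
    sel_clf = nca_weights(X, normed.label_task, cfg.n_classifier_features, seed=cfg.seed)
    log.info("NCA selection done in %.1f s", time.perf_counter() - t0)
    t0 = time.perf_counter()
    sel_reg = relieff_weights(X, normed.label_hr, cfg.n_regressor_features, seed=cfg.seed)
    log.info("ReliefF selection done in %.1f s", time.perf_counter() - t0)

    t0 = time.perf_counter()
    clf, cv_acc = train_classifier(normed, sel_clf, cfg, cv=cv)
    log.info("classifier trained in %.1f s", time.perf_counter() - t0)
    t0 = time.perf_counter()
    b1, b2, cv_rmse = train_regressors(normed, sel_reg, cfg, cv=cv)
    log.info("regressors trained in %.1f s", time.perf_counter() - t0)

    return TrainedBundle(
        classifier=clf,
        regressor_b1=b1,
        regressor_b2=b2,
        norm_stats=stats,
        selection_clf=sel_clf,
        selection_reg=sel_reg,
        metadata={
            "seed": cfg.seed,
            "cv_accuracy": cv_acc,
            "cv_rmse": cv_rmse,
            "n_train_windows": len(train_table),
            "selected_clf": [normed.catalogue[i] for i in sel_clf.selected_indices],
            "selected_reg": [normed.catalogue[i] for i in sel_reg.selected_indices],
        },
    )
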