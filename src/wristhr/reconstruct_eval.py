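"""Class-routed HR reconstruction and its evaluation.

Every 6-s window is classified into one of three activity groups and routed
accordingly: group 1 (rest) gets a spectral HR estimate from the filtered
PPG; group 2 (finger movement) uses the Gaussian-process regressor B1;
group 3 (displacement) uses the bagged-trees regressor B2.  Evaluation
reports classification metrics, total and per-task RMSE, and an
"FFT-everywhere" baseline in which routing is disabled.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import simulate as sim
from .features import WindowTable, apply_norm, featurize
from .models import TrainedBundle
from .preprocess import Window

log = logging.getLogger(__name__)

__all__ = ["ReconstructionResult", "hr_from_fft", "reconstruct", "evaluate", "rmse"]

ROUTE_BY_CLASS = {1: "fft", 2: "b1", 3: "b2"}


def hr_from_fft(
    ppg_window: np.ndarray,
    fs: float = sim.PPG_RATE,
    band: tuple[float, float] = (0.6, 3.0),
    nfft: int = 2048,
) -> float:
    """HR (bpm) from the dominant in-band peak of the zero-padded spectrum.

    Returns NaN when the window carries no energy in the band (sentinel for
    "no estimate"; the router falls back to the B1 regressor).
    """
    x = np.asarray(ppg_window, dtype=float)
    nfft = max(nfft, len(x))
    spec = np.abs(np.fft.rfft(x - x.mean(), n=nfft))
    freqs = np.fft.rfftfreq(nfft, d=1.0 / fs)
    mask = (freqs >= band[0]) & (freqs <= band[1])
    if not np.any(spec[mask] > 0):
        return float("nan")
    return 60.0 * float(freqs[mask][np.argmax(spec[mask])])


@dataclass
class ReconstructionResult:
    """Per-window reconstruction records plus session-level context.

    ``df`` columns: ``t_start``, ``pred_class``, ``route``, ``hr_pred``,
    ``hr_fft`` (the FFT estimate for every window, used by the no-routing
    baseline), ``label_task`` and ``label_hr`` when available.
    """

    df: pd.DataFrame
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        bad = self.df[
            self.df["route"] != self.df["pred_class"].map(ROUTE_BY_CLASS)
        ]
        # fallback rows are tagged b1 while pred_class == 1
        fallback = (bad["pred_class"] == 1) & (bad["route"] == "b1")
        if len(bad) and not fallback.all():
            raise ValueError("routing tags inconsistent with predicted classes")


def reconstruct(
    windows: list[Window],
    bundle: TrainedBundle,
    cfg=None,
) -> ReconstructionResult:
    """Run the routed estimator over featurized, normalized windows."""
    from .session_io import PipelineConfig

    if cfg is None:
        cfg = PipelineConfig()
    if not windows:
        raise ValueError("no windows to reconstruct")
    table = featurize(windows, band=cfg.bandpass)
    normed = apply_norm(table, bundle.norm_stats)
    if list(normed.catalogue) != list(bundle.norm_stats.names):
        raise ValueError("window table does not match the bundle's feature catalogue")
    X = normed.features
    pred = bundle.classifier.predict(bundle.classifier_features(X)).astype(int)

    Xreg = bundle.regressor_features(X)
    hr_b1 = bundle.regressor_b1.predict(Xreg)
    hr_b2 = bundle.regressor_b2.predict(Xreg)
    hr_fft = np.array([hr_from_fft(w.ppg, band=cfg.bandpass) for w in windows])

    hr_pred = np.empty(len(windows))
    routes = []
    n_fallback = 0
    for i, cls in enumerate(pred):
        route = ROUTE_BY_CLASS[cls]
        if route == "fft" and not np.isfinite(hr_fft[i]):
            route = "b1"
            n_fallback += 1
        hr_pred[i] = {"fft": hr_fft[i], "b1": hr_b1[i], "b2": hr_b2[i]}[route]
        routes.append(route)
    if n_fallback:
        log.info("%d window(s) had no in-band spectral peak; fell back to B1", n_fallback)

    df = pd.DataFrame(
        {
            "t_start": [w.t_start for w in windows],
            "pred_class": pred,
            "route": routes,
            "hr_pred": hr_pred,
            "hr_fft": hr_fft,
            "label_task": [w.label_task for w in windows],
            "label_hr": [w.label_hr if w.label_hr is not None else np.nan
                         for w in windows],
        }
    )
    return ReconstructionResult(df, meta={"n_fft_fallback": n_fallback})


def rmse(pred: np.ndarray, truth: np.ndarray) -> float:
    """Root-mean-square error sqrt(sum((truth - pred)^2) / n)."""
    pred, truth = np.asarray(pred, dtype=float), np.asarray(truth, dtype=float)
    ok = np.isfinite(pred) & np.isfinite(truth)
    if not ok.any():
        return float("nan")
    return float(np.sqrt(np.mean((truth[ok] - pred[ok]) ** 2)))


def _confusion(y_true: np.ndarray, y_pred: np.ndarray, classes=(1, 2, 3)) -> np.ndarray:
    cm = np.zeros((len(classes), len(classes)), dtype=int)
    for i, t in enumerate(classes):
        for j, p in enumerate(classes):
            cm[i, j] = int(np.sum((y_true == t) & (y_pred == p)))
    return cm


def evaluate(result: ReconstructionResult) -> dict:
    """Classification and HR-error report for a labelled reconstruction.

    Per-task RMSE is grouped by the TRUE task label, so misclassified
    windows mix routing paths within a row.  The baseline applies the
    spectral estimator to every window regardless of class.
    """
    df = result.df
    if len(df) == 0 or df["label_task"].isna().all():
        raise ValueError("no labelled windows to evaluate")
    labelled = df[np.isfinite(df["label_hr"])] if "label_hr" in df else df.iloc[0:0]

    y_true = df["label_task"].to_numpy(dtype=int)
    y_pred = df["pred_class"].to_numpy(dtype=int)
    cm = _confusion(y_true, y_pred)
    accuracy = float(np.trace(cm) / cm.sum())

    per_class = {}
    for i, cls in enumerate((1, 2, 3)):
        tp = cm[i, i]
        prec = tp / cm[:, i].sum() if cm[:, i].sum() else 0.0
        rec = tp / cm[i, :].sum() if cm[i, :].sum() else 0.0
        f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
        per_class[cls] = {"precision": float(prec), "recall": float(rec), "f1": float(f1)}

    report = {
        "accuracy": accuracy,
        "confusion_matrix": cm.tolist(),
        "per_class": per_class,
        "rmse_total": rmse(labelled["hr_pred"], labelled["label_hr"]),
        "baseline_rmse_total": rmse(labelled["hr_fft"], labelled["label_hr"]),
        "rmse_per_task": {},
        "baseline_rmse_per_task": {},
        "n_windows": int(len(df)),
    }
    for cls in (1, 2, 3):
        sub = labelled[labelled["label_task"] == cls]
        report["rmse_per_task"][cls] = (
            rmse(sub["hr_pred"], sub["label_hr"]) if len(sub) else float("nan")
        )
        report["baseline_rmse_per_task"][cls] = (
            rmse(sub["hr_fft"], sub["label_hr"]) if len(sub) else float("nan")
        )
    return report


def plot_reconstruction(result: ReconstructionResult, path=None):
    """Overlay of reconstructed vs reference HR, colored by routing path."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = result.df
    fig, ax = plt.subplots(figsize=(10, 4))
    if np.isfinite(df["label_hr"]).any():
        ax.plot(df["t_start"], df["label_hr"], "k-", lw=1, label="reference HR")
    for route, color in (("fft", "tab:red"), ("b1", "tab:green"), ("b2", "tab:blue")):
        sub = df[df["route"] == route]
        ax.plot(sub["t_start"], sub["hr_pred"], ".", ms=3, color=color, label=route)
    ax.set_xlabel("time (s)")
    ax.set_ylabel("HR (bpm)")
    ax.legend(loc="upper left", fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
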