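"""Frequentist change-point detectors.

Three families:

* AMOC ("at most one change") Gaussian likelihood tests for a change in the
  mean, the variance, or both, with an information-criterion penalty;
* batch change-point-model (CPM) detection: maximize a standardized
  two-sample statistic over all admissible splits of the full series and
  compare against a Monte-Carlo null quantile at significance ``alpha``;
* sequential CPM detection: process observations in order, computing the
  same max-statistic on the data seen so far, and signal when it exceeds a
  threshold curve calibrated for a configured in-control average run length
  (ARL0; the benchmark operating point is 50,000).

All reported onsets are the change-point *estimate* (the earliest
maximizing split), not the detection time.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from . import _kernels as _k
from .calibration import batch_null_quantile, sequential_threshold_curve
from .io import EmgRecording, full_wave_rectify
from .standard import OnsetResult

__all__ = [
    "AmocConfig",
    "CpmConfig",
    "amoc_detect",
    "two_sample_statistic",
    "batch_cpm_detect",
    "sequential_cpm_detect",
    "MODEL_CODES",
    "SEQUENTIAL_MODELS",
    "BATCH_MODELS",
]

MODEL_CODES = _k.MODEL_CODES

SEQUENTIAL_MODELS = (
    "Student",
    "Bartlett",
    "GLR",
    "GLR_Exponential",
    "GLR_Exponential_FiniteCorrection",
    "MannWhitney",
    "Mood",
    "CramerVonMises",
)

BATCH_MODELS = (
    "Student",
    "Bartlett",
    "GLR",
    "MannWhitney",
    "Mood",
    "KolmogorovSmirnov",
    "CramerVonMises",
)

_EXP_MODELS = ("GLR_Exponential", "GLR_Exponential_FiniteCorrection")


@dataclass(frozen=True)
class AmocConfig:
    """At-most-one-change test configuration.

    ``penalty``: numeric threshold on 2*Delta-logL, or one of
    ``"MBIC"`` ((p+2)*log n, the conventional default) and
    ``"BIC"`` (p*log n), with p the number of changing parameters.
    """

    statistic: str = "mean"  # 'mean' | 'variance' | 'meanvar'
    penalty: object = "MBIC"
    rectified: bool = False

    def __post_init__(self) -> None:
        if self.statistic not in ("mean", "variance", "meanvar"):
            raise ValueError(f"unknown AMOC statistic {self.statistic!r}")

    @property
    def config_id(self) -> str:
        return f"amoc_{self.statistic}_{'rect' if self.rectified else 'raw'}"


@dataclass(frozen=True)
class CpmConfig:
    """Change-point-model configuration (the benchmark grids use
    arl0=50000 for sequential and alpha=0.05 for batch)."""

    mode: str = "batch"  # 'batch' | 'sequential'
    model: str = "Student"
    arl0: float = 50000.0
    alpha: float = 0.05
    startup: int = 20
    rectified: bool = False

    def __post_init__(self) -> None:
        if self.mode == "sequential":
            if self.model not in SEQUENTIAL_MODELS:
                raise ValueError(
                    f"{self.model!r} is not a sequential CPM model"
                )
        elif self.mode == "batch":
            if self.model not in BATCH_MODELS:
                raise ValueError(f"{self.model!r} is not a batch CPM model")
        else:
            raise ValueError(f"unknown mode {self.mode!r}")

    @property
    def config_id(self) -> str:
        tag = "rect" if self.rectified else "raw"
        return f"cpm_{'seq' if self.mode == 'sequential' else 'batch'}_{self.model}_{tag}"


def _prepare(rec: EmgRecording, rectified: bool, model: Optional[str]) -> np.ndarray:
    x = full_wave_rectify(rec).samples if rectified else rec.samples
    if model in _EXP_MODELS and np.any(x < 0):
        raise ValueError(
            f"{model} requires positive data; run on rectified EMG"
        )
    return np.ascontiguousarray(x, dtype=np.float64)


# ---------------------------------------------------------------------------
# AMOC

def _amoc_curve(x: np.ndarray, statistic: str) -> np.ndarray:
    """2*Delta-logL for a single split at every k in [2, n-2] (vectorized);
    index i of the returned array corresponds to split k = i + 2."""
    n = x.size
    k = np.arange(2, n - 1)
    cx = np.concatenate(([0.0], np.cumsum(x)))
    cxx = np.concatenate(([0.0], np.cumsum(x * x)))
    s1, s2 = cx[k], cx[-1] - cx[k]
    q1, q2 = cxx[k], cxx[-1] - cxx[k]
    l = n - k
    rss0 = cxx[-1] - cx[-1] ** 2 / n
    with np.errstate(divide="ignore", invalid="ignore"):
        if statistic == "mean":
            rss1 = (q1 - s1**2 / k) + (q2 - s2**2 / l)
            # a zero residual is a perfect fit of the changed model
            stat = np.where(rss1 <= 0, np.inf, n * np.log(rss0 / rss1))
        elif statistic == "variance":
            mu = cx[-1] / n
            a1 = q1 - 2 * mu * s1 + k * mu**2
            a2 = q2 - 2 * mu * s2 + l * mu**2
            stat = n * np.log(rss0 / n) - k * np.log(a1 / k) - l * np.log(a2 / l)
        else:  # meanvar
            w1 = q1 - s1**2 / k
            w2 = q2 - s2**2 / l
            stat = n * np.log(rss0 / n) - k * np.log(w1 / k) - l * np.log(w2 / l)
    # degenerate zero-variance segments make the variance models unbounded;
    # those splits are excluded (-inf). +inf from a perfect mean fit stands.
    return np.where(np.isnan(stat) | (stat == -np.inf), -np.inf, stat)


_AMOC_NPARAMS = {"mean": 1, "variance": 1, "meanvar": 2}


def amoc_detect(rec: EmgRecording, cfg: AmocConfig = AmocConfig()) -> OnsetResult:
    """Single-change Gaussian likelihood test; reports the maximizing split
    (first index of the new regime) when 2*Delta-logL exceeds the penalty."""
    x = _prepare(rec, cfg.rectified, None)
    n = x.size
    if n < 4:
        raise ValueError("AMOC needs at least 4 samples")
    if np.ptp(x) == 0:
        return OnsetResult.none(cfg.config_id, note="zero-variance series")
    curve = _amoc_curve(x, cfg.statistic)
    if isinstance(cfg.penalty, str):
        p = _AMOC_NPARAMS[cfg.statistic]
        pen = (p + 2) * np.log(n) if cfg.penalty == "MBIC" else p * np.log(n)
    else:
        pen = float(cfg.penalty)
    best = int(np.argmax(curve))
    if curve[best] <= pen:
        return OnsetResult.none(cfg.config_id, note="no significant change")
    return OnsetResult.at(best + 2, rec.fs, cfg.config_id)


# ---------------------------------------------------------------------------
# two-sample statistics and CPM detection

def two_sample_statistic(x: np.ndarray, split: int, model: str) -> float:
    """Standardized two-sample statistic comparing x[0:split] vs x[split:].

    Parametric models return likelihood-ratio-type statistics; rank models
    return |Z| scores standardized by their null mean/SD.
    """
    x = np.ascontiguousarray(x, dtype=np.float64)
    n = x.size
    if not 2 <= split <= n - 2:
        raise ValueError(f"split {split} not in [2, {n - 2}]")
    code = MODEL_CODES[model]
    if model in _EXP_MODELS and np.any(x < 0):
        raise ValueError(f"{model} requires positive data; rectify first")
    if code <= _k.GLR_EXP_FC:
        cumx = np.concatenate(([0.0], np.cumsum(x)))
        cumxx = np.concatenate(([0.0], np.cumsum(x * x)))
        return float(_k._param_stat(cumx, cumxx, n, split, code))
    order = np.argsort(x, kind="mergesort")
    if code == _k.KS:
        s, _ = _k._ks_scan(x[order], order, n, split, split)
        return float(s)
    if code == _k.CVM:
        s, _ = _k._cvm_scan(order, n, split, split)
        return float(s)
    r = np.empty(n)
    r[order] = np.arange(1, n + 1)
    s, _ = _k._rank_max(r, n, split, split, code)
    return float(s)


def batch_cpm_detect(rec: EmgRecording, cfg: CpmConfig) -> OnsetResult:
    """Retrospective CPM detection on the whole series at level alpha."""
    if cfg.mode != "batch":
        raise ValueError("config mode must be 'batch'")
    x = _prepare(rec, cfg.rectified, cfg.model)
    n = x.size
    if n < 2 * cfg.startup:
        raise ValueError(
            f"series of length {n} shorter than 2*startup={2 * cfg.startup}"
        )
    if np.ptp(x) == 0:
        return OnsetResult.none(cfg.config_id, note="constant series")
    d, k = _k.batch_scan(x, MODEL_CODES[cfg.model], cfg.startup)
    thr = batch_null_quantile(cfg.model, n, cfg.alpha, startup=cfg.startup)
    if d <= thr or k < 0:
        return OnsetResult.none(cfg.config_id, note=f"D={d:.3f} <= h={thr:.3f}")
    return OnsetResult.at(k, rec.fs, cfg.config_id)


def sequential_cpm_detect(rec: EmgRecording, cfg: CpmConfig) -> OnsetResult:
    """Streaming CPM detection with ARL0-calibrated threshold curve.

    The reported onset is the change-point estimate at signal time; the
    detection (signal) time is recorded in the result note.
    """
    if cfg.mode != "sequential":
        raise ValueError("config mode must be 'sequential'")
    x = _prepare(rec, cfg.rectified, cfg.model)
    n = x.size
    if n < 2 * cfg.startup:
        raise ValueError(
            f"series of length {n} shorter than 2*startup={2 * cfg.startup}"
        )
    h = sequential_threshold_curve(cfg.model, cfg.arl0, n, startup=cfg.startup)
    t, k, _ = _k.seq_scan(x, MODEL_CODES[cfg.model], cfg.startup, h, n, 0)
    if t < 0 or k < 0:
        return OnsetResult.none(cfg.config_id, note="stream ended unsignalled")
    return OnsetResult.at(k, rec.fs, cfg.config_id, note=f"signal at t={t}")
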