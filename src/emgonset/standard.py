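"""Standard EMG onset detectors: linear envelope, TKEO-preconditioned
envelope, and sliding-window sample entropy.

The linear-envelope pipeline follows the classic amplitude-threshold recipe:
(optional Teager-Kaiser preconditioning) -> full-wave rectification ->
zero-lag low-pass -> first strict exceedance of mean + k*SD of a baseline
window. The TKEO stage is applied *before* rectification because the
operator's output can be negative on noisy data.

The sample-entropy detector slides a short window along the signal and
declares onset at the first window whose SampEn exceeds a fixed threshold
(0.6). SampEn is computed with Chebyshev distance, self-matches excluded.
The tolerance r is, by default, a fraction of the whole-recording SD: with a
per-window scale the statistic is scale-invariant and a white-noise baseline
would already exceed the threshold, which defeats onset detection.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .io import EmgRecording, lowpass_envelope

__all__ = [
    "OnsetResult",
    "LinearEnvelopeConfig",
    "SampEnConfig",
    "teager_kaiser",
    "linear_envelope_onset",
    "sample_entropy",
    "sampen_onset",
    "ENVELOPE_CUTOFFS_HZ",
    "ENVELOPE_THRESHOLD_SDS",
]

#: the low-pass cutoff grid: 2-20 Hz every 2 Hz, then 25-50 Hz every 5 Hz
ENVELOPE_CUTOFFS_HZ = tuple(range(2, 21, 2)) + tuple(range(25, 51, 5))
#: the threshold grid, in baseline standard deviations
ENVELOPE_THRESHOLD_SDS = (1.0, 2.0, 3.0, 15.0)


@dataclass(frozen=True)
class OnsetResult:
    """A detector's verdict on a single trial.

    ``detected=False`` covers both "no onset found" and configurations that
    errored on this input (see ``note``); index/time are then ``None``.
    """

    detected: bool
    index: Optional[int] = None
    time_s: Optional[float] = None
    config_id: str = ""
    note: str = ""

    def __post_init__(self) -> None:
        if self.detected:
            if self.index is None or self.index < 0:
                raise ValueError("detected result requires a valid index")
        else:
            if self.index is not None or self.time_s is not None:
                raise ValueError("undetected result must not carry an index")

    @staticmethod
    def at(index: int, fs: float, config_id: str = "", note: str = "") -> "OnsetResult":
        return OnsetResult(
            detected=True, index=int(index), time_s=index / fs,
            config_id=config_id, note=note,
        )

    @staticmethod
    def none(config_id: str = "", note: str = "") -> "OnsetResult":
        return OnsetResult(detected=False, config_id=config_id, note=note)


@dataclass(frozen=True)
class LinearEnvelopeConfig:
    """Linear-envelope threshold detector settings.

    ``edge_guard_s`` excludes threshold crossings within the zero-phase
    filter's boundary transient at the start of the record (default: one
    cutoff period, 1/cutoff_hz); crossings there are filter artifacts, not
    muscle activity.
    """

    cutoff_hz: float = 10.0
    threshold_sd: float = 3.0
    baseline_dur_s: float = 0.5
    tkeo: bool = False
    edge_guard_s: Optional[float] = None

    @property
    def effective_edge_guard_s(self) -> float:
        if self.edge_guard_s is not None:
            return self.edge_guard_s
        return 1.0 / self.cutoff_hz

    @property
    def config_id(self) -> str:
        stem = "tkeo" if self.tkeo else "env"
        return f"{stem}_lp{self.cutoff_hz:g}_sd{self.threshold_sd:g}"


@dataclass(frozen=True)
class SampEnConfig:
    """Sliding-window SampEn detector settings.

    ``r`` scales the match tolerance by the whole-recording SD (default):
    because the recording includes the burst, the tolerance adapts to
    signal strength — baselines match almost everywhere (SampEn near 0)
    while active EMG stays well above the 0.6 threshold.
    ``min_consecutive`` windows must exceed the threshold before onset is
    declared, suppressing isolated baseline excursions; onset is reported
    at the first window of the run.
    """

    window_ms: float = 32.0
    step_ms: float = 4.0
    m: int = 2
    r: float = 0.35
    threshold: float = 0.6
    r_scale: str = "signal"  # 'signal' | 'baseline' | 'window'
    baseline_dur_s: float = 0.5
    min_consecutive: int = 3

    def __post_init__(self) -> None:
        if not self.window_ms > self.step_ms > 0:
            raise ValueError("need window_ms > step_ms > 0")
        if self.m < 1 or self.r <= 0:
            raise ValueError("need m >= 1 and r > 0")
        if self.r_scale not in ("signal", "baseline", "window"):
            raise ValueError("r_scale must be 'signal', 'baseline' or 'window'")

    @property
    def config_id(self) -> str:
        return f"sampen_w{self.window_ms:g}_s{self.step_ms:g}_t{self.threshold:g}"


def teager_kaiser(x: np.ndarray) -> np.ndarray:
    """Teager-Kaiser energy operator, psi[n] = x[n]^2 - x[n-1]*x[n+1].

    Output has the input's length; the two endpoints replicate the nearest
    interior value (onsets are interior, so the replication is inert).
    For a discrete sinusoid A*sin(w0*n + phi) the interior output is the
    constant A^2 sin^2(w0).
    """
    x = np.asarray(x, dtype=np.float64)
    if x.size < 3:
        raise ValueError("TKEO needs at least 3 samples")
    psi = np.empty_like(x)
    psi[1:-1] = x[1:-1] ** 2 - x[:-2] * x[2:]
    psi[0] = psi[1]
    psi[-1] = psi[-2]
    return psi


def linear_envelope_onset(
    rec: EmgRecording, cfg: LinearEnvelopeConfig = LinearEnvelopeConfig()
) -> OnsetResult:
    """Linear-envelope threshold detector (optionally TKEO-preconditioned).

    Threshold T = mean + k*SD of the envelope over the first
    ``baseline_dur_s`` seconds; onset is the first index with envelope > T
    (strict, so an all-zero signal is never detected). If the baseline SD is
    zero, T degenerates to the baseline mean.
    """
    n_base = int(round(cfg.baseline_dur_s * rec.fs))
    if rec.n_samples < n_base or n_base < 2:
        raise ValueError("recording shorter than the baseline window")
    x = rec.samples
    if cfg.tkeo:
        x = teager_kaiser(x)
    env = lowpass_envelope(rec.with_samples(np.abs(x)), cfg.cutoff_hz).samples
    base = env[:n_base]
    thr = base.mean() + cfg.threshold_sd * base.std(ddof=1)
    guard = int(round(cfg.effective_edge_guard_s * rec.fs))
    above = np.nonzero(env[guard:] > thr)[0]
    if above.size == 0:
        return OnsetResult.none(cfg.config_id, note="threshold never exceeded")
    return OnsetResult.at(int(above[0]) + guard, rec.fs, cfg.config_id)


def sample_entropy(window: np.ndarray, m: int = 2, r: float = 0.2) -> float:
    """Sample entropy of a window: -ln(A/B) with A the number of (m+1)-point
    template matches and B the number of m-point matches, Chebyshev distance
    within tolerance ``r`` (amplitude units, match iff d <= r), self-matches
    excluded.

    Returns ``nan`` ("undefined") when either count is zero.
    """
    x = np.asarray(window, dtype=np.float64)
    n = x.size
    if n <= m + 1:
        raise ValueError(f"window length {n} must exceed m+1={m + 1}")

    # both template sets run over the same n-m starting points, so A/B is a
    # conditional probability of continued matching (tolerance is <= r)
    n_templ = n - m
    xm = x[np.arange(m)[None, :] + np.arange(n_templ)[:, None]]
    xm1 = x[np.arange(m + 1)[None, :] + np.arange(n_templ)[:, None]]

    dm = np.abs(xm[:, None, :] - xm[None, :, :]).max(axis=2)
    b = int((dm <= r).sum() - n_templ) // 2
    dm1 = np.abs(xm1[:, None, :] - xm1[None, :, :]).max(axis=2)
    a = int((dm1 <= r).sum() - n_templ) // 2
    if a == 0 or b == 0:
        return math.nan
    return -math.log(a / b)


def sampen_onset(
    rec: EmgRecording, cfg: SampEnConfig = SampEnConfig()
) -> OnsetResult:
    """Sliding-window SampEn detector: onset at the start of the first window
    whose sample entropy strictly exceeds ``cfg.threshold``.

    Windows where SampEn is undefined (no template matches) are skipped.
    """
    fs = rec.fs
    x = rec.samples
    w = int(round(cfg.window_ms * 1e-3 * fs))
    step = max(int(round(cfg.step_ms * 1e-3 * fs)), 1)
    if x.size <= w:
        raise ValueError("recording shorter than one SampEn window")
    if cfg.r_scale == "signal":
        scale = x.std()
    elif cfg.r_scale == "baseline":
        scale = x[: int(round(cfg.baseline_dur_s * fs))].std()
    else:
        scale = None  # per-window
    n_skipped = 0
    run_start = None
    run_len = 0
    for start in range(0, x.size - w + 1, step):
        win = x[start : start + w]
        r_abs = cfg.r * (win.std() if scale is None else scale)
        if r_abs == 0:
            n_skipped += 1
            run_len = 0
            continue
        se = sample_entropy(win, m=cfg.m, r=r_abs)
        if math.isnan(se):
            n_skipped += 1
            run_len = 0
            continue
        if se > cfg.threshold:
            if run_len == 0:
                run_start = start
            run_len += 1
            if run_len >= cfg.min_consecutive:
                note = f"{n_skipped} undefined windows skipped" if n_skipped else ""
                return OnsetResult.at(run_start, fs, cfg.config_id, note=note)
        else:
            run_len = 0
    return OnsetResult.none(cfg.config_id, note="SampEn never exceeded threshold")
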