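"""Reading, writing and preprocessing of single-channel surface EMG.

The on-disk format is deliberately minimal and diff-friendly: ``#``-prefixed
``key=value`` header lines (``fs``, ``trial_id``, ``movement``,
``gold_onset_s``, ``seed``) followed by one amplitude sample per row.

All filters are zero-lag (forward-backward) Butterworth filters implemented
as second-order sections, the standard choice for surface-EMG conditioning.
Edge handling uses reflective padding of length 3x the filter order so that
onset indices near the boundaries are reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Optional

import numpy as np
from scipy import signal as _sig

__all__ = [
    "EmgRecording",
    "FilterSpec",
    "read_recording",
    "write_recording",
    "bandpass",
    "full_wave_rectify",
    "lowpass_envelope",
]


@dataclass(frozen=True)
class EmgRecording:
    """A sampled single-channel EMG signal.

    Parameters
    ----------
    samples : np.ndarray
        Amplitude series (arbitrary units, typically mV).
    fs : float
        Sampling rate in Hz; 2048 Hz is the benchmark convention.
    trial_id : str
        Text label for the trial.
    movement : str, optional
        Text label of the movement performed.
    gold_onset_s : float, optional
        Known (synthetic) or consensus onset time in seconds. Absent for
        unlabeled data.
    """

    samples: np.ndarray
    fs: float
    trial_id: str = ""
    movement: Optional[str] = None
    gold_onset_s: Optional[float] = None

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=np.float64)
        if samples.ndim != 1:
            raise ValueError("samples must be one-dimensional")
        if samples.size < 2:
            raise ValueError("a recording needs at least 2 samples")
        if not np.isfinite(self.fs) or self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        object.__setattr__(self, "samples", samples)
        if self.gold_onset_s is not None:
            dur = samples.size / self.fs
            if not 0.0 <= self.gold_onset_s < dur:
                raise ValueError(
                    f"gold_onset_s={self.gold_onset_s} outside [0, {dur}) s"
                )

    @property
    def n_samples(self) -> int:
        return int(self.samples.size)

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.fs

    @property
    def gold_onset_index(self) -> Optional[int]:
        if self.gold_onset_s is None:
            return None
        return int(round(self.gold_onset_s * self.fs))

    def with_samples(self, samples: np.ndarray) -> "EmgRecording":
        """Copy of this recording with the amplitude series replaced."""
        return replace(self, samples=np.asarray(samples, dtype=np.float64))


@dataclass(frozen=True)
class FilterSpec:
    """Butterworth filter specification.

    ``kind`` is ``"bandpass"`` (uses ``low_hz`` and ``high_hz``) or
    ``"lowpass"`` (uses ``high_hz`` only). ``zero_lag`` selects
    forward-backward application, giving zero phase shift.
    """

    kind: str
    high_hz: float
    low_hz: Optional[float] = None
    order: int = 4
    zero_lag: bool = True

    def __post_init__(self) -> None:
        if self.kind not in ("bandpass", "lowpass"):
            raise ValueError(f"unknown filter kind {self.kind!r}")
        if self.order < 1:
            raise ValueError("filter order must be >= 1")
        if self.kind == "bandpass":
            if self.low_hz is None:
                raise ValueError("bandpass requires low_hz")
            if not 0 < self.low_hz < self.high_hz:
                raise ValueError("need 0 < low_hz < high_hz")
        elif self.high_hz <= 0:
            raise ValueError("need high_hz > 0")

    def validate_for(self, fs: float) -> None:
        nyq = fs / 2.0
        if self.high_hz >= nyq:
            raise ValueError(
                f"cutoff {self.high_hz} Hz >= Nyquist {nyq} Hz (fs={fs})"
            )


_HEADER_KEYS = ("fs", "trial_id", "movement", "gold_onset_s", "seed")


def read_recording(path, fs_default: Optional[float] = None) -> EmgRecording:
    """Read a delimited-text EMG recording.

    Header lines of the form ``# key=value`` carry metadata; header values
    override ``fs_default``. Raises ``ValueError`` naming the offending line
    for a malformed numeric row, and if no sampling rate is available at all.
    """
    path = Path(path)
    meta: dict = {}
    values = []
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if "=" in body:
                    key, _, val = body.partition("=")
                    meta[key.strip()] = val.strip()
                continue
            try:
                values.append(float(line))
            except ValueError as exc:
                raise ValueError(
                    f"{path}: malformed numeric row at line {lineno}: {line!r}"
                ) from exc
    fs = float(meta["fs"]) if "fs" in meta else fs_default
    if fs is None:
        raise ValueError(
            f"{path}: no 'fs' header and no fs_default supplied"
        )
    gold = meta.get("gold_onset_s")
    return EmgRecording(
        samples=np.asarray(values, dtype=np.float64),
        fs=float(fs),
        trial_id=meta.get("trial_id", path.stem),
        movement=meta.get("movement") or None,
        gold_onset_s=float(gold) if gold is not None else None,
    )


def write_recording(rec: EmgRecording, path) -> Path:
    """Write a recording in the package's text format; returns the path.

    Round-trips samples at full double precision (%.17g) and metadata exactly.
    """
    path = Path(path)
    lines = [f"# fs={rec.fs:.17g}"]
    if rec.trial_id:
        lines.append(f"# trial_id={rec.trial_id}")
    if rec.movement:
        lines.append(f"# movement={rec.movement}")
    if rec.gold_onset_s is not None:
        lines.append(f"# gold_onset_s={rec.gold_onset_s:.17g}")
    lines.extend(f"{v:.17g}" for v in rec.samples)
    path.write_text("\n".join(lines) + "\n")
    return path


def _sos(spec: FilterSpec, fs: float) -> np.ndarray:
    spec.validate_for(fs)
    nyq = fs / 2.0
    if spec.kind == "bandpass":
        wn = (spec.low_hz / nyq, spec.high_hz / nyq)
        return _sig.butter(spec.order, wn, btype="bandpass", output="sos")
    return _sig.butter(spec.order, spec.high_hz / nyq, btype="lowpass", output="sos")


def _apply(rec: EmgRecording, spec: FilterSpec) -> EmgRecording:
    sos = _sos(spec, rec.fs)
    x = rec.samples
    if spec.zero_lag:
        # padlen = 3 * order: reflective padding fixed so boundary-adjacent
        # onset indices are reproducible across releases.
        padlen = min(3 * spec.order * 2, x.size - 1)
        y = _sig.sosfiltfilt(sos, x, padtype="even", padlen=padlen)
    else:
        y = _sig.sosfilt(sos, x)
    return rec.with_samples(y)


def bandpass(rec: EmgRecording, spec: FilterSpec) -> EmgRecording:
    """Band-pass filter a recording (default use: the 10-1000 Hz artifact
    filter applied before every detector)."""
    if spec.kind != "bandpass":
        raise ValueError("bandpass() requires a bandpass FilterSpec")
    return _apply(rec, spec)


def full_wave_rectify(rec: EmgRecording) -> EmgRecording:
    """Full-wave rectification: every sample replaced by its absolute value."""
    return rec.with_samples(np.abs(rec.samples))


def lowpass_envelope(
    rec: EmgRecording, cutoff_hz: float, order: int = 2, zero_lag: bool = True
) -> EmgRecording:
    """Zero-lag low-pass filter, the smoothing stage of a linear envelope.

    A 2nd-order Butterworth applied forward-backward (4th-order magnitude
    response overall), the conventional envelope smoother for surface EMG.
    """
    spec = FilterSpec(kind="lowpass", high_hz=cutoff_hz, order=order, zero_lag=zero_lag)
    return _apply(rec, spec)
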