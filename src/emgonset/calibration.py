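"""Monte-Carlo calibration of CPM detection thresholds.

Batch thresholds are the (1 - alpha) quantile of the null distribution of
the max-split statistic D at the requested series length, simulated under
an i.i.d. Gaussian null (Exponential(1) for the exponential-likelihood
models, which assume positive data). They are computed on demand and cached
in-process; a full calibration at n ~ 1000 takes seconds.

Sequential threshold curves h_t aim at a constant false-alarm hazard
1/ARL0 per observation. They are calibrated by the conditional-quantile
method: simulate many in-control streams, and at each t set h_t to the
(1 - 1/ARL0) quantile of D_t among streams that have not yet alarmed,
removing those that alarm. Direct calibration at the benchmark's ARL0 = 50,000
would need ~10^6 streams, so curves are calibrated on a grid of reachable
ARL0 values and extended to large ARL0 by a per-t linear fit in ln(ARL0)
(threshold growth in ln ARL0 is the standard first-order behaviour for
maxima of standardized statistics). A coarse pre-built table ships with the
package (``data/seq_thresholds.json``, built by
``scripts/build_calibration.py``); thresholds for any ARL0 within the
table's range are interpolated log-linearly.
"""

from __future__ import annotations

import json
from functools import lru_cache
from importlib import resources
from typing import Dict, Optional, Sequence

import numpy as np

from . import _kernels as _k

__all__ = [
    "batch_null_quantile",
    "sequential_threshold_curve",
    "calibrate_sequential",
    "load_sequential_table",
]

_EXP_MODELS = {"GLR_Exponential", "GLR_Exponential_FiniteCorrection"}

#: fixed seed for threshold calibration: thresholds are part of the method,
#: not of any particular analysis, so they do not vary with analysis seeds.
_CAL_SEED = 746291


def _null_stream(model: str, size, rng: np.random.Generator) -> np.ndarray:
    if model in _EXP_MODELS:
        return rng.exponential(1.0, size)
    return rng.standard_normal(size)


_batch_cache: Dict[tuple, float] = {}


def batch_null_quantile(
    model: str,
    n: int,
    alpha: float = 0.05,
    startup: int = 20,
    reps: int = 2000,
    seed: int = _CAL_SEED,
) -> float:
    """(1-alpha) null quantile of the batch max-split statistic D."""
    key = (model, int(n), round(float(alpha), 6), int(startup), int(reps), int(seed))
    if key not in _batch_cache:
        code = _k.MODEL_CODES[model]
        rng = np.random.default_rng([seed, code, n])
        ds = np.empty(reps)
        for i in range(reps):
            x = _null_stream(model, n, rng)
            ds[i], _ = _k.batch_scan(x, code, startup)
        _batch_cache[key] = float(np.quantile(ds, 1.0 - alpha))
    return _batch_cache[key]


# ---------------------------------------------------------------------------
# sequential calibration

def _running_median(h: np.ndarray, width: int = 31) -> np.ndarray:
    out = h.copy()
    half = width // 2
    n = h.size
    for i in range(n):
        lo = max(0, i - half)
        hi = min(n, i + half + 1)
        out[i] = np.median(h[lo:hi])
    return out


def calibrate_sequential(
    model: str,
    arl0_grid: Sequence[float],
    extrapolate_to: Sequence[float] = (),
    n_streams: int = 4000,
    tmax: int = 1024,
    startup: int = 20,
    seed: int = _CAL_SEED,
    t_grid: Optional[Sequence[int]] = None,
) -> dict:
    """Conditional-quantile calibration of h_t curves for one model.

    Returns a dict with ``t_grid``, ``arl0_grid`` (calibrated + extrapolated,
    ascending) and ``h`` (one curve per ARL0, sampled on ``t_grid``).
    """
    code = _k.MODEL_CODES[model]
    rng = np.random.default_rng([seed, code])
    hinf = np.full(tmax, np.inf)
    trajs = np.empty((n_streams, tmax))
    for i in range(n_streams):
        x = _null_stream(model, tmax, rng)
        _, _, traj = _k.seq_scan(x, code, startup, hinf, tmax, 1)
        trajs[i] = traj
    t0 = 2 * startup  # first monitored t

    curves: Dict[float, np.ndarray] = {}
    for arl0 in sorted(arl0_grid):
        p = 1.0 - 1.0 / arl0
        alive = np.ones(n_streams, dtype=bool)
        h = np.full(tmax, np.nan)
        for ti in range(t0 - 1, tmax):
            d = trajs[alive, ti]
            if d.size < 20:
                h[ti] = h[ti - 1]
                continue
            q = float(np.quantile(d, p))
            h[ti] = q
            alive &= ~(trajs[:, ti] > q)
        h[t0 - 1 :] = _running_median(h[t0 - 1 :])
        curves[float(arl0)] = h

    cal_arl0s = np.array(sorted(curves))
    if extrapolate_to:
        # per-t linear fit of h against ln(ARL0) over the calibrated grid
        la = np.log(cal_arl0s)
        hmat = np.stack([curves[a] for a in cal_arl0s])  # (n_arl0, tmax)
        a_ = np.vstack([np.ones_like(la), la]).T
        coef, *_ = np.linalg.lstsq(a_, hmat, rcond=None)  # (2, tmax)
        for target in extrapolate_to:
            pred = coef[0] + coef[1] * np.log(target)
            pred[t0 - 1 :] = _running_median(pred[t0 - 1 :])
            curves[float(target)] = pred

    all_arl0s = sorted(curves)
    # enforce monotonicity in ARL0 (larger ARL0 -> rarer alarms -> higher h)
    stack = np.stack([curves[a] for a in all_arl0s])
    stack = np.maximum.accumulate(stack, axis=0)

    if t_grid is None:
        dense = list(range(t0, min(t0 + 40, tmax + 1)))
        rest = np.unique(
            np.geomspace(min(t0 + 40, tmax), tmax, 40).astype(int)
        ).tolist()
        t_grid = sorted(set(dense + rest))
    t_idx = np.asarray(t_grid, dtype=int) - 1
    return {
        "model": model,
        "startup": startup,
        "n_streams": n_streams,
        "tmax": tmax,
        "seed": seed,
        "calibrated_arl0": [float(a) for a in cal_arl0s],
        "arl0_grid": [float(a) for a in all_arl0s],
        "t_grid": [int(t) for t in t_grid],
        "h": [
            [round(float(v), 4) for v in stack[i, t_idx]]
            for i in range(len(all_arl0s))
        ],
    }


@lru_cache(maxsize=1)
def load_sequential_table() -> dict:
    """Load the shipped coarse sequential-threshold table."""
    ref = resources.files("emgonset").joinpath("data/seq_thresholds.json")
    with ref.open() as fh:
        return json.load(fh)


@lru_cache(maxsize=256)
def _curve_cached(model: str, arl0: float, n: int, startup: int) -> tuple:
    table = load_sequential_table()
    if model not in table["models"]:
        raise ValueError(
            f"no calibration table for sequential model {model!r}; "
            "run calibrate_sequential() and extend the table"
        )
    entry = table["models"][model]
    if startup != entry["startup"]:
        raise ValueError(
            f"table calibrated with startup={entry['startup']}, got {startup}"
        )
    arl0s = np.asarray(entry["arl0_grid"])
    hmat = np.asarray(entry["h"])  # (n_arl0, n_tgrid)
    if not arl0s[0] <= arl0 <= arl0s[-1]:
        raise ValueError(
            f"ARL0={arl0} outside table range [{arl0s[0]}, {arl0s[-1]}]; "
            "recalibrate to extend"
        )
    # log-linear interpolation across the ARL0 grid
    la = np.log(arl0s)
    hi = np.searchsorted(la, np.log(arl0))
    if hi == 0 or la[min(hi, la.size - 1)] == np.log(arl0):
        hrow = hmat[min(hi, la.size - 1)]
    else:
        lo = hi - 1
        w = (np.log(arl0) - la[lo]) / (la[hi] - la[lo])
        hrow = (1 - w) * hmat[lo] + w * hmat[hi]
    t_grid = np.asarray(entry["t_grid"], dtype=float)
    t = np.arange(1, n + 1, dtype=float)
    h = np.interp(t, t_grid, hrow)  # constant beyond the grid ends
    h[: 2 * startup - 1] = np.inf  # not monitored before 2*startup
    return tuple(h)


def sequential_threshold_curve(
    model: str, arl0: float, n: int, startup: int = 20
) -> np.ndarray:
    """Threshold curve h (length n, h[t-1] applies at observation t)."""
    return np.asarray(
        _curve_cached(model, float(arl0), int(n), int(startup))
    )
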