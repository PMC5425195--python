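"""Build the shipped sequential-threshold table.

Calibrates h_t curves for every sequential CPM model by the
conditional-quantile method on in-control streams, extends them to large
ARL0 by a per-t linear fit in ln(ARL0), and writes
src/emgonset/data/seq_thresholds.json.

Run from the repository root:  python scripts/build_calibration.py
"""

import json
import sys
import time
from pathlib import Path

from emgonset.calibration import calibrate_sequential
from emgonset.changepoint import SEQUENTIAL_MODELS

OUT = Path(__file__).resolve().parents[1] / "src" / "emgonset" / "data" / "seq_thresholds.json"

# directly calibrated ARL0 values (tail quantiles reachable with the stream
# counts below) and the extrapolated targets, including the operating 50,000
ARL0_GRID = [74.0, 150.0, 370.0, 1000.0, 3000.0]
EXTRAPOLATE = [5000.0, 50000.0]


def main() -> None:
    table = {"meta": {"arl0_grid": ARL0_GRID, "extrapolated": EXTRAPOLATE}, "models": {}}
    for model in SEQUENTIAL_MODELS:
        # the CvM scan is O(t log t) per step; use a shorter horizon there
        if model == "CramerVonMises":
            n_streams, tmax = 1500, 640
        else:
            n_streams, tmax = 6000, 1024
        t0 = time.time()
        entry = calibrate_sequential(
            model,
            ARL0_GRID,
            extrapolate_to=EXTRAPOLATE,
            n_streams=n_streams,
            tmax=tmax,
        )
        print(f"{model}: {time.time() - t0:.1f} s", file=sys.stderr)
        table["models"][model] = entry
    OUT.parent.mkdir(parents=True, exist_ok=True)
    OUT.write_text(json.dumps(table))
    print(f"wrote {OUT} ({OUT.stat().st_size / 1024:.1f} KiB)")


if __name__ == "__main__":
    main()
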