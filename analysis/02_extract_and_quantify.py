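#!/usr/bin/env python
"""Extract dF/F0, detect events and quantify oscillations and morphology.

Runs neuropil correction (r = 0.7), baseline F0 estimation, 3-SD event
detection with waveform metrics, per-view Spearman synchrony, FFT band
fractions and image morphometry for every simulated stage/condition, and
writes per-cell, per-view and per-image metric tables under
results/run/metrics/.
"""

import importlib.util
import sys
from pathlib import Path

import pandas as pd

from caosc.pipeline import run_pipeline

_sim = importlib.util.spec_from_file_location(
    "sim01", Path(__file__).resolve().parent / "01_simulate.py"
)
sim01 = importlib.util.module_from_spec(_sim)
_sim.loader.exec_module(sim01)


def main() -> None:
    run_pipeline(sim01.config(("simulate", "analyze")))
    metrics = sim01.OUT / "metrics"
    cells = pd.read_csv(metrics / "cell_metrics.csv")

    def mean_of(day, cond, col):
        sel = cells[(cells["div"] == day) & (cells["condition"] == cond)]
        return sel[col].mean()

    f3 = mean_of(3, "healthy", "frequency_mHz")
    f28 = mean_of(28, "healthy", "frequency_mHz")
    print(f"healthy mean event frequency: DIV3 {f3:.1f} mHz -> DIV28 {f28:.1f} mHz")
    w_t = mean_of(28, "toxic", "fwhm_s")
    w_h = mean_of(28, "healthy", "fwhm_s")
    print(
        f"DIV28 mean FWHM: toxic {w_t:.1f} s vs healthy {w_h:.1f} s "
        f"({w_t / w_h:.1f}-fold)"
    )
    views = pd.read_csv(metrics / "view_metrics.csv")
    sync = views[views["condition"] == "healthy"].set_index("div")["synchrony"]
    print(
        "healthy synchrony trajectory:",
        ", ".join(f"DIV{d}={v:.2f}" for d, v in sync.items()),
    )
    morph = pd.read_csv(metrics / "morph_records.csv")
    late = morph[morph["div"] == 28]
    for cond in ("healthy", "toxic"):
        sel = late[late["condition"] == cond]
        filled = (sel["nuclear_class"] == "nucleus_filled").mean()
        print(
            f"DIV28 {cond}: soma {sel['soma_area_um2'].mean():.0f} um^2, "
            f"neurites {sel['neurite_length_um'].mean():.0f} um, "
            f"nucleus-filled fraction {filled:.2f}"
        )


if __name__ == "__main__":
    sys.exit(main())
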