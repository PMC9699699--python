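#!/usr/bin/env python
"""Simulate the chronic-imaging experiment: 7 stages x 2 conditions.

Generates one field of view (30 cells, 600 s at 5 Hz) per developmental
stage (DIV 3-28) and condition (healthy GCaMP-X-like vs toxic GCaMP-like
probe), with neuropil-contaminated trace CSVs, ground-truth event tables
and representative neuron images, under results/run/data/.
"""

import sys
from pathlib import Path

from caosc.kernels import kernel_fwhm
from caosc.pipeline import RunConfig, run_pipeline
from caosc.presets import STAGE_DAYS, build_stage_presets

OUT = Path(__file__).resolve().parent.parent / "results" / "run"
SEED = 7


def config(stages):
    return RunConfig.from_dict(
        {
            "seed": SEED,
            "out_dir": str(OUT),
            "stages": list(stages),
            "simulate": {"write_images": True},
        }
    )


def main() -> None:
    presets = build_stage_presets()
    print("stage preset table (healthy | toxic):")
    print(f"{'DIV':>5} {'rate mHz':>18} {'amp dF/F0':>18} {'kernel FWHM s':>20}")
    for day in STAGE_DAYS:
        h = presets[(f"DIV{day}", "healthy")]
        t = presets[(f"DIV{day}", "toxic")]
        fw_h = kernel_fwhm(h.rise_tau, h.decay_tau, h.plateau_s)
        fw_t = kernel_fwhm(t.rise_tau, t.decay_tau, t.plateau_s)
        print(
            f"{day:>5} {h.event_rate_mHz:>8.0f} | {t.event_rate_mHz:<7.0f}"
            f" {h.amplitude_mean:>8.2f} | {t.amplitude_mean:<7.2f}"
            f" {fw_h:>9.2f} | {fw_t:<8.2f}"
        )
    run_pipeline(config(("simulate",)))
    n_files = len(list((OUT / "data").glob("*")))
    print(f"\nwrote {n_files} files under {OUT / 'data'}")


if __name__ == "__main__":
    sys.exit(main())
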