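#!/usr/bin/env python
"""Longitudinal profiles, growth rates, correlations and group tests.

Aggregates the per-cell/per-image metrics into stage (DIV) temporal
profiles with SEM, derives neurite/soma growth rates as first derivatives,
correlates the functional profiles (frequency, amplitude) with total
neurite length, and compares healthy vs toxic at DIV 28 (two-tailed
unpaired t-tests with star coding).  Tables land in results/run/report/.
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
    report = run_pipeline(sim01.config(("simulate", "analyze", "report")))
    tables = report.tables

    corr = tables["profile_correlations"].set_index("pair")
    r2_freq = corr.loc["frequency_vs_length"]
    r2_amp = corr.loc["amplitude_vs_length"]
    print(
        "frequency vs neurite length: slope "
        f"{r2_freq['slope']:.3f} (R^2 = {r2_freq['r2']:.2f}) — inverse relation"
    )
    print(
        "amplitude vs neurite length: slope "
        f"{r2_amp['slope']:.4f} (R^2 = {r2_amp['r2']:.2f}) — positive relation"
    )

    rates = tables["growth_rates_healthy"]
    for metric, grp in rates.groupby("metric"):
        peak = grp.loc[grp["rate_per_day"].idxmax()]
        print(
            f"peak {metric} growth rate {peak['rate_per_day']:.1f}/day "
            f"around DIV {peak['mid_div']:.0f}"
        )

    comp = tables["comparisons_DIV28"]
    print("\nDIV28 healthy vs toxic comparisons:")
    with pd.option_context("display.width", 120):
        print(comp.to_string(index=False))
    print(f"\nreport written under {sim01.OUT / 'report'}")


if __name__ == "__main__":
    sys.exit(main())
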