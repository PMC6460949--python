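#!/usr/bin/env python
"""Graded-pinch intensity coding: categories, recruitment, fidelity.

Runs the P0..P3 graded-pinch cohort (6 mice), classifies responders by the
shape of their amplitude-vs-intensity profile, and summarizes per level how
many cells are recruited, the mean response fidelity, and the mean peak
amplitude.  Expected pattern: recruitment, fidelity and amplitude all rise
monotonically from the innocuous P0 to the strongest pinch P3, and the
intensity-coding subpopulation is recovered nearly perfectly.
"""

from pathlib import Path

import pandas as pd

from s1pop.experiments import run_graded_pinch_experiment

RESULTS = Path(__file__).resolve().parent.parent / "results"
SEED = 3


def main():
    RESULTS.mkdir(exist_ok=True)
    result = run_graded_pinch_experiment(seed=SEED)

    cats = pd.Series(result["category_percent"], name="percent")
    cats.to_csv(RESULTS / "04_intensity_categories.csv")
    print(f"graded-pinch cohort: {result['n_responders']} responders")
    for cat, pct in result["category_percent"].items():
        print(f"  {cat:>16s}: {pct:5.2f}%")

    summary = pd.DataFrame(
        {
            "recruited_cells": result["recruited_cells"],
            "mean_fidelity": result["mean_fidelity"],
            "mean_amplitude": result["mean_amplitude"],
        }
    )
    summary.to_csv(RESULTS / "04_intensity_summary.csv")
    print("\nper-level summary:")
    print(summary.round(3).to_string())
    print(
        "\nintensity-coding recovery: "
        f"{100 * result['intensity_coding_recovery']:.1f}% of ground-truth "
        "intensity-coding cells classified correctly"
    )


if __name__ == "__main__":
    main()
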