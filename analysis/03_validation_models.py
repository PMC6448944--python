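#!/usr/bin/env python
"""Validation arm: OGTT indices, prevalent and incident disease, meta.

Takes the candidate ratios selected by 02_discovery_screen.py into
independent synthetic validation cohorts: linear models against six
OGTT surrogate indices (two cohorts), logistic models against prevalent
disease (three cohorts) and Cox models against incident disease (two
cohorts), each pooled by inverse-variance fixed-effects meta-analysis
with pooled p_gain columns.
"""

from pathlib import Path

import pandas as pd

from ratiomics.pipeline import RunConfig, run_validation

BASE = Path(__file__).resolve().parent.parent
OUT = BASE / "results" / "validation"
SEED = 1
N_METABOLITES = 40


def main() -> None:
    candidates_file = BASE / "results" / "discovery" / "candidate_ratios.txt"
    if candidates_file.exists():
        candidates = candidates_file.read_text().strip().splitlines()
    else:  # discovery step not run yet: fall back to the planted ratio
        candidates = ["Val_PC ae C32:2"]
    config = RunConfig(seed=SEED, n_metabolites=N_METABOLITES)
    summary = run_validation(config, candidates, OUT)

    print(f"candidates: {summary['n_candidates']} "
          f"({summary['n_usable']} usable, {len(summary['na_ratios'])} na)")
    ogtt = summary["ogtt_table"]
    print("\nOGTT meta-analysis (significant rows at p < "
          f"{summary['ogtt_threshold']:.1e}):")
    sig = ogtt[ogtt["significant"]]
    with pd.option_context("display.width", 120):
        print(sig.to_string(index=False) if len(sig) else "  none")
        print("\nprevalent-disease meta-analysis:")
        print(summary["prevalent_table"]
              [["ratio", "meta_beta", "meta_se", "meta_p", "p_gain"]]
              .to_string(index=False))
        print("\nincident-disease meta-analysis:")
        print(summary["incident_table"]
              [["ratio", "meta_beta", "meta_se", "meta_p", "p_gain"]]
              .to_string(index=False))


if __name__ == "__main__":
    main()
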