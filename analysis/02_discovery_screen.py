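#!/usr/bin/env python
"""Discovery arm: timepoint dynamics + exhaustive ratio screen.

Runs the family-clustered GEE screen on a simulated clamp cohort and
reports (a) per-class metabolite dynamics between clamp stages and
(b) the pairwise log-ratio screen with Bonferroni and p_gain criteria.

A 40-metabolite panel (780 ratios x 6 phenotypes = 4680 GEE fits) keeps
the demonstration quick; the machinery is identical at full panel size.
"""

from pathlib import Path

import numpy as np
import pandas as pd

import ratiomics as rm
from ratiomics import gee
from ratiomics.pipeline import RunConfig, run_discovery
from ratiomics.results import results_to_frame

OUT = Path(__file__).resolve().parent.parent / "results" / "discovery"
SCRATCH = Path(__file__).resolve().parent.parent / "scratch" / "discovery"
SEED = 1
N_METABOLITES = 40


def main() -> None:
    config = RunConfig(seed=SEED, n_metabolites=N_METABOLITES)

    # Timepoint contrasts (glucose, GLP-1 and arginine stages)
    panel = rm.make_panel(N_METABOLITES)
    bundle = rm.simulate_clamp_cohort(panel, config.effects,
                                      n_families=54, seed=SEED)
    dyn_rows = []
    for t_from, t_to, stage in ((0, 120, "glucose"), (120, 180, "glp1"),
                                (180, 190, "arginine")):
        res = gee.test_timepoint_change(bundle, t_from, t_to)
        frame = results_to_frame(res)
        frame["class"] = [panel.class_of(m) for m in frame["feature"]]
        frame["stage"] = stage
        frame["significant"] = frame["p"] < 0.05 / N_METABOLITES
        dyn_rows.append(frame)
    dynamics = pd.concat(dyn_rows, ignore_index=True)
    per_class = (
        dynamics.groupby(["stage", "class"])
        .agg(n=("feature", "size"), n_significant=("significant", "sum"),
             mean_log_change=("beta", "mean"))
        .reset_index()
    )

    # full per-test tables are bulky and reproducible from the seed:
    # persist them under scratch/, keep compact summaries in results/
    decisions = run_discovery(config, SCRATCH)
    hits = [d for d in decisions if d.selected]

    OUT.mkdir(parents=True, exist_ok=True)
    per_class.to_csv(OUT / "timepoint_dynamics_by_class.tsv", sep="\t",
                     index=False, float_format="%.4g")
    print("metabolite dynamics by clamp stage (counts significant at "
          f"p < {0.05 / N_METABOLITES:.1e}):")
    print(per_class.to_string(index=False))
    print(f"\nratio screen: {len(decisions)} ratio x phenotype tests, "
          f"{len(hits)} pass both Bonferroni and p_gain criteria")
    for d in hits[:10]:
        print(f"  {d.ratio:>24s}  {d.phenotype:<22s} "
              f"beta {d.beta:+.3f} (SE {d.se:.3f})  p {d.p_ratio:.2e}  "
              f"p_gain {d.p_gain:.3g}")
    np.savetxt(OUT / "candidate_ratios.txt",
               sorted({d.ratio for d in hits}), fmt="%s")
    from ratiomics.screen import decisions_to_frame
    decisions_to_frame(hits).to_csv(OUT / "screen_hits.tsv", sep="\t",
                                    index=False, float_format="%.6g")


if __name__ == "__main__":
    main()
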