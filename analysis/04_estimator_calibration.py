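#!/usr/bin/env python
"""Calibration of the improvement-oriented Cohen's d estimator.

Plants a single module-vs-retest improvement of d = 0.25 (upper end of the
reported Presence range) on one distress-coded variable and recovers it
with the two-sample estimator over many simulation replicates at the
study's group sizes (module n = 161 vs retest n = 90).  Writes the per-
replicate estimates and prints their mean and spread.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from modulearn import EffectSpec, NoiseSpec, cohens_d, default_panel, generate
from modulearn.design import Cohort, CohortDesign


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--n-replicates", type=int, default=1000)
    ap.add_argument("--out", type=Path, default=Path("results/d_calibration.tsv"))
    args = ap.parse_args()

    panel = default_panel()
    design = CohortDesign(
        (Cohort("RCC", 90, ()), Cohort("TC1", 80, ("Presence",)), Cohort("TC2", 81, ("Presence",)))
    )
    effects = EffectSpec({("Presence", "pcs_helplessness"): 0.25})
    seeds = np.random.SeedSequence(args.seed).generate_state(args.n_replicates) % (2**31)
    estimates = []
    for s in seeds:
        ds = generate(design, panel, effects, NoiseSpec(), seed=int(s))
        df = ds.frame
        estimates.append(
            cohens_d(
                df.loc[df.episode_label == "Presence", "pcs_helplessness"],
                df.loc[df.episode_label == "Retest", "pcs_helplessness"],
                direction=1,
            )
        )
    args.out.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame({"replicate": range(len(estimates)), "d_hat": estimates}).to_csv(
        args.out, sep="\t", index=False
    )
    est = np.asarray(estimates)
    print(f"planted d = 0.25; recovered mean = {est.mean():.4f} "
          f"(sd {est.std(ddof=1):.4f}, n = {len(est)} replicates)")


if __name__ == "__main__":
    main()
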