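#!/usr/bin/env python
"""Specific-effects questions: Presence vs Affect, Affect vs Perspective.

For each module contrast on the synthetic study dataset: repeated 10-fold
CV over the four classifier configurations, stability selection rates, and
— for the variables that survive the replicability criterion — the
module-attributed effect profile (logistic coefficients, Cohen's d and
one-sided Welch tests vs the other module and vs retest).

At the generator's reported-range effect sizes (d ~ 0.24-0.33) the BACs sit
modestly above chance and few variables reach the stringent 95% selection
rate at desk scale; pass --strong to multiply the planted effects by 4 and
see the procedure recover the full profile.

Writes per-contrast outputs under results/specific_effects/<contrast>/.
"""

import argparse
from pathlib import Path

from modulearn import (
    ContrastSpec,
    NoiseSpec,
    build_profile,
    default_design,
    default_panel,
    generate,
    paper_effect_spec,
    write_profile,
)
from modulearn.cv import analyze_contrast


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--n-repeats", type=int, default=10)
    ap.add_argument("--n-selection-repetitions", type=int, default=20)
    ap.add_argument("--strong", action="store_true",
                    help="plant 4x effects (clear recovery regime)")
    ap.add_argument("--out", type=Path, default=Path("results/specific_effects"))
    args = ap.parse_args()

    effects = paper_effect_spec().scaled(4.0) if args.strong else paper_effect_spec()
    dataset = generate(
        default_design(), default_panel(), effects, NoiseSpec(), seed=args.seed
    )
    for name in ("PresenceVsAffect", "AffectVsPerspective"):
        contrast = ContrastSpec(name)
        result = analyze_contrast(
            dataset, contrast,
            n_repeats=args.n_repeats,
            n_selection_repetitions=args.n_selection_repetitions,
            seed=args.seed,
        )
        outdir = args.out / name
        outdir.mkdir(parents=True, exist_ok=True)
        result.summary().to_csv(outdir / "bac_summary.tsv", sep="\t", index=False)
        result.per_repetition_frame().to_csv(outdir / "bac_per_repetition.tsv", sep="\t", index=False)
        selected = []
        for trace in result.traces.values():
            trace.to_tsv(outdir / "selection_rates.tsv")
            selected = sorted(trace.final_set)
            break
        print(f"== {name} ==")
        print(result.summary().to_string(index=False))
        print(f"replicable variables: {selected or 'none'}")
        if selected:
            entries = build_profile(dataset, contrast, selected)
            write_profile(entries, outdir / "effect_profile.tsv", outdir / "radar_profile.json")
            specific = [e.variable_id for e in entries if e.specific_effect]
            print(f"specific effect profile: {specific or 'none'}")


if __name__ == "__main__":
    main()
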