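#!/usr/bin/env python
"""Decompose amyloid-attributable mortality into displacement and gradient.

Fits trimmed ln-mortality trajectories for the four induction cohorts
(simulated at 10,000 flies/cohort for stable hazard estimates), measures the
early-life displacement and the mature-life gradient increase, and prints
the decomposition alongside the same arithmetic applied to the canonical
in-study inputs (displacements 1.2 and 0.7 over a 15-day window; gradient
differences 0.10 and 0.09 per day).
"""

import argparse
from pathlib import Path

from flyaging import pipeline as pl


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--n-flies", type=int, default=10_000)
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    report = pl.run_survival_pipeline(
        pl.SurvivalConfig(seed=args.seed, n_flies=args.n_flies)
    )
    pl.write_report(report, args.out / "mortality_decomposition.json")

    m = report["measured"]
    ref = report["reference_arithmetic"]
    print("measured from simulated cohorts:")
    print(f"  displacement (continuous vs late):  {m['displacement_continuous_vs_late']:.3f}")
    print(f"  accrual rate over 15 days:          {m['accrual_rate_continuous_vs_late']:.4f} /day")
    print(f"  gradient delta (cont. vs early):    {m['gradient_delta_continuous_vs_early']:.4f} /day")
    print(f"  gradient delta (late vs never):     {m['gradient_delta_late_vs_never']:.4f} /day")
    print(f"  mature/young relative excess:       {m['relative_excess_pct']:.1f} %")
    print("canonical arithmetic (in-study inputs):")
    print(f"  1.2/15 = {ref['accrual_rate_squares']:.2f};  0.7/15 -> {ref['accrual_rate_circles_2dp']:.2f}")
    print(f"  young mean {ref['young_mean']:.2f};  mature mean {ref['late_mean']:.2f};"
          f"  excess {ref['relative_excess_pct']:.0f} %")


if __name__ == "__main__":
    main()
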