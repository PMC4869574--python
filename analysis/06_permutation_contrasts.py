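#!/usr/bin/env python
"""Permutation-calibrated metabolite significance for the two contrasts.

Contrast 1 (adaptation): 51D-style controls vs Abeta40/Abeta42, 14-24 days.
Contrast 2 (toxicity): Abeta40/Abeta42 vs Arctic Abeta42, 14-24 days.
The per-variable R^2 cutoff comes from refitting the predictive component on
permuted group labels (default 1,000 permutations here; raise --n-perm to
10,000 for the full protocol) at p < 0.01 Bonferroni-corrected for an
assumed 100 metabolites. Significant contiguous ppm runs are merged into
regions with their direction of change.
"""

import argparse
from pathlib import Path

import pandas as pd

from flyaging import permutation as perm
from flyaging import pipeline as pl
from flyaging import spectra as sp

CONTRASTS = {
    "nontoxic": (("control",), ("ab40", "ab42")),
    "toxic": (("ab40", "ab42"), ("arctic",)),
}


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--n-perm", type=int, default=1000)
    ap.add_argument("--results", type=Path, default=Path("results"))
    args = ap.parse_args()

    stream = {("nontoxic", "head"): 210, ("toxic", "head"): 211,
              ("nontoxic", "body"): 220, ("toxic", "body"): 221}
    for tissue in ("head", "body"):
        proc = sp.read_spectrum_set(
            args.results / f"spectra_{tissue}_processed.tsv",
            args.results / f"spectra_{tissue}_processed.json",
        )
        meta = proc.sample_meta
        in_age = meta["age_days"].between(14, 24).to_numpy()
        for name, (ga, gb) in CONTRASTS.items():
            a = in_age & meta["genotype"].isin(ga).to_numpy()
            b = in_age & meta["genotype"].isin(gb).to_numpy()
            keep = a | b
            res = perm.permutation_r2_cutoff(
                proc.intensities[keep],
                b[keep].astype(float),
                seed=pl.derive_seed(args.seed, stream[(name, tissue)]),
                n_perm=args.n_perm,
                alpha=0.01,
                n_metab=100,
                n_orthogonal=1,
            )
            regions = perm.contrast_report(proc.ppm, res.observed_r, res.r2_cutoff)
            path = args.results / f"contrast_{name}_{tissue}.tsv"
            regions.to_csv(path, sep="\t", index=False)
            print(f"[{tissue}] {name}: R^2 cutoff {res.r2_cutoff:.3f}, "
                  f"{len(regions)} significant regions")
            for _, r in regions.iterrows():
                print(f"    {r.ppm_high:6.2f}-{r.ppm_low:5.2f} ppm  "
                      f"{r.direction:<8}  |R|max {r.max_abs_r:.2f}")


if __name__ == "__main__":
    main()
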