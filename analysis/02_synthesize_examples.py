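#!/usr/bin/env python
"""A false-discovery demonstration on one null dataset.

Takes a single n=20,000 null Gaussian dataset (no real group difference),
generates DP-synthetic versions with the perturbed histogram and the
smoothed histogram at a strict privacy budget (eps=0.1), and runs the MW U
test on each.  The perturbed histogram tends to manufacture spurious
group differences at this budget, while the smoothed histogram flattens
both groups toward the same near-uniform distribution; the original data
show no difference, as expected.  Writes results/synthesis_example.csv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from dpsyntest.generators import GaussianSpec, gaussian_two_group
from dpsyntest.histograms import GAUSSIAN_BINS, build_joint_histogram
from dpsyntest.stat_tests import run_test
from dpsyntest.synthesizers import (
    PrivacyBudget,
    perturbed_histogram_synthesize,
    smoothed_histogram_synthesize,
)

OUT = Path(__file__).resolve().parent.parent / "results"
SEED = 7
EPSILON = 0.1


def main() -> None:
    rng = np.random.default_rng(SEED)
    original = gaussian_two_group(GaussianSpec(mode="null", n=20000), rng)
    hist = build_joint_histogram(original, GAUSSIAN_BINS)
    budget = PrivacyBudget(EPSILON)

    datasets = {
        "original": original,
        "perturbed_hist": perturbed_histogram_synthesize(hist, budget, rng).sample,
        "smoothed_hist": smoothed_histogram_synthesize(hist, budget, 500, rng).sample,
    }

    rows = []
    for name, sample in datasets.items():
        res = run_test(sample, "mwu")
        rows.append({
            "dataset": name, "epsilon": None if name == "original" else EPSILON,
            "n": sample.n, "n_group0": sample.n1, "n_group1": sample.n2,
            "mw_u": res.statistic, "p_value": res.p_value,
        })
        verdict = "rejects at 0.05 (FALSE DISCOVERY)" if res.p_value < 0.05 \
            else "does not reject"
        print(f"{name:>15}: n={sample.n:>6}  U={res.statistic:>12.1f}  "
              f"p={res.p_value:.3g}  -> {verdict}")

    OUT.mkdir(exist_ok=True)
    pd.DataFrame(rows).to_csv(OUT / "synthesis_example.csv", index=False)
    print("wrote results/synthesis_example.csv")


if __name__ == "__main__":
    main()
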