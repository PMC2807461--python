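#!/usr/bin/env python
"""Score the challenge predictions against the held-out truth.

Reports the pooled Pearson correlation between the median predictions and
the 476 hidden measurements, the fraction of truths escaping the min-max
prediction range (expected near 2/(m+1) = 3.9% at m=50 when the model
holds), and the null-model normalized-squared-error p-value.  The outlier
table goes to results/evaluation_challenge.tsv.
"""

from pathlib import Path

import pandas as pd

from embimpute import evaluation, read_panel

SEED = 20240918
ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    masked = read_panel(ROOT / "results" / "panel_challenge_masked.csv")
    pred = pd.read_csv(ROOT / "results" / "predictions_challenge.tsv", sep="\t", comment="#")

    class _Res:
        summary = pred

    rep = evaluation.evaluate(_Res(), masked, n_null=9999, seed=SEED)
    rep.to_tsv(ROOT / "results" / "evaluation_challenge.tsv", f"seed={SEED}")
    print(f"pooled r = {rep.r:.4f} over {rep.n_masked} masked cells")
    print(f"outliers: {rep.n_outliers}/{rep.n_masked} = {100 * rep.outlier_rate:.1f}% "
          f"outside the min-max prediction range")
    print(f"null model: nse = {rep.nse:.4f}, empirical p = {rep.p_null:.2e} "
          f"(Gaussian tail approximation {rep.p_gauss:.2e})")
    if rep.n_outliers:
        top = rep.outliers.groupby(["Stimulus", "Inhibitor"]).size().sort_values(ascending=False)
        print("outliers by masked condition:")
        print(top.to_string())


if __name__ == "__main__":
    main()
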