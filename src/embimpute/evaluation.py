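"""Scoring predictions against held-out truth.

Three scores, mirroring how blind-prediction juries and the tuning harness
judge imputations:

- pooled Pearson correlation between point predictions and truth;
- min-max range coverage: a masked cell is an "outlier" when its true value
  falls strictly outside the envelope of the m imputed draws (with m draws
  from the right predictive distribution this happens at rate 2/(m+1));
- a null-model p-value: the normalized squared error of the predictions,
  compared against predictions resampled from each protein's observed pool.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .errors import UndefinedCorrelationError, ValidationError
from .panel_io import KEY_COLS, PanelDataset

_SORT_ORDER = ["CellType", "Stimulus", "Inhibitor", "Time", "Protein"]


def pearson(x, y) -> float:
    """Product-moment correlation; errors on constant or too-short input."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValidationError(f"length mismatch: {x.size} vs {y.size}")
    if x.size < 3:
        raise ValidationError(f"need at least 3 points, got {x.size}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError("correlation undefined for constant input")
    return float(stats.pearsonr(x, y).statistic)


@dataclass
class NullModelResult:
    """Normalized squared error and its null-model p-value.

    ``p_null`` is the add-one empirical estimate (1 + #better-nulls) /
    (n_null + 1), bounded below by 1/(n_null+1); ``p_gauss`` is a Gaussian
    tail approximation of the null distribution, reported because the
    empirical estimate cannot resolve below its bound — it is an
    approximation, not an exact tail probability.
    """

    nse: float
    p_null: float
    p_gauss: float
    n_null: int
    n_cells: int


@dataclass
class EvaluationReport:
    """Combined correlation / coverage / null-model report."""

    r: float
    n_masked: int
    n_outliers: int
    outlier_rate: float
    outliers: pd.DataFrame
    nse: float
    p_null: float
    p_gauss: float
    n_null: int

    def to_tsv(self, path, header_comment: str | None = None) -> None:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w", encoding="utf-8", newline="") as fh:
            if header_comment:
                fh.write(f"# {header_comment}\n")
            fh.write(f"# r={self.r:.6f}\tn_masked={self.n_masked}\t")
            fh.write(
                f"n_outliers={self.n_outliers}\toutlier_rate={self.outlier_rate:.6f}\t"
            )
            fh.write(
                f"nse={self.nse:.6f}\tp_null={self.p_null:.3e}\tp_gauss={self.p_gauss:.3e}\tn_null={self.n_null}\n"
            )
            self.outliers.to_csv(fh, sep="\t", index=False)


def _aligned_predictions(summary: pd.DataFrame, ds_truth: PanelDataset) -> pd.DataFrame:
    """Attach truth to the per-cell prediction summary; error when absent."""
    pred = summary.copy()
    truth_col = None
    rec = ds_truth.records
    if "Truth" in rec.columns and rec["Truth"].notna().any():
        truth_col = "Truth"
    merged = pred.merge(
        rec[KEY_COLS + ([truth_col] if truth_col else ["Value"])],
        on=KEY_COLS,
        how="left",
    )
    merged["truth_eval"] = merged[truth_col] if truth_col else merged["Value"]
    if "truth" in pred.columns:
        merged["truth_eval"] = merged["truth_eval"].fillna(merged["truth"])
    missing = merged["truth_eval"].isna()
    if missing.any():
        keys = merged.loc[missing, KEY_COLS].head(5).to_dict("records")
        raise ValidationError(f"truth missing for masked cells, e.g. {keys}")
    return merged


def coverage_from_summary(summary: pd.DataFrame) -> tuple[int, pd.DataFrame]:
    """Count truths strictly outside [min, max]; list them sorted by key.

    A truth exactly equal to the min or max draw is NOT an outlier.
    """
    t = summary["truth"].to_numpy(dtype=float)
    lo = summary["min"].to_numpy(dtype=float)
    hi = summary["max"].to_numpy(dtype=float)
    outside = (t < lo) | (t > hi)
    out = summary.loc[outside, KEY_COLS + ["truth", "median", "min", "max"]]
    out = out.sort_values(_SORT_ORDER).reset_index(drop=True)
    return int(outside.sum()), out


def coverage_report(res, ds_truth: PanelDataset) -> tuple[int, int, pd.DataFrame]:
    """(n_masked, n_outliers, outlier table) for an ImputationResult."""
    merged = _aligned_predictions(res.summary, ds_truth)
    merged = merged.assign(truth=merged["truth_eval"])
    n_out, table = coverage_from_summary(merged)
    return len(merged), n_out, table


def null_model_pvalue(
    point: np.ndarray,
    truth: np.ndarray,
    proteins: np.ndarray,
    observed_pool: dict[str, np.ndarray],
    n_null: int = 10_000,
    seed: int = 0,
) -> NullModelResult:
    """Normalized-squared-error p-value against a resampling null model.

    nse = mean over masked cells of ((point - truth) / s_protein)^2, where
    s_protein is the standard deviation of that protein's observed values.
    Each null replicate replaces every prediction by a uniform draw (with
    replacement) from the same protein's observed pool.  Proteins with zero
    observed spread are excluded with a warning.
    """
    if n_null < 1:
        raise ValidationError("n_null must be >= 1")
    point = np.asarray(point, dtype=float)
    truth = np.asarray(truth, dtype=float)
    proteins = np.asarray(proteins)
    if not observed_pool:
        raise ValidationError("observed pool is empty")

    s = {}
    for prot, pool in observed_pool.items():
        pool = np.asarray(pool, dtype=float)
        sd = float(np.std(pool, ddof=1)) if pool.size > 1 else 0.0
        s[prot] = sd

    keep = np.array([s.get(p, 0.0) > 0 for p in proteins])
    dropped = sorted({str(p) for p in proteins[~keep]})
    if dropped:
        warnings.warn(
            f"excluding proteins with zero observed spread: {dropped}", RuntimeWarning
        )
    if not keep.any():
        raise ValidationError("no masked cell has a protein with nonzero spread")
    point, truth, proteins = point[keep], truth[keep], proteins[keep]
    n_cells = point.size

    sd_vec = np.array([s[p] for p in proteins])
    nse = float(np.mean(((point - truth) / sd_vec) ** 2))

    rng = np.random.default_rng(seed)
    null_sq_sum = np.zeros(n_null)
    for prot in sorted({str(p) for p in np.unique(proteins)}):
        sel = proteins == prot
        pool = np.asarray(observed_pool[prot], dtype=float)
        draws = pool[rng.integers(0, pool.size, size=(n_null, int(sel.sum())))]
        err = (draws - truth[sel]) / s[prot]
        null_sq_sum += (err**2).sum(axis=1)
    null_nse = null_sq_sum / n_cells

    p_null = float((1 + (null_nse <= nse).sum()) / (n_null + 1))
    mu_n, sd_n = float(null_nse.mean()), float(null_nse.std(ddof=1))
    p_gauss = float(stats.norm.cdf((nse - mu_n) / sd_n)) if sd_n > 0 else np.nan
    return NullModelResult(nse, p_null, p_gauss, n_null, n_cells)


def observed_pools(ds: PanelDataset) -> dict[str, np.ndarray]:
    """Per-protein arrays of observed (non-masked) values."""
    obs = ds.records[ds.records["Value"].notna()]
    return {
        prot: grp["Value"].to_numpy(dtype=float)
        for prot, grp in obs.groupby("Protein")
    }


def evaluate(
    res, ds_truth: PanelDataset, n_null: int = 10_000, seed: int = 0
) -> EvaluationReport:
    """Full report: pooled correlation, range coverage, null-model p-value."""
    merged = _aligned_predictions(res.summary, ds_truth)
    merged = merged.assign(truth=merged["truth_eval"])
    r = pearson(merged["median"].to_numpy(), merged["truth"].to_numpy())
    n_out, outliers = coverage_from_summary(merged)
    null = null_model_pvalue(
        merged["median"].to_numpy(),
        merged["truth"].to_numpy(),
        merged["Protein"].to_numpy(),
        observed_pools(ds_truth),
        n_null=n_null,
        seed=seed,
    )
    n_masked = len(merged)
    return EvaluationReport(
        r=r,
        n_masked=n_masked,
        n_outliers=n_out,
        outlier_rate=n_out / n_masked,
        outliers=outliers,
        nse=null.nse,
        p_null=null.p_null,
        p_gauss=null.p_gauss,
        n_null=null.n_null,
    )
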