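"""Mask-and-score selection of multiple-imputation parameters.

Candidate parameter sets are scored on known answers: three conflict-free
stimulus/inhibitor pairs are drawn at random, their measurements at the
non-zero time points are masked, the candidate imputes them, and the Pearson
correlation between the per-cell median prediction and the held-out truth
(pooled over all masked cells, on the measurement scale) is the trial score.
Repeating with fresh pair draws yields a distribution of correlations per
candidate; the candidate with the highest median wins.

The repeat design is paired: within one repeat every candidate sees the
identical masked cells, so between-candidate comparisons are not confounded
by which conditions happened to be masked.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from .em_core import impute
from .errors import (
    EmbImputeError,
    TrialError,
    UndefinedCorrelationError,
    ValidationError,
)
from .evaluation import pearson
from .panel_io import PanelDataset, tuning_mask
from .params import EMConfig, ImputationParams

DEFAULT_M_VALUES = (1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 15, 20, 25, 30, 35, 40, 45, 50)


def select_mask_pairs(
    available: list[tuple[str, str]],
    k: int = 3,
    rng: np.random.Generator | None = None,
) -> list[tuple[str, str]]:
    """Draw k pairs uniformly among subsets with no repeated stimulus/inhibitor.

    Rejection sampling over k-subsets of `available`; if rejection keeps
    failing, the valid subsets are enumerated (erroring when none exists).
    """
    rng = rng if rng is not None else np.random.default_rng()
    available = list(available)
    if len(available) < k:
        raise ValidationError(f"need at least {k} pairs, got {len(available)}")

    def ok(subset) -> bool:
        stim = {s for s, _ in subset}
        inh = {i for _, i in subset}
        return len(stim) == len(subset) and len(inh) == len(subset)

    for _ in range(1000):
        idx = rng.choice(len(available), size=k, replace=False)
        subset = [available[i] for i in idx]
        if ok(subset):
            return subset
    valid = [list(c) for c in itertools.combinations(available, k) if ok(c)]
    if not valid:
        raise ValidationError(
            f"no {k}-subset of the given pairs avoids repeating a stimulus or inhibitor"
        )
    return valid[int(rng.integers(len(valid)))]


def run_trial(
    ds: PanelDataset,
    params: ImputationParams,
    pairs: list[tuple[str, str]],
    seed: int,
) -> float:
    """One mask-and-score trial: mask the pairs, impute, return Pearson r.

    Raises TrialError (with a reason) when the trial cannot be scored, e.g.
    when predictions or truth are constant ("zero variance").
    """
    masked, _ = tuning_mask(ds, pairs)
    try:
        res = impute(masked, params.with_seed(seed))
    except (EmbImputeError, np.linalg.LinAlgError) as exc:
        raise TrialError(f"imputation failure: {exc}") from exc
    summ = res.summary
    if "truth" not in summ.columns or summ["truth"].isna().any():
        raise TrialError("held-out truth unavailable for some masked cells")
    try:
        return pearson(summ["median"].to_numpy(), summ["truth"].to_numpy())
    except UndefinedCorrelationError:
        raise TrialError("zero variance") from None


def _n_covariate_columns(p: ImputationParams, n_cell_types: int = 2) -> int:
    q = p.polytime_order
    n_dummy = (n_cell_types - 1) if p.cross_section else 0
    return q + n_dummy + (q * n_dummy if p.intercs else 0)


@dataclass
class TuningResult:
    """Grid x repeats correlation table with the selected best entry.

    ``correlations[e][r]`` is the Pearson r of grid entry e at repeat r, or
    NaN when that trial failed (reason in ``failures[e][r]``).  ``best`` is
    the index of the selected entry, None when no entry is selectable.
    """

    grid: list[ImputationParams]
    correlations: list[list[float]]
    failures: list[list[str | None]]
    best: int | None
    repeats: int
    seed: int

    def medians(self) -> np.ndarray:
        out = np.full(len(self.grid), np.nan)
        for e, rs in enumerate(self.correlations):
            vals = [r for r in rs if not np.isnan(r)]
            if vals:
                out[e] = float(np.median(vals))
        return out

    def failure_rates(self) -> np.ndarray:
        return np.array(
            [np.mean([np.isnan(r) for r in rs]) for rs in self.correlations]
        )

    @property
    def best_params(self) -> ImputationParams | None:
        return self.grid[self.best] if self.best is not None else None

    def to_table(self) -> pd.DataFrame:
        rows = []
        for e, params in enumerate(self.grid):
            for rep in range(self.repeats):
                rows.append(
                    {
                        "entry": e,
                        "repeat": rep,
                        "m": params.m,
                        "polytime_order": params.polytime_order,
                        "cross_section": params.cross_section,
                        "intercs": params.intercs,
                        "sqrt_all": params.transform_for("*") == "sqrt"
                        or params.transform.get("*") == "sqrt",
                        "init": params.em.init,
                        "r": self.correlations[e][rep],
                        "failure": self.failures[e][rep] or "",
                    }
                )
        return pd.DataFrame(rows)

    def to_tsv(self, path, header_comment: str | None = None) -> None:
        from pathlib import Path

        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w", encoding="utf-8", newline="") as fh:
            if header_comment:
                fh.write(f"# {header_comment}\n")
            self.to_table().to_csv(fh, sep="\t", index=False)


def _select_best(
    grid: list[ImputationParams],
    medians: np.ndarray,
    failure_rates: np.ndarray,
    n_cell_types: int,
) -> int | None:
    """Highest median; ties broken by smaller m, fewer covariate columns,
    then grid order.  Entries failing more than 20% of trials are barred."""
    eligible = [
        e
        for e in range(len(grid))
        if not np.isnan(medians[e]) and failure_rates[e] <= 0.2
    ]
    if not eligible:
        return None
    return min(
        eligible,
        key=lambda e: (
            -medians[e],
            grid[e].m,
            _n_covariate_columns(grid[e], n_cell_types),
            e,
        ),
    )


def grid_search(
    ds: PanelDataset,
    grid: list[ImputationParams],
    repeats: int = 50,
    seed: int = 0,
) -> TuningResult:
    """Score every grid entry over `repeats` paired mask-and-score trials."""
    if not grid:
        raise ValidationError("grid must be nonempty")
    ss = np.random.SeedSequence(seed)
    pair_ss, trial_ss = ss.spawn(2)
    pair_children = pair_ss.spawn(repeats)
    trial_children = trial_ss.spawn(repeats)

    available = ds.observed_pairs()
    correlations = [[np.nan] * repeats for _ in grid]
    failures: list[list[str | None]] = [[None] * repeats for _ in grid]

    for rep in range(repeats):
        pairs = select_mask_pairs(available, 3, np.random.default_rng(pair_children[rep]))
        entry_seeds = trial_children[rep].spawn(len(grid))
        for e, params in enumerate(grid):
            s = int(entry_seeds[e].generate_state(1)[0] & 0x7FFFFFFF)
            try:
                correlations[e][rep] = run_trial(ds, params, pairs, s)
            except TrialError as exc:
                failures[e][rep] = exc.reason

    medians = np.full(len(grid), np.nan)
    for e in range(len(grid)):
        vals = [r for r in correlations[e] if not np.isnan(r)]
        if vals:
            medians[e] = np.median(vals)
    rates = np.array([np.mean([np.isnan(r) for r in rs]) for rs in correlations])
    best = _select_best(grid, medians, rates, len(ds.cell_types))
    return TuningResult(
        grid=list(grid),
        correlations=correlations,
        failures=failures,
        best=best,
        repeats=repeats,
        seed=seed,
    )


def default_grid(m_values=DEFAULT_M_VALUES) -> list[ImputationParams]:
    """The full 32 x 18 = 576 entry selection grid.

    Axes: sqrt-all on/off, polynomial order 1/2, cross-section on/off,
    per-cross-section time modeling on/off, EM init listwise/identity, at 18
    imputation counts.  The intercs axis only takes effect when the
    cross-section is on; the off/on combinations without a cross-section are
    retained as (behaviorally duplicate) grid entries so the bookkeeping
    matches the 32-combination layout.
    """
    grid = []
    for m in m_values:
        for sqrt_all in (False, True):
            for q in (1, 2):
                for cs in (False, True):
                    for intercs in (False, True):
                        for init in ("listwise_deletion", "identity"):
                            grid.append(
                                ImputationParams(
                                    m=m,
                                    polytime_order=q,
                                    cross_section=cs,
                                    intercs=intercs and cs,
                                    transform={"*": "sqrt"} if sqrt_all else {},
                                    em=EMConfig(init=init),
                                )
                            )
    return grid


@dataclass
class RefinementResult:
    """Outcome of the selective-transform comparison.

    ``best_subset`` is the winning per-protein sqrt subset (empty tuple when
    the untransformed base wins); ``p_value`` is the Welch two-sample t-test
    comparing the best candidate's correlations against the base's.
    """

    best_subset: tuple[str, ...]
    p_value: float
    base_correlations: list[float]
    candidate_correlations: dict[tuple[str, ...], list[float]]

    def median(self, subset: tuple[str, ...] | None = None) -> float:
        vals = (
            self.base_correlations
            if subset is None
            else self.candidate_correlations[tuple(subset)]
        )
        vals = [v for v in vals if not np.isnan(v)]
        return float(np.median(vals)) if vals else np.nan


def refine_transforms(
    ds: PanelDataset,
    base: ImputationParams,
    candidate_sets: list[list[str]],
    repeats: int = 50,
    seed: int = 0,
) -> RefinementResult:
    """Compare selective sqrt-transform subsets against the selected base.

    Each candidate runs the same paired mask-and-score trials as the base
    (same pair draws and imputation seeds), and the best-median candidate is
    tested against the base with Welch's unpaired t-test.  An empty candidate
    list returns the base with p-value 1.
    """
    if not candidate_sets:
        return RefinementResult(
            best_subset=tuple(),
            p_value=1.0,
            base_correlations=[],
            candidate_correlations={},
        )
    configs: list[tuple[tuple[str, ...] | None, ImputationParams]] = [(None, base)]
    for subset in candidate_sets:
        subset_t = tuple(sorted(subset))
        params = replace(base, transform={p: "sqrt" for p in subset_t})
        configs.append((subset_t, params))

    ss = np.random.SeedSequence(seed)
    pair_ss, trial_ss = ss.spawn(2)
    pair_children = pair_ss.spawn(repeats)
    trial_children = trial_ss.spawn(repeats)
    available = ds.observed_pairs()

    results: dict[tuple[str, ...] | None, list[float]] = {
        key: [np.nan] * repeats for key, _ in configs
    }
    for rep in range(repeats):
        pairs = select_mask_pairs(available, 3, np.random.default_rng(pair_children[rep]))
        s = int(trial_children[rep].generate_state(1)[0] & 0x7FFFFFFF)
        for key, params in configs:
            try:
                results[key][rep] = run_trial(ds, params, pairs, s)
            except TrialError:
                pass

    def med(key):
        vals = [v for v in results[key] if not np.isnan(v)]
        return np.median(vals) if vals else -np.inf

    candidates = [key for key, _ in configs if key is not None]
    best_cand = max(candidates, key=med)
    a = [v for v in results[best_cand] if not np.isnan(v)]
    b = [v for v in results[None] if not np.isnan(v)]
    if len(a) >= 2 and len(b) >= 2 and (np.std(a) > 0 or np.std(b) > 0):
        p_value = float(stats.ttest_ind(a, b, equal_var=False).pvalue)
    else:
        p_value = 1.0
    best_subset = best_cand if med(best_cand) >= med(None) else tuple()
    return RefinementResult(
        best_subset=best_subset,
        p_value=p_value,
        base_correlations=results[None],
        candidate_correlations={k: results[k] for k in candidates},
    )
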