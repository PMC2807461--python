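"""Incomplete-data multivariate-normal estimation and EMB multiple imputation.

The model: each row of the wide frame (proteins plus covariate columns) is a
draw from N(mu, Sigma) with an arbitrary pattern of missing entries among the
protein columns.  EM maximizes the observed-data likelihood: the E-step
computes expected sufficient statistics per missingness pattern using the
sweep operator on the augmented parameter matrix

    theta = [[-1, mu'], [mu, Sigma]],

which, swept on the observed positions, yields the regression of the missing
block on the observed block (intercepts in row 0, slopes in the observed
rows, residual covariance in the missing block) plus -Sigma_OO^{-1} and
log det Sigma_OO as by-products.  The M-step re-estimates (mu, Sigma) from
the completed moments.

Multiple imputation follows the EM-with-bootstrapping (EMB) scheme: each of
the m completed datasets uses parameters fitted on an independent
nonparametric bootstrap resample of the rows — this is how parameter
uncertainty enters the imputations — and fills each incomplete row with one
draw from the conditional normal given that row's observed entries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._transforms import apply_transform, inverse_transform  # noqa: F401 (re-export)
from .errors import DegenerateDataError, SingularMatrixError, ValidationError
from .panel_io import (
    KEY_COLS,
    ImputationFrame,
    PanelDataset,
    from_frame,
    to_frame,
)
from .params import EMConfig, ImputationParams  # noqa: F401 (re-export)

_PIVOT_TINY = 1e-12


# ---------------------------------------------------------------------------
# Sweep operator


def sweep(a: np.ndarray, k: int) -> np.ndarray:
    """Sweep the symmetric matrix `a` on pivot `k` (returns a new matrix)."""
    a = np.asarray(a, dtype=float)
    b = a.copy()
    _sweep_inplace(b, k)
    return b


def reverse_sweep(a: np.ndarray, k: int) -> np.ndarray:
    """Undo `sweep` on pivot `k`: reverse_sweep(sweep(A, k), k) == A."""
    a = np.asarray(a, dtype=float)
    d = a[k, k]
    if abs(d) < _PIVOT_TINY:
        raise SingularMatrixError(f"zero pivot at index {k}", index=k)
    b = a - np.outer(a[:, k], a[k, :]) / d
    b[k, :] = -a[k, :] / d
    b[:, k] = -a[:, k] / d
    b[k, k] = -1.0 / d
    return b


def _sweep_inplace(a: np.ndarray, k: int) -> float:
    """Sweep in place; returns the pivot value (for log-determinants)."""
    d = a[k, k]
    if abs(d) < _PIVOT_TINY:
        raise SingularMatrixError(f"zero pivot at index {k}", index=k)
    col = a[:, k].copy()
    a -= np.outer(col, col) / d
    a[k, :] = col / d
    a[:, k] = col / d
    a[k, k] = -1.0 / d
    return d


# ---------------------------------------------------------------------------
# Parameters and diagnostics


@dataclass
class EMDiagnostics:
    n_iter: int = 0
    converged: bool = True
    loglik_trace: list[float] = field(default_factory=list)
    ridge_used: float = 0.0


@dataclass
class MVNParams:
    """Mean vector, covariance matrix and observed-data log-likelihood."""

    mu: np.ndarray
    sigma: np.ndarray
    loglik: float
    columns: list[str] | None = None
    diagnostics: EMDiagnostics | None = None

    def __post_init__(self):
        self.mu = np.asarray(self.mu, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        asym = np.abs(self.sigma - self.sigma.T).max() if self.sigma.size else 0.0
        if asym > 1e-10:
            raise ValidationError(f"sigma asymmetric by {asym:g}")
        if self.sigma.size:
            w = np.linalg.eigvalsh(self.sigma)
            if w.min() < -1e-8 * max(1.0, w.max()):
                raise ValidationError(f"sigma not PSD: min eigenvalue {w.min():g}")


# ---------------------------------------------------------------------------
# EM fit


def _patterns(mask: np.ndarray) -> list[tuple[np.ndarray, np.ndarray, np.ndarray]]:
    """Group rows by missingness pattern: (row_idx, observed_idx, missing_idx)."""
    keys = {}
    for i, row in enumerate(mask):
        keys.setdefault(row.tobytes(), []).append(i)
    out = []
    for key, rows in keys.items():
        m = np.frombuffer(key, dtype=bool)
        out.append((np.array(rows), np.flatnonzero(~m), np.flatnonzero(m)))
    return out


def _augmented(mu: np.ndarray, sigma: np.ndarray) -> np.ndarray:
    p = mu.size
    a = np.empty((p + 1, p + 1))
    a[0, 0] = -1.0
    a[0, 1:] = mu
    a[1:, 0] = mu
    a[1:, 1:] = sigma
    return a


def _estep(X, mu, sigma, patterns, log_scale_corr):
    """One E-step: expected sufficient statistics and observed-data loglik."""
    n, p = X.shape
    t1 = np.zeros(p)
    t2 = np.zeros((p, p))
    ll = 0.0
    log2pi = np.log(2.0 * np.pi)
    for rows, obs, mis in patterns:
        nr = rows.size
        if obs.size == 0:
            t1[mis] += nr * mu[mis]
            t2[np.ix_(mis, mis)] += nr * (sigma[np.ix_(mis, mis)] + np.outer(mu[mis], mu[mis]))
            continue
        a = _augmented(mu, sigma)
        logdet = 0.0
        for o in obs:
            piv = a[o + 1, o + 1]
            if piv < _PIVOT_TINY:
                raise SingularMatrixError(
                    f"non-positive pivot while sweeping column {o}", index=int(o)
                )
            logdet += np.log(piv)
            _sweep_inplace(a, o + 1)
        xo = X[np.ix_(rows, obs)]
        d = xo - mu[obs]
        prec = -a[np.ix_(obs + 1, obs + 1)]  # Sigma_OO^{-1}
        quad = np.einsum("ij,jk,ik->i", d, prec, d)
        ll += -0.5 * (nr * (obs.size * log2pi + logdet) + quad.sum())
        ll -= nr * log_scale_corr[obs].sum()

        t1[obs] += xo.sum(axis=0)
        t2[np.ix_(obs, obs)] += xo.T @ xo
        if mis.size:
            c0 = a[0, mis + 1]
            beta = a[np.ix_(obs + 1, mis + 1)]
            em = c0 + xo @ beta  # E[x_M | x_O], rows x mis
            cond = a[np.ix_(mis + 1, mis + 1)]
            t1[mis] += em.sum(axis=0)
            cross = xo.T @ em
            t2[np.ix_(obs, mis)] += cross
            t2[np.ix_(mis, obs)] += cross.T
            t2[np.ix_(mis, mis)] += em.T @ em + nr * cond
    return t1, t2, ll


def _shrink(sigma: np.ndarray, lam: float) -> np.ndarray:
    """Ridge prior: shrink toward the diagonal with prior weight lam * n."""
    if lam <= 0:
        return sigma
    d = np.maximum(np.diag(sigma), 1e-8)
    return (sigma + lam * np.diag(d)) / (1.0 + lam)


def _initial_params(Z: np.ndarray, init: str) -> tuple[np.ndarray, np.ndarray]:
    """Starting point on the standardized scale."""
    n, p = Z.shape
    mu0 = np.zeros(p)  # columns are centered
    if init == "listwise_deletion":
        complete = ~np.isnan(Z).any(axis=1)
        if complete.sum() >= p + 1:
            zc = Z[complete]
            mu = zc.mean(axis=0)
            sigma = np.cov(zc, rowvar=False, bias=True)
            sigma = np.atleast_2d(sigma)
            if np.linalg.matrix_rank(sigma) == p:
                return mu, sigma
        # fall back to identity when too few complete rows
    return mu0, np.eye(p)


def em_fit(fr: ImputationFrame | np.ndarray, cfg: EMConfig | None = None) -> MVNParams:
    """Fit (mu, Sigma) of the incomplete-data MVN by EM.

    Accepts an ImputationFrame or a plain (n x p) array with NaN for missing.
    Columns are standardized internally; the returned parameters and
    log-likelihood are on the original scale.  A singular covariance during
    iteration triggers one retry with ridge 0.01; non-convergence within
    ``max_iter`` sets ``diagnostics.converged = False`` (no exception).
    """
    cfg = cfg or EMConfig()
    columns = None
    if isinstance(fr, ImputationFrame):
        columns = fr.columns
        X = fr.data.astype(float, copy=True)
    else:
        X = np.asarray(fr, dtype=float).copy()
    if X.ndim != 2:
        raise ValidationError("expected a 2-d matrix")
    n, p = X.shape
    if n < 2:
        raise DegenerateDataError(f"need at least 2 rows, got {n}")
    n_obs_col = (~np.isnan(X)).sum(axis=0)
    if (n_obs_col < 2).any():
        bad = np.flatnonzero(n_obs_col < 2).tolist()
        raise DegenerateDataError(f"columns with fewer than 2 observed values: {bad}")

    try:
        return _em_fit_standardized(X, cfg, cfg.ridge, columns)
    except SingularMatrixError:
        if cfg.ridge > 0:
            raise
        return _em_fit_standardized(X, cfg, 0.01, columns)


def _em_fit_standardized(X, cfg, ridge, columns) -> MVNParams:
    n, p = X.shape
    center = np.nanmean(X, axis=0)
    scale = np.nanstd(X, axis=0)
    scale[scale == 0] = 1.0
    Z = (X - center) / scale
    log_scale_corr = np.log(scale)

    mask = np.isnan(Z)
    patterns = _patterns(mask)
    mu, sigma = _initial_params(Z, cfg.init)

    diag = EMDiagnostics(ridge_used=ridge)
    converged = False
    for it in range(1, cfg.max_iter + 1):
        t1, t2, ll = _estep(Z, mu, sigma, patterns, log_scale_corr)
        diag.loglik_trace.append(ll)
        mu_new = t1 / n
        sigma_new = t2 / n - np.outer(mu_new, mu_new)
        sigma_new = 0.5 * (sigma_new + sigma_new.T)
        sigma_new = _shrink(sigma_new, ridge)

        old = np.concatenate([mu, sigma.ravel()])
        new = np.concatenate([mu_new, sigma_new.ravel()])
        delta = np.max(np.abs(new - old) / (np.abs(old) + cfg.tol))
        mu, sigma = mu_new, sigma_new
        diag.n_iter = it
        if delta < cfg.tol:
            converged = True
            break
    diag.converged = converged
    if not converged:
        warnings.warn(
            f"EM did not converge in {cfg.max_iter} iterations", RuntimeWarning
        )
    _, _, ll_final = _estep(Z, mu, sigma, patterns, log_scale_corr)
    diag.loglik_trace.append(ll_final)

    mu_raw = center + scale * mu
    sigma_raw = sigma * np.outer(scale, scale)
    sigma_raw = 0.5 * (sigma_raw + sigma_raw.T)
    return MVNParams(mu_raw, sigma_raw, float(ll_final), columns, diag)


# ---------------------------------------------------------------------------
# Bootstrap and conditional draws


def bootstrap_em(
    fr: ImputationFrame | np.ndarray,
    cfg: EMConfig | None = None,
    rng: np.random.Generator | None = None,
) -> MVNParams:
    """EM fit on one nonparametric bootstrap resample of the rows.

    A resample in which some column loses (nearly) all its observations is
    redrawn, up to 20 attempts.
    """
    rng = rng if rng is not None else np.random.default_rng()
    X = fr.data if isinstance(fr, ImputationFrame) else np.asarray(fr, dtype=float)
    columns = fr.columns if isinstance(fr, ImputationFrame) else None
    n = X.shape[0]
    for _ in range(20):
        idx = rng.integers(0, n, size=n)
        Xb = X[idx]
        if ((~np.isnan(Xb)).sum(axis=0) < 2).any():
            continue
        pars = em_fit(Xb, cfg)
        pars.columns = columns
        return pars
    raise DegenerateDataError(
        "20 bootstrap resamples in a row left some column without observations"
    )


def conditional_draw(
    row: np.ndarray, params: MVNParams, rng: np.random.Generator
) -> np.ndarray:
    """Fill the missing entries of `row` with one conditional-normal draw.

    Missing entries get a draw from
    N(mu_M + S_MO S_OO^-1 (x_O - mu_O), S_MM - S_MO S_OO^-1 S_OM);
    a fully missing row draws from the marginal N(mu, Sigma).  Observed
    entries are returned untouched.
    """
    x = np.asarray(row, dtype=float).copy()
    mis = np.flatnonzero(np.isnan(x))
    if mis.size == 0:
        return x
    obs = np.flatnonzero(~np.isnan(x))
    mu, sigma = params.mu, params.sigma
    if obs.size == 0:
        mean = mu.copy()
        cov = sigma.copy()
    else:
        s_oo = sigma[np.ix_(obs, obs)]
        s_mo = sigma[np.ix_(mis, obs)]
        try:
            solved = np.linalg.solve(s_oo, np.column_stack([(x[obs] - mu[obs]), s_mo.T]))
        except np.linalg.LinAlgError as exc:
            jitter = 1e-8 * max(1.0, float(np.trace(s_oo)) / obs.size)
            try:
                solved = np.linalg.solve(
                    s_oo + jitter * np.eye(obs.size),
                    np.column_stack([(x[obs] - mu[obs]), s_mo.T]),
                )
            except np.linalg.LinAlgError:
                raise SingularMatrixError("observed-block covariance is singular") from exc
        mean = mu[mis] + s_mo @ solved[:, 0]
        cov = sigma[np.ix_(mis, mis)] - s_mo @ solved[:, 1:]
        cov = 0.5 * (cov + cov.T)

    w, v = np.linalg.eigh(np.atleast_2d(cov))
    if w.min() < -1e-6 * max(1.0, w.max()):
        raise ValidationError(
            f"conditional covariance not PSD (min eigenvalue {w.min():g})"
        )
    w = np.clip(w, 0.0, None)
    z = rng.standard_normal(mis.size)
    x[mis] = mean + v @ (np.sqrt(w) * z)
    return x


# ---------------------------------------------------------------------------
# Multiple imputation driver


@dataclass
class ImputationResult:
    """m completed panels plus per-missing-cell median and min-max range.

    ``completed`` holds the m completed long tables on the measurement scale;
    ``summary`` has one row per originally missing cell with columns
    median/min/max (and truth where the input carried it).
    """

    completed: list[pd.DataFrame]
    summary: pd.DataFrame
    params: ImputationParams
    em_diagnostics: pd.DataFrame

    @property
    def m(self) -> int:
        return len(self.completed)


def _draw_pattern_rows(X, rows, obs, mis, pars, rng):
    """Vectorized conditional draws for all rows sharing one missing pattern."""
    mu, sigma = pars.mu, pars.sigma
    if obs.size == 0:
        mean = np.broadcast_to(mu[mis], (rows.size, mis.size))
        cov = sigma[np.ix_(mis, mis)]
    else:
        s_oo = sigma[np.ix_(obs, obs)]
        s_mo = sigma[np.ix_(mis, obs)]
        try:
            sol = np.linalg.solve(s_oo, s_mo.T)  # obs x mis
        except np.linalg.LinAlgError as exc:
            raise SingularMatrixError("observed-block covariance is singular") from exc
        xo = X[np.ix_(rows, obs)]
        mean = mu[mis] + (xo - mu[obs]) @ sol
        cov = sigma[np.ix_(mis, mis)] - s_mo @ sol
        cov = 0.5 * (cov + cov.T)
    w, v = np.linalg.eigh(np.atleast_2d(cov))
    if w.min() < -1e-6 * max(1.0, w.max()):
        raise ValidationError(
            f"conditional covariance not PSD (min eigenvalue {w.min():g})"
        )
    root = v * np.sqrt(np.clip(w, 0.0, None))
    z = rng.standard_normal((rows.size, mis.size))
    return mean + z @ root.T


def impute(ds: PanelDataset, params: ImputationParams) -> ImputationResult:
    """EMB multiple imputation of every missing cell of the panel.

    Builds the wide frame (transforms applied), then for each of the m draws
    fits EM on a bootstrap resample and draws each incomplete row from its
    conditional normal (vectorized per missingness pattern); results are
    inverse-transformed to the measurement scale.  Fully deterministic given
    ``params.seed``.
    """
    if ds.n_missing == 0:
        raise ValidationError("panel has no missing cells to impute")
    fr = to_frame(ds, params)
    X = fr.data
    mask = np.isnan(X)
    incomplete_patterns = [
        (rows, obs, mis) for rows, obs, mis in _patterns(mask) if mis.size
    ]

    # map each source record to its (row, column) position in the frame
    rec = ds.records
    row_pos = fr.row_keys.get_indexer(
        pd.MultiIndex.from_frame(rec[["CellType", "Stimulus", "Inhibitor", "Time"]])
    )
    col_lookup = {p: j for j, p in enumerate(fr.protein_cols)}
    col_pos = rec["Protein"].map(col_lookup).to_numpy()
    observed_vals = rec["Value"].to_numpy(dtype=float)
    missing_mask = rec["Value"].isna().to_numpy()

    seeds = np.random.SeedSequence(params.seed).spawn(params.m)
    completed_tables: list[pd.DataFrame] = []
    diag_rows = []
    draws_at_missing = np.empty((params.m, int(missing_mask.sum())))

    inv_kinds = [fr.transforms[p] for p in fr.protein_cols]
    for j in range(params.m):
        rng = np.random.default_rng(seeds[j])
        try:
            pars = bootstrap_em(fr, params.em, rng)
            C = X.copy()
            for rows, obs, mis in incomplete_patterns:
                C[np.ix_(rows, mis)] = _draw_pattern_rows(X, rows, obs, mis, pars, rng)
        except Exception as exc:
            raise type(exc)(f"imputation draw {j + 1}: {exc}") from exc
        prot = C[:, : len(fr.protein_cols)].copy()
        for jj, kind in enumerate(inv_kinds):
            if kind != "none":
                prot[:, jj] = inverse_transform(prot[:, jj], kind)
        vals = np.where(missing_mask, prot[row_pos, col_pos], observed_vals)
        draws_at_missing[j] = vals[missing_mask]
        table = rec.copy()
        table["Value"] = vals
        completed_tables.append(table)
        d = pars.diagnostics
        diag_rows.append(
            {
                "draw": j + 1,
                "n_iter": d.n_iter if d else np.nan,
                "converged": d.converged if d else True,
                "loglik": pars.loglik,
                "ridge_used": d.ridge_used if d else 0.0,
                "n_negative_imputed": int((vals[missing_mask] < 0).sum()),
            }
        )

    summary = ds.records.loc[missing_mask, KEY_COLS].reset_index(drop=True)
    summary["median"] = np.median(draws_at_missing, axis=0)
    summary["min"] = draws_at_missing.min(axis=0)
    summary["max"] = draws_at_missing.max(axis=0)
    if "Truth" in ds.records.columns:
        summary["truth"] = ds.records.loc[missing_mask, "Truth"].to_numpy()
    return ImputationResult(
        completed=completed_tables,
        summary=summary,
        params=params,
        em_diagnostics=pd.DataFrame(diag_rows),
    )
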