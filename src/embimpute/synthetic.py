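"""Synthetic phosphoproteomics-style panel generator.

Emulates the statistical structure the imputation pipeline assumes: 17
correlated protein intensities measured in two cell types (normal vs
cancer-like) under a 7x7 grid of stimulus/inhibitor combinations at times
0/30/180 min.  Each protein follows a quadratic-in-time response that
differs by cell type, plus condition-specific deviations that peak at the
intermediate time point, plus cross-protein correlated noise.  A subset of
proteins is generated as squares of (shifted) Gaussians, giving the
right-skewed marginals that a square-root transform approximately
normalizes.

Protein base scales are drawn log-uniformly over [10, 5000], so
between-protein variation dominates within-protein effects — the regime in
which block-masked conditions remain predictable from time/cell-type
structure while condition-specific deviations create range outliers.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ConfigError
from .panel_io import MaskSpec, PanelDataset, challenge_mask

PROTEINS = (
    "AKT", "CREB", "ERK12", "GSK3", "HistH3", "HSP27", "IRS1s", "IkBa",
    "JNK12", "MEK12", "MK2", "STAT3", "ZAP70", "p38", "p53", "p70S6K",
    "p90RSK",
)
SKEWED_DEFAULT = ("AKT", "IkBa", "p38", "p70S6K", "HSP27")
STIMULI = ("IFNg", "IGF1", "IL1a", "IL6", "LPS", "TGFa", "TNFa")
INHIBITORS = ("GSK3i", "IKKi", "JNKi", "MEKi", "PI3Ki", "mTORi", "p38i")
CELL_TYPES = ("Cancer", "Normal")

# Published size of the original blind-challenge dataset: 4624 measurements
# in total, of which 476 were masked for the challenge and 952 in the later
# completely-at-random re-masking experiment.  Used to express masked-cell
# counts as fractions of the full challenge table.
CHALLENGE_TOTAL_MEASUREMENTS = 4624


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator settings; defaults mirror the full challenge layout.

    Effect magnitudes are relative to each protein's latent scale:
    ``celltype_effect_sd`` for the cell-type offset, ``time_effect_sd`` for
    the linear/quadratic time coefficients, ``condition_effect_sd`` for the
    per-(stimulus, inhibitor, protein) deviation (which enters through
    h(t) = 4*t*(1-t) on the scaled time axis, peaking between the
    endpoints), ``noise_sd`` for the residual, with exchangeable
    cross-protein residual correlation ``noise_corr``.  Conditions listed in
    ``outlier_conditions`` get their condition effects inflated by
    ``outlier_inflation``.
    """

    n_proteins: int = 17
    n_cell_types: int = 2
    n_stimuli: int = 7
    n_inhibitors: int = 7
    times: tuple[float, ...] = (0.0, 30.0, 180.0)
    scale_range: tuple[float, float] = (10.0, 5000.0)
    celltype_effect_sd: float = 0.25
    time_effect_sd: float = 0.35
    condition_effect_sd: float = 0.12
    noise_sd: float = 0.08
    noise_corr: float = 0.3
    skewed_proteins: tuple[str, ...] | None = None  # None = canonical 5
    outlier_conditions: tuple[tuple[str, str], ...] = ()
    outlier_inflation: float = 5.0
    seed: int = 0

    def __post_init__(self):
        if self.n_proteins < 1 or self.n_cell_types < 1:
            raise ConfigError("need at least one protein and one cell type")
        if not (0 < self.scale_range[0] <= self.scale_range[1]):
            raise ConfigError("scale_range must be positive and ordered")
        if not abs(self.noise_corr) < 1:
            raise ConfigError("|noise_corr| must be < 1")
        for sd in (
            self.celltype_effect_sd,
            self.time_effect_sd,
            self.condition_effect_sd,
            self.noise_sd,
        ):
            if sd < 0:
                raise ConfigError("effect standard deviations must be >= 0")

    # -- name helpers -------------------------------------------------------
    def protein_names(self) -> list[str]:
        base = list(PROTEINS[: self.n_proteins])
        base += [f"P{i}" for i in range(len(base) + 1, self.n_proteins + 1)]
        return sorted(base)

    def skewed_set(self) -> set[str]:
        names = set(self.protein_names())
        if self.skewed_proteins is not None:
            unknown = set(self.skewed_proteins) - names
            if unknown:
                raise ConfigError(f"skewed_proteins not in panel: {sorted(unknown)}")
            return set(self.skewed_proteins)
        return {p for p in SKEWED_DEFAULT if p in names}

    def stimulus_names(self) -> list[str]:
        base = list(STIMULI[: self.n_stimuli])
        base += [f"S{i}" for i in range(len(base) + 1, self.n_stimuli + 1)]
        return sorted(base)

    def inhibitor_names(self) -> list[str]:
        base = list(INHIBITORS[: self.n_inhibitors])
        base += [f"I{i}" for i in range(len(base) + 1, self.n_inhibitors + 1)]
        return sorted(base)

    def cell_type_names(self) -> list[str]:
        base = list(CELL_TYPES[: self.n_cell_types])
        base += [f"C{i}" for i in range(len(base) + 1, self.n_cell_types + 1)]
        return sorted(base)


def generate(cfg: SyntheticConfig) -> PanelDataset:
    """Generate a fully observed panel; deterministic given ``cfg.seed``."""
    rng = np.random.default_rng(cfg.seed)
    proteins = cfg.protein_names()
    stimuli = cfg.stimulus_names()
    inhibitors = cfg.inhibitor_names()
    cell_types = cfg.cell_type_names()
    times = np.asarray(sorted(cfg.times), dtype=float)
    skewed = cfg.skewed_set()
    p = len(proteins)

    lo, hi = cfg.scale_range
    scales = np.exp(rng.uniform(np.log(lo), np.log(hi), size=p))
    is_skewed = np.array([name in skewed for name in proteins])
    latent_scale = np.where(is_skewed, np.sqrt(scales), scales)

    n_c, n_s, n_i, n_t = len(cell_types), len(stimuli), len(inhibitors), len(times)
    a = rng.normal(0.0, 1.0, size=(p, n_c)) * (cfg.celltype_effect_sd * latent_scale)[:, None]
    b1 = rng.normal(0.0, 1.0, size=(p, n_c)) * (cfg.time_effect_sd * latent_scale)[:, None]
    b2 = rng.normal(0.0, 1.0, size=(p, n_c)) * (cfg.time_effect_sd * latent_scale)[:, None]
    gamma = rng.normal(0.0, 1.0, size=(p, n_s, n_i)) * (
        cfg.condition_effect_sd * latent_scale
    )[:, None, None]
    for s_name, i_name in cfg.outlier_conditions:
        si = stimuli.index(s_name)
        ii = inhibitors.index(i_name)
        gamma[:, si, ii] *= cfg.outlier_inflation

    # exchangeable residual correlation across proteins
    corr = np.full((p, p), cfg.noise_corr)
    np.fill_diagonal(corr, 1.0)
    chol = np.linalg.cholesky(corr)

    tmax = times.max()
    t_scaled = times / tmax if tmax > 0 else np.zeros_like(times)
    h = 4.0 * t_scaled * (1.0 - t_scaled)

    n_rows = n_c * n_s * n_i * n_t
    z = rng.standard_normal((n_rows, p))
    eps = (z @ chol.T) * (cfg.noise_sd * latent_scale)

    rows = []
    values = np.empty((n_rows, p))
    r = 0
    for ci, c in enumerate(cell_types):
        for si, s in enumerate(stimuli):
            for ii, i in enumerate(inhibitors):
                for ti, t in enumerate(times):
                    y = (
                        latent_scale
                        + a[:, ci]
                        + b1[:, ci] * t_scaled[ti]
                        + b2[:, ci] * t_scaled[ti] ** 2
                        + gamma[:, si, ii] * h[ti]
                        + eps[r]
                    )
                    values[r] = y
                    rows.append((c, s, i, float(t)))
                    r += 1

    # skewed proteins: shift the latent values positive, then square
    for j in range(p):
        col = values[:, j]
        if is_skewed[j]:
            shift = max(0.0, 0.05 * latent_scale[j] - col.min())
            values[:, j] = np.square(col + shift)
        else:
            values[:, j] = np.maximum(col, 0.0)

    frame = pd.DataFrame(rows, columns=["CellType", "Stimulus", "Inhibitor", "Time"])
    frame = pd.concat(
        [frame, pd.DataFrame(values, columns=proteins)], axis=1
    )
    long = frame.melt(
        id_vars=["CellType", "Stimulus", "Inhibitor", "Time"],
        var_name="Protein",
        value_name="Value",
    )
    long = long.sort_values(
        ["CellType", "Stimulus", "Inhibitor", "Time", "Protein"]
    ).reset_index(drop=True)
    return PanelDataset(long)


def make_challenge_fixture(
    cfg: SyntheticConfig, seed: int
) -> tuple[PanelDataset, MaskSpec, pd.DataFrame]:
    """Generate a panel and mask a random diagonal blind-prediction layout.

    The diagonal is a perfect matching of stimuli to inhibitors (each used
    exactly once), as in the blind challenge; returns the masked panel, the
    mask record, and the held-out truth table.
    """
    if cfg.n_stimuli != cfg.n_inhibitors:
        raise ConfigError("challenge layout needs equally many stimuli and inhibitors")
    ss = np.random.SeedSequence(seed)
    gen_seed, diag_seed = ss.spawn(2)
    ds = generate(replace(cfg, seed=int(gen_seed.generate_state(1)[0] & 0x7FFFFFFF)))
    rng = np.random.default_rng(diag_seed)
    stimuli = ds.stimuli
    inhibitors = list(np.array(ds.inhibitors)[rng.permutation(len(ds.inhibitors))])
    pairs = list(zip(stimuli, inhibitors))
    masked, spec = challenge_mask(ds, pairs)
    return masked, spec, masked.truth_table()
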