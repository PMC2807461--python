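"""Long-format panel tables, the wide imputation matrix, and masking schemes.

A panel dataset holds one intensity measurement per (cell type, stimulus,
inhibitor, time, protein) key; a missing measurement is an empty Value field
on disk and NaN in memory.  For imputation the panel is pivoted into a wide
matrix with one row per experimental condition (cell type x stimulus x
inhibitor x time), the proteins as jointly-modeled columns, and fully
observed covariate columns encoding a polynomial time trend, a cell-type
cross-section dummy, and (optionally) their interactions.

Three masking schemes mirror the blind-prediction setting:

- ``challenge_mask``: a "diagonal" of 7 stimulus/inhibitor pairs, every
  protein and cell type at the non-zero time points (476 cells at full size);
- ``tuning_mask``: the same block pattern for 3 conflict-free pairs (204
  cells), used to score candidate imputation parameters on known answers;
- ``mcar_mask``: a fixed number of cells drawn uniformly at random from
  non-zero time points.

Masked cells keep their original value in a ``Truth`` column so downstream
evaluation can score predictions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from ._transforms import apply_transform, inverse_transform
from .errors import PanelParseError, ValidationError, ConfigError
from .params import ImputationParams

KEY_COLS = ["CellType", "Stimulus", "Inhibitor", "Time", "Protein"]
CONDITION_COLS = ["CellType", "Stimulus", "Inhibitor", "Time"]


# ---------------------------------------------------------------------------
# PanelDataset


@dataclass
class PanelDataset:
    """Long-format measurement table with an optional held-out truth column.

    ``records`` has columns CellType, Stimulus, Inhibitor, Time, Protein,
    Value and optionally Truth.  Value is NaN where missing; Truth is
    populated exactly for cells hidden by a masking operation.
    """

    records: pd.DataFrame

    def __post_init__(self):
        df = self.records
        missing_cols = [c for c in KEY_COLS + ["Value"] if c not in df.columns]
        if missing_cols:
            raise ValidationError(f"panel table lacks columns {missing_cols}")
        df = df.copy()
        df["Time"] = pd.to_numeric(df["Time"])
        df["Value"] = pd.to_numeric(df["Value"])
        if "Truth" in df.columns:
            df["Truth"] = pd.to_numeric(df["Truth"])
        if (df["Time"] < 0).any():
            raise ValidationError("Time must be >= 0")
        neg = df["Value"].lt(0)
        if neg.any():
            keys = df.loc[neg, KEY_COLS].head(5).to_dict("records")
            raise ValidationError(f"negative intensity values at keys {keys}")
        dup = df.duplicated(subset=KEY_COLS, keep=False)
        if dup.any():
            keys = df.loc[dup, KEY_COLS].head(5).to_dict("records")
            raise ValidationError(f"duplicate measurement keys, e.g. {keys}")
        self.records = df.reset_index(drop=True)

    # -- simple accessors ---------------------------------------------------
    @property
    def proteins(self) -> list[str]:
        return sorted(self.records["Protein"].unique())

    @property
    def cell_types(self) -> list[str]:
        return sorted(self.records["CellType"].unique())

    @property
    def stimuli(self) -> list[str]:
        return sorted(self.records["Stimulus"].unique())

    @property
    def inhibitors(self) -> list[str]:
        return sorted(self.records["Inhibitor"].unique())

    @property
    def times(self) -> list[float]:
        return sorted(self.records["Time"].unique())

    @property
    def n_missing(self) -> int:
        return int(self.records["Value"].isna().sum())

    @property
    def n_observed(self) -> int:
        return int(self.records["Value"].notna().sum())

    def condition_pairs(self) -> list[tuple[str, str]]:
        """Distinct (stimulus, inhibitor) combinations present in the table."""
        pairs = self.records[["Stimulus", "Inhibitor"]].drop_duplicates()
        return sorted(map(tuple, pairs.itertuples(index=False)))

    def observed_pairs(self) -> list[tuple[str, str]]:
        """(stimulus, inhibitor) combinations with at least one observed value."""
        obs = self.records[self.records["Value"].notna()]
        pairs = obs[["Stimulus", "Inhibitor"]].drop_duplicates()
        return sorted(map(tuple, pairs.itertuples(index=False)))

    def truth_table(self) -> pd.DataFrame:
        """Key table of masked cells with their held-out true values."""
        if "Truth" not in self.records.columns:
            return pd.DataFrame(columns=KEY_COLS + ["Truth"])
        t = self.records[self.records["Truth"].notna()]
        return t[KEY_COLS + ["Truth"]].reset_index(drop=True)

    def copy(self) -> "PanelDataset":
        return PanelDataset(self.records.copy())

    def __eq__(self, other) -> bool:
        if not isinstance(other, PanelDataset):
            return NotImplemented
        a = self.records.sort_values(KEY_COLS).reset_index(drop=True)
        b = other.records.sort_values(KEY_COLS).reset_index(drop=True)
        if list(a.columns) != list(b.columns):
            return False
        return a.equals(b)


# ---------------------------------------------------------------------------
# Reading and writing


def read_panel(path, dialect: dict | None = None) -> PanelDataset:
    """Read a panel CSV.

    The canonical dialect is long format with columns CellType, Stimulus,
    Inhibitor, Time, Protein, Value (optionally Truth); empty Value means
    missing.  ``dialect`` may rename columns ({"columns": {canonical: actual}})
    or declare a wide layout ({"format": "wide"}) in which every non-key
    column is one protein.  Lines starting with '#' are ignored.
    """
    dialect = dialect or {}
    path = Path(path)
    if not path.exists():
        raise PanelParseError(f"no such file: {path}")
    try:
        raw = pd.read_csv(path, comment="#", dtype=str, skip_blank_lines=True)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise PanelParseError(f"{path}: {exc}") from exc
    rename = {v: k for k, v in dialect.get("columns", {}).items()}
    raw = raw.rename(columns=rename)

    if dialect.get("format", "long") == "wide":
        id_cols = [c for c in CONDITION_COLS if c in raw.columns]
        if len(id_cols) != 4:
            raise PanelParseError(
                f"{path}: wide format requires columns {CONDITION_COLS}"
            )
        raw = raw.melt(
            id_vars=id_cols, var_name="Protein", value_name="Value"
        )

    missing_cols = [c for c in KEY_COLS + ["Value"] if c not in raw.columns]
    if missing_cols:
        raise PanelParseError(f"{path}: missing columns {missing_cols}")

    for col in ("Time", "Value", "Truth"):
        if col not in raw.columns:
            continue
        coerced = pd.to_numeric(raw[col], errors="coerce")
        bad = coerced.isna() & raw[col].notna() & (raw[col].str.strip() != "")
        if bad.any():
            lines = (raw.index[bad] + 2).tolist()[:5]  # +2: header + 1-based
            raise PanelParseError(
                f"{path}: non-numeric {col} value(s) near line(s) {lines}"
            )
        raw[col] = coerced
    try:
        return PanelDataset(raw)
    except ValidationError as exc:
        raise ValidationError(f"{path}: {exc}") from exc


def write_panel(ds: PanelDataset, path, header_comment: str | None = None) -> None:
    """Write the long-format CSV (UTF-8, '.' decimal, missing = empty field)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        ds.records.to_csv(fh, index=False)


# ---------------------------------------------------------------------------
# Wide frame assembly


@dataclass
class ImputationFrame:
    """Wide numeric matrix: protein variables plus fully observed covariates.

    Rows are distinct (cell_type, stimulus, inhibitor, time) conditions;
    ``data`` holds transformed protein columns (NaN = missing) followed by
    the covariate columns, which are never missing.
    """

    data: np.ndarray
    columns: list[str]
    protein_cols: list[str]
    covariate_cols: list[str]
    column_roles: dict[str, str]
    row_keys: pd.MultiIndex
    transforms: dict[str, str]
    time_scale: float
    source: pd.DataFrame = field(repr=False)

    @property
    def n_rows(self) -> int:
        return self.data.shape[0]

    @property
    def n_cols(self) -> int:
        return self.data.shape[1]

    def protein_block(self) -> np.ndarray:
        return self.data[:, : len(self.protein_cols)]


def _covariate_columns(
    t_scaled: np.ndarray,
    cell_types: pd.Series,
    q: int,
    cross_section: bool,
    intercs: bool,
) -> tuple[list[str], list[np.ndarray], dict[str, str]]:
    cols, arrays, roles = [], [], {}
    for k in range(1, q + 1):
        name = f"t{k}" if k > 1 else "t"
        cols.append(name)
        arrays.append(t_scaled**k)
        roles[name] = f"time_poly({k})"
    categories = sorted(cell_types.unique())
    dummies = []
    if cross_section and len(categories) > 1:
        for ct in categories[1:]:  # lexicographically first is the reference
            name = f"cs[{ct}]"
            d = (cell_types == ct).to_numpy(dtype=float)
            cols.append(name)
            arrays.append(d)
            roles[name] = "cross_section_dummy"
            dummies.append((ct, d))
    if intercs and dummies:
        for k in range(1, q + 1):
            for ct, d in dummies:
                name = (f"t{k}" if k > 1 else "t") + f":cs[{ct}]"
                cols.append(name)
                arrays.append((t_scaled**k) * d)
                roles[name] = f"interaction({k})"
    return cols, arrays, roles


def to_frame(ds: PanelDataset, params: ImputationParams) -> ImputationFrame:
    """Pivot the panel to the wide imputation matrix with covariates.

    Time enters as powers of t-tilde = t / max(t), scaled to [0, 1] so that
    higher polynomial orders stay numerically comparable.  Per-protein
    transforms from ``params.transform`` are applied to the protein columns
    before assembly.
    """
    if ds.records.empty:
        raise ValidationError("cannot build a frame from an empty panel")
    wide = (
        ds.records.set_index(CONDITION_COLS + ["Protein"])["Value"]
        .unstack("Protein")
        .sort_index()
    )
    proteins = sorted(wide.columns)
    wide = wide[proteins]

    transforms = {p: params.transform_for(p) for p in proteins}
    mat = np.empty(wide.shape, dtype=float)
    for j, p in enumerate(proteins):
        try:
            mat[:, j] = apply_transform(wide[p].to_numpy(dtype=float), transforms[p])
        except ValidationError as exc:
            raise ValidationError(f"protein {p!r}: {exc}") from exc

    times = wide.index.get_level_values("Time").to_numpy(dtype=float)
    tmax = float(times.max())
    q = params.polytime_order if len(np.unique(times)) > 1 else 0
    t_scaled = times / tmax if tmax > 0 else np.zeros_like(times)
    cell_types = pd.Series(wide.index.get_level_values("CellType"))

    cov_cols, cov_arrays, cov_roles = _covariate_columns(
        t_scaled, cell_types, q, params.cross_section, params.intercs
    )
    blocks = [mat] + [a.reshape(-1, 1) for a in cov_arrays]
    data = np.hstack(blocks) if cov_arrays else mat.copy()

    roles = {p: "protein_variable" for p in proteins}
    roles.update(cov_roles)
    return ImputationFrame(
        data=data,
        columns=proteins + cov_cols,
        protein_cols=proteins,
        covariate_cols=cov_cols,
        column_roles=roles,
        row_keys=wide.index,
        transforms=transforms,
        time_scale=tmax,
        source=ds.records.copy(),
    )


def from_frame(fr: ImputationFrame, completed: np.ndarray) -> PanelDataset:
    """Map a completed matrix back to the long panel on the measurement scale.

    Per-variable transforms are inverted; cells observed in the source panel
    report their original values bit-exactly regardless of the matrix content.
    """
    completed = np.asarray(completed, dtype=float)
    if completed.shape != fr.data.shape:
        raise ValidationError(
            f"completed matrix shape {completed.shape} != frame shape {fr.data.shape}"
        )
    prot = completed[:, : len(fr.protein_cols)]
    if np.isnan(prot).any():
        raise ValidationError("completed protein block still contains missing values")

    wide = pd.DataFrame(prot, index=fr.row_keys, columns=fr.protein_cols)
    wide.columns.name = "Protein"
    for p in fr.protein_cols:
        wide[p] = inverse_transform(wide[p].to_numpy(), fr.transforms[p])
    long = wide.stack().rename("Imputed").reset_index()

    out = fr.source.merge(long, on=KEY_COLS, how="left", validate="one_to_one")
    observed = out["Value"].notna()
    out["Value"] = out["Value"].where(observed, out["Imputed"])
    out = out.drop(columns=["Imputed"])
    # bypass the >= 0 validation: 'none'-transform draws may be negative and
    # the observed-data contract requires returning them unmodified
    ds = object.__new__(PanelDataset)
    ds.records = out.reset_index(drop=True)
    return ds


# ---------------------------------------------------------------------------
# Masking


@dataclass(frozen=True)
class MaskSpec:
    """Record of one masking operation (scheme, where, how many, seed)."""

    scheme: str
    pairs: tuple[tuple[str, str], ...] | None
    times: tuple[float, ...]
    n_cells: int
    seed: int | None = None


def _check_pairs_distinct(pairs: Sequence[tuple[str, str]]) -> None:
    stimuli = [s for s, _ in pairs]
    inhibitors = [i for _, i in pairs]
    if len(set(stimuli)) != len(stimuli):
        raise ValidationError(f"a stimulus repeats among pairs {list(pairs)}")
    if len(set(inhibitors)) != len(inhibitors):
        raise ValidationError(f"an inhibitor repeats among pairs {list(pairs)}")


def _apply_block_mask(
    ds: PanelDataset,
    pairs: Sequence[tuple[str, str]],
    times: Sequence[float],
    scheme: str,
) -> tuple[PanelDataset, MaskSpec]:
    df = ds.records.copy()
    if "Truth" not in df.columns:
        df["Truth"] = np.nan
    pair_index = pd.MultiIndex.from_tuples(pairs)
    in_block = (
        pd.MultiIndex.from_frame(df[["Stimulus", "Inhibitor"]]).isin(pair_index)
        & df["Time"].isin(list(times)).to_numpy()
    )
    newly = in_block & df["Value"].notna().to_numpy()
    df.loc[newly, "Truth"] = df.loc[newly, "Value"]
    df.loc[newly, "Value"] = np.nan
    n_masked = int((in_block & df["Truth"].notna().to_numpy()).sum())
    masked = object.__new__(PanelDataset)
    masked.records = df
    spec = MaskSpec(
        scheme=scheme,
        pairs=tuple(map(tuple, pairs)),
        times=tuple(float(t) for t in times),
        n_cells=n_masked,
    )
    return masked, spec


def challenge_mask(
    ds: PanelDataset,
    pairs: Sequence[tuple[str, str]],
    times: Iterable[float] = (30, 180),
) -> tuple[PanelDataset, MaskSpec]:
    """Mask the full "diagonal" blind-prediction layout.

    The pairs must use each of the panel's stimuli and each of its inhibitors
    exactly once; every protein and cell type is masked at the given non-zero
    time points, so the masked count is n_proteins x n_pairs x n_times x
    n_cell_types (476 at the full 17-protein, 7x7, 2-cell-type size).
    """
    pairs = list(pairs)
    _check_pairs_distinct(pairs)
    if set(s for s, _ in pairs) != set(ds.stimuli):
        raise ValidationError("challenge pairs must cover every stimulus exactly once")
    if set(i for _, i in pairs) != set(ds.inhibitors):
        raise ValidationError("challenge pairs must cover every inhibitor exactly once")
    return _apply_block_mask(ds, pairs, list(times), "challenge")


def tuning_mask(
    ds: PanelDataset,
    pairs: Sequence[tuple[str, str]],
    times: Iterable[float] = (30, 180),
) -> tuple[PanelDataset, MaskSpec]:
    """Mask 3 conflict-free stimulus/inhibitor pairs at the non-zero times.

    This is the mask-and-score device: the held-out truth of the 204 masked
    cells (at full size) scores one candidate parameter set.  Re-masking with
    the same spec is a no-op (idempotent).
    """
    pairs = list(pairs)
    if len(pairs) != 3:
        raise ValidationError(f"tuning mask needs exactly 3 pairs, got {len(pairs)}")
    _check_pairs_distinct(pairs)
    times = list(times)
    df = ds.records
    for s, i in pairs:
        block = df[
            (df["Stimulus"] == s) & (df["Inhibitor"] == i) & df["Time"].isin(times)
        ]
        if block.empty or not (
            block["Value"].notna().any()
            or ("Truth" in df.columns and block["Truth"].notna().any())
        ):
            raise ValidationError(
                f"pair ({s}, {i}) has no scoreable values at times {times}"
            )
    return _apply_block_mask(ds, pairs, times, "tuning")


def mcar_mask(
    ds: PanelDataset, n_cells: int, seed: int
) -> tuple[PanelDataset, MaskSpec]:
    """Mask `n_cells` observed cells uniformly at random, never at time 0."""
    df = ds.records.copy()
    if "Truth" not in df.columns:
        df["Truth"] = np.nan
    eligible = np.flatnonzero(df["Value"].notna().to_numpy() & (df["Time"] != 0).to_numpy())
    if n_cells > eligible.size:
        raise ValidationError(
            f"n_cells={n_cells} exceeds the {eligible.size} observed non-zero-time cells"
        )
    rng = np.random.default_rng(seed)
    chosen = rng.choice(eligible, size=n_cells, replace=False) if n_cells else np.array([], int)
    df.loc[df.index[chosen], "Truth"] = df.loc[df.index[chosen], "Value"]
    df.loc[df.index[chosen], "Value"] = np.nan
    masked = object.__new__(PanelDataset)
    masked.records = df
    return masked, MaskSpec("mcar", None, (), int(n_cells), int(seed))
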