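"""Specimen measurement tables: reading, validation, QC and imputation.

The central object is :class:`MeasurementTable`, a specimens × characters
matrix of linear body measurements in µm together with group (OTU/species)
and optional strain labels, a mask of originally-missing cells and a mask of
imputed cells.  All downstream analyses (shape PCA, ratio extraction) work on
natural-log measurements; quality control and imputation therefore operate on
the log scale as well.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CharacterDef",
    "CHARACTER_REGISTRY",
    "MeasurementTable",
    "QCReport",
    "ImputationLog",
    "read_measurement_table",
    "write_measurement_table",
    "correlation_qc",
    "drop_variables",
    "impute_missing",
]

#: Sentinels (case-insensitive) accepted for a missing measurement cell.
MISSING_SENTINELS = {"", "na", "nan"}

ID_COLUMNS = ("specimen_id", "group", "strain")


@dataclass(frozen=True)
class CharacterDef:
    """One linear measurement character.

    Parameters
    ----------
    abbreviation : str
        Short code used as the column name, e.g. ``"eye.b"``.
    name : str
        Human-readable character name.
    definition : str
        How the measurement is taken.
    magnification : float
        Microscope magnification (×) at which the character is measured.
    """

    abbreviation: str
    name: str
    definition: str
    magnification: float


#: The 20 female body measurements of the *Anisopteromalus* study.
CHARACTER_REGISTRY: tuple[CharacterDef, ...] = (
    CharacterDef("eye.b", "Eye breadth",
                 "Greatest breadth of eye, lateral view", 150),
    CharacterDef("eye.d", "Eye distance",
                 "Shortest distance between eyes, dorsal view", 150),
    CharacterDef("eye.h", "Eye height",
                 "Greatest length of eye height, lateral view", 150),
    CharacterDef("gst.b", "Gaster breadth",
                 "Greatest breadth of gaster, distance between the outermost "
                 "lateral edges of the gaster, dorsal view", 100),
    CharacterDef("gst.l", "Gaster length",
                 "Length of gaster along median line from posterior edge of "
                 "nucha to tip of ovipositor sheath, dorsal view", 70),
    CharacterDef("hea.b", "Head breadth",
                 "Greatest breadth of head, dorsal view", 100),
    CharacterDef("hea.h", "Head height",
                 "Distance between lower edge of clypeus and lower edge of "
                 "anterior ocellus, frontal view", 100),
    CharacterDef("msc.b", "Mesoscutum breadth",
                 "Greatest breadth of mesoscutum just in front of level of "
                 "tegula, dorsal view", 100),
    CharacterDef("msc.l", "Mesoscutum length",
                 "Length of mesoscutum along median line from posterior edge "
                 "of pronotum to posterior edge of mesoscutum, dorsal view", 150),
    CharacterDef("msp.l", "Malar space",
                 "Distance between the point where malar sulcus enters mouth "
                 "margin and malar sulcus enters lower edge of eye, lateral "
                 "view", 150),
    CharacterDef("mss.l", "Mesosoma length",
                 "Length of mesosoma along median line from anterior edge of "
                 "pronotum collar to posterior edge of nucha, dorsal view", 70),
    CharacterDef("mv.l", "Marginal vein",
                 "Length of marginal vein, distance between the point at which "
                 "the submarginal vein touches the leading edge of the wing "
                 "and the point at which stigmal vein and postmarginal vein "
                 "unite", 150),
    CharacterDef("ool.l", "OOL",
                 "Shortest distance between posterior ocellus and eye margin, "
                 "dorsal view", 150),
    CharacterDef("pdl.flg", "Pedicel + flagellum",
                 "Combined length of pedicel plus flagellum, outer aspect", 100),
    CharacterDef("pol.l", "POL",
                 "Shortest distance between posterior ocelli, dorsal view", 150),
    CharacterDef("ppd.l", "Propodeum length",
                 "Length of propodeum measured along median line from anterior "
                 "edge to posterior edge of nucha, dorsal view", 150),
    CharacterDef("scp.l", "Scape length",
                 "Length of scape exclusive of radicle, outer aspect", 150),
    CharacterDef("sct.l", "Scutellum length",
                 "Length of scutellum along median line from posterior edge of "
                 "mesoscutum to posterior edge of scutellum, dorsal view", 150),
    CharacterDef("stv.l", "Stigmal vein",
                 "Length of stigmal vein, distance between the point at which "
                 "stigmal vein and postmarginal vein unite apically, and the "
                 "distal end of the stigma", 150),
    CharacterDef("tb3.l", "Metatibia",
                 "Length of metatibia, measured along midline, outer aspect", 100),
)

_REGISTRY_ABBREVS = tuple(c.abbreviation for c in CHARACTER_REGISTRY)


class ValidationError(ValueError):
    """Raised when a measurement table violates its invariants."""


@dataclass
class MeasurementTable:
    """Specimens × characters measurement matrix in µm.

    Attributes
    ----------
    values : pandas.DataFrame
        Float matrix indexed by ``specimen_id``; one column per character
        abbreviation; NaN where a value is (still) missing.
    group : pandas.Series
        OTU / species label per specimen.
    strain : pandas.Series
        Optional sub-group label per specimen ("" when absent).
    missing_mask : pandas.DataFrame
        True where the cell was missing in the source data.
    imputed_mask : pandas.DataFrame
        True where a missing cell has been filled by :func:`impute_missing`;
        always a subset of ``missing_mask``.
    """

    values: pd.DataFrame
    group: pd.Series
    strain: pd.Series
    missing_mask: pd.DataFrame
    imputed_mask: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    # ------------------------------------------------------------------
    @property
    def columns(self) -> list[str]:
        return list(self.values.columns)

    @property
    def specimen_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def n_specimens(self) -> int:
        return len(self.values)

    def validate(self) -> None:
        v = self.values
        if v.index.has_duplicates:
            dups = v.index[v.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate specimen_id: {dups}")
        filled = v.to_numpy(dtype=float)
        observed = ~np.isnan(filled)
        if not np.all((filled[observed] > 0) & np.isfinite(filled[observed])):
            raise ValidationError("non-positive or non-finite measurement value")
        if not self.missing_mask.to_numpy().shape == filled.shape:
            raise ValidationError("missing_mask shape mismatch")
        imput = self.imputed_mask.to_numpy()
        if np.any(imput & ~self.missing_mask.to_numpy()):
            raise ValidationError("imputed cell that was never missing")
        # a missing cell is NaN unless it has been imputed
        still_missing = self.missing_mask.to_numpy() & ~imput
        if np.any(observed & still_missing):
            raise ValidationError("missing (non-imputed) cell holds a value")

    def copy(self) -> "MeasurementTable":
        return MeasurementTable(
            self.values.copy(), self.group.copy(), self.strain.copy(),
            self.missing_mask.copy(), self.imputed_mask.copy())

    def subset_groups(self, labels) -> "MeasurementTable":
        """Return the sub-table of specimens whose group is in *labels*."""
        keep = self.group.isin(list(labels))
        return MeasurementTable(
            self.values.loc[keep].copy(), self.group.loc[keep].copy(),
            self.strain.loc[keep].copy(), self.missing_mask.loc[keep].copy(),
            self.imputed_mask.loc[keep].copy())

    def complete(self) -> bool:
        """True when no cell is currently NaN (all missing cells imputed)."""
        return not self.values.isna().to_numpy().any()


@dataclass
class QCReport:
    """Pearson-correlation quality-control report on log-measurements."""

    correlation_matrix: pd.DataFrame
    flagged_variables: list[str]
    per_variable_summary: pd.DataFrame  # columns: min, median, max
    threshold: float
    reasons: dict[str, str] = field(default_factory=dict)

    def to_tsv(self) -> str:
        buf = io.StringIO()
        buf.write(f"# correlation QC, threshold={self.threshold}\n")
        self.per_variable_summary.to_csv(buf, sep="\t")
        return buf.getvalue()

    def summary_text(self) -> str:
        lines = [f"Pearson correlation QC on log-measurements "
                 f"(flag when median off-diagonal r < {self.threshold})"]
        for var, row in self.per_variable_summary.iterrows():
            mark = " *FLAGGED*" if var in self.flagged_variables else ""
            reason = self.reasons.get(var, "")
            if reason:
                mark += f" ({reason})"
            lines.append(f"  {var:8s} r: min {row['min']:+.2f} "
                         f"median {row['median']:+.2f} max {row['max']:+.2f}{mark}")
        return "\n".join(lines)


@dataclass
class ImputationLog:
    """Record of an imputation run."""

    n_imputed_cells: int
    seed: int
    method_tag: str
    per_cell: list[tuple[str, str, float]]
    converged: bool = True
    n_sweeps: int = 0

    def to_tsv(self) -> str:
        buf = io.StringIO()
        buf.write(f"# imputation: {self.method_tag}, seed={self.seed}, "
                  f"sweeps={self.n_sweeps}, converged={self.converged}\n")
        buf.write("specimen_id\tcharacter\timputed_value\n")
        for sid, abbr, val in self.per_cell:
            buf.write(f"{sid}\t{abbr}\t{val:.6g}\n")
        return buf.getvalue()


# ----------------------------------------------------------------------
# IO


def _is_missing(cell: str) -> bool:
    return str(cell).strip().lower() in MISSING_SENTINELS


def read_measurement_table(path, registry=CHARACTER_REGISTRY) -> MeasurementTable:
    """Read a measurement CSV into a validated :class:`MeasurementTable`.

    The file must have a header row with ``specimen_id``, ``group``, optional
    ``strain``, then character abbreviations; values are µm with decimal
    point, comma-delimited.  Empty cells and the sentinels "NA"/"NaN"
    (case-insensitive) mark missing values.  Columns not in *registry* (and
    not id/group/strain) raise a warning and are ignored.
    """
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    if "specimen_id" not in raw.columns or "group" not in raw.columns:
        raise ValidationError("header must contain specimen_id and group")
    known = set(c.abbreviation for c in registry)
    char_cols = [c for c in raw.columns if c in known]
    unknown = [c for c in raw.columns if c not in known and c not in ID_COLUMNS]
    if unknown:
        warnings.warn(f"ignoring unknown columns: {unknown}", stacklevel=2)

    index = raw["specimen_id"].astype(str)
    if index.duplicated().any():
        raise ValidationError(
            f"duplicate specimen_id: {index[index.duplicated()].tolist()}")
    vals = np.full((len(raw), len(char_cols)), np.nan)
    missing = np.zeros_like(vals, dtype=bool)
    for j, col in enumerate(char_cols):
        for i, cell in enumerate(raw[col]):
            if _is_missing(cell):
                missing[i, j] = True
                continue
            try:
                x = float(cell)
            except ValueError:
                raise ValidationError(
                    f"non-numeric value {cell!r} at specimen "
                    f"{index.iloc[i]!r}, column {col!r}") from None
            if not (x > 0 and np.isfinite(x)):
                raise ValidationError(
                    f"non-positive value {x} at specimen "
                    f"{index.iloc[i]!r}, column {col!r}")
            vals[i, j] = x

    values = pd.DataFrame(vals, index=pd.Index(index, name="specimen_id"),
                          columns=char_cols)
    group = pd.Series(raw["group"].astype(str).to_numpy(), index=values.index,
                      name="group")
    if "strain" in raw.columns:
        strain = pd.Series(raw["strain"].astype(str).to_numpy(),
                           index=values.index, name="strain")
    else:
        strain = pd.Series("", index=values.index, name="strain")
    mmask = pd.DataFrame(missing, index=values.index, columns=char_cols)
    imask = pd.DataFrame(False, index=values.index, columns=char_cols)
    return MeasurementTable(values, group, strain, mmask, imask)


def write_measurement_table(table: MeasurementTable, path) -> None:
    """Write *table* back to CSV (inverse of :func:`read_measurement_table`).

    Imputed cells are written with their imputed values; cells that are still
    missing are written as "NA".  Formats values with repr-level precision so
    a read → write → read round trip is bit-identical.
    """
    out = pd.DataFrame(index=table.values.index)
    out["specimen_id"] = table.values.index
    out["group"] = table.group
    out["strain"] = table.strain
    for col in table.columns:
        out[col] = [
            "NA" if (np.isnan(v)) else np.format_float_positional(v, trim="-")
            for v in table.values[col]
        ]
    out.to_csv(path, index=False)


# ----------------------------------------------------------------------
# QC


def correlation_qc(table: MeasurementTable, threshold: float = 0.5) -> QCReport:
    """Pearson-correlation QC of log-measurements, pairwise-complete.

    Body measurements of related taxa should correlate strongly and
    positively; a variable whose median off-diagonal correlation falls below
    *threshold* is flagged as a likely measurement artifact (e.g. a deformed
    body part).  A constant (zero-variance) variable is flagged with reason
    ``"constant"``.
    """
    logv = np.log(table.values)
    corr = logv.corr(method="pearson", min_periods=3)
    cols = table.columns
    reasons: dict[str, str] = {}
    flagged: list[str] = []
    rows = []
    cmat = corr.to_numpy(dtype=float)
    np.fill_diagonal(cmat, 1.0)
    for j, col in enumerate(cols):
        # zero-variance within some group or overall -> pandas yields NaN
        col_vals = logv[col].dropna()
        off = np.delete(cmat[j], j)
        if len(col_vals) and float(col_vals.max()) == float(col_vals.min()):
            reasons[col] = "constant"
            flagged.append(col)
            rows.append((np.nan, np.nan, np.nan))
            continue
        if np.all(np.isnan(off)):
            # no evaluable partner variable (e.g. all others constant)
            rows.append((np.nan, np.nan, np.nan))
            continue
        med = float(np.nanmedian(off))
        rows.append((float(np.nanmin(off)), med, float(np.nanmax(off))))
        if med < threshold:
            flagged.append(col)
            reasons[col] = f"median r {med:.2f} < {threshold}"
    summary = pd.DataFrame(rows, index=pd.Index(cols, name="character"),
                           columns=["min", "median", "max"])
    corr = pd.DataFrame(cmat, index=cols, columns=cols)
    return QCReport(corr, flagged, summary, threshold, reasons)


def drop_variables(table: MeasurementTable, names) -> MeasurementTable:
    """Return a copy of *table* without the characters in *names*."""
    names = list(names)
    unknown = [n for n in names if n not in table.columns]
    if unknown:
        raise KeyError(f"unknown variable(s): {unknown}")
    keep = [c for c in table.columns if c not in names]
    return MeasurementTable(
        table.values[keep].copy(), table.group.copy(), table.strain.copy(),
        table.missing_mask[keep].copy(), table.imputed_mask[keep].copy())


# ----------------------------------------------------------------------
# Imputation


def impute_missing(table: MeasurementTable, seed: int = 0,
                   max_sweeps: int = 50, tol: float = 1e-6,
                   ridge_scale: float = 1e-3) -> tuple[MeasurementTable, ImputationLog]:
    """Fill missing cells by deterministic iterated ridge regression on logs.

    Each incomplete character is regressed, on the natural-log scale, on all
    other characters (fit on its observed rows using the current completed
    matrix, ridge penalty λ = *ridge_scale* · mean diagonal of the centred
    predictor cross-product).  Missing log-values start from the column
    median plus a small seeded jitter and are updated column-by-column until
    the largest absolute change is below *tol* or *max_sweeps* sweeps have
    run.  Identical seeds give bit-identical results.
    """
    miss = table.values.isna().to_numpy()
    if not miss.any():
        return table.copy(), ImputationLog(0, seed, "iterated-ridge-log", [])
    if miss.all(axis=0).any():
        bad = [c for c, m in zip(table.columns, miss.all(axis=0)) if m]
        raise ValidationError(f"column(s) entirely missing: {bad}")
    if miss.all(axis=1).any():
        bad = [s for s, m in zip(table.specimen_ids, miss.all(axis=1)) if m]
        raise ValidationError(f"specimen(s) entirely missing: {bad}")

    rng = np.random.default_rng(seed)
    L = np.log(table.values.to_numpy(dtype=float))
    n, p = L.shape
    # initial fill: column medians of observed logs + tiny jitter
    for j in range(p):
        med = np.nanmedian(L[:, j])
        idx = np.where(miss[:, j])[0]
        L[idx, j] = med + rng.normal(0.0, 1e-3, size=len(idx))

    incomplete = [j for j in range(p) if miss[:, j].any()]
    converged = False
    sweep = 0
    for sweep in range(1, max_sweeps + 1):
        max_change = 0.0
        for j in incomplete:
            obs = ~miss[:, j]
            X = np.delete(L, j, axis=1)
            y = L[:, j]
            xm = X[obs].mean(axis=0)
            ym = y[obs].mean()
            Xc = X[obs] - xm
            G = Xc.T @ Xc
            lam = ridge_scale * np.trace(G) / G.shape[0]
            beta = np.linalg.solve(G + lam * np.eye(G.shape[0]), Xc.T @ (y[obs] - ym))
            pred = ym + (X[miss[:, j]] - xm) @ beta
            change = np.max(np.abs(pred - y[miss[:, j]])) if pred.size else 0.0
            max_change = max(max_change, float(change))
            L[miss[:, j], j] = pred
        if max_change < tol:
            converged = True
            break

    filled = table.values.copy()
    per_cell: list[tuple[str, str, float]] = []
    ids = table.specimen_ids
    cols = table.columns
    for i, j in zip(*np.where(miss)):
        val = float(np.exp(L[i, j]))
        filled.iat[i, j] = val
        per_cell.append((ids[i], cols[j], val))
    if not converged:
        warnings.warn("imputation did not converge within "
                      f"{max_sweeps} sweeps", stacklevel=2)
    new_imputed = table.imputed_mask.copy()
    new_imputed |= pd.DataFrame(miss, index=table.values.index, columns=cols)
    out = MeasurementTable(filled, table.group.copy(), table.strain.copy(),
                           table.missing_mask.copy(), new_imputed)
    log = ImputationLog(int(miss.sum()), seed, "iterated-ridge-log",
                        per_cell, converged, sweep)
    return out, log
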