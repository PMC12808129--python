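"""Tabular I/O for protein-group matrices, sample metadata, marker panels and QC reports.

The wide-matrix dialects follow the conventions of DIA search-engine output:
a ``diann_pg`` table carries five leading annotation columns (protein group,
protein ids, protein names, genes, description) followed by one intensity
column per run, while ``generic_wide`` expects a protein-id column, an
optional gene-symbol column and then sample columns.

Intensities are linear-scale.  Blank cells, literal ``NaN`` and zeros are all
mapped to a single missing state: search engines emit either blanks or zeros
for undetected protein groups, so the two are not distinguished.  No present
cell may be <= 0.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

CONTAMINATION_TYPES = ("platelet", "erythrocyte", "coagulation")
ID_KINDS = ("protein_group", "gene_symbol")
MATRIX_TYPES = ("plasma", "serum")

#: string tokens (case-insensitive) interpreted as a missing intensity
_MISSING_TOKENS = {"", "na", "nan", "n/a", "null", "none"}
#: header names (case-insensitive) recognised as a gene-symbol column in
#: the generic_wide dialect
_GENE_HEADERS = {"gene", "genes", "gene_symbol", "gene_symbols", "symbol"}
#: number of leading annotation columns in a DIA-NN pg_matrix table
_DIANN_ANNOTATION_NCOL = 5


def _check_unique(values: Iterable[str], what: str) -> None:
    seen: set[str] = set()
    for v in values:
        if v in seen:
            raise ValueError(f"duplicate {what}: {v!r}")
        seen.add(v)


@dataclass(eq=False)
class ProteinMatrix:
    """Proteins x samples intensity table with explicit missingness.

    ``intensities`` is indexed by protein-group identifier with one column
    per sample.  Missing cells are NaN; zeros are converted to missing on
    construction and every present cell is strictly positive.
    ``gene_symbols`` is an optional parallel series of gene symbols (empty
    string where unknown); DIA-NN style multi-gene entries ("A;B") are kept
    verbatim and split only at marker-matching time.
    """

    intensities: pd.DataFrame
    gene_symbols: pd.Series | None = None

    def __post_init__(self) -> None:
        df = self.intensities
        if not isinstance(df, pd.DataFrame):
            df = pd.DataFrame(df)
        df = df.astype(float)
        _check_unique(df.index.astype(str), "protein identifier")
        _check_unique(df.columns.astype(str), "sample identifier")
        vals = df.to_numpy()
        if np.any(vals[np.isfinite(vals)] < 0):
            raise ValueError("negative intensity encountered; intensities must be linear-scale and non-negative")
        df = df.mask(df == 0.0)  # zero means undetected
        df.index = df.index.astype(str)
        df.columns = df.columns.astype(str)
        self.intensities = df
        if self.gene_symbols is None:
            self.gene_symbols = pd.Series("", index=df.index, dtype=str)
        else:
            gs = pd.Series(self.gene_symbols).astype(str)
            if len(gs) != len(df.index):
                raise ValueError("gene_symbols length does not match number of proteins")
            gs.index = df.index
            self.gene_symbols = gs.fillna("")

    # -- basic accessors -------------------------------------------------
    @property
    def protein_ids(self) -> list[str]:
        return list(self.intensities.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.intensities.columns)

    @property
    def n_proteins(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_samples(self) -> int:
        return self.intensities.shape[1]

    @property
    def present(self) -> pd.DataFrame:
        """Boolean mask of detected (non-missing) cells."""
        return self.intensities.notna()

    def missing_fraction(self) -> pd.Series:
        """Per-protein fraction of samples in which the protein is missing."""
        return self.intensities.isna().mean(axis=1)

    def subset_proteins(self, protein_ids: Sequence[str]) -> "ProteinMatrix":
        ids = list(protein_ids)
        missing = [p for p in ids if p not in self.intensities.index]
        if missing:
            raise KeyError(f"unknown protein identifiers: {missing[:5]}")
        return ProteinMatrix(
            self.intensities.loc[ids].copy(),
            self.gene_symbols.loc[ids].copy(),
        )

    def copy(self) -> "ProteinMatrix":
        return ProteinMatrix(self.intensities.copy(), self.gene_symbols.copy())


@dataclass(frozen=True)
class SampleMetadata:
    """Per-sample design annotations for a contamination experiment.

    ``gradient_value`` is the ordinal or numeric contamination level (mixing
    fraction or group rank), ``cell_count`` the hematology count per measured
    volume (0 is a valid value meaning no contamination), and ``matrix_type``
    is ``plasma`` or ``serum``.  In paired plasma/serum designs
    ``group_label`` carries the donor identity.
    """

    sample_id: str
    group_label: str = ""
    gradient_value: float | None = None
    cell_count: float | None = None
    replicate_id: str = ""
    matrix_type: str = "plasma"

    def __post_init__(self) -> None:
        if self.matrix_type not in MATRIX_TYPES:
            raise ValueError(f"matrix_type must be one of {MATRIX_TYPES}, got {self.matrix_type!r}")
        if self.cell_count is not None and self.cell_count < 0:
            raise ValueError(f"cell_count must be non-negative, got {self.cell_count}")


@dataclass(frozen=True)
class MarkerPanel:
    """A named contamination type with its ordered marker identifier list."""

    contamination_type: str
    marker_ids: tuple[str, ...]
    id_kind: str = "gene_symbol"

    def __post_init__(self) -> None:
        if self.contamination_type not in CONTAMINATION_TYPES:
            raise ValueError(
                f"unknown contamination_type {self.contamination_type!r}; expected one of {CONTAMINATION_TYPES}"
            )
        if self.id_kind not in ID_KINDS:
            raise ValueError(f"unknown id_kind {self.id_kind!r}; expected one of {ID_KINDS}")
        ids = tuple(self.marker_ids)
        if len(ids) == 0:
            raise ValueError("marker panel is empty")
        _check_unique(ids, "marker id")
        object.__setattr__(self, "marker_ids", ids)

    def __len__(self) -> int:
        return len(self.marker_ids)


# ---------------------------------------------------------------------------
# protein matrices
# ---------------------------------------------------------------------------

def _parse_intensity_block(block: pd.DataFrame, protein_ids: Sequence[str]) -> pd.DataFrame:
    """Parse a string-valued sample block into floats with NaN for missing.

    Raises on any non-numeric, non-missing cell, naming the offending
    protein row and sample column.
    """
    out = np.full(block.shape, np.nan)
    arr = block.to_numpy(dtype=object)
    for j, col in enumerate(block.columns):
        for i in range(arr.shape[0]):
            cell = str(arr[i, j]).strip()
            if cell.lower() in _MISSING_TOKENS:
                continue
            try:
                v = float(cell)
            except ValueError:
                raise ValueError(
                    f"non-numeric intensity {cell!r} at protein {protein_ids[i]!r}, sample column {col!r}"
                ) from None
            if np.isnan(v):
                continue
            out[i, j] = v
    return pd.DataFrame(out, index=list(protein_ids), columns=list(block.columns))


def read_protein_matrix(path: str | Path, dialect: str = "generic_wide") -> ProteinMatrix:
    """Read a wide protein-group intensity matrix.

    Parameters
    ----------
    path:
        Tab-separated file.
    dialect:
        ``"diann_pg"`` for a DIA-NN pg_matrix-style table (five annotation
        columns, then samples; sample order is column order) or
        ``"generic_wide"`` (protein-id column, optional gene-symbol column,
        then samples).
    """
    path = Path(path)
    raw = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if raw.shape[1] < 2:
        raise ValueError(f"{path}: expected at least two columns")
    if dialect == "diann_pg":
        if raw.shape[1] <= _DIANN_ANNOTATION_NCOL:
            raise ValueError(
                f"{path}: diann_pg dialect expects {_DIANN_ANNOTATION_NCOL} annotation columns followed by samples"
            )
        protein_ids = raw.iloc[:, 0].astype(str).str.strip()
        genes = raw.iloc[:, 3].astype(str).str.strip()
        block = raw.iloc[:, _DIANN_ANNOTATION_NCOL:]
    elif dialect == "generic_wide":
        protein_ids = raw.iloc[:, 0].astype(str).str.strip()
        if raw.shape[1] > 2 and raw.columns[1].strip().lower() in _GENE_HEADERS:
            genes = raw.iloc[:, 1].astype(str).str.strip()
            block = raw.iloc[:, 2:]
        else:
            genes = pd.Series("", index=raw.index, dtype=str)
            block = raw.iloc[:, 1:]
    else:
        raise ValueError(f"unknown dialect {dialect!r}; expected 'diann_pg' or 'generic_wide'")
    _check_unique(protein_ids, "protein identifier")
    _check_unique(block.columns, "sample identifier")
    values = _parse_intensity_block(block, list(protein_ids))
    genes.index = values.index
    return ProteinMatrix(values, genes)


def write_protein_matrix(matrix: ProteinMatrix, path: str | Path, dialect: str = "generic_wide") -> None:
    """Write a matrix as tab-separated text; missing cells become blanks."""
    path = Path(path)
    if dialect == "generic_wide":
        out = matrix.intensities.copy()
        out.insert(0, "gene_symbol", matrix.gene_symbols)
        out.index.name = "protein_id"
        out.to_csv(path, sep="\t", na_rep="")
    elif dialect == "diann_pg":
        out = matrix.intensities.copy()
        out.insert(0, "First.Protein.Description", "")
        out.insert(0, "Genes", matrix.gene_symbols)
        out.insert(0, "Protein.Names", "")
        out.insert(0, "Protein.Ids", matrix.intensities.index)
        out.index.name = "Protein.Group"
        out.to_csv(path, sep="\t", na_rep="")
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


# ---------------------------------------------------------------------------
# sample metadata
# ---------------------------------------------------------------------------

def read_sample_metadata(path: str | Path) -> list[SampleMetadata]:
    """Read a CSV/TSV sample-metadata table (``sample_id`` column required).

    Unknown columns are ignored.  When no numeric ``gradient_value`` column
    is present but ``group_label`` is, the gradient defaults to the rank of
    the group label in sorted order (suits G01..G10 / A..G group codes).
    ``matrix_type`` defaults to plasma.
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline()
    sep = "\t" if "\t" in header else ","
    table = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    cols = {c.strip().lower(): c for c in table.columns}
    if "sample_id" not in cols:
        raise ValueError(f"{path}: metadata table lacks required 'sample_id' column")

    def col(name: str) -> pd.Series | None:
        return table[cols[name]].astype(str).str.strip() if name in cols else None

    sample_ids = table[cols["sample_id"]].astype(str).str.strip()
    _check_unique(sample_ids, "sample_id")
    group = col("group_label")
    gradient = col("gradient_value")
    cell_count = col("cell_count")
    replicate = col("replicate_id")
    mtype = col("matrix_type")

    rank: dict[str, int] = {}
    if gradient is None and group is not None:
        rank = {g: i for i, g in enumerate(sorted(set(group) - {""}))}

    records: list[SampleMetadata] = []
    for i in range(len(table)):
        g = group.iloc[i] if group is not None else ""
        if gradient is not None and gradient.iloc[i] != "":
            gv: float | None = float(gradient.iloc[i])
        elif g in rank:
            gv = float(rank[g])
        else:
            gv = None
        cc = None
        if cell_count is not None and cell_count.iloc[i] != "":
            cc = float(cell_count.iloc[i])
        mt = mtype.iloc[i].lower() if mtype is not None and mtype.iloc[i] != "" else "plasma"
        records.append(
            SampleMetadata(
                sample_id=sample_ids.iloc[i],
                group_label=g,
                gradient_value=gv,
                cell_count=cc,
                replicate_id=replicate.iloc[i] if replicate is not None else "",
                matrix_type=mt,
            )
        )
    return records


def write_sample_metadata(records: Sequence[SampleMetadata], path: str | Path) -> None:
    rows = [dataclasses.asdict(r) for r in records]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, na_rep="")


# ---------------------------------------------------------------------------
# marker panels
# ---------------------------------------------------------------------------

def read_marker_panel(path: str | Path) -> MarkerPanel:
    """Read a marker panel from a TSV with columns contamination_type, marker_id [, id_kind].

    Lines starting with ``#`` are comments.  The file defines one panel:
    all rows must share the same contamination type.
    """
    path = Path(path)
    table = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False, comment="#")
    cols = {c.strip().lower(): c for c in table.columns}
    for required in ("contamination_type", "marker_id"):
        if required not in cols:
            raise ValueError(f"{path}: panel file lacks required column {required!r}")
    if len(table) == 0:
        raise ValueError(f"{path}: marker panel is empty")
    ctypes = set(table[cols["contamination_type"]].str.strip().str.lower())
    if len(ctypes) != 1:
        raise ValueError(f"{path}: panel file mixes contamination types {sorted(ctypes)}")
    (ctype,) = ctypes
    markers = [m.strip() for m in table[cols["marker_id"]]]
    _check_unique(markers, "marker id")
    id_kind = "gene_symbol"
    if "id_kind" in cols:
        kinds = set(table[cols["id_kind"]].str.strip()) - {""}
        if len(kinds) > 1:
            raise ValueError(f"{path}: panel file mixes id kinds {sorted(kinds)}")
        if kinds:
            (id_kind,) = kinds
    return MarkerPanel(contamination_type=ctype, marker_ids=tuple(markers), id_kind=id_kind)


def write_marker_panel(panel: MarkerPanel, path: str | Path) -> None:
    table = pd.DataFrame(
        {
            "contamination_type": panel.contamination_type,
            "marker_id": list(panel.marker_ids),
            "id_kind": panel.id_kind,
        }
    )
    table.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# QC reports
# ---------------------------------------------------------------------------

#: column layout of the written QC report
QC_REPORT_COLUMNS = (
    "sample_id",
    "platelet_index",
    "erythrocyte_index",
    "coagulation_index",
    "platelet_flag",
    "erythrocyte_flag",
    "coagulation_flag",
    "any_flag",
)


def write_qc_report(report, path: str | Path) -> None:
    """Write a :class:`~plasmaqc.contamination_index.ContaminationReport` as TSV.

    One row per sample; indices with six decimal places; contamination types
    that were not evaluated are written as blanks with flag False.
    """
    table = report.table
    if len(table) == 0:
        raise ValueError("cannot write an empty contamination report")
    out = pd.DataFrame(index=table.index)
    for ctype in CONTAMINATION_TYPES:
        icol, fcol = f"{ctype}_index", f"{ctype}_flag"
        idx = table[icol] if icol in table.columns else pd.Series(np.nan, index=table.index)
        flg = table[fcol] if fcol in table.columns else pd.Series(False, index=table.index)
        out[icol] = [("" if pd.isna(v) else f"{v:.6f}") for v in idx]
        out[fcol] = flg.astype(bool)
    out["any_flag"] = table["any_flag"].astype(bool)
    out.index.name = "sample_id"
    out = out.reset_index()[list(QC_REPORT_COLUMNS)]
    out.to_csv(path, sep="\t", index=False)


def read_qc_report(path: str | Path) -> pd.DataFrame:
    """Read a written QC report back into a DataFrame indexed by sample_id."""
    table = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if "sample_id" not in table.columns:
        raise ValueError(f"{path}: not a QC report (no sample_id column)")
    table = table.set_index("sample_id")
    for ctype in CONTAMINATION_TYPES:
        icol, fcol = f"{ctype}_index", f"{ctype}_flag"
        if icol in table.columns:
            table[icol] = pd.to_numeric(table[icol].where(table[icol] != "", np.nan))
        if fcol in table.columns:
            table[fcol] = table[fcol].str.lower().isin({"true", "1"})
    if "any_flag" in table.columns:
        table["any_flag"] = table["any_flag"].str.lower().isin({"true", "1"})
    return table
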