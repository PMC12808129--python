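"""Per-sample contamination indices and sample flagging.

The contamination index of a sample for a marker panel is the summed
intensity of the detected panel markers divided by the summed intensity of
all detected proteins in that sample:

    index = sum(marker intensities) / sum(all protein intensities)

It is computed on linear intensities, lies in [0, 1], and is invariant to
rescaling all of a sample's intensities by a positive constant.  A sample
is flagged for a contamination type when its index strictly exceeds the
configured threshold for that type.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .matrix_io import CONTAMINATION_TYPES, MarkerPanel, ProteinMatrix

__all__ = [
    "ContaminationReport",
    "match_markers",
    "compute_contamination_index",
    "evaluate_samples",
]


@dataclass(eq=False)
class ContaminationReport:
    """Per-sample contamination indices, thresholds and flags.

    ``table`` is indexed by sample id with, per evaluated contamination
    type, columns ``{type}_index``, ``{type}_threshold``, ``{type}_flag``
    and ``{type}_n_markers``, plus ``any_flag``.  A flag is set only when
    a threshold is configured and the index strictly exceeds it.
    """

    table: pd.DataFrame
    unmatched_markers: dict[str, tuple[str, ...]] | None = None

    def __post_init__(self) -> None:
        if "any_flag" not in self.table.columns:
            raise ValueError("report table lacks an any_flag column")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    def evaluated_types(self) -> list[str]:
        return [t for t in CONTAMINATION_TYPES if f"{t}_index" in self.table.columns]

    def with_threshold(self, contamination_type: str, threshold: float) -> "ContaminationReport":
        """Return a new report with the given type's threshold and flags recomputed."""
        if contamination_type not in self.evaluated_types():
            raise ValueError(f"report has no {contamination_type} index to threshold")
        table = self.table.copy()
        table[f"{contamination_type}_threshold"] = float(threshold)
        table[f"{contamination_type}_flag"] = table[f"{contamination_type}_index"] > threshold
        flag_cols = [c for c in table.columns if c.endswith("_flag") and c != "any_flag"]
        table["any_flag"] = table[flag_cols].any(axis=1)
        return ContaminationReport(table, self.unmatched_markers)


def _symbol_lookup(matrix: ProteinMatrix) -> dict[str, str]:
    """Case-insensitive gene-symbol -> protein-id lookup (first match wins).

    DIA-NN style multi-gene annotations ("A;B") contribute each symbol.
    """
    lookup: dict[str, str] = {}
    for pid, genes in matrix.gene_symbols.items():
        for symbol in str(genes).split(";"):
            key = symbol.strip().casefold()
            if key and key not in lookup:
                lookup[key] = pid
    return lookup


def match_markers(matrix: ProteinMatrix, panel: MarkerPanel) -> dict[str, str | None]:
    """Map each panel marker to a matrix protein row (or None if unmatched).

    Gene-symbol panels match case-insensitively on the gene annotation,
    falling back to the protein-group identifier; protein-group panels
    match the identifier directly (exact, then case-insensitive).
    """
    id_exact = {pid: pid for pid in matrix.protein_ids}
    id_fold: dict[str, str] = {}
    for pid in matrix.protein_ids:
        id_fold.setdefault(pid.casefold(), pid)
    symbols = _symbol_lookup(matrix) if panel.id_kind == "gene_symbol" else {}

    out: dict[str, str | None] = {}
    for marker in panel.marker_ids:
        hit = None
        if panel.id_kind == "gene_symbol":
            hit = symbols.get(marker.casefold())
        if hit is None:
            hit = id_exact.get(marker) or id_fold.get(marker.casefold())
        out[marker] = hit
    return out


def compute_contamination_index(matrix: ProteinMatrix, panel: MarkerPanel) -> pd.Series:
    """Per-sample contamination index for one marker panel.

    Missing cells contribute to neither sum.  A sample with zero total
    detected intensity gets index 0 with a warning.  Raises if no panel
    marker matches the matrix at all, listing the unmatched identifiers.
    """
    index, _, _ = _index_with_details(matrix, panel)
    return index


def _index_with_details(
    matrix: ProteinMatrix, panel: MarkerPanel
) -> tuple[pd.Series, pd.Series, tuple[str, ...]]:
    matches = match_markers(matrix, panel)
    matched_rows = sorted({pid for pid in matches.values() if pid is not None})
    unmatched = tuple(m for m, pid in matches.items() if pid is None)
    if not matched_rows:
        raise ValueError(
            f"no {panel.contamination_type} panel marker matched the matrix; "
            f"unmatched ids: {list(unmatched)}"
        )
    total = matrix.intensities.sum(axis=0, skipna=True)
    marker_block = matrix.intensities.loc[matched_rows]
    marker_sum = marker_block.sum(axis=0, skipna=True)
    n_detected = marker_block.notna().sum(axis=0)
    zero_total = total == 0
    if zero_total.any():
        warnings.warn(
            f"samples with zero total intensity assigned index 0: {list(total.index[zero_total])}",
            stacklevel=3,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        index = (marker_sum / total).where(~zero_total, 0.0)
    index.name = f"{panel.contamination_type}_index"
    return index, n_detected, unmatched


def evaluate_samples(
    matrix: ProteinMatrix,
    panels: Sequence[MarkerPanel],
    thresholds: Mapping[str, float] | None = None,
) -> ContaminationReport:
    """Evaluate every sample against one panel per contamination type.

    ``thresholds`` maps contamination type to an index threshold; types
    without a threshold are reported unflagged.  Unmatched panel markers
    are recorded on the report, not fatal (as long as at least one marker
    matches per panel).
    """
    if not panels:
        raise ValueError("at least one marker panel is required")
    types = [p.contamination_type for p in panels]
    if len(set(types)) != len(types):
        raise ValueError("multiple panels share a contamination type")
    thresholds = dict(thresholds or {})

    table = pd.DataFrame(index=pd.Index(matrix.sample_ids, name="sample_id"))
    unmatched_all: dict[str, tuple[str, ...]] = {}
    for panel in panels:
        ctype = panel.contamination_type
        index, n_detected, unmatched = _index_with_details(matrix, panel)
        if unmatched:
            warnings.warn(
                f"{ctype} panel: {len(unmatched)} marker(s) not matched: {list(unmatched)}",
                stacklevel=2,
            )
            unmatched_all[ctype] = unmatched
        thr = thresholds.get(ctype)
        table[f"{ctype}_index"] = index
        table[f"{ctype}_threshold"] = np.nan if thr is None else float(thr)
        table[f"{ctype}_flag"] = False if thr is None else (index > thr)
        table[f"{ctype}_n_markers"] = n_detected
    flag_cols = [f"{t}_flag" for t in types]
    table["any_flag"] = table[flag_cols].any(axis=1)
    return ContaminationReport(table, unmatched_all or None)
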