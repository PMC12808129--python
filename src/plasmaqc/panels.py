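"""Default marker panels shipped with the package.

These contain only the handful of marker gene symbols that are public
knowledge for each contamination type — well-characterised platelet
proteins (platelet factor 4 and its variant, ADP/ATP translocase 2,
thromboxane A synthase, integrin beta-1), erythrocyte proteins
(hemoglobin subunits, spectrins, band 3 anion transporter) and
coagulation-related proteins (the fibrinogen chains consumed by clotting,
plus AGGF1 and TFRC).  They are deliberately small placeholders: a
properly calibrated deployment should supply its own 30/30/20 panels
discovered on matched spike-in data via :mod:`plasmaqc.marker_discovery`
(panel files are accepted by every entry point).
"""

from __future__ import annotations

from .matrix_io import MarkerPanel

DEFAULT_PANELS: dict[str, MarkerPanel] = {
    "platelet": MarkerPanel(
        contamination_type="platelet",
        marker_ids=("SLC25A5", "PF4V1", "TBXAS1", "ITGB1", "PF4"),
        id_kind="gene_symbol",
    ),
    "erythrocyte": MarkerPanel(
        contamination_type="erythrocyte",
        marker_ids=("HBD", "HBB", "HBA1", "SPTA1", "SPTB", "SLC4A1"),
        id_kind="gene_symbol",
    ),
    "coagulation": MarkerPanel(
        contamination_type="coagulation",
        marker_ids=("FGA", "FGG", "FGB", "AGGF1", "TFRC"),
        id_kind="gene_symbol",
    ),
}


def default_panel(contamination_type: str) -> MarkerPanel:
    try:
        return DEFAULT_PANELS[contamination_type]
    except KeyError:
        raise ValueError(f"no default panel for contamination type {contamination_type!r}") from None
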