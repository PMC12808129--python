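"""Replicate-precision and spike-in accuracy metrics.

Two benchmarking views of a quantitative proteomics workflow: per-protein
coefficients of variation across biological replicates (precision), and
observed-versus-theoretical fold changes of contaminant-specific features
across known spike-in ratio pairs (accuracy).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .matrix_io import ProteinMatrix

__all__ = ["ReplicateCV", "protein_cv", "median_cv", "foldchange_vs_expected"]


@dataclass(frozen=True)
class ReplicateCV:
    """Coefficient of variation of one protein over one replicate group.

    ``cv_percent`` is 100 * sd / mean on linear intensities with the
    sample (n-1) standard deviation; defined only when the protein is
    present in every replicate of the group.
    """

    protein_id: str
    cv_percent: float
    n_replicates: int


def protein_cv(
    matrix: ProteinMatrix,
    replicate_groups: Mapping[str, Sequence[str]],
) -> dict[str, list[ReplicateCV]]:
    """Per-protein CV within each replicate group.

    Proteins missing in any replicate of a group are skipped for that
    group.  Every group must contain at least two samples.
    """
    out: dict[str, list[ReplicateCV]] = {}
    for group, samples in replicate_groups.items():
        samples = list(samples)
        if len(samples) < 2:
            raise ValueError(f"replicate group {group!r} has fewer than 2 samples")
        block = matrix.intensities[samples]
        complete = block.notna().all(axis=1)
        sub = block.loc[complete]
        mean = sub.mean(axis=1)
        sd = sub.std(axis=1, ddof=1)
        cv = 100.0 * sd / mean
        out[group] = [
            ReplicateCV(pid, float(cv[pid]), len(samples)) for pid in sub.index
        ]
    return out


def median_cv(cvs: Sequence[ReplicateCV] | Sequence[float]) -> float:
    """Median CV (percent); even counts average the middle two."""
    values = [c.cv_percent if isinstance(c, ReplicateCV) else float(c) for c in cvs]
    if not values:
        raise ValueError("median of an empty CV list is undefined")
    return float(np.median(values))


def foldchange_vs_expected(
    matrix: ProteinMatrix,
    species_specific_ids: Sequence[str],
    group_pairs: Sequence[tuple[str, str]],
    expected_ratios: Mapping[tuple[str, str], float],
    groups: Mapping[str, Sequence[str]],
    median_normalize: bool = True,
) -> pd.DataFrame:
    """Observed log2 fold changes of spike-specific features versus truth.

    Intensities are log2-transformed and, when ``median_normalize`` is
    set, per-sample median-centred (global median normalisation of
    log-intensities, correcting technical scale differences between
    runs).  For each group pair the per-feature fold change is the
    difference of group means of the (centred) log2 intensities over
    samples where the feature is present; features absent from either
    group are skipped.  Returns one row per pair with the median and
    quartiles of the fold-change distribution and the deviation of the
    median from log2(expected ratio).

    Note: on volumetric mixtures the diluted background shifts the
    per-sample medians, so median centring biases spike fold changes by
    log2((1 - f1)/(1 - f2)); disable it (or fold that term into the
    expected ratio) when exact mixture arithmetic is wanted.
    """
    log = np.log2(matrix.intensities)
    if median_normalize:
        log = log.sub(log.median(axis=0, skipna=True), axis=1)

    ids = [p for p in species_specific_ids if p in log.index]
    rows = []
    for g1, g2 in group_pairs:
        s1, s2 = list(groups[g1]), list(groups[g2])
        fcs = []
        for pid in ids:
            a = log.loc[pid, s1].dropna()
            b = log.loc[pid, s2].dropna()
            if a.empty or b.empty:
                continue  # feature absent in one group
            fcs.append(float(a.mean() - b.mean()))
        fcs = np.asarray(fcs)
        expected = float(expected_ratios[(g1, g2)])
        med = float(np.median(fcs)) if fcs.size else np.nan
        rows.append(
            {
                "group_1": g1,
                "group_2": g2,
                "n_features": int(fcs.size),
                "median_log2_fc": med,
                "q1_log2_fc": float(np.percentile(fcs, 25)) if fcs.size else np.nan,
                "q3_log2_fc": float(np.percentile(fcs, 75)) if fcs.size else np.nan,
                "expected_log2_fc": float(np.log2(expected)),
                "deviation": med - float(np.log2(expected)) if fcs.size else np.nan,
            }
        )
    return pd.DataFrame(rows)
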