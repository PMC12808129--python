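"""Seeded simulators for contamination spike-in experiments.

Three generators emulate the designs used to establish and calibrate
contamination markers in nanoparticle-enriched plasma proteomics:

* a graded volumetric mixing series of a contaminant (platelet concentrate
  or packed erythrocytes) into platelet-poor plasma, with planted
  contaminant-enriched proteins, log-normal abundances, multiplicative
  noise and detection-limit censoring;
* paired plasma/serum samples from the same donors, with planted
  coagulation proteins depleted in serum;
* a piecewise-linear contamination-index-versus-cell-count curve used to
  exercise change-point calibration.

Every generator is fully determined by its integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .matrix_io import MarkerPanel, ProteinMatrix, SampleMetadata

__all__ = [
    "DilutionDesign",
    "SyntheticTruth",
    "simulate_contamination_series",
    "simulate_paired_plasma_serum",
    "simulate_index_curve",
]


@dataclass(frozen=True)
class DilutionDesign:
    """Volumetric mixing design for a contaminant dilution series.

    ``mixing_fractions`` are contaminant volume fractions f per level,
    sorted non-decreasing (the first may be 0 = pure platelet-poor plasma,
    the last may be 1 = pure contaminant).  ``cell_count_at_full`` is the
    hematology cell count corresponding to f = 1; per-sample counts scale
    linearly, count = f * cell_count_at_full.
    """

    mixing_fractions: tuple[float, ...]
    replicates_per_level: int = 3
    cell_count_at_full: float = 2.5e8

    def __post_init__(self) -> None:
        f = tuple(float(x) for x in self.mixing_fractions)
        if len(f) == 0:
            raise ValueError("empty dilution design")
        if any(x < 0 or x > 1 for x in f):
            raise ValueError("mixing fractions must lie in [0, 1]")
        if any(b < a for a, b in zip(f, f[1:])):
            raise ValueError("mixing fractions must be sorted non-decreasing")
        if self.replicates_per_level < 1:
            raise ValueError("replicates_per_level must be >= 1")
        if self.cell_count_at_full <= 0:
            raise ValueError("cell_count_at_full must be positive")
        object.__setattr__(self, "mixing_fractions", f)

    @property
    def n_levels(self) -> int:
        return len(self.mixing_fractions)

    @classmethod
    def geometric(
        cls,
        n_levels: int = 7,
        f_min: float = 0.01,
        f_max: float = 1.0,
        include_zero: bool = True,
        replicates_per_level: int = 3,
        cell_count_at_full: float = 2.5e8,
    ) -> "DilutionDesign":
        """Geometric series of mixing fractions, optionally prefixed with f = 0.

        The default (7 levels, f = 0 then 0.01 .. 1 geometric, triplicates)
        stands in for a seven-ratio contaminant mixing design run in
        triplicate; the exact published volumetric ratios are not printed,
        so a geometric ladder spanning two decades is used.
        """
        n_geo = n_levels - 1 if include_zero else n_levels
        if n_geo < 1:
            raise ValueError("need at least one non-zero level")
        if n_geo == 1:
            geo = [f_max]
        else:
            geo = list(np.geomspace(f_min, f_max, n_geo))
        fractions = ([0.0] if include_zero else []) + geo
        return cls(
            mixing_fractions=tuple(fractions),
            replicates_per_level=replicates_per_level,
            cell_count_at_full=cell_count_at_full,
        )


@dataclass(eq=False)
class SyntheticTruth:
    """Ground truth of a simulated cohort, reproducible from its seed."""

    contamination_type: str
    planted_marker_ids: tuple[str, ...]
    independent_ids: tuple[str, ...]
    seed: int
    noise_cv: float
    #: planted markers absent from clean plasma (contaminant-specific)
    contaminant_specific_ids: tuple[str, ...] = ()
    #: plasma-only proteins absent from the contaminant (decline with f)
    absent_in_contaminant_ids: tuple[str, ...] = ()
    #: per-sample contaminant volume fraction (dilution designs)
    mixing_fraction: dict[str, float] = field(default_factory=dict)
    #: per-sample cell count = f * cell_count_at_full (dilution designs)
    cell_count: dict[str, float] = field(default_factory=dict)
    lod_quantile: float = 0.0
    lod_threshold: float = 0.0
    contaminant_enrichment: float | None = None
    coagulation_fold: float | None = None
    #: noiseless clean-plasma profile (dilution designs)
    base_plasma: pd.Series | None = None
    #: noiseless pure-contaminant profile (dilution designs)
    contaminant_profile: pd.Series | None = None

    def true_panel(self, panel_size: int | None = None) -> MarkerPanel:
        """The planted markers as a protein-group panel (optionally truncated)."""
        ids = self.planted_marker_ids
        if panel_size is not None:
            ids = ids[:panel_size]
        return MarkerPanel(
            contamination_type=self.contamination_type,
            marker_ids=tuple(ids),
            id_kind="protein_group",
        )


def _lognormal_noise(rng: np.random.Generator, cv: float, shape) -> np.ndarray:
    """Mean-one multiplicative log-normal noise with the given CV."""
    if cv == 0:
        return np.ones(shape)
    sigma = np.sqrt(np.log1p(cv**2))
    return rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=shape)


def simulate_contamination_series(
    design: DilutionDesign | None = None,
    n_plasma_proteins: int = 2000,
    n_planted: int = 200,
    contaminant_enrichment: float = 50.0,
    noise_cv: float = 0.2,
    lod_quantile: float = 0.05,
    seed: int = 0,
    *,
    contamination_type: str = "platelet",
    absent_fraction: float = 0.2,
    specific_fraction: float = 0.3,
    planted_log10_shift: float = -1.0,
    log10_mean: float = 5.0,
    log10_sd: float = 1.0,
) -> tuple[ProteinMatrix, list[SampleMetadata], SyntheticTruth]:
    """Simulate a graded contaminant/plasma volumetric mixing series.

    Each sample at mixing fraction f is the convex combination
    ``(1 - f) * plasma + f * contaminant`` multiplied by mean-one
    log-normal noise of coefficient of variation ``noise_cv``, then
    left-censored at the global ``lod_quantile`` of the pooled intensity
    distribution (missing-not-at-random at the low end).

    The contaminant profile equals the plasma profile except that the
    ``n_planted`` planted markers are multiplied by
    ``contaminant_enrichment``, a fraction ``specific_fraction`` of them is
    absent from clean plasma entirely (contaminant-specific, rarely
    detected without contamination), and a fraction ``absent_fraction`` of
    the remaining plasma proteins is absent from the contaminant.  Planted
    markers draw their clean-plasma abundance ``planted_log10_shift``
    decades below the plasma base distribution (contaminant cell proteins
    are scarce in clean plasma).
    """
    if design is None:
        design = DilutionDesign.geometric()
    if not 0 < n_planted < n_plasma_proteins:
        raise ValueError("require 0 < n_planted < n_plasma_proteins")
    if not 0 <= lod_quantile < 1:
        raise ValueError("lod_quantile must lie in [0, 1)")
    if noise_cv < 0:
        raise ValueError("noise_cv must be non-negative")

    rng = np.random.default_rng(seed)
    width = max(4, len(str(n_plasma_proteins)))
    ids = np.array([f"P{i + 1:0{width}d}" for i in range(n_plasma_proteins)])

    perm = rng.permutation(n_plasma_proteins)
    planted = np.sort(perm[:n_planted])
    rest = np.sort(perm[n_planted:])
    n_specific = int(round(specific_fraction * n_planted))
    specific = planted[:n_specific] if n_specific else np.array([], dtype=int)
    n_absent = int(round(absent_fraction * len(rest)))
    absent = rest[:n_absent] if n_absent else np.array([], dtype=int)

    base = 10.0 ** rng.normal(log10_mean, log10_sd, n_plasma_proteins)
    base[planted] *= 10.0**planted_log10_shift
    plasma = base.copy()
    plasma[specific] = 0.0  # contaminant-specific, undetectable in clean plasma
    contaminant = base.copy()
    contaminant[planted] *= contaminant_enrichment
    contaminant[absent] = 0.0

    columns: dict[str, np.ndarray] = {}
    metadata: list[SampleMetadata] = []
    mixing: dict[str, float] = {}
    counts: dict[str, float] = {}
    for level, f in enumerate(design.mixing_fractions):
        label = f"G{level + 1:02d}"
        for rep in range(design.replicates_per_level):
            sid = f"{label}_R{rep + 1}"
            signal = (1.0 - f) * plasma + f * contaminant
            signal = signal * _lognormal_noise(rng, noise_cv, n_plasma_proteins)
            columns[sid] = signal
            mixing[sid] = float(f)
            counts[sid] = float(f * design.cell_count_at_full)
            metadata.append(
                SampleMetadata(
                    sample_id=sid,
                    group_label=label,
                    gradient_value=float(f),
                    cell_count=counts[sid],
                    replicate_id=f"R{rep + 1}",
                    matrix_type="plasma",
                )
            )

    values = pd.DataFrame(columns, index=ids)
    pooled = values.to_numpy().ravel()
    pooled = pooled[pooled > 0]
    threshold = float(np.quantile(pooled, lod_quantile)) if lod_quantile > 0 else 0.0
    if threshold > 0:
        values = values.mask(values < threshold)

    matrix = ProteinMatrix(values)
    independent = np.setdiff1d(rest, absent)
    truth = SyntheticTruth(
        contamination_type=contamination_type,
        planted_marker_ids=tuple(ids[planted]),
        contaminant_specific_ids=tuple(ids[specific]),
        absent_in_contaminant_ids=tuple(ids[absent]),
        independent_ids=tuple(ids[independent]),
        mixing_fraction=mixing,
        cell_count=counts,
        noise_cv=noise_cv,
        lod_quantile=lod_quantile,
        lod_threshold=threshold,
        contaminant_enrichment=contaminant_enrichment,
        seed=seed,
        base_plasma=pd.Series(plasma, index=ids),
        contaminant_profile=pd.Series(contaminant, index=ids),
    )
    return matrix, metadata, truth


def simulate_paired_plasma_serum(
    n_donors: int = 10,
    n_proteins: int = 800,
    n_coag_planted: int = 40,
    coag_fold: float = 8.0,
    noise_cv: float = 0.1,
    seed: int = 0,
    *,
    replicates: int = 1,
    donor_cv: float = 0.3,
    log10_mean: float = 5.0,
    log10_sd: float = 1.0,
) -> tuple[ProteinMatrix, list[SampleMetadata], SyntheticTruth]:
    """Simulate paired plasma and serum samples from the same donors.

    Serum equals the donor's plasma with the planted coagulation proteins
    divided by ``coag_fold`` (fibrinogen-like proteins are consumed by
    clotting, hence elevated in plasma relative to serum).  Donor-level
    biological variation is multiplicative log-normal with CV ``donor_cv``;
    per-sample technical noise has CV ``noise_cv``.  Donor identity is
    carried in ``SampleMetadata.group_label``.
    """
    if n_donors < 2:
        raise ValueError("paired testing requires at least 2 donors")
    if not 0 < n_coag_planted < n_proteins:
        raise ValueError("require 0 < n_coag_planted < n_proteins")
    if coag_fold <= 1:
        raise ValueError("coag_fold must exceed 1")

    rng = np.random.default_rng(seed)
    width = max(4, len(str(n_proteins)))
    ids = np.array([f"P{i + 1:0{width}d}" for i in range(n_proteins)])
    planted = np.sort(rng.permutation(n_proteins)[:n_coag_planted])

    base = 10.0 ** rng.normal(log10_mean, log10_sd, n_proteins)
    columns: dict[str, np.ndarray] = {}
    metadata: list[SampleMetadata] = []
    for d in range(n_donors):
        donor = f"D{d + 1:02d}"
        donor_profile = base * _lognormal_noise(rng, donor_cv, n_proteins)
        serum_profile = donor_profile.copy()
        serum_profile[planted] /= coag_fold
        for mtype, profile in (("plasma", donor_profile), ("serum", serum_profile)):
            for rep in range(replicates):
                sid = f"{donor}_{mtype}" if replicates == 1 else f"{donor}_{mtype}_R{rep + 1}"
                columns[sid] = profile * _lognormal_noise(rng, noise_cv, n_proteins)
                metadata.append(
                    SampleMetadata(
                        sample_id=sid,
                        group_label=donor,
                        replicate_id=f"R{rep + 1}",
                        matrix_type=mtype,
                    )
                )

    matrix = ProteinMatrix(pd.DataFrame(columns, index=ids))
    truth = SyntheticTruth(
        contamination_type="coagulation",
        planted_marker_ids=tuple(ids[planted]),
        independent_ids=tuple(np.delete(ids, planted)),
        noise_cv=noise_cv,
        coagulation_fold=coag_fold,
        seed=seed,
    )
    return matrix, metadata, truth


def simulate_index_curve(
    counts: Sequence[float],
    knot: float = 6.0,
    base_index: float = 0.01,
    slope: float = 0.1,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Piecewise-linear contamination-index curve over cell counts.

    The index is flat at ``base_index`` for log10(count) <= ``knot`` and
    rises with ``slope`` per log10 unit beyond it, plus Gaussian noise of
    standard deviation ``noise_sd``.
    """
    counts = np.asarray(counts, dtype=float)
    if np.any(counts <= 0):
        raise ValueError("counts must be positive")
    if slope < 0:
        raise ValueError("slope must be non-negative")
    x = np.log10(counts)
    indices = base_index + slope * np.maximum(x - knot, 0.0)
    if noise_sd > 0:
        indices = indices + np.random.default_rng(seed).normal(0.0, noise_sd, len(counts))
    return counts, indices
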