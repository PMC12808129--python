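"""Marker-panel establishment from graded spike-in and paired designs.

Platelet and erythrocyte panels come from a dilution-series design: filter
protein groups by missingness, rank by Spearman correlation with the
contamination gradient (signed — markers must rise with contamination),
keep the top correlation pool, and retain the most abundant members as the
panel.  Coagulation panels come from a paired plasma/serum design: paired
t-tests on log2 donor means with Benjamini-Hochberg correction, a strict
fold-change floor, and an abundance-ranked cut.  Fuzzy c-means trend
clustering is provided as an exploratory view of abundance trajectories;
it is not on the selection path.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .matrix_io import MarkerPanel, ProteinMatrix, SampleMetadata

__all__ = [
    "CorrelationProfile",
    "ClusterResult",
    "filter_by_missingness",
    "spearman_with_gradient",
    "fuzzy_cmeans_cluster",
    "select_contamination_markers",
    "select_independent_proteins",
    "paired_t_test",
    "bh_adjust",
    "coagulation_differential",
    "select_coagulation_markers",
    "pairing_from_metadata",
    "rank_gradient_markers",
]

MIN_PAIRS = 3  # Spearman rho is undefined below this many complete pairs


@dataclass(frozen=True)
class CorrelationProfile:
    """Spearman association of one protein with the contamination gradient.

    ``rho`` is NaN when undefined (fewer than :data:`MIN_PAIRS` complete
    observations, or zero variance in either variable over the complete
    pairs).  ``mean_abundance`` is the mean linear intensity over samples
    where the protein is present.
    """

    protein_id: str
    rho: float
    n_pairs: int
    mean_abundance: float

    @property
    def defined(self) -> bool:
        return not np.isnan(self.rho)


@dataclass(eq=False)
class ClusterResult:
    """Fuzzy c-means clustering of standardized per-level abundance trends."""

    n_clusters: int
    fuzzifier: float
    membership: pd.DataFrame  # proteins x clusters, rows sum to 1
    cluster_centroids: np.ndarray  # clusters x levels, zero mean per row
    n_iter: int
    converged: bool


# ---------------------------------------------------------------------------
# filtering and correlation
# ---------------------------------------------------------------------------

def filter_by_missingness(matrix: ProteinMatrix, max_missing_fraction: float = 0.5) -> ProteinMatrix:
    """Drop protein groups whose missing fraction strictly exceeds the threshold.

    A protein missing in exactly ``max_missing_fraction`` of samples is
    kept; the sample set is unchanged.
    """
    if not 0 <= max_missing_fraction <= 1:
        raise ValueError("max_missing_fraction must lie in [0, 1]")
    if matrix.n_proteins == 0 or matrix.n_samples == 0:
        raise ValueError("cannot filter an empty matrix")
    keep = matrix.missing_fraction() <= max_missing_fraction
    return ProteinMatrix(
        matrix.intensities.loc[keep].copy(),
        matrix.gene_symbols.loc[keep].copy(),
    )


def _as_gradient(gradient, sample_ids: Sequence[str]) -> np.ndarray:
    """Align a gradient specification (array, Series or mapping) to samples."""
    if isinstance(gradient, Mapping):
        gradient = [gradient[s] for s in sample_ids]
    elif isinstance(gradient, pd.Series):
        gradient = gradient.reindex(sample_ids).to_numpy()
    g = np.asarray(gradient, dtype=float)
    if len(g) != len(sample_ids):
        raise ValueError("gradient must provide one value per sample")
    if np.any(np.isnan(g)):
        raise ValueError("gradient is undefined for some samples")
    return g


def spearman_with_gradient(matrix: ProteinMatrix, gradient) -> list[CorrelationProfile]:
    """Per-protein Spearman rho against the contamination gradient.

    Pairwise-complete: each protein uses only the samples where it is
    present.  Ties are handled by average ranks.  Proteins with fewer than
    three complete pairs, or zero variance in either variable, carry an
    undefined (NaN) rho.
    """
    g = _as_gradient(gradient, matrix.sample_ids)
    if np.ptp(g) == 0:
        raise ValueError("gradient is constant; correlation undefined for all proteins")
    values = matrix.intensities.to_numpy()
    profiles: list[CorrelationProfile] = []
    for i, pid in enumerate(matrix.protein_ids):
        row = values[i]
        mask = ~np.isnan(row)
        n = int(mask.sum())
        mean_ab = float(row[mask].mean()) if n else np.nan
        rho = np.nan
        if n >= MIN_PAIRS:
            x, y = row[mask], g[mask]
            if np.ptp(x) > 0 and np.ptp(y) > 0:
                with warnings.catch_warnings():
                    # near-constant rows (e.g. noiseless fixtures) trip scipy's
                    # precision-loss warning; ranks are still well defined
                    warnings.simplefilter("ignore", RuntimeWarning)
                    rho = float(stats.spearmanr(x, y).statistic)
        profiles.append(CorrelationProfile(pid, rho, n, mean_ab))
    return profiles


def _level_mean_abundance(matrix: ProteinMatrix, levels: np.ndarray) -> pd.Series:
    """Mean over levels of the per-level mean of present intensities.

    This is the abundance metric used for panel ranking: averaging within
    each gradient level first prevents designs with unequal replication
    from dominating the mean.
    """
    df = matrix.intensities
    level_means = df.T.groupby(levels).mean()  # levels x proteins, NaN-aware
    return level_means.mean(axis=0)


def rank_gradient_markers(matrix: ProteinMatrix, gradient) -> pd.DataFrame:
    """Full ranking table behind marker selection.

    Columns: rho, n_pairs, mean_abundance (per-level mean), sorted by rho
    descending with deterministic tie-breaking (higher abundance, then
    lexicographic protein id).  Proteins with undefined rho sort last.
    """
    g = _as_gradient(gradient, matrix.sample_ids)
    profiles = spearman_with_gradient(matrix, g)
    abundance = _level_mean_abundance(matrix, g)
    table = pd.DataFrame(
        {
            "protein_id": [p.protein_id for p in profiles],
            "rho": [p.rho for p in profiles],
            "n_pairs": [p.n_pairs for p in profiles],
            "mean_abundance": abundance.reindex([p.protein_id for p in profiles]).to_numpy(),
        }
    )
    table = table.sort_values(
        by=["rho", "mean_abundance", "protein_id"],
        ascending=[False, False, True],
        na_position="last",
        kind="mergesort",
    ).reset_index(drop=True)
    return table


def select_contamination_markers(
    matrix: ProteinMatrix,
    gradient,
    correlation_pool: int = 100,
    panel_size: int = 30,
    contamination_type: str = "platelet",
) -> MarkerPanel:
    """Select a contamination marker panel from a graded spike-in series.

    Rank proteins by signed Spearman rho with the gradient (descending),
    take the top ``correlation_pool``, then keep the ``panel_size`` most
    abundant of that pool.  The matrix is expected to be
    missingness-filtered already.  If fewer than ``correlation_pool``
    proteins have a defined rho, all of them form the pool.
    """
    table = rank_gradient_markers(matrix, gradient)
    defined = table[table["rho"].notna()]
    if len(defined) < panel_size:
        raise ValueError(
            f"only {len(defined)} proteins with defined correlation; cannot select a panel of {panel_size}"
        )
    pool = defined.head(correlation_pool)
    chosen = pool.sort_values(
        by=["mean_abundance", "protein_id"],
        ascending=[False, True],
        kind="mergesort",
    ).head(panel_size)
    return MarkerPanel(
        contamination_type=contamination_type,
        marker_ids=tuple(chosen["protein_id"]),
        id_kind="protein_group",
    )


def select_independent_proteins(
    matrix: ProteinMatrix,
    gradient,
    rho_threshold: float = 0.7,
) -> list[str]:
    """Contamination-independent proteins: present in the zero-contamination
    samples and without a strong positive gradient association.

    A protein qualifies when it is detected in at least one sample at the
    lowest gradient level and its signed rho is strictly below
    ``rho_threshold`` (strongly negatively correlated proteins qualify).
    Proteins whose rho is undefined are included — an undefined correlation
    is no evidence of association.
    """
    g = _as_gradient(gradient, matrix.sample_ids)
    zero_level = g.min()
    zero_cols = [s for s, gv in zip(matrix.sample_ids, g) if gv == zero_level]
    present_at_zero = matrix.present[zero_cols].any(axis=1)
    out: list[str] = []
    for p in spearman_with_gradient(matrix, g):
        if not present_at_zero[p.protein_id]:
            continue
        if np.isnan(p.rho) or p.rho < rho_threshold:
            out.append(p.protein_id)
    return out


# ---------------------------------------------------------------------------
# fuzzy c-means trend clustering
# ---------------------------------------------------------------------------

def fuzzy_cmeans_cluster(
    matrix: ProteinMatrix,
    levels,
    n_clusters: int = 8,
    fuzzifier: float = 2.0,
    max_iter: int = 300,
    tol: float = 1e-6,
    seed: int = 0,
) -> ClusterResult:
    """Cluster standardized per-level abundance trends with fuzzy c-means.

    Each protein's trend is its mean present intensity per gradient level,
    z-standardized; proteins with zero trend variance or with an empty
    level are excluded.  Classic Bezdek fuzzy c-means: memberships
    u_ik ∝ d_ik^(-2/(m-1)) row-normalized, centroids the u^m-weighted
    means, iterated until the largest centroid movement drops below
    ``tol`` or ``max_iter`` is reached.  ``seed`` selects the initial
    centroids (random distinct proteins).
    """
    if fuzzifier <= 1:
        raise ValueError("fuzzifier must be > 1")
    g = _as_gradient(levels, matrix.sample_ids)
    trends = matrix.intensities.T.groupby(g).mean().T  # proteins x levels
    trends = trends.dropna(axis=0, how="any")
    sd = trends.std(axis=1, ddof=0)
    trends = trends.loc[sd > 0]
    z = trends.sub(trends.mean(axis=1), axis=0).div(sd.loc[trends.index], axis=0)
    n, L = z.shape
    if n_clusters > n:
        raise ValueError(f"n_clusters={n_clusters} exceeds the {n} clusterable proteins")

    X = z.to_numpy()
    rng = np.random.default_rng(seed)
    centroids = X[rng.choice(n, size=n_clusters, replace=False)].copy()
    exponent = 2.0 / (fuzzifier - 1.0)
    converged = False
    u = np.full((n, n_clusters), 1.0 / n_clusters)
    it = 0
    for it in range(1, max_iter + 1):
        d2 = ((X[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
        with np.errstate(divide="ignore", invalid="ignore"):
            inv = d2 ** (-exponent / 2.0)
            u = inv / inv.sum(axis=1, keepdims=True)
        # points coinciding with a centroid get full membership there
        bad = ~np.isfinite(u).all(axis=1)
        if bad.any():
            hard = d2[bad].argmin(axis=1)
            u[bad] = 0.0
            u[np.nonzero(bad)[0], hard] = 1.0
        um = u**fuzzifier
        new_centroids = (um.T @ X) / um.sum(axis=0)[:, None]
        shift = np.abs(new_centroids - centroids).max()
        centroids = new_centroids
        if shift < tol:
            converged = True
            break

    membership = pd.DataFrame(u, index=z.index, columns=[f"C{k + 1}" for k in range(n_clusters)])
    return ClusterResult(
        n_clusters=n_clusters,
        fuzzifier=fuzzifier,
        membership=membership,
        cluster_centroids=centroids,
        n_iter=it,
        converged=converged,
    )


# ---------------------------------------------------------------------------
# paired differential selection (coagulation)
# ---------------------------------------------------------------------------

def paired_t_test(x: Sequence[float], y: Sequence[float]) -> float:
    """Two-sided paired Student's t-test p-value.

    Pairs are by position (donor).  All-zero differences return p = 1.0 by
    convention; zero-variance non-zero differences return p = 0.0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired samples must have equal length")
    if len(x) < 2:
        raise ValueError("paired t-test requires at least 2 pairs")
    d = x - y
    if np.allclose(d, 0.0):
        return 1.0
    if np.ptp(d) == 0:
        return 0.0
    return float(stats.ttest_rel(x, y).pvalue)


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def pairing_from_metadata(metadata: Sequence[SampleMetadata]) -> dict[str, dict[str, list[str]]]:
    """Build the donor -> {plasma: [...], serum: [...]} map from metadata.

    Donor identity is taken from ``group_label``; donors missing either
    condition are dropped.
    """
    pairing: dict[str, dict[str, list[str]]] = {}
    for m in metadata:
        pairing.setdefault(m.group_label, {"plasma": [], "serum": []})[m.matrix_type].append(m.sample_id)
    return {d: v for d, v in pairing.items() if v["plasma"] and v["serum"]}


def coagulation_differential(
    plasma: ProteinMatrix,
    serum: ProteinMatrix,
    donor_pairing: Mapping[str, Mapping[str, Sequence[str]]],
    min_donors: int = 2,
) -> pd.DataFrame:
    """Paired plasma-vs-serum differential abundance per protein.

    For each protein, the per-donor condition value is the mean of its
    present replicate intensities; donors lacking the protein in a
    condition are dropped, and the protein is tested only if at least
    ``min_donors`` donors have values in both conditions.  Fold change is
    computed on linear condition means over the common donors; the paired
    t-test runs on log2 donor means; BH adjustment spans all tested
    proteins.
    """
    donors = sorted(donor_pairing)
    if not donors:
        raise ValueError("no paired donors: pairing map is empty")

    shared = [p for p in plasma.protein_ids if p in set(serum.protein_ids)]
    rows = []
    for pid in shared:
        pv, sv = [], []
        for d in donors:
            prow = plasma.intensities.loc[pid, list(donor_pairing[d]["plasma"])]
            srow = serum.intensities.loc[pid, list(donor_pairing[d]["serum"])]
            pmean, smean = prow.mean(), srow.mean()
            if pd.isna(pmean) or pd.isna(smean):
                continue
            pv.append(float(pmean))
            sv.append(float(smean))
        if len(pv) < min_donors:
            continue
        pv, sv = np.asarray(pv), np.asarray(sv)
        fold = pv.mean() / sv.mean()
        rows.append(
            {
                "protein_id": pid,
                "n_donors": len(pv),
                "fold_change": fold,
                "log2_fc": np.log2(fold),
                "p_value": paired_t_test(np.log2(pv), np.log2(sv)),
                "mean_abundance": float(np.concatenate([pv, sv]).mean()),
            }
        )
    if not rows:
        raise ValueError("no protein testable in at least 2 donors across both conditions")
    table = pd.DataFrame(rows)
    table["adj_p"] = bh_adjust(table["p_value"].to_numpy())
    return table


def select_coagulation_markers(
    plasma: ProteinMatrix,
    serum: ProteinMatrix,
    donor_pairing: Mapping[str, Mapping[str, Sequence[str]]],
    min_fold: float = 5.0,
    alpha: float = 0.05,
    panel_size: int = 20,
) -> MarkerPanel:
    """Select coagulation markers from a paired plasma/serum design.

    Survivors must show a plasma/serum fold change strictly greater than
    ``min_fold`` and a BH-adjusted p-value below ``alpha``; the
    ``panel_size`` most abundant survivors form the panel.  Fewer survivors
    than ``panel_size`` yields a warning and the full survivor set; zero
    survivors is an error.
    """
    table = coagulation_differential(plasma, serum, donor_pairing)
    survivors = table[(table["fold_change"] > min_fold) & (table["adj_p"] < alpha)]
    if len(survivors) == 0:
        warnings.warn("no protein passed the fold-change and FDR criteria", stacklevel=2)
        raise ValueError(
            f"no protein with fold change > {min_fold} and adjusted p < {alpha}; cannot build a panel"
        )
    if len(survivors) < panel_size:
        warnings.warn(
            f"only {len(survivors)} proteins passed selection; returning all of them "
            f"instead of the requested {panel_size}",
            stacklevel=2,
        )
    chosen = survivors.sort_values(
        by=["mean_abundance", "protein_id"],
        ascending=[False, True],
        kind="mergesort",
    ).head(panel_size)
    return MarkerPanel(
        contamination_type="coagulation",
        marker_ids=tuple(chosen["protein_id"]),
        id_kind="protein_group",
    )
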