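"""Microarray-style processing of donor sample tables into a left-hemisphere
region x gene expression matrix.

Pipeline order matters and is fixed: (1) intensity-based probe filtering,
(2) one probe per gene by reference correlation, (3) sample-to-region
assignment within a distance cap, (4) per-donor scaled-sigmoid normalization
within structure classes followed by within-region then cross-donor
averaging, (5) left-hemisphere restriction.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from ._types import DonorTable, ExpressionMatrix, ProbeTable

__all__ = [
    "filter_probes_by_intensity",
    "select_probe_per_gene",
    "assign_samples_to_regions",
    "normalize_and_aggregate",
    "process_expression",
]

log = logging.getLogger(__name__)


def filter_probes_by_intensity(
    donor_tables: list[DonorTable],
    probe_table: ProbeTable,
    min_fraction: float = 0.5,
) -> ProbeTable:
    """Keep probes above background in at least ``min_fraction`` of samples.

    Fractions are pooled over all donors' samples; the boundary is inclusive
    (a probe at exactly ``min_fraction`` survives).
    """
    flags = pd.concat([dt.above_background for dt in donor_tables], axis=0)
    frac = flags.mean(axis=0)
    keep = frac[frac >= min_fraction].index
    if len(keep) == 0:
        raise ValueError(
            f"no probes exceed background in >= {min_fraction:.0%} of samples"
        )
    probes = probe_table.probes[probe_table.probes["probe_id"].isin(keep)].reset_index(drop=True)
    return ProbeTable(probes=probes, reference_profile=probe_table.reference_profile)


def select_probe_per_gene(
    donor_tables: list[DonorTable],
    probe_table: ProbeTable,
) -> ProbeTable:
    """Pick one probe per gene.

    With a reference profile: the probe whose pooled intensity vector has the
    highest Spearman correlation to the gene's reference vector. Without one:
    the probe with the highest mean intensity. Ties break on lexicographic
    probe_id. Genes left with zero probes are dropped with a log entry.
    """
    pooled = pd.concat([dt.intensities for dt in donor_tables], axis=0)
    ref = probe_table.reference_profile
    rows = []
    for gene, grp in probe_table.probes.groupby("gene_symbol", sort=True):
        cand = sorted(grp["probe_id"])
        cand = [p for p in cand if p in pooled.columns]
        if not cand:
            log.info("gene %s dropped: no surviving probes", gene)
            continue
        if len(cand) == 1:
            best = cand[0]
        elif ref is not None and gene in ref.index:
            rvec = ref.loc[gene, pooled.index].to_numpy(dtype=float)
            scores = []
            for p in cand:
                rho = stats.spearmanr(pooled[p].to_numpy(), rvec).statistic
                scores.append(0.0 if np.isnan(rho) else rho)
            # ties -> first (lexicographically smallest) candidate
            best = cand[int(np.argmax(scores))]
        else:
            means = [pooled[p].mean() for p in cand]
            best = cand[int(np.argmax(means))]
        rows.append(grp[grp["probe_id"] == best].iloc[0])
    probes = pd.DataFrame(rows).reset_index(drop=True)
    return ProbeTable(probes=probes, reference_profile=ref)


def assign_samples_to_regions(
    samples: pd.DataFrame,
    atlas: pd.DataFrame,
    max_dist_mm: float = 10.0,
) -> pd.DataFrame:
    """Assign each sample to the nearest atlas centroid within a distance cap.

    Returns a DataFrame (indexed like ``samples``) with columns region_id
    (-1 if unassigned) and distance_mm. Distance ties break on the smaller
    region_id; samples farther than ``max_dist_mm`` from every centroid stay
    unassigned.
    """
    coords = samples[["x", "y", "z"]].to_numpy(dtype=float)
    cents = atlas[["x", "y", "z"]].to_numpy(dtype=float)
    d = np.sqrt(((coords[:, None, :] - cents[None, :, :]) ** 2).sum(axis=2))
    nearest = d.argmin(axis=1)  # argmin returns first (smallest region_id) on ties
    dist = d[np.arange(len(samples)), nearest]
    region_ids = atlas["region_id"].to_numpy()[nearest]
    assigned = dist <= max_dist_mm
    out = pd.DataFrame(
        {
            "region_id": np.where(assigned, region_ids, -1),
            "distance_mm": dist,
        },
        index=samples.index,
    )
    n_drop = int((~assigned).sum())
    if n_drop:
        log.info("%d/%d samples unassigned (> %.1f mm)", n_drop, len(samples), max_dist_mm)
    return out


def _scaled_robust_sigmoid(x: np.ndarray) -> np.ndarray:
    """x' = 1/(1+exp(-(x-median)/(IQR/1.35))), then min-max rescaled to [0,1].

    Constant input (IQR = 0) maps to 0.5 everywhere.
    """
    med = np.median(x)
    iqr = np.subtract(*np.percentile(x, [75, 25]))
    if iqr == 0:
        return np.full_like(x, 0.5, dtype=float)
    sig = 1.0 / (1.0 + np.exp(-(x - med) / (iqr / 1.35)))
    lo, hi = sig.min(), sig.max()
    if hi == lo:
        return np.full_like(x, 0.5, dtype=float)
    return (sig - lo) / (hi - lo)


def normalize_and_aggregate(
    assignments: dict[str, pd.DataFrame],
    donor_tables: list[DonorTable],
    probe_table: ProbeTable,
    atlas: pd.DataFrame,
) -> ExpressionMatrix:
    """Normalize per donor within structure classes, aggregate to regions.

    For each donor, each structure class and each gene, samples get the
    scaled robust sigmoid; samples are then averaged within region per donor
    and regions averaged across the donors that have data there. Only
    left-hemisphere regions are kept; left regions without any sample are
    reported in ``missing_regions``.
    """
    probes = probe_table.probes
    probe_ids = probes["probe_id"].tolist()
    gene_of = dict(zip(probes["probe_id"], probes["gene_symbol"]))
    left_ids = atlas.loc[atlas["hemisphere"] == "L", "region_id"].tolist()

    per_donor: list[pd.DataFrame] = []
    any_assigned = False
    for dt in donor_tables:
        assign = assignments[dt.donor_id]
        keep = assign["region_id"] >= 0
        if not keep.any():
            continue
        any_assigned = True
        intens = dt.intensities.loc[keep, probe_ids].copy()
        intens.columns = [gene_of[p] for p in probe_ids]
        classes = dt.samples.loc[keep, "structure_class"]
        norm = intens.copy()
        for cls in classes.unique():
            mask = (classes == cls).to_numpy()
            block = intens.loc[mask].to_numpy(dtype=float)
            for j in range(block.shape[1]):
                block[:, j] = _scaled_robust_sigmoid(block[:, j])
            norm.iloc[np.where(mask)[0], :] = block
        norm["__region__"] = assign.loc[keep, "region_id"].to_numpy()
        per_donor.append(norm.groupby("__region__").mean())
    if not any_assigned:
        raise ValueError("no assigned samples in any donor table")

    combined = pd.concat(per_donor, axis=0)
    region_mean = combined.groupby(level=0).mean()
    region_mean = region_mean.loc[region_mean.index.intersection(left_ids)]
    missing = sorted(set(left_ids) - set(region_mean.index))
    if missing:
        log.info("%d left-hemisphere regions without samples", len(missing))
    region_mean = region_mean.sort_index()
    region_mean.index.name = "region_id"
    return ExpressionMatrix(data=region_mean, missing_regions=missing)


def process_expression(
    donor_tables: list[DonorTable],
    probe_table: ProbeTable,
    atlas: pd.DataFrame,
    *,
    min_fraction: float = 0.5,
    max_dist_mm: float = 10.0,
) -> ExpressionMatrix:
    """Run the full (1)-(5) processing chain in order."""
    pt = filter_probes_by_intensity(donor_tables, probe_table, min_fraction)
    pt = select_probe_per_gene(donor_tables, pt)
    assignments = {
        dt.donor_id: assign_samples_to_regions(dt.samples, atlas, max_dist_mm)
        for dt in donor_tables
    }
    return normalize_and_aggregate(assignments, donor_tables, pt, atlas)
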