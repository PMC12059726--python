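"""Seeded generators for atlas, cohort, donor-expression and gene-set fixtures.

Every generator is a pure function of its arguments and the seed: calling it
twice with identical inputs produces identical outputs.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from ._types import (
    DonorTable,
    EffectSpec,
    GeneSetCollection,
    NETWORKS,
    ProbeTable,
    SubjectRecord,
)

__all__ = [
    "generate_atlas",
    "generate_cohort",
    "generate_donor_expression",
    "generate_gene_sets",
    "nearest_positive_definite",
    "planted_target_map",
    "write_atlas_tsv",
    "read_atlas_tsv",
    "write_gmt",
]

# Bounding box (mm) for synthetic centroids, roughly brain-sized.
_BOX = {"x": (6.0, 68.0), "y": (-98.0, 68.0), "z": (-48.0, 76.0)}


def generate_atlas(
    n_regions: int,
    network_proportions: dict[str, float] | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Generate atlas metadata: centroids, network labels and hemispheres.

    Returns a DataFrame with columns region_id, name, x, y, z, network,
    hemisphere. Hemisphere follows the sign of x; within each network the
    regions alternate hemispheres so both are always populated.
    """
    if n_regions < 2 * len(NETWORKS):
        raise ValueError(
            f"n_regions={n_regions} too small: need at least 2 regions for each of "
            f"the {len(NETWORKS)} networks"
        )
    if network_proportions is None:
        network_proportions = {net: 1.0 / len(NETWORKS) for net in NETWORKS}
    props = np.array([network_proportions[net] for net in NETWORKS], dtype=float)
    if not np.isclose(props.sum(), 1.0, atol=1e-6):
        raise ValueError("network proportions must sum to 1")

    # Guarantee >=2 per network, distribute the rest by largest remainder.
    counts = np.full(len(NETWORKS), 2, dtype=int)
    remaining = n_regions - counts.sum()
    raw = props * remaining
    extra = np.floor(raw).astype(int)
    counts += extra
    leftovers = n_regions - counts.sum()
    order = np.argsort(-(raw - extra))
    for i in range(leftovers):
        counts[order[i % len(NETWORKS)]] += 1

    rng = np.random.default_rng(seed)
    rows = []
    rid = 0
    for net, cnt in zip(NETWORKS, counts):
        for k in range(cnt):
            hemi = "L" if k % 2 == 0 else "R"
            x = rng.uniform(*_BOX["x"])
            if hemi == "L":
                x = -x
            rows.append(
                {
                    "region_id": rid,
                    "name": f"{net}_{k:03d}",
                    "x": x,
                    "y": rng.uniform(*_BOX["y"]),
                    "z": rng.uniform(*_BOX["z"]),
                    "network": net,
                    "hemisphere": hemi,
                }
            )
            rid += 1
    atlas = pd.DataFrame(rows)
    return atlas.set_index("region_id", drop=False).rename_axis(None)


def write_atlas_tsv(atlas: pd.DataFrame, path) -> None:
    atlas.to_csv(path, sep="\t", index=False)


def read_atlas_tsv(path) -> pd.DataFrame:
    atlas = pd.read_csv(path, sep="\t")
    return atlas.set_index("region_id", drop=False).rename_axis(None)


def nearest_positive_definite(corr: np.ndarray, eig_floor: float = 1e-6) -> np.ndarray:
    """Repair a symmetric matrix to a positive-definite correlation matrix.

    Eigenvalues are clipped at ``eig_floor`` and the result is rescaled to
    unit diagonal.
    """
    sym = (corr + corr.T) / 2.0
    vals, vecs = np.linalg.eigh(sym)
    if vals.min() >= eig_floor:
        return sym
    vals = np.clip(vals, eig_floor, None)
    repaired = (vecs * vals) @ vecs.T
    d = np.sqrt(np.diag(repaired))
    repaired = repaired / np.outer(d, d)
    np.fill_diagonal(repaired, 1.0)
    return repaired


def _block_correlation(
    atlas: pd.DataFrame,
    r_within: float,
    r_between: float,
    pairs_delta: dict[frozenset, float],
) -> np.ndarray:
    nets = atlas["network"].to_numpy()
    R = len(atlas)
    corr = np.full((R, R), r_between)
    same = nets[:, None] == nets[None, :]
    corr[same] = r_within
    for pair, delta in pairs_delta.items():
        members = tuple(pair)
        a = members[0]
        b = members[1] if len(members) > 1 else members[0]
        mask = ((nets[:, None] == a) & (nets[None, :] == b)) | (
            (nets[:, None] == b) & (nets[None, :] == a)
        )
        corr[mask] += delta
    np.clip(corr, -0.97, 0.97, out=corr)
    np.fill_diagonal(corr, 1.0)
    return corr


def generate_cohort(
    atlas: pd.DataFrame,
    n_group1: int,
    n_group2: int,
    n_timepoints: int,
    sites: list[str],
    effect: EffectSpec,
    seed: int | None = None,
    *,
    r_within: float = 0.25,
    r_between: float = 0.05,
    age_shift_group2: float = 0.0,
    female_prob: tuple[float, float] = (0.5, 0.5),
    repair_pd: bool = True,
) -> list[SubjectRecord]:
    """Simulate a two-group multi-site cohort of regional time series.

    Time series are multivariate normal draws from a block correlation
    structure; group-2 subjects get ``effect.delta`` added on the edges of
    ``effect.network_pairs``. Site effects are per-site affine transforms of
    the latent correlation (applied before sampling). HAMA is sampled so that
    the planted group is recoverable via the >18 rule.
    """
    if n_timepoints < 2:
        raise ValueError("n_timepoints must be >= 2")
    if not sites:
        raise ValueError("need at least one site")
    R = len(atlas)
    if n_timepoints < 2 * R:
        warnings.warn(
            f"n_timepoints={n_timepoints} < 2*R={2 * R}: correlation estimates "
            "may be rank-deficient",
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)

    base = _block_correlation(atlas, r_within, r_between, {})
    delta_map = {frozenset(p): effect.delta for p in effect.network_pairs}
    perturbed = _block_correlation(atlas, r_within, r_between, delta_map)

    def site_transform(corr: np.ndarray, site: str) -> np.ndarray:
        off = effect.site_offsets.get(site, 0.0)
        scale = effect.site_scales.get(site, 1.0)
        out = np.clip(scale * corr + off, -0.97, 0.97)
        np.fill_diagonal(out, 1.0)
        return out

    # Pre-factorize one covariance per (group, site) combination.
    chols: dict[tuple[int, str], np.ndarray] = {}
    for g, corr in ((1, base), (2, perturbed)):
        for site in sites:
            c = site_transform(corr, site)
            vals = np.linalg.eigvalsh((c + c.T) / 2)
            if vals.min() < 1e-10:
                if not repair_pd:
                    raise ValueError(
                        "planted correlation matrix is not positive definite; "
                        "pass repair_pd=True to clip eigenvalues to the nearest "
                        "positive-definite correlation matrix"
                    )
                c = nearest_positive_definite(c)
            chols[(g, site)] = np.linalg.cholesky(c)

    subjects: list[SubjectRecord] = []
    total = n_group1 + n_group2
    site_assign = [sites[i % len(sites)] for i in range(total)]
    idx = 0
    for group, n in ((1, n_group1), (2, n_group2)):
        for _ in range(n):
            site = site_assign[idx]
            L = chols[(group, site)]
            ts = rng.standard_normal((n_timepoints, R)) @ L.T
            age = float(np.clip(rng.normal(38.0 + (age_shift_group2 if group == 2 else 0.0), 11.0), 18, 65))
            sex = "F" if rng.random() < female_prob[group - 1] else "M"
            hama = int(rng.integers(19, 41)) if group == 2 else int(rng.integers(3, 19))
            subjects.append(
                SubjectRecord(
                    subject_id=f"sub-{idx:04d}",
                    site=site,
                    age=age,
                    sex=sex,
                    education=float(np.clip(rng.normal(12.0, 3.0), 3, 22)),
                    fd=float(np.clip(abs(rng.normal(0.10, 0.04)), 0.01, 0.19)),
                    hamd=int(rng.integers(8, 31)),
                    hama=hama,
                    quality_score=int(rng.integers(4, 6)),
                    timeseries=ts,
                    group=group,
                )
            )
            idx += 1
    return subjects


def planted_target_map(atlas: pd.DataFrame, effect: EffectSpec) -> pd.Series:
    """Per-region count of planted edges, scaled by delta.

    This is the regional footprint of the planted FC effect: region i's value
    is delta times the number of its edges lying in a perturbed
    between-network block. It is the map planted genes are coupled to.
    """
    nets = atlas["network"].to_numpy()
    counts = np.zeros(len(atlas))
    for a, b in effect.network_pairs:
        in_a = nets == a
        in_b = nets == b
        counts[in_a] += in_b.sum()
        counts[in_b] += in_a.sum()
    return pd.Series(effect.delta * counts, index=atlas["region_id"].to_numpy(), name="target")


def _sq_exp_kernel(centroids: np.ndarray, length: float) -> np.ndarray:
    d2 = ((centroids[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
    return np.exp(-d2 / (2.0 * length**2)) + 1e-8 * np.eye(len(centroids))


def generate_donor_expression(
    atlas: pd.DataFrame,
    n_donors: int,
    n_genes: int,
    target_map: np.ndarray | pd.Series,
    effect: EffectSpec,
    seed: int | None = None,
    *,
    planted_strength: float = 1.0,
    planted_noise_sd: float = 0.3,
    sample_noise_sd: float = 0.25,
    jitter_sd: float = 4.0,
    samples_per_region: int = 2,
    two_probe_fraction: float = 0.1,
    bad_probe_fraction: float = 0.1,
    n_right_hemi_donors: int = 2,
) -> tuple[list[DonorTable], ProbeTable]:
    """Simulate multi-donor microarray-style tissue sample tables.

    Planted genes (the first ``effect.n_planted_genes``) have regional means
    ``planted_strength * z(target_map)`` plus spatially autocorrelated noise
    drawn from a squared-exponential Gaussian process over centroid distances
    with length scale ``effect.spatial_corr_length``; decoy genes are GP noise
    only. Only the first ``n_right_hemi_donors`` donors have right-hemisphere
    samples. A ``bad_probe_fraction`` of probes is flagged below background
    in most samples; a ``two_probe_fraction`` of genes carries a second,
    noisier probe.
    """
    if effect.spatial_corr_length <= 0:
        raise ValueError("spatial kernel length must be > 0")
    if effect.n_planted_genes > n_genes:
        raise ValueError("n_planted_genes exceeds n_genes")
    target = np.asarray(
        target_map.loc[atlas["region_id"]].to_numpy()
        if isinstance(target_map, pd.Series)
        else target_map,
        dtype=float,
    )
    if target.shape != (len(atlas),):
        raise ValueError("target_map must be indexed by atlas regions")
    tsd = target.std()
    target_z = (target - target.mean()) / (tsd if tsd > 0 else 1.0)

    rng = np.random.default_rng(seed)
    centroids = atlas[["x", "y", "z"]].to_numpy()
    K = _sq_exp_kernel(centroids, effect.spatial_corr_length)
    chol = np.linalg.cholesky(K)
    R = len(atlas)

    genes = [f"G{i:05d}" for i in range(n_genes)]
    planted = set(genes[: effect.n_planted_genes])

    # Regional gene profiles shared across donors (the biological signal).
    # Planted genes track the target map with spatially autocorrelated (GP)
    # noise; decoys are independent of the target map.
    n_planted = len(planted)
    gp = chol @ rng.standard_normal((R, n_planted))
    profiles = rng.standard_normal((R, n_genes))
    for j, g in enumerate(genes):
        if g in planted:
            profiles[:, j] = planted_strength * target_z + planted_noise_sd * gp[:, j]

    # Probe design: every gene gets one probe; a fraction gets a noisy second.
    probe_rows = []
    probe_gene_idx = []
    probe_noise = []
    for j, g in enumerate(genes):
        probe_rows.append({"probe_id": f"P{j:05d}_a", "gene_symbol": g, "is_planted": g in planted})
        probe_gene_idx.append(j)
        probe_noise.append(0.0)
        if rng.random() < two_probe_fraction:
            probe_rows.append({"probe_id": f"P{j:05d}_b", "gene_symbol": g, "is_planted": g in planted})
            probe_gene_idx.append(j)
            probe_noise.append(1.0)  # extra noise sd -> lower reference correlation
    probes_df = pd.DataFrame(probe_rows)
    n_probes = len(probes_df)
    bad_probe = rng.random(n_probes) < bad_probe_fraction
    probe_gene_idx = np.array(probe_gene_idx)
    probe_noise = np.array(probe_noise)

    donors: list[DonorTable] = []
    ref_cols: dict[str, np.ndarray] = {}
    for d in range(n_donors):
        donor_id = f"donor{d:02d}"
        keep_right = d < n_right_hemi_donors
        sample_rows = []
        region_idx = []
        for ridx, (_, reg) in enumerate(atlas.iterrows()):
            if reg["hemisphere"] == "R" and not keep_right:
                continue
            for s in range(samples_per_region):
                coord = centroids[ridx] + rng.normal(0.0, jitter_sd, size=3)
                sample_rows.append(
                    {
                        "sample_id": f"{donor_id}_s{len(sample_rows):04d}",
                        "x": coord[0],
                        "y": coord[1],
                        "z": coord[2],
                        "structure_class": "subcortex" if reg["network"] == "SC" else "cortex",
                        "hemisphere": reg["hemisphere"],
                        "source_region": reg["region_id"],
                    }
                )
                region_idx.append(ridx)
        samples = pd.DataFrame(sample_rows).set_index("sample_id", drop=False).rename_axis(None)
        region_idx = np.array(region_idx)
        n_samp = len(samples)

        base = profiles[region_idx][:, probe_gene_idx]  # n_samp x n_probes
        noise = rng.normal(0.0, sample_noise_sd, size=base.shape)
        extra = rng.standard_normal(base.shape) * probe_noise[None, :]
        intens = 7.0 + base + noise + extra
        p_above = np.where(bad_probe, 0.3, 0.95)
        flags = rng.random(intens.shape) < p_above[None, :]

        donors.append(
            DonorTable(
                donor_id=donor_id,
                samples=samples,
                intensities=pd.DataFrame(intens, index=samples.index, columns=probes_df["probe_id"]),
                above_background=pd.DataFrame(flags, index=samples.index, columns=probes_df["probe_id"]),
            )
        )
        # Reference profile: noiseless regional value at each sample's region.
        for j, g in enumerate(genes):
            ref_cols.setdefault(g, np.empty(0))
        ref_block = profiles[region_idx]  # n_samp x n_genes
        for j, g in enumerate(genes):
            ref_cols[g] = np.concatenate([ref_cols[g], ref_block[:, j]])

    all_sample_ids = [sid for dt in donors for sid in dt.samples.index]
    reference = pd.DataFrame(
        {g: ref_cols[g] for g in genes}, index=all_sample_ids
    ).T
    probe_table = ProbeTable(probes=probes_df, reference_profile=reference)
    return donors, probe_table


def generate_gene_sets(
    gene_universe: list[str],
    planted_genes: list[str],
    n_terms: int,
    term_size_range: tuple[int, int],
    seed: int | None = None,
    *,
    planted_fraction: float = 1.0,
) -> GeneSetCollection:
    """Build a GMT-writable collection with one planted term and decoys.

    The planted term contains ``planted_fraction`` (>= 0.8) of the planted
    genes; decoy terms are uniform draws from the universe. With an empty
    planted set no planted term is emitted.
    """
    universe = list(gene_universe)
    missing = set(planted_genes) - set(universe)
    if missing:
        raise ValueError(f"planted genes not in universe: {sorted(missing)[:5]}")
    lo, hi = term_size_range
    if hi > len(universe):
        raise ValueError("term size exceeds gene universe")
    if planted_fraction < 0.8:
        raise ValueError("planted term must contain >= 80% of planted genes")
    rng = np.random.default_rng(seed)
    terms: dict[str, tuple[str, frozenset[str]]] = {}
    if planted_genes:
        n_keep = max(1, int(np.ceil(planted_fraction * len(planted_genes))))
        keep = list(rng.choice(planted_genes, size=n_keep, replace=False))
        size = int(rng.integers(lo, hi + 1))
        if size > len(keep):
            pool = [g for g in universe if g not in set(keep)]
            pad = list(rng.choice(pool, size=min(size - len(keep), len(pool)), replace=False))
            keep = keep + pad
        terms["PLANTED_TERM"] = ("planted synthetic term", frozenset(keep))
    for i in range(n_terms):
        size = int(rng.integers(lo, hi + 1))
        genes = frozenset(rng.choice(universe, size=size, replace=False))
        terms[f"DECOY_{i:04d}"] = ("decoy synthetic term", genes)
    return GeneSetCollection(terms=terms)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name, (desc, genes) in collection:
            fh.write("\t".join([name, desc, *sorted(genes)]) + "\n")
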