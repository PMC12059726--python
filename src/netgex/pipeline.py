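"""File-mediated pipeline stages and the end-to-end orchestrator.

Each stage reads its inputs from the run directory (so any stage can be
skipped if its inputs are provided externally in the same layout) and writes
plain-text artifacts: TSV matrices, GMT gene sets, JSON summaries. ``run_all``
chains the stages and records a manifest with the config hash, the seeds and
every artifact path.
"""

from __future__ import annotations

import json
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import connectome, enrich, expression, groupdiff, plsassoc, synthdata
from ._types import DonorTable, EffectSpec, ProbeTable, SubjectRecord
from .config import PipelineConfig, validate_config

__all__ = [
    "stage_simulate", "stage_fc", "stage_harmonize", "stage_groupdiff",
    "stage_net_t", "stage_expression", "stage_pls", "stage_enrich", "run_all",
]

_STAGES = (
    "simulate", "fc", "harmonize", "groupdiff",
    "net-t", "expression", "pls", "enrich",
)


def _effect_from_cfg(cfg: PipelineConfig) -> EffectSpec:
    sim = cfg.simulation
    return EffectSpec(
        network_pairs=[tuple(p) for p in sim.network_pairs],
        delta=sim.delta,
        n_planted_genes=sim.n_planted_genes,
        spatial_corr_length=sim.spatial_corr_length,
        site_offsets=dict(sim.site_offsets),
        site_scales=dict(sim.site_scales),
    )


def _write_matrix(mat, path, index=None, columns=None) -> None:
    pd.DataFrame(mat, index=index, columns=columns).to_csv(path, sep="\t")


def stage_simulate(cfg: PipelineConfig, outdir: Path) -> dict:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = cfg.seeds.get("simulate", 0)
    sim = cfg.simulation
    effect = _effect_from_cfg(cfg)

    atlas = synthdata.generate_atlas(sim.n_regions, seed=seed)
    synthdata.write_atlas_tsv(atlas, outdir / "atlas.tsv")

    subjects = synthdata.generate_cohort(
        atlas, sim.n_group1, sim.n_group2, sim.n_timepoints, list(sim.sites),
        effect, seed=seed + 1,
    )
    cov_rows = []
    for s in subjects:
        _write_matrix(
            s.timeseries, outdir / f"ts_{s.subject_id}.tsv",
            columns=atlas["region_id"].tolist(),
        )
        cov_rows.append(
            {k: getattr(s, k) for k in
             ("subject_id", "site", "age", "sex", "education", "fd",
              "hamd", "hama", "quality_score", "group")}
        )
    pd.DataFrame(cov_rows).to_csv(outdir / "cohort.tsv", sep="\t", index=False)

    target = synthdata.planted_target_map(atlas, effect)
    target.rename_axis("region_id").to_csv(outdir / "target_map.tsv", sep="\t")
    donors, probe_table = synthdata.generate_donor_expression(
        atlas, sim.n_donors, sim.n_genes, target, effect, seed=seed + 2,
    )
    for dt in donors:
        dt.samples.to_csv(outdir / f"{dt.donor_id}_samples.tsv", sep="\t", index=False)
        dt.intensities.to_csv(outdir / f"{dt.donor_id}_intensities.tsv", sep="\t")
        dt.above_background.to_csv(outdir / f"{dt.donor_id}_flags.tsv", sep="\t")
    probe_table.probes.to_csv(outdir / "probes.tsv", sep="\t", index=False)
    probe_table.reference_profile.to_csv(outdir / "reference_profile.tsv", sep="\t")

    genes = probe_table.probes["gene_symbol"].unique().tolist()
    planted = probe_table.probes.loc[probe_table.probes["is_planted"], "gene_symbol"].unique().tolist()
    sets = synthdata.generate_gene_sets(
        genes, planted, sim.n_terms, (sim.term_size_min, sim.term_size_max),
        seed=seed + 3,
    )
    synthdata.write_gmt(sets, outdir / "gene_sets.gmt")
    manifest = {
        "seed": seed,
        "n_subjects": len(subjects),
        "n_donors": len(donors),
        "files": sorted(p.name for p in outdir.iterdir()),
    }
    (outdir / "simulate_manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def _load_cohort(outdir: Path) -> tuple[pd.DataFrame, list[SubjectRecord], pd.DataFrame]:
    atlas = synthdata.read_atlas_tsv(outdir / "atlas.tsv")
    cov = pd.read_csv(outdir / "cohort.tsv", sep="\t")
    subjects = []
    for _, row in cov.iterrows():
        ts = pd.read_csv(outdir / f"ts_{row['subject_id']}.tsv", sep="\t", index_col=0).to_numpy()
        subjects.append(
            SubjectRecord(
                subject_id=row["subject_id"], site=row["site"], age=row["age"],
                sex=row["sex"], education=row["education"], fd=row["fd"],
                hamd=None if pd.isna(row["hamd"]) else int(row["hamd"]),
                hama=None if pd.isna(row["hama"]) else int(row["hama"]),
                quality_score=int(row["quality_score"]), timeseries=ts,
                group=None if pd.isna(row.get("group")) else int(row["group"]),
            )
        )
    return atlas, subjects, cov


def stage_fc(cfg: PipelineConfig, outdir: Path) -> dict:
    outdir = Path(outdir)
    _require(outdir, "cohort.tsv", "fc")
    atlas, subjects, _ = _load_cohort(outdir)
    included, excluded = groupdiff.apply_inclusion_criteria(
        subjects, fd_max=cfg.fd_max, hamd_min_exclusive=cfg.hamd_remission,
        quality_min=cfg.quality_min,
    )
    rows = []
    for s in included:
        z = connectome.compute_fc(s.timeseries)
        _write_matrix(z, outdir / f"fc_{s.subject_id}.tsv",
                      index=atlas["region_id"].tolist(), columns=atlas["region_id"].tolist())
        rows.append(s.subject_id)
    summary = {
        "included": rows,
        "excluded": [{"subject_id": s.subject_id, "reasons": r} for s, r in excluded],
    }
    (outdir / "fc_summary.json").write_text(json.dumps(summary, indent=2))
    return summary


def _load_fc_stack(outdir: Path) -> tuple[np.ndarray, list[str], pd.DataFrame]:
    summary = json.loads((outdir / "fc_summary.json").read_text())
    ids = summary["included"]
    cov = pd.read_csv(outdir / "cohort.tsv", sep="\t").set_index("subject_id").loc[ids]
    prefix = "fch" if (outdir / f"fch_{ids[0]}.tsv").exists() else "fc"
    stack = np.stack([
        pd.read_csv(outdir / f"{prefix}_{sid}.tsv", sep="\t", index_col=0).to_numpy()
        for sid in ids
    ])
    return stack, ids, cov


def stage_harmonize(cfg: PipelineConfig, outdir: Path) -> dict:
    outdir = Path(outdir)
    _require(outdir, "fc_summary.json", "harmonize")
    summary = json.loads((outdir / "fc_summary.json").read_text())
    ids = summary["included"]
    cov = pd.read_csv(outdir / "cohort.tsv", sep="\t").set_index("subject_id").loc[ids]
    stack = np.stack([
        pd.read_csv(outdir / f"fc_{sid}.tsv", sep="\t", index_col=0).to_numpy()
        for sid in ids
    ])
    prot = cov[cfg.protected_covariates].copy()
    if "sex" in prot.columns:
        prot["sex"] = (prot["sex"] == "F").astype(float)
    if cov["site"].nunique() > 1:
        stack = connectome.combat_harmonize(stack, cov["site"], prot)
    atlas = synthdata.read_atlas_tsv(outdir / "atlas.tsv")
    for sid, mat in zip(ids, stack):
        _write_matrix(mat, outdir / f"fch_{sid}.tsv",
                      index=atlas["region_id"].tolist(), columns=atlas["region_id"].tolist())
    return {"harmonized": ids, "n_sites": int(cov["site"].nunique())}


def stage_groupdiff(cfg: PipelineConfig, outdir: Path) -> dict:
    outdir = Path(outdir)
    _require(outdir, "fc_summary.json", "groupdiff")
    stack, ids, cov = _load_fc_stack(outdir)
    atlas = synthdata.read_atlas_tsv(outdir / "atlas.tsv")
    group = np.where(cov["hama"] > cfg.hama_cut, "ANX+", "ANX-")
    covs = cov[cfg.glm_covariates].copy()
    if "sex" in covs.columns:
        covs["sex"] = (covs["sex"] == "F").astype(float)
    seed = cfg.seeds.get("groupdiff", 1)

    stats_map = groupdiff.edge_glm_ttest(stack, group, covs)
    rids = atlas["region_id"].tolist()
    _write_matrix(stats_map.t, outdir / "edge_t.tsv", index=rids, columns=rids)
    _write_matrix(stats_map.p, outdir / "edge_p.tsv", index=rids, columns=rids)

    nbs = groupdiff.nbs_correct(
        stack, group, covs, edge_p=cfg.edge_p, alpha=cfg.alpha,
        n_perm=cfg.n_perm, seed=seed,
    )
    nbs_json = {
        "edge_p": nbs.edge_p, "alpha": nbs.alpha, "n_perm": nbs.n_perm,
        "t_threshold": nbs.t_threshold,
        "components": [
            {"edges": c.edges, "size": c.size, "p_value": c.p_value}
            for c in nbs.components
        ],
        "null_max_size": nbs.null_max_size.tolist(),
    }
    (outdir / "nbs.json").write_text(json.dumps(nbs_json, indent=2))

    net_stack = np.stack([connectome.network_average(m, atlas).to_numpy() for m in stack])
    t7, p7 = groupdiff.network_ttest(net_stack, group, covs, n_perm=cfg.n_perm, seed=seed + 1)
    t7.to_csv(outdir / "network_t.tsv", sep="\t")
    p7.to_csv(outdir / "network_p.tsv", sep="\t")
    return {
        "df": stats_map.df,
        "n_significant_components": len(nbs.significant),
        "groups": {g: int((group == g).sum()) for g in np.unique(group)},
    }


def stage_net_t(cfg: PipelineConfig, outdir: Path) -> dict:
    outdir = Path(outdir)
    _require(outdir, "edge_t.tsv", "net-t")
    atlas = synthdata.read_atlas_tsv(outdir / "atlas.tsv")
    t = pd.read_csv(outdir / "edge_t.tsv", sep="\t", index_col=0).to_numpy()
    from ._types import EdgeStatMap
    left = atlas.index[atlas["hemisphere"] == "L"].to_numpy()
    scores = groupdiff.net_t_value(EdgeStatMap(t=t, p=np.ones_like(t), df=0), left)
    scores.index = atlas.loc[left, "region_id"].to_numpy()
    scores.rename_axis("region_id").to_csv(outdir / "net_t.tsv", sep="\t")
    return {"n_regions": len(scores)}


def stage_expression(cfg: PipelineConfig, outdir: Path) -> dict:
    outdir = Path(outdir)
    _require(outdir, "probes.tsv", "expression")
    atlas = synthdata.read_atlas_tsv(outdir / "atlas.tsv")
    probes = pd.read_csv(outdir / "probes.tsv", sep="\t")
    ref = pd.read_csv(outdir / "reference_profile.tsv", sep="\t", index_col=0)
    donors = []
    for f in sorted(outdir.glob("donor*_samples.tsv")):
        did = f.name.split("_samples")[0]
        samples = pd.read_csv(f, sep="\t").set_index("sample_id", drop=False).rename_axis(None)
        donors.append(DonorTable(
            donor_id=did,
            samples=samples,
            intensities=pd.read_csv(outdir / f"{did}_intensities.tsv", sep="\t", index_col=0),
            above_background=pd.read_csv(outdir / f"{did}_flags.tsv", sep="\t", index_col=0),
        ))
    pt = ProbeTable(probes=probes, reference_profile=ref)
    em = expression.process_expression(
        donors, pt, atlas, min_fraction=cfg.probe_min_fraction,
        max_dist_mm=cfg.max_dist_mm,
    )
    em.data.to_csv(outdir / "expression.tsv", sep="\t")
    return {"n_regions": em.data.shape[0], "n_genes": em.data.shape[1],
            "missing_regions": em.missing_regions}


def stage_pls(cfg: PipelineConfig, outdir: Path) -> dict:
    outdir = Path(outdir)
    _require(outdir, "expression.tsv", "pls")
    _require(outdir, "net_t.tsv", "pls")
    atlas = synthdata.read_atlas_tsv(outdir / "atlas.tsv")
    X = pd.read_csv(outdir / "expression.tsv", sep="\t", index_col=0)
    y = pd.read_csv(outdir / "net_t.tsv", sep="\t", index_col=0).iloc[:, 0]
    common = X.index.intersection(y.index)
    X = X.loc[common]
    yv = y.loc[common].to_numpy()
    cents = atlas.set_index("region_id").loc[common, ["x", "y", "z"]].to_numpy()

    model = plsassoc.simpls_fit(X.to_numpy(), yv, cfg.n_components)
    sel = plsassoc.select_component(model)
    ens = plsassoc.surrogate_maps(
        yv, cents, cfg.n_surrogates, seed=cfg.seeds.get("surrogates", 3),
    )
    p_perm, observed, _ = plsassoc.permutation_test(X.to_numpy(), yv, ens, cfg.n_components)
    table = plsassoc.bootstrap_gene_weights(
        X.to_numpy(), yv, cfg.n_components, selected=sel, n_boot=cfg.n_boot,
        seed=cfg.seeds.get("bootstrap", 4), gene_names=X.columns.tolist(),
    )
    pos, neg = plsassoc.select_genes(table, cfg.z_thresh)
    table.to_csv(outdir / "gene_weights.tsv", sep="\t", index=False)
    (outdir / "genes_pos.txt").write_text("\n".join(pos) + ("\n" if pos else ""))
    (outdir / "genes_neg.txt").write_text("\n".join(neg) + ("\n" if neg else ""))
    (outdir / "population.txt").write_text("\n".join(X.columns) + "\n")
    summary = {
        "selected_component": sel + 1,
        "var_y": model.var_y.tolist(),
        "var_x": model.var_x.tolist(),
        "var_y_selected": float(model.var_y[sel]),
        "p_permutation": p_perm,
        "n_selected_genes": {"positive": len(pos), "negative": len(neg)},
    }
    (outdir / "pls_summary.json").write_text(json.dumps(summary, indent=2))
    return summary


def stage_enrich(cfg: PipelineConfig, outdir: Path) -> dict:
    outdir = Path(outdir)
    _require(outdir, "gene_sets.gmt", "enrich")
    _require(outdir, "genes_pos.txt", "enrich")
    sets = enrich.read_gmt(outdir / "gene_sets.gmt")
    population = [g for g in (outdir / "population.txt").read_text().splitlines() if g]
    selected = [
        g for f in ("genes_pos.txt", "genes_neg.txt")
        for g in (outdir / f).read_text().splitlines() if g
    ]
    if selected:
        res = enrich.hypergeom_ora(
            selected, population, sets,
            min_term=cfg.min_term, max_term_fraction=cfg.max_term_fraction,
        )
    else:
        res = pd.DataFrame(columns=["term", "description", "N", "K", "n", "k", "p", "q", "overlap"])
    res.to_csv(outdir / "enrichment.tsv", sep="\t", index=False)
    sig = res[res["q"] < cfg.fdr_alpha] if "q" in res and len(res) else res
    summary = {"n_terms_tested": len(res), "n_significant": int(len(sig)),
               "n_selected_genes": len(selected)}
    (outdir / "enrich_summary.json").write_text(json.dumps(summary, indent=2))
    return summary


def _require(outdir: Path, fname: str, stage: str) -> None:
    if not (Path(outdir) / fname).exists():
        raise FileNotFoundError(
            f"stage {stage!r}: missing upstream output {fname} in {outdir}"
        )


_STAGE_FN = {
    "simulate": stage_simulate,
    "fc": stage_fc,
    "harmonize": stage_harmonize,
    "groupdiff": stage_groupdiff,
    "net-t": stage_net_t,
    "expression": stage_expression,
    "pls": stage_pls,
    "enrich": stage_enrich,
}


def run_all(cfg: PipelineConfig, outdir: Path, skip: tuple[str, ...] = ()) -> dict:
    """Run every stage in order; returns (and writes) the run manifest."""
    report = validate_config(cfg)
    if not report["ok"]:
        raise ValueError("invalid config: " + "; ".join(report["errors"]))
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg.to_yaml(outdir / "config.yaml")
    stage_results = {}
    for stage in _STAGES:
        if stage in skip:
            continue
        stage_results[stage] = _STAGE_FN[stage](cfg, outdir)
    manifest = {
        "config_digest": cfg.digest(),
        "seeds": cfg.seeds,
        "stages": stage_results,
        "artifacts": sorted(p.name for p in outdir.iterdir()),
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
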