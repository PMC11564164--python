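"""End-to-end orchestration: config, synthetic demo inputs, and run_all.

The pipeline runs expression processing -> group contrasts -> sphere
extraction -> PLS + bootstrap Z -> cross-contrast intersection -> per-gene
Spearman statistics -> enrichment, from a single declarative config, with
one seed controlling every random stage and a provenance manifest
(parameters, input/output hashes) written next to the results. Every
stage is also callable on its own with file handoffs (see cli).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import contrast as ct
from . import enrichment as en
from . import expression as ex
from . import genestats as gs
from . import mapping as mp
from . import pls as pl
from . import synthetic as syn
from .types import VolumetricMap

log = logging.getLogger("imgx.pipeline")


@dataclass
class ContrastSpec:
    name: str
    group_a: str
    group_b: str


@dataclass
class PipelineConfig:
    cohort_dir: str = "inputs/cohort"
    donor_dir: str = "inputs/donors"
    rnaseq_path: str = "inputs/donors/rnaseq_reference.tsv"
    risk_genes_path: str | None = None    # None -> packaged default list
    gmt_path: str = "inputs/gene_sets.gmt"
    out_dir: str = "results"
    contrasts: list[ContrastSpec] = field(default_factory=lambda: [
        ContrastSpec("EMCI-NC", "EMCI", "NC"),
        ContrastSpec("LMCI-NC", "LMCI", "NC"),
        ContrastSpec("AD-NC", "AD", "NC"),
    ])
    covariates: list[str] = field(default_factory=lambda: ["gender"])
    radius_mm: float = 4.5
    voxel_p: float = 0.001
    cluster_p: float = 0.05
    n_boot: int = 1000
    z_thr: float = 5.0
    alpha: float = 0.05
    n_tests: int | None = None
    min_overlap: int = 3
    kappa_thr: float = 0.3
    min_present_fraction: float = 0.5
    connectivity: int = 26
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        contrasts = [ContrastSpec(**c) for c in raw.pop("contrasts", [])]
        cfg = cls(**raw)
        if contrasts:
            cfg.contrasts = contrasts
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))


# ---------------------------------------------------------------------------
# synthetic demo inputs
# ---------------------------------------------------------------------------

def demo_cohort_spec(seed: int = 0, n_per_group: int = 83,
                     grid_shape: tuple[int, int, int] = (40, 48, 40),
                     d: float = 1.5) -> syn.CohortSpec:
    """Cohort with one atrophy and one hypertrophy cluster, both in the
    left hemisphere so they drive the left-restricted tissue samples."""
    patients = {"EMCI": -d, "LMCI": -d, "AD": -d}
    hyper = {"EMCI": d, "LMCI": d, "AD": d}

    def at(fx: float, fy: float, fz: float) -> tuple[int, int, int]:
        return tuple(int(round(f * (s - 1)))
                     for f, s in zip((fx, fy, fz), grid_shape))

    return syn.CohortSpec(
        grid_shape=grid_shape, n_per_group=n_per_group, seed=seed,
        effect_clusters=[
            # atrophy in the left hemisphere (negative world x)
            syn.EffectCluster(center_vox=at(0.30, 0.50, 0.50),
                              radius_mm=6.0, d=patients),
            # hypertrophy, also left, posterior
            syn.EffectCluster(center_vox=at(0.35, 0.71, 0.45),
                              radius_mm=6.0, d=hyper),
        ])


def simulate_inputs(root: str | Path, seed: int = 0,
                    cohort_spec: syn.CohortSpec | None = None,
                    expr_spec: syn.ExpressionSpec | None = None) -> None:
    """Write a complete synthetic input tree under ``root``.

    Produces the cohort NIfTIs + subject table, the donor microarray file
    set + RNA-seq reference, the risk-gene list, and a GMT with one
    planted term per signed consistent-gene set.
    """
    root = Path(root)
    cohort_spec = cohort_spec or demo_cohort_spec(seed)
    cohort = syn.make_cohort(cohort_spec)
    syn.write_cohort(cohort, root / "cohort")

    expr_spec = expr_spec or syn.ExpressionSpec(seed=seed + 1)
    synth = syn.make_expression(expr_spec, cohort.effect_field("AD"))
    syn.write_expression(synth, root / "donors")

    risk = expr_spec.risk_genes or syn.load_default_risk_genes()
    (root / "risk_genes.txt").write_text("\n".join(risk) + "\n")

    universe = expr_spec.gene_universe()
    planted = expr_spec.planted_genes or syn.default_planted_genes()
    pos = [p.gene for p in planted if p.rho > 0]
    neg = [p.gene for p in planted if p.rho < 0]
    sets = syn.make_gene_sets(universe, pos, n_terms=12, seed=seed + 2,
                              prefix="POS")
    sets.update(syn.make_gene_sets(universe, neg, n_terms=12, seed=seed + 3,
                                   prefix="NEG"))
    en.write_gmt(sets, root / "gene_sets.gmt")


def run_synthetic(seed: int = 0, n_per_group: int = 83,
                  grid_shape: tuple[int, int, int] = (40, 48, 40),
                  d: float = 1.5, n_samples_left: int = 1285,
                  n_boot: int = 500, z_thr: float = 5.0,
                  radius_mm: float = 4.5, voxel_p: float = 0.001,
                  cluster_p: float = 0.05, alpha: float = 0.05,
                  min_overlap: int = 3, kappa_thr: float = 0.3) -> dict:
    """Full in-memory end-to-end run on freshly generated synthetic data.

    Generates a cohort with one planted atrophy and one planted
    hypertrophy cluster (standardized effect ``d`` in the three patient
    groups), a donor expression set with the default planted gene-atrophy
    correlations, runs every pipeline stage, and returns the stage
    outputs alongside the planted ground truth. This is the
    parameter-recovery harness: with the defaults, the signed
    consistent-gene intersection should equal the planted gene sets and
    the planted GMT terms should top the enrichment tables.
    """
    cohort_spec = demo_cohort_spec(seed, n_per_group=n_per_group,
                                   grid_shape=grid_shape, d=d)
    cohort = syn.make_cohort(cohort_spec)
    expr_spec = syn.ExpressionSpec(n_samples_left=n_samples_left,
                                   seed=seed + 1)
    synth = syn.make_expression(expr_spec, cohort.effect_field("AD"))
    expr = ex.build_expression_matrix(synth.donors, synth.rnaseq)
    interesting = ex.intersect_risk_genes(syn.load_default_risk_genes(),
                                          expr.genes)

    gender = {g: (cohort.subjects.loc[cohort.subjects["group"] == g,
                                      "gender"] == "M"
                  ).astype(float).to_numpy() for g in cohort_spec.groups}
    results = {}
    for name, ga in (("EMCI-NC", "EMCI"), ("LMCI-NC", "LMCI"),
                     ("AD-NC", "AD")):
        cov = np.concatenate([gender[ga], gender["NC"]])[:, None]
        res = ct.voxelwise_glm_t(cohort.maps(ga), cohort.maps("NC"), cov,
                                 name=name)
        results[name] = ct.grf_cluster_correct(res, voxel_p, cluster_p)

    profiles = {}
    common = expr.values.index
    for name, res in results.items():
        prof = mp.sphere_mean_t(res.t_map, expr.samples, radius_mm)
        profiles[name] = prof.t
        common = common.intersection(prof.table.index)
    X = expr.values.loc[common, interesting]
    pls_results = {}
    for i, name in enumerate(results):
        pls_results[name] = pl.bootstrap_gene_z(
            X, profiles[name].loc[common].to_numpy(), n_boot, z_thr,
            seed=seed + 1000 * (i + 1))
    consistent_pos = pl.intersect_gene_lists(
        [pls_results[n].positive for n in results])
    consistent_neg = pl.intersect_gene_lists(
        [pls_results[n].negative for n in results])
    consistent = consistent_pos + consistent_neg

    gene_table = gs.gene_association_table(
        expr.values.loc[common], {n: profiles[n].loc[common] for n in results},
        consistent, alpha) if consistent else None

    planted = expr_spec.planted_genes or syn.default_planted_genes()
    planted_pos = [p.gene for p in planted if p.rho > 0]
    planted_neg = [p.gene for p in planted if p.rho < 0]
    universe = expr_spec.gene_universe()
    sets = syn.make_gene_sets(universe, planted_pos, n_terms=12,
                              seed=seed + 2, prefix="POS")
    sets.update(syn.make_gene_sets(universe, planted_neg, n_terms=12,
                                   seed=seed + 3, prefix="NEG"))
    enrich_tables = {}
    for label, query in (("positive", consistent_pos),
                         ("negative", consistent_neg)):
        if query:
            enrich_tables[label] = en.enrich(query, sets, expr.genes, alpha,
                                             min_overlap, kappa_thr)

    return {"cohort": cohort, "cohort_spec": cohort_spec,
            "expression": expr, "interesting": interesting,
            "contrasts": results, "profiles": profiles, "pls": pls_results,
            "consistent_positive": consistent_pos,
            "consistent_negative": consistent_neg,
            "gene_stats": gene_table, "enrichment": enrich_tables,
            "planted_positive": planted_pos, "planted_negative": planted_neg,
            "synth_expression": synth}


# ---------------------------------------------------------------------------
# run-all
# ---------------------------------------------------------------------------

def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _load_group(cohort_dir: Path, subjects: pd.DataFrame, group: str,
                mask: np.ndarray | None) -> tuple[list[VolumetricMap], pd.DataFrame]:
    sub = subjects[subjects["group"] == group]
    if len(sub) == 0:
        raise ValueError(f"no subjects in group {group!r}")
    vols = [VolumetricMap.from_nifti(cohort_dir / p, mask)
            for p in sub["path"]]
    return vols, sub


def run_all(config: PipelineConfig) -> dict:
    """Execute every stage in order and write results + manifest.

    Returns a dict with the key result objects; any stage failure raises
    with a stage-tagged message.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"parameters": dataclasses.asdict(config),
                      "stages": {}, "inputs": {}, "outputs": {}}

    def stage(name):
        log.info("stage %s", name)
        manifest["stages"][name] = "ok"

    try:
        stage("expression")
        donors = ex.load_donor_folders(config.donor_dir)
        rnaseq = pd.read_csv(config.rnaseq_path, sep="\t", index_col=0)
        rnaseq.columns = [int(float(c)) if str(c).replace(".", "").isdigit()
                          else c for c in rnaseq.columns]
        expr = ex.build_expression_matrix(donors, rnaseq,
                                          config.min_present_fraction)
        expr.write(out / "expression")
        if config.risk_genes_path:
            risk = [ln.strip() for ln in
                    Path(config.risk_genes_path).read_text().splitlines()
                    if ln.strip() and not ln.startswith("#")]
        else:
            risk = syn.load_default_risk_genes()
        interesting = ex.intersect_risk_genes(risk, expr.genes)
        (out / "interesting_genes.txt").write_text(
            "\n".join(interesting) + "\n")
        log.info("expression: %d samples x %d genes, %d interesting",
                 *expr.values.shape, len(interesting))
    except Exception as err:
        raise RuntimeError(f"[expression] {err}") from err

    try:
        stage("contrasts")
        cohort_dir = Path(config.cohort_dir)
        subjects = pd.read_csv(cohort_dir / "subjects.tsv", sep="\t")
        mask_path = cohort_dir / "brain_mask.nii"
        brain_mask = None
        if mask_path.exists():
            brain_mask = np.asarray(
                VolumetricMap.from_nifti(mask_path).values > 0.5)
        (out / "contrasts").mkdir(exist_ok=True)
        results: dict[str, object] = {}
        for cs in config.contrasts:
            va, sa = _load_group(cohort_dir, subjects, cs.group_a, brain_mask)
            vb, sb = _load_group(cohort_dir, subjects, cs.group_b, brain_mask)
            cov = None
            if config.covariates:
                frames = pd.concat([sa, sb])
                cols = []
                for c in config.covariates:
                    v = frames[c]
                    cols.append((v == "M").astype(float).to_numpy()
                                if c == "gender" else
                                pd.to_numeric(v).to_numpy())
                cov = np.column_stack(cols)
            res = ct.voxelwise_glm_t(va, vb, cov, name=cs.name)
            res = ct.grf_cluster_correct(res, config.voxel_p,
                                         config.cluster_p,
                                         connectivity=config.connectivity)
            res.t_map.save(out / "contrasts" / f"{cs.name}_tmap.nii")
            for sgn in ("neg", "pos"):
                VolumetricMap(res.corrected_mask(sgn).astype(float),
                              res.t_map.affine).save(
                    out / "contrasts" / f"{cs.name}_mask_{sgn}.nii")
            res.cluster_table.to_csv(
                out / "contrasts" / f"{cs.name}_clusters.tsv",
                sep="\t", index=False)
            results[cs.name] = res
            log.info("contrast %s: df=%d, %d retained clusters", cs.name,
                     res.df, int(res.cluster_table["retained"].sum()))
        for sgn in ("neg", "pos"):
            ov = ct.overlap_maps([results[cs.name].corrected_mask(sgn)
                                  for cs in config.contrasts])
            VolumetricMap(ov.astype(float),
                          results[config.contrasts[0].name].t_map.affine
                          ).save(out / f"overlap_{sgn}.nii")
    except Exception as err:
        raise RuntimeError(f"[contrasts] {err}") from err

    try:
        stage("extract")
        profiles: dict[str, pd.Series] = {}
        common = expr.values.index
        for cs in config.contrasts:
            prof = mp.sphere_mean_t(results[cs.name].t_map, expr.samples,
                                    config.radius_mm)
            profiles[cs.name] = prof.t
            common = common.intersection(prof.table.index)
        expr_common = expr.values.loc[common]
        (out / "profiles").mkdir(exist_ok=True)
        for cs in config.contrasts:
            profiles[cs.name] = profiles[cs.name].loc[common]
            profiles[cs.name].rename("t_mean").to_csv(
                out / "profiles" / f"{cs.name}_regional_t.tsv", sep="\t")
        log.info("extract: %d samples retained across contrasts", len(common))
    except Exception as err:
        raise RuntimeError(f"[extract] {err}") from err

    try:
        stage("pls")
        (out / "pls").mkdir(exist_ok=True)
        X = expr_common[interesting]
        pls_results: dict[str, pl.PLSResult] = {}
        for i, cs in enumerate(config.contrasts):
            y = profiles[cs.name].to_numpy()
            res = pl.bootstrap_gene_z(X, y, config.n_boot, config.z_thr,
                                      seed=config.seed + 1000 * (i + 1))
            pls_results[cs.name] = res
            res.gene_table().to_csv(out / "pls" / f"{cs.name}_genes.tsv",
                                    sep="\t")
            pd.Series(res.scores, index=common, name="pls1_score").to_csv(
                out / "pls" / f"{cs.name}_scores.tsv", sep="\t")
            log.info("pls %s: score~T spearman r=%.3f, %d pos / %d neg genes",
                     cs.name, res.spearman_r, len(res.positive),
                     len(res.negative))
        consistent_pos = pl.intersect_gene_lists(
            [pls_results[cs.name].positive for cs in config.contrasts])
        consistent_neg = pl.intersect_gene_lists(
            [pls_results[cs.name].negative for cs in config.contrasts])
        (out / "consistent_positive.txt").write_text(
            "\n".join(consistent_pos) + "\n")
        (out / "consistent_negative.txt").write_text(
            "\n".join(consistent_neg) + "\n")
        log.info("consistent genes: %d positive, %d negative",
                 len(consistent_pos), len(consistent_neg))
    except Exception as err:
        raise RuntimeError(f"[pls] {err}") from err

    consistent = consistent_pos + consistent_neg
    gene_table = None
    try:
        stage("genestats")
        if consistent:
            gene_table = gs.gene_association_table(
                expr_common, profiles, consistent, config.alpha,
                config.n_tests)
            gene_table.to_csv(out / "gene_stats.tsv", sep="\t")
    except Exception as err:
        raise RuntimeError(f"[genestats] {err}") from err

    enrich_tables = {}
    try:
        stage("enrichment")
        sets = en.read_gmt(config.gmt_path)
        for label, query in (("positive", consistent_pos),
                             ("negative", consistent_neg)):
            if not query:
                continue
            table = en.enrich(query, sets, expr.genes, config.alpha,
                              config.min_overlap, config.kappa_thr)
            table.to_csv(out / f"enrichment_{label}.tsv", sep="\t",
                         index=False)
            enrich_tables[label] = table
    except Exception as err:
        raise RuntimeError(f"[enrichment] {err}") from err

    for key, p in (("subjects", Path(config.cohort_dir) / "subjects.tsv"),
                   ("rnaseq", Path(config.rnaseq_path)),
                   ("gmt", Path(config.gmt_path))):
        if p.exists():
            manifest["inputs"][key] = _sha256(p)
    for p in sorted(out.rglob("*.tsv")) + sorted(out.rglob("*.txt")):
        manifest["outputs"][str(p.relative_to(out))] = _sha256(p)
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n")

    return {"expression": expr, "interesting": interesting,
            "contrasts": results, "profiles": profiles,
            "pls": pls_results, "consistent_positive": consistent_pos,
            "consistent_negative": consistent_neg,
            "gene_stats": gene_table, "enrichment": enrich_tables}
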