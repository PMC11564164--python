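"""Synthetic inputs with the statistical structure the analysis assumes.

This module fabricates every input the pipeline consumes, so the whole
chain can be exercised and calibrated without any imaging or microarray
download:

* a multi-group cohort of modulated/smoothed gray-matter-volume (GMV)
  volumes with planted cluster atrophy of known effect size,
* a six-donor microarray-dialect expression file set (expression, sample
  annotation, probe table, present/absent calls, RNA-seq reference) with
  planted spatial gene-atrophy correlations and multi-probe structure,
* a risk-gene list partially covered by the expression background,
* gene-set (GMT) annotations with planted enriched terms.

The noise model is deliberately simple: independent Gaussian voxel noise
smoothed to a target FWHM (periodic boundaries, so the field is stationary
by construction), then planted effects added in units of the noise SD.
That matches the covariance structure assumed by smoothed-VBM random-field
inference, which is exactly what makes the generator usable as a
calibration oracle for the cluster correction.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .expression import DonorExpressionSet
from .types import VolumetricMap

FWHM_TO_SIGMA = 1.0 / np.sqrt(8.0 * np.log(2.0))

#: Default group labels, ordered by disease stage.
DEFAULT_GROUPS = ("NC", "EMCI", "LMCI", "AD")


def load_default_risk_genes() -> list[str]:
    """The packaged 52-symbol AD risk-gene list (see data/ for provenance)."""
    text = (importlib.resources.files("imgx.data") / "risk_genes_default.txt"
            ).read_text()
    return [ln.strip().upper() for ln in text.splitlines()
            if ln.strip() and not ln.startswith("#")]


# ---------------------------------------------------------------------------
# cohort specification
# ---------------------------------------------------------------------------

@dataclass
class EffectCluster:
    """A planted spherical group effect.

    ``d`` maps group label -> standardized effect size (units of the
    voxelwise noise SD); groups absent from the mapping get 0. The sphere
    indicator is convolved with the cohort smoothing kernel and rescaled to
    unit peak, so the *peak* voxel shift is exactly ``d`` noise-SDs.
    """

    center_vox: tuple[int, int, int]
    radius_mm: float
    d: dict[str, float]


@dataclass
class GenderSpec:
    """Gender covariate: P(female) and an additive global GMV offset for
    males, in units of the voxelwise noise SD."""

    p_female: float = 45.0 / 83.0
    male_offset: float = 0.05


@dataclass
class CohortSpec:
    grid_shape: tuple[int, int, int] = (40, 48, 40)
    voxel_size_mm: float = 1.5
    n_per_group: int = 83
    groups: tuple[str, ...] = DEFAULT_GROUPS
    effect_clusters: list[EffectCluster] = field(default_factory=list)
    smoothing_fwhm_mm: float = 8.0
    covariate_spec: GenderSpec = field(default_factory=GenderSpec)
    baseline: float = 0.5
    noise_sd: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.voxel_size_mm <= 0:
            raise ValueError("voxel_size_mm must be > 0")
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2")
        for c in self.effect_clusters:
            if c.radius_mm < self.voxel_size_mm:
                raise ValueError("effect radius must be >= voxel size")
            unknown = set(c.d) - set(self.groups)
            if unknown:
                raise ValueError(f"effect cluster names unknown groups {unknown}")


@dataclass
class Cohort:
    """In-memory synthetic cohort: per-group 4-D stacks plus ground truth."""

    spec: CohortSpec
    affine: np.ndarray
    mask: np.ndarray
    volumes: dict[str, np.ndarray]          # group -> (n, nx, ny, nz)
    subjects: pd.DataFrame                  # subject_id, group, gender
    templates: list[np.ndarray]             # unit-peak effect templates

    def maps(self, group: str) -> list[VolumetricMap]:
        return [VolumetricMap(v, self.affine, self.mask)
                for v in self.volumes[group]]

    def effect_field(self, group: str) -> VolumetricMap:
        """True (noise-free) standardized effect field for one group."""
        out = np.zeros(self.spec.grid_shape)
        for cl, tmpl in zip(self.spec.effect_clusters, self.templates):
            out += cl.d.get(group, 0.0) * tmpl
        return VolumetricMap(out, self.affine, self.mask)


def _centered_ras_affine(shape, voxel_size) -> np.ndarray:
    aff = np.diag([voxel_size] * 3 + [1.0])
    aff[:3, 3] = -voxel_size * (np.asarray(shape) - 1) / 2.0
    return aff


def _ellipsoid_mask(shape, fraction: float = 0.92) -> np.ndarray:
    """Brain-ish mask: ellipsoid with semi-axes = fraction * half-extent."""
    grids = np.meshgrid(*[np.arange(n) for n in shape], indexing="ij")
    r2 = np.zeros(shape)
    for g, n in zip(grids, shape):
        half = (n - 1) / 2.0
        r2 += ((g - half) / (fraction * half)) ** 2
    return r2 <= 1.0


def _smooth_unit_noise(rng: np.random.Generator, shape,
                       sigma_vox: float) -> np.ndarray:
    """Gaussian-smoothed white noise rescaled to unit voxelwise SD.

    Periodic ('wrap') smoothing keeps the field stationary everywhere,
    including at the grid edge, so random-field theory holds by
    construction for in-mask voxels.
    """
    noise = rng.standard_normal(shape)
    sm = ndimage.gaussian_filter(noise, sigma=sigma_vox, mode="wrap")
    return sm / sm.std()


def cluster_template(spec: CohortSpec, cluster: EffectCluster) -> np.ndarray:
    """Unit-peak smoothed spherical template for one planted cluster."""
    shape = spec.grid_shape
    center = np.asarray(cluster.center_vox, dtype=float)
    r_vox = cluster.radius_mm / spec.voxel_size_mm
    lo = np.floor(center - r_vox).astype(int)
    hi = np.ceil(center + r_vox).astype(int)
    if np.any(lo < 0) or np.any(hi >= np.asarray(shape)):
        raise ValueError(
            f"effect cluster at {cluster.center_vox} (radius {cluster.radius_mm} mm) "
            f"extends outside grid of shape {shape}")
    grids = np.meshgrid(*[np.arange(n) for n in shape], indexing="ij")
    dist2 = sum((g - c) ** 2 for g, c in zip(grids, center))
    sphere = (dist2 <= r_vox ** 2).astype(float)
    sigma = spec.smoothing_fwhm_mm * FWHM_TO_SIGMA / spec.voxel_size_mm
    tmpl = ndimage.gaussian_filter(sphere, sigma=sigma, mode="constant")
    peak = tmpl.max()
    if peak <= 0:
        raise ValueError("degenerate effect template")
    return tmpl / peak


def make_cohort(spec: CohortSpec) -> Cohort:
    """Generate per-subject smoothed GMV volumes plus a subject table.

    Planted clusters shift the in-cluster group mean by ``d`` times the
    (unit) smoothed-noise SD; gender adds a small global offset so
    covariate adjustment is exercised downstream. The seed fully
    determines the output.
    """
    rng = np.random.default_rng(spec.seed)
    affine = _centered_ras_affine(spec.grid_shape, spec.voxel_size_mm)
    mask = _ellipsoid_mask(spec.grid_shape)
    sigma = spec.smoothing_fwhm_mm * FWHM_TO_SIGMA / spec.voxel_size_mm
    templates = [cluster_template(spec, c) for c in spec.effect_clusters]

    volumes: dict[str, np.ndarray] = {}
    rows = []
    for group in spec.groups:
        effect = np.zeros(spec.grid_shape)
        for cl, tmpl in zip(spec.effect_clusters, templates):
            effect += cl.d.get(group, 0.0) * tmpl
        stack = np.empty((spec.n_per_group, *spec.grid_shape))
        for i in range(spec.n_per_group):
            gender = "F" if rng.random() < spec.covariate_spec.p_female else "M"
            off = 0.0 if gender == "F" else spec.covariate_spec.male_offset
            f = _smooth_unit_noise(rng, spec.grid_shape, sigma)
            vol = spec.baseline + spec.noise_sd * (f + effect + off)
            stack[i] = np.where(mask, vol, 0.0)
            rows.append({"subject_id": f"{group}_{i:03d}",
                         "group": group, "gender": gender})
        volumes[group] = stack

    subjects = pd.DataFrame(rows)
    return Cohort(spec, affine, mask, volumes, subjects, templates)


def write_cohort(cohort: Cohort, outdir: str | Path) -> pd.DataFrame:
    """Write one NIfTI per subject plus ``subjects.tsv`` and the truth mask."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for group in cohort.spec.groups:
        for i, vol in enumerate(cohort.volumes[group]):
            p = outdir / f"{group}_{i:03d}.nii"
            VolumetricMap(vol, cohort.affine, cohort.mask).save(p)
            paths.append(str(p.name))
    table = cohort.subjects.copy()
    table["path"] = paths
    table.to_csv(outdir / "subjects.tsv", sep="\t", index=False)
    VolumetricMap(cohort.mask.astype(float), cohort.affine).save(
        outdir / "brain_mask.nii")
    return table


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

@dataclass
class PlantedGene:
    """A gene whose true spatial profile is constructed to have a target
    Spearman correlation (Gaussian-copula construction) with the atrophy
    field sampled at the tissue coordinates."""

    gene: str
    rho: float

    def __post_init__(self) -> None:
        if not -1.0 < self.rho < 1.0:
            raise ValueError("planted correlation must lie in (-1, 1)")


def default_planted_genes() -> list[PlantedGene]:
    """Eight positively and four negatively associated risk genes."""
    risk = load_default_risk_genes()
    return ([PlantedGene(g, +0.4) for g in risk[:8]]
            + [PlantedGene(g, -0.4) for g in risk[8:12]])


@dataclass
class ExpressionSpec:
    n_donors: int = 6
    n_samples_left: int = 1285      # target retained count after left filter
    n_genes: int = 100
    probes_per_gene: int = 3
    planted_genes: list[PlantedGene] | None = None
    pa_dropout: float = 0.3         # mean absent fraction for degraded probes
    rnaseq_coverage: float = 0.9    # fraction of filler genes with RNA-seq
    n_rnaseq_wells: int = 120
    risk_genes: list[str] | None = None
    n_risk_in_universe: int = 41
    seed: int = 0

    def __post_init__(self) -> None:
        if self.probes_per_gene < 1:
            raise ValueError("probes_per_gene must be >= 1")
        if not 0.0 <= self.pa_dropout < 1.0:
            raise ValueError("pa_dropout must be in [0, 1)")

    def gene_universe(self) -> list[str]:
        risk = self.risk_genes if self.risk_genes is not None \
            else load_default_risk_genes()
        n_risk = min(self.n_risk_in_universe, len(risk), self.n_genes)
        fillers = [f"GENE{i:04d}" for i in range(self.n_genes - n_risk)]
        return list(risk[:n_risk]) + fillers


@dataclass
class SyntheticExpression:
    """Donor file set plus the ground truth used to plant it."""

    donors: list[DonorExpressionSet]
    rnaseq: pd.DataFrame                # genes x RNA-seq well columns
    samples: pd.DataFrame               # all samples: well_id -> coords, donor
    atrophy_at_samples: pd.Series       # true field value per well_id
    true_profiles: pd.DataFrame         # samples x genes latent profiles
    spec: ExpressionSpec


def _sample_coords_in_mask(rng: np.random.Generator, vmap: VolumetricMap,
                           n: int) -> np.ndarray:
    """Uniform world-mm coordinates within the mask, by rejection."""
    mask = vmap.effective_mask()
    lo = vmap.voxel_to_world(np.zeros(3)) - vmap.voxel_sizes / 2
    hi = vmap.voxel_to_world(np.asarray(vmap.shape) - 1.0) + vmap.voxel_sizes / 2
    out = np.empty((n, 3))
    got = 0
    while got < n:
        cand = rng.uniform(lo, hi, size=(4 * (n - got) + 64, 3))
        idx = np.rint(vmap.world_to_voxel(cand)).astype(int)
        ok = np.all((idx >= 0) & (idx < np.asarray(vmap.shape)), axis=1)
        ok[ok] &= mask[tuple(idx[ok].T)]
        take = cand[ok][: n - got]
        out[got: got + len(take)] = take
        got += len(take)
    return out


def _normal_scores(x: np.ndarray) -> np.ndarray:
    """Rank-based normal scores (zero vector if x is constant)."""
    ranks = stats.rankdata(x, method="average")
    return stats.norm.ppf(ranks / (len(x) + 1))


def make_expression(spec: ExpressionSpec,
                    atrophy_field: VolumetricMap) -> SyntheticExpression:
    """Generate a microarray-dialect donor file set with planted signal.

    Tissue-sample coordinates are drawn uniformly within the brain mask of
    ``atrophy_field`` (both hemispheres, so downstream left-filtering is
    exercised). For each planted gene, the latent spatial profile is
    ``rho * z + sqrt(1-rho^2) * noise`` where ``z`` are normal scores of
    the atrophy values at the sample coordinates; the Spearman correlation
    between profile and field is then close to ``rho`` by the Gaussian
    copula argument. Each gene gets one high-fidelity probe (unit slope,
    low noise, low absent rate) and ``probes_per_gene - 1`` degraded
    probes (attenuated slope, heteroscedastic noise, Beta-distributed
    absent rates with mean ``pa_dropout``), so probe filtering/selection
    is exercised.
    """
    if not np.all(np.isfinite(atrophy_field.values)):
        raise ValueError("atrophy_field must be finite")
    rng = np.random.default_rng(spec.seed)
    genes = spec.gene_universe()
    planted = spec.planted_genes if spec.planted_genes is not None \
        else default_planted_genes()
    planted = [p for p in planted]
    missing = [p.gene for p in planted if p.gene not in genes]
    if missing:
        raise ValueError(f"planted genes not in gene universe: {missing}")

    n_total = 2 * spec.n_samples_left   # ~half the mask is left-hemisphere
    coords = _sample_coords_in_mask(rng, atrophy_field, n_total)
    vox = np.rint(atrophy_field.world_to_voxel(coords)).astype(int)
    a_vals = atrophy_field.values[tuple(vox.T)]
    z = _normal_scores(a_vals)

    well_ids = np.arange(n_total) + 100001
    donor_of = np.sort(np.arange(n_total) % spec.n_donors)
    samples = pd.DataFrame({
        "well_id": well_ids,
        "donor_id": [f"D{d + 1:02d}" for d in donor_of],
        "mni_x": coords[:, 0], "mni_y": coords[:, 1], "mni_z": coords[:, 2],
    }).set_index("well_id")
    a_series = pd.Series(a_vals, index=samples.index, name="atrophy")

    rho = {p.gene: p.rho for p in planted}
    profiles = np.empty((n_total, len(genes)))
    for j, g in enumerate(genes):
        r = rho.get(g, 0.0)
        profiles[:, j] = r * z + np.sqrt(1 - r ** 2) * rng.standard_normal(n_total)
    true_profiles = pd.DataFrame(profiles, index=samples.index, columns=genes)

    # probe design
    probe_rows = []
    probe_gene, slopes, noise_sd, drop_p = [], [], [], []
    pid = 1000
    mu = spec.pa_dropout
    beta_b = 2.0 * (1.0 - mu) / max(mu, 1e-6)
    for g in genes:
        base = rng.normal(7.5, 0.8)
        for k in range(spec.probes_per_gene):
            pid += 1
            probe_rows.append({"probe_id": pid, "gene_symbol": g,
                               "probe_name": f"P_{g}_{k}"})
            probe_gene.append((g, base))
            if k == 0:      # high-fidelity probe
                slopes.append(1.0)
                noise_sd.append(0.15)
                drop_p.append(rng.uniform(0.02, 0.30))
            else:
                slopes.append(rng.uniform(0.2, 0.6))
                noise_sd.append(rng.uniform(0.8, 1.5))
                drop_p.append(np.clip(rng.beta(2.0, beta_b), 0.0, 0.95))
    probe_table = pd.DataFrame(probe_rows).set_index("probe_id")

    gene_col = {g: j for j, g in enumerate(genes)}
    n_probes = len(probe_table)
    intensity = np.empty((n_probes, n_total))
    for i, ((g, base), sl, sd) in enumerate(zip(probe_gene, slopes, noise_sd)):
        t = profiles[:, gene_col[g]]
        # mild heteroscedasticity: noisier where the latent signal is high
        het = sd * (0.75 + 0.5 / (1.0 + np.exp(-t)))
        intensity[i] = base + sl * t + het * rng.standard_normal(n_total)

    # per-donor affine batch shifts
    offsets = rng.normal(0.0, 0.5, size=spec.n_donors)
    scales = rng.uniform(0.85, 1.15, size=spec.n_donors)

    donors: list[DonorExpressionSet] = []
    for d in range(spec.n_donors):
        cols = donor_of == d
        donor_wells = samples.index[cols]
        expr = pd.DataFrame(offsets[d] + scales[d] * intensity[:, cols],
                            index=probe_table.index, columns=donor_wells)
        pa = pd.DataFrame(0, index=expr.index, columns=expr.columns, dtype=int)
        for i, p in enumerate(drop_p):
            thr = np.quantile(expr.iloc[i].to_numpy(), p)
            pa.iloc[i] = (expr.iloc[i].to_numpy() > thr).astype(int)
        donors.append(DonorExpressionSet(
            donor_id=f"D{d + 1:02d}",
            probes=probe_table[["gene_symbol"]].copy(),
            expression=expr, pacall=pa,
            samples=samples.loc[donor_wells, ["mni_x", "mni_y", "mni_z"]].copy(),
        ))

    # RNA-seq reference over a subset of wells from the first two donors
    ref_wells = samples.index[np.isin(donor_of, [0, 1])]
    ref_wells = ref_wells[:spec.n_rnaseq_wells]
    covered = [g for g in genes
               if g in rho or not g.startswith("GENE")
               or rng.random() < spec.rnaseq_coverage]
    ridx = [gene_col[g] for g in covered]
    rvals = (profiles[np.isin(donor_of, [0, 1]), :][:len(ref_wells)][:, ridx].T
             + 0.3 * rng.standard_normal((len(covered), len(ref_wells))))
    rnaseq = pd.DataFrame(rvals, index=pd.Index(covered, name="gene_symbol"),
                          columns=ref_wells)

    return SyntheticExpression(donors, rnaseq, samples, a_series,
                               true_profiles, spec)


def write_expression(synth: SyntheticExpression, outdir: str | Path) -> None:
    """Write per-donor CSV file sets plus the RNA-seq reference TSV."""
    outdir = Path(outdir)
    for donor in synth.donors:
        donor.write(outdir / f"donor_{donor.donor_id}")
    rnaseq = synth.rnaseq.copy()
    rnaseq.columns = [str(c) for c in rnaseq.columns]
    rnaseq.to_csv(outdir / "rnaseq_reference.tsv", sep="\t")


# ---------------------------------------------------------------------------
# gene sets
# ---------------------------------------------------------------------------

def make_gene_sets(genes: list[str], planted_term_genes: list[str],
                   n_terms: int = 20, seed: int = 0,
                   term_size_range: tuple[int, int] = (5, 15),
                   planted_extra: int = 2,
                   prefix: str = "TERM") -> dict[str, tuple[str, list[str]]]:
    """Build GMT-style gene sets with one planted enriched term.

    Returns ``{term_id: (description, member_genes)}``. The planted term
    (``<prefix>_PLANTED``) contains ``planted_term_genes`` plus up to
    ``planted_extra`` random background genes; the remaining ``n_terms - 1``
    terms are uniform random draws from ``genes``.
    """
    if n_terms < 1:
        raise ValueError("n_terms must be >= 1")
    missing = set(planted_term_genes) - set(genes)
    if missing:
        raise ValueError(f"planted term genes not in background: {sorted(missing)}")
    rng = np.random.default_rng(seed)
    sets: dict[str, tuple[str, list[str]]] = {}
    pool = [g for g in genes if g not in set(planted_term_genes)]
    extra = list(rng.choice(pool, size=min(planted_extra, len(pool)),
                            replace=False)) if pool else []
    sets[f"{prefix}_PLANTED"] = ("planted enriched term",
                                 list(planted_term_genes) + extra)
    lo, hi = term_size_range
    for i in range(1, n_terms):
        size = int(rng.integers(lo, hi + 1))
        size = min(size, len(genes))
        members = list(rng.choice(genes, size=size, replace=False))
        sets[f"{prefix}_{i:03d}"] = (f"random term {i}", members)
    return sets
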