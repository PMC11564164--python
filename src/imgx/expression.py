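"""Microarray expression processing: raw donor files -> normalized matrix.

Implements the standard multi-donor microarray reduction used in
imaging-transcriptomics work:

1. drop probes whose signal is above background (present/absent call = 1)
   in fewer than 50% of all pooled sample sites;
2. collapse multiple probes per gene by keeping, for each gene present in
   an RNA-seq reference, the probe most highly (Spearman) correlated with
   the RNA-seq profile over shared samples; genes without an RNA-seq
   entry are dropped;
3. keep left-hemisphere samples only (MNI x strictly < 0; the midline
   x = 0 is excluded);
4. normalize within each donor with a scaled robust sigmoid (SRS),
   ``s = 1 / (1 + exp(-(x - median) / (IQR / 1.35)))``, then min-max
   rescale each gene to [0, 1] within the donor, and concatenate donors
   sample-wise.

The result is a samples x genes matrix in the unit interval with MNI
coordinates and donor IDs attached; all downstream joins are by sample
(well) ID, never by position.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import special, stats

log = logging.getLogger(__name__)


@dataclass
class DonorExpressionSet:
    """Raw per-donor microarray files, as read from a donor folder."""

    donor_id: str
    probes: pd.DataFrame       # index probe_id, column gene_symbol
    expression: pd.DataFrame   # probes x samples (log2-scale intensities)
    pacall: pd.DataFrame       # binary, same shape as expression
    samples: pd.DataFrame      # index well_id, columns mni_x, mni_y, mni_z

    def __post_init__(self) -> None:
        if self.expression.shape != self.pacall.shape:
            raise ValueError("expression and PA matrices must share shape")
        if not self.expression.index.isin(self.probes.index).all():
            raise ValueError("expression contains probes missing from probe table")
        if not self.expression.columns.equals(self.pacall.columns):
            raise ValueError("expression and PA column (sample) IDs differ")

    def write(self, outdir: str | Path) -> None:
        """Write the four-file donor folder (CSV dialect, probe ID first)."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        # expression/PA files carry no header row; first column is probe ID
        self.expression.to_csv(outdir / "MicroarrayExpression.csv", header=False)
        self.pacall.to_csv(outdir / "PACall.csv", header=False)
        self.probes.reset_index().to_csv(outdir / "Probes.csv", index=False)
        ann = self.samples.reset_index()
        ann.to_csv(outdir / "SampleAnnot.csv", index=False)

    @classmethod
    def read(cls, folder: str | Path) -> "DonorExpressionSet":
        folder = Path(folder)
        probes = pd.read_csv(folder / "Probes.csv").set_index("probe_id")
        expr = pd.read_csv(folder / "MicroarrayExpression.csv", header=None,
                           index_col=0)
        pa = pd.read_csv(folder / "PACall.csv", header=None, index_col=0)
        ann = pd.read_csv(folder / "SampleAnnot.csv").set_index("well_id")
        wells = ann.index.to_numpy()
        expr.index.name = "probe_id"
        pa.index.name = "probe_id"
        expr.columns = wells
        pa.columns = wells
        return cls(folder.name.replace("donor_", ""), probes, expr, pa, ann)


@dataclass
class ExpressionMatrix:
    """Normalized samples x genes matrix with sample metadata.

    ``values`` is indexed by well ID with unique gene-symbol columns, all
    entries in [0, 1]; ``samples`` carries mni_x/y/z and donor_id per well.
    """

    values: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        v = self.values.to_numpy()
        if np.isnan(v).any():
            raise ValueError("expression matrix contains missing values")
        if v.size and (v.min() < -1e-9 or v.max() > 1 + 1e-9):
            raise ValueError("expression values must lie in [0, 1]")
        if self.values.columns.duplicated().any():
            raise ValueError("gene symbols must be unique")
        if not self.values.index.equals(self.samples.index):
            raise ValueError("values and samples must share the well-ID index")

    @property
    def genes(self) -> list[str]:
        return list(self.values.columns)

    def write(self, outdir: str | Path, stem: str = "expression") -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.values.to_csv(outdir / f"{stem}_matrix.tsv", sep="\t")
        self.samples.to_csv(outdir / f"{stem}_samples.tsv", sep="\t")

    @classmethod
    def read(cls, outdir: str | Path, stem: str = "expression") -> "ExpressionMatrix":
        outdir = Path(outdir)
        values = pd.read_csv(outdir / f"{stem}_matrix.tsv", sep="\t", index_col=0)
        samples = pd.read_csv(outdir / f"{stem}_samples.tsv", sep="\t", index_col=0)
        return cls(values, samples)


# ---------------------------------------------------------------------------
# individual steps
# ---------------------------------------------------------------------------

def filter_probes_by_background(pa: pd.DataFrame | list[pd.DataFrame],
                                min_fraction: float = 0.5) -> pd.Index:
    """Probes whose present fraction across all pooled samples >= threshold.

    ``pa`` is one binary probes x samples frame, or a list of them (one
    per donor) that is pooled column-wise before computing the fraction.
    """
    if isinstance(pa, (list, tuple)):
        pa = pd.concat(pa, axis=1)
    if pa.size == 0:
        raise ValueError("empty PA matrix")
    vals = pa.to_numpy()
    if not np.isin(vals, (0, 1)).all():
        raise ValueError("PA matrix must be binary")
    frac = vals.mean(axis=1)
    return pa.index[frac >= min_fraction]


def select_probes_by_rnaseq(expression: pd.DataFrame, probe_table: pd.DataFrame,
                            rnaseq: pd.DataFrame) -> pd.Series:
    """One probe per gene: the probe best Spearman-correlated with RNA-seq.

    ``expression`` is a pooled probes x samples frame restricted to
    background-filtered probes; ``rnaseq`` is genes x reference samples,
    whose columns must overlap the expression columns. Genes absent from
    the RNA-seq reference are dropped. Returns gene_symbol -> probe_id.
    """
    shared = expression.columns.intersection(rnaseq.columns)
    if len(shared) < 3:
        raise ValueError("need >= 3 shared samples between microarray and RNA-seq")
    choice: dict[str, int] = {}
    gene_of = probe_table.loc[expression.index, "gene_symbol"]
    for gene, probe_ids in gene_of.groupby(gene_of).groups.items():
        if gene not in rnaseq.index:
            continue
        ref = rnaseq.loc[gene, shared].to_numpy(dtype=float)
        best, best_r = None, -np.inf
        for pid in probe_ids:
            r = stats.spearmanr(expression.loc[pid, shared].to_numpy(), ref)[0]
            if np.isnan(r):
                continue
            if r > best_r:
                best, best_r = pid, r
        if best is not None:
            choice[str(gene)] = best
    if not choice:
        warnings.warn("no probes survive RNA-seq-based selection for any gene")
    return pd.Series(choice, name="probe_id").sort_index()


def filter_left_hemisphere(samples: pd.DataFrame) -> pd.Index:
    """Well IDs of left-hemisphere samples (mni_x strictly < 0).

    Samples with a missing x coordinate are rejected with a warning; the
    midline (x = 0) is excluded, since its hemisphere is ambiguous.
    """
    x = pd.to_numeric(samples["mni_x"], errors="coerce")
    bad = x.isna()
    if bad.any():
        warnings.warn(f"dropping {int(bad.sum())} samples with missing mni_x")
    return samples.index[(~bad) & (x < 0)]


def robust_sigmoid(x: np.ndarray) -> np.ndarray:
    """Median/IQR sigmoid: ``1 / (1 + exp(-(x - median) / (IQR / 1.35)))``.

    The median element maps to exactly 0.5; the transform is invariant to
    affine shifts a + b*x (b > 0) of the input. A zero IQR falls back to
    rank-based scores (logged) so degenerate genes still get an order-
    preserving embedding.
    """
    x = np.asarray(x, dtype=float)
    if np.ptp(x) == 0:
        return np.full_like(x, 0.5)
    med = np.median(x)
    iqr = np.subtract(*np.percentile(x, [75, 25]))
    if iqr <= 0:
        log.info("zero IQR; falling back to rank-based scores")
        r = stats.rankdata(x, method="average")
        return (r - 0.5) / len(x)
    return special.expit((x - med) / (iqr / 1.35))


def scaled_robust_sigmoid(x: np.ndarray) -> np.ndarray:
    """SRS normalization of one gene's values within one donor.

    :func:`robust_sigmoid` followed by min-max rescaling to [0, 1]; both
    steps are monotone, so within-donor ranks are preserved.
    """
    s = robust_sigmoid(x)
    lo, hi = s.min(), s.max()
    if hi == lo:
        return np.full_like(s, 0.5)
    return (s - lo) / (hi - lo)


def normalize_expression(donor_matrices: dict[str, pd.DataFrame],
                         donor_samples: dict[str, pd.DataFrame] | None = None
                         ) -> ExpressionMatrix:
    """SRS-normalize each donor's samples x genes block and concatenate.

    ``donor_matrices`` maps donor_id -> samples x genes frame (common gene
    set); ``donor_samples`` optionally maps donor_id -> per-well metadata
    to carry through. Normalization is entirely within-donor, which is
    what removes per-donor location/scale batch shifts.
    """
    genes = None
    blocks, meta = [], []
    for donor_id, mat in donor_matrices.items():
        if genes is None:
            genes = list(mat.columns)
        elif list(mat.columns) != genes:
            raise ValueError("donors must share an identical gene set")
        norm = np.column_stack([scaled_robust_sigmoid(mat[g].to_numpy())
                                for g in genes]) if len(genes) else \
            np.empty((len(mat), 0))
        blocks.append(pd.DataFrame(norm, index=mat.index, columns=genes))
        sm = donor_samples[donor_id].loc[mat.index].copy() if donor_samples \
            else pd.DataFrame(index=mat.index)
        sm["donor_id"] = donor_id
        meta.append(sm)
    values = pd.concat(blocks, axis=0)
    samples = pd.concat(meta, axis=0)
    return ExpressionMatrix(values, samples)


def intersect_risk_genes(risk_list: list[str],
                         background: list[str]) -> list[str]:
    """Risk symbols present in the background, ordered as in the risk list.

    Symbols are upper-cased and whitespace-trimmed on both sides; an
    empty intersection aborts, since no downstream stage can run.
    """
    bg = {str(g).strip().upper() for g in background}
    seen: set[str] = set()
    out = []
    for g in risk_list:
        g = str(g).strip().upper()
        if g in bg and g not in seen:
            out.append(g)
            seen.add(g)
    if not out:
        raise ValueError("risk-gene list and background are disjoint")
    return out


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

def build_expression_matrix(donors: list[DonorExpressionSet],
                            rnaseq: pd.DataFrame,
                            min_present_fraction: float = 0.5
                            ) -> ExpressionMatrix:
    """Full reduction: background filter -> probe selection -> left filter
    -> within-donor SRS normalization -> pooled samples x genes matrix."""
    kept = filter_probes_by_background([d.pacall for d in donors],
                                       min_present_fraction)
    log.info("background filter kept %d/%d probes", len(kept),
             len(donors[0].expression))
    pooled = pd.concat([d.expression.loc[kept] for d in donors], axis=1)
    probe_of_gene = select_probes_by_rnaseq(
        pooled, donors[0].probes, rnaseq)
    genes = list(probe_of_gene.index)
    log.info("probe selection kept %d genes", len(genes))

    donor_matrices: dict[str, pd.DataFrame] = {}
    donor_samples: dict[str, pd.DataFrame] = {}
    for d in donors:
        left = filter_left_hemisphere(d.samples)
        if len(left) == 0:
            warnings.warn(f"donor {d.donor_id} has no left-hemisphere samples")
            continue
        block = d.expression.loc[probe_of_gene.to_numpy(), left].T
        block.columns = genes
        donor_matrices[d.donor_id] = block
        donor_samples[d.donor_id] = d.samples.loc[left]
    log.info("left-hemisphere filter kept %d samples",
             sum(len(v) for v in donor_matrices.values()))
    return normalize_expression(donor_matrices, donor_samples)


def load_donor_folders(root: str | Path) -> list[DonorExpressionSet]:
    """Read every ``donor_*`` folder under ``root``, sorted by name."""
    root = Path(root)
    folders = sorted(p for p in root.iterdir()
                     if p.is_dir() and p.name.startswith("donor_"))
    if not folders:
        raise FileNotFoundError(f"no donor_* folders under {root}")
    return [DonorExpressionSet.read(p) for p in folders]
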