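"""First-component PLS association with bootstrap Z gene ranking.

For a single response, the first partial-least-squares component has a
closed form: after per-gene standardization of X and centering of y, the
weight vector maximizing cov(Xw, y) is w = X'y / ||X'y||, and the PLS1
score of a sample is the corresponding linear combination of its gene
expression values. Weights are sign-oriented so the scores correlate
non-negatively with y (PLS components are sign-indeterminate).

Gene ranking follows the bootstrap convention of the PLS
imaging-transcriptomics literature: resample samples with replacement,
refit, re-orient each replicate's weights against the full-data solution,
take the per-gene standard deviation of replicate weights as the standard
error, and define Z = full-data weight / SE. Genes with Z beyond a fixed
threshold (default |Z| > 5) form the positively / negatively associated
lists; consistency across contrasts is their intersection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class PLSResult:
    """First-component PLS fit, optionally with bootstrap gene statistics."""

    genes: list[str]
    weights: np.ndarray          # unit-norm, aligned with genes
    scores: np.ndarray           # one per sample
    spearman_r: float
    spearman_p: float
    dropped_genes: list[str] = field(default_factory=list)
    se: np.ndarray | None = None
    z: np.ndarray | None = None
    positive: list[str] = field(default_factory=list)
    negative: list[str] = field(default_factory=list)
    n_boot: int | None = None
    z_threshold: float | None = None

    def gene_table(self) -> pd.DataFrame:
        out = pd.DataFrame({"weight": self.weights}, index=self.genes)
        out.index.name = "gene"
        if self.se is not None:
            out["se"] = self.se
            out["z"] = self.z
            out["list"] = ["positive" if g in set(self.positive)
                           else "negative" if g in set(self.negative)
                           else "" for g in self.genes]
        return out


def _prepare(X: pd.DataFrame | np.ndarray,
             y: np.ndarray) -> tuple[np.ndarray, np.ndarray, list[str], list[str]]:
    if isinstance(X, pd.DataFrame):
        genes = [str(g) for g in X.columns]
        Xv = X.to_numpy(dtype=float)
    else:
        Xv = np.asarray(X, dtype=float)
        genes = [f"g{i}" for i in range(Xv.shape[1])]
    y = np.asarray(y, dtype=float).ravel()
    if Xv.shape[0] != len(y):
        raise ValueError("X rows and y length differ")
    if Xv.shape[0] < 3:
        raise ValueError("need >= 3 samples")
    if np.ptp(y) == 0:
        raise ValueError("constant response")
    sd = Xv.std(axis=0)
    dropped = [g for g, s in zip(genes, sd) if s == 0]
    if dropped:
        warnings.warn(f"dropping constant gene columns: {dropped}")
        keep = sd > 0
        Xv = Xv[:, keep]
        genes = [g for g, k in zip(genes, keep) if k]
    return Xv, y, genes, dropped


def _pls1_weights(Xs: np.ndarray, yc: np.ndarray) -> np.ndarray:
    w = Xs.T @ yc
    norm = np.linalg.norm(w)
    if norm == 0:
        return np.zeros_like(w)
    return w / norm


def fit_pls1(X: pd.DataFrame | np.ndarray, y: np.ndarray) -> PLSResult:
    """Fit the first PLS component of standardized X against centered y.

    Returns unit-norm gene weights and per-sample scores, oriented so the
    Pearson correlation of scores with y is >= 0, plus the Spearman
    correlation between scores and y.
    """
    Xv, y, genes, dropped = _prepare(X, y)
    Xs = (Xv - Xv.mean(axis=0)) / Xv.std(axis=0)
    yc = y - y.mean()
    w = _pls1_weights(Xs, yc)
    scores = Xs @ w
    if np.ptp(scores) > 0 and np.corrcoef(scores, y)[0, 1] < 0:
        w = -w
        scores = -scores
    r, p = stats.spearmanr(scores, y)
    return PLSResult(genes=genes, weights=w, scores=scores,
                     spearman_r=float(r), spearman_p=float(p),
                     dropped_genes=dropped)


def bootstrap_gene_z(X: pd.DataFrame | np.ndarray, y: np.ndarray,
                     n_boot: int = 1000, z_thr: float = 5.0,
                     seed: int | None = None) -> PLSResult:
    """Bootstrap Z scores for PLS1 gene weights and signed gene lists.

    Samples (rows) are resampled with replacement ``n_boot`` times; each
    replicate's weight vector is sign-aligned to the full-data solution
    by the sign of their dot product before the per-gene SD is taken as
    the bootstrap SE. Genes whose SE is zero have undefined Z and are
    excluded from the lists with a warning. The positive list is ordered
    by descending Z, the negative list by ascending Z.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    full = fit_pls1(X, y)
    Xv, yv, genes, _ = _prepare(X, y)
    rng = np.random.default_rng(seed)
    n = len(yv)
    W = np.empty((n_boot, len(genes)))
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        Xb = Xv[idx]
        yb = yv[idx]
        sd = Xb.std(axis=0)
        sd[sd == 0] = 1.0
        Xbs = (Xb - Xb.mean(axis=0)) / sd
        wb = _pls1_weights(Xbs, yb - yb.mean())
        if wb @ full.weights < 0:
            wb = -wb
        W[b] = wb
    se = W.std(axis=0, ddof=1)
    z = np.full(len(genes), np.nan)
    ok = se > 0
    if not ok.all():
        warnings.warn(f"{int((~ok).sum())} genes have zero bootstrap SE; "
                      "excluded from lists")
    z[ok] = full.weights[ok] / se[ok]
    order = np.argsort(z)
    positive = [genes[i] for i in order[::-1]
                if np.isfinite(z[i]) and z[i] > z_thr]
    negative = [genes[i] for i in order
                if np.isfinite(z[i]) and z[i] < -z_thr]
    full.se = se
    full.z = z
    full.positive = positive
    full.negative = negative
    full.n_boot = n_boot
    full.z_threshold = z_thr
    return full


def intersect_gene_lists(lists: list[list[str]]) -> list[str]:
    """Genes common to every list, ordered as in the first list."""
    if len(lists) < 2:
        raise ValueError("need >= 2 lists to intersect")
    common = set(lists[0])
    for lst in lists[1:]:
        common &= set(lst)
    return [g for g in lists[0] if g in common]


def pls_score_correlation(scores: np.ndarray, y: np.ndarray
                          ) -> tuple[float, float]:
    """Spearman correlation (average ranks, two-sided p) of scores vs y."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(scores) != len(y) or len(y) < 3:
        raise ValueError("inputs must be aligned with length >= 3")
    if np.ptp(scores) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input")
    r, p = stats.spearmanr(scores, y)
    return float(r), float(p)
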