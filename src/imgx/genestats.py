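"""Per-gene Spearman statistics with Bonferroni correction.

For each consistent gene and each contrast, the expression column is
rank-correlated (average ranks) against the regional T profile across
tissue samples. Significance is controlled with a Bonferroni threshold
alpha / n_tests, where n_tests defaults to the number of consistent
genes, and the comparison is strict (p < threshold).
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
from scipy import stats

#: sample sizes up to which the exact permutation p-value is enumerated
EXACT_PERMUTATION_MAX_N = 8


def spearman_gene_t(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Spearman r (average ranks) and two-sided p for one gene vs T.

    For n <= 8 the p-value is exact, from full enumeration of rank
    permutations; for larger n the usual t approximation is used.
    Constant input raises, since the correlation is undefined.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("inputs must be aligned with length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant column; correlation undefined")
    r = float(stats.spearmanr(x, y)[0])
    n = len(x)
    if n <= EXACT_PERMUTATION_MAX_N:
        rx = stats.rankdata(x)
        ry = stats.rankdata(y)
        perms = np.array(list(itertools.permutations(range(n))))
        null = np.array([np.corrcoef(rx, ry[p])[0, 1] for p in perms])
        p = float((np.abs(null) >= abs(r) - 1e-12).mean())
    else:
        p = float(stats.spearmanr(x, y)[1])
    return r, min(max(p, np.finfo(float).tiny), 1.0)


def bonferroni_threshold(alpha: float, n_tests: int) -> float:
    """Per-test threshold alpha / n_tests (flags use strict less-than)."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return alpha / n_tests


def gene_association_table(expr: pd.DataFrame,
                           profiles: dict[str, pd.Series],
                           genes: list[str] | None = None,
                           alpha: float = 0.05,
                           n_tests: int | None = None) -> pd.DataFrame:
    """Gene x contrast Spearman table with Bonferroni significance flags.

    ``expr`` is the normalized samples x genes matrix; ``profiles`` maps
    contrast name -> regional T Series indexed by sample ID (joined by
    ID, not position). Returns one row per gene with ``r_<contrast>``,
    ``p_<contrast>`` and ``sig_<contrast>`` columns; the threshold is
    ``alpha / n_tests`` with ``n_tests`` defaulting to the number of
    genes tested.
    """
    genes = list(expr.columns) if genes is None else list(genes)
    missing = [g for g in genes if g not in expr.columns]
    if missing:
        raise KeyError(f"genes absent from expression matrix: {missing}")
    n_tests = len(genes) if n_tests is None else n_tests
    thr = bonferroni_threshold(alpha, n_tests)
    rows = []
    for g in genes:
        row: dict[str, float | bool | str] = {"gene": g}
        for cname, t in profiles.items():
            joined = pd.concat([expr[g], t], axis=1, join="inner")
            r, p = spearman_gene_t(joined.iloc[:, 0].to_numpy(),
                                   joined.iloc[:, 1].to_numpy())
            row[f"r_{cname}"] = r
            row[f"p_{cname}"] = p
            row[f"sig_{cname}"] = p < thr
        rows.append(row)
    out = pd.DataFrame(rows).set_index("gene")
    out.attrs["alpha"] = alpha
    out.attrs["n_tests"] = n_tests
    out.attrs["threshold"] = thr
    return out
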