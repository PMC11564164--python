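"""Over-representation analysis: hypergeometric terms + kappa clustering.

A local implementation of the usual gene-set over-representation
statistics: for each annotation term the upper-tail (cumulative)
hypergeometric p of the query/term overlap within a background universe,
an enrichment factor (k/n)/(K/N), a significance-and-minimum-overlap
filter, and grouping of surviving terms by Cohen's-kappa similarity of
their gene memberships with average-linkage hierarchical clustering cut
at a kappa threshold (default 0.3).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy


# ---------------------------------------------------------------------------
# GMT I/O
# ---------------------------------------------------------------------------

def read_gmt(path: str | Path) -> dict[str, tuple[str, list[str]]]:
    """Parse a GMT file: term<TAB>description<TAB>gene1<TAB>gene2..."""
    sets: dict[str, tuple[str, list[str]]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line: {line[:80]!r}")
        sets[parts[0]] = (parts[1], [g for g in parts[2:] if g])
    return sets


def write_gmt(sets: dict[str, tuple[str, list[str]]], path: str | Path) -> None:
    lines = ["\t".join([term, desc, *genes]) for term, (desc, genes)
             in sets.items()]
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# statistics
# ---------------------------------------------------------------------------

def hypergeom_upper_p(k: int, K: int, n: int, N: int) -> float:
    """P(overlap >= k) drawing n query genes from N with K term genes."""
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def hypergeom_enrich(query: list[str],
                     gene_sets: dict[str, tuple[str, list[str]]],
                     background: list[str], alpha: float = 0.05,
                     min_overlap: int = 3) -> pd.DataFrame:
    """Term-wise over-representation of ``query`` within ``background``.

    Terms are intersected with the background before testing; survivors
    need overlap >= ``min_overlap`` and p < ``alpha`` and are returned
    sorted ascending by p (ties broken by term ID). The ``overlap_genes``
    column keeps memberships for downstream kappa clustering.
    """
    bg = sorted({str(g).strip().upper() for g in background})
    bg_set = set(bg)
    q = [str(g).strip().upper() for g in query]
    q_set = {g for g in q if g in bg_set}
    if not q_set:
        raise ValueError("empty query after background intersection")
    N, n = len(bg), len(q_set)
    rows = []
    for term, (desc, members) in gene_sets.items():
        mem = {str(g).strip().upper() for g in members} & bg_set
        K = len(mem)
        if K == 0:
            continue
        overlap = sorted(mem & q_set)
        k = len(overlap)
        p = hypergeom_upper_p(k, K, n, N)
        factor = (k / n) / (K / N)
        rows.append({"term": term, "description": desc, "k": k, "K": K,
                     "n": n, "N": N, "p": p, "enrichment_factor": factor,
                     "overlap_genes": ";".join(overlap),
                     "member_genes": ";".join(sorted(mem))})
    table = pd.DataFrame(rows, columns=["term", "description", "k", "K", "n",
                                        "N", "p", "enrichment_factor",
                                        "overlap_genes", "member_genes"])
    keep = table[(table["k"] >= min_overlap) & (table["p"] < alpha)]
    return keep.sort_values(["p", "term"], kind="mergesort"
                            ).reset_index(drop=True)


def cohen_kappa_membership(a: set[str], b: set[str], background: set[str]
                           ) -> float:
    """Cohen's kappa between two term memberships over the background.

    Absent-absent pairs count as agreement; kappa <= 0 means no better
    than chance.
    """
    N = len(background)
    both = len(a & b)
    neither = N - len(a | b)
    po = (both + neither) / N
    pa_, pb = len(a) / N, len(b) / N
    pe = pa_ * pb + (1 - pa_) * (1 - pb)
    if pe == 1.0:
        return 1.0
    return (po - pe) / (1 - pe)


def kappa_cluster(enrich_table: pd.DataFrame, background: list[str],
                  kappa_thr: float = 0.3) -> pd.DataFrame:
    """Group surviving terms by kappa similarity of gene membership.

    Average-linkage hierarchical clustering on distance 1 - kappa; the
    tree is cut so that terms merged at similarity >= ``kappa_thr`` share
    a cluster. Each cluster is labeled by its representative term: lowest
    p, ties broken by lexicographic term ID. Adds ``cluster`` (integer)
    and ``cluster_label`` columns.
    """
    if len(enrich_table) == 0:
        raise ValueError("no surviving terms to cluster")
    bg = {str(g).strip().upper() for g in background}
    table = enrich_table.copy()
    members = [set(m.split(";")) if m else set()
               for m in table["member_genes"]]
    m = len(table)
    if m == 1:
        table["cluster"] = 1
        table["cluster_label"] = table["term"].iloc[0]
        return table
    dist = np.zeros(m * (m - 1) // 2)
    pos = 0
    for i in range(m):
        for j in range(i + 1, m):
            kap = cohen_kappa_membership(members[i], members[j], bg)
            dist[pos] = 1.0 - kap
            pos += 1
    link = hierarchy.linkage(dist, method="average")
    labels = hierarchy.fcluster(link, t=1.0 - kappa_thr, criterion="distance")
    table["cluster"] = labels
    reps = {}
    for cl in np.unique(labels):
        sub = table[table["cluster"] == cl].sort_values(
            ["p", "term"], kind="mergesort")
        reps[cl] = sub["term"].iloc[0]
    table["cluster_label"] = [reps[cl] for cl in labels]
    return table


def enrich(query: list[str], gene_sets: dict[str, tuple[str, list[str]]],
           background: list[str], alpha: float = 0.05, min_overlap: int = 3,
           kappa_thr: float = 0.3) -> pd.DataFrame:
    """Hypergeometric filtering followed by kappa clustering (may be empty)."""
    table = hypergeom_enrich(query, gene_sets, background, alpha, min_overlap)
    if len(table) == 0:
        table["cluster"] = pd.Series(dtype=int)
        table["cluster_label"] = pd.Series(dtype=str)
        return table
    return kappa_cluster(table, background, kappa_thr)
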