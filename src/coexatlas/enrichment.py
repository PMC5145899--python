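"""Hypergeometric term enrichment of gene clusters with BH FDR control.

Over-representation only: for a cluster of n genes drawn from a background
of N genes of which K carry a term, the p-value is the upper hypergeometric
tail P(X >= k).  Benjamini–Hochberg correction is applied across every
(cluster, term) test of one invocation; clusters below a minimum size are
skipped entirely.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests


def normalize_annotation(annotation: Mapping) -> dict[str, set]:
    """Canonicalize an annotation to term → gene-set form.

    Accepts term → iterable-of-genes, or gene → iterable-of-terms (detected
    when values are strings or short term lists is ambiguous, so the caller
    should prefer term → genes; gene → terms is recognized by the
    ``gene_to_terms`` helper instead).
    """
    return {str(t): set(gs) for t, gs in annotation.items()}


def invert_gene_to_terms(gene_terms: Mapping[str, Iterable[str]]) -> dict[str, set]:
    """Convert a gene → terms map into term → genes form."""
    out: dict[str, set] = {}
    for gene, terms in gene_terms.items():
        for t in terms:
            out.setdefault(str(t), set()).add(gene)
    return out


def read_gmt(path: str | Path) -> dict[str, set]:
    """Read a GMT file (term, description, genes...) into term → genes."""
    out: dict[str, set] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            out[parts[0]] = set(g for g in parts[2:] if g)
    return out


def write_gmt(annotation: Mapping[str, set], path: str | Path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for term in sorted(annotation):
            genes = "\t".join(sorted(annotation[term]))
            fh.write(f"{term}\t{description}\t{genes}\n")


def hypergeom_enrichment(
    clusters,
    annotation: Mapping[str, set],
    background: set,
    alpha_fdr: float = 0.05,
    min_cluster_size: int = 5,
) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment per (cluster, term) pair.

    ``clusters`` is a ClusterSet or an iterable of gene sets.  Terms are
    restricted to the background; pairs with zero overlap are not tested.
    Returns a DataFrame with counts, p, BH q, and a significance flag at
    q < ``alpha_fdr``.
    """
    background = set(background)
    if not background:
        raise ValueError("empty enrichment background")
    cluster_list = list(getattr(clusters, "clusters", clusters))
    terms = {t: set(gs) & background for t, gs in annotation.items()}
    terms = {t: gs for t, gs in terms.items() if gs}
    N = len(background)
    rows = []
    for ci, cluster in enumerate(cluster_list, start=1):
        cl = set(cluster) & background
        n = len(cl)
        if n < min_cluster_size:
            continue
        for term, gs in terms.items():
            k = len(cl & gs)
            if k == 0:
                continue
            K = len(gs)
            p = float(hypergeom.sf(k - 1, N, K, n))
            rows.append((ci, term, k, n, K, N, p))
    result = pd.DataFrame(
        rows, columns=["cluster", "term", "k", "n", "K", "N", "p"]
    )
    if len(result):
        _, q, _, _ = multipletests(result["p"], alpha=alpha_fdr, method="fdr_bh")
        result["q"] = q
        result["significant"] = q < alpha_fdr
    else:
        result["q"] = pd.Series(dtype=float)
        result["significant"] = pd.Series(dtype=bool)
    return result.sort_values(["cluster", "q", "term"], ignore_index=True) if len(result) else result
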