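"""Hypergeometric over-representation of validated miRNA target genes.

Given the union of validated target genes of the DE panel (the query) and a
collection of pathway gene sets, each set is tested with the hypergeometric
upper tail P(X >= k) for k = |query ∩ set|, K = |set|, n = |query| drawn
from an N-gene background.  Both Bonferroni and BH corrections are reported.
The background size N is an explicit parameter (default 20,000
protein-coding genes); enrichment p-values are sensitive to it.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .containers import GeneSetCollection, ValidationError
from .diffexpr import bh_adjust

logger = logging.getLogger("circmir")


def collect_target_genes(
    de_mirnas: list[str], targets: pd.DataFrame
) -> tuple[set[str], pd.Series]:
    """Union of validated target genes over the DE panel.

    Returns (gene set, per-miRNA target counts).  A panel miRNA absent from
    the target table yields a warning, not an error.
    """
    counts = {}
    union: set[str] = set()
    for mir in de_mirnas:
        genes = set(targets.loc[targets["mirna"] == mir, "gene"])
        if not genes:
            logger.warning("DE miRNA %s has no validated targets in the table", mir)
        counts[mir] = len(genes)
        union |= genes
    per_mirna = pd.Series(counts, name="n_targets", dtype=int)
    logger.info("target union over %d miRNAs: %d genes", len(de_mirnas), len(union))
    return union, per_mirna


def hypergeom_upper_tail(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) with X ~ Hypergeometric(N population, K successes, n draws)."""
    if not (0 <= k <= min(K, n)) or K > N or n > N:
        raise ValidationError(f"inconsistent hypergeometric arguments k={k}, K={K}, n={n}, N={N}")
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def enrich_gene_sets(
    query: set[str],
    collection: GeneSetCollection,
    background_size: int | None = None,
    restrict_to_universe: bool = True,
) -> pd.DataFrame:
    """One hypergeometric upper-tail test per gene set; sorted by raw p.

    Query genes outside a declared universe are counted, logged and excluded
    from n when ``restrict_to_universe`` (default).  Columns: set, k, K, n,
    N, p, p_bonferroni, q_bh, overlap_genes.
    """
    N = background_size if background_size is not None else collection.background_size
    query = {g.strip().upper() for g in query}
    if collection.universe is not None and restrict_to_universe:
        outside = query - collection.universe
        if outside:
            logger.info("%d query genes outside the universe excluded from n", len(outside))
        query = query & collection.universe
    n = len(query)
    if N < n:
        raise ValidationError(f"background N={N} smaller than query size n={n}")
    rows = []
    for name, members in collection:
        if len(members) > N:
            raise ValidationError(f"set {name!r} larger than background N={N}")
        overlap = sorted(query & members)
        k = len(overlap)
        p = hypergeom_upper_tail(k, len(members), n, N)
        rows.append((name, k, len(members), n, N, p, ",".join(overlap)))
    res = pd.DataFrame(
        rows, columns=["set", "k", "K", "n", "N", "p", "overlap_genes"]
    )
    m = len(res)
    res["p_bonferroni"] = np.minimum(1.0, res["p"] * m)
    res["q_bh"] = bh_adjust(res["p"].to_numpy())
    res = res[["set", "k", "K", "n", "N", "p", "p_bonferroni", "q_bh", "overlap_genes"]]
    return res.sort_values("p", kind="stable").reset_index(drop=True)
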