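"""Right-sided hypergeometric gene-set enrichment.

Given a query gene set, a universe (the strains present in at least one
collection, for roster work) and a term -> genes annotation table, each term
of acceptable size is tested with the right-tail hypergeometric p-value
P(X >= k), corrected across terms by Bonferroni step-down (Holm). No
ontology propagation is performed; parent-term up-propagation, if wanted,
must happen upstream of the annotation table.
"""

from __future__ import annotations

import warnings

import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from ._types import EnrichmentResult, InputError


def load_annotations(path) -> pd.DataFrame:
    """Read a term_id / term_name / gene_id TSV (one row per pair)."""
    df = pd.read_csv(path, sep="\t")
    for col in ("term_id", "term_name", "gene_id"):
        if col not in df.columns:
            raise InputError(f"annotation table is missing column {col!r}")
    return df


def hypergeometric_enrichment(
    query: set[str],
    universe: set[str],
    annotations: pd.DataFrame,
    min_size: int = 5,
    max_size: int = 300,
    p_cut: float = 0.0005,
) -> list[EnrichmentResult]:
    """Test every annotation term against a query gene set.

    Terms are restricted to the universe and filtered to sizes within
    [min_size, max_size]; query genes outside the universe are dropped with
    a warning. Results carry the raw right-tail p, the Holm-adjusted p, a
    ``passed`` flag (adjusted p <= p_cut) and are sorted by adjusted p.
    """
    if not query:
        raise InputError("query gene set is empty")
    if not universe:
        raise InputError("universe gene set is empty")
    stray = query - universe
    if stray:
        warnings.warn(
            f"{len(stray)} query gene(s) outside the universe were dropped"
        )
        query = query & universe
        if not query:
            raise InputError("no query gene remains inside the universe")

    N = len(universe)
    n = len(query)
    tested = []
    for (term_id, term_name), grp in annotations.groupby(
        ["term_id", "term_name"], sort=True
    ):
        genes = set(grp["gene_id"]) & universe
        K = len(genes)
        if not min_size <= K <= max_size:
            continue
        k = len(genes & query)
        p = float(hypergeom.sf(k - 1, N, K, n))
        tested.append((term_id, term_name, k, K, p))
    if not tested:
        return []
    p_adj = multipletests([t[4] for t in tested], method="holm")[1]
    results = [
        EnrichmentResult(
            term_id=tid,
            term_name=tname,
            k=k,
            K=K,
            n=n,
            N=N,
            p_raw=p,
            p_adj=float(pa),
            passed=bool(pa <= p_cut),
        )
        for (tid, tname, k, K, p), pa in zip(tested, p_adj)
    ]
    results.sort(key=lambda r: (r.p_adj, r.p_raw, r.term_id))
    return results


def results_frame(results: list[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "term_id": r.term_id,
                "term_name": r.term_name,
                "k": r.k,
                "K": r.K,
                "n": r.n,
                "N": r.N,
                "p_raw": r.p_raw,
                "p_adj": r.p_adj,
                "passed": int(r.passed),
            }
            for r in results
        ]
    )
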