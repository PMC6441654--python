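"""GO term over-representation in a DEG set.

One-sided hypergeometric upper tail against an annotated background (genes
with ≥ 1 GO assignment), Benjamini–Hochberg corrected across all tested
terms within one DEG set.  No ontology-DAG ancestor propagation is applied
by default; a parent map can be supplied to propagate annotations upward
before testing.
"""

from __future__ import annotations

import pandas as pd
from scipy import stats

from .errors import DegflowError
from .types import DEGSet, GOMap
from .de import bh_fdr

ENRICHMENT_COLUMNS = ["go_id", "term_name", "k", "K", "n", "N", "p_value", "corrected_p"]


def hypergeom_upper(k: int, K: int, n: int, N: int) -> float:
    """P(X ≥ k) for X ~ Hypergeometric(N population, K marked, n drawn)."""
    if not (0 <= K <= N and 0 <= n <= N and 0 <= k <= min(K, n)):
        raise DegflowError("bad-contingency", f"inconsistent counts k={k} K={K} n={n} N={N}")
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def propagate(go: GOMap, parent_map: dict[str, list[str]]) -> GOMap:
    """Extend annotations to ancestor terms via a child → parents map."""
    pairs = set(go.pairs)
    frontier = list(pairs)
    while frontier:
        gene, term = frontier.pop()
        for parent in parent_map.get(term, []):
            if (gene, parent) not in pairs:
                pairs.add((gene, parent))
                frontier.append((gene, parent))
    return GOMap(pairs=pairs, term_names=dict(go.term_names))


def enrich(
    deg: DEGSet,
    go: GOMap,
    background: list[str],
    correction: str = "BH",
    parent_map: dict[str, list[str]] | None = None,
) -> pd.DataFrame:
    """Over-representation of every GO term among the DEG set's genes.

    The background is restricted to genes with ≥ 1 GO annotation (the
    annotatable pool); one row per term present in that background, sorted
    by corrected p (BH across all tested terms), then raw p, then go_id.
    """
    if correction != "BH":
        raise DegflowError("bad-format", f"unsupported correction {correction!r}")
    if parent_map:
        go = propagate(go, parent_map)
    annotated = go.annotated_genes()
    bg = sorted(set(background) & annotated)
    if not bg:
        raise DegflowError("empty-background", "no annotated genes in the background")
    bg_set = set(bg)
    deg_genes = sorted(set(deg.gene_ids) & bg_set)
    n, N = len(deg_genes), len(bg)
    if n == 0:
        return pd.DataFrame(columns=ENRICHMENT_COLUMNS)
    deg_set = set(deg_genes)
    rows = []
    for term in sorted(go.term_ids()):
        members = go.genes_for(term) & bg_set
        K = len(members)
        if K < 1:
            continue
        k = len(members & deg_set)
        rows.append((term, go.term_names.get(term, "."), k, K, hypergeom_upper(k, K, n, N)))
    out = pd.DataFrame(rows, columns=["go_id", "term_name", "k", "K", "p_value"])
    out["n"] = n
    out["N"] = N
    out["corrected_p"] = bh_fdr(out["p_value"].to_numpy())
    return out.sort_values(
        ["corrected_p", "p_value", "go_id"], ignore_index=True
    )[ENRICHMENT_COLUMNS]
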