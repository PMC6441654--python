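"""Thresholded TF ↔ structural-gene coexpression networks.

With only five timepoint means per treatment, correlation estimates are
crude, so edges are kept only at a very stringent cutoff (r ≥ 0.9 or
r ≤ −0.9) and no significance test is attached.  Under an independent
bivariate-normal null the exceedance P(|r| ≥ 0.9) at n = 5 is ≈ 0.037, so
isolated edges carry little evidence; the analysis leans on planted or
biologically coherent modules producing many concordant edges.

Profiles are log2(RPKM + 1) replicate means over the timepoints of one
treatment; the network is bipartite between a declared TF set and a
declared structural-gene (lignin-pathway enzyme) set.
"""

from __future__ import annotations

import logging

import networkx as nx
import numpy as np
import pandas as pd

from .errors import DegflowError
from .types import Condition, CoexpressionNetwork, ExpressionMatrix
from .de import timepoint_means

logger = logging.getLogger("degflow")


def pearson_r(x, y) -> float:
    """Product–moment correlation of two profiles (≥3 points, nonzero variance)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise DegflowError("constant-profile", "need two equal-length profiles of >= 3 points")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegflowError("constant-profile", "zero variance profile")
    return float(np.corrcoef(x, y)[0, 1])


def build_network(
    expr: ExpressionMatrix,
    treatment: Condition,
    tf_ids: list[str],
    structural_ids: list[str],
    pos: float = 0.9,
    neg: float = -0.9,
) -> CoexpressionNetwork:
    """All TF × structural pairs passing the correlation threshold in one treatment.

    An edge (tf, structural, r) is kept iff r ≥ pos or r ≤ neg; pairs where
    either profile is constant are skipped and counted.
    """
    if not tf_ids or not structural_ids:
        raise DegflowError("empty-node-set", "need non-empty TF and structural sets")
    overlap = set(tf_ids) & set(structural_ids)
    if overlap:
        raise DegflowError("empty-node-set", f"TF and structural sets overlap: {sorted(overlap)[:5]}")
    profiles = timepoint_means(expr, treatment, transform="log2p1")
    missing = (set(tf_ids) | set(structural_ids)) - set(profiles.index)
    if missing:
        raise DegflowError("missing-cell", f"genes absent from expression matrix: {sorted(missing)[:5]}")

    tf_mat = profiles.loc[tf_ids].to_numpy()
    st_mat = profiles.loc[structural_ids].to_numpy()
    tf_sd = tf_mat.std(axis=1)
    st_sd = st_mat.std(axis=1)
    tf_ok = tf_sd > 0
    st_ok = st_sd > 0
    n_skipped = int((~tf_ok).sum() * len(structural_ids) + tf_ok.sum() * (~st_ok).sum())
    if n_skipped:
        logger.info("%s network: skipped %d constant-profile pair(s)", treatment.value, n_skipped)

    tz = (tf_mat - tf_mat.mean(axis=1, keepdims=True)) / np.where(tf_sd > 0, tf_sd, 1.0)[:, None]
    sz = (st_mat - st_mat.mean(axis=1, keepdims=True)) / np.where(st_sd > 0, st_sd, 1.0)[:, None]
    rmat = tz @ sz.T / tf_mat.shape[1]

    rows = []
    for i, tf in enumerate(tf_ids):
        if not tf_ok[i]:
            continue
        for j, st in enumerate(structural_ids):
            if not st_ok[j]:
                continue
            r = float(np.clip(rmat[i, j], -1.0, 1.0))
            if r >= pos or r <= neg:
                rows.append((tf, st, r, "pos" if r > 0 else "neg"))
    edges = pd.DataFrame(rows, columns=["tf_id", "structural_id", "r", "sign"])
    return CoexpressionNetwork(
        treatment=treatment,
        edges=edges,
        tf_ids=list(tf_ids),
        structural_ids=list(structural_ids),
        pos=pos,
        neg=neg,
        n_constant_skipped=n_skipped,
    )


def shared_neighbor_fraction(
    net_a: CoexpressionNetwork,
    net_b: CoexpressionNetwork,
    gene_pair: tuple[str, str],
    mode: str = "jaccard",
) -> float:
    """Overlap of two structural genes' TF-neighbor sets across two networks.

    ``gene_pair`` = (structural gene in net_a, structural gene in net_b);
    passing the same gene twice compares its TF neighborhood across
    treatments.  ``mode`` "jaccard" gives |∩|/|∪| (0 when the union is
    empty); "own" gives the mean of each gene's own-neighbor overlap
    fraction.
    """
    na = net_a.tf_neighbors(gene_pair[0])
    nb = net_b.tf_neighbors(gene_pair[1])
    inter = len(na & nb)
    if mode == "jaccard":
        union = len(na | nb)
        return inter / union if union else 0.0
    if mode == "own":
        fracs = [inter / len(s) for s in (na, nb) if s]
        return float(np.mean(fracs)) if fracs else 0.0
    raise DegflowError("bad-format", f"unknown mode {mode!r}")


def export_network(net: CoexpressionNetwork, path, format: str = "edge_tsv") -> None:
    """Write the network as an edge TSV (width = |r|) or GML."""
    fmt = format.lower()
    if fmt == "edge_tsv":
        out = net.edges.copy()
        out["width"] = out["r"].abs()
        out.to_csv(path, sep="\t", index=False)
    elif fmt == "gml":
        g = nx.Graph()
        for tf in net.tf_ids:
            g.add_node(tf, type="tf")
        for st in net.structural_ids:
            g.add_node(st, type="structural")
        for row in net.edges.itertuples(index=False):
            g.add_edge(row.tf_id, row.structural_id, weight=abs(row.r), r=row.r, sign=row.sign)
        nx.write_gml(g, path)
    else:
        raise DegflowError("bad-format", f"unknown export format {format!r}")


def read_network_edges(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", keep_default_na=False, na_values=[])
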