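"""Entropy-weight gene ranking.

A multi-criteria scheme that collapses m non-negative indicators per gene
(here: five per-timepoint mean RPKM values under a treatment plus five
linear fold changes versus the chilling control) into one composite score.
Each indicator column is normalized to proportions f_ij = r_ij / Σ_j r_ij;
its Shannon entropy over genes

    H_i = −(1/ln n) Σ_j f_ij ln f_ij          (conventional form, H ∈ [0, 1])

measures how undiscriminating the indicator is, and the weight

    w_i = (1 − H_i) / (m − Σ_i H_i)

gives discriminating (low-entropy) indicators high weight; Σ w_i = 1 by
construction.  The composite score is the weighted sum Σ_i w_i f_ij.

``sign_convention="as_printed"`` computes H_i without the leading minus
sign, i.e. H_i = +(1/ln n) Σ f ln f ∈ [−1, 0]; some published descriptions
of the method write the formula this way, which inverts which indicators
receive weight.  Both conventions are exposed; "conventional" is the
default because it matches the method's purpose of up-weighting
discriminating indicators.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .errors import DegflowError
from .types import Condition, DEGSet, EntropyRanking, ExpressionMatrix, GeneMeta, IndicatorMatrix
from .de import timepoint_means

logger = logging.getLogger("degflow")

SIGN_CONVENTIONS = ("conventional", "as_printed")
WEIGHT_SUM_TOL = 1e-12


def build_indicator_matrix(
    expr: ExpressionMatrix,
    de_results: pd.DataFrame,
    treatment: Condition,
    genes: DEGSet | list[str],
) -> IndicatorMatrix:
    """Assemble the gene × 10 indicator panel for one treatment.

    Columns 1–5: per-timepoint replicate-mean RPKM under the treatment.
    Columns 6–10: linear fold change 2^|log2fc| versus control at the
    matching timepoints (absolute, so down-regulation counts as strongly as
    up-regulation and all entries stay non-negative).
    """
    gene_ids = genes.gene_ids if isinstance(genes, DEGSet) else list(genes)
    missing = set(gene_ids) - set(expr.gene_ids)
    if missing:
        raise DegflowError("missing-cell", f"genes absent from expression matrix: {sorted(missing)[:5]}")
    tps = expr.timepoints()
    means = timepoint_means(expr, treatment, transform="linear").loc[gene_ids]

    de_t = de_results[de_results["treatment"] == treatment.value]
    lfc = de_t.pivot(index="gene_id", columns="timepoint_day", values="log2fc")
    missing_de = set(gene_ids) - set(lfc.index)
    if missing_de:
        raise DegflowError("missing-cell", f"genes without DE results: {sorted(missing_de)[:5]}")
    lfc = lfc.loc[gene_ids, tps]
    if lfc.isna().any().any():
        raise DegflowError("missing-cell", "a gene lacks a timepoint in the DE results")
    fc = np.power(2.0, np.abs(lfc.to_numpy()))

    r = pd.DataFrame(
        np.column_stack([means.to_numpy(), fc]),
        index=gene_ids,
        columns=[f"RPKM_d{t}" for t in tps] + [f"FC_d{t}" for t in tps],
    )
    return IndicatorMatrix(r=r)


def entropy_weights(mat: IndicatorMatrix, sign_convention: str = "conventional") -> EntropyRanking:
    """Per-indicator entropy H_i and weight w_i (score/rank left unset)."""
    if sign_convention not in SIGN_CONVENTIONS:
        raise DegflowError("bad-convention", f"sign_convention must be one of {SIGN_CONVENTIONS}")
    r = mat.r.to_numpy(dtype=float)
    n, m = r.shape
    colsum = r.sum(axis=0)
    degenerate = [lab for lab, s in zip(mat.indicator_labels, colsum) if s <= 0]
    if degenerate:
        raise DegflowError("degenerate-indicator", f"all-zero indicator column(s): {degenerate}")
    f = r / colsum[None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        flogf = np.where(f > 0, f * np.log(np.where(f > 0, f, 1.0)), 0.0)  # 0·ln 0 := 0
    h = flogf.sum(axis=0) / np.log(n)
    if sign_convention == "conventional":
        h = -h
    denom = m - h.sum()
    if abs(denom) < 1e-15:
        logger.warning("all indicators uniform (m - sum(H) = 0); falling back to equal weights")
        w = np.full(m, 1.0 / m)
    else:
        w = (1.0 - h) / denom
    return EntropyRanking(
        matrix=mat,
        H=pd.Series(h, index=mat.indicator_labels, name="H"),
        w=pd.Series(w, index=mat.indicator_labels, name="w"),
        sign_convention=sign_convention,
    )


def composite_score(mat: IndicatorMatrix, ranking: EntropyRanking) -> EntropyRanking:
    """Fill per-gene composite scores (Σ_i w_i f_ij) and 1-based ranks.

    Genes sort by descending score; ties break by ascending gene_id.
    """
    r = mat.r.to_numpy(dtype=float)
    f = r / r.sum(axis=0)[None, :]
    score = pd.Series(f @ ranking.w.to_numpy(), index=mat.gene_ids, name="score")
    order = sorted(mat.gene_ids, key=lambda g: (-score[g], g))
    rank = pd.Series({g: i + 1 for i, g in enumerate(order)}, name="rank").reindex(mat.gene_ids)
    return EntropyRanking(
        matrix=mat, H=ranking.H, w=ranking.w, score=score, rank=rank,
        sign_convention=ranking.sign_convention,
    )


def rank_genes(mat: IndicatorMatrix, sign_convention: str = "conventional") -> EntropyRanking:
    """Convenience: entropy weights followed by composite scoring."""
    return composite_score(mat, entropy_weights(mat, sign_convention))


def exclude_by_annotation(
    ranking: EntropyRanking, meta: list[GeneMeta], patterns: list[str]
) -> EntropyRanking:
    """Drop genes whose annotation matches any pattern and re-rank the rest.

    Patterns are case-insensitive substrings (e.g. "heat shock"); the
    reduced indicator matrix is re-weighted and re-scored from scratch, so
    the result equals ranking the survivors directly.
    """
    if not patterns:
        return ranking
    pats = [p.lower() for p in patterns]
    ann = {m.gene_id: (m.annotation or "") for m in meta}
    drop = {
        g for g in ranking.matrix.gene_ids if any(p in ann.get(g, "").lower() for p in pats)
    }
    if not drop:
        return ranking
    keep = [g for g in ranking.matrix.gene_ids if g not in drop]
    reduced = IndicatorMatrix(r=ranking.matrix.r.loc[keep])
    return rank_genes(reduced, ranking.sign_convention)


def ranking_table(ranking: EntropyRanking) -> pd.DataFrame:
    """gene_id / score / rank table, sorted by rank."""
    if ranking.score is None or ranking.rank is None:
        raise DegflowError("no-scores", "composite_score has not been applied")
    out = pd.DataFrame(
        {"gene_id": ranking.matrix.gene_ids, "score": ranking.score.values, "rank": ranking.rank.values}
    )
    return out.sort_values("rank", ignore_index=True)


def weights_table(ranking: EntropyRanking) -> pd.DataFrame:
    return pd.DataFrame(
        {"indicator_label": ranking.H.index, "H": ranking.H.values, "w": ranking.w.values}
    )
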