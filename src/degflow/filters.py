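"""DEG-set constructions and assembly utilities.

The per-timepoint DE calls are noisy; the study design retains a gene only
when it is called in the same direction at a minimum number of timepoints
(2 of 5 for the broad candidate set, 4 of 5 for the strong responder set).
Also houses the strand-artifact contig filter and N50/mean-length summary
statistics for de novo assemblies.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .errors import DegflowError
from .types import Call, Condition, ContigAlignmentSummary, DEGSet

logger = logging.getLogger("degflow")


def consistency_filter(
    results: pd.DataFrame, min_support: int = 2, filter_name: str | None = None
) -> DEGSet:
    """Retain genes called DE in one coherent direction at ≥ min_support timepoints.

    ``results`` is a DE results table for a single treatment.  A gene with
    ≥ min_support "up" calls is retained as up (symmetrically for down);
    a gene reaching the threshold in both directions has no coherent trend
    and is excluded (logged).  Support is the count of timepoints called in
    the retained direction.
    """
    if min_support < 1:
        raise DegflowError("bad-support", "min_support must be >= 1")
    treatments = set(results["treatment"])
    if len(treatments) != 1:
        raise DegflowError("mixed-treatments", f"expected one treatment, got {sorted(treatments)}")
    treatment = Condition.parse(next(iter(treatments)))
    name = filter_name or f"same-trend>={min_support}"

    called = results[results["call"] != Call.NONE.value]
    support = (
        called.groupby(["gene_id", "call"], sort=True).size().unstack(fill_value=0)
        if len(called)
        else pd.DataFrame(columns=[Call.UP.value, Call.DOWN.value])
    )
    for col in (Call.UP.value, Call.DOWN.value):
        if col not in support.columns:
            support[col] = 0
    up_ok = support[Call.UP.value] >= min_support
    down_ok = support[Call.DOWN.value] >= min_support
    ambiguous = support.index[up_ok & down_ok]
    if len(ambiguous):
        logger.info(
            "%s: excluded %d gene(s) supported in both directions: %s",
            name,
            len(ambiguous),
            list(ambiguous[:10]),
        )
    rows = []
    for gid in support.index:
        if gid in set(ambiguous):
            continue
        if up_ok.loc[gid]:
            rows.append((gid, Call.UP.value, int(support.loc[gid, Call.UP.value])))
        elif down_ok.loc[gid]:
            rows.append((gid, Call.DOWN.value, int(support.loc[gid, Call.DOWN.value])))
    members = pd.DataFrame(rows, columns=["gene_id", "direction", "support"]).sort_values(
        "gene_id", ignore_index=True
    )
    return DEGSet(treatment=treatment, members=members, filter_name=name)


def responder_set(results: pd.DataFrame, min_support: int = 4) -> DEGSet:
    """Strong responders: same-trend filter at ≥ min_support (default 4) timepoints."""
    return consistency_filter(results, min_support=min_support, filter_name=f"responder>={min_support}")


def cross_treatment_intersection(set_ltc: DEGSet, set_ht: DEGSet) -> pd.DataFrame:
    """Genes present in both treatments' DEG sets, with each direction reported."""
    a = set_ltc.members.set_index("gene_id")
    b = set_ht.members.set_index("gene_id")
    shared = sorted(set(a.index) & set(b.index))
    out = pd.DataFrame(
        {
            "gene_id": shared,
            "direction_ltc": [a.loc[g, "direction"] for g in shared],
            "direction_ht": [b.loc[g, "direction"] for g in shared],
        }
    )
    out["agree"] = out["direction_ltc"] == out["direction_ht"]
    disagreeing = out.loc[~out["agree"], "gene_id"].tolist()
    if disagreeing:
        logger.info("cross-treatment direction disagreement for %s", disagreeing)
    return out


def strand_filter(
    summaries: list[ContigAlignmentSummary], ratio: float = 0.10
) -> tuple[list[str], list[str]]:
    """Discard contigs whose sense reads are strictly below ratio × antisense reads.

    Contigs without antisense reads are kept (no antisense evidence of a
    second-strand artifact).  Returns (kept_ids, discarded_ids).
    """
    if not 0 < ratio < 1:
        raise DegflowError("bad-ratio", "ratio must be in (0, 1)")
    kept, discarded = [], []
    for s in summaries:
        if s.antisense_reads > 0 and s.sense_reads < ratio * s.antisense_reads:
            discarded.append(s.contig_id)
        else:
            kept.append(s.contig_id)
    return kept, discarded


def assembly_stats(lengths) -> tuple[int, int, float, int]:
    """(n, N50, mean length, total bp) of an assembly.

    N50 is the length of the contig at which the descending-sorted
    cumulative length first reaches half the total assembled bases.
    """
    lengths = list(lengths)
    if not lengths:
        raise DegflowError("empty-input", "no contig lengths given")
    if any(l < 1 for l in lengths):
        raise DegflowError("bad-length", "contig lengths must be >= 1")
    arr = np.sort(np.asarray(lengths, dtype=np.int64))[::-1]
    total = int(arr.sum())
    cum = np.cumsum(arr)
    n50 = int(arr[np.searchsorted(cum, total / 2.0)])
    return len(arr), n50, total / len(arr), total
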