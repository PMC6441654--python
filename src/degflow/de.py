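"""RPKM normalization and per-timepoint differential expression.

Each treatment (LTC, HT) is contrasted against the 0 °C control separately
at every timepoint with a negative-binomial exact test: replicate counts
are rescaled to a common effective library size (the rounded geometric mean
of the library sizes), group sums are compared under NB group-sum
distributions conditional on the total, and the two-sided p-value sums the
probability of every split as or less probable than the observed one.
Dispersion is a per-gene method-of-moments estimate pooled (median) over
(condition, timepoint) replicate cells.  A gene is called up/down when
|log2FC| ≥ log2(threshold) and Benjamini–Hochberg FDR ≤ alpha within its
contrast.

This is an analogue of the classic exact-test workflow for two-group count
data, defined in full here (library rescaling by rounding, probability-mass
two-sided rule, moment dispersion with a floor); no numerical identity with
any external implementation is claimed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import DegflowError
from .types import (
    Call,
    Condition,
    CountMatrix,
    DE_COLUMNS,
    ExpressionMatrix,
    GeneMeta,
)

DISPERSION_FLOOR = 1e-4
_LOG2FC_PSEUDOCOUNT = 0.5


def rpkm(counts: CountMatrix, meta: list[GeneMeta]) -> ExpressionMatrix:
    """Reads per kilobase of transcript per million mapped reads.

    rpkm[g, s] = counts[g, s] × 10⁹ / (length_bp[g] × libsize[s]) with
    libsize the column sum of counts.
    """
    lengths = {m.gene_id: m.length_bp for m in meta}
    missing = [g for g in counts.gene_ids if g not in lengths]
    if missing:
        raise DegflowError("missing-length", f"no length for genes {missing[:5]}...")
    libsize = counts.counts.sum(axis=0).astype(float)
    if np.any(libsize <= 0):
        empties = [counts.sample_ids[j] for j in np.where(libsize <= 0)[0]]
        raise DegflowError("empty-library", f"zero total count in samples {empties}")
    length_bp = np.array([lengths[g] for g in counts.gene_ids], dtype=float)
    values = counts.counts * 1e9 / (length_bp[:, None] * libsize[None, :])
    return ExpressionMatrix(gene_ids=list(counts.gene_ids), samples=list(counts.samples), rpkm=values)


def timepoint_means(
    expr: ExpressionMatrix, condition: Condition, transform: str = "linear"
) -> pd.DataFrame:
    """Per-gene replicate-mean expression at each timepoint of one condition.

    ``transform`` is "linear" (plain mean) or "log2p1" (log2(mean + 1),
    the profile convention used by the coexpression stage).
    """
    if transform not in ("linear", "log2p1"):
        raise DegflowError("bad-transform", f"unknown transform {transform!r}")
    tps = expr.timepoints()
    out = np.empty((len(expr.gene_ids), len(tps)))
    for k, t in enumerate(tps):
        cols = expr.columns_for(condition, t)
        if not cols:
            raise DegflowError("missing-cell", f"no replicates for {condition.value} day {t}")
        out[:, k] = expr.rpkm[:, cols].mean(axis=1)
    if transform == "log2p1":
        out = np.log2(out + 1.0)
    return pd.DataFrame(out, index=expr.gene_ids, columns=tps)


def _nb_logpmf(k: np.ndarray, mean: float, phi: float) -> np.ndarray:
    if phi < 1e-12:
        return stats.poisson.logpmf(k, mean)
    r = 1.0 / phi
    return stats.nbinom.logpmf(k, r, r / (r + mean))


def _scale_to_common(counts: np.ndarray, libs: np.ndarray, common: float) -> np.ndarray:
    return np.rint(np.asarray(counts, dtype=float) * common / np.asarray(libs, dtype=float)).astype(
        np.int64
    )


def nb_exact_test(
    counts_a,
    counts_b,
    lib_a,
    lib_b,
    dispersion: float,
) -> tuple[float, float]:
    """Two-group NB exact test on replicate counts.

    Counts are rescaled to the rounded geometric mean of all library sizes;
    the group sums S_a, S_b (total T) are compared under S_a ~ NB(n_a·μ̂,
    φ/n_a), S_b ~ NB(n_b·μ̂, φ/n_b) with μ̂ = T/(n_a+n_b); the two-sided
    p-value is the total conditional probability of splits whose probability
    does not exceed the observed one.  Returns (log2fc of a over b from the
    rescaled group means with pseudocount 0.5, p-value).
    """
    if dispersion < 0:
        raise DegflowError("bad-dispersion", "dispersion must be >= 0")
    counts_a, counts_b = np.asarray(counts_a), np.asarray(counts_b)
    lib_a, lib_b = np.asarray(lib_a, dtype=float), np.asarray(lib_b, dtype=float)
    if counts_a.size < 1 or counts_b.size < 1:
        raise DegflowError("empty-group", "need >= 1 replicate per group")
    if np.any(lib_a <= 0) or np.any(lib_b <= 0):
        raise DegflowError("empty-library", "library sizes must be > 0")
    common = np.rint(np.exp(np.mean(np.log(np.concatenate([lib_a, lib_b])))))
    sa = _scale_to_common(counts_a, lib_a, common)
    sb = _scale_to_common(counts_b, lib_b, common)
    mean_a, mean_b = sa.mean(), sb.mean()
    log2fc = float(
        np.log2((mean_a + _LOG2FC_PSEUDOCOUNT) / (mean_b + _LOG2FC_PSEUDOCOUNT))
    )
    p = _exact_p(int(sa.sum()), int(sb.sum()), len(sa), len(sb), dispersion)
    return log2fc, p


def _exact_p(s_a: int, s_b: int, n_a: int, n_b: int, phi: float) -> float:
    total = s_a + s_b
    if total == 0:
        return 1.0
    mu_hat = total / (n_a + n_b)
    k = np.arange(total + 1)
    logp = _nb_logpmf(k, n_a * mu_hat, phi / n_a) + _nb_logpmf(total - k, n_b * mu_hat, phi / n_b)
    logp -= logp.max()  # stabilize; p is a ratio so the shift cancels
    probs = np.exp(logp)
    observed = probs[s_a]
    # relative tolerance guards against ties broken by floating-point noise
    return float(probs[probs <= observed * (1 + 1e-10)].sum() / probs.sum())


def estimate_dispersion(counts: CountMatrix, design=None) -> pd.Series:
    """Per-gene method-of-moments NB dispersion, pooled across replicate cells.

    Counts are first rescaled to the mean library size so depth differences
    do not masquerade as overdispersion; for each (condition, timepoint)
    cell with ≥2 replicates the moment estimate (s² − m̄)/m̄² is formed and
    the per-gene median across cells is floored at 10⁻⁴.
    """
    samples = design if design is not None else counts.samples
    libs = counts.counts.sum(axis=0).astype(float)
    scaled = counts.counts * (libs.mean() / libs)[None, :]
    cells: dict[tuple, list[int]] = {}
    for j, s in enumerate(samples):
        cells.setdefault((s.condition, s.timepoint_day), []).append(j)
    usable = [cols for cols in cells.values() if len(cols) >= 2]
    if not usable:
        raise DegflowError("no-replicates", "need >= 2 replicates in at least one cell")
    ests = np.full((counts.counts.shape[0], len(usable)), np.nan)
    for k, cols in enumerate(usable):
        block = scaled[:, cols]
        m = block.mean(axis=1)
        v = block.var(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            ests[:, k] = np.where(m > 0, (v - m) / np.square(m), np.nan)
    with np.errstate(all="ignore"):
        med = np.nanmedian(ests, axis=1)
    med = np.where(np.isnan(med), DISPERSION_FLOOR, med)
    return pd.Series(np.maximum(med, DISPERSION_FLOOR), index=counts.gene_ids, name="dispersion")


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise DegflowError("bad-pvalue", "p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_degs(
    counts: CountMatrix,
    meta: list[GeneMeta],
    treatment: Condition,
    fc_threshold: float = 2.0,
    alpha: float = 0.05,
    dispersion: pd.Series | float | None = None,
) -> pd.DataFrame:
    """Exact-test DE calls for one treatment vs control at every timepoint.

    Returns one row per (gene, timepoint) with columns gene_id, treatment,
    timepoint_day, log2fc (treatment over control), p_value, fdr and call
    ("up"/"down"/"none").  FDR is computed across genes within each
    (treatment, timepoint) contrast; the call requires both |log2FC| ≥
    log2(fc_threshold) and fdr ≤ alpha.
    """
    if treatment == Condition.CONTROL:
        raise DegflowError("bad-condition", "treatment must be LTC or HT")
    if dispersion is None:
        phi = estimate_dispersion(counts).to_numpy()
    elif np.isscalar(dispersion):
        phi = np.full(len(counts.gene_ids), float(dispersion))
    else:
        phi = dispersion.reindex(counts.gene_ids).to_numpy()
    libs = counts.counts.sum(axis=0).astype(float)
    lfc_gate = np.log2(fc_threshold)
    frames = []
    for t in counts.timepoints():
        cols_t = counts.columns_for(treatment, t)
        cols_c = counts.columns_for(Condition.CONTROL, t)
        if not cols_t or not cols_c:
            raise DegflowError("missing-cell", f"no samples for day {t}")
        lib_t, lib_c = libs[cols_t], libs[cols_c]
        common = np.rint(np.exp(np.mean(np.log(np.concatenate([lib_t, lib_c])))))
        sa = _scale_to_common(counts.counts[:, cols_t], lib_t, common)
        sb = _scale_to_common(counts.counts[:, cols_c], lib_c, common)
        mean_a, mean_b = sa.mean(axis=1), sb.mean(axis=1)
        log2fc = np.log2((mean_a + _LOG2FC_PSEUDOCOUNT) / (mean_b + _LOG2FC_PSEUDOCOUNT))
        pvals = np.array(
            [
                _exact_p(int(ra), int(rb), len(cols_t), len(cols_c), float(ph))
                for ra, rb, ph in zip(sa.sum(axis=1), sb.sum(axis=1), phi)
            ]
        )
        fdr = bh_fdr(pvals)
        call = np.where(
            (fdr <= alpha) & (log2fc >= lfc_gate),
            Call.UP.value,
            np.where((fdr <= alpha) & (log2fc <= -lfc_gate), Call.DOWN.value, Call.NONE.value),
        )
        frames.append(
            pd.DataFrame(
                {
                    "gene_id": counts.gene_ids,
                    "treatment": treatment.value,
                    "timepoint_day": t,
                    "log2fc": log2fc,
                    "p_value": pvals,
                    "fdr": fdr,
                    "call": call,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)[DE_COLUMNS]
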