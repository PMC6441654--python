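"""Synthetic experiment generator.

Emulates the statistical structure of a postharvest chilling time-course:
three conditions (0 °C control, LTC, HT) × five timepoints × three
replicates, negative-binomial counts over a log-normal baseline, planted
direction-consistent differentially expressed genes, planted TF ↔
structural-gene coexpression modules sharing a latent per-timepoint profile,
and a GO term planted at an elevated rate among the true DEGs.  Ground
truth is returned (and written) so recovery tests are file-driven like the
pipeline itself.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DegflowError
from .types import (
    Condition,
    ContigAlignmentSummary,
    CountMatrix,
    DEFAULT_TIMEPOINTS,
    GOMap,
    GeneMeta,
    SampleDesign,
    TREATMENTS,
)

#: Rate at which the planted-enrichment GO term is assigned to non-DEG genes.
GO_BACKGROUND_RATE = 0.05

#: GO id used for the planted enrichment (lignin metabolic process).
PLANTED_GO_TERM = "GO:0009808"

_TF_FAMILIES = ("AP2/ERF", "MYB", "NAC", "bZIP", "WRKY", "HSF", "bHLH", "GRAS")
_STRUCTURAL_NAMES = (
    "phenylalanine ammonia-lyase (PAL)",
    "4-coumarate:CoA ligase (4CL)",
    "hydroxycinnamoyl transferase (HCT)",
    "caffeic acid O-methyltransferase (COMT)",
    "cinnamyl alcohol dehydrogenase (CAD)",
    "cinnamoyl-CoA reductase (CCR)",
)


@dataclass
class SimulationConfig:
    """Parameters of the synthetic experiment.

    Counts are drawn NB(mean = libfactor_s × μ_g × effect, variance =
    μ + φμ²).  ``baseline_log2_mean`` gives (mean, sd) of a base-2
    log-normal over per-gene expected counts μ_g.  Planted DEGs multiply the
    mean by 2^±planted_log2fc at their perturbed (treatment, timepoint)
    cells; the control is never perturbed.  Coexpression-module members
    share a latent 5-point log2 profile (amplitude sd ``module_amplitude``)
    plus per-gene noise of sd ``module_profile_sd``; the profile is common
    to all three conditions so modules do not create treatment-vs-control
    differences.
    """

    n_genes: int = 5000
    n_tfs: int = 100
    n_structural: int = 10
    timepoints: tuple[int, ...] = DEFAULT_TIMEPOINTS
    replicates: int = 3
    baseline_log2_mean: tuple[float, float] = (5.0, 1.5)
    dispersion: float = 0.05
    frac_deg: float = 0.05
    planted_log2fc: float = 3.0
    deg_support_distribution: dict[int, float] = field(
        default_factory=lambda: {2: 0.25, 3: 0.25, 4: 0.25, 5: 0.25}
    )
    n_coexpression_modules: int = 3
    module_profile_sd: float = 0.1
    module_amplitude: float = 1.5
    frac_go_enriched: float = 0.6
    library_size_factor_sd: float = 0.15
    planted_baseline_min: float = 50.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_tfs + self.n_structural > self.n_genes:
            raise DegflowError("config-overflow", "n_tfs + n_structural > n_genes")
        if self.dispersion <= 0:
            raise DegflowError("bad-dispersion", "dispersion must be > 0")
        if not (0 <= self.frac_deg <= 1 and 0 <= self.frac_go_enriched <= 1):
            raise DegflowError("bad-fraction", "fractions must be in [0, 1]")
        probs = self.deg_support_distribution
        if abs(sum(probs.values()) - 1.0) > 1e-9:
            raise DegflowError("bad-distribution", "support probabilities must sum to 1")
        if any(k not in range(1, len(self.timepoints) + 1) for k in probs):
            raise DegflowError("bad-distribution", "support levels must fit the timepoint series")
        if self.planted_log2fc <= 0:
            raise DegflowError("bad-effect", "planted_log2fc must be > 0")


@dataclass
class GroundTruth:
    """Planted structure of a simulated experiment.

    deg_table: one row per (gene, treatment) with direction and the comma
    separated perturbed timepoints.  module_table: one row per module member
    with its role and the latent profile.  enriched_terms: GO ids planted at
    elevated rate among true DEGs.
    """

    deg_table: pd.DataFrame
    module_table: pd.DataFrame
    enriched_terms: list[str]

    def degs_for(self, treatment: Condition, min_support: int = 1) -> set[str]:
        t = self.deg_table
        sel = t[t["treatment"] == treatment.value]
        if min_support > 1:
            sel = sel[sel["n_perturbed"] >= min_support]
        return set(sel["gene_id"])


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, phi: float) -> np.ndarray:
    if phi < 1e-12:
        return rng.poisson(mean)
    r = 1.0 / phi
    p = r / (r + mean)
    return rng.negative_binomial(r, p)


def simulate_experiment(
    config: SimulationConfig,
) -> tuple[CountMatrix, list[GeneMeta], GOMap, GroundTruth]:
    """Draw one synthetic experiment; fully reproducible from config.seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_genes
    tps = list(config.timepoints)
    n_tp = len(tps)
    gene_ids = [f"UN{i:05d}" for i in range(n)]

    # gene roles: TFs and lignin-pathway structural genes
    perm = rng.permutation(n)
    tf_idx = np.sort(perm[: config.n_tfs])
    structural_idx = np.sort(perm[config.n_tfs : config.n_tfs + config.n_structural])

    # coexpression modules: disjoint members drawn from the TF and structural pools
    module_rows = []
    module_ids = {}  # gene index -> module
    # latent 5-point profiles, standardized so every module's realized spread
    # equals module_amplitude (guarantees high member correlation at low noise)
    profiles = rng.normal(0.0, 1.0, size=(config.n_coexpression_modules, n_tp))
    if config.n_coexpression_modules > 0:
        profiles -= profiles.mean(axis=1, keepdims=True)
        sd = profiles.std(axis=1, keepdims=True)
        profiles = config.module_amplitude * profiles / np.where(sd > 0, sd, 1.0)
    if config.n_coexpression_modules > 0:
        tfs_per = max(2, config.n_tfs // (2 * max(config.n_coexpression_modules, 1)))
        str_per = max(1, config.n_structural // max(config.n_coexpression_modules + 1, 1))
        tf_pool = list(rng.permutation(tf_idx))
        str_pool = list(rng.permutation(structural_idx))
        for m in range(config.n_coexpression_modules):
            mem_tf = [tf_pool.pop() for _ in range(min(tfs_per, len(tf_pool)))]
            mem_str = [str_pool.pop() for _ in range(min(str_per, len(str_pool)))]
            for g in mem_tf + mem_str:
                module_ids[g] = m
            for g in mem_tf:
                module_rows.append((m, gene_ids[g], "tf"))
            for g in mem_str:
                module_rows.append((m, gene_ids[g], "structural"))
    module_members = set(module_ids)

    # baselines
    mu = 2.0 ** rng.normal(config.baseline_log2_mean[0], config.baseline_log2_mean[1], size=n)

    # planted DEGs among genes outside coexpression modules
    n_deg = int(round(config.frac_deg * n))
    eligible = np.array([i for i in range(n) if i not in module_members])
    deg_idx = rng.choice(eligible, size=min(n_deg, len(eligible)), replace=False)
    directions = rng.choice([1, -1], size=len(deg_idx))
    support_levels = np.array(sorted(config.deg_support_distribution))
    support_probs = np.array([config.deg_support_distribution[k] for k in support_levels])

    special = np.zeros(n, dtype=bool)
    special[deg_idx] = True
    special[list(module_members)] = True
    mu[special] = np.maximum(mu[special], config.planted_baseline_min)

    # per-gene membership and perturbed cells for each treatment
    log2effect = np.zeros((n, 3, n_tp))  # conditions indexed control=0, LTC=1, HT=2
    cond_index = {Condition.CONTROL: 0, Condition.LTC: 1, Condition.HT: 2}
    deg_rows = []
    for g, d in zip(deg_idx, directions):
        in_ltc = rng.random() < 0.7
        in_ht = rng.random() < 0.45
        if not (in_ltc or in_ht):
            in_ltc = True
        for flag, treat in ((in_ltc, Condition.LTC), (in_ht, Condition.HT)):
            if not flag:
                continue
            k = int(rng.choice(support_levels, p=support_probs))
            pert = np.sort(rng.choice(n_tp, size=k, replace=False))
            log2effect[g, cond_index[treat], pert] += d * config.planted_log2fc
            deg_rows.append(
                {
                    "gene_id": gene_ids[g],
                    "treatment": treat.value,
                    "direction": "up" if d > 0 else "down",
                    "perturbed_timepoints": ",".join(str(tps[j]) for j in pert),
                    "n_perturbed": k,
                }
            )

    # module profiles, shared across conditions (per-gene noise also shared)
    for g, m in module_ids.items():
        dev = rng.normal(0.0, config.module_profile_sd, size=n_tp)
        log2effect[g, :, :] += profiles[m] + dev

    # samples and library factors
    samples = []
    for cond in (Condition.CONTROL, Condition.LTC, Condition.HT):
        for t in tps:
            for r in range(1, config.replicates + 1):
                samples.append(
                    SampleDesign(
                        sample_id=f"{cond.value}_d{t}_r{r}",
                        condition=cond,
                        timepoint_day=t,
                        replicate=r,
                    )
                )
    libf = np.exp(rng.normal(0.0, config.library_size_factor_sd, size=len(samples)))

    means = np.empty((n, len(samples)))
    for j, s in enumerate(samples):
        ci = cond_index[s.condition]
        ti = tps.index(s.timepoint_day)
        means[:, j] = libf[j] * mu * 2.0 ** log2effect[:, ci, ti]
    counts = _nb_draw(rng, means, config.dispersion)

    cm = CountMatrix(gene_ids=gene_ids, samples=samples, counts=counts.astype(np.int64))

    # gene metadata: lengths log-normal around ~800 bp, roles and annotations
    lengths = np.clip(np.rint(2.0 ** rng.normal(9.6, 0.6, size=n)).astype(int), 200, None)
    tf_fams = rng.choice(len(_TF_FAMILIES), size=n)
    heat_shock = rng.random(n) < 0.01
    meta = []
    structural_set = set(structural_idx.tolist())
    tf_set = set(tf_idx.tolist())
    for i, gid in enumerate(gene_ids):
        if i in structural_set:
            ann = _STRUCTURAL_NAMES[i % len(_STRUCTURAL_NAMES)]
        elif heat_shock[i]:
            ann = "heat shock protein 70"
        else:
            ann = None
        meta.append(
            GeneMeta(
                gene_id=gid,
                length_bp=int(lengths[i]),
                tf_family=_TF_FAMILIES[tf_fams[i]] if i in tf_set else None,
                is_structural=i in structural_set,
                annotation=ann,
            )
        )

    # GO map: background terms plus one term planted among true DEGs
    term_pool = [f"GO:{1000000 + k:07d}" for k in range(40)]
    term_names = {t: f"biological process {k + 1}" for k, t in enumerate(term_pool)}
    term_names[PLANTED_GO_TERM] = "lignin metabolic process"
    pairs: set[tuple[str, str]] = set()
    n_terms = rng.poisson(2.0, size=n)
    deg_union = {gene_ids[g] for g in deg_idx}
    for i, gid in enumerate(gene_ids):
        if n_terms[i] > 0:
            for t in rng.choice(len(term_pool), size=min(n_terms[i], len(term_pool)), replace=False):
                pairs.add((gid, term_pool[t]))
        rate = config.frac_go_enriched if gid in deg_union else GO_BACKGROUND_RATE
        if rng.random() < rate:
            pairs.add((gid, PLANTED_GO_TERM))
    go = GOMap(pairs=pairs, term_names=term_names)

    truth = GroundTruth(
        deg_table=pd.DataFrame(
            deg_rows,
            columns=["gene_id", "treatment", "direction", "perturbed_timepoints", "n_perturbed"],
        ),
        module_table=pd.DataFrame(module_rows, columns=["module", "gene_id", "role"]),
        enriched_terms=[PLANTED_GO_TERM],
    )
    return cm, meta, go, truth


def simulate_contig_summary(
    n_contigs: int, frac_antisense_artifacts: float, seed: int
) -> tuple[list[ContigAlignmentSummary], list[bool]]:
    """Draw sense/antisense read totals with built-in separation at the 10% rule.

    Artifact contigs have sense/antisense strictly below 0.10; genuine
    contigs are at or above it (or have no antisense reads).  Returns the
    summaries and the planted is-artifact labels for recovery tests.
    """
    if not 0 <= frac_antisense_artifacts <= 1:
        raise DegflowError("bad-fraction", "frac_antisense_artifacts must be in [0, 1]")
    rng = np.random.default_rng(seed)
    summaries, labels = [], []
    for i in range(n_contigs):
        is_artifact = rng.random() < frac_antisense_artifacts
        if is_artifact:
            anti = int(rng.integers(200, 2000))
            sense = int(np.floor(anti * rng.uniform(0.0, 0.095)))
        else:
            sense = int(rng.integers(100, 1000))
            anti = int(np.rint(sense * rng.uniform(0.0, 8.0)))
        summaries.append(
            ContigAlignmentSummary(contig_id=f"CT{i:05d}", sense_reads=sense, antisense_reads=anti)
        )
        labels.append(is_artifact)
    return summaries, labels


def simulate_contig_lengths(n_contigs: int, seed: int) -> list[int]:
    """Contig lengths, log-normal with mean near 800 bp (assembly-stat fixture)."""
    rng = np.random.default_rng(seed)
    return list(np.clip(np.rint(2.0 ** rng.normal(9.6, 0.6, size=n_contigs)).astype(int), 200, None))
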