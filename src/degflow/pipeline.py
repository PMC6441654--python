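"""Pipeline orchestration: simulate → de → filter → stats → rank → network → enrich.

Each stage reads and writes TSVs in one output directory so stages can be
re-run independently; a run manifest (JSON) records per-stage parameters,
input-file hashes, row counts and runtimes.  With a fixed seed and config
a re-run reproduces byte-identical result tables.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import io as dio
from .de import call_degs, estimate_dispersion, rpkm
from .entropy import build_indicator_matrix, exclude_by_annotation, rank_genes, ranking_table, weights_table
from .enrichment import enrich
from .errors import DegflowError
from .filters import (
    assembly_stats,
    consistency_filter,
    cross_treatment_intersection,
    responder_set,
    strand_filter,
)
from .network import build_network, export_network, shared_neighbor_fraction
from .simulate import (
    SimulationConfig,
    simulate_contig_lengths,
    simulate_contig_summary,
    simulate_experiment,
)
from .types import Condition, DEGSet, TREATMENTS

logger = logging.getLogger("degflow")

STAGES = ("simulate", "de", "filter", "stats", "rank", "network", "enrich")


@dataclass
class RunConfig:
    """All knobs of one pipeline run.

    Thresholds default to the study's printed cutoffs: fold change ≥ 2 and
    FDR ≤ 0.05 for DE calls, same-trend support ≥ 2 (responders ≥ 4), and
    correlation cutoffs ±0.9 for the coexpression networks.
    """

    outdir: str = "degflow_run"
    seed: int = 0
    stages: tuple[str, ...] = STAGES
    fc_threshold: float = 2.0
    alpha: float = 0.05
    min_support: int = 2
    responder_support: int = 4
    pos_r: float = 0.9
    neg_r: float = -0.9
    sign_convention: str = "conventional"
    exclude_patterns: tuple[str, ...] = ()
    n_contigs: int = 1000
    frac_antisense_artifacts: float = 0.1
    simulation: SimulationConfig = field(default_factory=SimulationConfig)

    def __post_init__(self):
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise DegflowError("bad-stage", f"unknown stage(s): {sorted(unknown)}")
        if not (0 < self.alpha <= 1) or self.fc_threshold < 1:
            raise DegflowError("bad-threshold", "alpha in (0,1] and fc_threshold >= 1 required")
        if self.min_support < 1 or self.responder_support < 1:
            raise DegflowError("bad-support", "support thresholds must be >= 1")
        if not (-1 <= self.neg_r < self.pos_r <= 1):
            raise DegflowError("bad-threshold", "need -1 <= neg_r < pos_r <= 1")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim_keys = {f.name for f in dataclasses.fields(SimulationConfig)}
        run_keys = {f.name for f in dataclasses.fields(cls)} - {"simulation"}
        sim_kwargs = {k: v for k, v in raw.items() if k in sim_keys}
        run_kwargs = {k: v for k, v in raw.items() if k in run_keys}
        bad = set(raw) - sim_keys - run_keys
        if bad:
            raise DegflowError("bad-config", f"unknown config key(s): {sorted(bad)}")
        if "stages" in run_kwargs:
            run_kwargs["stages"] = tuple(run_kwargs["stages"])
        cfg = cls(**run_kwargs)
        sim_kwargs.setdefault("seed", cfg.seed)
        cfg.simulation = SimulationConfig(**sim_kwargs)
        return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


class PipelineRun:
    """Stateful executor for one output directory."""

    def __init__(self, config: RunConfig):
        self.config = config
        self.outdir = Path(config.outdir)
        self.outdir.mkdir(parents=True, exist_ok=True)
        self.manifest: list[dict] = []

    def path(self, name: str) -> Path:
        return self.outdir / name

    def _need(self, stage: str, *names: str) -> list[Path]:
        return [dio.ensure_exists(self.path(n), stage) for n in names]

    def _record(self, stage: str, inputs: list[Path], outputs: dict[str, int], params: dict, t0: float):
        self.manifest.append(
            {
                "stage": stage,
                "inputs": {p.name: _sha256(p) for p in inputs},
                "outputs": outputs,
                "parameters": params,
                "runtime_s": round(time.monotonic() - t0, 3),
            }
        )

    # ------------------------------------------------------------------ stages

    def stage_simulate(self):
        t0 = time.monotonic()
        cfg = self.config
        cm, meta, go, truth = simulate_experiment(cfg.simulation)
        dio.write_count_matrix(cm, self.path("counts.tsv"), self.path("design.tsv"))
        dio.write_gene_meta(meta, self.path("gene_meta.tsv"))
        dio.write_go_map(go, self.path("go_map.tsv"))
        summaries, labels = simulate_contig_summary(
            cfg.n_contigs, cfg.frac_antisense_artifacts, seed=cfg.simulation.seed + 1
        )
        dio.write_contig_summary(summaries, self.path("contig_strand.tsv"))
        dio.write_table(
            pd.DataFrame(
                {"contig_id": [s.contig_id for s in summaries], "is_artifact": labels}
            ),
            self.path("truth_contigs.tsv"),
        )
        lengths = simulate_contig_lengths(cfg.n_contigs, seed=cfg.simulation.seed + 2)
        dio.write_table(pd.DataFrame({"length_bp": lengths}), self.path("contig_lengths.tsv"))
        dio.write_table(truth.deg_table, self.path("truth_degs.tsv"))
        dio.write_table(truth.module_table, self.path("truth_modules.tsv"))
        dio.write_table(
            pd.DataFrame({"go_id": truth.enriched_terms}), self.path("truth_enrichment.tsv")
        )
        self._record(
            "simulate",
            [],
            {"genes": len(cm.gene_ids), "samples": len(cm.samples), "contigs": len(summaries)},
            dataclasses.asdict(cfg.simulation),
            t0,
        )

    def stage_de(self):
        t0 = time.monotonic()
        inputs = self._need("de", "counts.tsv", "design.tsv", "gene_meta.tsv")
        cm = dio.read_count_matrix(self.path("counts.tsv"), self.path("design.tsv"))
        meta = dio.read_gene_meta(self.path("gene_meta.tsv"))
        phi = estimate_dispersion(cm)
        dio.write_table(
            phi.rename_axis("gene_id").reset_index(), self.path("dispersion.tsv")
        )
        tables = [
            call_degs(
                cm,
                meta,
                treatment,
                fc_threshold=self.config.fc_threshold,
                alpha=self.config.alpha,
                dispersion=phi,
            )
            for treatment in TREATMENTS
        ]
        de = pd.concat(tables, ignore_index=True)
        dio.write_table(de, self.path("de_results.tsv"))
        self._record(
            "de",
            inputs,
            {"de_rows": len(de)},
            {"fc_threshold": self.config.fc_threshold, "alpha": self.config.alpha},
            t0,
        )

    def _read_de(self) -> pd.DataFrame:
        return dio.read_table(
            self.path("de_results.tsv"), timepoint_day=int, log2fc=float, p_value=float, fdr=float
        )

    def _read_deg_sets(self) -> dict[tuple[str, str], DEGSet]:
        df = dio.read_table(self.path("deg_sets.tsv"), support=int)
        out = {}
        for (treatment, fname), grp in df.groupby(["treatment", "filter_name"]):
            out[(treatment, fname)] = DEGSet(
                treatment=Condition.parse(treatment),
                members=grp[["gene_id", "direction", "support"]].reset_index(drop=True),
                filter_name=fname,
            )
        return out

    def stage_filter(self):
        t0 = time.monotonic()
        inputs = self._need("filter", "de_results.tsv", "contig_strand.tsv")
        de = self._read_de()
        sets = []
        consistency: dict[Condition, DEGSet] = {}
        for treatment in TREATMENTS:
            sub = de[de["treatment"] == treatment.value]
            cons = consistency_filter(sub, min_support=self.config.min_support)
            resp = responder_set(sub, min_support=self.config.responder_support)
            consistency[treatment] = cons
            for s in (cons, resp):
                m = s.members.copy()
                m.insert(1, "treatment", s.treatment.value)
                m["filter_name"] = s.filter_name
                sets.append(m)
        deg_sets = pd.concat(sets, ignore_index=True)
        dio.write_table(deg_sets, self.path("deg_sets.tsv"))
        inter = cross_treatment_intersection(
            consistency[Condition.LTC], consistency[Condition.HT]
        )
        dio.write_table(inter, self.path("intersection.tsv"))
        summaries = dio.read_contig_summary(self.path("contig_strand.tsv"))
        kept, discarded = strand_filter(summaries, ratio=0.10)
        dio.write_table(pd.DataFrame({"contig_id": kept}), self.path("strand_kept.tsv"))
        dio.write_table(pd.DataFrame({"contig_id": discarded}), self.path("strand_discarded.tsv"))
        self._record(
            "filter",
            inputs,
            {"deg_set_rows": len(deg_sets), "shared_genes": len(inter), "discarded_contigs": len(discarded)},
            {"min_support": self.config.min_support, "responder_support": self.config.responder_support},
            t0,
        )

    def stage_stats(self):
        t0 = time.monotonic()
        inputs = self._need("stats", "contig_lengths.tsv")
        lengths = dio.read_table(self.path("contig_lengths.tsv"), length_bp=int)["length_bp"]
        n, n50, mean_len, total = assembly_stats(lengths)
        dio.write_table(
            pd.DataFrame(
                {"n_contigs": [n], "n50_bp": [n50], "mean_length_bp": [round(mean_len, 2)], "total_bp": [total]}
            ),
            self.path("assembly_stats.tsv"),
        )
        self._record("stats", inputs, {"n_contigs": n}, {}, t0)

    def stage_rank(self):
        t0 = time.monotonic()
        inputs = self._need("rank", "counts.tsv", "design.tsv", "gene_meta.tsv", "de_results.tsv", "deg_sets.tsv")
        cm = dio.read_count_matrix(self.path("counts.tsv"), self.path("design.tsv"))
        meta = dio.read_gene_meta(self.path("gene_meta.tsv"))
        expr = rpkm(cm, meta)
        de = self._read_de()
        sets = self._read_deg_sets()
        rows_out = {}
        for treatment in TREATMENTS:
            key = (treatment.value, f"same-trend>={self.config.min_support}")
            deg = sets.get(key)
            if deg is None or len(deg.members) < 2:
                logger.info("rank: <2 genes in the %s DEG set; writing empty ranking", treatment.value)
                dio.write_table(
                    pd.DataFrame(columns=["gene_id", "score", "rank"]),
                    self.path(f"ranking_{treatment.value}.tsv"),
                )
                continue
            mat = build_indicator_matrix(expr, de, treatment, deg)
            ranking = rank_genes(mat, self.config.sign_convention)
            if self.config.exclude_patterns:
                ranking = exclude_by_annotation(ranking, meta, list(self.config.exclude_patterns))
            dio.write_table(ranking_table(ranking), self.path(f"ranking_{treatment.value}.tsv"))
            dio.write_table(weights_table(ranking), self.path(f"weights_{treatment.value}.tsv"))
            rows_out[treatment.value] = len(ranking.matrix.gene_ids)
        self._record(
            "rank",
            inputs,
            rows_out,
            {"sign_convention": self.config.sign_convention, "exclude": list(self.config.exclude_patterns)},
            t0,
        )

    def stage_network(self):
        t0 = time.monotonic()
        inputs = self._need("network", "counts.tsv", "design.tsv", "gene_meta.tsv")
        cm = dio.read_count_matrix(self.path("counts.tsv"), self.path("design.tsv"))
        meta = dio.read_gene_meta(self.path("gene_meta.tsv"))
        expr = rpkm(cm, meta)
        tf_ids = [m.gene_id for m in meta if m.tf_family is not None]
        structural_ids = [m.gene_id for m in meta if m.is_structural]
        nets = {}
        for treatment in TREATMENTS:
            net = build_network(
                expr, treatment, tf_ids, structural_ids, pos=self.config.pos_r, neg=self.config.neg_r
            )
            export_network(net, self.path(f"network_{treatment.value}.tsv"), "edge_tsv")
            export_network(net, self.path(f"network_{treatment.value}.gml"), "gml")
            nets[treatment] = net
        pair_rows = []
        for st in structural_ids:
            na = nets[Condition.LTC].tf_neighbors(st)
            nb = nets[Condition.HT].tf_neighbors(st)
            pair_rows.append(
                (
                    st,
                    len(na),
                    len(nb),
                    shared_neighbor_fraction(nets[Condition.LTC], nets[Condition.HT], (st, st)),
                )
            )
        dio.write_table(
            pd.DataFrame(pair_rows, columns=["structural_id", "n_tf_ltc", "n_tf_ht", "shared_fraction"]),
            self.path("shared_pairs.tsv"),
        )
        self._record(
            "network",
            inputs,
            {t.value: len(nets[t].edges) for t in TREATMENTS},
            {"pos_r": self.config.pos_r, "neg_r": self.config.neg_r},
            t0,
        )

    def stage_enrich(self):
        t0 = time.monotonic()
        inputs = self._need("enrich", "deg_sets.tsv", "go_map.tsv", "counts.tsv", "design.tsv")
        go = dio.read_go_map(self.path("go_map.tsv"))
        cm = dio.read_count_matrix(self.path("counts.tsv"), self.path("design.tsv"))
        sets = self._read_deg_sets()
        out_rows = {}
        for treatment in TREATMENTS:
            key = (treatment.value, f"same-trend>={self.config.min_support}")
            deg = sets.get(
                key,
                DEGSet(
                    treatment=treatment,
                    members=pd.DataFrame(columns=["gene_id", "direction", "support"]),
                    filter_name=key[1],
                ),
            )
            table = enrich(deg, go, background=cm.gene_ids)
            dio.write_table(table, self.path(f"enrichment_{treatment.value}.tsv"))
            out_rows[treatment.value] = len(table)
        self._record("enrich", inputs, out_rows, {"correction": "BH"}, t0)

    # --------------------------------------------------------------------- run

    def run(self) -> list[dict]:
        dispatch = {
            "simulate": self.stage_simulate,
            "de": self.stage_de,
            "filter": self.stage_filter,
            "stats": self.stage_stats,
            "rank": self.stage_rank,
            "network": self.stage_network,
            "enrich": self.stage_enrich,
        }
        for stage in STAGES:
            if stage not in self.config.stages:
                continue
            logger.info("stage %s ...", stage)
            dispatch[stage]()
            logger.info("stage %s done (%.2fs)", stage, self.manifest[-1]["runtime_s"])
        with open(self.path("manifest.json"), "w") as fh:
            json.dump(self.manifest, fh, indent=2)
        return self.manifest


def run_pipeline(config: RunConfig) -> list[dict]:
    """Execute the configured stages in order; returns the manifest."""
    return PipelineRun(config).run()
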