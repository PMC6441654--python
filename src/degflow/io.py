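"""Readers and writers for the pipeline's on-disk tables.

Every file is TSV (tab-separated, UTF-8) with a header row; missing optional
values are written as ".".  Readers validate and reject malformed input
rather than coercing it; every writer/reader pair round-trips valid data
exactly.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DegflowError
from .types import (
    Condition,
    ContigAlignmentSummary,
    CountMatrix,
    GOMap,
    GeneMeta,
    SampleDesign,
)

logger = logging.getLogger("degflow")

MISSING = "."


def _read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)


def read_count_matrix(path_counts, path_design) -> CountMatrix:
    """Read a raw count matrix and its sample design.

    The counts file has gene_id in the first column and one column per
    sample; the design file has columns sample_id, condition, timepoint_day,
    replicate.  Sample column order follows the design file.
    """
    design = _read_tsv(path_design)
    need = {"sample_id", "condition", "timepoint_day", "replicate"}
    if not need.issubset(design.columns):
        raise DegflowError("design-mismatch", f"design file must have columns {sorted(need)}")
    samples = [
        SampleDesign(
            sample_id=row["sample_id"],
            condition=Condition.parse(row["condition"]),
            timepoint_day=int(row["timepoint_day"]),
            replicate=int(row["replicate"]),
        )
        for _, row in design.iterrows()
    ]

    raw = _read_tsv(path_counts)
    if raw.columns[0] != "gene_id":
        raise DegflowError("malformed-counts", "first column of counts file must be gene_id")
    count_cols = list(raw.columns[1:])
    design_ids = [s.sample_id for s in samples]
    missing_in_design = set(count_cols) - set(design_ids)
    missing_in_counts = set(design_ids) - set(count_cols)
    if missing_in_design or missing_in_counts:
        raise DegflowError(
            "design-mismatch",
            f"samples only in counts: {sorted(missing_in_design)}; "
            f"only in design: {sorted(missing_in_counts)}",
        )
    gene_ids = list(raw["gene_id"])
    if len(set(gene_ids)) != len(gene_ids):
        raise DegflowError("duplicate-gene", "duplicate gene_id in counts file")
    try:
        counts = raw[design_ids].astype(np.int64).to_numpy()
    except ValueError as exc:
        raise DegflowError("malformed-counts", f"non-integer count: {exc}") from exc
    if (counts < 0).any():
        raise DegflowError("malformed-counts", "negative count")
    return CountMatrix(gene_ids=gene_ids, samples=samples, counts=counts)


def write_count_matrix(cm: CountMatrix, path_counts, path_design) -> None:
    frame = cm.to_frame()
    frame.index.name = "gene_id"
    frame.to_csv(path_counts, sep="\t")
    cm.design_frame().to_csv(path_design, sep="\t", index=False)


def read_gene_meta(path) -> list[GeneMeta]:
    """Read per-gene metadata; tf_family, is_structural and annotation are optional."""
    df = _read_tsv(path)
    if not {"gene_id", "length_bp"}.issubset(df.columns):
        raise DegflowError("malformed-meta", "gene meta needs gene_id and length_bp columns")
    out = []
    for _, row in df.iterrows():
        try:
            length = int(row["length_bp"])
        except ValueError as exc:
            raise DegflowError("bad-length", f"non-integer length for {row['gene_id']}") from exc
        tf = row.get("tf_family", MISSING)
        ann = row.get("annotation", MISSING)
        structural = str(row.get("is_structural", "false")).strip().lower() in {"true", "1", "yes"}
        out.append(
            GeneMeta(
                gene_id=row["gene_id"],
                length_bp=length,
                tf_family=None if tf in (MISSING, "") else tf,
                is_structural=structural,
                annotation=None if ann in (MISSING, "") else ann,
            )
        )
    return out


def write_gene_meta(meta: list[GeneMeta], path) -> None:
    pd.DataFrame(
        {
            "gene_id": [m.gene_id for m in meta],
            "length_bp": [m.length_bp for m in meta],
            "tf_family": [m.tf_family if m.tf_family is not None else MISSING for m in meta],
            "is_structural": ["true" if m.is_structural else "false" for m in meta],
            "annotation": [m.annotation if m.annotation is not None else MISSING for m in meta],
        }
    ).to_csv(path, sep="\t", index=False)


def read_go_map(path) -> GOMap:
    """Read gene → GO assignments (2 or 3 columns); duplicates collapse to a set."""
    df = _read_tsv(path)
    if not {"gene_id", "go_id"}.issubset(df.columns):
        raise DegflowError("malformed-go", "go map needs gene_id and go_id columns")
    has_names = "term_name" in df.columns
    pairs: set[tuple[str, str]] = set()
    names: dict[str, str] = {}
    for _, row in df.iterrows():
        go_id = row["go_id"]
        if not go_id.startswith("GO:"):
            raise DegflowError("bad-go-id", f"{go_id!r} does not start with 'GO:'")
        pairs.add((row["gene_id"], go_id))
        if has_names and row["term_name"] not in (MISSING, ""):
            if go_id in names and names[go_id] != row["term_name"]:
                logger.warning("term %s renamed %r -> %r", go_id, names[go_id], row["term_name"])
            names[go_id] = row["term_name"]
    return GOMap(pairs=pairs, term_names=names)


def write_go_map(go: GOMap, path) -> None:
    rows = sorted(go.pairs)
    pd.DataFrame(
        {
            "gene_id": [g for g, _ in rows],
            "go_id": [t for _, t in rows],
            "term_name": [go.term_names.get(t, MISSING) for _, t in rows],
        }
    ).to_csv(path, sep="\t", index=False)


def read_contig_summary(path) -> list[ContigAlignmentSummary]:
    df = _read_tsv(path)
    need = {"contig_id", "sense_reads", "antisense_reads"}
    if not need.issubset(df.columns):
        raise DegflowError("malformed-counts", f"contig summary needs columns {sorted(need)}")
    try:
        return [
            ContigAlignmentSummary(
                contig_id=row["contig_id"],
                sense_reads=int(row["sense_reads"]),
                antisense_reads=int(row["antisense_reads"]),
            )
            for _, row in df.iterrows()
        ]
    except ValueError as exc:
        raise DegflowError("malformed-counts", str(exc)) from exc


def write_contig_summary(summaries: list[ContigAlignmentSummary], path) -> None:
    pd.DataFrame(
        {
            "contig_id": [s.contig_id for s in summaries],
            "sense_reads": [s.sense_reads for s in summaries],
            "antisense_reads": [s.antisense_reads for s in summaries],
        }
    ).to_csv(path, sep="\t", index=False)


def write_table(df: pd.DataFrame, path) -> None:
    """Write a results table (DE results, DEG sets, rankings, ...) as TSV."""
    df.to_csv(path, sep="\t", index=False)


def read_table(path, **dtypes) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", keep_default_na=False, na_values=[])
    for col, dt in dtypes.items():
        if col in df.columns:
            df[col] = df[col].astype(dt)
    return df


def ensure_exists(path, stage: str) -> Path:
    p = Path(path)
    if not p.exists():
        raise DegflowError("missing-upstream", f"stage {stage!r} needs missing input {p}")
    return p
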