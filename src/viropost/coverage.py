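"""Coverage statistics and vOTU abundance matrices.

Read placements (aligned spans on a contig) are reduced to the three
numbers viromics abundance work runs on: mean depth (sum of span lengths
over contig length), horizontal covered fraction (union of spans over
contig length), and read count.  Per-sample statistics are assembled into
a complete vOTU x sample matrix with the detector/quality annotations
joined on, and then filtered two ways:

* horizontal-coverage filtration — an abundance cell whose covered
  fraction falls below a threshold is zeroed (a handful of reads piled on
  a small part of a genome is not evidence the virus is present), and
  rows left with no signal at that threshold are dropped;
* sequence-quality filtration — the conservative rule keeps sequences
  longer than 5 kb, or longer than 1 kb and of at least medium quality
  (strict ">", unlike the inclusive detection presets); the relaxed rule
  re-applies only the default gene-content filters.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .gene_filtering import apply_gene_filters
from .tables_io import (
    ConfigError,
    CoverageRow,
    DetectionRecord,
    NA,
    Placement,
    ValidationError,
    _fmt_opt,
    _fmt_region,
)

DEPTH_SUFFIX = "__mean_depth"
CF_SUFFIX = "__covered_fraction"
READS_SUFFIX = "__read_count"

GOOD_QUALITY = {"Complete", "High-quality", "Medium-quality"}


# ---------------------------------------------------------------------------
# Per-contig statistics from placements
# ---------------------------------------------------------------------------

def covered_stats(
    placements: Iterable[Placement],
    contig_length: int,
    contig_id: str = "",
    sample_id: str = "",
) -> CoverageRow:
    """Reduce one contig's placements to (mean depth, covered fraction, reads).

    covered_fraction = |union of spans| / length; mean_depth = sum of span
    lengths / length; read_count = number of placements.  A span past the
    contig end is a hard error.
    """
    if contig_length <= 0:
        raise ValidationError(f"{contig_id}: non-positive contig length")
    spans = []
    for p in placements:
        if p.end > contig_length:
            raise ValidationError(
                f"{p.contig_id}: span end {p.end} exceeds contig length "
                f"{contig_length}"
            )
        spans.append((p.start, p.end))
        if not contig_id:
            contig_id = p.contig_id
    if not spans:
        return CoverageRow(contig_id, sample_id, 0.0, 0.0, 0)
    spans.sort()
    union = 0
    cur_s, cur_e = spans[0]
    for s, e in spans[1:]:
        if s <= cur_e + 1:
            cur_e = max(cur_e, e)
        else:
            union += cur_e - cur_s + 1
            cur_s, cur_e = s, e
    union += cur_e - cur_s + 1
    total = sum(e - s + 1 for s, e in spans)
    return CoverageRow(
        contig_id,
        sample_id,
        mean_depth=total / contig_length,
        covered_fraction=union / contig_length,
        read_count=len(spans),
    )


# ---------------------------------------------------------------------------
# Matrix construction
# ---------------------------------------------------------------------------

_ANNOTATION_FIELDS = [
    "sample_id", "is_provirus", "parent_contig_id", "region", "length",
    "virus_score", "n_hallmarks", "n_genes", "viral_genes", "host_genes",
    "quality", "completeness", "taxonomy", "genome_type", "host_domain",
    "round",
]


def build_matrix(
    coverage_rows: Iterable[CoverageRow],
    votu_records: Sequence[DetectionRecord],
) -> pd.DataFrame:
    """Assemble a complete (representative x sample) abundance matrix.

    Rows are the vOTU representatives (annotation columns joined from
    their detection records); for each sample there are mean-depth,
    covered-fraction and read-count columns.  Cells with no observation
    are 0.  Coverage rows naming an unknown representative are skipped
    with a warning; duplicate (contig, sample) observations are a hard
    error.
    """
    reps = {r.contig_id: r for r in votu_records}
    if len(reps) != len(votu_records):
        raise ValidationError("duplicate representative ids in vOTU table")

    cells: dict[tuple[str, str], CoverageRow] = {}
    samples: set[str] = set()
    for row in coverage_rows:
        if row.contig_id not in reps:
            warnings.warn(
                f"coverage row for unknown representative {row.contig_id!r}; skipped"
            )
            continue
        key = (row.contig_id, row.sample_id)
        if key in cells:
            raise ValidationError(
                f"duplicate coverage row for {row.contig_id!r} in sample "
                f"{row.sample_id!r}"
            )
        cells[key] = row
        samples.add(row.sample_id)

    sample_order = sorted(samples)
    index = sorted(reps)
    data: dict[str, list] = {}
    for f in _ANNOTATION_FIELDS:
        col = []
        for cid in index:
            v = getattr(reps[cid], f)
            if f == "region":
                col.append(_fmt_region(v))
            elif f in ("sample_id", "taxonomy"):
                col.append(v or NA)
            else:
                col.append(_fmt_opt(v))
        data[f] = col
    for s in sample_order:
        data[f"{s}{DEPTH_SUFFIX}"] = [
            cells[(cid, s)].mean_depth if (cid, s) in cells else 0.0
            for cid in index
        ]
        data[f"{s}{CF_SUFFIX}"] = [
            cells[(cid, s)].covered_fraction if (cid, s) in cells else 0.0
            for cid in index
        ]
        data[f"{s}{READS_SUFFIX}"] = [
            cells[(cid, s)].read_count if (cid, s) in cells else 0
            for cid in index
        ]
    df = pd.DataFrame(data, index=pd.Index(index, name="contig_id"))
    return df


def matrix_samples(matrix: pd.DataFrame) -> list[str]:
    """Sample names present in a matrix, from its depth-column suffixes."""
    return sorted(
        c[: -len(DEPTH_SUFFIX)] for c in matrix.columns if c.endswith(DEPTH_SUFFIX)
    )


def apply_horizontal_coverage(
    matrix: pd.DataFrame,
    thresholds: Sequence[float] = (0.1, 0.5, 0.9),
) -> dict[float, pd.DataFrame]:
    """Per threshold t: zero abundance where covered fraction < t, then
    drop rows left with no non-zero abundance.  The input is untouched.
    """
    for t in thresholds:
        if not 0.0 <= t <= 1.0:
            raise ConfigError(f"covered-fraction threshold {t} outside [0, 1]")
    samples = matrix_samples(matrix)
    out: dict[float, pd.DataFrame] = {}
    for t in thresholds:
        m = matrix.copy()
        for s in samples:
            mask = m[f"{s}{CF_SUFFIX}"] < t
            m.loc[mask, f"{s}{DEPTH_SUFFIX}"] = 0.0
            m.loc[mask, f"{s}{READS_SUFFIX}"] = 0
        depth_cols = [f"{s}{DEPTH_SUFFIX}" for s in samples]
        if depth_cols:
            m = m.loc[(m[depth_cols] != 0).any(axis=1)]
        out[t] = m
    return out


def apply_sequence_filter(
    records: Iterable[DetectionRecord],
    mode: str = "conservative",
    min_viral_genes: int = 1,
    max_host_viral_ratio: float = 1.0,
) -> list[DetectionRecord]:
    """Final sequence-quality filter ahead of the abundance table.

    ``conservative``: keep iff length > 5000, or length > 1000 and quality
    in {Complete, High-quality, Medium-quality} (both comparisons strict).
    ``relaxed``: re-apply the gene-content filters only.
    """
    records = list(records)
    if mode == "conservative":
        return [
            r for r in records
            if r.length > 5000 or (r.length > 1000 and r.quality in GOOD_QUALITY)
        ]
    if mode == "relaxed":
        kept, _ = apply_gene_filters(records, min_viral_genes, max_host_viral_ratio)
        return kept
    raise ConfigError(f"unknown filtration mode {mode!r}")


# ---------------------------------------------------------------------------
# Matrix I/O (plain TSV with the index as first column)
# ---------------------------------------------------------------------------

def write_matrix(matrix: pd.DataFrame, path) -> None:
    out = matrix.copy()
    # repr-format floats so a read-back parses to identical values
    for c in out.columns:
        if out[c].dtype.kind == "f":
            out[c] = out[c].map(repr)
    out.to_csv(path, sep="\t", lineterminator="\n")


def read_matrix(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0, keep_default_na=False, dtype=str)
    for c in df.columns:
        if c.endswith(DEPTH_SUFFIX) or c.endswith(CF_SUFFIX):
            df[c] = df[c].astype(float)
        elif c.endswith(READS_SUFFIX):
            df[c] = df[c].astype(int)
    return df
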