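"""Post-detection processing of predicted viral and proviral contigs.

After an assembly has been screened by a virus detector and its predictions
scored by a genome-quality tool, several bespoke steps remain before the
contigs are usable: sample-prefixing of headers so ids stay unique across
assemblies, a minimum-size pre-filter, score/length/hallmark presets that
gate what counts as a confident virus, inference of genome type and host
domain from the taxonomic lineage, and — crucially — reconciliation of
proviruses.  A provirus predicted inside a host contig is trimmed to its
viral region and re-scored in a second detection round, so that every
metric reflects the viral region only; this module substitutes those
round-2 records for their round-1 parents.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional

import yaml

from .tables_io import (
    ConfigError,
    ContigSeq,
    DetectionRecord,
    GENOME_TYPES,
    HOST_DOMAINS,
    ValidationError,
)

PREFIX_SEP = "__"


# ---------------------------------------------------------------------------
# Header prefixing and size pre-filter
# ---------------------------------------------------------------------------

def prefix_headers(
    contigs: Iterable[ContigSeq], sample_id: str, enabled: bool = True
) -> list[ContigSeq]:
    """Prefix contig ids with ``<sample_id>__`` so ids are unique per run.

    Idempotent: an id already carrying the prefix is left untouched.  With
    ``enabled=False`` ids pass through unchanged.  Duplicate ids in the
    result are a hard error either way.
    """
    if not sample_id or PREFIX_SEP in sample_id:
        raise ValidationError(
            f"sample_id must be non-empty and must not contain {PREFIX_SEP!r}: "
            f"{sample_id!r}"
        )
    out: list[ContigSeq] = []
    for c in contigs:
        if enabled and not c.contig_id.startswith(sample_id + PREFIX_SEP):
            new_id = f"{sample_id}{PREFIX_SEP}{c.contig_id}"
        else:
            new_id = c.contig_id
        out.append(ContigSeq(new_id, c.sequence, sample_id=sample_id))
    ids = [c.contig_id for c in out]
    dupes = sorted({i for i in ids if ids.count(i) > 1})
    if dupes:
        raise ValidationError(f"duplicate contig ids after prefixing: {dupes}")
    return out


def filter_min_seq_size(contigs: Iterable[ContigSeq], min_len: int) -> list[ContigSeq]:
    """Keep contigs with ``length >= min_len`` (inclusive), order preserved."""
    if min_len < 0:
        raise ConfigError(f"min_len must be >= 0, got {min_len}")
    return [c for c in contigs if c.length >= min_len]


# ---------------------------------------------------------------------------
# Score presets
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FilterPreset:
    """Thresholds gating confident virus classification.

    All three comparisons are inclusive (``>=``): virus score, sequence
    length in bp, and the number of virus hallmark genes.
    """

    name: str
    min_score: float
    min_length: int
    min_hallmarks: int


CONSERVATIVE = FilterPreset("conservative", 0.8, 2500, 1)
RELAXED = FilterPreset("relaxed", 0.7, 2500, 0)

PRESETS = {"conservative": CONSERVATIVE, "relaxed": RELAXED}


def passes_preset(record: DetectionRecord, preset: FilterPreset) -> bool:
    """True iff score, length and hallmark count all meet the preset.

    For proviruses the length tested is the trimmed-region length carried
    by the record, so host sequence never inflates the test.  A missing
    score or hallmark count is a hard error — a record must never pass
    silently.
    """
    if record.virus_score is None:
        raise ValidationError(f"{record.contig_id}: virus_score missing")
    if record.n_hallmarks is None:
        raise ValidationError(f"{record.contig_id}: n_hallmarks missing")
    if record.length <= 0:
        raise ValidationError(f"{record.contig_id}: length missing")
    return (
        record.virus_score >= preset.min_score
        and record.length >= preset.min_length
        and record.n_hallmarks >= preset.min_hallmarks
    )


# ---------------------------------------------------------------------------
# Genome type and host domain from taxonomy
# ---------------------------------------------------------------------------

# Bundled default: taxon name -> (genome type, host domain).  Lineages are
# scanned right-to-left (most specific rank first), so a class-level entry
# like Caudoviricetes wins over its realm.  User-overridable via a YAML map.
DEFAULT_TAXON_MAP: dict[str, tuple[str, str]] = {
    "Caudoviricetes": ("dsDNA", "prokaryotic"),
    "Microviridae": ("ssDNA", "prokaryotic"),
    "Inoviridae": ("ssDNA", "prokaryotic"),
    "Tectiviridae": ("dsDNA", "prokaryotic"),
    "Corticoviridae": ("dsDNA", "prokaryotic"),
    "Nucleocytoviricota": ("dsDNA", "eukaryotic"),
    "Herviviricetes": ("dsDNA", "eukaryotic"),
    "Cressdnaviricota": ("ssDNA", "eukaryotic"),
    "Riboviria": ("RNA", "unknown"),
    "Duplodnaviria": ("dsDNA", "unknown"),
    "Monodnaviria": ("ssDNA", "unknown"),
}


def load_taxon_map(path: str | Path) -> dict[str, tuple[str, str]]:
    """Load a taxon -> (genome_type, host_domain) map from a YAML file.

    Accepted per-taxon forms: a two-element list ``[dsDNA, prokaryotic]``
    or a mapping ``{genome_type: ..., host_domain: ...}``.
    """
    try:
        with open(path) as fh:
            raw = yaml.safe_load(fh)
    except yaml.YAMLError as exc:
        raise ConfigError(f"malformed taxon map {path}: {exc}") from exc
    if not isinstance(raw, dict):
        raise ConfigError(f"taxon map {path} must be a mapping of taxon names")
    out: dict[str, tuple[str, str]] = {}
    for taxon, value in raw.items():
        if isinstance(value, dict):
            gt = value.get("genome_type")
            hd = value.get("host_domain")
        elif isinstance(value, (list, tuple)) and len(value) == 2:
            gt, hd = value
        else:
            raise ConfigError(f"taxon map entry {taxon!r}: unrecognised form")
        if gt not in GENOME_TYPES or hd not in HOST_DOMAINS:
            raise ConfigError(
                f"taxon map entry {taxon!r}: genome_type must be one of "
                f"{GENOME_TYPES} and host_domain one of {HOST_DOMAINS}"
            )
        out[str(taxon)] = (gt, hd)
    return out


def infer_genome_type(
    taxonomy: str,
    mapping: Optional[Mapping[str, tuple[str, str]]] = None,
) -> tuple[str, str]:
    """Infer (genome_type, host_domain) from a semicolon-delimited lineage.

    The lineage is scanned right-to-left so the most specific mapped rank
    wins; no match yields ("unknown", "unknown").
    """
    if mapping is None:
        mapping = DEFAULT_TAXON_MAP
    for rank in reversed([r.strip() for r in taxonomy.split(";") if r.strip()]):
        if rank in mapping:
            return mapping[rank]
    return ("unknown", "unknown")


def annotate_genome_types(
    records: Iterable[DetectionRecord],
    mapping: Optional[Mapping[str, tuple[str, str]]] = None,
) -> list[DetectionRecord]:
    """Fill genome_type/host_domain on every record from its taxonomy."""
    out = []
    for r in records:
        gt, hd = infer_genome_type(r.taxonomy, mapping)
        r.genome_type, r.host_domain = gt, hd
        out.append(r)
    return out


# ---------------------------------------------------------------------------
# Two-round provirus reconciliation
# ---------------------------------------------------------------------------

def reconcile_provirus_rounds(
    round1: Iterable[DetectionRecord],
    round2: Iterable[DetectionRecord],
) -> list[DetectionRecord]:
    """Substitute re-scored trimmed provirus records for their parents.

    Output = round-1 records with no round-2 child, plus all round-2
    records.  A parent with k >= 1 children contributes exactly its k
    children and is itself dropped, so counts obey n1 - p + k where p is
    the number of parents.  Round-2 ids are normalised to
    ``<parent>|provirus_<start>_<end>`` with the region taken on the
    round-1 parent.  Records that are not parents — in particular every
    plain (non-provirus) virus — pass through untouched.
    """
    round1 = list(round1)
    round2 = list(round2)
    by_id = {r.contig_id: r for r in round1}
    # a round-1 provirus record already named <parent>|provirus_<s>_<e> is
    # also addressable by its parent contig id
    by_parent: dict[str, list[DetectionRecord]] = {}
    for r in round1:
        if r.is_provirus and r.parent_contig_id is not None:
            by_parent.setdefault(r.parent_contig_id, []).append(r)

    children_of: dict[str, list[DetectionRecord]] = {}
    out_children: list[DetectionRecord] = []
    for child in round2:
        if child.round != 2:
            child.round = 2
        if child.parent_contig_id is None or child.region is None:
            raise ValidationError(
                f"{child.contig_id}: round-2 record lacks parent or region"
            )
        s, e = child.region
        normalized_id = f"{child.parent_contig_id}|provirus_{s}_{e}"
        if normalized_id in by_id:  # re-scored round-1 provirus, same region
            replaced = by_id[normalized_id]
        elif child.parent_contig_id in by_id:  # untrimmed round-1 parent
            replaced = by_id[child.parent_contig_id]
        elif child.parent_contig_id in by_parent:  # re-trimmed, new region
            replaced = by_parent[child.parent_contig_id][0]
        else:
            raise ValidationError(
                f"{child.contig_id}: orphan round-2 record — parent "
                f"{child.parent_contig_id!r} not in round 1"
            )
        child.contig_id = normalized_id
        if not child.sample_id:
            child.sample_id = replaced.sample_id
        children_of.setdefault(replaced.contig_id, []).append(child)
        out_children.append(child)

    for parent_id, kids in children_of.items():
        spans = sorted(k.region for k in kids)
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            if s2 <= e1:
                warnings.warn(
                    f"{parent_id}: overlapping trimmed regions "
                    f"({s1}-{e1}, {s2}-{e2}); both kept"
                )

    kept = [r for r in round1 if r.contig_id not in children_of]
    return kept + out_children


def merge_virus_provirus(
    records: Iterable[DetectionRecord],
    contigs: Mapping[str, ContigSeq],
) -> tuple[list[DetectionRecord], list[ContigSeq]]:
    """Pair every record with its sequence; sort by (sample, contig_id).

    Provirus sequences are the extracted parent subsequence at the record's
    region (1-based inclusive).  The returned table and sequence list carry
    identical id sets in identical order; any record without an obtainable
    sequence is a hard error.
    """
    paired: list[tuple[DetectionRecord, ContigSeq]] = []
    for r in records:
        if r.is_provirus:
            parent = contigs.get(r.parent_contig_id)
            if parent is None:
                raise ValidationError(
                    f"{r.contig_id}: parent sequence {r.parent_contig_id!r} missing"
                )
            s, e = r.region
            if e > parent.length:
                raise ValidationError(
                    f"{r.contig_id}: region end {e} exceeds parent length "
                    f"{parent.length}"
                )
            seq = parent.sequence[s - 1 : e]
            paired.append(
                (r, ContigSeq(r.contig_id, seq, sample_id=r.sample_id))
            )
        else:
            c = contigs.get(r.contig_id)
            if c is None:
                raise ValidationError(f"{r.contig_id}: sequence missing")
            paired.append(
                (r, ContigSeq(r.contig_id, c.sequence, sample_id=r.sample_id))
            )
    paired.sort(key=lambda rc: (rc[0].sample_id, rc[0].contig_id))
    return [r for r, _ in paired], [c for _, c in paired]
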