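"""Typed I/O for every tabular and sequence format the pipeline touches.

The pipeline consumes and produces a small set of plain-text formats:
multi-record FASTA, virus-detector summary tables (geNomad-style),
genome-quality tables (CheckV-style), BLAST tabular (outfmt 6) alignments,
and per-sample coverage tables.  Each format maps onto a frozen record
type with validated invariants; parsing is strict — malformed input raises
a typed error rather than being silently coerced.

Conventions fixed here and used everywhere downstream:

* all coordinates are 1-based inclusive (BLAST / detector convention);
  conversion to half-open intervals happens only inside interval algebra;
* the missing-value token in every written table is ``"NA"``;
* tables are tab-separated, UTF-8, ``"\\n"`` newlines, with a header row
  (except BLAST tabular, which by convention has none);
* CheckV-style quality tiers are normalised to the five canonical strings.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


# ---------------------------------------------------------------------------
# Errors
# ---------------------------------------------------------------------------

class ViropostError(Exception):
    """Base class for all errors raised by this package."""


class SchemaError(ViropostError):
    """A table is missing required columns or has an unknown schema."""


class ValidationError(ViropostError):
    """A record violates a declared invariant, or an input is malformed."""


class ConfigError(ViropostError):
    """A parameter or configuration file is invalid."""


# ---------------------------------------------------------------------------
# Controlled vocabularies
# ---------------------------------------------------------------------------

NA = "NA"

QUALITY_TIERS = (
    "Complete",
    "High-quality",
    "Medium-quality",
    "Low-quality",
    "Not-determined",
)

TOPOLOGIES = ("linear", "provirus", "circular-DTR", "circular-ITR", "unknown")

GENOME_TYPES = ("dsDNA", "ssDNA", "RNA", "unknown")

HOST_DOMAINS = ("prokaryotic", "eukaryotic", "unknown")

# IUPAC nucleotide codes, both cases, plus gap-free N runs.
_IUPAC = set("ACGTUNRYSWKMBDHV")
_IUPAC |= {c.lower() for c in _IUPAC}

# geNomad-style topology strings mapped onto the canonical vocabulary.
_TOPOLOGY_ALIASES = {
    "linear": "linear",
    "no terminal repeats": "linear",
    "provirus": "provirus",
    "dtr": "circular-DTR",
    "circular-dtr": "circular-DTR",
    "itr": "circular-ITR",
    "circular-itr": "circular-ITR",
    "unknown": "unknown",
}

_QUALITY_CANON = {t.lower(): t for t in QUALITY_TIERS}


def normalize_quality(value: str) -> str:
    """Map a quality-tier string onto the five canonical tiers.

    Matching is case-insensitive and tolerant of ``_`` / space in place of
    ``-``.  Unknown strings map to ``Not-determined`` with a warning.
    """
    key = str(value).strip().lower().replace("_", "-").replace(" ", "-")
    if key in _QUALITY_CANON:
        return _QUALITY_CANON[key]
    warnings.warn(
        f"unknown quality tier {value!r}; mapped to Not-determined", stacklevel=2
    )
    return "Not-determined"


def normalize_topology(value: str) -> str:
    key = str(value).strip().lower()
    if key in _TOPOLOGY_ALIASES:
        return _TOPOLOGY_ALIASES[key]
    raise ValidationError(f"unknown topology {value!r}")


# ---------------------------------------------------------------------------
# Record types
# ---------------------------------------------------------------------------

@dataclass
class ContigSeq:
    """A single assembled contig (or extracted provirus region)."""

    contig_id: str
    sequence: str
    sample_id: str = ""
    length: int = field(init=False)

    def __post_init__(self) -> None:
        if not self.contig_id or re.search(r"\s", self.contig_id):
            raise ValidationError(
                f"contig_id must be non-empty and whitespace-free: {self.contig_id!r}"
            )
        if not self.sequence:
            raise ValidationError(f"empty sequence for contig {self.contig_id!r}")
        bad = set(self.sequence) - _IUPAC
        if bad:
            raise ValidationError(
                f"contig {self.contig_id!r} contains non-IUPAC characters: "
                f"{sorted(bad)!r}"
            )
        self.length = len(self.sequence)


@dataclass
class GenomadRow:
    """One row of a geNomad-style virus summary table."""

    contig_id: str
    length: int
    topology: str = "unknown"
    provirus_coords: Optional[tuple[int, int]] = None
    n_genes: int = 0
    virus_score: float = 0.0
    n_hallmarks: int = 0
    taxonomy: str = ""

    def __post_init__(self) -> None:
        self.topology = normalize_topology(self.topology)
        if not 0.0 <= self.virus_score <= 1.0:
            raise ValidationError(
                f"{self.contig_id}: virus_score {self.virus_score} outside [0, 1]"
            )
        if self.n_genes < 0 or self.n_hallmarks < 0:
            raise ValidationError(f"{self.contig_id}: negative gene counts")
        if self.n_hallmarks > self.n_genes:
            raise ValidationError(
                f"{self.contig_id}: n_hallmarks ({self.n_hallmarks}) exceeds "
                f"n_genes ({self.n_genes})"
            )
        if self.length <= 0:
            raise ValidationError(f"{self.contig_id}: non-positive length")
        if (self.topology == "provirus") != (self.provirus_coords is not None):
            raise ValidationError(
                f"{self.contig_id}: provirus_coords must be present iff "
                f"topology is 'provirus'"
            )
        if self.provirus_coords is not None:
            s, e = self.provirus_coords
            if not 1 <= s < e:
                raise ValidationError(
                    f"{self.contig_id}: bad provirus coordinates ({s}, {e})"
                )


@dataclass
class CheckVRow:
    """One row of a CheckV-style quality summary table."""

    contig_id: str
    contig_length: int
    gene_count: int = 0
    viral_genes: int = 0
    host_genes: int = 0
    quality: str = "Not-determined"
    completeness: Optional[float] = None
    provirus_flag: bool = False
    trimmed_region: Optional[tuple[int, int]] = None

    def __post_init__(self) -> None:
        self.quality = normalize_quality(self.quality)
        if min(self.gene_count, self.viral_genes, self.host_genes) < 0:
            raise ValidationError(f"{self.contig_id}: negative gene counts")
        if self.viral_genes + self.host_genes > self.gene_count:
            raise ValidationError(
                f"{self.contig_id}: viral_genes + host_genes exceeds gene_count"
            )
        if self.completeness is not None and not 0.0 <= self.completeness <= 100.0:
            raise ValidationError(
                f"{self.contig_id}: completeness {self.completeness} outside [0, 100]"
            )
        if self.trimmed_region is not None and not self.provirus_flag:
            raise ValidationError(
                f"{self.contig_id}: trimmed_region present without provirus flag"
            )


@dataclass
class AlignmentRow:
    """One local nucleotide alignment, BLAST tabular (outfmt 6) convention.

    ``t_start > t_end`` is permitted and means a reverse-strand hit;
    coordinate normalisation happens inside the pairwise-identity step.
    """

    query_id: str
    target_id: str
    pident: float
    aln_len: int
    mismatches: int = 0
    gap_opens: int = 0
    q_start: int = 1
    q_end: int = 1
    t_start: int = 1
    t_end: int = 1
    evalue: float = 0.0
    bitscore: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.pident <= 100.0:
            raise ValidationError(
                f"{self.query_id}/{self.target_id}: pident outside [0, 100]"
            )
        if self.aln_len <= 0:
            raise ValidationError(
                f"{self.query_id}/{self.target_id}: non-positive alignment length"
            )
        if self.evalue < 0:
            raise ValidationError(
                f"{self.query_id}/{self.target_id}: negative e-value"
            )


@dataclass
class CoverageRow:
    """Per-(contig, sample) coverage statistics."""

    contig_id: str
    sample_id: str
    mean_depth: float
    covered_fraction: float
    read_count: int

    def __post_init__(self) -> None:
        if self.mean_depth < 0 or self.read_count < 0:
            raise ValidationError(f"{self.contig_id}: negative coverage values")
        if not 0.0 <= self.covered_fraction <= 1.0:
            raise ValidationError(
                f"{self.contig_id}: covered_fraction {self.covered_fraction} "
                f"outside [0, 1]"
            )


@dataclass
class Placement:
    """A single aligned read span on a contig (1-based inclusive)."""

    contig_id: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not 1 <= self.start <= self.end:
            raise ValidationError(
                f"{self.contig_id}: bad placement span ({self.start}, {self.end})"
            )


@dataclass
class DetectionRecord:
    """A predicted viral or proviral contig with detector and quality
    metrics joined.

    ``round`` distinguishes the initial detection pass (1) from the
    re-scoring pass run on trimmed provirus regions (2); round-2 records
    are always proviruses and their metrics describe only the trimmed
    region, never host sequence.
    """

    contig_id: str
    sample_id: str = ""
    is_provirus: bool = False
    parent_contig_id: Optional[str] = None
    region: Optional[tuple[int, int]] = None
    length: int = 0
    virus_score: Optional[float] = None
    n_hallmarks: Optional[int] = None
    n_genes: Optional[int] = None
    viral_genes: Optional[int] = None
    host_genes: Optional[int] = None
    quality: str = "Not-determined"
    completeness: Optional[float] = None
    taxonomy: str = ""
    genome_type: str = "unknown"
    host_domain: str = "unknown"
    round: int = 1

    def __post_init__(self) -> None:
        self.quality = normalize_quality(self.quality)
        if self.genome_type not in GENOME_TYPES:
            raise ValidationError(f"{self.contig_id}: bad genome_type")
        if self.host_domain not in HOST_DOMAINS:
            raise ValidationError(f"{self.contig_id}: bad host_domain")
        if self.round not in (1, 2):
            raise ValidationError(f"{self.contig_id}: round must be 1 or 2")
        if self.round == 2 and not self.is_provirus:
            raise ValidationError(
                f"{self.contig_id}: round-2 records must be proviruses"
            )
        if self.is_provirus:
            if self.parent_contig_id is None or self.region is None:
                raise ValidationError(
                    f"{self.contig_id}: provirus requires parent_contig_id and region"
                )
            s, e = self.region
            if not 1 <= s < e:
                raise ValidationError(f"{self.contig_id}: bad region ({s}, {e})")
            if self.length != e - s + 1:
                raise ValidationError(
                    f"{self.contig_id}: length {self.length} != region span {e - s + 1}"
                )


@dataclass
class PairwiseANI:
    """Merged global identity between one sequence pair.

    ``ani`` is the alignment-length-weighted mean percent identity over all
    local alignments of the pair; ``qcov``/``tcov`` are the fractions of the
    query/target covered by the union of aligned intervals.
    """

    query_id: str
    target_id: str
    n_alns: int
    ani: float
    qcov: float
    tcov: float

    def __post_init__(self) -> None:
        if self.n_alns < 1:
            raise ValidationError("PairwiseANI requires at least one alignment")
        if not 0.0 <= self.ani <= 100.0:
            raise ValidationError(f"ani {self.ani} outside [0, 100]")
        for name, v in (("qcov", self.qcov), ("tcov", self.tcov)):
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} {v} outside [0, 1]")
        if self.query_id == self.target_id:
            raise ValidationError("self-pairs are excluded from PairwiseANI")


@dataclass
class VOTUCluster:
    """A species-level cluster: representative plus members.

    ``member_stats`` maps every member id (including the representative)
    to its (ani, af) versus the representative.
    """

    representative_id: str
    member_ids: list[str]
    member_stats: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.representative_id not in self.member_ids:
            raise ValidationError("representative must be among member_ids")
        if len(set(self.member_ids)) != len(self.member_ids):
            raise ValidationError("duplicate member ids in cluster")


@dataclass
class BinRecord:
    """A viral genome bin: ordered member contigs plus quality metrics."""

    bin_id: str
    member_contig_ids: list[str]
    protein_redundancy: int = 0
    length: int = 0
    quality: str = "Not-determined"

    def __post_init__(self) -> None:
        if len(self.member_contig_ids) < 2:
            raise ValidationError(
                f"bin {self.bin_id}: a viral bin needs at least two members"
            )
        if len(set(self.member_contig_ids)) != len(self.member_contig_ids):
            raise ValidationError(f"bin {self.bin_id}: duplicate members")
        if self.protein_redundancy < 0:
            raise ValidationError(f"bin {self.bin_id}: negative protein redundancy")
        self.quality = normalize_quality(self.quality)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path, sample_id: str = "") -> list[ContigSeq]:
    """Read a FASTA file into :class:`ContigSeq` records, in file order.

    The header token before the first whitespace becomes ``contig_id``.
    Duplicate ids and empty sequences are hard errors; content that is not
    FASTA raises a parse error naming the offending line.
    """
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"FASTA file not found: {path}")
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            if not line.startswith(">"):
                raise ValidationError(
                    f"{path}: not FASTA — line {lineno} does not start a record"
                )
            break
        else:
            raise ValidationError(f"{path}: empty FASTA file")
    records: list[ContigSeq] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        contig_id = rec.id
        if contig_id in seen:
            raise ValidationError(f"{path}: duplicate contig id {contig_id!r}")
        seen.add(contig_id)
        seq = str(rec.seq)
        if not seq:
            raise ValidationError(f"{path}: empty sequence for {contig_id!r}")
        records.append(ContigSeq(contig_id, seq, sample_id=sample_id))
    return records


def write_fasta(contigs: Iterable[ContigSeq], path: str | Path, width: int = 70) -> None:
    """Write contigs as wrapped FASTA (deterministic byte layout)."""
    seq_records = [
        SeqRecord(Seq(c.sequence), id=c.contig_id, description="") for c in contigs
    ]
    with open(path, "w", newline="\n") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seq_records)


# ---------------------------------------------------------------------------
# Cell (de)serialisation helpers
# ---------------------------------------------------------------------------

def _fmt_region(v: Optional[tuple[int, int]]) -> str:
    return NA if v is None else f"{v[0]}-{v[1]}"


def _parse_region(s: str) -> Optional[tuple[int, int]]:
    if s in ("", NA):
        return None
    m = re.fullmatch(r"(\d+)\s*-\s*(\d+)", s.strip())
    if not m:
        raise ValidationError(f"cannot parse coordinate range {s!r}")
    return int(m.group(1)), int(m.group(2))


def _fmt_opt(v) -> str:
    if v is None:
        return NA
    if isinstance(v, bool):
        return "True" if v else "False"
    if isinstance(v, float):
        return repr(v)
    return str(v)


def _parse_bool(s: str) -> bool:
    key = s.strip().lower()
    if key in ("true", "yes", "1"):
        return True
    if key in ("false", "no", "0", "", "na"):
        return False
    raise ValidationError(f"cannot parse boolean {s!r}")


def _opt(s: str, conv):
    return None if s in ("", NA) else conv(s)


# ---------------------------------------------------------------------------
# Schemas: canonical column order + converters, and accepted header aliases
# ---------------------------------------------------------------------------

GENOMAD_COLUMNS = [
    "contig_id", "length", "topology", "provirus_coords",
    "n_genes", "virus_score", "n_hallmarks", "taxonomy",
]
GENOMAD_ALIASES = {
    "contig_id": ("contig_id", "seq_name"),
    "length": ("length",),
    "topology": ("topology",),
    "provirus_coords": ("provirus_coords", "coordinates"),
    "n_genes": ("n_genes", "genes"),
    "virus_score": ("virus_score", "score"),
    "n_hallmarks": ("n_hallmarks", "hallmarks"),
    "taxonomy": ("taxonomy",),
}
GENOMAD_REQUIRED = {"contig_id", "length", "topology", "n_genes",
                    "virus_score", "n_hallmarks"}

CHECKV_COLUMNS = [
    "contig_id", "contig_length", "gene_count", "viral_genes", "host_genes",
    "quality", "completeness", "provirus_flag", "trimmed_region",
]
CHECKV_ALIASES = {
    "contig_id": ("contig_id",),
    "contig_length": ("contig_length",),
    "gene_count": ("gene_count",),
    "viral_genes": ("viral_genes",),
    "host_genes": ("host_genes",),
    "quality": ("quality", "checkv_quality"),
    "completeness": ("completeness",),
    "provirus_flag": ("provirus_flag", "provirus"),
    "trimmed_region": ("trimmed_region",),
}
CHECKV_REQUIRED = {"contig_id", "contig_length", "gene_count",
                   "viral_genes", "host_genes", "quality"}

COVERAGE_COLUMNS = ["contig_id", "sample_id", "mean_depth",
                    "covered_fraction", "read_count"]
COVERAGE_ALIASES = {
    "contig_id": ("contig_id", "contig", "genome"),
    "sample_id": ("sample_id", "sample"),
    "mean_depth": ("mean_depth", "mean", "mean coverage", "depth"),
    "covered_fraction": ("covered_fraction", "covered fraction"),
    "read_count": ("read_count", "read count", "reads"),
}
COVERAGE_REQUIRED = {"contig_id", "mean_depth", "covered_fraction", "read_count"}

DETECTION_COLUMNS = [
    "contig_id", "sample_id", "is_provirus", "parent_contig_id", "region",
    "length", "virus_score", "n_hallmarks", "n_genes", "viral_genes",
    "host_genes", "quality", "completeness", "taxonomy", "genome_type",
    "host_domain", "round",
]

PLACEMENT_COLUMNS = ["contig_id", "start", "end"]

BIN_COLUMNS = ["bin_id", "members", "protein_redundancy", "length", "quality"]

PAIRWISE_COLUMNS = ["query_id", "target_id", "n_alns", "ani", "qcov", "tcov"]

BLAST6_COLUMNS = [
    "query_id", "target_id", "pident", "aln_len", "mismatches", "gap_opens",
    "q_start", "q_end", "t_start", "t_end", "evalue", "bitscore",
]


def _resolve_aliases(df: pd.DataFrame, aliases: dict, required: set,
                     what: str) -> pd.DataFrame:
    """Rename recognised columns to canonical names; check required set."""
    lower = {c.lower(): c for c in df.columns}
    rename = {}
    for canon, names in aliases.items():
        for name in names:
            if name.lower() in lower:
                rename[lower[name.lower()]] = canon
                break
    out = df.rename(columns=rename)
    missing = sorted(required - set(out.columns))
    if missing:
        raise SchemaError(f"{what}: missing required column(s): {', '.join(missing)}")
    return out


def _read_tsv(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"table not found: {path}")
    return pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)


# ---------------------------------------------------------------------------
# Table readers
# ---------------------------------------------------------------------------

def read_genomad_table(path: str | Path) -> list[GenomadRow]:
    """Parse a geNomad-style virus summary TSV (either header dialect)."""
    df = _resolve_aliases(_read_tsv(path), GENOMAD_ALIASES, GENOMAD_REQUIRED,
                          f"geNomad table {path}")
    rows = []
    for _, r in df.iterrows():
        rows.append(GenomadRow(
            contig_id=r["contig_id"],
            length=int(r["length"]),
            topology=r["topology"],
            provirus_coords=_parse_region(r.get("provirus_coords", NA)),
            n_genes=int(r["n_genes"]),
            virus_score=float(r["virus_score"]),
            n_hallmarks=int(r["n_hallmarks"]),
            taxonomy="" if r.get("taxonomy", "") in (NA,) else r.get("taxonomy", ""),
        ))
    return rows


def read_checkv_table(path: str | Path) -> list[CheckVRow]:
    """Parse a CheckV-style quality summary TSV (either header dialect)."""
    df = _resolve_aliases(_read_tsv(path), CHECKV_ALIASES, CHECKV_REQUIRED,
                          f"CheckV table {path}")
    rows = []
    for _, r in df.iterrows():
        rows.append(CheckVRow(
            contig_id=r["contig_id"],
            contig_length=int(r["contig_length"]),
            gene_count=int(r["gene_count"]),
            viral_genes=int(r["viral_genes"]),
            host_genes=int(r["host_genes"]),
            quality=r["quality"],
            completeness=_opt(r.get("completeness", NA), float),
            provirus_flag=_parse_bool(r.get("provirus_flag", "False")),
            trimmed_region=_parse_region(r.get("trimmed_region", NA)),
        ))
    return rows


def read_alignment_table(path: str | Path) -> list[AlignmentRow]:
    """Parse BLAST tabular (outfmt 6): 12 standard columns, no header."""
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"alignment table not found: {path}")
    rows: list[AlignmentRow] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 12:
                raise ValidationError(
                    f"{path}: line {lineno} has {len(parts)} columns, expected 12"
                )
            rows.append(AlignmentRow(
                query_id=parts[0], target_id=parts[1],
                pident=float(parts[2]), aln_len=int(parts[3]),
                mismatches=int(parts[4]), gap_opens=int(parts[5]),
                q_start=int(parts[6]), q_end=int(parts[7]),
                t_start=int(parts[8]), t_end=int(parts[9]),
                evalue=float(parts[10]), bitscore=float(parts[11]),
            ))
    return rows


def read_coverage_table(path: str | Path, sample_id: str = "") -> list[CoverageRow]:
    """Parse a per-sample coverage TSV (native or CoverM-style headers)."""
    df = _resolve_aliases(_read_tsv(path), COVERAGE_ALIASES, COVERAGE_REQUIRED,
                          f"coverage table {path}")
    rows = []
    for _, r in df.iterrows():
        rows.append(CoverageRow(
            contig_id=r["contig_id"],
            sample_id=r.get("sample_id", "") or sample_id,
            mean_depth=float(r["mean_depth"]),
            covered_fraction=float(r["covered_fraction"]),
            read_count=int(float(r["read_count"])),
        ))
    return rows


def read_detection_table(path: str | Path) -> list[DetectionRecord]:
    df = _read_tsv(path)
    missing = sorted(set(DETECTION_COLUMNS) - set(df.columns))
    if missing:
        raise SchemaError(
            f"detection table {path}: missing required column(s): {', '.join(missing)}"
        )
    rows = []
    for _, r in df.iterrows():
        rows.append(DetectionRecord(
            contig_id=r["contig_id"],
            sample_id="" if r["sample_id"] == NA else r["sample_id"],
            is_provirus=_parse_bool(r["is_provirus"]),
            parent_contig_id=_opt(r["parent_contig_id"], str),
            region=_parse_region(r["region"]),
            length=int(r["length"]),
            virus_score=_opt(r["virus_score"], float),
            n_hallmarks=_opt(r["n_hallmarks"], int),
            n_genes=_opt(r["n_genes"], int),
            viral_genes=_opt(r["viral_genes"], int),
            host_genes=_opt(r["host_genes"], int),
            quality=r["quality"],
            completeness=_opt(r["completeness"], float),
            taxonomy="" if r["taxonomy"] == NA else r["taxonomy"],
            genome_type=r["genome_type"],
            host_domain=r["host_domain"],
            round=int(r["round"]),
        ))
    return rows


def read_placement_table(path: str | Path) -> list[Placement]:
    df = _read_tsv(path)
    missing = sorted(set(PLACEMENT_COLUMNS) - set(df.columns))
    if missing:
        raise SchemaError(
            f"placement table {path}: missing required column(s): {', '.join(missing)}"
        )
    return [Placement(r["contig_id"], int(r["start"]), int(r["end"]))
            for _, r in df.iterrows()]


def read_bin_table(path: str | Path) -> list[BinRecord]:
    """Parse a bin summary TSV: bin_id, comma-separated members, redundancy."""
    df = _read_tsv(path)
    missing = sorted({"bin_id", "members", "protein_redundancy"} - set(df.columns))
    if missing:
        raise SchemaError(
            f"bin table {path}: missing required column(s): {', '.join(missing)}"
        )
    rows = []
    for _, r in df.iterrows():
        rows.append(BinRecord(
            bin_id=r["bin_id"],
            member_contig_ids=[m for m in r["members"].split(",") if m],
            protein_redundancy=int(r["protein_redundancy"]),
            length=int(r.get("length", "0") or 0),
            quality=r.get("quality", "Not-determined") or "Not-determined",
        ))
    return rows


def read_pairwise_table(path: str | Path) -> list[PairwiseANI]:
    df = _read_tsv(path)
    missing = sorted(set(PAIRWISE_COLUMNS) - set(df.columns))
    if missing:
        raise SchemaError(
            f"pairwise table {path}: missing required column(s): {', '.join(missing)}"
        )
    return [PairwiseANI(r["query_id"], r["target_id"], int(r["n_alns"]),
                        float(r["ani"]), float(r["qcov"]), float(r["tcov"]))
            for _, r in df.iterrows()]


# ---------------------------------------------------------------------------
# Joined read of detector + quality tables
# ---------------------------------------------------------------------------

_PROVIRUS_ID_RE = re.compile(r"^(?P<parent>.+)\|provirus_(?P<s>\d+)[_-](?P<e>\d+)$")


def parse_provirus_id(contig_id: str) -> Optional[tuple[str, int, int]]:
    """Decompose ``<parent>|provirus_<start>_<end>`` ids; None if not one."""
    m = _PROVIRUS_ID_RE.match(contig_id)
    if not m:
        return None
    return m.group("parent"), int(m.group("s")), int(m.group("e"))


def join_detection_rows(
    genomad_rows: Iterable[GenomadRow],
    checkv_rows: Iterable[CheckVRow],
    sample_id: str = "",
    round: int = 1,
) -> list[DetectionRecord]:
    """Inner-join detector rows and quality rows into DetectionRecords.

    Rows present in only one table are reported as warnings and excluded;
    a join producing zero rows is a hard error.  A row whose topology is
    ``provirus`` (with coordinates) becomes a provirus record with the id
    ``<parent>|provirus_<start>_<end>``; a row flagged as provirus by the
    quality table *with* a trimmed region does likewise.  A provirus flag
    without coordinates is kept as a plain (untrimmed) record with a
    warning — the trimmed-region metrics arrive with the round-2 child.
    """
    gen = {g.contig_id: g for g in genomad_rows}
    chk = {c.contig_id: c for c in checkv_rows}
    only_g = sorted(set(gen) - set(chk))
    only_c = sorted(set(chk) - set(gen))
    for cid in only_g:
        warnings.warn(f"{cid}: present only in detector table; excluded")
    for cid in only_c:
        warnings.warn(f"{cid}: present only in quality table; excluded")
    shared = [cid for cid in gen if cid in chk]
    if not shared:
        raise ValidationError(
            "join of detector and quality tables produced zero rows"
        )

    records = []
    for cid in shared:
        g, c = gen[cid], chk[cid]
        is_provirus = False
        parent = None
        region = None
        length = g.length
        contig_id = cid

        decomposed = parse_provirus_id(cid)
        if decomposed is not None:
            parent, s, e = decomposed
            is_provirus, region, length = True, (s, e), e - s + 1
        elif g.topology == "provirus":
            s, e = g.provirus_coords  # guaranteed by GenomadRow invariant
            parent, is_provirus, region = cid, True, (s, e)
            contig_id = f"{cid}|provirus_{s}_{e}"
            length = e - s + 1
        elif c.provirus_flag and c.trimmed_region is not None:
            s, e = c.trimmed_region
            parent, is_provirus, region = cid, True, (s, e)
            contig_id = f"{cid}|provirus_{s}_{e}"
            length = e - s + 1
        elif c.provirus_flag:
            warnings.warn(
                f"{cid}: provirus flag without trimmed coordinates; kept "
                f"untrimmed pending a second-round record"
            )

        if round == 2 and not is_provirus:
            raise ValidationError(
                f"{cid}: round-2 table row does not encode a provirus region"
            )

        records.append(DetectionRecord(
            contig_id=contig_id,
            sample_id=sample_id,
            is_provirus=is_provirus,
            parent_contig_id=parent,
            region=region,
            length=length,
            virus_score=g.virus_score,
            n_hallmarks=g.n_hallmarks,
            n_genes=g.n_genes,
            viral_genes=c.viral_genes,
            host_genes=c.host_genes,
            quality=c.quality,
            completeness=c.completeness,
            taxonomy=g.taxonomy,
            round=round,
        ))
    return records


def read_detection_tables(
    genomad_path: str | Path,
    checkv_path: str | Path,
    sample_id: str = "",
    round: int = 1,
) -> list[DetectionRecord]:
    """File-path front end to :func:`join_detection_rows`."""
    return join_detection_rows(
        read_genomad_table(genomad_path),
        read_checkv_table(checkv_path),
        sample_id=sample_id,
        round=round,
    )


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------

def _row_cells(row, schema_name: str) -> list[str]:
    if schema_name == "genomad":
        return [row.contig_id, str(row.length), row.topology,
                _fmt_region(row.provirus_coords), str(row.n_genes),
                repr(row.virus_score), str(row.n_hallmarks),
                row.taxonomy or NA]
    if schema_name == "checkv":
        return [row.contig_id, str(row.contig_length), str(row.gene_count),
                str(row.viral_genes), str(row.host_genes), row.quality,
                _fmt_opt(row.completeness), _fmt_opt(row.provirus_flag),
                _fmt_region(row.trimmed_region)]
    if schema_name == "alignment":
        return [row.query_id, row.target_id, repr(row.pident), str(row.aln_len),
                str(row.mismatches), str(row.gap_opens),
                str(row.q_start), str(row.q_end), str(row.t_start),
                str(row.t_end), repr(row.evalue), repr(row.bitscore)]
    if schema_name == "coverage":
        return [row.contig_id, row.sample_id or NA, repr(row.mean_depth),
                repr(row.covered_fraction), str(row.read_count)]
    if schema_name == "detection":
        return [row.contig_id, row.sample_id or NA, _fmt_opt(row.is_provirus),
                _fmt_opt(row.parent_contig_id), _fmt_region(row.region),
                str(row.length), _fmt_opt(row.virus_score),
                _fmt_opt(row.n_hallmarks), _fmt_opt(row.n_genes),
                _fmt_opt(row.viral_genes), _fmt_opt(row.host_genes),
                row.quality, _fmt_opt(row.completeness), row.taxonomy or NA,
                row.genome_type, row.host_domain, str(row.round)]
    if schema_name == "placement":
        return [row.contig_id, str(row.start), str(row.end)]
    if schema_name == "bin":
        return [row.bin_id, ",".join(row.member_contig_ids),
                str(row.protein_redundancy), str(row.length), row.quality]
    if schema_name == "pairwise_ani":
        return [row.query_id, row.target_id, str(row.n_alns), repr(row.ani),
                repr(row.qcov), repr(row.tcov)]
    raise SchemaError(f"unknown schema {schema_name!r}")


_SCHEMA_HEADERS = {
    "genomad": GENOMAD_COLUMNS,
    "checkv": CHECKV_COLUMNS,
    "alignment": None,  # outfmt 6: headerless by convention
    "coverage": COVERAGE_COLUMNS,
    "detection": DETECTION_COLUMNS,
    "placement": PLACEMENT_COLUMNS,
    "bin": BIN_COLUMNS,
    "pairwise_ani": PAIRWISE_COLUMNS,
}


def write_table(rows: Sequence, path: str | Path, schema_name: str) -> None:
    """Serialise homogeneous records to a TSV (or headerless BLAST tabular).

    Missing values are written as ``NA``; floats use ``repr`` so that a
    read-back parses to the identical value (round-trip fidelity).
    """
    if schema_name not in _SCHEMA_HEADERS:
        raise SchemaError(f"unknown schema {schema_name!r}")
    header = _SCHEMA_HEADERS[schema_name]
    with open(path, "w", newline="\n") as fh:
        if header is not None:
            fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(_row_cells(row, schema_name)) + "\n")


_SCHEMA_READERS = {
    "genomad": read_genomad_table,
    "checkv": read_checkv_table,
    "alignment": read_alignment_table,
    "coverage": read_coverage_table,
    "detection": read_detection_table,
    "placement": read_placement_table,
    "bin": read_bin_table,
    "pairwise_ani": read_pairwise_table,
}


def read_table(path: str | Path, schema_name: str):
    """Dispatch to the reader for ``schema_name`` (inverse of write_table)."""
    if schema_name not in _SCHEMA_READERS:
        raise SchemaError(f"unknown schema {schema_name!r}")
    return _SCHEMA_READERS[schema_name](path)
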