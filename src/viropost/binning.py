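"""Post-processing of viral genome bins (vBins).

A binner groups scaffolds into putative viral genomes; duplicated
("redundant") proteins within a bin signal contamination, so bins are
quality-filtered on protein redundancy: the conservative mode keeps bins
with fewer than two redundant proteins, the relaxed mode rejects only
bins with more than five.  Giant viruses (NCLDVs) legitimately carry
around ten redundant proteins, so an explicit per-bin override exempts
them rather than silently widening the rule.  Multi-scaffold bins are
concatenated with a 10-N linker so single-sequence quality tools can
score them, and kept bins are combined with the vOTUs that remained
unbinned into one abundance table.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .coverage import CF_SUFFIX, DEPTH_SUFFIX, READS_SUFFIX, matrix_samples
from .tables_io import (
    BinRecord,
    ConfigError,
    ContigSeq,
    NA,
    ValidationError,
)

N_LINKER = "N" * 10

REASON_REDUNDANCY = "protein_redundancy"

# Uncontaminated NCLDV bins can carry roughly this many redundant proteins.
NCLDV_MAX_REDUNDANCY = 10


def filter_bins(
    bins: Iterable[BinRecord],
    mode: str = "conservative",
    ncldv_bins: Optional[set[str]] = None,
) -> tuple[list[BinRecord], list[tuple[BinRecord, str]]]:
    """Partition bins into (kept, rejected-with-reason) on redundancy.

    conservative: keep iff protein_redundancy < 2 (i.e. 0 or 1);
    relaxed: keep iff protein_redundancy <= 5.  Bins named in
    ``ncldv_bins`` are instead kept up to a redundancy of
    ``NCLDV_MAX_REDUNDANCY`` in either mode.
    """
    if mode not in ("conservative", "relaxed"):
        raise ConfigError(f"unknown bin filtration mode {mode!r}")
    ncldv_bins = ncldv_bins or set()
    limit = 2 if mode == "conservative" else 6  # strict upper bound
    kept, rejected = [], []
    for b in bins:
        bound = NCLDV_MAX_REDUNDANCY + 1 if b.bin_id in ncldv_bins else limit
        if b.protein_redundancy < bound:
            kept.append(b)
        else:
            rejected.append((b, REASON_REDUNDANCY))
    return kept, rejected


def concatenate_bin(
    members: Sequence[ContigSeq],
    bin_id: str = "",
) -> ContigSeq:
    """Join a multi-scaffold bin's members with 10-N linkers.

    Members are joined in the order given (the membership-table order);
    the result's length is the sum of member lengths plus 10·(k − 1).
    A single-member bin is a hard error — it is not a multi-scaffold bin.
    """
    members = list(members)
    if len(members) < 2:
        raise ValidationError(
            f"bin {bin_id or '?'}: concatenation requires at least two members"
        )
    seq = N_LINKER.join(m.sequence for m in members)
    return ContigSeq(bin_id or members[0].contig_id, seq,
                     sample_id=members[0].sample_id)


def combine_vbins_unbinned(
    kept_bins: Sequence[BinRecord],
    matrix: pd.DataFrame,
    lengths: Mapping[str, int],
) -> pd.DataFrame:
    """One abundance table over kept bins plus unbinned representatives.

    Rows are the kept bins followed by every representative in ``matrix``
    that is not a member of any kept bin; no representative appears both
    inside a bin row and as an unbinned row.  A bin row's per-sample depth
    and covered fraction are the length-weighted means of its members'
    values, and its read count is their sum.  A representative claimed by
    two kept bins is a hard error.
    """
    claimed: dict[str, str] = {}
    for b in kept_bins:
        for m in b.member_contig_ids:
            if m in claimed:
                raise ValidationError(
                    f"representative {m!r} claimed by bins {claimed[m]!r} "
                    f"and {b.bin_id!r}"
                )
            if m not in matrix.index:
                raise ValidationError(
                    f"bin {b.bin_id!r}: member {m!r} is not a known representative"
                )
            if m not in lengths:
                raise ValidationError(f"no length for bin member {m!r}")
            claimed[m] = b.bin_id

    samples = matrix_samples(matrix)
    annotation_cols = [
        c for c in matrix.columns
        if not any(c.endswith(sfx) for sfx in (DEPTH_SUFFIX, CF_SUFFIX, READS_SUFFIX))
    ]

    bin_rows = []
    for b in kept_bins:
        weights = [lengths[m] for m in b.member_contig_ids]
        wtot = sum(weights)
        row: dict = {c: NA for c in annotation_cols}
        if "length" in row:
            row["length"] = str(
                sum(weights) + len(N_LINKER) * (len(b.member_contig_ids) - 1)
            )
        if "quality" in row:
            row["quality"] = b.quality
        for s in samples:
            depths = matrix.loc[b.member_contig_ids, f"{s}{DEPTH_SUFFIX}"]
            cfs = matrix.loc[b.member_contig_ids, f"{s}{CF_SUFFIX}"]
            reads = matrix.loc[b.member_contig_ids, f"{s}{READS_SUFFIX}"]
            row[f"{s}{DEPTH_SUFFIX}"] = float(
                sum(d * w for d, w in zip(depths, weights)) / wtot
            )
            row[f"{s}{CF_SUFFIX}"] = float(
                sum(c * w for c, w in zip(cfs, weights)) / wtot
            )
            row[f"{s}{READS_SUFFIX}"] = int(reads.sum())
        bin_rows.append(pd.Series(row, name=b.bin_id))

    unbinned = matrix.loc[[cid for cid in matrix.index if cid not in claimed]]
    if bin_rows:
        combined = pd.concat(
            [pd.DataFrame(bin_rows)[matrix.columns], unbinned], axis=0
        )
    else:
        combined = unbinned.copy()
    combined.index.name = matrix.index.name
    return combined
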