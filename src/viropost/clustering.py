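"""Species-level vOTU clustering from all-vs-all nucleotide alignments.

Viral contigs are dereplicated into viral operational taxonomic units
(vOTUs) at the community-standard species rank: average nucleotide
identity (ANI) >= 95% over an alignment fraction (AF) >= 85% of the
shorter sequence.  The procedure has two stages:

1. merge the local alignments (BLAST tabular) of each sequence pair into
   a single global estimate — ANI is the alignment-length-weighted mean of
   per-alignment percent identities, while the per-sequence aligned
   fractions are computed on the *union* of aligned intervals so that
   overlapping local alignments are not double-counted;
2. greedy centroid clustering — sequences are scanned longest-first, each
   unassigned sequence founds a cluster, and every later unassigned
   sequence meeting both thresholds against that representative joins it.

The representative of each vOTU is therefore always its longest member
(ties broken by lexicographically smallest id).
"""

from __future__ import annotations

from typing import Iterable, Mapping

from .tables_io import (
    AlignmentRow,
    ConfigError,
    ContigSeq,
    PairwiseANI,
    ValidationError,
    VOTUCluster,
)


# ---------------------------------------------------------------------------
# Interval algebra (half-open internally; inputs are 1-based inclusive)
# ---------------------------------------------------------------------------

def _union_length(intervals: list[tuple[int, int]]) -> int:
    """Total length covered by a set of 1-based inclusive intervals."""
    if not intervals:
        return 0
    intervals = sorted(intervals)
    total = 0
    cur_s, cur_e = intervals[0]
    for s, e in intervals[1:]:
        if s <= cur_e + 1:
            cur_e = max(cur_e, e)
        else:
            total += cur_e - cur_s + 1
            cur_s, cur_e = s, e
    total += cur_e - cur_s + 1
    return total


def _norm_span(a: int, b: int) -> tuple[int, int]:
    """Normalise a possibly reverse-strand span to (low, high)."""
    return (a, b) if a <= b else (b, a)


# ---------------------------------------------------------------------------
# Pairwise global ANI
# ---------------------------------------------------------------------------

def compute_pairwise_ani(
    alignments: Iterable[AlignmentRow],
    lengths: Mapping[str, int],
) -> list[PairwiseANI]:
    """Merge local alignments into one global record per sequence pair.

    Self-hits are removed.  When both orientations of a pair were emitted
    by the aligner, the orientation with the greater summed alignment
    length is kept (on a tie, the orientation whose query id sorts first).
    ANI is the alignment-length-weighted mean of ``pident``; qcov and tcov
    divide the union of aligned intervals by the declared sequence
    lengths.  Coordinates exceeding a declared length, or ids without a
    declared length, are hard errors.
    """
    groups: dict[tuple[str, str], list[AlignmentRow]] = {}
    for aln in alignments:
        if aln.query_id == aln.target_id:
            continue
        for sid in (aln.query_id, aln.target_id):
            if sid not in lengths:
                raise ValidationError(f"alignment references unknown id {sid!r}")
        qs, qe = _norm_span(aln.q_start, aln.q_end)
        ts, te = _norm_span(aln.t_start, aln.t_end)
        if qs < 1 or qe > lengths[aln.query_id]:
            raise ValidationError(
                f"{aln.query_id}: query span ({qs}, {qe}) exceeds declared "
                f"length {lengths[aln.query_id]}"
            )
        if ts < 1 or te > lengths[aln.target_id]:
            raise ValidationError(
                f"{aln.target_id}: target span ({ts}, {te}) exceeds declared "
                f"length {lengths[aln.target_id]}"
            )
        groups.setdefault((aln.query_id, aln.target_id), []).append(aln)

    # Resolve the two possible orientations of each unordered pair.
    chosen: dict[frozenset, tuple[str, str]] = {}
    for (q, t), alns in groups.items():
        key = frozenset((q, t))
        total = sum(a.aln_len for a in alns)
        if key not in chosen:
            chosen[key] = (q, t)
            continue
        cur = chosen[key]
        cur_total = sum(a.aln_len for a in groups[cur])
        if total > cur_total or (total == cur_total and (q, t) < cur):
            chosen[key] = (q, t)

    out: list[PairwiseANI] = []
    for q, t in sorted(chosen.values()):
        alns = groups[(q, t)]
        wsum = sum(a.pident * a.aln_len for a in alns)
        lsum = sum(a.aln_len for a in alns)
        q_ivs = [_norm_span(a.q_start, a.q_end) for a in alns]
        t_ivs = [_norm_span(a.t_start, a.t_end) for a in alns]
        out.append(PairwiseANI(
            query_id=q,
            target_id=t,
            n_alns=len(alns),
            ani=wsum / lsum,
            qcov=_union_length(q_ivs) / lengths[q],
            tcov=_union_length(t_ivs) / lengths[t],
        ))
    return out


def alignment_fraction(pair: PairwiseANI, lengths: Mapping[str, int]) -> float:
    """AF of a pair: coverage of the shorter sequence.

    If the two lengths tie, the larger of the two coverages is used.
    """
    lq, lt = lengths[pair.query_id], lengths[pair.target_id]
    if lq < lt:
        return pair.qcov
    if lt < lq:
        return pair.tcov
    return max(pair.qcov, pair.tcov)


# ---------------------------------------------------------------------------
# Greedy centroid clustering
# ---------------------------------------------------------------------------

def greedy_cluster(
    pairs: Iterable[PairwiseANI],
    lengths: Mapping[str, int],
    min_ani: float = 95.0,
    min_af: float = 0.85,
) -> list[VOTUCluster]:
    """Greedy longest-first clustering of all ids in ``lengths``.

    Sequences are sorted by length descending (ties: id ascending).  Each
    unassigned sequence in scan order founds a cluster as representative;
    every later unassigned sequence whose pair with that representative
    satisfies ``ani >= min_ani`` and ``af >= min_af`` joins it.  A sequence
    joins the *first* qualifying representative only.  Ids without any
    qualifying pair end up as singleton clusters.
    """
    if not 0.0 <= min_ani <= 100.0:
        raise ConfigError(f"min_ani must be in [0, 100], got {min_ani}")
    if not 0.0 <= min_af <= 1.0:
        raise ConfigError(f"min_af must be in [0, 1], got {min_af}")

    lookup: dict[frozenset, PairwiseANI] = {}
    for p in pairs:
        for sid in (p.query_id, p.target_id):
            if sid not in lengths:
                raise ValidationError(f"pair references unknown id {sid!r}")
        key = frozenset((p.query_id, p.target_id))
        if key in lookup:
            raise ValidationError(
                f"duplicate pair {p.query_id}/{p.target_id}: deduplicate first"
            )
        lookup[key] = p

    order = sorted(lengths, key=lambda i: (-lengths[i], i))
    assigned: set[str] = set()
    clusters: list[VOTUCluster] = []
    for i, rep in enumerate(order):
        if rep in assigned:
            continue
        assigned.add(rep)
        members = [rep]
        stats = {rep: (100.0, 1.0)}
        for other in order[i + 1 :]:
            if other in assigned:
                continue
            p = lookup.get(frozenset((rep, other)))
            if p is None:
                continue
            af = alignment_fraction(p, lengths)
            if p.ani >= min_ani and af >= min_af:
                assigned.add(other)
                members.append(other)
                stats[other] = (p.ani, af)
        clusters.append(VOTUCluster(rep, members, stats))
    return clusters


def select_representative_fasta(
    clusters: Iterable[VOTUCluster],
    contigs: Mapping[str, ContigSeq],
) -> list[ContigSeq]:
    """One sequence per cluster, in cluster order; missing sequence errors."""
    out = []
    for cl in clusters:
        c = contigs.get(cl.representative_id)
        if c is None:
            raise ValidationError(
                f"representative {cl.representative_id!r} has no sequence"
            )
        out.append(c)
    return out
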