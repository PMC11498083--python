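"""Independent reference implementations used to check the package.

These deliberately use different machinery from the implementation:
exact rational arithmetic and explicit position sets for the pairwise
identity merge, a literal transcription of the sorted-scan clustering
definition, and a per-position counting array for coverage.
"""

from fractions import Fraction

import numpy as np

from viropost import AlignmentRow, PairwiseANI


def exact_pairwise_ani(alignments, lengths):
    """Exact-arithmetic merge of local alignments into per-pair stats.

    Returns {(query_id, target_id): (ani, qcov, tcov)} as Fractions, with
    the same orientation rule as the implementation: drop self-hits, and
    for a pair seen in both orientations keep the one with the larger
    summed alignment length (ties: lexicographically first orientation).
    """
    groups = {}
    for a in alignments:
        if a.query_id == a.target_id:
            continue
        groups.setdefault((a.query_id, a.target_id), []).append(a)

    chosen = {}
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

    out = {}
    for q, t in chosen.values():
        alns = groups[(q, t)]
        num = sum(Fraction(a.pident) * a.aln_len for a in alns)
        den = sum(a.aln_len for a in alns)
        q_positions, t_positions = set(), set()
        for a in alns:
            qs, qe = sorted((a.q_start, a.q_end))
            ts, te = sorted((a.t_start, a.t_end))
            q_positions.update(range(qs, qe + 1))
            t_positions.update(range(ts, te + 1))
        out[(q, t)] = (
            num / den,
            Fraction(len(q_positions), lengths[q]),
            Fraction(len(t_positions), lengths[t]),
        )
    return out


def naive_greedy(pairs, lengths, min_ani=95.0, min_af=0.85):
    """Literal sorted-scan clustering: list of member-id lists, rep first."""
    qualifies = set()
    for p in pairs:
        lq, lt = lengths[p.query_id], lengths[p.target_id]
        if lq < lt:
            af = p.qcov
        elif lt < lq:
            af = p.tcov
        else:
            af = max(p.qcov, p.tcov)
        if p.ani >= min_ani and af >= min_af:
            qualifies.add(frozenset((p.query_id, p.target_id)))

    order = sorted(lengths, key=lambda i: (-lengths[i], i))
    assigned = set()
    clusters = []
    for rep in order:
        if rep in assigned:
            continue
        assigned.add(rep)
        members = [rep]
        for other in order:
            if other in assigned:
                continue
            if frozenset((rep, other)) in qualifies:
                assigned.add(other)
                members.append(other)
        clusters.append(members)
    return clusters


def position_coverage(placements, contig_length):
    """Per-position counting oracle: (mean_depth, covered_fraction, reads)."""
    depth = np.zeros(contig_length, dtype=np.int64)
    n = 0
    for p in placements:
        depth[p.start - 1 : p.end] += 1
        n += 1
    return depth.mean(), float((depth > 0).mean()), n


def random_alignment_table(rng, max_seqs=50, max_alns=150):
    """A random but valid BLAST-style table plus its length map."""
    n = int(rng.integers(2, max_seqs + 1))
    ids = [f"seq{i:03d}" for i in range(n)]
    lengths = {i: int(rng.integers(500, 5001)) for i in ids}
    alignments = []
    for _ in range(int(rng.integers(1, max_alns + 1))):
        q, t = rng.choice(ids, size=2, replace=True)  # occasional self-hit
        qs = int(rng.integers(1, lengths[q] + 1))
        qe = int(rng.integers(qs, lengths[q] + 1))
        ts = int(rng.integers(1, lengths[t] + 1))
        te = int(rng.integers(ts, lengths[t] + 1))
        if rng.integers(2):  # reverse-strand convention on the target
            ts, te = te, ts
        span = max(qe - qs + 1, max(ts, te) - min(ts, te) + 1)
        alignments.append(AlignmentRow(
            query_id=q, target_id=t,
            pident=float(np.round(rng.uniform(70, 100), 3)),
            aln_len=span + int(rng.integers(0, 20)),  # gap slack
            q_start=qs, q_end=qe, t_start=ts, t_end=te,
            evalue=0.0, bitscore=float(span),
        ))
    return alignments, lengths


def random_pair_instance(rng, max_seqs=12, all_tie=False):
    """A random greedy-clustering instance: (pairs, lengths)."""
    n = int(rng.integers(2, max_seqs + 1))
    ids = [f"s{i:02d}" for i in range(n)]
    if all_tie:
        common = int(rng.integers(1000, 5001))
        lengths = {i: common for i in ids}
    else:
        lengths = {i: int(rng.integers(1000, 5001)) for i in ids}
    pairs = []
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < 0.4:
                pairs.append(PairwiseANI(
                    query_id=ids[i], target_id=ids[j],
                    n_alns=1,
                    ani=float(np.round(rng.uniform(88, 100), 3)),
                    qcov=float(np.round(rng.uniform(0.5, 1.0), 3)),
                    tcov=float(np.round(rng.uniform(0.5, 1.0), 3)),
                ))
    return pairs, lengths
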