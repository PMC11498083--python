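"""Deterministic synthetic fixtures with known ground truth.

Every input format the pipeline consumes can be emulated here without
external tools or downloads: sequence communities with planted vOTU
structure at controlled divergence, detector/quality tables with planted
filter pass/fail composition, read placements with planted horizontal
coverage, and bin tables with planted redundancy.  All generators are
pure functions of (parameters, seed).

The mutation model is substitution-only (no indels), so percent identity
and divergence are in closed form and the planted clustering truth is
analytic: each cluster's ancestor is its longest member, every other
member is the ancestor mutated at a divergence well inside the species
threshold and slightly truncated, and the emitted alignment table carries
one full-length alignment per within-cluster pair whose identity equals
100·(1 − observed divergence).  Between-cluster divergence is far beyond
what a local aligner would report, so no between-cluster rows are
emitted (a documented hook: pass a real aligner's tabular output instead).
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .detection import PREFIX_SEP
from .tables_io import (
    AlignmentRow,
    BinRecord,
    CheckVRow,
    ContigSeq,
    DetectionRecord,
    GenomadRow,
    Placement,
    ValidationError,
    write_fasta,
    write_table,
)

_BASES = np.array(list("ACGT"))


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def random_sequence(length: int, seed) -> str:
    rng = _rng(seed)
    return "".join(rng.choice(_BASES, size=length))


# ---------------------------------------------------------------------------
# Mutation
# ---------------------------------------------------------------------------

def mutate_sequence(seq: str, divergence: float, seed) -> str:
    """Substitute exactly ``round(divergence * len)`` positions.

    Each chosen position is replaced by a *different* base, so the Hamming
    distance to the input equals the substitution count exactly.  Length
    is preserved; divergence outside [0, 1] is an error.
    """
    if not 0.0 <= divergence <= 1.0:
        raise ValidationError(f"divergence {divergence} outside [0, 1]")
    rng = _rng(seed)
    n = round(divergence * len(seq))
    if n == 0:
        return seq
    positions = rng.choice(len(seq), size=n, replace=False)
    out = list(seq)
    for pos in positions:
        alternatives = [b for b in "ACGT" if b != out[pos].upper()]
        out[pos] = alternatives[rng.integers(len(alternatives))]
    return "".join(out)


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


# ---------------------------------------------------------------------------
# Planted communities
# ---------------------------------------------------------------------------

def generate_community(
    n_clusters: int,
    members_per_cluster: int,
    len_range: tuple[int, int] = (3000, 12000),
    d_within: float = 0.03,
    d_between: float = 0.25,
    seed=0,
) -> tuple[list[ContigSeq], pd.DataFrame, list[AlignmentRow]]:
    """Plant a community of diverged clusters with analytic truth.

    Each cluster has an independent random ancestor (the longest member)
    and ``members_per_cluster − 1`` mutated, slightly truncated copies.
    The truth table lists (contig_id, cluster_id, is_representative,
    length); the alignment table carries within-cluster pairs plus
    self-hits, with identity computed from the realised Hamming distance
    on the aligned prefix.  Requires ``d_within < d_between``; ancestors
    failing the mutual-divergence floor are an error (vanishingly unlikely
    for independent random sequences and d_between <= 0.7).
    """
    if not d_within < d_between:
        raise ValidationError(
            f"d_within ({d_within}) must be below d_between ({d_between})"
        )
    rng = _rng(seed)
    lo, hi = len_range
    contigs: list[ContigSeq] = []
    truth_rows = []
    alignments: list[AlignmentRow] = []
    ancestors: list[str] = []

    for ci in range(n_clusters):
        cluster_id = f"vC{ci:03d}"
        length = int(rng.integers(lo, hi + 1))
        ancestor = random_sequence(length, rng)
        ancestors.append(ancestor)
        member_seqs = [ancestor]
        member_ids = [f"{cluster_id}_s00"]
        for mi in range(1, members_per_cluster):
            mutated = mutate_sequence(ancestor, d_within, rng)
            # strictly shorter than the ancestor so the representative
            # (longest member) is unique and known
            cut = int(rng.integers(1, max(2, length // 20)))
            member_seqs.append(mutated[: length - cut])
            member_ids.append(f"{cluster_id}_s{mi:02d}")
        for mid, mseq in zip(member_ids, member_seqs):
            contigs.append(ContigSeq(mid, mseq))
            truth_rows.append({
                "contig_id": mid,
                "cluster_id": cluster_id,
                "is_representative": mid == member_ids[0],
                "length": len(mseq),
            })
        # within-cluster alignments: one row per unordered pair + self-hits
        for i in range(len(member_ids)):
            li = len(member_seqs[i])
            alignments.append(AlignmentRow(
                member_ids[i], member_ids[i], 100.0, li, 0, 0,
                1, li, 1, li, 0.0, 2.0 * li,
            ))
            for j in range(i + 1, len(member_ids)):
                m = min(li, len(member_seqs[j]))
                mism = _hamming(member_seqs[i][:m], member_seqs[j][:m])
                alignments.append(AlignmentRow(
                    member_ids[i], member_ids[j],
                    100.0 * (1.0 - mism / m), m, mism, 0,
                    1, m, 1, m, 0.0, 2.0 * (m - mism),
                ))

    for i in range(n_clusters):
        for j in range(i + 1, n_clusters):
            m = min(len(ancestors[i]), len(ancestors[j]))
            if _hamming(ancestors[i][:m], ancestors[j][:m]) / m < d_between:
                raise ValidationError(
                    f"ancestors {i} and {j} closer than d_between={d_between}"
                )

    truth = pd.DataFrame(truth_rows)
    return contigs, truth, alignments


# ---------------------------------------------------------------------------
# Planted detection tables
# ---------------------------------------------------------------------------

def generate_detection_fixture(
    n_pass_conservative: int,
    n_pass_relaxed_only: int,
    n_fail: int,
    seed=0,
) -> tuple[list[GenomadRow], list[CheckVRow]]:
    """Detector + quality rows with planted preset pass/fail composition.

    Exactly ``n_pass_conservative`` rows satisfy the conservative preset
    (score >= 0.8, length >= 2500, hallmarks >= 1) — and therefore also the
    relaxed one; ``n_pass_relaxed_only`` rows satisfy only the relaxed
    preset (score >= 0.7, length >= 2500, hallmarks >= 0); ``n_fail`` rows
    fail both.  Row order is shuffled so class is not positional.
    """
    rng = _rng(seed)
    kinds: list[str] = (
        ["cons"] * n_pass_conservative
        + ["relaxed"] * n_pass_relaxed_only
        + ["fail"] * n_fail
    )
    order = rng.permutation(len(kinds))
    genomad_rows, checkv_rows = [], []
    for idx, pos in enumerate(order):
        kind = kinds[pos]
        cid = f"det_{idx:05d}"
        if kind == "cons":
            score = float(rng.uniform(0.8, 1.0))
            length = int(rng.integers(2500, 50001))
            hallmarks = int(rng.integers(1, 6))
        elif kind == "relaxed":
            # fails conservative via a sub-0.8 score, zero hallmarks, or both
            mode = rng.integers(3)
            score = float(rng.uniform(0.7, 0.8)) if mode in (0, 2) \
                else float(rng.uniform(0.8, 1.0))
            hallmarks = 0 if mode in (1, 2) else int(rng.integers(1, 6))
            if mode == 0 and hallmarks == 0:
                hallmarks = 1  # keep the single-violation case single
            length = int(rng.integers(2500, 50001))
        else:
            # fails relaxed: low score and/or short sequence
            mode = rng.integers(3)
            score = float(rng.uniform(0.0, 0.7)) if mode in (0, 2) \
                else float(rng.uniform(0.7, 1.0))
            length = int(rng.integers(300, 2500)) if mode in (1, 2) \
                else int(rng.integers(2500, 50001))
            hallmarks = int(rng.integers(0, 6))
        viral = int(rng.integers(1, 6))
        host = int(rng.integers(0, viral + 1))
        n_genes = hallmarks + viral + host + int(rng.integers(0, 10))
        genomad_rows.append(GenomadRow(
            contig_id=cid, length=length, topology="linear",
            n_genes=n_genes, virus_score=score, n_hallmarks=hallmarks,
            taxonomy="Viruses;Duplodnaviria;Caudoviricetes",
        ))
        checkv_rows.append(CheckVRow(
            contig_id=cid, contig_length=length, gene_count=n_genes,
            viral_genes=viral, host_genes=host,
            quality=["Low-quality", "Medium-quality", "Not-determined"][
                int(rng.integers(3))
            ],
            completeness=float(np.round(rng.uniform(0, 100), 2)),
        ))
    return genomad_rows, checkv_rows


def _minimal_record(cid: str, length: int, viral: int, host: int,
                    quality: str = "Not-determined") -> DetectionRecord:
    return DetectionRecord(
        contig_id=cid, length=length, virus_score=0.9, n_hallmarks=1,
        n_genes=viral + host + 1, viral_genes=viral, host_genes=host,
        quality=quality,
    )


def generate_gene_filter_fixture(
    n_keep: int, n_drop_ratio: int, n_drop_min_viral: int, seed=0
) -> list[DetectionRecord]:
    """Records planted against the default gene-content filters.

    ``n_keep`` pass (viral >= 1, host/viral <= 1); ``n_drop_ratio`` fail
    only the ratio rule; ``n_drop_min_viral`` have zero viral genes.
    """
    rng = _rng(seed)
    records = []
    kinds = ["keep"] * n_keep + ["ratio"] * n_drop_ratio + ["viral"] * n_drop_min_viral
    for idx, pos in enumerate(rng.permutation(len(kinds))):
        kind = kinds[pos]
        cid = f"gf_{idx:05d}"
        if kind == "keep":
            viral = int(rng.integers(1, 6))
            host = int(rng.integers(0, viral + 1))
        elif kind == "ratio":
            viral = int(rng.integers(1, 6))
            host = viral + int(rng.integers(1, 5))
        else:
            viral = 0
            host = int(rng.integers(0, 5))
        records.append(_minimal_record(cid, int(rng.integers(2500, 20000)),
                                       viral, host))
    return records


def generate_quality_filter_fixture(
    n_keep_long: int, n_keep_quality: int, n_drop: int, seed=0
) -> list[DetectionRecord]:
    """Records planted against the conservative 5 kb / 1 kb+quality rule.

    ``n_keep_long`` are > 5 kb of poor quality; ``n_keep_quality`` are
    1–5 kb and at least medium quality; ``n_drop`` fail both branches
    (short, or 1–5 kb of poor quality).
    """
    rng = _rng(seed)
    good = ["Complete", "High-quality", "Medium-quality"]
    poor = ["Low-quality", "Not-determined"]
    records = []
    kinds = ["long"] * n_keep_long + ["qual"] * n_keep_quality + ["drop"] * n_drop
    for idx, pos in enumerate(rng.permutation(len(kinds))):
        kind = kinds[pos]
        cid = f"qf_{idx:05d}"
        if kind == "long":
            length = int(rng.integers(5001, 50001))
            quality = poor[int(rng.integers(2))]
        elif kind == "qual":
            length = int(rng.integers(1001, 5001))
            quality = good[int(rng.integers(3))]
        elif rng.integers(2) == 0:
            length = int(rng.integers(100, 1001))  # below the 1 kb floor
            quality = (good + poor)[int(rng.integers(5))]
        else:
            length = int(rng.integers(1001, 5001))
            quality = poor[int(rng.integers(2))]
        viral = int(rng.integers(1, 4))
        records.append(_minimal_record(cid, length, viral,
                                       int(rng.integers(0, viral + 1)), quality))
    return records


# ---------------------------------------------------------------------------
# Planted placements
# ---------------------------------------------------------------------------

def generate_placements(
    lengths: Mapping[str, int],
    target_cf: Mapping[str, float],
    seed=0,
    span_len: int = 150,
) -> list[Placement]:
    """Tile non-overlapping spans to hit each contig's target coverage.

    The realised covered fraction is ``round(target·length) / length`` —
    exact whenever ``target·length`` is integral, and always within half a
    position of the target.
    """
    _ = _rng(seed)  # reserved: layout is currently deterministic tiling
    placements: list[Placement] = []
    for cid, length in lengths.items():
        t = target_cf.get(cid, 0.0)
        if not 0.0 <= t <= 1.0:
            raise ValidationError(f"{cid}: target covered fraction {t} outside [0, 1]")
        covered = round(t * length)
        pos = 1
        while covered > 0:
            span = min(span_len, covered)
            placements.append(Placement(cid, pos, pos + span - 1))
            pos += span
            covered -= span
    return placements


# ---------------------------------------------------------------------------
# Whole-pipeline file fixture
# ---------------------------------------------------------------------------

def generate_pipeline_fixture(
    outdir: str | Path,
    seed: int = 0,
    n_samples: int = 2,
    n_clusters: int = 8,
    members_per_cluster: int = 3,
    len_range: tuple[int, int] = (3000, 12000),
    d_within: float = 0.03,
    d_between: float = 0.25,
) -> dict[str, Path]:
    """Write a complete, internally consistent input set for the CLI.

    Emits per-sample assemblies, detector and quality tables (with one
    trimmed-provirus case and low-score decoys per sample, plus the
    second-round tables for the provirus), an alignment table over the
    surviving prefixed ids, per-sample read placements over the truth
    representatives, a bin table, a metadata table tying it together, and
    the ground-truth cluster table.  Deterministic for a given seed.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = _rng(seed)
    samples = [f"S{i + 1}" for i in range(n_samples)]

    contigs, truth, alignments = generate_community(
        n_clusters, members_per_cluster, len_range, d_within, d_between, rng
    )
    sample_of = {c.contig_id: samples[i % n_samples] for i, c in enumerate(contigs)}
    prefixed = {cid: f"{sample_of[cid]}{PREFIX_SEP}{cid}" for cid in sample_of}

    cf_grid = np.array([0.0, 0.05, 0.2, 0.4, 0.6, 0.8, 0.95, 1.0])
    paths: dict[str, Path] = {}
    meta_rows = []
    blast_rows: list[AlignmentRow] = []
    rep_lengths: dict[str, int] = {}
    provirus_child_ids: list[str] = []

    # remap the community's alignment table onto prefixed ids
    for a in alignments:
        blast_rows.append(AlignmentRow(
            prefixed[a.query_id], prefixed[a.target_id], a.pident, a.aln_len,
            a.mismatches, a.gap_opens, a.q_start, a.q_end, a.t_start, a.t_end,
            a.evalue, a.bitscore,
        ))

    for si, sample in enumerate(samples):
        sdir = outdir / sample
        sdir.mkdir(exist_ok=True)
        own = [c for c in contigs if sample_of[c.contig_id] == sample]
        assembly = list(own)
        genomad_rows, checkv_rows = [], []

        for c in own:
            pid = prefixed[c.contig_id]
            hallmarks = int(rng.integers(1, 5))
            viral = int(rng.integers(1, 5))
            host = int(rng.integers(0, viral + 1))
            n_genes = hallmarks + viral + host + int(rng.integers(0, 10))
            genomad_rows.append(GenomadRow(
                contig_id=pid, length=c.length, topology="linear",
                n_genes=n_genes, virus_score=float(rng.uniform(0.82, 0.99)),
                n_hallmarks=hallmarks,
                taxonomy="Viruses;Duplodnaviria;Heunggongvirae;Uroviricota;"
                         "Caudoviricetes",
            ))
            checkv_rows.append(CheckVRow(
                contig_id=pid, contig_length=c.length, gene_count=n_genes,
                viral_genes=viral, host_genes=host, quality="Medium-quality",
                completeness=float(np.round(rng.uniform(40, 100), 2)),
            ))

        # low-score decoys removed by either preset
        for di in range(2):
            junk = ContigSeq(f"junk_{sample}_{di}",
                             random_sequence(int(rng.integers(3000, 4001)), rng))
            assembly.append(junk)
            pid = f"{sample}{PREFIX_SEP}{junk.contig_id}"
            genomad_rows.append(GenomadRow(
                contig_id=pid, length=junk.length, topology="linear",
                n_genes=3, virus_score=float(rng.uniform(0.1, 0.5)),
                n_hallmarks=0,
            ))
            checkv_rows.append(CheckVRow(
                contig_id=pid, contig_length=junk.length, gene_count=3,
                viral_genes=0, host_genes=3, quality="Not-determined",
            ))

        # one trimmed provirus: viral core flanked by host sequence,
        # with second-round tables re-scoring the trimmed region
        vlen = int(rng.integers(3000, 4001))
        core = random_sequence(vlen, rng)
        parent_seq = random_sequence(800, rng) + core + random_sequence(400, rng)
        parent = ContigSeq(f"prov_{sample}", parent_seq)
        assembly.append(parent)
        ppid = f"{sample}{PREFIX_SEP}{parent.contig_id}"
        region = (801, 800 + vlen)
        genomad_rows.append(GenomadRow(
            contig_id=ppid, length=parent.length, topology="linear",
            n_genes=8, virus_score=0.85, n_hallmarks=2,
            taxonomy="Viruses;Duplodnaviria;Heunggongvirae;Uroviricota;"
                     "Caudoviricetes",
        ))
        checkv_rows.append(CheckVRow(
            contig_id=ppid, contig_length=parent.length, gene_count=8,
            viral_genes=4, host_genes=2, quality="Medium-quality",
            completeness=90.0, provirus_flag=True, trimmed_region=region,
        ))
        child_id = f"{ppid}|provirus_{region[0]}_{region[1]}"
        provirus_child_ids.append(child_id)
        rep_lengths[child_id] = vlen
        genomad2 = [GenomadRow(
            contig_id=child_id, length=vlen, topology="linear",
            n_genes=6, virus_score=0.9, n_hallmarks=2,
            taxonomy="Viruses;Duplodnaviria;Heunggongvirae;Uroviricota;"
                     "Caudoviricetes",
        )]
        checkv2 = [CheckVRow(
            contig_id=child_id, contig_length=vlen, gene_count=6,
            viral_genes=4, host_genes=0, quality="Medium-quality",
            completeness=95.0, provirus_flag=True, trimmed_region=region,
        )]
        blast_rows.append(AlignmentRow(
            child_id, child_id, 100.0, vlen, 0, 0, 1, vlen, 1, vlen,
            0.0, 2.0 * vlen,
        ))

        p_assembly = sdir / f"{sample}_assembly.fna"
        p_genomad = sdir / f"{sample}_genomad.tsv"
        p_checkv = sdir / f"{sample}_checkv.tsv"
        p_genomad2 = sdir / f"{sample}_genomad_round2.tsv"
        p_checkv2 = sdir / f"{sample}_checkv_round2.tsv"
        write_fasta(assembly, p_assembly)
        write_table(genomad_rows, p_genomad, "genomad")
        write_table(checkv_rows, p_checkv, "checkv")
        write_table(genomad2, p_genomad2, "genomad")
        write_table(checkv2, p_checkv2, "checkv")

        meta_rows.append({
            "sample": sample, "group": f"G{si % 2 + 1}",
            "assembly": str(p_assembly), "reads": str(sdir / f"{sample}_placements.tsv"),
            "genomad": str(p_genomad), "checkv": str(p_checkv),
            "genomad2": str(p_genomad2), "checkv2": str(p_checkv2),
        })

    # truth on prefixed ids
    truth = truth.copy()
    truth["contig_id"] = truth["contig_id"].map(prefixed)
    for child_id in provirus_child_ids:
        truth.loc[len(truth)] = {
            "contig_id": child_id, "cluster_id": child_id,
            "is_representative": True, "length": rep_lengths[child_id],
        }
    p_truth = outdir / "truth_clusters.tsv"
    truth.to_csv(p_truth, sep="\t", index=False, lineterminator="\n")

    # placements over truth representatives, per sample
    rep_rows = truth[truth["is_representative"]]
    all_rep_lengths = dict(zip(rep_rows["contig_id"], rep_rows["length"]))
    for sample in samples:
        targets = {
            rid: float(rng.choice(cf_grid)) for rid in sorted(all_rep_lengths)
        }
        placements = generate_placements(all_rep_lengths, targets, rng)
        write_table(placements, outdir / sample / f"{sample}_placements.tsv",
                    "placement")

    p_blast = outdir / "blast.tsv"
    write_table(blast_rows, p_blast, "alignment")

    # two bins over community representatives: one clean, one borderline
    community_reps = [
        r for r in rep_rows["contig_id"] if r not in provirus_child_ids
    ]
    bins = []
    if len(community_reps) >= 4:
        bins = [
            BinRecord("vBin_1", community_reps[:2], protein_redundancy=1,
                      quality="Medium-quality"),
            BinRecord("vBin_2", community_reps[2:4], protein_redundancy=3,
                      quality="Low-quality"),
        ]
    p_bins = outdir / "bins.tsv"
    write_table(bins, p_bins, "bin")

    p_meta = outdir / "metadata.tsv"
    pd.DataFrame(meta_rows).to_csv(p_meta, sep="\t", index=False,
                                   lineterminator="\n")

    paths.update(metadata=p_meta, blast=p_blast, bins=p_bins, truth=p_truth)
    return paths
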