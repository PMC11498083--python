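"""Gene-content filtration of detected viral contigs.

Two cutoffs, kept separate from detection so they can be re-applied
without re-running the detectors: a minimum number of viral genes
(default 1) and a maximum ratio of host genes to viral genes (default 1).
A contig with many host genes relative to viral genes is most likely a
mis-trimmed provirus or a false positive.
"""

from __future__ import annotations

from typing import Iterable

from .tables_io import DetectionRecord, ValidationError

REASON_MIN_VIRAL = "min_viral_genes"
REASON_RATIO = "host_viral_ratio"


def apply_gene_filters(
    records: Iterable[DetectionRecord],
    min_viral_genes: int = 1,
    max_host_viral_ratio: float = 1.0,
) -> tuple[list[DetectionRecord], list[tuple[DetectionRecord, str]]]:
    """Partition records into (kept, dropped-with-reason).

    Keep iff ``viral_genes >= min_viral_genes`` and
    ``host_genes / viral_genes <= max_host_viral_ratio``.  Rules are tested
    in that order and a dropped record carries the first failed rule's code.

    When ``viral_genes == 0`` is allowed through the first rule
    (``min_viral_genes == 0``) the ratio is undefined; the convention is to
    keep the record iff ``host_genes == 0``.
    """
    kept: list[DetectionRecord] = []
    dropped: list[tuple[DetectionRecord, str]] = []
    for r in records:
        if r.viral_genes is None or r.host_genes is None:
            raise ValidationError(
                f"{r.contig_id}: viral_genes/host_genes must be populated"
            )
        if r.viral_genes < min_viral_genes:
            dropped.append((r, REASON_MIN_VIRAL))
            continue
        if r.viral_genes == 0:
            # ratio undefined: only a host-gene-free record may pass
            if r.host_genes == 0:
                kept.append(r)
            else:
                dropped.append((r, REASON_RATIO))
            continue
        if r.host_genes / r.viral_genes <= max_host_viral_ratio:
            kept.append(r)
        else:
            dropped.append((r, REASON_RATIO))
    return kept, dropped
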