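import pytest

from viropost import DetectionRecord


@pytest.fixture
def make_record():
    """Factory for minimal DetectionRecords with sensible defaults."""

    def _make(contig_id="c1", length=3000, virus_score=0.9, n_hallmarks=1,
              viral_genes=2, host_genes=0, quality="Medium-quality", **kw):
        return DetectionRecord(
            contig_id=contig_id,
            length=length,
            virus_score=virus_score,
            n_hallmarks=n_hallmarks,
            n_genes=(viral_genes or 0) + (host_genes or 0) + 1,
            viral_genes=viral_genes,
            host_genes=host_genes,
            quality=quality,
            **kw,
        )

    return _make
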