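import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from cneduo.io_formats import GenomicInterval, TranscriptModel
from cneduo.synthetic import SimulationConfig, example_retained_transcript


@pytest.fixture
def two_exon_transcript() -> TranscriptModel:
    """Exons [100,150) and [200,260) on '+': one intron [150,200)."""
    return TranscriptModel(
        transcript_id="tx1",
        gene_id="g1",
        interval=GenomicInterval("chr1", 100, 260, "+"),
        exons=(
            GenomicInterval("chr1", 100, 150, "+"),
            GenomicInterval("chr1", 200, 260, "+"),
        ),
        biotype="noncoding",
    )


@pytest.fixture
def retained_transcript() -> TranscriptModel:
    return example_retained_transcript()


@pytest.fixture
def base_config() -> SimulationConfig:
    return SimulationConfig(seed=11)
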