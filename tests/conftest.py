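import pytest

from splicepanel.panel_model import GeneRecord, TranscriptModel, load_transcript_models


@pytest.fixture(scope="session")
def models():
    return load_transcript_models()


@pytest.fixture(scope="session")
def pten_model(models):
    return models["PTEN"]


@pytest.fixture(scope="session")
def mlh1_model(models):
    return models["MLH1"]


@pytest.fixture(scope="session")
def brca2_window_model(models):
    return models["BRCA2"]


@pytest.fixture(scope="session")
def msh2_model(models):
    return models["MSH2"]


@pytest.fixture(scope="session")
def toy3_model():
    """Small 3-exon gene for exhaustive/brute-force comparisons."""
    return TranscriptModel(
        gene=GeneRecord("TOY3", "TOY3.1"),
        exon_lengths=[120, 90, 150],
        intron_lengths=[80, 60],
        cds_start_offset=0,
        cds_length=360,
    )


@pytest.fixture(scope="session")
def toy4_model():
    """Small 4-exon gene for exhaustive/brute-force comparisons."""
    return TranscriptModel(
        gene=GeneRecord("TOY4", "TOY4.1"),
        exon_lengths=[130, 75, 96, 140],
        intron_lengths=[70, 90, 55],
        cds_start_offset=0,
        cds_length=441,
    )
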