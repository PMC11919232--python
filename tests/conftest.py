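import pytest

from ssaso_triage import build_hypothetical_transcript, generate_random_transcript


@pytest.fixture(scope="session")
def bundle():
    return build_hypothetical_transcript()


@pytest.fixture(scope="session")
def model(bundle):
    return bundle.model


@pytest.fixture()
def simple_plus_model():
    """Small hand-laid plus-strand transcript: 3 exons, fully coding.

    exon1 genomic 1001-1120 (120 nt), intron 200 nt,
    exon2 1321-1404 (84 nt), intron 300 nt, exon3 1705-1800 (96 nt).
    CDS = all 300 nt.
    """
    from ssaso_triage import Exon, TranscriptModel

    return TranscriptModel(
        transcript_id="SIMPLE+",
        gene_symbol="SIM",
        strand="+",
        exons=[Exon(1, 1001, 1120), Exon(2, 1321, 1404), Exon(3, 1705, 1800)],
        cds_start=1,
        cds_end=300,
    )


@pytest.fixture(params=[11, 23, 47])
def random_model(request):
    return generate_random_transcript(request.param, n_exons=5)
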