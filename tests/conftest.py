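import pytest

from drivermosaic.transcripts import TranscriptModel, load_transcript_models

# 30-codon toy CDS used by the consequence brute-force oracle; starts with
# ATG, contains no internal stop, and has a codon (TAT) one change from TAA.
TOY_CDS = (
    "ATG" "GCT" "GAA" "TTC" "GGT" "CTG" "AAA" "ATG" "CCA" "CAA"
    "CGT" "TCT" "ACG" "GTT" "TGG" "TAT" "GCC" "GAC" "GAG" "TTT"
    "GGA" "CAT" "ATC" "AAG" "CTC" "AAT" "CCG" "AGA" "TCC" "GTG"
)


@pytest.fixture(scope="session")
def models():
    return load_transcript_models()


@pytest.fixture(scope="session")
def toy_plus():
    """Single-segment plus-strand toy model: chrT:1001-1090."""
    return TranscriptModel(
        gene="KRAS",
        chrom="chrT",
        strand="+",
        cds_segments=((1001, 1090),),
        cds_sequence=TOY_CDS,
        codon_offset=1,
        targets=((981, 1110),),
    )


@pytest.fixture(scope="session")
def toy_minus():
    """Two-segment minus-strand toy model carrying the same CDS.

    Transcription order: (2001, 2045) then (1001, 1045); the coding strand
    reads segment 1 from 2045 down to 2001, then segment 2 from 1045 down.
    """
    return TranscriptModel(
        gene="KRAS",
        chrom="chrT",
        strand="-",
        cds_segments=((2001, 2045), (1001, 1045)),
        cds_sequence=TOY_CDS,
        codon_offset=1,
        targets=((951, 1095), (1951, 2095)),
    )
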