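"""Seed-pattern construction, window classification, and site scanning."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mirscreen.seeds import (
    MIR194,
    SITE_7MER_A1,
    SITE_7MER_M8,
    SITE_8MER,
    InvalidSequenceError,
    MatureMiRNA,
    SeedSite,
    TranscriptModel,
    build_seed_patterns,
    classify_window,
    find_seed_sites,
    annotate_site_region,
    normalize_rna,
    reverse_complement_rna,
    summarize_sites,
)

from conftest import random_mirna, random_transcript


# ---------------------------------------------------------------- oracle
def oracle_patterns(mirna_seq: str) -> dict:
    """Independent pattern construction from first principles."""
    comp = {"A": "U", "C": "G", "G": "C", "U": "A"}
    rc = lambda s: "".join(comp[c] for c in reversed(s))
    seq = mirna_seq.upper().replace("T", "U")
    return {
        SITE_7MER_A1: rc(seq[1:7]) + "A",
        SITE_7MER_M8: rc(seq[1:8]),
        SITE_8MER: rc(seq[1:8]) + "A",
    }


def oracle_sites(mirna_seq: str, transcript: TranscriptModel) -> list[tuple]:
    """Brute-force window-by-window scan with 8mer > 7mer-m8 > 7mer-A1 priority."""
    pats = oracle_patterns(mirna_seq)
    seq = transcript.sequence
    raw = []
    for i in range(len(seq) - 7):
        w = seq[i : i + 8]
        if w == pats[SITE_8MER]:
            raw.append((i, 8, SITE_8MER))
        elif w[:7] == pats[SITE_7MER_M8]:
            raw.append((i, 7, SITE_7MER_M8))
        elif w[1:] == pats[SITE_7MER_A1]:
            raw.append((i + 1, 7, SITE_7MER_A1))
    eights = [(s, s + 8) for s, ln, _ in raw if ln == 8]
    return sorted(
        (s, ln, t)
        for s, ln, t in raw
        if ln == 8 or not any(a <= s and s + ln <= b for a, b in eights)
    )


# ---------------------------------------------------------------- patterns
def test_mir194_patterns_match_printed_guide(mir194_patterns):
    """The guide sequence yields the wild-type reporter heptamer as 7mer-A1."""
    assert mir194_patterns == {
        SITE_7MER_A1: "UGUUACA",
        SITE_7MER_M8: "CUGUUAC",
        SITE_8MER: "CUGUUACA",
    }
    # DNA form of the 7mer-A1 pattern is the mutagenized reporter site
    assert mir194_patterns[SITE_7MER_A1].replace("U", "T") == "TGTTACA"


def test_homopolymer_patterns():
    pats = build_seed_patterns(MatureMiRNA("polyA", "AAAAAAAA"))
    assert pats == {
        SITE_7MER_A1: "UUUUUUA",
        SITE_7MER_M8: "UUUUUUU",
        SITE_8MER: "UUUUUUUA",
    }


@settings(derandomize=True, max_examples=50)
@given(st.text(alphabet="ACGU", min_size=8, max_size=25))
def test_pattern_structural_identities(seq):
    """8mer = 7mer-m8 + 'A' and 8mer[1:] = 7mer-A1, for any miRNA."""
    pats = build_seed_patterns(MatureMiRNA("m", seq))
    assert pats[SITE_8MER] == pats[SITE_7MER_M8] + "A"
    assert pats[SITE_8MER][1:] == pats[SITE_7MER_A1]


def test_short_mirna_rejected():
    with pytest.raises(InvalidSequenceError):
        MatureMiRNA("short", "ACGUACG")


def test_alphabet_normalization():
    m = MatureMiRNA("m", " tgta acagcaacuccaugugga ")
    assert m.sequence == MIR194.sequence
    with pytest.raises(InvalidSequenceError):
        normalize_rna("ACGX")
    assert reverse_complement_rna("ACGU") == "ACGU"


# ---------------------------------------------------------------- classify
@pytest.mark.parametrize(
    "window,expected",
    [
        ("CUGUUACA", SITE_8MER),
        ("CUGUUACG", SITE_7MER_M8),
        ("GUGUUACA", SITE_7MER_A1),
        ("GGGGGGGG", None),
    ],
)
def test_classify_window_priority(mir194_patterns, window, expected):
    """Derived by comparing each window to all three patterns with priority."""
    assert classify_window(window, mir194_patterns) == expected


def test_classify_window_wrong_length(mir194_patterns):
    with pytest.raises(InvalidSequenceError):
        classify_window("CUGUUAC", mir194_patterns)


# ---------------------------------------------------------------- scanning
def test_ccnd1_wildtype_single_7mer_a1_site(mir194):
    """The printed reporter heptamer in a toy 3'UTR gives exactly one 7mer-A1."""
    tx = TranscriptModel("CCND1-frag", "CCND1", "GGGGTGTTACAGGGG", 0, 4)
    sites = find_seed_sites(mir194, tx)
    assert len(sites) == 1
    assert sites[0].site_type == SITE_7MER_A1
    assert sites[0].region == "3UTR"


def test_ccnd1_mutant_has_no_sites(mir194):
    """The 4-nt reporter mutation abolishes the site."""
    tx = TranscriptModel("CCND1-mut", "CCND1", "GGGGAAAAACAGGGG", 0, 4)
    assert find_seed_sites(mir194, tx) == []


def test_passenger_strand_8mer(mir194):
    """The guide finds one 8mer at position 12 of its passenger strand."""
    tx = TranscriptModel("pass", "pass", "CACAUGGAGUUGCUGUUACAUU", 0, 4)
    sites = find_seed_sites(mir194, tx)
    assert [(s.start, s.site_type) for s in sites] == [(12, SITE_8MER)]


def test_short_transcript_empty(mir194):
    tx = TranscriptModel("t", "g", "ACGUACG", 0, 3)
    assert find_seed_sites(mir194, tx) == []


def test_dna_rna_idempotence(mir194):
    rng = np.random.default_rng(11)
    for _ in range(20):
        tx = random_transcript(rng, 300)
        dna = TranscriptModel(
            tx.transcript_id,
            tx.gene_id,
            tx.sequence.replace("U", "T"),
            tx.cds_start,
            tx.cds_end,
        )
        assert find_seed_sites(mir194, dna) == find_seed_sites(mir194, tx)


def test_scan_matches_bruteforce_oracle():
    """Random miRNAs vs random transcripts: exact agreement with brute force."""
    rng = np.random.default_rng(2024)
    for _ in range(300):
        mir = random_mirna(rng)
        tx = random_transcript(rng, 500)
        got = [(s.start, s.length, s.site_type) for s in find_seed_sites(mir, tx)]
        assert got == oracle_sites(mir.sequence, tx)


def test_no_7mer_nested_in_8mer(mir194):
    """Priority exclusivity: reported 7mers never sit inside a reported 8mer."""
    rng = np.random.default_rng(5)
    base = list("ACGU")
    pats = build_seed_patterns(mir194)
    for _ in range(50):
        flank1 = "".join(rng.choice(base, size=30))
        flank2 = "".join(rng.choice(base, size=30))
        seq = flank1 + pats[SITE_8MER] + flank2
        tx = TranscriptModel("t", "g", seq, 0, 10)
        sites = find_seed_sites(mir194, tx)
        eights = [(s.start, s.end) for s in sites if s.site_type == SITE_8MER]
        for s in sites:
            if s.length == 7:
                assert not any(a <= s.start and s.end <= b for a, b in eights)


# ---------------------------------------------------------------- regions
@pytest.mark.parametrize(
    "start,length,expected",
    [
        (20, 7, "3UTR"),
        (10, 8, "junction"),
        (6, 8, "CDS"),
        (0, 5, "5UTR"),
    ],
)
def test_region_annotation(start, length, expected):
    tx = TranscriptModel("t", "g", "A" * 30, 5, 15)
    site = SeedSite("t", "g", start, length, SITE_8MER, "")
    assert annotate_site_region(site, tx) == expected


def test_region_out_of_range():
    tx = TranscriptModel("t", "g", "A" * 20, 5, 15)
    with pytest.raises(ValueError):
        tx.region_of(15, 21)


def test_invalid_cds_span():
    with pytest.raises(ValueError):
        TranscriptModel("t", "g", "ACGUACGU", 5, 3)
    with pytest.raises(ValueError):
        TranscriptModel("t", "g", "ACGUACGU", 0, 9)
    with pytest.raises(ValueError):
        TranscriptModel("t", "g", "ACGUACGU", None, None)


# ---------------------------------------------------------------- summaries
def test_summarize_sites_il6st_like():
    """4 sites (3x 7mer-A1, 1x 8mer), all 3'UTR, tallies like the worked row."""
    sites = [
        SeedSite("t", "IL6ST", 10, 7, SITE_7MER_A1, "3UTR"),
        SeedSite("t", "IL6ST", 30, 7, SITE_7MER_A1, "3UTR"),
        SeedSite("t", "IL6ST", 50, 7, SITE_7MER_A1, "3UTR"),
        SeedSite("t", "IL6ST", 70, 8, SITE_8MER, "3UTR"),
    ]
    s = summarize_sites("IL6ST", sites)
    assert s.total_sites == 4
    assert s.counts_by_type == {SITE_7MER_A1: 3, SITE_8MER: 1}
    assert s.counts_by_region == {"3UTR": 4}


def test_summarize_empty_and_conservation(mir194):
    s = summarize_sites("g", [])
    assert s.total_sites == 0 and s.counts_by_type == {} and s.counts_by_region == {}
    rng = np.random.default_rng(3)
    for _ in range(20):
        tx = random_transcript(rng, 400)
        sites = find_seed_sites(mir194, tx)
        summ = summarize_sites(tx.gene_id, sites)
        assert sum(summ.counts_by_type.values()) == summ.total_sites
        assert sum(summ.counts_by_region.values()) == summ.total_sites


def test_summarize_rejects_mixed_genes():
    with pytest.raises(ValueError):
        summarize_sites("a", [SeedSite("t", "b", 0, 7, SITE_7MER_A1, "3UTR")])
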