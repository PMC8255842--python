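"""Canonical miRNA seed-match site detection and transcript-region localization.

A mature miRNA recognizes most of its targets through Watson–Crick pairing of
its *seed* (nucleotides 2–8 from the 5' end) to the target mRNA.  Three
canonical site classes are distinguished on the target strand, written 5'→3':

* ``7mer-m8`` — perfect match to miRNA positions 2–8;
* ``7mer-A1`` — perfect match to positions 2–7 followed by a literal adenosine
  opposite miRNA position 1 (the A is a target-side feature, not a pair);
* ``8mer``   — both: the 2–8 match plus the position-1 adenosine.

Sites are localized to the 5'UTR, CDS or 3'UTR of the transcript; windows that
straddle a region boundary are labelled ``junction``.  Only exact Watson–Crick
complementarity is considered (no G:U wobble), and only the sense strand of the
supplied transcript sequence is scanned.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

__all__ = [
    "SITE_7MER_A1",
    "SITE_7MER_M8",
    "SITE_8MER",
    "SITE_TYPES",
    "REGION_5UTR",
    "REGION_CDS",
    "REGION_3UTR",
    "REGION_JUNCTION",
    "REGIONS",
    "InvalidSequenceError",
    "MatureMiRNA",
    "TranscriptModel",
    "SeedSite",
    "SiteSummary",
    "MIR194",
    "normalize_rna",
    "reverse_complement_rna",
    "build_seed_patterns",
    "classify_window",
    "find_seed_sites",
    "annotate_site_region",
    "summarize_sites",
    "scan_transcripts",
    "summarize_by_gene",
]

SITE_7MER_A1 = "7mer-A1"
SITE_7MER_M8 = "7mer-m8"
SITE_8MER = "8mer"
#: classes ordered weakest → strongest
SITE_TYPES = (SITE_7MER_A1, SITE_7MER_M8, SITE_8MER)

REGION_5UTR = "5UTR"
REGION_CDS = "CDS"
REGION_3UTR = "3UTR"
REGION_JUNCTION = "junction"
REGIONS = (REGION_5UTR, REGION_CDS, REGION_3UTR, REGION_JUNCTION)

_RNA_COMPLEMENT = str.maketrans("ACGU", "UGCA")
_RNA_ALPHABET = frozenset("ACGU")


class InvalidSequenceError(ValueError):
    """Raised for sequences outside the nucleotide alphabet or malformed windows."""


def normalize_rna(sequence: str, *, allow_n: bool = False) -> str:
    """Uppercase, strip whitespace, convert DNA T to RNA U, validate alphabet."""
    seq = "".join(str(sequence).split()).upper().replace("T", "U")
    allowed = _RNA_ALPHABET | ({"N"} if allow_n else set())
    bad = set(seq) - allowed
    if bad:
        raise InvalidSequenceError(
            f"sequence contains characters outside {{A,C,G,T,U}}: {sorted(bad)}"
        )
    return seq


def reverse_complement_rna(sequence: str) -> str:
    """Reverse complement in the RNA alphabet (A<->U, C<->G)."""
    return sequence.translate(_RNA_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class MatureMiRNA:
    """A named mature miRNA sequence, 5'→3'.

    DNA input (T) is normalized to RNA (U); whitespace and case are ignored.
    At least 8 nucleotides are required so that seed positions 1–8 exist.
    """

    id: str
    sequence: str

    def __post_init__(self) -> None:
        seq = normalize_rna(self.sequence)
        if len(seq) < 8:
            raise InvalidSequenceError(
                f"miRNA {self.id!r} is {len(seq)} nt; at least 8 nt are required"
            )
        object.__setattr__(self, "sequence", seq)

    @property
    def seed(self) -> str:
        """Seed region, miRNA positions 2–8 (0-based slice [1:8])."""
        return self.sequence[1:8]


#: the miR-194-5p guide strand (mimic guide used in the transfection screen)
MIR194 = MatureMiRNA("miR-194", "UGUAACAGCAACUCCAUGUGGA")


@dataclass(frozen=True)
class TranscriptModel:
    """A spliced protein-coding transcript with its CDS span.

    Coordinates are 0-based, half-open, in transcript space:
    5'UTR = [0, cds_start), CDS = [cds_start, cds_end), 3'UTR = [cds_end, len).
    Noncoding transcripts (no CDS) are not accepted.
    """

    transcript_id: str
    gene_id: str
    sequence: str
    cds_start: int
    cds_end: int

    def __post_init__(self) -> None:
        seq = normalize_rna(self.sequence, allow_n=True)
        object.__setattr__(self, "sequence", seq)
        if self.cds_start is None or self.cds_end is None:
            raise ValueError(
                f"transcript {self.transcript_id!r} lacks a CDS span; "
                "noncoding transcripts are not supported"
            )
        if not (0 <= self.cds_start < self.cds_end <= len(seq)):
            raise ValueError(
                f"transcript {self.transcript_id!r}: CDS span "
                f"[{self.cds_start}, {self.cds_end}) invalid for length {len(seq)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def utr5_span(self) -> tuple[int, int]:
        return (0, self.cds_start)

    @property
    def cds_span(self) -> tuple[int, int]:
        return (self.cds_start, self.cds_end)

    @property
    def utr3_span(self) -> tuple[int, int]:
        return (self.cds_end, len(self.sequence))

    def region_of(self, start: int, end: int) -> str:
        """Region containing the whole interval [start, end); ``junction`` if it
        straddles a boundary."""
        if not (0 <= start < end <= len(self.sequence)):
            raise ValueError(
                f"interval [{start}, {end}) out of range for transcript "
                f"{self.transcript_id!r} of length {len(self.sequence)}"
            )
        if end <= self.cds_start:
            return REGION_5UTR
        if start >= self.cds_end:
            return REGION_3UTR
        if start >= self.cds_start and end <= self.cds_end:
            return REGION_CDS
        return REGION_JUNCTION


@dataclass(frozen=True, order=True)
class SeedSite:
    """One detected seed-match site on a transcript.

    ``start`` is the 0-based coordinate of the 5'-most matched target base;
    ``length`` is 7 or 8 (8 iff ``site_type == '8mer'``).
    """

    transcript_id: str
    gene_id: str
    start: int
    length: int
    site_type: str
    region: str

    @property
    def end(self) -> int:
        return self.start + self.length


@dataclass
class SiteSummary:
    """Per-gene tally of seed sites by class and by transcript region."""

    gene_id: str
    total_sites: int
    counts_by_type: dict[str, int] = field(default_factory=dict)
    counts_by_region: dict[str, int] = field(default_factory=dict)


def build_seed_patterns(mirna: MatureMiRNA) -> dict[str, str]:
    """Target-strand (5'→3') match patterns for the three canonical site classes.

    * ``7mer-A1`` = revcomp(miRNA positions 2–7) + ``"A"``
    * ``7mer-m8`` = revcomp(miRNA positions 2–8)
    * ``8mer``    = revcomp(miRNA positions 2–8) + ``"A"``

    The terminal A is a literal target adenosine regardless of the identity of
    miRNA position 1.
    """
    if not isinstance(mirna, MatureMiRNA):
        mirna = MatureMiRNA("mirna", str(mirna))
    m = mirna.sequence
    core_2_7 = reverse_complement_rna(m[1:7])
    core_2_8 = reverse_complement_rna(m[1:8])
    return {
        SITE_7MER_A1: core_2_7 + "A",
        SITE_7MER_M8: core_2_8,
        SITE_8MER: core_2_8 + "A",
    }


def classify_window(window: str, patterns: Mapping[str, str]) -> Optional[str]:
    """Classify one 8-nt target window; strongest class wins.

    Priority 8mer > 7mer-m8 > 7mer-A1 so each window yields at most one call
    and an 8mer is never double-counted as its nested 7mers.  Returns ``None``
    for no match.
    """
    if len(window) != 8:
        raise InvalidSequenceError(f"window must be 8 nt, got {len(window)}")
    if window == patterns[SITE_8MER]:
        return SITE_8MER
    if window[0:7] == patterns[SITE_7MER_M8]:
        return SITE_7MER_M8
    if window[1:8] == patterns[SITE_7MER_A1]:
        return SITE_7MER_A1
    return None


def find_seed_sites(mirna: MatureMiRNA, transcript: TranscriptModel) -> list[SeedSite]:
    """Scan every 8-nt window of the transcript and report classified sites.

    For a 7mer-m8 the reported span is the first 7 nt of the window; for a
    7mer-A1 it is the last 7 (the reported start is the first matched base).
    7mer calls nested inside a reported 8mer span are suppressed.  Transcripts
    shorter than 8 nt yield an empty list.
    """
    patterns = build_seed_patterns(mirna)
    seq = transcript.sequence
    raw: list[tuple[int, int, str]] = []
    for i in range(len(seq) - 7):
        call = classify_window(seq[i : i + 8], patterns)
        if call is None:
            continue
        if call == SITE_8MER:
            raw.append((i, 8, SITE_8MER))
        elif call == SITE_7MER_M8:
            raw.append((i, 7, SITE_7MER_M8))
        else:
            raw.append((i + 1, 7, SITE_7MER_A1))
    eightmers = [(s, s + 8) for s, ln, _ in raw if ln == 8]
    kept = [
        (s, ln, t)
        for s, ln, t in raw
        if ln == 8 or not any(a <= s and s + ln <= b for a, b in eightmers)
    ]
    return [
        SeedSite(
            transcript_id=transcript.transcript_id,
            gene_id=transcript.gene_id,
            start=s,
            length=ln,
            site_type=t,
            region=transcript.region_of(s, s + ln),
        )
        for s, ln, t in sorted(kept)
    ]


def annotate_site_region(site: SeedSite, transcript: TranscriptModel) -> str:
    """Region of the whole matched span; ``junction`` when it straddles a boundary."""
    return transcript.region_of(site.start, site.end)


def summarize_sites(gene_id: str, sites: Iterable[SeedSite]) -> SiteSummary:
    """Tally sites of one gene by class and region; totals are conserved."""
    sites = list(sites)
    for s in sites:
        if s.gene_id != gene_id:
            raise ValueError(
                f"site on gene {s.gene_id!r} passed to summary for {gene_id!r}"
            )
    by_type = Counter(s.site_type for s in sites)
    by_region = Counter(s.region for s in sites)
    return SiteSummary(
        gene_id=gene_id,
        total_sites=len(sites),
        counts_by_type=dict(by_type),
        counts_by_region=dict(by_region),
    )


def scan_transcripts(
    mirna: MatureMiRNA, transcripts: Sequence[TranscriptModel]
) -> "pandas.DataFrame":
    """Scan many transcripts; one row per site.

    Columns: transcript_id, gene_id, start (0-based), start_1based, end_1based
    (inclusive), site_type, region.  1-based inclusive coordinates are the
    reporting convention; 0-based half-open is internal.
    """
    import pandas as pd

    rows = []
    for tx in transcripts:
        for s in find_seed_sites(mirna, tx):
            rows.append(
                {
                    "transcript_id": s.transcript_id,
                    "gene_id": s.gene_id,
                    "start": s.start,
                    "start_1based": s.start + 1,
                    "end_1based": s.end,
                    "site_type": s.site_type,
                    "region": s.region,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "transcript_id",
            "gene_id",
            "start",
            "start_1based",
            "end_1based",
            "site_type",
            "region",
        ],
    )


def summarize_by_gene(sites_df: "pandas.DataFrame") -> dict[str, SiteSummary]:
    """Per-gene SiteSummary from a ``scan_transcripts`` frame."""
    out: dict[str, SiteSummary] = {}
    for gene_id, grp in sites_df.groupby("gene_id", sort=True):
        out[str(gene_id)] = SiteSummary(
            gene_id=str(gene_id),
            total_sites=len(grp),
            counts_by_type=grp["site_type"].value_counts().to_dict(),
            counts_by_region=grp["region"].value_counts().to_dict(),
        )
    return out
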