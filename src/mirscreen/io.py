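"""Readers and writers for the plain-text formats the pipeline touches.

FASTA goes through Biopython; tables are tab-separated and read with pandas.
The transcript annotation TSV carries 0-based half-open CDS coordinates (its
header comment line documents this); all *reports* written here use 1-based
inclusive coordinates.
"""

from __future__ import annotations

import os
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO

from .seeds import MatureMiRNA, SiteSummary, TranscriptModel

ANNOTATION_COLUMNS = ["transcript_id", "gene_id", "cds_start", "cds_end"]
CLINICAL_COLUMNS = ["os_days", "os_event", "t_stage", "p_stage", "m_stage"]

_ROMAN_STAGES = {"I": 1, "II": 2, "III": 3, "IV": 4}


class ParseError(ValueError):
    """Malformed input file; the message names the file."""


def read_fasta(path: str) -> dict[str, str]:
    """FASTA → {record id: sequence string}."""
    try:
        records = {rec.id: str(rec.seq) for rec in SeqIO.parse(path, "fasta")}
    except (ValueError, OSError) as exc:  # pragma: no cover - passthrough detail
        raise ParseError(f"{path}: {exc}") from exc
    if not records:
        raise ParseError(f"{path}: no FASTA records found")
    return records


def read_mirna(source: str, mirna_id: str = "mirna") -> MatureMiRNA:
    """Load a mature miRNA from a FASTA path or accept an inline sequence string."""
    if os.path.exists(source):
        records = read_fasta(source)
        name, seq = next(iter(records.items()))
        return MatureMiRNA(name, seq)
    return MatureMiRNA(mirna_id, source)


def read_annotation(path: str) -> pd.DataFrame:
    """Region-annotation TSV: transcript_id, gene_id, cds_start, cds_end.

    CDS coordinates are 0-based half-open in transcript space; lines starting
    with ``#`` are comments.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype={0: str, 1: str})
    missing = [c for c in ANNOTATION_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing annotation columns {missing}")
    return df[ANNOTATION_COLUMNS]


def load_transcripts(fasta_path: str, annotation_path: str) -> list[TranscriptModel]:
    """Join transcript FASTA with the annotation table into TranscriptModels.

    Transcripts absent from the annotation, or annotated without a CDS, are
    rejected (the scanner handles protein-coding transcripts only).
    """
    seqs = read_fasta(fasta_path)
    ann = read_annotation(annotation_path).set_index("transcript_id")
    transcripts = []
    for tx_id, seq in seqs.items():
        if tx_id not in ann.index:
            raise ParseError(
                f"{annotation_path}: transcript {tx_id!r} has no annotation row"
            )
        row = ann.loc[tx_id]
        if pd.isna(row["cds_start"]) or pd.isna(row["cds_end"]):
            raise ParseError(
                f"{annotation_path}: transcript {tx_id!r} has no CDS "
                "(noncoding transcripts are not supported)"
            )
        transcripts.append(
            TranscriptModel(
                transcript_id=tx_id,
                gene_id=str(row["gene_id"]),
                sequence=seq,
                cds_start=int(row["cds_start"]),
                cds_end=int(row["cds_end"]),
            )
        )
    return transcripts


def read_expression(path: str) -> pd.DataFrame:
    """Expression TSV: first column gene ids, remaining columns samples."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.empty:
        raise ParseError(f"{path}: empty expression table")
    if (df.to_numpy() < 0).any():
        raise ParseError(f"{path}: negative abundances found")
    return df


def read_sample_metadata(path: str) -> pd.DataFrame:
    """Sample metadata TSV: sample_id, cell_line, condition (mimic/NC)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = ["sample_id", "cell_line", "condition"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing metadata columns {missing}")
    bad = set(df["condition"]) - {"mimic", "NC"}
    if bad:
        raise ParseError(f"{path}: unknown conditions {sorted(bad)}")
    return df[required]


def parse_stage(value) -> float:
    """Normalize a TNM stage label to a float, NaN for missing/unknown.

    Sub-stages collapse to their integer stage ("IIIa" → 3, "T2b" → 2);
    TX/MX/NX and empty values are treated as missing.
    """
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return float("nan")
    s = str(value).strip().upper()
    if s in {"", "NA", "NAN", "NONE"}:
        return float("nan")
    s = s.lstrip("TPMN")  # prefix letters of TNM codes
    if s in {"X", ""}:
        return float("nan")
    roman = s.rstrip("ABC")
    if roman in _ROMAN_STAGES:
        return float(_ROMAN_STAGES[roman])
    digits = "".join(ch for ch in s if ch.isdigit())
    if not digits:
        return float("nan")
    return float(digits[0])


def read_clinical(path: str) -> pd.DataFrame:
    """Clinical TSV: sample_id, os_days, os_event, t_stage, p_stage, m_stage.

    Stages are normalized with :func:`parse_stage`; NA marks missing values.
    """
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str}, na_values=["NA"])
    missing = [c for c in ["sample_id", *CLINICAL_COLUMNS] if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing clinical columns {missing}")
    df = df.set_index("sample_id")
    for col in ["t_stage", "p_stage", "m_stage"]:
        df[col] = df[col].map(parse_stage)
    df["os_days"] = pd.to_numeric(df["os_days"], errors="coerce")
    df["os_event"] = pd.to_numeric(df["os_event"], errors="coerce")
    if (df["os_days"].dropna() <= 0).any():
        raise ParseError(f"{path}: nonpositive survival times present")
    return df[CLINICAL_COLUMNS]


def read_mirna_matrix(path: str) -> pd.DataFrame:
    """miRNA × sample matrix of log2(TPM+1)-like values."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.empty:
        raise ParseError(f"{path}: empty miRNA matrix")
    return df


def read_gmt(path: str) -> dict[str, set[str]]:
    """GMT gene sets: name <tab> description <tab> gene1 <tab> gene2 ..."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: GMT line has <3 fields")
            sets[fields[0]] = {g for g in fields[2:] if g}
    if not sets:
        raise ParseError(f"{path}: no gene sets found")
    return sets


def write_fasta(path: str, records: Mapping[str, str]) -> None:
    with open(path, "w") as fh:
        for name, seq in records.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


def write_annotation(path: str, transcripts: Iterable[TranscriptModel]) -> None:
    with open(path, "w") as fh:
        fh.write("# CDS coordinates are 0-based half-open in transcript space\n")
        fh.write("\t".join(ANNOTATION_COLUMNS) + "\n")
        for tx in transcripts:
            fh.write(
                f"{tx.transcript_id}\t{tx.gene_id}\t{tx.cds_start}\t{tx.cds_end}\n"
            )


def write_tsv(path: str, df: pd.DataFrame, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format="%.6g")


def summaries_to_frame(summaries: Mapping[str, SiteSummary]) -> pd.DataFrame:
    """Per-gene summary table mirroring a 'Number / Type / Position' report."""
    rows = []
    for gene_id in sorted(summaries):
        s = summaries[gene_id]
        type_str = "; ".join(
            f"{t} ({n})" for t, n in sorted(s.counts_by_type.items())
        )
        region_str = "; ".join(
            f"{r} ({n})" for r, n in sorted(s.counts_by_region.items())
        )
        rows.append(
            {
                "gene_id": gene_id,
                "n_sites": s.total_sites,
                "site_types": type_str,
                "regions": region_str,
            }
        )
    return pd.DataFrame(rows, columns=["gene_id", "n_sites", "site_types", "regions"])
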