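"""Readers and writers for the pipeline's on-disk formats.

Annotation travels as a block-level TSV (one row per UTR/CDS block,
GTF-style 1-based inclusive coordinates on disk, converted to 0-based
half-open at this boundary) plus a FASTA of UTR sequences keyed
``transcript|side``. Motifs are emitted as BED6 with a companion tract/gap
TSV; peaks as ENCODE narrowPeak.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .g4_annotation import G4Motif, TranscriptModel


def write_fasta(sequences: dict[str, str], path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


_FEATURES = {"utr5": "utr5_blocks", "cds": "cds_blocks", "utr3": "utr3_blocks"}


def write_annotation(transcripts: list[TranscriptModel], tsv_path, fasta_path) -> None:
    """Block-level annotation TSV (1-based inclusive) + UTR sequence FASTA."""
    rows = []
    seqs: dict[str, str] = {}
    for t in transcripts:
        for feature, attr in _FEATURES.items():
            for s, e in getattr(t, attr):
                rows.append(
                    {
                        "transcript_id": t.transcript_id,
                        "gene_id": t.gene_id,
                        "chrom": t.chrom,
                        "strand": t.strand,
                        "feature": feature,
                        "start": s + 1,  # 1-based inclusive on disk
                        "end": e,
                        "loeuf": t.loeuf if t.loeuf is not None else "",
                    }
                )
        if t.utr5_seq:
            seqs[f"{t.transcript_id}|5p"] = t.utr5_seq
        if t.utr3_seq:
            seqs[f"{t.transcript_id}|3p"] = t.utr3_seq
    pd.DataFrame(rows).to_csv(tsv_path, sep="\t", index=False)
    write_fasta(seqs, fasta_path)


def read_annotation(tsv_path, fasta_path) -> list[TranscriptModel]:
    df = pd.read_csv(tsv_path, sep="\t")
    seqs = read_fasta(fasta_path)
    out = []
    for (tx, gene, chrom, strand), grp in df.groupby(
        ["transcript_id", "gene_id", "chrom", "strand"], sort=True
    ):
        blocks = {"utr5_blocks": [], "cds_blocks": [], "utr3_blocks": []}
        loeuf = None
        for r in grp.itertuples(index=False):
            blocks[_FEATURES[r.feature]].append((int(r.start) - 1, int(r.end)))
            if r.loeuf != "" and not pd.isna(r.loeuf):
                loeuf = float(r.loeuf)
        out.append(
            TranscriptModel(
                transcript_id=tx,
                gene_id=gene,
                chrom=chrom,
                strand=strand,
                utr5_blocks=sorted(blocks["utr5_blocks"]),
                utr3_blocks=sorted(blocks["utr3_blocks"]),
                cds_blocks=sorted(blocks["cds_blocks"]),
                utr5_seq=seqs.get(f"{tx}|5p", ""),
                utr3_seq=seqs.get(f"{tx}|3p", ""),
                loeuf=loeuf,
            )
        )
    return out


def motifs_to_bed(
    motifs: list[G4Motif],
    transcripts: list[TranscriptModel],
    bed_path,
    tract_tsv_path=None,
) -> None:
    """BED6 of genomic motif blocks plus an optional tract/gap sub-interval TSV.

    BED name is ``gene|transcript|side``; score is the tract count.
    """
    by_id = {t.transcript_id: t for t in transcripts}
    bed_rows, tract_rows = [], []
    for m in motifs:
        t = by_id[m.transcript_id]
        name = f"{t.gene_id}|{m.transcript_id}|{m.utr_side}"
        for s, e in m.genomic_blocks:
            bed_rows.append((t.chrom, s, e, name, m.n_tracts, t.strand))
        for tr in m.tracts:
            tract_rows.append(
                {
                    "name": name,
                    "kind": "tract",
                    "start": tr.start,
                    "end": tr.end,
                    "labels": ";".join(
                        f"{k}={v}" for k, v in (tr.positional_labels or {}).items()
                    ),
                }
            )
        for s, e in m.gaps:
            tract_rows.append({"name": name, "kind": "gap", "start": s, "end": e, "labels": ""})
    pd.DataFrame(
        bed_rows, columns=["chrom", "start", "end", "name", "score", "strand"]
    ).to_csv(bed_path, sep="\t", index=False, header=False)
    if tract_tsv_path is not None:
        pd.DataFrame(tract_rows).to_csv(tract_tsv_path, sep="\t", index=False)


NARROWPEAK_COLUMNS = [
    "chrom", "start", "end", "name", "score", "strand",
    "signalValue", "pValue", "qValue", "peak",
]


def write_narrowpeak(peaks: pd.DataFrame, path) -> None:
    df = peaks.copy()
    df["name"] = df.get("rbp_name", ".")
    df["score"] = 1000
    df["strand"] = "."
    df["signalValue"] = 0.0
    df["pValue"] = -1
    df["qValue"] = -1
    df["peak"] = -1
    df[NARROWPEAK_COLUMNS].to_csv(path, sep="\t", index=False, header=False)


def read_narrowpeak(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, names=NARROWPEAK_COLUMNS)
    df["rbp_name"] = df["name"]
    df["idr_pass"] = df["score"] >= 1000
    return df


def read_variants_tsv(path) -> pd.DataFrame:
    """Variant table TSV with at least chrom, pos, ref, alt, ac, an."""
    df = pd.read_csv(path, sep="\t")
    for col, default in (
        ("rf_prob", 1.0), ("segdup", False), ("lcr", False), ("decoy", False),
    ):
        if col not in df.columns:
            df[col] = default
    return df


def read_bed(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df = df.rename(columns={0: "chrom", 1: "start", 2: "end", 3: "name", 4: "score", 5: "strand"})
    keep = [c for c in ("chrom", "start", "end", "name", "score", "strand") if c in df.columns]
    return df[keep]
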