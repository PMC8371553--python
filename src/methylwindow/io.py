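"""Readers and writers for the plain-text formats exchanged between stages.

Coordinates are 0-based half-open internally (BED convention); the
cytosine-report TSV is 1-based, matching the usual per-cytosine report
convention.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

CYTOSINE_REPORT_COLUMNS = [
    "chrom",
    "pos",
    "strand",
    "count_methylated",
    "count_unmethylated",
    "context",
    "trinucleotide",
]


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def write_fasta(genome: Mapping[str, str], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in genome.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


# ---------------------------------------------------------------------------
# BED (genes as BED12, islands as BED3)
# ---------------------------------------------------------------------------

@dataclass
class GeneModel:
    """One gene with a single TSS and a flat exon structure."""

    gene_id: str
    chrom: str
    start: int  # 0-based
    end: int  # half-open
    strand: str
    exons: list[tuple[int, int]] = field(default_factory=list)

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1

    @property
    def tes(self) -> int:
        return self.end - 1 if self.strand == "+" else self.start


def write_genes_bed12(genes: Iterable[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            exons = sorted(g.exons) if g.exons else [(g.start, g.end)]
            sizes = ",".join(str(e - s) for s, e in exons)
            starts = ",".join(str(s - g.start) for s, e in exons)
            fh.write(
                "\t".join(
                    [
                        g.chrom,
                        str(g.start),
                        str(g.end),
                        g.gene_id,
                        "0",
                        g.strand,
                        str(g.start),
                        str(g.end),
                        "0",
                        str(len(exons)),
                        sizes + ",",
                        starts + ",",
                    ]
                )
                + "\n"
            )


def read_genes_bed12(path: str | Path) -> list[GeneModel]:
    genes: list[GeneModel] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            chrom, start, end, name = f[0], int(f[1]), int(f[2]), f[3]
            strand = f[5] if len(f) > 5 else "+"
            exons: list[tuple[int, int]] = []
            if len(f) >= 12:
                sizes = [int(x) for x in f[10].rstrip(",").split(",") if x]
                offs = [int(x) for x in f[11].rstrip(",").split(",") if x]
                exons = [(start + o, start + o + s) for o, s in zip(offs, sizes)]
            genes.append(GeneModel(name, chrom, start, end, strand, exons))
    return genes


def write_islands_bed(islands: Iterable[tuple[str, int, int]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, start, end in islands:
            fh.write(f"{chrom}\t{start}\t{end}\n")


def read_islands_bed(path: str | Path) -> list[tuple[str, int, int]]:
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            out.append((f[0], int(f[1]), int(f[2])))
    return out


# ---------------------------------------------------------------------------
# Sample sheet
# ---------------------------------------------------------------------------

def write_sample_sheet(sheet: pd.DataFrame, path: str | Path) -> None:
    sheet.to_csv(path, sep="\t", index=False, columns=["sample_id", "age", "treatment", "kit"])


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    sheet = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "age", "treatment", "kit"}
    missing = required - set(sheet.columns)
    if missing:
        raise ValueError(f"sample sheet missing columns: {sorted(missing)}")
    return sheet


# ---------------------------------------------------------------------------
# Cytosine report TSV (1-based positions on output)
# ---------------------------------------------------------------------------

def write_cytosine_report(df: pd.DataFrame, path: str | Path) -> None:
    """Write per-site counts; ``df.pos`` is 0-based and is shifted to 1-based."""
    out = df.copy()
    out["pos"] = out["pos"].astype(int) + 1
    out.to_csv(path, sep="\t", index=False, columns=CYTOSINE_REPORT_COLUMNS)


def read_cytosine_report(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "strand": str, "context": str})
    df["pos"] = df["pos"].astype(int) - 1
    return df


# ---------------------------------------------------------------------------
# SAM subset
# ---------------------------------------------------------------------------

@dataclass
class AlignedRead:
    """A mapped read from the minimal SAM subset (ungapped, FLAG 0/16)."""

    qname: str
    chrom: str
    pos: int  # 0-based leftmost reference coordinate
    strand: str  # '+' for FLAG 0, '-' for FLAG 16
    seq_forward: str  # sequence as stored in SAM (forward-strand orientation)

    @property
    def read_space_seq(self) -> str:
        """Sequence in original read orientation (bisulfite space)."""
        if self.strand == "+":
            return self.seq_forward
        return str(Seq(self.seq_forward).reverse_complement())

    @property
    def end(self) -> int:
        return self.pos + len(self.seq_forward)


def _sam_header(genome_lengths: Mapping[str, int]) -> dict:
    return {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": name, "LN": length} for name, length in genome_lengths.items()],
    }


def write_sam(
    reads: Iterable[AlignedRead],
    genome_lengths: Mapping[str, int],
    path: str | Path,
) -> None:
    header = pysam.AlignmentHeader.from_dict(_sam_header(genome_lengths))
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for r in reads:
            seg = pysam.AlignedSegment(header)
            seg.query_name = r.qname
            seg.flag = 0 if r.strand == "+" else 16
            seg.reference_name = r.chrom
            seg.reference_start = r.pos
            seg.mapping_quality = 60
            seg.cigartuples = [(0, len(r.seq_forward))]
            seg.query_sequence = r.seq_forward
            seg.query_qualities = None
            out.write(seg)


def read_sam(path: str | Path) -> tuple[list[AlignedRead], int]:
    """Parse the SAM subset; malformed records are skipped, not fatal.

    Returns (reads, n_skipped).
    """
    reads: list[AlignedRead] = []
    n_skipped = 0
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        for seg in fh:
            try:
                if seg.is_unmapped or seg.query_sequence is None:
                    n_skipped += 1
                    continue
                reads.append(
                    AlignedRead(
                        qname=seg.query_name or "",
                        chrom=seg.reference_name,
                        pos=seg.reference_start,
                        strand="-" if seg.is_reverse else "+",
                        seq_forward=seg.query_sequence.upper(),
                    )
                )
            except (ValueError, TypeError) as exc:  # pragma: no cover - defensive
                n_skipped += 1
                logger.warning("skipping malformed SAM record: %s", exc)
    if n_skipped:
        logger.info("read_sam: skipped %d malformed/unmapped records", n_skipped)
    return reads, n_skipped


# ---------------------------------------------------------------------------
# GMT gene-set collections
# ---------------------------------------------------------------------------

def read_gmt(path: str | Path) -> dict[str, set[str]]:
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"malformed GMT line: {line[:80]!r}")
            sets[fields[0]] = {g for g in fields[2:] if g}
    return sets


def write_gmt(sets: Mapping[str, set[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for set_id, genes in sets.items():
            fh.write("\t".join([set_id, set_id] + sorted(genes)) + "\n")
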