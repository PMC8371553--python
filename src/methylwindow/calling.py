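"""Cytosine context classification, conversion-QC read filtering, and
per-site methylation calling from aligned bisulfite reads.

Context is strand-relative: a site is the position of a cytosine on its own
strand, which on the minus strand is a reference ``G``. Contexts partition
every cytosine into CpG / CHG / CHH (H = A, C or T); windows truncated by a
chromosome end default to CHH, except that a next-base ``G`` is always CpG.

The lone-cytosine filter operates on the read sequence itself (bisulfite
space): incomplete conversion leaves an excess of read cytosines outside
CG/GC dinucleotides.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io import AlignedRead

logger = logging.getLogger(__name__)

CONTEXTS = ("CpG", "CHG", "CHH")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class ReadFilterConfig:
    """Thresholds for the incomplete-conversion read filter.

    ``max_lone_count`` is an optional absolute cap, disabled by default:
    reads are removed on the lone-cytosine *fraction* unless a count cap is
    explicitly configured.
    """

    max_lone_fraction: float = 0.05
    max_lone_count: int | None = None

    def validate(self) -> None:
        if not 0.0 <= self.max_lone_fraction <= 1.0:
            raise ValueError("max_lone_fraction must be in [0, 1]")
        if self.max_lone_count is not None and self.max_lone_count < 0:
            raise ValueError("max_lone_count must be >= 0 when enabled")


def classify_context(genome: Mapping[str, str], chrom: str, pos: int, strand: str) -> str:
    """Context of the cytosine at ``(chrom, pos, strand)`` (0-based).

    Raises ``ValueError`` if the reference base is not a strand-relative C
    (reference C on '+', reference G on '-').
    """
    seq = genome[chrom]
    base = seq[pos]
    if strand == "+":
        if base != "C":
            raise ValueError(f"{chrom}:{pos}(+) is {base}, not C")
        nxt = seq[pos + 1] if pos + 1 < len(seq) else None
        nxt2 = seq[pos + 2] if pos + 2 < len(seq) else None
    elif strand == "-":
        if base != "G":
            raise ValueError(f"{chrom}:{pos}(-) is {base}, not a minus-strand C")
        # strand-relative downstream bases are upstream complements
        nxt = revcomp(seq[pos - 1]) if pos - 1 >= 0 else None
        nxt2 = revcomp(seq[pos - 2]) if pos - 2 >= 0 else None
    else:
        raise ValueError(f"invalid strand {strand!r}")
    if nxt == "G":
        return "CpG"
    if nxt is None:
        return "CHH"  # truncated window
    if nxt2 == "G":
        return "CHG"
    return "CHH"


def _context_codes_plus(arr: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(positions, contexts) of plus-strand cytosines in a byte array."""
    pos = np.flatnonzero(arr == ord("C"))
    n = len(arr)
    nxt = np.full(len(pos), -1, dtype=np.int64)
    ok1 = pos + 1 < n
    nxt[ok1] = arr[pos[ok1] + 1]
    nxt2 = np.full(len(pos), -1, dtype=np.int64)
    ok2 = pos + 2 < n
    nxt2[ok2] = arr[pos[ok2] + 2]
    ctx = np.where(
        nxt == ord("G"),
        0,
        np.where((nxt != -1) & (nxt2 == ord("G")), 1, 2),
    )
    return pos, ctx


def enumerate_cytosines(genome: Mapping[str, str]) -> pd.DataFrame:
    """Every strand-relative cytosine in the genome with its context.

    Returns a DataFrame with columns chrom, pos (0-based reference
    coordinate of the C/G base), strand, context, sorted by chrom, pos,
    strand.
    """
    frames = []
    for chrom in genome:
        seq = genome[chrom]
        arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).astype(np.int64)
        ppos, pctx = _context_codes_plus(arr)
        # minus strand: reverse-complement, classify, map back
        rc = np.frombuffer(revcomp(seq).encode("ascii"), dtype=np.uint8).astype(np.int64)
        mpos_rc, mctx = _context_codes_plus(rc)
        mpos = len(seq) - 1 - mpos_rc
        chrom_frames = [
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "pos": ppos,
                    "strand": "+",
                    "context": np.array(CONTEXTS)[pctx],
                }
            ),
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "pos": mpos,
                    "strand": "-",
                    "context": np.array(CONTEXTS)[mctx],
                }
            ),
        ]
        frames.extend(chrom_frames)
    if not frames:
        return pd.DataFrame(columns=["chrom", "pos", "strand", "context"])
    df = pd.concat(frames, ignore_index=True)
    return df.sort_values(["chrom", "pos", "strand"], kind="mergesort").reset_index(drop=True)


def trinucleotide(genome: Mapping[str, str], chrom: str, pos: int, strand: str) -> str:
    """Strand-relative trinucleotide starting at the cytosine, N-padded."""
    seq = genome[chrom]
    if strand == "+":
        tri = seq[pos : pos + 3]
        return tri + "N" * (3 - len(tri))
    tri = revcomp(seq[max(pos - 2, 0) : pos + 1])
    return tri + "N" * (3 - len(tri))


# ---------------------------------------------------------------------------
# Lone-cytosine conversion filter
# ---------------------------------------------------------------------------

def lone_cytosine_count(read_sequence: str) -> tuple[int, int]:
    """(#lone cytosines, #cytosines) in a read sequence.

    A cytosine is lone when neither the preceding nor the following base is
    G; terminal cytosines only consider the existing neighbour.
    """
    n_c = 0
    n_lone = 0
    last = len(read_sequence) - 1
    for i, base in enumerate(read_sequence):
        if base != "C":
            continue
        n_c += 1
        prev_g = i > 0 and read_sequence[i - 1] == "G"
        next_g = i < last and read_sequence[i + 1] == "G"
        if not prev_g and not next_g:
            n_lone += 1
    return n_lone, n_c


def lone_cytosine_fraction(read_sequence: str) -> float:
    n_lone, n_c = lone_cytosine_count(read_sequence)
    if n_c == 0:
        return 0.0
    return n_lone / n_c


def filter_reads(
    reads: Sequence[AlignedRead],
    filter_config: ReadFilterConfig | None = None,
) -> tuple[list[AlignedRead], int]:
    """Remove reads that fail the lone-cytosine conversion QC.

    A read is removed iff its lone-cytosine fraction exceeds
    ``max_lone_fraction``, or (when the absolute cap is enabled) its lone
    count exceeds ``max_lone_count``. Order-preserving.
    Returns (retained_reads, n_removed).
    """
    cfg = filter_config or ReadFilterConfig()
    cfg.validate()
    retained: list[AlignedRead] = []
    n_removed = 0
    for read in reads:
        n_lone, n_c = lone_cytosine_count(read.read_space_seq)
        frac = n_lone / n_c if n_c else 0.0
        remove = frac > cfg.max_lone_fraction
        if cfg.max_lone_count is not None:
            remove = remove or n_lone > cfg.max_lone_count
        if remove:
            n_removed += 1
        else:
            retained.append(read)
    return retained, n_removed


# ---------------------------------------------------------------------------
# Methylation calling
# ---------------------------------------------------------------------------

def call_methylation(
    retained_reads: Iterable[AlignedRead],
    genome: Mapping[str, str],
    sample_id: str,
) -> pd.DataFrame:
    """Tally methylated/unmethylated observations per covered cytosine.

    Plus-strand reads: at reference C positions, read C counts methylated,
    read T unmethylated. Minus-strand reads: at reference G positions, read
    G (forward orientation) counts methylated, read A unmethylated. Other
    read bases are ignored. Reads extending past the chromosome end are
    rejected. Sites with zero observations are omitted.

    Returns a cytosine-report DataFrame (0-based pos) with a sample_id
    column appended.
    """
    counts: dict[tuple[str, int, str], list[int]] = {}
    n_rejected = 0
    for read in retained_reads:
        seq = genome.get(read.chrom)
        if seq is None or read.pos < 0 or read.end > len(seq):
            n_rejected += 1
            continue
        ref = seq[read.pos : read.end]
        if read.strand == "+":
            for i, base in enumerate(ref):
                if base != "C":
                    continue
                obs = read.seq_forward[i]
                if obs == "C":
                    counts.setdefault((read.chrom, read.pos + i, "+"), [0, 0])[0] += 1
                elif obs == "T":
                    counts.setdefault((read.chrom, read.pos + i, "+"), [0, 0])[1] += 1
        else:
            for i, base in enumerate(ref):
                if base != "G":
                    continue
                obs = read.seq_forward[i]
                if obs == "G":
                    counts.setdefault((read.chrom, read.pos + i, "-"), [0, 0])[0] += 1
                elif obs == "A":
                    counts.setdefault((read.chrom, read.pos + i, "-"), [0, 0])[1] += 1
    if n_rejected:
        logger.warning("call_methylation: rejected %d out-of-bounds reads", n_rejected)
    rows = []
    for (chrom, pos, strand), (m, u) in sorted(counts.items()):
        rows.append(
            {
                "chrom": chrom,
                "pos": pos,
                "strand": strand,
                "count_methylated": m,
                "count_unmethylated": u,
                "context": classify_context(genome, chrom, pos, strand),
                "trinucleotide": trinucleotide(genome, chrom, pos, strand),
            }
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "chrom",
            "pos",
            "strand",
            "count_methylated",
            "count_unmethylated",
            "context",
            "trinucleotide",
        ],
    )
    df["sample_id"] = sample_id
    return df
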