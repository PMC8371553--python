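"""Synthetic genomes, cohorts, methylomes, and bisulfite reads.

The generator builds a small genome with CpG-boosted islands, non-overlapping
gene models on alternating strands, a cohort of 3 age groups x {control,
treated} x 2 library kits, per-site true methylation fractions on the logit
scale (baseline + age + kit + planted treatment effects), binomially sampled
counts at Poisson coverage, and optionally ungapped bisulfite reads with
incomplete conversion in a configurable fraction of reads.

Every operation is a pure function of (inputs, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from . import calling
from .io import AlignedRead, GeneModel

AGES = ("Y", "M", "A")
TREATMENTS = ("C", "T")
KITS = ("kitA", "kitB")

#: promoter flank (bases) used when planting promoter-scoped effects;
#: matches the annotation stage's default promoter window
PROMOTER_FLANK = 1000

_BASES = np.array([ord(b) for b in "ACGT"], dtype=np.uint8)


def default_group_sizes() -> dict[tuple[str, str], int]:
    """Study-sized cohort: treated 6/6/7, controls 4 per age."""
    return {
        ("Y", "T"): 6,
        ("M", "T"): 6,
        ("A", "T"): 7,
        ("Y", "C"): 4,
        ("M", "C"): 4,
        ("A", "C"): 4,
    }


@dataclass
class PlantedEffect:
    """A treatment effect on one gene region, active in a subset of ages."""

    gene_id: str
    region: str  # 'promoter' | 'body'
    context: str  # 'CpG' | 'CHG' | 'CHH'
    direction: str  # 'hypo' | 'hyper'
    delta_logit: float
    active_in: frozenset = frozenset({"Y", "M"})

    def __post_init__(self) -> None:
        self.active_in = frozenset(self.active_in)
        if self.region not in ("promoter", "body"):
            raise ValueError(f"invalid region {self.region!r}")
        if self.context not in calling.CONTEXTS:
            raise ValueError(f"invalid context {self.context!r}")
        if self.direction not in ("hypo", "hyper"):
            raise ValueError(f"invalid direction {self.direction!r}")
        if not np.isfinite(self.delta_logit):
            raise ValueError("delta_logit must be finite")
        if self.direction == "hypo" and self.delta_logit > 0:
            raise ValueError("hypo effect requires delta_logit <= 0")
        if self.direction == "hyper" and self.delta_logit < 0:
            raise ValueError("hyper effect requires delta_logit >= 0")
        if not self.active_in <= set(AGES):
            raise ValueError(f"active_in must be a subset of {AGES}")


@dataclass
class SimulationConfig:
    genome_length: int = 100_000
    n_chromosomes: int = 2
    gc_content: float = 0.4
    n_genes: int = 20
    gene_length: int = 2000
    n_islands: int = 10
    island_length: int = 500
    island_cpg_boost: float = 5.0
    group_sizes: dict = field(default_factory=default_group_sizes)
    kit_assignment: dict | None = None  # sample_id -> kit; default alternates
    baseline_methylation: dict = field(
        default_factory=lambda: {"CpG": 0.75, "CHG": 0.02, "CHH": 0.02}
    )
    kit_effect_logit: float = 0.0
    age_effect_logit: dict = field(default_factory=lambda: {"Y": 0.0, "M": 0.0, "A": 0.0})
    planted_effects: list = field(default_factory=list)
    coverage_mean: float = 30.0
    read_length: int = 150
    conversion_rate_converted: float = 0.995
    conversion_rate_failed: float = 0.2
    failed_read_fraction: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        for name in (
            "gc_content",
            "conversion_rate_converted",
            "conversion_rate_failed",
            "failed_read_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not 0.0 < self.gc_content < 1.0:
            raise ValueError("gc_content must be in (0, 1)")
        for name in ("genome_length", "n_chromosomes", "n_genes", "gene_length",
                     "n_islands", "island_length", "read_length"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.island_cpg_boost < 1.0:
            raise ValueError("island_cpg_boost must be >= 1")
        if self.coverage_mean <= 0:
            raise ValueError("coverage_mean must be > 0")
        for ctx, frac in self.baseline_methylation.items():
            if ctx not in calling.CONTEXTS:
                raise ValueError(f"unknown context {ctx!r} in baseline_methylation")
            if not 0.0 <= frac <= 1.0:
                raise ValueError("baseline methylation fractions must be in [0, 1]")
        for (age, trt), n in self.group_sizes.items():
            if age not in AGES or trt not in TREATMENTS:
                raise ValueError(f"invalid group {(age, trt)}")
            if n < 1:
                raise ValueError("group sizes must be >= 1")

    def sample_sheet(self) -> pd.DataFrame:
        """Deterministic cohort layout with kits alternating within groups."""
        rows = []
        for (age, trt) in sorted(self.group_sizes):
            for i in range(self.group_sizes[(age, trt)]):
                sample_id = f"{age}{trt}{i + 1}"
                if self.kit_assignment is not None:
                    kit = self.kit_assignment[sample_id]
                else:
                    kit = KITS[i % 2]
                rows.append({"sample_id": sample_id, "age": age, "treatment": trt, "kit": kit})
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Genome generation
# ---------------------------------------------------------------------------

def _base_probs(gc: float) -> np.ndarray:
    return np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])


def _boosted_island(rng: np.random.Generator, length: int, gc: float, boost: float) -> str:
    """Sequential sampling with the G weight boosted after a C.

    boost=1 reduces exactly to i.i.d. sampling at the background base
    composition.
    """
    p = _base_probs(gc)
    p_after_c = p.copy()
    p_after_c[2] *= boost
    p_after_c /= p_after_c.sum()
    out = np.empty(length, dtype=np.uint8)
    prev_c = False
    # draw uniforms up front so the loop is cheap and fully seeded
    u = rng.random(length)
    cum = np.cumsum(p)
    cum_c = np.cumsum(p_after_c)
    for i in range(length):
        thresholds = cum_c if prev_c else cum
        j = int(np.searchsorted(thresholds, u[i], side="right"))
        j = min(j, 3)
        out[i] = _BASES[j]
        prev_c = j == 1
    return out.tobytes().decode("ascii")


def _chrom_lengths(config: SimulationConfig) -> dict[str, int]:
    base = config.genome_length // config.n_chromosomes
    lengths = {}
    for i in range(config.n_chromosomes):
        extra = config.genome_length % config.n_chromosomes if i == 0 else 0
        lengths[f"chr{i + 1}"] = base + extra
    return lengths


def _place_intervals(
    lengths: Mapping[str, int], n: int, item_length: int, what: str
) -> list[tuple[str, int, int]]:
    """Evenly space ``n`` non-overlapping intervals across chromosomes."""
    chroms = list(lengths)
    per_chrom = [n // len(chroms) + (1 if i < n % len(chroms) else 0) for i in range(len(chroms))]
    placed = []
    for chrom, k in zip(chroms, per_chrom):
        if k == 0:
            continue
        L = lengths[chrom]
        if k * item_length > L:
            raise ValueError(
                f"cannot place {k} {what} of length {item_length} on {chrom} (length {L})"
            )
        gap = (L - k * item_length) / (k + 1)
        for j in range(k):
            start = int(round(gap * (j + 1) + item_length * j))
            placed.append((chrom, start, start + item_length))
    return placed


def generate_genome(
    config: SimulationConfig,
) -> tuple[dict[str, str], list[GeneModel], list[tuple[str, int, int]]]:
    """Seeded toy genome with CpG-boosted islands and alternating-strand genes.

    Genes get two exons (first and last fifth of the span) with a single
    intron between them. Islands are evenly spaced, non-overlapping, and
    in-bounds; genes are non-overlapping.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    lengths = _chrom_lengths(config)
    if min(lengths.values()) < 1:
        raise ValueError("more chromosomes than genome bases")

    genome: dict[str, str] = {}
    for chrom, L in lengths.items():
        draws = rng.choice(_BASES, size=L, p=_base_probs(config.gc_content))
        genome[chrom] = draws.tobytes().decode("ascii")

    islands = _place_intervals(lengths, config.n_islands, config.island_length, "islands")
    for chrom, start, end in islands:
        seq = genome[chrom]
        genome[chrom] = (
            seq[:start]
            + _boosted_island(rng, end - start, config.gc_content, config.island_cpg_boost)
            + seq[end:]
        )

    gene_spans = _place_intervals(lengths, config.n_genes, config.gene_length, "genes")
    genes = []
    for idx, (chrom, start, end) in enumerate(gene_spans):
        strand = "+" if idx % 2 == 0 else "-"
        fifth = max((end - start) // 5, 1)
        exons = [(start, start + fifth), (end - fifth, end)]
        genes.append(GeneModel(f"gene{idx + 1}", chrom, start, end, strand, exons))
    return genome, genes, islands


# ---------------------------------------------------------------------------
# Methylome simulation
# ---------------------------------------------------------------------------

@dataclass
class SiteCountsMatrix:
    """Methylated/total read counts per cytosine site per sample."""

    sites: pd.DataFrame  # chrom, pos (0-based), strand, context
    samples: list
    meth: np.ndarray  # (n_sites, n_samples)
    total: np.ndarray
    sample_sheet: pd.DataFrame

    def __post_init__(self) -> None:
        if self.meth.shape != self.total.shape:
            raise ValueError("meth/total shape mismatch")
        if self.meth.shape != (len(self.sites), len(self.samples)):
            raise ValueError("count matrix shape does not match sites x samples")
        if (self.meth > self.total).any():
            raise ValueError("methylated counts exceed totals")

    def subset(self, mask: np.ndarray) -> "SiteCountsMatrix":
        return SiteCountsMatrix(
            sites=self.sites.loc[mask].reset_index(drop=True),
            samples=self.samples,
            meth=self.meth[np.asarray(mask)],
            total=self.total[np.asarray(mask)],
            sample_sheet=self.sample_sheet,
        )

    def to_cytosine_reports(self, genome: Mapping[str, str], out_dir) -> None:
        from pathlib import Path

        from .io import write_cytosine_report

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        tri = [
            calling.trinucleotide(genome, c, p, s)
            for c, p, s in zip(self.sites["chrom"], self.sites["pos"], self.sites["strand"])
        ]
        for j, sample in enumerate(self.samples):
            covered = self.total[:, j] > 0
            df = self.sites.loc[covered, ["chrom", "pos", "strand", "context"]].copy()
            df["count_methylated"] = self.meth[covered, j]
            df["count_unmethylated"] = self.total[covered, j] - self.meth[covered, j]
            df["trinucleotide"] = np.asarray(tri, dtype=object)[covered]
            write_cytosine_report(df, out / f"{sample}.cytosine_report.tsv")

    @staticmethod
    def from_cytosine_reports(paths: Mapping[str, str], sample_sheet: pd.DataFrame) -> "SiteCountsMatrix":
        """Assemble a matrix from per-sample report TSVs (outer-joined sites)."""
        from .io import read_cytosine_report

        samples = list(paths)
        per_sample = {s: read_cytosine_report(paths[s]) for s in samples}
        keys = pd.concat(
            [df[["chrom", "pos", "strand", "context"]] for df in per_sample.values()],
            ignore_index=True,
        ).drop_duplicates().sort_values(["chrom", "pos", "strand"], kind="mergesort")
        keys = keys.reset_index(drop=True)
        index = {t: i for i, t in enumerate(zip(keys["chrom"], keys["pos"], keys["strand"]))}
        meth = np.zeros((len(keys), len(samples)), dtype=np.int64)
        total = np.zeros_like(meth)
        for j, s in enumerate(samples):
            df = per_sample[s]
            rows = [index[t] for t in zip(df["chrom"], df["pos"], df["strand"])]
            meth[rows, j] = df["count_methylated"].to_numpy()
            total[rows, j] = (
                df["count_methylated"].to_numpy() + df["count_unmethylated"].to_numpy()
            )
        return SiteCountsMatrix(keys, samples, meth, total, sample_sheet.reset_index(drop=True))


@dataclass
class TrueEffectTable:
    """Ground truth: per-gene/context labels and per-site/sample fractions."""

    gene_labels: pd.DataFrame  # gene_id, context, label
    true_fraction: np.ndarray  # (n_sites, n_samples)
    sites: pd.DataFrame
    samples: list


def _effect_region(gene: GeneModel, region: str) -> tuple[int, int]:
    if region == "body":
        return gene.start, gene.end
    if gene.strand == "+":
        return gene.tss - PROMOTER_FLANK, gene.tss + PROMOTER_FLANK + 1
    return gene.tss - PROMOTER_FLANK, gene.tss + PROMOTER_FLANK + 1


def gene_truth_labels(config: SimulationConfig) -> pd.DataFrame:
    """One label per gene x context: critical_window / always_responsive /
    never_responsive, derived from planted_effects."""
    labels = {}
    for eff in config.planted_effects:
        key = (eff.gene_id, eff.context)
        if eff.active_in == frozenset(AGES):
            labels[key] = "always_responsive"
        elif eff.active_in == frozenset({"Y", "M"}):
            labels[key] = "critical_window"
        else:
            labels[key] = "other"
    rows = []
    for idx in range(config.n_genes):
        gene_id = f"gene{idx + 1}"
        for ctx in calling.CONTEXTS:
            rows.append(
                {
                    "gene_id": gene_id,
                    "context": ctx,
                    "label": labels.get((gene_id, ctx), "never_responsive"),
                }
            )
    return pd.DataFrame(rows)


def simulate_methylomes(
    genome: Mapping[str, str],
    genes: Sequence[GeneModel],
    islands: Sequence[tuple[str, int, int]],
    config: SimulationConfig,
) -> tuple[SiteCountsMatrix, TrueEffectTable]:
    """Per-site counts under the additive logit model.

    true logit = logit(baseline[context]) + age_effect + kit_effect
                 + sum(planted deltas over matching site/sample)
    coverage ~ Poisson(coverage_mean); methylated ~ Binomial(coverage, p).
    """
    config.validate()
    if config.coverage_mean <= 0:
        raise ValueError("coverage_mean must be positive")
    rng = np.random.default_rng(config.seed + 1)  # distinct stream from genome
    sheet = config.sample_sheet()
    samples = list(sheet["sample_id"])
    sites = calling.enumerate_cytosines(genome)
    n_sites, n_samples = len(sites), len(samples)

    with np.errstate(divide="ignore"):  # baseline 0 or 1 -> infinite logit, valid
        base = np.array(
            [logit(config.baseline_methylation.get(c, 0.0)) for c in sites["context"]]
        )
    logits = np.tile(base[:, None], (1, n_samples))
    for j, row in sheet.iterrows():
        logits[:, j] += config.age_effect_logit.get(row["age"], 0.0)
        if row["kit"] == "kitB":
            logits[:, j] += config.kit_effect_logit

    gene_by_id = {g.gene_id: g for g in genes}
    chrom_arr = sites["chrom"].to_numpy()
    pos_arr = sites["pos"].to_numpy()
    ctx_arr = sites["context"].to_numpy()
    for eff in config.planted_effects:
        gene = gene_by_id.get(eff.gene_id)
        if gene is None:
            raise ValueError(f"planted effect references unknown gene {eff.gene_id!r}")
        lo, hi = _effect_region(gene, eff.region)
        site_mask = (
            (chrom_arr == gene.chrom)
            & (pos_arr >= lo)
            & (pos_arr < hi)
            & (ctx_arr == eff.context)
        )
        sample_mask = (
            (sheet["treatment"] == "T") & sheet["age"].isin(eff.active_in)
        ).to_numpy()
        logits[np.ix_(site_mask, sample_mask)] += eff.delta_logit

    frac = expit(logits)
    total = rng.poisson(config.coverage_mean, size=(n_sites, n_samples))
    meth = rng.binomial(total, frac)
    matrix = SiteCountsMatrix(sites, samples, meth, total, sheet)
    truth = TrueEffectTable(gene_truth_labels(config), frac, sites, samples)
    return matrix, truth


# ---------------------------------------------------------------------------
# Read simulation
# ---------------------------------------------------------------------------

@dataclass
class SimulatedRead:
    qname: str
    sample_id: str
    chrom: str
    start: int
    strand: str
    sequence: str  # bisulfite space, original read orientation
    failed_conversion: bool

    def as_aligned_read(self) -> AlignedRead:
        seq_fwd = self.sequence if self.strand == "+" else calling.revcomp(self.sequence)
        return AlignedRead(self.qname, self.chrom, self.start, self.strand, seq_fwd)


@dataclass
class ReadAlignmentSet:
    reads: list
    genome_lengths: dict

    def aligned_reads(self, sample_id: str | None = None) -> list[AlignedRead]:
        return [
            r.as_aligned_read()
            for r in self.reads
            if sample_id is None or r.sample_id == sample_id
        ]

    def truth_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "qname": [r.qname for r in self.reads],
                "sample_id": [r.sample_id for r in self.reads],
                "failed_conversion": [r.failed_conversion for r in self.reads],
            }
        )

    def to_sam(self, path, sample_id: str | None = None) -> None:
        from .io import write_sam

        write_sam(self.aligned_reads(sample_id), self.genome_lengths, path)


def simulate_reads(
    genome: Mapping[str, str],
    methylome_truth: TrueEffectTable,
    config: SimulationConfig,
    samples: Sequence[str] | None = None,
) -> ReadAlignmentSet:
    """Emit ungapped bisulfite reads from the true methylomes.

    Strand alternates deterministically with read index; a
    ``failed_read_fraction`` of reads converts at ``conversion_rate_failed``
    instead of ``conversion_rate_converted``. At each read cytosine the
    emitted base is C if the site is (sampled) methylated, else C with
    probability (1 - conversion rate) and T otherwise. Non-cytosine bases
    copy the reference.
    """
    config.validate()
    for chrom, seq in genome.items():
        if config.read_length > len(seq):
            raise ValueError(
                f"read_length {config.read_length} exceeds {chrom} length {len(seq)}"
            )
    rng = np.random.default_rng(config.seed + 2)
    if samples is None:
        samples = list(methylome_truth.samples)
    sample_col = {s: j for j, s in enumerate(methylome_truth.samples)}
    sites = methylome_truth.sites
    site_row = {
        (c, p, s): i
        for i, (c, p, s) in enumerate(zip(sites["chrom"], sites["pos"], sites["strand"]))
    }
    frac = methylome_truth.true_fraction

    reads: list[SimulatedRead] = []
    idx = 0
    for sample in samples:
        j = sample_col[sample]
        for chrom, seq in genome.items():
            L = len(seq)
            n_reads = max(int(round(config.coverage_mean * L / config.read_length)), 1)
            starts = rng.integers(0, L - config.read_length + 1, size=n_reads)
            failed = rng.random(n_reads) < config.failed_read_fraction
            for k in range(n_reads):
                strand = "+" if idx % 2 == 0 else "-"
                start = int(starts[k])
                conv = (
                    config.conversion_rate_failed
                    if failed[k]
                    else config.conversion_rate_converted
                )
                template = (
                    seq[start : start + config.read_length]
                    if strand == "+"
                    else calling.revcomp(seq[start : start + config.read_length])
                )
                chars = list(template)
                for i, b in enumerate(chars):
                    if b != "C":
                        continue
                    if strand == "+":
                        ref_pos = start + i
                    else:
                        ref_pos = start + config.read_length - 1 - i
                    row = site_row.get((chrom, ref_pos, strand))
                    p_meth = frac[row, j] if row is not None else 0.0
                    methylated = rng.random() < p_meth
                    if not methylated and rng.random() < conv:
                        chars[i] = "T"
                reads.append(
                    SimulatedRead(
                        qname=f"read{idx}",
                        sample_id=sample,
                        chrom=chrom,
                        start=start,
                        strand=strand,
                        sequence="".join(chars),
                        failed_conversion=bool(failed[k]),
                    )
                )
                idx += 1
    return ReadAlignmentSet(reads, {c: len(s) for c, s in genome.items()})
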