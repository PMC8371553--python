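"""Canonical simulation scenarios used for validation.

These configs pin down desk-scale datasets with known ground truth:
a conversion-QC scenario with a CpG-dense genome, a null scenario with a
library-kit batch effect for calibration checks, and a critical-window
recovery scenario with planted age-restricted treatment effects.
"""

from __future__ import annotations

from .simulate import PlantedEffect, SimulationConfig

#: gene ids with effects active in young+middle only (ground truth:
#: critical-window) and in all ages (always-responsive) in the recovery
#: scenario
CRITICAL_WINDOW_GENES = tuple(f"gene{i}" for i in range(1, 11))
ALWAYS_RESPONSIVE_GENES = tuple(f"gene{i}" for i in range(11, 21))


def conversion_qc_config(seed: int = 0) -> SimulationConfig:
    """CpG-dense genome for exercising the lone-cytosine read filter.

    High island CpG density keeps the retained-cytosine count per 150 bp
    read high enough that rare unconverted non-CpG cytosines in properly
    converted reads stay below the 5% lone fraction, while
    conversion-failed reads exceed it overwhelmingly.
    """
    return SimulationConfig(
        genome_length=30_000,
        n_chromosomes=1,
        gc_content=0.5,
        n_genes=1,
        gene_length=1000,
        n_islands=30,
        island_length=990,
        island_cpg_boost=8.0,
        group_sizes={("Y", "C"): 1},
        baseline_methylation={"CpG": 0.95, "CHG": 0.0, "CHH": 0.0},
        coverage_mean=50.0,
        read_length=150,
        conversion_rate_converted=0.995,
        conversion_rate_failed=0.2,
        failed_read_fraction=0.05,
        seed=seed,
    )


def null_calibration_config(seed: int = 0, kit_effect_logit: float = 0.5) -> SimulationConfig:
    """No group effect, kit batch effect present; 4 vs 4 young samples."""
    return SimulationConfig(
        genome_length=20_000,
        n_chromosomes=1,
        gc_content=0.5,
        n_genes=2,
        gene_length=1000,
        n_islands=4,
        island_length=200,
        island_cpg_boost=3.0,
        group_sizes={("Y", "C"): 4, ("Y", "T"): 4},
        kit_effect_logit=kit_effect_logit,
        coverage_mean=30.0,
        seed=seed,
    )


def critical_window_config(seed: int = 0, delta_logit: float = -1.5) -> SimulationConfig:
    """10 critical-window + 10 always-responsive genes, study-sized cohort.

    Genes are spaced so promoter windows never overlap a neighbouring
    gene's; CpG density is kept low so per-gene false-positive
    multiplicity in the aged contrast stays small.
    """
    effects = [
        PlantedEffect(
            gene_id=g,
            region="promoter",
            context="CpG",
            direction="hypo",
            delta_logit=delta_logit,
            active_in=frozenset({"Y", "M"}),
        )
        for g in CRITICAL_WINDOW_GENES
    ] + [
        PlantedEffect(
            gene_id=g,
            region="promoter",
            context="CpG",
            direction="hypo",
            delta_logit=delta_logit,
            active_in=frozenset({"Y", "M", "A"}),
        )
        for g in ALWAYS_RESPONSIVE_GENES
    ]
    return SimulationConfig(
        genome_length=64_100,
        n_chromosomes=1,
        gc_content=0.10,
        n_genes=20,
        gene_length=1000,
        n_islands=2,
        island_length=200,
        island_cpg_boost=1.0,
        planted_effects=effects,
        coverage_mean=30.0,
        seed=seed,
    )
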