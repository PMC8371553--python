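"""Per-gene responsiveness calls and the critical-window set algebra.

A gene is called hypo (hyper) for a contrast when at least
``min_sites_per_call`` significant hypo (hyper) sites annotate to it, in any
feature including intergenic nearest-gene assignment; a gene can appear in
both direction sets. The critical-window filter intersects the young and
middle-age treatment hypo sets and splits them by aged responsiveness.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd


@dataclass
class GeneCalls:
    """Directional per-gene calls for one contrast x context."""

    contrast: str
    context: str
    hypo_genes: set = field(default_factory=set)
    hyper_genes: set = field(default_factory=set)


@dataclass
class CriticalWindowResult:
    context: str
    shared_young_middle: set
    nonresponsive_in_aged: set
    responsive_in_all: set

    def sizes(self) -> dict:
        return {
            "shared_young_middle": len(self.shared_young_middle),
            "nonresponsive_in_aged": len(self.nonresponsive_in_aged),
            "responsive_in_all": len(self.responsive_in_all),
        }

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "gene_id": g,
                "shared": True,
                "nonresponsive_in_aged": g in self.nonresponsive_in_aged,
                "responsive_in_all": g in self.responsive_in_all,
            }
            for g in sorted(self.shared_young_middle)
        ]
        return pd.DataFrame(
            rows, columns=["gene_id", "shared", "nonresponsive_in_aged", "responsive_in_all"]
        )


def gene_calls(
    annotated: pd.DataFrame,
    contrast_name: str,
    context: str | None = None,
    min_sites_per_call: int = 1,
) -> GeneCalls:
    """Derive per-gene directional calls from an annotated contrast table.

    ``annotated`` needs direction, gene_id, and context columns (the output
    of annotating a contrast result).
    """
    if min_sites_per_call < 1:
        raise ValueError("min_sites_per_call must be >= 1")
    df = annotated
    if context is not None:
        df = df[df["context"] == context]
    df = df[df["gene_id"] != ""]
    out = GeneCalls(contrast=contrast_name, context=context or "all")
    for direction, target in (("hypo", out.hypo_genes), ("hyper", out.hyper_genes)):
        counts = df[df["direction"] == direction].groupby("gene_id").size()
        target.update(counts[counts >= min_sites_per_call].index)
    return out


def critical_window_genes(
    young_calls: GeneCalls,
    middle_calls: GeneCalls,
    aged_calls: GeneCalls,
    context: str,
    direction: str = "hypo",
) -> CriticalWindowResult:
    """Set algebra across the three treatment contrasts for one context.

    shared = responsive(Y) & responsive(M); the aged split partitions it
    into nonresponsive_in_aged and responsive_in_all. ``direction='hyper'``
    runs the mirror analysis with the hyper sets.
    """
    for label, calls in (("young", young_calls), ("middle", middle_calls), ("aged", aged_calls)):
        if calls is None:
            raise ValueError(f"missing {label} contrast calls")
    if direction not in ("hypo", "hyper"):
        raise ValueError("direction must be 'hypo' or 'hyper'")
    attr = f"{direction}_genes"
    young = getattr(young_calls, attr)
    middle = getattr(middle_calls, attr)
    aged = getattr(aged_calls, attr)
    shared = young & middle
    return CriticalWindowResult(
        context=context,
        shared_young_middle=shared,
        nonresponsive_in_aged=shared - aged,
        responsive_in_all=shared & aged,
    )
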