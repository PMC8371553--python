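"""Gene-set over-representation testing with BH FDR adjustment."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

logger = logging.getLogger(__name__)


@dataclass
class EnrichmentConfig:
    fdr_threshold: float = 0.05
    directed_p_threshold: float = 0.05

    def validate(self) -> None:
        for name in ("fdr_threshold", "directed_p_threshold"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must be in (0, 1)")


@dataclass
class GeneSetCollection:
    """Annotation sets plus the gene universe they are tested against.

    Sets are intersected with the universe before testing. The universe
    defaults to the union of all annotation sets.
    """

    sets: dict = field(default_factory=dict)
    universe: set = field(default_factory=set)

    def __post_init__(self) -> None:
        if not self.universe:
            self.universe = set().union(*self.sets.values()) if self.sets else set()
        self.sets = {k: set(v) & self.universe for k, v in self.sets.items()}

    @classmethod
    def from_gmt(cls, path, universe: set | None = None) -> "GeneSetCollection":
        from .io import read_gmt

        return cls(sets=read_gmt(path), universe=set(universe) if universe else set())


def bh_adjust(p_values: Iterable[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (monotone, capped at 1)."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must be in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def hypergeom_enrichment(
    query: Iterable[str], collection: GeneSetCollection
) -> pd.DataFrame:
    """Upper-tail hypergeometric over-representation of ``query`` in each set.

    Genes outside the universe are dropped (with a logged count). Returns a
    table sorted by p with columns set_id, overlap, set_size, query_size,
    universe_size, p, q.
    """
    query_set = set(query)
    if not query_set:
        raise ValueError("empty query gene set")
    if not collection.universe:
        raise ValueError("empty gene universe")
    dropped = query_set - collection.universe
    if dropped:
        logger.info("hypergeom_enrichment: dropped %d genes outside universe", len(dropped))
    query_set &= collection.universe
    if not query_set:
        raise ValueError("no query genes remain inside the universe")
    M = len(collection.universe)
    N = len(query_set)
    rows = []
    for set_id, genes in collection.sets.items():
        K = len(genes)
        k = len(query_set & genes)
        # P(X >= k) drawing N from a universe of M with K successes
        p = float(hypergeom.sf(k - 1, M, K, N))
        rows.append(
            {
                "set_id": set_id,
                "overlap": k,
                "set_size": K,
                "query_size": N,
                "universe_size": M,
                "p": min(p, 1.0),
            }
        )
    table = pd.DataFrame(rows)
    table["q"] = bh_adjust(table["p"]) if len(table) else []
    return table.sort_values(["p", "set_id"], kind="mergesort").reset_index(drop=True)
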