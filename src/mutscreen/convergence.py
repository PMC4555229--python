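"""Convergent resistance genes across replicate isolates + pathway enrichment.

A gene mutated (by a qualifying effect class) in *every* replicate isolate
is the prime resistance-target candidate.  When no single gene converges,
pathway-level convergence is tested by a one-sided hypergeometric test of
hit genes against user-supplied gene sets, with Benjamini-Hochberg
correction across sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .variant_analysis import Effect, EffectAnnotation

__all__ = [
    "ConvergenceResult",
    "DEFAULT_QUALIFYING_EFFECTS",
    "convergence_analysis",
    "pathway_enrichment",
]

#: effects counted toward convergence; missense is included because loss of
#: transporter function through a destabilizing substitution (the HNM1 G65R
#: case) can confer resistance just like a truncation.
DEFAULT_QUALIFYING_EFFECTS = frozenset(
    {Effect.FRAMESHIFT, Effect.NONSENSE, Effect.SPLICE_DONOR, Effect.MISSENSE}
)


@dataclass
class ConvergenceResult:
    n_isolates: int
    #: gene_id -> (number of isolates hit, sorted effect classes observed)
    per_gene: dict[str, tuple[int, tuple[str, ...]]]
    #: genes hit by qualifying mutations in ALL isolates, sorted
    convergent_genes: list[str]
    #: flagged when too few replicates to make convergence meaningful
    underpowered: bool
    #: ordering: (isolate count desc, gene_id asc)
    ranked_genes: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "gene": g,
                "n_isolates_hit": self.per_gene[g][0],
                "effects": ",".join(self.per_gene[g][1]),
                "convergent": g in self.convergent_genes,
            }
            for g in self.ranked_genes
        ]
        return pd.DataFrame(rows)


def convergence_analysis(
    isolate_annotations: Mapping[str, Iterable[EffectAnnotation]],
    *,
    qualifying_effects: frozenset[Effect] = DEFAULT_QUALIFYING_EFFECTS,
) -> ConvergenceResult:
    """Count isolates (not variants) per gene and identify genes hit in all.

    Isolates with no annotations are allowed and simply contribute nothing.
    """
    if not isolate_annotations:
        raise ValueError("need at least one isolate")
    if not qualifying_effects:
        raise ValueError("qualifying_effects must be non-empty")
    n_isolates = len(isolate_annotations)

    hits: dict[str, set[str]] = {}
    effects: dict[str, set[str]] = {}
    for iso_id, anns in isolate_annotations.items():
        for a in anns:
            if a.gene_id is None or a.effect not in qualifying_effects:
                continue
            hits.setdefault(a.gene_id, set()).add(iso_id)
            effects.setdefault(a.gene_id, set()).add(a.effect.value)

    per_gene = {
        g: (len(isos), tuple(sorted(effects[g]))) for g, isos in hits.items()
    }
    ranked = sorted(per_gene, key=lambda g: (-per_gene[g][0], g))
    convergent = sorted(g for g, (n, _) in per_gene.items() if n == n_isolates)
    return ConvergenceResult(
        n_isolates=n_isolates,
        per_gene=per_gene,
        convergent_genes=convergent,
        underpowered=n_isolates < 3,
        ranked_genes=ranked,
    )


def pathway_enrichment(
    hit_genes: Iterable[str],
    gene_sets: Mapping[str, Sequence[str]],
    universe_genes: Iterable[str],
) -> pd.DataFrame:
    """One-sided hypergeometric enrichment of hit genes in each gene set.

    For a universe of ``M`` genes, a set of size ``n`` and ``N`` hit genes
    of which ``k`` fall in the set, the p-value is ``P(X >= k)`` for
    ``X ~ Hypergeom(M, n, N)``; q-values are Benjamini-Hochberg across
    sets.  Rows are ordered by (p-value, set name).
    """
    universe = set(universe_genes)
    if not universe:
        raise ValueError("universe_genes must be non-empty")
    hits = set(hit_genes)
    if not hits <= universe:
        raise ValueError(f"hit genes outside the universe: {sorted(hits - universe)}")
    columns = [
        "set_name", "k_hit_genes", "set_size", "n_hit_genes_total",
        "universe_size", "p_value", "q_value",
    ]
    if not hits or not gene_sets:
        return pd.DataFrame(columns=columns)

    M, N = len(universe), len(hits)
    rows = []
    for name in sorted(gene_sets):
        members = set(gene_sets[name]) & universe
        if set(gene_sets[name]) - universe:
            raise ValueError(f"gene set {name!r} contains genes outside the universe")
        k = len(hits & members)
        p = float(hypergeom.sf(k - 1, M, len(members), N))
        rows.append((name, k, len(members), N, M, min(p, 1.0)))
    df = pd.DataFrame(rows, columns=columns[:-1])
    df["q_value"] = multipletests(df["p_value"], method="fdr_bh")[1]
    return df.sort_values(["p_value", "set_name"], kind="stable").reset_index(drop=True)
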