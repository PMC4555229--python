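"""End-to-end resistance-discovery protocol on synthetic data.

Mirrors the wet-lab workflow: grow mutator cultures under drug (prolonged
lag = selection of a resistant subpopulation), passage the saturated
cultures drug-free (1:200), re-expose to drug, keep cultures that no longer
show a significant lag (< 24 h — evidence the resistance is mutational,
not regulatory), "sequence" the kept cultures (generate isolate genomes
with a planted resistance mutation plus background MMR-spectrum mutations),
call and annotate variants, and run convergence / pathway enrichment.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

from . import growth_metrics as gm
from .convergence import DEFAULT_QUALIFYING_EFFECTS, convergence_analysis, pathway_enrichment
from .growth_sim import SimParams, simulate_culture
from .synthetic_genome import MutationSpectrum, generate_isolate_cohort, generate_reference
from .variant_analysis import annotate_effect, annotation_frame, call_variants

__all__ = ["DiscoveryConfig", "run_resistance_discovery", "write_report"]


@dataclass(frozen=True)
class DiscoveryConfig:
    """Configuration of one discovery run."""

    n_replicate_cultures: int = 6
    dilution: float = 200.0  # 1:200 passage dilution
    drug_params: SimParams = field(
        default_factory=lambda: SimParams(f_res=1e-5, r_sens=-0.05, noise_sd=0.01, t_end=72.0)
    )
    lag_threshold_h: float = 24.0  # reselection rule: keep lag < threshold
    # genome / spectrum / planting
    genome_kwargs: dict = field(
        default_factory=lambda: dict(n_chrom=1, chrom_len=20_000, n_genes=10, n_sets=3)
    )
    spectrum: MutationSpectrum = field(default_factory=MutationSpectrum)
    plant_target: str = "GENE003"  # gene id or gene-set name
    plant_effect: str = "frameshift"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_replicate_cultures < 1:
            raise ValueError("n_replicate_cultures must be >= 1")
        if self.dilution <= 1:
            raise ValueError("dilution must be > 1")


def _reseeded(params: SimParams, cfg: DiscoveryConfig, culture_idx: int, stage: int) -> SimParams:
    return dataclasses.replace(
        params, seed=(cfg.seed * 1_000_003 + culture_idx * 101 + stage) % (2**31)
    )


def run_resistance_discovery(cfg: DiscoveryConfig) -> dict:
    """Run the full select -> passage -> reselect -> sequence -> converge
    protocol and return a structured report.

    When no culture passes reselection the report is an explicit empty
    result (``n_selected == 0``), not an exception.
    """
    cultures = []
    selected: list[int] = []
    for i in range(cfg.n_replicate_cultures):
        # first drug exposure: standing resistant minority is selected
        p1 = _reseeded(cfg.drug_params, cfg, i, stage=1)
        curve1, n_res, n_sens = simulate_culture(p1, return_populations=True)
        m1 = gm.estimate_growth_metrics(curve1)
        f_evolved = float(n_res[-1] / max(n_res[-1] + n_sens[-1], 1.0))

        # drug-free passage at 1:200: composition carried over, no selection
        # (both subpopulations grow at r_nodrug, so the fraction is stable)
        # re-exposure: fresh inoculum at the evolved resistant fraction
        p3 = dataclasses.replace(
            _reseeded(cfg.drug_params, cfg, i, stage=3), f_res=min(f_evolved, 1.0)
        )
        curve3 = simulate_culture(p3)
        m3 = gm.estimate_growth_metrics(curve3)
        relag = m3.lag_h if m3.lag_h is not None else float("inf")
        keep = relag < cfg.lag_threshold_h
        if keep:
            selected.append(i)
        cultures.append(
            {
                "culture": i,
                "first_exposure_lag_h": m1.lag_h,
                "evolved_resistant_fraction": f_evolved,
                "reexposure_lag_h": m3.lag_h,
                "selected": keep,
            }
        )

    report: dict = {
        "config_seed": cfg.seed,
        "plant_target": cfg.plant_target,
        "plant_effect": cfg.plant_effect,
        "cultures": cultures,
        "n_selected": len(selected),
    }
    if not selected:
        report.update(
            convergent_genes=[], per_gene={}, enrichment=[], annotations=[],
            message="no cultures passed reselection; empty result",
        )
        return report

    genome = generate_reference(seed=cfg.seed, **cfg.genome_kwargs)
    isolates, truth = generate_isolate_cohort(
        genome,
        n_isolates=len(selected),
        spectrum=cfg.spectrum,
        plant=(cfg.plant_target, cfg.plant_effect),
        seed=cfg.seed,
    )

    annotations = {}
    for iso_id, seqs in isolates.items():
        called = call_variants(genome.chroms, seqs)
        annotations[iso_id] = [annotate_effect(v, genome) for v in called]

    conv = convergence_analysis(annotations)
    hit_genes = sorted(
        {
            a.gene_id
            for anns in annotations.values()
            for a in anns
            if a.gene_id is not None and a.effect in DEFAULT_QUALIFYING_EFFECTS
        }
    )
    enrichment = pathway_enrichment(hit_genes, genome.gene_sets, genome.universe)

    ann_df = annotation_frame(annotations, genome, min_hpr_len=cfg.spectrum.min_hpr_len)
    report.update(
        n_isolates=len(selected),
        convergent_genes=conv.convergent_genes,
        per_gene={g: list(conv.per_gene[g]) for g in conv.ranked_genes},
        ranked_genes=conv.ranked_genes,
        underpowered=conv.underpowered,
        hit_genes=hit_genes,
        enrichment=enrichment.to_dict(orient="records"),
        top_enriched_set=(enrichment.iloc[0]["set_name"] if len(enrichment) else None),
        annotations=ann_df.to_dict(orient="records"),
        truth_counts={iso: len(vs) for iso, vs in truth.items()},
    )
    return report


def write_report(report: dict, outdir: str | Path) -> None:
    """JSON report + human-readable TSVs."""
    import pandas as pd

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "discovery_report.json").write_text(json.dumps(report, indent=1, default=str))
    pd.DataFrame(report["cultures"]).to_csv(outdir / "cultures.tsv", sep="\t", index=False)
    if report.get("annotations"):
        pd.DataFrame(report["annotations"]).to_csv(
            outdir / "annotations.tsv", sep="\t", index=False
        )
    if report.get("enrichment"):
        pd.DataFrame(report["enrichment"]).to_csv(
            outdir / "enrichment.tsv", sep="\t", index=False
        )
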