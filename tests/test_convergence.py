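"""Convergent gene detection across isolates and hypergeometric enrichment."""

import math

import pytest

from mutscreen import (
    DEFAULT_QUALIFYING_EFFECTS,
    Effect,
    EffectAnnotation,
    MutationSpectrum,
    Variant,
    annotate_effect,
    convergence_analysis,
    generate_isolate_cohort,
    generate_reference,
    pathway_enrichment,
)


def _ann(gene, effect, pos=100):
    v = Variant("chr1", pos, "A", "C" if effect != Effect.FRAMESHIFT else "CA")
    return EffectAnnotation(variant=v, gene_id=gene, effect=effect)


def test_gene_hit_in_all_isolates_is_convergent():
    """Six isolates with frameshifts in the same gene (two sharing the same
    position) converge on that gene; shared positions do not double-count."""
    anns = {
        f"iso{i}": [_ann("CAN1", Effect.FRAMESHIFT, pos=100 if i < 2 else 100 + i)]
        for i in range(6)
    }
    anns["iso0"].append(_ann("OTHER1", Effect.FRAMESHIFT, pos=500))
    res = convergence_analysis(anns)
    assert res.per_gene["CAN1"] == (6, ("frameshift",))
    assert res.convergent_genes == ["CAN1"]
    assert res.ranked_genes[0] == "CAN1"
    assert not res.underpowered


def test_distinct_genes_not_convergent():
    anns = {f"iso{i}": [_ann(f"G{i}", Effect.FRAMESHIFT)] for i in range(6)}
    res = convergence_analysis(anns)
    assert res.convergent_genes == []
    assert all(n == 1 for n, _ in res.per_gene.values())


def test_single_isolate_flagged_underpowered():
    res = convergence_analysis({"iso0": [_ann("G1", Effect.NONSENSE)]})
    assert res.convergent_genes == ["G1"] and res.underpowered


def test_nonqualifying_mutations_never_change_counts():
    base = {f"iso{i}": [_ann("T1", Effect.FRAMESHIFT)] for i in range(4)}
    res0 = convergence_analysis(base)
    noisy = {
        k: v + [_ann("T1", Effect.SYNONYMOUS, pos=900), _ann("X9", Effect.INTRONIC, pos=950)]
        for k, v in base.items()
    }
    res1 = convergence_analysis(noisy)
    assert res1.per_gene == res0.per_gene
    assert res1.convergent_genes == res0.convergent_genes


def test_empty_isolate_contributes_nothing():
    anns = {"iso0": [_ann("G1", Effect.FRAMESHIFT)], "iso1": []}
    res = convergence_analysis(anns)
    assert res.per_gene["G1"] == (1, ("frameshift",))
    assert res.convergent_genes == []


def test_qualifying_effects_must_be_nonempty():
    with pytest.raises(ValueError):
        convergence_analysis({"iso0": []}, qualifying_effects=frozenset())


# ---------------------------------------------------------------------------
# enrichment


def _hypergeom_tail_bruteforce(k, M, n, N):
    """P(overlap >= k) drawing N from M with n marked, by enumeration."""
    total = math.comb(M, N)
    return sum(
        math.comb(n, j) * math.comb(M - n, N - j) / total
        for j in range(k, min(n, N) + 1)
    )


def test_enrichment_matches_bruteforce_enumeration():
    """Six hit genes all inside a 10-gene set, universe 200."""
    universe = [f"G{i:03d}" for i in range(200)]
    the_set = universe[:10]
    hits = universe[:6]
    df = pathway_enrichment(hits, {"S": the_set, "T": universe[50:80]}, universe)
    row = df[df.set_name == "S"].iloc[0]
    expected = _hypergeom_tail_bruteforce(6, 200, 10, 6)
    assert row.p_value == pytest.approx(expected, rel=1e-12)
    assert row.k_hit_genes == 6 and row.set_size == 10 and row.universe_size == 200


def test_set_equal_to_universe_has_p_one():
    universe = [f"G{i}" for i in range(20)]
    df = pathway_enrichment(universe[:4], {"ALL": universe}, universe)
    assert df.iloc[0].p_value == pytest.approx(1.0)


def test_no_hits_gives_empty_table():
    df = pathway_enrichment([], {"S": ["G1"]}, ["G1", "G2"])
    assert df.empty


def test_enrichment_input_validation():
    with pytest.raises(ValueError, match="universe"):
        pathway_enrichment(["G1"], {"S": ["G1"]}, [])
    with pytest.raises(ValueError, match="outside"):
        pathway_enrichment(["NOT_THERE"], {"S": ["G1"]}, ["G1"])


def test_growing_universe_makes_fixed_overlap_more_surprising():
    """With the hit list and set fixed, enlarging the universe with genes
    outside the set shifts the null overlap down, so the tail p-value is
    non-increasing in the universe size (and stays within [0, 1])."""
    sets = {"S": [f"G{i}" for i in range(8)]}
    hits = [f"G{i}" for i in range(5)]
    p_prev = 1.0
    for extra in (0, 20, 100, 400):
        universe = [f"G{i}" for i in range(8)] + [f"X{i}" for i in range(extra)]
        p = pathway_enrichment(hits, sets, universe).iloc[0].p_value
        assert 0.0 <= p <= p_prev + 1e-15
        p_prev = p


def test_bh_qvalues_bounded_and_ordered():
    universe = [f"G{i}" for i in range(50)]
    sets = {f"S{j}": universe[j * 5 : j * 5 + 5] for j in range(8)}
    df = pathway_enrichment(universe[:5], sets, universe)
    assert ((df.q_value >= df.p_value - 1e-15) & (df.q_value <= 1.0)).all()
    assert df.p_value.is_monotonic_increasing


# ---------------------------------------------------------------------------
# end-to-end recovery on synthetic cohorts


def _annotate_truth(genome, truth):
    return {
        iso: [annotate_effect(v, genome) for v in vs] for iso, vs in truth.items()
    }


def test_planted_gene_tops_ranking_across_seeds():
    """Single-gene plant: the planted gene is the top-ranked convergent
    candidate in >= 95% of 100 seeded cohorts at default spectrum rates."""
    genome = generate_reference(n_chrom=1, chrom_len=30_000, n_genes=15, n_sets=3, seed=7)
    wins = 0
    for seed in range(100):
        _, truth = generate_isolate_cohort(
            genome, 6, MutationSpectrum(), plant=("GENE007", "frameshift"), seed=seed
        )
        res = convergence_analysis(_annotate_truth(genome, truth))
        wins += res.ranked_genes[0] == "GENE007" and "GENE007" in res.convergent_genes
    assert wins >= 95


def test_planted_pathway_tops_enrichment_across_seeds():
    """Pathway plant: with each isolate hitting a random member of the
    designated set, that set tops the enrichment table in >= 95% of 100
    seeded cohorts."""
    genome = generate_reference(n_chrom=1, chrom_len=90_000, n_genes=40, n_sets=4, seed=8)
    wins = 0
    for seed in range(100):
        _, truth = generate_isolate_cohort(
            genome, 6, MutationSpectrum(), plant=("PATHWAY", "frameshift"), seed=seed
        )
        anns = _annotate_truth(genome, truth)
        hit_genes = sorted(
            {
                a.gene_id
                for alist in anns.values()
                for a in alist
                if a.gene_id and a.effect in DEFAULT_QUALIFYING_EFFECTS
            }
        )
        df = pathway_enrichment(hit_genes, genome.gene_sets, genome.universe)
        wins += df.iloc[0].set_name == "PATHWAY"
    assert wins >= 95
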