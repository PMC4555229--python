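#!/usr/bin/env python
"""Score the mitoxantrone combination-therapy arms: resistant-culture
fraction ± SE of proportion (n = 40 cultures per arm) and rank the
combinations by effectiveness.

The pooled resistant fractions per arm are the published outcomes of the
wet-lab combination experiment (inputs to this analysis, not something a
simulation can reproduce). Writes results/combination_ranking.tsv.
"""

from pathlib import Path

from mutscreen import rank_combinations, resistance_proportion

RESULTS = Path(__file__).resolve().parent.parent / "results"

# (arm, pooled fraction of n = 40 cultures that developed resistance)
ARMS = [
    ("mitoxantrone + DMSO control", 0.98),
    ("mitoxantrone + mechlorethamine", 0.74),
    ("mitoxantrone + floxuridine", 0.64),
    ("mitoxantrone + bleomycin", 0.28),
    ("mitoxantrone + camptothecin", 0.13),
    ("mitoxantrone + mitomycin C", 0.03),
    ("mitoxantrone + rapamycin", 0.0),
    ("mitoxantrone + FK-506", 0.0),
]


def main() -> None:
    ests = [(label, resistance_proportion(40, fraction=p)) for label, p in ARMS]
    ranked = rank_combinations(ests)
    RESULTS.mkdir(exist_ok=True)
    ranked.to_csv(RESULTS / "combination_ranking.tsv", sep="\t", index=False)
    print(ranked[["rank", "arm", "display"]].to_string(index=False))
    best = ranked[ranked.p_hat == ranked.p_hat.min()]["arm"].tolist()
    print(f"\nmost effective regimens (lowest resistant fraction): {', '.join(best)}")


if __name__ == "__main__":
    main()
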