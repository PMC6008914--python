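"""Two-generation DFNB1 allele-frequency contrast on a simulated cohort.

The published parental/offspring frequencies (36.98% -> 38.67% in DXD
families) correspond to a 4.6% relative rise.  Individual-level offspring
genotypes are not published, so here the same contrast is computed on a
simulated assortative-mating cohort where the truth is known: deaf-by-deaf
couples are allele-enriched and (under relaxed selection) at least as
fertile, so in expectation their children tilt the offspring pool upward.
Any single simulated cohort is noisy; the test-suite averages hundreds of
replicates to pin the sign down.
"""

from dfnb1 import SimParams, generation_frequencies, relative_increase, simulate_cohort
from dfnb1.frequencies import round_half_up

print("Published worked example: parental 36.98%, offspring 38.67%",
      "-> relative increase", round_half_up(relative_increase(36.98, 38.67), 1), "%")

params = SimParams(
    population_size=2000, generations=2, q0=0.3, het_freqs=(0.05,),
    epsilon=0.15, assortment=0.9, consanguinity=0.3, fertility_dd=2.0, seed=5,
)
cohort, _ = simulate_cohort(params, families=80, seed=5)
for subgroup in ("DXD", "DXN"):
    c = generation_frequencies(cohort, subgroup)
    r = c.rounded()
    print(
        f"{subgroup}: parental {r['parental_frequency']}% "
        f"({c.parental_alleles}/{c.parental_chromosomes}) -> offspring "
        f"{r['offspring_frequency']}% ({c.offspring_alleles}/{c.offspring_chromosomes}); "
        f"relative change {r['relative_increase']}% over {c.n_families} families"
    )
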