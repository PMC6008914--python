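"""Forward-time dynamics of a recessive deafness allele.

Contrasts three regimes of the deterministic recursion: neutral random
mating (allele frequency flat), pure phenotypic assortment (frequency still
flat, but homozygote excess builds — assortment reshapes genotypes, not
alleles), and assortment plus relaxed selection via fertile deaf-by-deaf
unions (the frequency itself climbs — the mechanism proposed to have
doubled DFNB1 deafness where sign language made assortative mating easy).
"""

from dfnb1 import SimParams, deterministic_recursion

regimes = {
    "neutral random mating": dict(assortment=0.0, fertility_dd=1.0),
    "assortment only": dict(assortment=1.0, fertility_dd=1.0),
    "assortment + fertile DXD": dict(assortment=0.9, fertility_dd=1.5),
}

for label, kw in regimes.items():
    params = SimParams(
        population_size=10_000, generations=8, q0=0.1, het_freqs=(),
        epsilon=0.1, consanguinity=0.3, deaf_fitness=1.0, **kw,
    )
    tr = deterministic_recursion(params)
    q = ", ".join(f"{x:.4f}" for x in tr.q[::2, 0])
    hom = tr.genotype_freqs[-1, 0, 2]
    print(f"{label:26s} q every 2 gens: [{q}]  final aa freq {hom:.4f}")
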