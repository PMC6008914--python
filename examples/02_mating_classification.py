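"""Complementarity classification of deaf-by-deaf families.

Cross-tabulates the 60 DXD families by offspring phenotype (non-
complementary / complementary / segregating / childless) against the
partners' GJB2/GJB6 genotype cell, then stratifies the 46 deaf-by-normal
families by mating consanguinity.  Non-complementary matings — both
partners biallelic at the same recessive locus — can produce only deaf
children, which is what makes the first row's both-biallelic cell the
genetically forced one.
"""

from dfnb1 import default_registry, make_fixture, stratify_dxn, tabulate_dxd

registry = default_registry()

grid = tabulate_dxd(make_fixture("T13", registry), registry)
print(grid.to_string())
g1 = grid.loc["I-non-complementary"]
print(
    f"\n{g1['TOTAL']} of 60 families are non-complementary; "
    f"{g1['both-biallelic']} of those ({100 * g1['both-biallelic'] / g1['TOTAL']:.2f}%) "
    "are explained outright by biallelic GJB2 mutations in both partners."
)

print("\nDXN families by mating consanguinity:")
for label, s in stratify_dxn(make_fixture("T9", registry), registry).items():
    print(
        f"  {label}: {s.n_families} families, "
        f"{s.affected_offspring_percent}% with affected offspring, "
        f"{s.mutation_positive_percent}% with GJB2/GJB6 mutations in a partner"
    )
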