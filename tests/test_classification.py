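"""Mating complementarity groups and partner genotype cells."""

import pytest

from dfnb1 import SimParams, simulate_cohort
from dfnb1.classification import (
    ClassificationError,
    GenotypeCell,
    PhenotypeGroup,
    classify_family,
    classify_offspring_phenotype,
    genotype_cell,
    stratify_dxn,
    tabulate_dxd,
)
from dfnb1.cohort import Cohort, Family, Individual
from dfnb1.registry import parse_genotype


def _family(registry, p1, p2, offspring=(), p2_unsampled=False):
    """Two-partner DXD family; p1/p2 are (gjb2, gjb6) strings."""
    individuals = {}
    for iid, (g2, g6) in (("H", p1), ("W", p2)):
        genotypes = {}
        if not (iid == "W" and p2_unsampled):
            genotypes = {
                "GJB2": parse_genotype(g2, "GJB2", registry),
                "GJB6": parse_genotype(g6, "GJB6", registry),
            }
        individuals[iid] = Individual(
            individual_id=iid, family_id="F", sex="M" if iid == "H" else "F",
            hearing_status="HI", role="mate", genotypes=genotypes,
        )
    kids = []
    for k, status in enumerate(offspring, 1):
        oid = f"O{k}"
        kids.append(oid)
        individuals[oid] = Individual(
            individual_id=oid, family_id="F", sex="U", hearing_status=status,
            role="offspring", father_id="H", mother_id="W",
        )
    fam = Family(family_id="F", mating_type="DXD", partner_ids=("H", "W"),
                 offspring_ids=tuple(kids))
    return fam, Cohort(individuals=individuals, families={"F": fam}, registry=registry)


@pytest.mark.parametrize(
    "offspring,expected",
    [
        (("HI", "HI"), PhenotypeGroup.I),
        (("normal", "normal", "normal"), PhenotypeGroup.II),
        (("HI", "normal"), PhenotypeGroup.III),
        ((), PhenotypeGroup.IV),
    ],
)
def test_phenotype_groups(registry, offspring, expected):
    fam, cohort = _family(registry, ("+/+", "+/+"), ("+/+", "+/+"), offspring)
    assert classify_offspring_phenotype(fam, cohort) == expected
    # order invariance
    fam2, cohort2 = _family(registry, ("+/+", "+/+"), ("+/+", "+/+"), offspring[::-1])
    assert classify_offspring_phenotype(fam2, cohort2) == expected


def test_unknown_offspring_phenotype_is_an_error(registry):
    fam, cohort = _family(registry, ("+/+", "+/+"), ("+/+", "+/+"), ("HI", "unknown"))
    with pytest.raises(ClassificationError, match="unknown phenotype"):
        classify_offspring_phenotype(fam, cohort)


@pytest.mark.parametrize(
    "p1,p2,expected",
    [
        (("W24X/W24X", "+/+"), ("W24X/W24X", "+/+"), GenotypeCell.BOTH_BIALLELIC),
        (("W24X/I35S", "+/+"), ("Q124X/IVS1+1G>A", "+/+"), GenotypeCell.BOTH_BIALLELIC),
        (("W24X/+", "+/+"), ("Q124X/+", "+/+"), GenotypeCell.BOTH_HETEROZYGOUS),
        (("W24X/W24X", "+/+"), ("W24X/+", "+/+"), GenotypeCell.ONE_BIALLELIC_ONE_HET),
        (("W24X/W24X", "+/+"), ("+/+", "+/+"), GenotypeCell.ONE_PARTNER_GJB2_HOMOZYGOUS),
        (("W24X/+", "+/+"), ("+/+", "+/+"), GenotypeCell.ONE_PARTNER_GJB2_HETEROZYGOUS),
        # dominant heterozygote is genotype-positive
        (("R75Q/+", "+/+"), ("+/+", "+/+"), GenotypeCell.ONE_PARTNER_GJB2_HETEROZYGOUS),
        (("+/+", "Q57R/+"), ("+/+", "+/+"), GenotypeCell.ONE_PARTNER_GJB6_HETEROZYGOUS),
        (("E42D/+", "R104H/+"), ("+/+", "+/+"), GenotypeCell.DIGENIC),
        (("+/+", "+/+"), ("+/+", "+/+"), GenotypeCell.NON_GJB2_NON_GJB6),
        # polymorphism-only calls count as non-carrier
        (("R127H/R127H", "+/+"), ("V153I/+", "+/+"), GenotypeCell.NON_GJB2_NON_GJB6),
        # a single pathogenic allele inside a triallelic call is heterozygous
        (("W24X/T55T/R127H", "+/+"), ("+/+", "+/+"), GenotypeCell.ONE_PARTNER_GJB2_HETEROZYGOUS),
        # digenic takes precedence over everything else
        (("E42D/+", "R104H/+"), ("W24X/W24X", "+/+"), GenotypeCell.DIGENIC),
    ],
)
def test_genotype_cells(registry, p1, p2, expected):
    fam, cohort = _family(registry, p1, p2)
    assert genotype_cell(fam, cohort).cell == expected


def test_unsampled_partner_flagged(registry):
    fam, cohort = _family(registry, ("W24X/W24X", "+/+"), ("+/+", "+/+"), p2_unsampled=True)
    assignment = genotype_cell(fam, cohort)
    assert assignment.cell == GenotypeCell.ONE_PARTNER_GJB2_HOMOZYGOUS
    assert assignment.partner_unsampled


def test_pseudo_dominant_transmission_annotated(registry):
    fam, cohort = _family(registry, ("R75Q/+", "+/+"), ("+/+", "+/+"), ("HI",))
    cohort.individuals["O1"].genotypes = {"GJB2": parse_genotype("R75Q/+", "GJB2", registry)}
    mc = classify_family(fam, cohort)
    assert mc.genotype_cell == GenotypeCell.ONE_PARTNER_GJB2_HETEROZYGOUS
    assert "O1" in mc.pseudo_dominant_note


def test_dxd_cross_tabulation_matches_published_grid(t13):
    table = tabulate_dxd(t13)
    assert list(table["TOTAL"]) == [17, 30, 2, 11, 60]
    assert table.loc["I-non-complementary", "both-biallelic"] == 8
    assert table.loc["III-segregating", "one-partner-GJB2-heterozygous"] == 1
    assert list(table.loc["TOTAL"])[:-1] == [8, 1, 2, 16, 8, 2, 1, 22]
    # every family lands in exactly one cell
    assert table.loc["TOTAL", "TOTAL"] == 60


def test_empty_cohort_gives_all_zero_table(registry):
    empty = Cohort(individuals={}, families={}, registry=registry)
    table = tabulate_dxd(empty)
    assert table.values.sum() == 0


def test_dxn_stratification(t9):
    strata = stratify_dxn(t9)
    cons = strata["consanguineous"]
    assert cons.n_families == 18
    assert cons.affected_offspring_percent == 66.67
    assert cons.mutation_positive_percent == 44.44
    noncons = strata["non-consanguineous"]
    assert noncons.n_families == 28
    assert noncons.n_mutation_positive == 12
    assert noncons.mutation_positive_percent == 42.86
    assert noncons.affected_offspring_percent == 25.0


def test_dxn_single_family_degenerate(registry):
    individuals = {
        "A": Individual(individual_id="A", family_id="F", sex="M", hearing_status="HI",
                        role="mate", genotypes={"GJB2": parse_genotype("+/+", "GJB2", registry)}),
        "B": Individual(individual_id="B", family_id="F", sex="F", hearing_status="normal",
                        role="hearing-partner",
                        genotypes={"GJB2": parse_genotype("+/+", "GJB2", registry)}),
    }
    fam = Family(family_id="F", mating_type="DXN", mating_consanguineous="yes",
                 partner_ids=("A", "B"))
    cohort = Cohort(individuals=individuals, families={"F": fam}, registry=registry)
    strata = stratify_dxn(cohort)
    assert strata["consanguineous"].n_families == 1
    assert strata["consanguineous"].affected_offspring_percent == 0.0
    assert strata["non-consanguineous"].n_families == 0
    assert strata["non-consanguineous"].mutation_positive_percent is None


def test_simulated_same_locus_homozygote_matings_are_group_one():
    """With a single fully penetrant locus, biallelic x biallelic matings can
    only produce deaf offspring, so every such family classifies Group I."""
    params = SimParams(population_size=3000, generations=2, q0=0.4, het_freqs=(),
                       epsilon=0.0, assortment=1.0, seed=31)
    cohort, _ = simulate_cohort(params, families=40, seed=31)
    checked = 0
    for fam in cohort.families_of_type("DXD"):
        partners = cohort.partners(fam)
        if all(p.genotypes["GJB2"].n_variant_alleles == 2 for p in partners):
            if cohort.offspring(fam):
                assert classify_offspring_phenotype(fam, cohort) == PhenotypeGroup.I
                checked += 1
    assert checked > 0
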