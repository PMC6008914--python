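"""Allele/genotype/carrier accounting against the published stratum tables."""

import re

import pytest

from dfnb1 import (
    SimParams,
    allele_counts,
    carrier_frequency,
    consanguinity_summary,
    genotype_frequency,
    simulate_cohort,
    write_cohort,
)
from dfnb1.cohort import Cohort, Family, Individual
from dfnb1.frequencies import EmptyStratumError, round_half_up
from dfnb1.registry import parse_genotype

# Published per-variant allele counts per stratum (gene GJB2).
DXD_COLUMN = {
    "W24X": 60, "V27I": 2, "I35S": 2, "V37I": 1, "E42D": 3, "T55T": 1,
    "R75Q": 1, "W77X": 5, "E114G": 2, "Q124X": 3, "R127H": 25, "V153I": 14,
    "R165W": 1, "R184Q": 1, "IVS1+1G>A": 4,
}
DXN_AFFECTED_COLUMN = {
    "W24X": 28, "W77X": 1, "T86M": 2, "A88A": 2, "Q124X": 2, "R127H": 4,
    "V153I": 1, "M195I": 1, "P225P": 1,
}
CONTROL_COLUMN = {
    "W24X": 6, "G45G": 1, "T55T": 3, "N62S": 1, "Q80Q": 2, "R127H": 57,
    "E147K": 1, "V153I": 6, "R165W": 3, "M195I": 1, "P225P": 1,
}


@pytest.mark.parametrize(
    "fixture,stratum,column,total,denom",
    [
        ("t8", "dxd-mates", DXD_COLUMN, 125, 236),
        ("t9", "dxn-affected", DXN_AFFECTED_COLUMN, 42, 92),
        ("t10", "controls", CONTROL_COLUMN, 82, 330),
    ],
)
def test_reconstructs_published_columns(request, fixture, stratum, column, total, denom):
    cohort = request.getfixturevalue(fixture)
    table = allele_counts(cohort, stratum, ("GJB2",), "all")
    assert table.denominator == denom
    assert table.total_count == total
    for variant, count in column.items():
        assert table.variant_count("GJB2", variant) == count, variant
    # per-variant counts sum to the overall count, and all percents in range
    assert sum(table.counts.values()) == table.total_count
    for key in table.counts:
        assert 0.0 <= table.variant_percent(*key) <= 100.0


def test_headline_percentages(t8, t9, t10):
    assert allele_counts(t8, "dxd-mates").overall_percent == pytest.approx(52.97, abs=0.011)
    assert allele_counts(t8, "dxd-mates").variant_percent("GJB2", "W24X") == 25.42
    assert allele_counts(t9, "dxn-affected").overall_percent == pytest.approx(45.65, abs=0.011)
    assert allele_counts(t10, "controls").overall_percent == pytest.approx(24.85, abs=0.011)
    assert allele_counts(t8, "dxd-mates", class_filter="pathogenic").overall_percent == pytest.approx(33.90, abs=0.011)
    assert allele_counts(t9, "dxn-affected", class_filter="pathogenic").overall_percent == pytest.approx(35.87, abs=0.011)


def _single_person_cohort(registry, gjb2):
    ind = Individual(
        individual_id="X", family_id="F", sex="M", hearing_status="normal",
        role="control", genotypes={"GJB2": parse_genotype(gjb2, "GJB2", registry)},
    )
    fam = Family(family_id="F", mating_type="control-group", other_ids=("X",))
    return Cohort(individuals={"X": ind}, families={"F": fam}, registry=registry)


def test_wildtype_individual_counts_zero_over_two(registry):
    cohort = _single_person_cohort(registry, "+/+")
    table = allele_counts(cohort, "controls")
    assert (table.total_count, table.denominator, table.overall_percent) == (0, 2, 0.0)


def test_empty_stratum_raises(t10):
    with pytest.raises(EmptyStratumError):
        allele_counts(t10, "dxd-mates")


def test_triallelic_counts_three_alleles_over_2n(registry):
    cohort = _single_person_cohort(registry, "W24X/T55T/R127H")
    table = allele_counts(cohort, "controls")
    assert table.total_count == 3 and table.denominator == 2


def test_allele_counts_match_naive_file_rescan(tmp_path, registry):
    """Oracle: re-count allele-name tokens straight off the written TSV."""
    params = SimParams(population_size=1500, generations=2, q0=0.2, het_freqs=(0.1,),
                       epsilon=0.2, assortment=0.7, seed=23)
    cohort, _ = simulate_cohort(params, families=40, seed=23)
    path = tmp_path / "sim.tsv"
    write_cohort(cohort, path)

    naive = 0
    n_rows = 0
    header = None
    for line in path.read_text().splitlines():
        fields = line.split("\t")
        if header is None:
            header = fields
            continue
        rec = dict(zip(header, fields))
        if rec["role"] != "mate" or rec["mating_type"] != "DXD":
            continue
        if rec["GJB2_genotype"] == ".":
            continue
        n_rows += 1
        naive += sum(
            1 for token in re.split(r"[/;]", rec["GJB2_genotype"]) if token not in ("+", "")
        )
    table = allele_counts(cohort, "dxd-mates", ("GJB2",), "all")
    assert table.total_count == naive
    assert table.denominator == 2 * n_rows


def test_genotype_frequencies(t8, t10, registry):
    inv = genotype_frequency(t8, "dxd-mates")
    row = inv[inv.genotype == "W24X/W24X"].iloc[0]
    assert (row["count"], row["n"]) == (26, 118)
    assert row["percent"] == 22.03
    digenic = inv[inv.section == "GJB2/GJB6-digenic"]
    assert list(digenic.genotype) == ["E42D/+;R104H/+"]

    ctrl = genotype_frequency(t10, "controls")
    row = ctrl[ctrl.genotype == "R127H/+"].iloc[0]
    assert (row["count"], row["percent"]) == (44, 26.67)

    one = _single_person_cohort(registry, "R127H/+")
    solo = genotype_frequency(one, "controls", genes=("GJB2",))
    assert solo.iloc[0]["percent"] == 100.0


def test_carrier_frequency_controls(registry_borderline):
    from dfnb1 import make_fixture

    t10b = make_fixture("T10", registry_borderline)
    cf = carrier_frequency(t10b, "controls", genes=("GJB2",), basis="alleles")
    assert (cf.numerator, cf.denominator) == (8, 330)
    assert cf.percent == 2.42


def test_carrier_frequency_individual_basis(registry):
    cohort = _single_person_cohort(registry, "W24X/+")
    cf = carrier_frequency(cohort, "controls", basis="individuals")
    assert cf.percent == 100.0 and cf.basis == "individuals"
    # a biallelic-pathogenic individual is affected, not a carrier
    hom = _single_person_cohort(registry, "W24X/W24X")
    assert carrier_frequency(hom, "controls", basis="individuals").percent == 0.0


def test_consanguinity_summary(study):
    s = consanguinity_summary(study)
    assert s["DXD"]["parental-combined"].percent == 45.0
    assert s["DXD"]["mating"].percent == 3.33
    assert s["DXD"]["parental-husband"].percent == 40.0
    assert s["DXD"]["parental-wife"].percent == 50.0
    assert s["DXN"]["mating"].percent == 39.13
    assert s["DXN"]["parental-combined"].percent == 32.61
    assert (s["DXN"]["parental-husband"].count, s["DXN"]["parental-wife"].count) == (17, 13)


def test_consanguinity_all_unknown(registry):
    ind = Individual(individual_id="A", family_id="F", sex="M", hearing_status="HI",
                     role="mate", parental_consanguinity="unknown")
    ind2 = Individual(individual_id="B", family_id="F", sex="F", hearing_status="HI",
                      role="mate", parental_consanguinity="unknown")
    fam = Family(family_id="F", mating_type="DXD", mating_consanguineous="unknown",
                 partner_ids=("A", "B"))
    cohort = Cohort(individuals={"A": ind, "B": ind2}, families={"F": fam}, registry=registry)
    s = consanguinity_summary(cohort)
    assert s["DXD"]["mating"].known == 0 and s["DXD"]["mating"].percent is None
    assert s["DXD"]["parental-combined"].percent is None


def test_round_half_up_is_half_up():
    assert round_half_up(2.425, 2) == 2.43
    assert round_half_up(52.9661, 2) == 52.97
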