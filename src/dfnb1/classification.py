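"""Family-level classification of assortative matings.

Deaf-by-deaf (DXD) families are grouped by offspring phenotype —
non-complementary (all offspring deaf), complementary (all hearing),
segregating (both), childless — and cross-tabulated against an eight-way
partner genotype cell derived solely from the two partners' GJB2/GJB6
calls.  Deaf-by-normal (DXN) families, where phenotypic complementarity
cannot be read off the offspring, are stratified by mating consanguinity
instead.

"Genotype-positive" means carrying at least one pathogenic-recessive,
pathogenic-dominant or novel-uncertain allele; polymorphism-only calls count
as non-carrier.  "Biallelic" means two or more such alleles at GJB2
(homozygous or compound heterozygous; a dominant heterozygote is positive
but not biallelic).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import pandas as pd

from .cohort import Cohort, Family, Individual
from .frequencies import percent
from .registry import VariantRegistry


class PhenotypeGroup(str, Enum):
    I = "I-non-complementary"  # all offspring hearing impaired
    II = "II-complementary"  # all offspring hearing
    III = "III-segregating"  # mixed offspring
    IV = "IV-no-offspring"


class GenotypeCell(str, Enum):
    BOTH_BIALLELIC = "both-biallelic"
    BOTH_HETEROZYGOUS = "both-heterozygous"
    ONE_BIALLELIC_ONE_HET = "one-biallelic-one-het"
    ONE_PARTNER_GJB2_HOMOZYGOUS = "one-partner-GJB2-homozygous"
    ONE_PARTNER_GJB2_HETEROZYGOUS = "one-partner-GJB2-heterozygous"
    ONE_PARTNER_GJB6_HETEROZYGOUS = "one-partner-GJB6-heterozygous"
    DIGENIC = "digenic"
    NON_GJB2_NON_GJB6 = "non-GJB2-non-GJB6"


CELL_ORDER = tuple(GenotypeCell)
GROUP_ORDER = tuple(PhenotypeGroup)


class ClassificationError(ValueError):
    pass


def classify_offspring_phenotype(family: Family, cohort: Cohort) -> PhenotypeGroup:
    """Group a family by its offspring phenotypes (order-invariant).

    Raises :class:`ClassificationError` if any offspring has unknown hearing
    status — a family cannot be placed with a partially phenotyped sibship.
    """
    offspring = cohort.offspring(family)
    if not offspring:
        return PhenotypeGroup.IV
    statuses = {o.hearing_status for o in offspring}
    if "unknown" in statuses:
        bad = [o.individual_id for o in offspring if o.hearing_status == "unknown"]
        raise ClassificationError(
            f"family {family.family_id}: offspring with unknown phenotype: {bad}"
        )
    if statuses == {"HI"}:
        return PhenotypeGroup.I
    if statuses == {"normal"}:
        return PhenotypeGroup.II
    return PhenotypeGroup.III


def _partner_burden(ind: Individual, registry: VariantRegistry) -> dict[str, int]:
    """Pathogenic/novel allele counts per gene for one partner."""
    return {
        gene: call.n_pathogenic_alleles(registry) for gene, call in ind.genotypes.items()
    }


@dataclass(frozen=True)
class CellAssignment:
    cell: GenotypeCell
    #: True when a partner was unsampled and the cell rests on one genotype
    #: only (footnoted in the published cross-tabulation).
    partner_unsampled: bool = False
    #: Set when a hearing-impaired offspring carries exactly one pathogenic
    #: allele — the pseudo-dominant transmission pattern.
    pseudo_dominant_note: str = ""


def genotype_cell(
    family: Family, cohort: Cohort, registry: VariantRegistry | None = None
) -> CellAssignment:
    """Assign one of the eight partner-genotype cells.

    Precedence: digenic > both-partner GJB2 cells > single-partner GJB2
    cells > single-partner GJB6 cell > no mutation.  Families with an
    unsampled partner are assigned from the available partner and flagged.
    """
    registry = registry or cohort.registry
    partners = cohort.partners(family)
    sampled = [p for p in partners if p.is_sampled]
    if not sampled:
        raise ClassificationError(
            f"family {family.family_id}: no sampled partner, genotype cell unresolvable"
        )
    unsampled = len(sampled) < len(partners) or len(partners) < 2

    burdens = [_partner_burden(p, registry) for p in sampled]
    digenic = any(b.get("GJB2", 0) >= 1 and b.get("GJB6", 0) >= 1 for b in burdens)
    gjb2 = sorted((b.get("GJB2", 0) for b in burdens), reverse=True)
    gjb6_positive = any(b.get("GJB6", 0) >= 1 for b in burdens)

    note = _pseudo_dominant_note(family, cohort, registry)

    if digenic:
        cell = GenotypeCell.DIGENIC
    elif len(gjb2) >= 2 and gjb2[0] >= 1 and gjb2[1] >= 1:
        if gjb2[0] >= 2 and gjb2[1] >= 2:
            cell = GenotypeCell.BOTH_BIALLELIC
        elif gjb2[0] >= 2:
            cell = GenotypeCell.ONE_BIALLELIC_ONE_HET
        else:
            cell = GenotypeCell.BOTH_HETEROZYGOUS
    elif gjb2 and gjb2[0] >= 2:
        cell = GenotypeCell.ONE_PARTNER_GJB2_HOMOZYGOUS
    elif gjb2 and gjb2[0] == 1:
        cell = GenotypeCell.ONE_PARTNER_GJB2_HETEROZYGOUS
    elif gjb6_positive:
        cell = GenotypeCell.ONE_PARTNER_GJB6_HETEROZYGOUS
    else:
        cell = GenotypeCell.NON_GJB2_NON_GJB6
    return CellAssignment(cell=cell, partner_unsampled=unsampled, pseudo_dominant_note=note)


def _pseudo_dominant_note(family: Family, cohort: Cohort, registry: VariantRegistry) -> str:
    hits = []
    for off in cohort.offspring(family):
        if off.hearing_status != "HI" or not off.is_sampled:
            continue
        n_path = sum(
            call.n_pathogenic_alleles(registry) for call in off.genotypes.values()
        )
        if n_path == 1:
            hits.append(off.individual_id)
    if hits:
        return f"HI offspring with a single pathogenic allele (pseudo-dominant pattern): {hits}"
    return ""


@dataclass(frozen=True)
class MatingClassification:
    family_id: str
    phenotype_group: PhenotypeGroup
    genotype_cell: GenotypeCell
    partner_unsampled: bool = False
    pseudo_dominant_note: str = ""


def classify_family(
    family: Family, cohort: Cohort, registry: VariantRegistry | None = None
) -> MatingClassification:
    assignment = genotype_cell(family, cohort, registry)
    return MatingClassification(
        family_id=family.family_id,
        phenotype_group=classify_offspring_phenotype(family, cohort),
        genotype_cell=assignment.cell,
        partner_unsampled=assignment.partner_unsampled,
        pseudo_dominant_note=assignment.pseudo_dominant_note,
    )


def tabulate_dxd(cohort: Cohort, registry: VariantRegistry | None = None) -> pd.DataFrame:
    """Phenotype-group x genotype-cell cross-tabulation of the DXD families.

    Returns a 4x8 integer table with a TOTAL row and column; each family
    falls in exactly one cell, so the grand total equals the number of DXD
    families.
    """
    counts = {(g, c): 0 for g in GROUP_ORDER for c in CELL_ORDER}
    for fam in cohort.families_of_type("DXD"):
        mc = classify_family(fam, cohort, registry)
        counts[(mc.phenotype_group, mc.genotype_cell)] += 1
    data = {
        c.value: [counts[(g, c)] for g in GROUP_ORDER] for c in CELL_ORDER
    }
    df = pd.DataFrame(data, index=[g.value for g in GROUP_ORDER])
    df["TOTAL"] = df.sum(axis=1)
    df.loc["TOTAL"] = df.sum(axis=0)
    return df


@dataclass(frozen=True)
class DxnStratum:
    consanguineous: bool
    n_families: int
    n_with_affected_offspring: int
    n_mutation_positive: int

    @property
    def affected_offspring_percent(self) -> float | None:
        return None if self.n_families == 0 else percent(self.n_with_affected_offspring, self.n_families)

    @property
    def mutation_positive_percent(self) -> float | None:
        return None if self.n_families == 0 else percent(self.n_mutation_positive, self.n_families)


def stratify_dxn(
    cohort: Cohort, registry: VariantRegistry | None = None
) -> dict[str, DxnStratum]:
    """DXN families stratified by mating consanguinity.

    Per stratum: family count, families with at least one hearing-impaired
    offspring, and families with pathogenic/novel GJB2 or GJB6 variants in
    at least one partner.
    """
    registry = registry or cohort.registry
    out = {}
    for label, want in (("consanguineous", "yes"), ("non-consanguineous", "no")):
        fams = [
            f for f in cohort.families_of_type("DXN") if f.mating_consanguineous == want
        ]
        affected = 0
        positive = 0
        for fam in fams:
            if any(o.hearing_status == "HI" for o in cohort.offspring(fam)):
                affected += 1
            burdens = [
                _partner_burden(p, registry) for p in cohort.partners(fam) if p.is_sampled
            ]
            if any(sum(b.values()) >= 1 for b in burdens):
                positive += 1
        out[label] = DxnStratum(
            consanguineous=(want == "yes"),
            n_families=len(fams),
            n_with_affected_offspring=affected,
            n_mutation_positive=positive,
        )
    return out
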