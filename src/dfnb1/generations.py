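"""Two-generation DFNB1 allele-frequency contrast.

The real-time test of the relaxed-selection hypothesis: compare the
frequency of pathogenic (including novel) GJB2/GJB6 alleles in the mating
generation against their own offspring.  Only families that contributed at
least one sampled offspring enter either pool, so parents and children
describe the same transmissions.
"""

from __future__ import annotations

from dataclasses import dataclass

from .cohort import Cohort
from .frequencies import round_half_up
from .registry import VariantRegistry

GENE_SET = ("GJB2", "GJB6")


class UndefinedIncreaseError(ZeroDivisionError):
    """Relative increase is undefined when the parental frequency is zero."""


def relative_increase(parental_pct: float, offspring_pct: float) -> float:
    """Percent change of the offspring frequency relative to the parental one.

    ``100 x (offspring - parental) / parental``; display convention is one
    decimal (e.g. parental 36.98%, offspring 38.67% -> 4.57, shown as 4.6).
    """
    if parental_pct == 0:
        raise UndefinedIncreaseError("parental frequency is zero; relative increase undefined")
    return 100.0 * (offspring_pct - parental_pct) / parental_pct


@dataclass(frozen=True)
class GenerationContrast:
    subgroup: str
    parental_frequency: float  # percent
    offspring_frequency: float  # percent
    parental_alleles: int
    parental_chromosomes: int
    offspring_alleles: int
    offspring_chromosomes: int
    n_families: int

    @property
    def absolute_change(self) -> float:
        return self.offspring_frequency - self.parental_frequency

    @property
    def relative_increase_percent(self) -> float | None:
        """None when the parental frequency is zero (undefined)."""
        if self.parental_frequency == 0:
            return None
        return relative_increase(self.parental_frequency, self.offspring_frequency)

    def rounded(self) -> dict[str, float | None]:
        ri = self.relative_increase_percent
        return {
            "parental_frequency": round_half_up(self.parental_frequency, 2),
            "offspring_frequency": round_half_up(self.offspring_frequency, 2),
            "absolute_change": round_half_up(self.absolute_change, 2),
            "relative_increase": None if ri is None else round_half_up(ri, 1),
        }


def _pathogenic_alleles(ind, registry: VariantRegistry) -> int:
    return sum(
        call.n_pathogenic_alleles(registry)
        for gene, call in ind.genotypes.items()
        if gene in GENE_SET
    )


def generation_frequencies(
    cohort: Cohort, subgroup: str, registry: VariantRegistry | None = None
) -> GenerationContrast:
    """Parental vs offspring DFNB1 pathogenic-allele frequency for DXD or DXN.

    The parental pool holds the sampled partners of families with at least
    one sampled offspring; the offspring pool holds those sampled children.
    Frequencies follow the package-wide 2N-chromosome convention; offspring
    without genotype data are excluded from the offspring denominator.
    """
    if subgroup not in ("DXD", "DXN"):
        raise ValueError(f"subgroup must be 'DXD' or 'DXN', got {subgroup!r}")
    registry = registry or cohort.registry

    par_alleles = par_n = off_alleles = off_n = n_families = 0
    for fam in cohort.families_of_type(subgroup):
        kids = [o for o in cohort.offspring(fam) if o.is_sampled]
        if not kids:
            continue
        n_families += 1
        for p in cohort.partners(fam):
            if p.is_sampled:
                par_n += 1
                par_alleles += _pathogenic_alleles(p, registry)
        for k in kids:
            off_n += 1
            off_alleles += _pathogenic_alleles(k, registry)

    if n_families == 0:
        raise ValueError(f"no {subgroup} families with sampled offspring")
    return GenerationContrast(
        subgroup=subgroup,
        parental_frequency=100.0 * par_alleles / (2 * par_n),
        offspring_frequency=100.0 * off_alleles / (2 * off_n),
        parental_alleles=par_alleles,
        parental_chromosomes=2 * par_n,
        offspring_alleles=off_alleles,
        offspring_chromosomes=2 * off_n,
        n_families=n_families,
    )
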