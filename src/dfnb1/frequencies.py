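"""Allele, genotype and carrier frequency accounting per cohort stratum.

Denominator convention
----------------------
Frequencies are computed over ``2N`` chromosomes, where ``N`` is the number
of *sampled* individuals in the stratum (unsampled members are excluded).
Triallelic calls contribute three variant alleles against the unchanged
``2N`` denominator, and a digenic individual contributes one allele to each
gene's own tally.  This is the accounting under which the study cohort's
published totals hold (e.g. 125 variant alleles over 236 chromosomes among
118 deaf-by-deaf mates, 52.96%), so it is adopted package-wide.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Callable, Iterable, Sequence

import pandas as pd

from .cohort import Cohort, Family, Individual
from .registry import PATHOGENIC_CLASSES, VariantRegistry

StratumSelector = str | Callable[[Individual, Family], bool]

#: Named strata used throughout the analysis.
NAMED_STRATA: dict[str, Callable[[Individual, Family], bool]] = {
    "dxd-mates": lambda i, f: f.mating_type == "DXD" and i.role == "mate",
    "dxn-affected": lambda i, f: f.mating_type == "DXN" and i.role == "mate",
    "dxn-hearing-partners": lambda i, f: f.mating_type == "DXN" and i.role == "hearing-partner",
    "controls": lambda i, f: i.role == "control",
    "dxd-offspring": lambda i, f: f.mating_type == "DXD" and i.role == "offspring",
    "dxn-offspring": lambda i, f: f.mating_type == "DXN" and i.role == "offspring",
}


class EmptyStratumError(ValueError):
    """Frequency requested over a stratum with no sampled individuals."""


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal half-up rounding, the convention of the published tables."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def percent(count: float, denominator: float, ndigits: int = 2) -> float:
    return round_half_up(100.0 * count / denominator, ndigits)


def select_stratum(cohort: Cohort, stratum: StratumSelector) -> list[Individual]:
    if isinstance(stratum, str):
        try:
            pred = NAMED_STRATA[stratum]
        except KeyError:
            raise KeyError(f"unknown stratum {stratum!r}; known: {sorted(NAMED_STRATA)}")
    else:
        pred = stratum
    out = []
    for fam in cohort.families.values():
        for ind in cohort.members(fam):
            if pred(ind, fam):
                out.append(ind)
    return out


def _resolve_classes(class_filter: str | Iterable[str]) -> frozenset[str] | None:
    if class_filter == "all":
        return None
    if class_filter == "pathogenic":
        return PATHOGENIC_CLASSES
    if isinstance(class_filter, str):
        return frozenset({class_filter})
    return frozenset(class_filter)


@dataclass
class FrequencyTable:
    """Stratum-wise per-variant allele counts with an explicit denominator."""

    stratum: str
    genes: tuple[str, ...]
    class_filter: str
    n_individuals: int
    counts: dict[tuple[str, str], int]  # (gene, protein_name) -> allele count

    @property
    def denominator(self) -> int:
        """Chromosomes: 2 x sampled individuals, regardless of triallelism."""
        return 2 * self.n_individuals

    @property
    def total_count(self) -> int:
        return sum(self.counts.values())

    @property
    def overall_percent(self) -> float:
        return percent(self.total_count, self.denominator)

    def variant_percent(self, gene: str, protein_name: str) -> float:
        return percent(self.counts.get((gene, protein_name), 0), self.denominator)

    def variant_count(self, gene: str, protein_name: str) -> int:
        return self.counts.get((gene, protein_name), 0)

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {
                "gene": g,
                "variant": v,
                "alleles": c,
                "denominator": self.denominator,
                "percent": percent(c, self.denominator),
            }
            for (g, v), c in sorted(self.counts.items())
        ]
        rows.append(
            {
                "gene": "*",
                "variant": "TOTAL",
                "alleles": self.total_count,
                "denominator": self.denominator,
                "percent": self.overall_percent,
            }
        )
        return pd.DataFrame(rows, columns=["gene", "variant", "alleles", "denominator", "percent"])


def allele_counts(
    cohort: Cohort,
    stratum: StratumSelector,
    genes: Sequence[str] = ("GJB2",),
    class_filter: str | Iterable[str] = "all",
) -> FrequencyTable:
    """Per-variant allele counts for a stratum over one or more genes.

    ``class_filter`` is ``"all"``, ``"pathogenic"`` (pathogenic-recessive,
    pathogenic-dominant and novel-uncertain together — the "pathogenic
    mutations including the novel variants" convention), a single effect
    class, or an explicit iterable of classes.
    """
    genes = tuple(genes)
    selected = [i for i in select_stratum(cohort, stratum) if i.sampled_for(genes)]
    if not selected:
        raise EmptyStratumError(
            f"stratum {stratum!r} has no individuals sampled for {genes}: frequency undefined"
        )
    classes = _resolve_classes(class_filter)
    registry = cohort.registry
    counts: dict[tuple[str, str], int] = {}
    for ind in selected:
        for gene in genes:
            for allele in ind.genotypes[gene].alleles:
                if classes is not None and registry.classify(gene, allele) not in classes:
                    continue
                counts[(gene, allele)] = counts.get((gene, allele), 0) + 1
    label = stratum if isinstance(stratum, str) else "<custom>"
    cf = class_filter if isinstance(class_filter, str) else ",".join(sorted(class_filter))
    return FrequencyTable(
        stratum=label, genes=genes, class_filter=cf, n_individuals=len(selected), counts=counts
    )


# -- genotype inventories ---------------------------------------------------

_SECTION_ORDER = (
    "GJB2-biallelic/triallelic",
    "GJB2-monoallelic",
    "GJB6-biallelic/triallelic",
    "GJB6-monoallelic",
    "GJB2/GJB6-digenic",
    "no-variant",
)


def _genotype_section_and_string(ind: Individual, genes: Sequence[str]) -> tuple[str, str]:
    calls = {g: ind.genotypes[g] for g in genes if g in ind.genotypes}
    with_variants = {g: c for g, c in calls.items() if c.n_variant_alleles > 0}
    if not with_variants:
        return "no-variant", "+/+"
    if len(with_variants) > 1:
        s = ";".join(c.render() for g, c in sorted(with_variants.items()))
        return "GJB2/GJB6-digenic", s
    gene, call = next(iter(with_variants.items()))
    kind = "monoallelic" if call.n_variant_alleles == 1 else "biallelic/triallelic"
    return f"{gene}-{kind}", call.render()


def genotype_frequency(
    cohort: Cohort,
    stratum: StratumSelector,
    genes: Sequence[str] = ("GJB2", "GJB6"),
    include_no_variant: bool = False,
) -> pd.DataFrame:
    """Inventory of distinct genotype strings in a stratum.

    Returns a DataFrame with columns section / genotype / count / percent,
    where percent is ``100 x count / N`` over the stratum's sampled
    individuals (individual basis, matching the published genotype tables).
    Genotypes spanning both genes are reported as a single digenic string.
    """
    genes = tuple(genes)
    selected = [i for i in select_stratum(cohort, stratum) if any(g in i.genotypes for g in genes)]
    if not selected:
        raise EmptyStratumError(f"stratum {stratum!r} is empty: genotype frequency undefined")
    n = len(selected)
    tally: dict[tuple[str, str], int] = {}
    for ind in selected:
        key = _genotype_section_and_string(ind, genes)
        tally[key] = tally.get(key, 0) + 1
    rows = []
    for (section, genotype), count in tally.items():
        if section == "no-variant" and not include_no_variant:
            continue
        rows.append(
            {
                "section": section,
                "genotype": genotype,
                "count": count,
                "n": n,
                "percent": percent(count, n),
            }
        )
    rows.sort(key=lambda r: (_SECTION_ORDER.index(r["section"]), -r["count"], r["genotype"]))
    return pd.DataFrame(rows, columns=["section", "genotype", "count", "n", "percent"])


# -- carrier frequency ------------------------------------------------------


@dataclass(frozen=True)
class CarrierFrequency:
    percent: float
    numerator: int
    denominator: int
    basis: str  # "alleles" | "individuals"


def carrier_frequency(
    cohort: Cohort,
    stratum: StratumSelector,
    registry: VariantRegistry | None = None,
    genes: Sequence[str] = ("GJB2",),
    basis: str = "alleles",
) -> CarrierFrequency:
    """Carrier frequency for pathogenic (incl. novel-uncertain) variants.

    A carrier holds at least one pathogenic allele but is not
    biallelic-pathogenic at any single gene (two pathogenic alleles at one
    gene constitute an affected genotype, not carriage).  ``basis`` selects
    the denominator: pathogenic alleles held by carriers over ``2N``
    chromosomes, or carrier individuals over ``N``.
    """
    if basis not in ("alleles", "individuals"):
        raise ValueError(f"basis must be 'alleles' or 'individuals', got {basis!r}")
    registry = registry or cohort.registry
    genes = tuple(genes)
    selected = [i for i in select_stratum(cohort, stratum) if i.sampled_for(genes)]
    if not selected:
        raise EmptyStratumError(f"stratum {stratum!r} empty: carrier frequency undefined")
    carrier_alleles = 0
    carrier_individuals = 0
    for ind in selected:
        per_gene = {g: ind.genotypes[g].n_pathogenic_alleles(registry) for g in genes}
        total = sum(per_gene.values())
        if total >= 1 and all(c < 2 for c in per_gene.values()):
            carrier_individuals += 1
            carrier_alleles += total
    n = len(selected)
    if basis == "alleles":
        return CarrierFrequency(percent(carrier_alleles, 2 * n), carrier_alleles, 2 * n, basis)
    return CarrierFrequency(percent(carrier_individuals, n), carrier_individuals, n, basis)


# -- consanguinity tallies --------------------------------------------------


@dataclass(frozen=True)
class Tally:
    count: int
    known: int

    @property
    def percent(self) -> float | None:
        return None if self.known == 0 else percent(self.count, self.known)


def consanguinity_summary(cohort: Cohort) -> dict[str, dict[str, Tally]]:
    """Consanguinity at two levels, per mating type.

    For each mating type: the fraction of consanguineous matings, and the
    parental consanguinity of the partners — husband side, wife side and
    combined.  Denominators count only individuals/families whose flag is
    known; with all flags unknown every tally is empty.
    """
    out: dict[str, dict[str, Tally]] = {}
    for mt in ("DXD", "DXN"):
        fams = cohort.families_of_type(mt)
        if not fams:
            continue
        mating_known = [f for f in fams if f.mating_consanguineous != "unknown"]
        mating_yes = sum(1 for f in mating_known if f.mating_consanguineous == "yes")
        sides: dict[str, list[Individual]] = {"husband": [], "wife": []}
        for fam in fams:
            for p in cohort.partners(fam):
                side = "husband" if p.sex == "M" else "wife"
                sides[side].append(p)
        tallies: dict[str, Tally] = {
            "mating": Tally(mating_yes, len(mating_known)),
        }
        combined_yes = combined_known = 0
        for side, people in sides.items():
            known = [p for p in people if p.parental_consanguinity != "unknown"]
            yes = sum(1 for p in known if p.parental_consanguinity == "yes")
            tallies[f"parental-{side}"] = Tally(yes, len(known))
            combined_yes += yes
            combined_known += len(known)
        tallies["parental-combined"] = Tally(combined_yes, combined_known)
        out[mt] = tallies

    controls = [i for i in cohort.individuals.values() if i.role == "control"]
    if controls:
        known = [c for c in controls if c.parental_consanguinity != "unknown"]
        yes = sum(1 for c in known if c.parental_consanguinity == "yes")
        out["control-group"] = {"parental-combined": Tally(yes, len(known))}
    return out
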