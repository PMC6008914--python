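"""Pedigree-structured cohort files for assortative-mating families.

The on-disk dialect is a PED-like TSV, one row per individual, with per-gene
genotype columns (``GJB2_genotype``, ``GJB6_genotype``) and family-level
mating descriptors repeated on each member row.  ``.`` means missing
throughout; a missing genotype marks an unsampled individual, which is
distinct from ``+/+`` (sampled, no variant found).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from .registry import (
    GENES,
    GenotypeCall,
    GenotypeParseError,
    VariantRegistry,
    parse_genotype,
)

MISSING = "."

HEARING_STATUSES = ("HI", "normal", "unknown")
ROLES = ("mate", "hearing-partner", "offspring", "other-HI", "other-hearing", "control")
MATING_TYPES = ("DXD", "DXN", "control-group")
YES_NO_UNKNOWN = ("yes", "no", "unknown")

COLUMNS = (
    "family_id",
    "individual_id",
    "father_id",
    "mother_id",
    "sex",
    "hearing_status",
    "role",
    "parental_consanguinity",
    "mating_type",
    "mating_consanguineous",
    "GJB2_genotype",
    "GJB6_genotype",
    "phenotype_notes",
)


class CohortFormatError(ValueError):
    """Malformed cohort file (reported with the offending line number)."""


class CohortValidationError(ValueError):
    """Structurally parseable cohort that violates a family invariant."""


@dataclass
class Individual:
    individual_id: str
    family_id: str
    father_id: str | None = None
    mother_id: str | None = None
    sex: str = "U"  # M / F / U
    hearing_status: str = "unknown"
    role: str = "other-hearing"
    parental_consanguinity: str = "unknown"
    #: gene -> GenotypeCall; a gene absent from the mapping was not sampled
    genotypes: dict[str, GenotypeCall] = field(default_factory=dict)
    phenotype_notes: str = ""

    @property
    def is_sampled(self) -> bool:
        return bool(self.genotypes)

    def sampled_for(self, genes: Iterable[str]) -> bool:
        return all(g in self.genotypes for g in genes)


@dataclass
class Family:
    family_id: str
    mating_type: str
    mating_consanguineous: str = "unknown"
    partner_ids: tuple[str, ...] = ()
    offspring_ids: tuple[str, ...] = ()
    other_ids: tuple[str, ...] = ()


@dataclass
class Cohort:
    """A set of families plus the registry their genotypes resolve against."""

    individuals: dict[str, Individual]
    families: dict[str, Family]
    registry: VariantRegistry

    def members(self, family: Family) -> list[Individual]:
        ids = list(family.partner_ids) + list(family.offspring_ids) + list(family.other_ids)
        return [self.individuals[i] for i in ids]

    def partners(self, family: Family) -> list[Individual]:
        return [self.individuals[i] for i in family.partner_ids]

    def offspring(self, family: Family) -> list[Individual]:
        return [self.individuals[i] for i in family.offspring_ids]

    def families_of_type(self, mating_type: str) -> list[Family]:
        return [f for f in self.families.values() if f.mating_type == mating_type]

    def __len__(self) -> int:
        return len(self.individuals)


def _parse_individual(rec: Mapping[str, str], registry: VariantRegistry, lineno: int) -> Individual:
    def opt(key: str) -> str | None:
        val = rec.get(key, MISSING)
        return None if val == MISSING else val

    hearing = rec["hearing_status"]
    role = rec["role"]
    if hearing not in HEARING_STATUSES:
        raise CohortFormatError(f"line {lineno}: bad hearing_status {hearing!r}")
    if role not in ROLES:
        raise CohortFormatError(f"line {lineno}: bad role {role!r}")
    pc = rec["parental_consanguinity"]
    if pc == MISSING:
        pc = "unknown"
    if pc not in YES_NO_UNKNOWN:
        raise CohortFormatError(f"line {lineno}: bad parental_consanguinity {pc!r}")

    genotypes: dict[str, GenotypeCall] = {}
    for gene in GENES:
        raw = rec.get(f"{gene}_genotype", MISSING)
        if raw == MISSING or raw == "":
            continue
        try:
            genotypes[gene] = parse_genotype(raw, gene, registry)
        except GenotypeParseError as exc:
            raise CohortFormatError(f"line {lineno}: {exc}") from exc

    return Individual(
        individual_id=rec["individual_id"],
        family_id=rec["family_id"],
        father_id=opt("father_id"),
        mother_id=opt("mother_id"),
        sex=rec.get("sex", MISSING).replace(MISSING, "U") or "U",
        hearing_status=hearing,
        role=role,
        parental_consanguinity=pc,
        genotypes=genotypes,
        phenotype_notes="" if rec.get("phenotype_notes", MISSING) == MISSING else rec["phenotype_notes"],
    )


def read_cohort(path: str | Path, registry: VariantRegistry) -> Cohort:
    """Read and validate a cohort TSV.

    Raises :class:`CohortFormatError` (with line number) for malformed rows
    and :class:`CohortValidationError` when a family invariant is violated
    (e.g. a DXD family whose partners are not both hearing impaired).
    """
    path = Path(path)
    individuals: dict[str, Individual] = {}
    fam_rows: dict[str, dict[str, str]] = {}
    fam_members: dict[str, dict[str, list[str]]] = {}

    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header: list[str] | None = None
        for lineno, row in enumerate(reader, 1):
            if not row or row[0].lstrip().startswith("#"):
                continue
            if header is None:
                header = [c.strip() for c in row]
                missing = [c for c in COLUMNS if c not in header]
                if missing:
                    raise CohortFormatError(f"{path}: header lacks columns {missing}")
                continue
            if len(row) != len(header):
                raise CohortFormatError(
                    f"line {lineno}: expected {len(header)} fields, got {len(row)}"
                )
            rec = dict(zip(header, row))
            ind = _parse_individual(rec, registry, lineno)
            if ind.individual_id in individuals:
                raise CohortFormatError(
                    f"line {lineno}: duplicate individual_id {ind.individual_id!r}"
                )
            individuals[ind.individual_id] = ind

            fam = fam_rows.setdefault(
                ind.family_id,
                {
                    "mating_type": rec["mating_type"],
                    "mating_consanguineous": rec["mating_consanguineous"].replace(MISSING, "unknown")
                    or "unknown",
                },
            )
            if rec["mating_type"] != fam["mating_type"]:
                raise CohortFormatError(
                    f"line {lineno}: family {ind.family_id} has conflicting mating_type"
                )
            slots = fam_members.setdefault(
                ind.family_id, {"partners": [], "offspring": [], "other": []}
            )
            if ind.role in ("mate", "hearing-partner"):
                slots["partners"].append(ind.individual_id)
            elif ind.role == "offspring":
                slots["offspring"].append(ind.individual_id)
            else:
                slots["other"].append(ind.individual_id)

    families: dict[str, Family] = {}
    for fid, meta in fam_rows.items():
        mt = meta["mating_type"]
        if mt not in MATING_TYPES:
            raise CohortFormatError(f"family {fid}: bad mating_type {mt!r}")
        mc = meta["mating_consanguineous"]
        if mc not in YES_NO_UNKNOWN:
            raise CohortFormatError(f"family {fid}: bad mating_consanguineous {mc!r}")
        slots = fam_members[fid]
        families[fid] = Family(
            family_id=fid,
            mating_type=mt,
            mating_consanguineous=mc,
            partner_ids=tuple(slots["partners"]),
            offspring_ids=tuple(slots["offspring"]),
            other_ids=tuple(slots["other"]),
        )

    cohort = Cohort(individuals=individuals, families=families, registry=registry)
    issues = validate_cohort(cohort)
    fatal = [i for i in issues if i.severity == "error"]
    if fatal:
        raise CohortValidationError(
            "; ".join(f"{i.kind}: {i.message}" for i in fatal)
        )
    return cohort


@dataclass(frozen=True)
class Issue:
    severity: str  # "error" | "warning"
    kind: str
    message: str


def validate_cohort(cohort: Cohort) -> list[Issue]:
    """Structural checks. Returns a (possibly empty) issue list; never mutates.

    Errors: partner-phenotype mismatches with the declared mating type, an
    individual appearing as partner in two families, role/phenotype
    contradictions.  Warnings: dangling parent links (treated as founders).
    """
    issues: list[Issue] = []
    partner_seen: dict[str, str] = {}

    for ind in cohort.individuals.values():
        if ind.role == "hearing-partner" and ind.hearing_status != "normal":
            issues.append(
                Issue("error", "role-phenotype", f"{ind.individual_id}: hearing-partner must be normal hearing")
            )
        if ind.role == "mate" and ind.hearing_status != "HI":
            issues.append(
                Issue("error", "role-phenotype", f"{ind.individual_id}: mate must be hearing impaired")
            )
        for pid, label in ((ind.father_id, "father"), (ind.mother_id, "mother")):
            if pid is not None and pid not in cohort.individuals:
                issues.append(
                    Issue("warning", "dangling-parent", f"{ind.individual_id}: {label}_id {pid!r} not in cohort")
                )

    for fam in cohort.families.values():
        partners = cohort.partners(fam)
        for p in partners:
            if p.individual_id in partner_seen and partner_seen[p.individual_id] != fam.family_id:
                issues.append(
                    Issue("error", "duplicate-partner", f"{p.individual_id} is a partner in two families")
                )
            partner_seen[p.individual_id] = fam.family_id
        if fam.mating_type == "DXD":
            if len(partners) != 2 or any(p.hearing_status != "HI" for p in partners):
                issues.append(
                    Issue("error", "mating-type", f"family {fam.family_id}: DXD requires two HI partners")
                )
        elif fam.mating_type == "DXN":
            n_hi = sum(1 for p in partners if p.hearing_status == "HI")
            if len(partners) != 2 or n_hi != 1:
                issues.append(
                    Issue("error", "mating-type", f"family {fam.family_id}: DXN requires one HI and one hearing partner")
                )
    return issues


def write_cohort(cohort: Cohort, path: str | Path) -> None:
    """Write a cohort TSV that :func:`read_cohort` round-trips structurally."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(COLUMNS)
        for fam in cohort.families.values():
            for ind in cohort.members(fam):
                writer.writerow(
                    [
                        fam.family_id,
                        ind.individual_id,
                        ind.father_id or MISSING,
                        ind.mother_id or MISSING,
                        ind.sex or "U",
                        ind.hearing_status,
                        ind.role,
                        ind.parental_consanguinity,
                        fam.mating_type,
                        fam.mating_consanguineous,
                        ind.genotypes["GJB2"].render() if "GJB2" in ind.genotypes else MISSING,
                        ind.genotypes["GJB6"].render() if "GJB6" in ind.genotypes else MISSING,
                        ind.phenotype_notes or MISSING,
                    ]
                )


def merge_cohorts(*cohorts: Cohort) -> Cohort:
    """Union of disjoint cohorts sharing one registry (ids must not clash)."""
    if not cohorts:
        raise ValueError("nothing to merge")
    individuals: dict[str, Individual] = {}
    families: dict[str, Family] = {}
    for c in cohorts:
        for iid, ind in c.individuals.items():
            if iid in individuals:
                raise CohortValidationError(f"duplicate individual_id {iid!r} across cohorts")
            individuals[iid] = ind
        for fid, fam in c.families.items():
            if fid in families:
                raise CohortValidationError(f"duplicate family_id {fid!r} across cohorts")
            families[fid] = fam
    return Cohort(individuals=individuals, families=families, registry=cohorts[0].registry)
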