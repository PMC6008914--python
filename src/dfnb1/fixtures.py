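"""Reference cohorts reproducing the published genotype inventories.

Four cohorts are constructible:

* ``T8``  — the 60 deaf-by-deaf (DXD) families: 118 sampled HI mates (58
  husbands, 60 wives; two husbands unsampled) with the full GJB2/GJB6
  genotype inventory, plus the two-level consanguinity flags (parental:
  24/60 husband-side, 30/60 wife-side; mating: 2/60).
* ``T9``  — the 46 deaf-by-normal (DXN) families: 46 affected partners and
  43 sampled hearing partners (three unsampled), the genotype inventory,
  the 18/28 mating-consanguinity split, offspring phenotypes and
  partner-level parental-consanguinity flags consistent with the published
  stratification.
* ``T10`` — 165 normal-hearing controls with their GJB2 genotype inventory.
* ``T13`` — a 60-family DXD cohort whose partner genotypes and offspring
  phenotypes realize the published phenotype-group x genotype-cell
  cross-tabulation (17/30/2/11 row totals; 8 both-biallelic
  non-complementary families).  Its genotypes are schematic cell
  representatives, independent of the T8 inventory.

GJB6 wild type is imputed (``+/+``) for sampled individuals without a GJB6
finding; in the source study only a subset was GJB6-screened, but no GJB6
variant exists outside the individuals encoded here, so the imputation is
count-neutral.  One historical transcription quirk is preserved: the hearing
partner printed as "R153I/R165W" is encoded V153I/R165W with the raw string
in ``phenotype_notes``.
"""

from __future__ import annotations

from .cohort import Cohort, Family, Individual, merge_cohorts
from .registry import GenotypeCall, VariantRegistry, default_registry, parse_genotype

TABLE_IDS = ("T8", "T9", "T10", "T13")


def _call(text: str | None, gene: str, registry: VariantRegistry) -> dict[str, GenotypeCall]:
    if text is None:
        return {}
    return {gene: parse_genotype(text, gene, registry)}


def _person(
    registry: VariantRegistry,
    iid: str,
    fid: str,
    *,
    sex: str,
    hearing: str,
    role: str,
    gjb2: str | None = "+/+",
    gjb6: str | None = "+/+",
    pc: str = "unknown",
    father: str | None = None,
    mother: str | None = None,
    notes: str = "",
) -> Individual:
    genotypes = {}
    genotypes.update(_call(gjb2, "GJB2", registry))
    genotypes.update(_call(gjb6, "GJB6", registry))
    return Individual(
        individual_id=iid,
        family_id=fid,
        father_id=father,
        mother_id=mother,
        sex=sex,
        hearing_status=hearing,
        role=role,
        parental_consanguinity=pc,
        genotypes=genotypes,
        phenotype_notes=notes,
    )


# -- T8: DXD mates ----------------------------------------------------------

# (GJB2, GJB6) per husband; None = unsampled.  Ordering is arbitrary.
_T8_HUSBANDS: list[tuple[str | None, str | None]] = (
    [("W24X/W24X", "+/+")] * 13
    + [
        ("V153I/V153I", "+/+"),
        ("W77X/W77X", "+/+"),
        ("R127H/R127H", "+/+"),
        ("R127H/V153I", "+/+"),
        ("V27I/E114G", "+/+"),
        ("V37I/V153I", "+/+"),
        ("R184Q/Q124X/IVS1+1G>A", "+/+"),
        ("W24X/T55T/R127H", "+/+"),
    ]
    + [("R127H/+", "+/+")] * 9
    + [("W24X/+", "+/+")] * 4
    + [("V153I/+", "+/+")] * 2
    + [
        ("+/+", "R104H/+"),
        ("+/+", "Q57R/+"),
        ("E42D/+", "R104H/+"),  # digenic
    ]
    + [("+/+", "+/+")] * 19
    + [(None, None)] * 2
)

_T8_WIVES: list[tuple[str | None, str | None]] = (
    [("W24X/W24X", "+/+")] * 13
    + [("V153I/V153I", "+/+")] * 2
    + [
        ("W77X/W77X", "+/+"),
        ("R127H/R127H", "+/+"),
        ("R127H/V153I", "+/+"),
        ("V27I/E114G", "+/+"),
        ("E42D/E42D", "+/+"),
        ("W77X/Q124X", "+/+"),
        ("W24X/I35S", "+/+"),
        ("Q124X/IVS1+1G>A", "+/+"),
        ("R75Q/V153I", "+/+"),
        ("V153I/R165W", "+/+"),
    ]
    + [("R127H/+", "+/+")] * 9
    + [("W24X/+", "+/+")] * 2
    + [("V153I/+", "+/+")]
    + [("IVS1+1G>A/+", "+/+")] * 2
    + [("I35S/+", "+/+")]
    + [("+/+", "+/+")] * 20
)


def _make_t8(registry: VariantRegistry) -> Cohort:
    assert len(_T8_HUSBANDS) == 60 and len(_T8_WIVES) == 60
    individuals: dict[str, Individual] = {}
    families: dict[str, Family] = {}
    for k in range(60):
        fid = f"DXD{k + 1:03d}"
        h2, h6 = _T8_HUSBANDS[k]
        w2, w6 = _T8_WIVES[k]
        hid, wid = f"{fid}-H", f"{fid}-W"
        individuals[hid] = _person(
            registry, hid, fid, sex="M", hearing="HI", role="mate",
            gjb2=h2, gjb6=h6, pc="yes" if k < 24 else "no",
        )
        individuals[wid] = _person(
            registry, wid, fid, sex="F", hearing="HI", role="mate",
            gjb2=w2, gjb6=w6, pc="yes" if k < 30 else "no",
        )
        families[fid] = Family(
            family_id=fid,
            mating_type="DXD",
            mating_consanguineous="yes" if k < 2 else "no",
            partner_ids=(hid, wid),
        )
    return Cohort(individuals=individuals, families=families, registry=registry)


# -- T9: DXN families -------------------------------------------------------

# Per family: affected partner GJB2, affected GJB6, hearing partner GJB2
# (None = unsampled), mating consanguinity, offspring phenotype
# ("A" affected / "N" normal hearing / "-" none), affected-partner parental
# consanguinity, hearing-partner parental consanguinity, affected sex.
_T9_FAMILIES: list[tuple[str, str, str | None, str, str, str, str, str]] = [
    # 18 consanguineous matings
    ("Q124X/Q124X", "+/+", "Q124X/+", "yes", "A", "yes", "no", "M"),
    ("T86M/T86M", "+/+", "T86M/+", "yes", "A", "yes", "no", "M"),
    ("W24X/W77X", "+/+", "+/+", "yes", "A", "yes", "no", "M"),
    ("W24X/A88A", "+/+", "+/+", "yes", "A", "yes", "no", "M"),
    ("W24X/W24X", "+/+", "+/+", "yes", "A", "yes", "no", "M"),
    ("W24X/W24X", "+/+", "+/+", "yes", "N", "no", "no", "M"),
    ("W24X/W24X", "+/+", "+/+", "yes", "N", "no", "no", "M"),
    ("W24X/W24X", "+/+", "+/+", "yes", "-", "no", "no", "M"),
    ("R127H/+", "+/+", "+/+", "yes", "A", "yes", "no", "M"),
    ("R127H/+", "+/+", "V153I/+", "yes", "A", "yes", "no", "M"),
    ("V153I/+", "+/+", "+/+", "yes", "A", "yes", "no", "M"),
    ("A88A/+", "+/+", "+/+", "yes", "A", "yes", "no", "M"),
    ("M195I/P225P", "+/+", "V153I/R165W", "yes", "A", "no", "no", "M"),
    ("+/+", "+/+", "A88A/+", "yes", "A", "yes", "no", "M"),
    ("+/+", "+/+", "+/+", "yes", "A", "yes", "no", "M"),
    ("+/+", "+/+", "+/+", "yes", "N", "yes", "no", "M"),
    ("+/+", "+/+", "+/+", "yes", "N", "yes", "no", "M"),
    ("+/+", "+/+", "+/+", "yes", "N", "yes", "no", "M"),
    # 28 non-consanguineous matings
    ("W24X/W24X", "+/+", "W24X/+", "no", "A", "no", "yes", "F"),
    ("W24X/W24X", "+/+", "+/+", "no", "N", "no", "yes", "F"),
    ("W24X/W24X", "+/+", "+/+", "no", "N", "no", "yes", "F"),
    ("W24X/W24X", "+/+", "+/+", "no", "N", "no", "yes", "M"),
    ("W24X/W24X", "+/+", "+/+", "no", "N", "no", "yes", "M"),
    ("W24X/W24X", "+/+", "+/+", "no", "N", "no", "yes", "M"),
    ("W24X/W24X", "+/+", "+/+", "no", "-", "no", "no", "M"),
    ("W24X/+", "+/+", "+/+", "no", "N", "yes", "no", "F"),
    ("W24X/+", "+/+", "+/+", "no", "N", "yes", "no", "F"),
    ("W24X/+", "+/+", "+/+", "no", "N", "no", "no", "M"),
    ("W24X/+", "+/+", "+/+", "no", "N", "no", "no", "F"),
    ("+/+", "E101Q/+", "R127H/+", "no", "A", "no", "no", "F"),
    ("R127H/+", "+/+", "+/+", "no", "A", "no", "no", "F"),
    ("R127H/+", "+/+", "+/+", "no", "A", "no", "no", "F"),
    ("+/+", "+/+", "V153I/+", "no", "A", "yes", "no", "F"),
    ("+/+", "+/+", "+/+", "no", "A", "yes", "no", "F"),
    ("+/+", "+/+", "+/+", "no", "A", "yes", "no", "F"),
    ("+/+", "+/+", None, "no", "N", "no", "no", "F"),
    ("+/+", "+/+", None, "no", "N", "no", "no", "F"),
    ("+/+", "+/+", None, "no", "N", "no", "no", "F"),
    ("+/+", "+/+", "+/+", "no", "N", "yes", "no", "F"),
    ("+/+", "+/+", "+/+", "no", "N", "yes", "no", "F"),
    ("+/+", "+/+", "+/+", "no", "N", "yes", "no", "F"),
    ("+/+", "+/+", "+/+", "no", "N", "yes", "no", "F"),
    ("+/+", "+/+", "+/+", "no", "N", "yes", "no", "F"),
    ("+/+", "+/+", "+/+", "no", "N", "no", "no", "F"),
    ("+/+", "+/+", "+/+", "no", "N", "no", "no", "F"),
    ("+/+", "+/+", "+/+", "no", "N", "no", "no", "F"),
]


def _make_t9(registry: VariantRegistry) -> Cohort:
    assert len(_T9_FAMILIES) == 46
    individuals: dict[str, Individual] = {}
    families: dict[str, Family] = {}
    for k, (a2, a6, n2, mc, off, apc, npc, asex) in enumerate(_T9_FAMILIES, 1):
        fid = f"DXN{k:03d}"
        aid, nid = f"{fid}-A", f"{fid}-N"
        nsex = "F" if asex == "M" else "M"
        notes = "printed as R153I/R165W" if n2 == "V153I/R165W" else ""
        individuals[aid] = _person(
            registry, aid, fid, sex=asex, hearing="HI", role="mate",
            gjb2=a2, gjb6=a6, pc=apc,
        )
        individuals[nid] = _person(
            registry, nid, fid, sex=nsex, hearing="normal", role="hearing-partner",
            gjb2=n2, gjb6=None if n2 is None else "+/+", pc=npc, notes=notes,
        )
        kids = []
        if off != "-":
            oid = f"{fid}-O1"
            kids.append(oid)
            individuals[oid] = _person(
                registry, oid, fid, sex="U",
                hearing="HI" if off == "A" else "normal",
                role="offspring", gjb2=None, gjb6=None,
                father=aid if asex == "M" else nid,
                mother=nid if asex == "M" else aid,
            )
        families[fid] = Family(
            family_id=fid, mating_type="DXN", mating_consanguineous=mc,
            partner_ids=(aid, nid), offspring_ids=tuple(kids),
        )
    return Cohort(individuals=individuals, families=families, registry=registry)


# -- T10: controls ----------------------------------------------------------

_T10_GENOTYPES: list[tuple[str, int]] = [
    ("W24X/+", 5),
    ("N62S/+", 1),
    ("E147K/T55T", 1),
    ("W24X/M195I/P225P", 1),
    ("R127H/R127H", 5),
    ("R127H/R165W", 1),
    ("R127H/T55T", 1),
    ("V153I/R165W", 2),
    ("Q80Q/R127H", 1),
    ("R127H/+", 44),
    ("V153I/+", 4),
    ("Q80Q/+", 1),
    ("T55T/+", 1),
    ("G45G/+", 1),
    ("+/+", 96),
]


def _make_t10(registry: VariantRegistry) -> Cohort:
    genotypes = [g for g, n in _T10_GENOTYPES for _ in range(n)]
    assert len(genotypes) == 165
    individuals: dict[str, Individual] = {}
    families: dict[str, Family] = {}
    for k, g2 in enumerate(genotypes, 1):
        fid = f"CTRL{k:03d}"
        iid = f"{fid}-C"
        individuals[iid] = _person(
            registry, iid, fid, sex="M" if k % 2 else "F", hearing="normal",
            role="control", gjb2=g2, gjb6=None,
            pc="yes" if k <= 19 else "no",  # 19/165 parental consanguinity
        )
        families[fid] = Family(family_id=fid, mating_type="control-group")
        families[fid].other_ids = (iid,)
    return Cohort(individuals=individuals, families=families, registry=registry)


# -- T13: DXD classification grid ------------------------------------------

# Cell representatives: (partner1 GJB2, partner1 GJB6, partner2 GJB2,
# partner2 GJB6); None = unsampled partner (footnoted in the source table).
_CELL_TEMPLATES: dict[str, tuple[str | None, str | None, str | None, str | None]] = {
    "both-biallelic": ("W24X/W24X", "+/+", "W24X/W24X", "+/+"),
    "both-heterozygous": ("W24X/+", "+/+", "Q124X/+", "+/+"),
    "one-biallelic-one-het": ("W24X/W24X", "+/+", "W24X/+", "+/+"),
    "one-partner-GJB2-homozygous": ("W24X/W24X", "+/+", "+/+", "+/+"),
    "one-partner-GJB2-heterozygous": ("W24X/+", "+/+", "+/+", "+/+"),
    "one-partner-GJB6-heterozygous": ("+/+", "Q57R/+", "+/+", "+/+"),
    "digenic": ("E42D/+", "R104H/+", "+/+", "+/+"),
    "non-GJB2-non-GJB6": ("+/+", "+/+", "+/+", "+/+"),
}

# Half of the Group-I both-biallelic families carry W24X homozygosity in
# both partners; the rest are compound-heterozygous combinations, one of
# them the unique dominant-including triallelic genotype.
_GROUP1_BOTH_BIALLELIC: list[tuple[str, str]] = [
    ("W24X/W24X", "W24X/W24X"),
    ("W24X/W24X", "W24X/W24X"),
    ("W24X/W24X", "W24X/W24X"),
    ("W24X/W24X", "W24X/W24X"),
    ("W77X/W77X", "W24X/W24X"),
    ("W77X/Q124X", "W24X/W24X"),
    ("Q124X/IVS1+1G>A", "W24X/W24X"),
    ("R184Q/Q124X/IVS1+1G>A", "W24X/W24X"),
]

_T13_GRID: dict[str, list[int]] = {
    # columns follow _CELL_TEMPLATES order
    "I": [8, 0, 0, 1, 1, 1, 0, 6],
    "II": [0, 1, 1, 11, 6, 0, 1, 10],
    "III": [0, 0, 0, 0, 1, 0, 0, 1],
    "IV": [0, 0, 1, 4, 0, 1, 0, 5],
}

_OFFSPRING_BY_GROUP = {"I": "AA", "II": "NN", "III": "AN", "IV": ""}


def _make_t13(registry: VariantRegistry) -> Cohort:
    individuals: dict[str, Individual] = {}
    families: dict[str, Family] = {}
    cells = list(_CELL_TEMPLATES)
    k = 0
    g1_biallelic = iter(_GROUP1_BOTH_BIALLELIC)
    unsampled_budget = {"I": 1, "II": 1}  # one footnoted family each
    for group, counts in _T13_GRID.items():
        for cell, n in zip(cells, counts):
            for _ in range(n):
                k += 1
                fid = f"T13-{k:02d}"
                p1g2, p1g6, p2g2, p2g6 = _CELL_TEMPLATES[cell]
                if group == "I" and cell == "both-biallelic":
                    p1g2, p2g2 = next(g1_biallelic)
                if cell == "non-GJB2-non-GJB6" and unsampled_budget.get(group, 0):
                    unsampled_budget[group] -= 1
                    p2g2 = p2g6 = None
                hid, wid = f"{fid}-H", f"{fid}-W"
                # Group III's heterozygous-partner family carries the
                # dominant mutation transmitted to the affected child.
                dominant_family = group == "III" and cell == "one-partner-GJB2-heterozygous"
                if dominant_family:
                    p1g2 = "R75Q/+"
                individuals[hid] = _person(
                    registry, hid, fid, sex="M", hearing="HI", role="mate",
                    gjb2=p1g2, gjb6=p1g6,
                )
                individuals[wid] = _person(
                    registry, wid, fid, sex="F", hearing="HI", role="mate",
                    gjb2=p2g2, gjb6=p2g6,
                )
                kids = []
                for j, code in enumerate(_OFFSPRING_BY_GROUP[group], 1):
                    oid = f"{fid}-O{j}"
                    kids.append(oid)
                    off_g2 = None
                    if dominant_family and code == "A":
                        off_g2 = "R75Q/+"
                    individuals[oid] = _person(
                        registry, oid, fid, sex="U",
                        hearing="HI" if code == "A" else "normal",
                        role="offspring", gjb2=off_g2,
                        gjb6="+/+" if off_g2 else None,
                        father=hid, mother=wid,
                    )
                families[fid] = Family(
                    family_id=fid, mating_type="DXD",
                    mating_consanguineous="yes" if k <= 2 else "no",
                    partner_ids=(hid, wid), offspring_ids=tuple(kids),
                )
    assert k == 60
    return Cohort(individuals=individuals, families=families, registry=registry)


# -- public entry points ----------------------------------------------------


def make_fixture(table_id: str, registry: VariantRegistry | None = None) -> Cohort:
    """Build one of the reference cohorts (``T8``, ``T9``, ``T10``, ``T13``)."""
    registry = registry or default_registry()
    builders = {"T8": _make_t8, "T9": _make_t9, "T10": _make_t10, "T13": _make_t13}
    try:
        return builders[table_id](registry)
    except KeyError:
        raise KeyError(f"unknown table id {table_id!r}; known: {TABLE_IDS}")


def full_study_cohort(registry: VariantRegistry | None = None) -> Cohort:
    """The DXD + DXN + control cohorts merged into one analysis cohort."""
    registry = registry or default_registry()
    return merge_cohorts(
        _make_t8(registry), _make_t9(registry), _make_t10(registry)
    )
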