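"""Point-mutation application and physicochemical property profiling.

Computes, from sequence alone, the twelve descriptors a protein chemist
reads off a standard parameter report: length, average molecular weight,
theoretical pI, charged-residue counts, total atoms, the two 280-nm molar
extinction coefficients (all-cystine and all-reduced), an N-end-rule
half-life estimate, the Guruprasad instability index, Ikai's aliphatic
index and the Kyte-Doolittle GRAVY.  Constant tables live in
:mod:`dfnb1.protparam_data` with per-table provenance.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path

from Bio import SeqIO

from . import protparam_data as D

AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")

_MUTATION_RE = re.compile(r"^(?:p\.)?([A-Z])(\d+)([A-Z])$")


class SequenceError(ValueError):
    pass


class MutationError(ValueError):
    pass


@dataclass(frozen=True)
class ProteinSequence:
    """An identifier plus a 1-based residue string over the 20 standard letters."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        if not self.residues:
            raise SequenceError("empty sequence")
        bad = set(self.residues) - AMINO_ACIDS
        if bad:
            raise SequenceError(
                f"{self.id}: non-standard or lowercase residues {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.residues)

    def residue_at(self, position: int) -> str:
        """1-based lookup."""
        if not 1 <= position <= len(self.residues):
            raise SequenceError(f"{self.id}: position {position} outside 1..{len(self)}")
        return self.residues[position - 1]


def read_fasta(path: str | Path) -> ProteinSequence:
    """First record of a FASTA file as a :class:`ProteinSequence`."""
    path = Path(path)
    for rec in SeqIO.parse(str(path), "fasta"):
        return ProteinSequence(id=rec.id, residues=str(rec.seq).upper())
    raise SequenceError(f"{path}: no FASTA records")


@dataclass(frozen=True)
class MutationSpec:
    """A single-residue substitution, e.g. ``p.E42D``."""

    position: int
    ref: str
    alt: str
    label: str = ""

    @classmethod
    def parse(cls, text: str) -> "MutationSpec":
        m = _MUTATION_RE.match(text.strip())
        if not m:
            raise MutationError(f"cannot parse mutation {text!r} (expected e.g. 'p.E42D')")
        ref, pos, alt = m.group(1), int(m.group(2)), m.group(3)
        if ref not in AMINO_ACIDS or alt not in AMINO_ACIDS:
            raise MutationError(f"{text!r}: non-standard residue letter")
        return cls(position=pos, ref=ref, alt=alt, label=text.strip())


def apply_mutation(seq: ProteinSequence, spec: MutationSpec) -> ProteinSequence:
    """Substitute one residue, guarding the reference letter.

    A reference mismatch raises with the residue actually observed — the
    usual symptom of profiling the wrong isoform.
    """
    observed = seq.residue_at(spec.position)
    if observed != spec.ref:
        raise MutationError(
            f"{seq.id}: expected {spec.ref} at position {spec.position}, found {observed}"
        )
    residues = seq.residues[: spec.position - 1] + spec.alt + seq.residues[spec.position :]
    label = spec.label or f"{spec.ref}{spec.position}{spec.alt}"
    return ProteinSequence(id=f"{seq.id}:{label}", residues=residues)


# -- individual metrics -----------------------------------------------------


def molecular_weight(residues: str) -> float:
    return sum(D.RESIDUE_MASS[a] for a in residues) + D.WATER_MASS


def atom_count(residues: str) -> int:
    return sum(sum(D.RESIDUE_ATOMS[a]) for a in residues) + D.WATER_ATOMS


def gravy(residues: str) -> float:
    return sum(D.KYTE_DOOLITTLE[a] for a in residues) / len(residues)


def aliphatic_index(residues: str) -> float:
    n = len(residues)
    x_ala = 100.0 * residues.count("A") / n
    x_val = 100.0 * residues.count("V") / n
    x_il = 100.0 * (residues.count("I") + residues.count("L")) / n
    return x_ala + D.ALIPHATIC_COEF_VAL * x_val + D.ALIPHATIC_COEF_ILE_LEU * x_il


def instability_index(residues: str) -> float:
    total = sum(D.DIWV[a][b] for a, b in zip(residues[:-1], residues[1:]))
    return 10.0 / len(residues) * total


def extinction_coefficients(residues: str) -> tuple[int, int]:
    """(all Cys paired as cystines, all Cys reduced), in M^-1 cm^-1."""
    w, y, c = residues.count("W"), residues.count("Y"), residues.count("C")
    reduced = D.EXTINCTION_TRP * w + D.EXTINCTION_TYR * y
    return reduced + D.EXTINCTION_CYSTINE * (c // 2), reduced


def half_life(residues: str) -> str:
    return D.HALF_LIFE_MAMMALIAN[residues[0]]


def net_charge(residues: str, ph: float) -> float:
    """Modeled net charge at a given pH under the Bjellqvist pK set."""
    pos_pk = [D.PK_NTERM_BY_RESIDUE.get(residues[0], D.PK_POSITIVE["Nterm"])]
    pos_pk += [D.PK_POSITIVE[a] for a in residues if a in ("K", "R", "H")]
    neg_pk = [D.PK_CTERM_BY_RESIDUE.get(residues[-1], D.PK_NEGATIVE["Cterm"])]
    neg_pk += [D.PK_NEGATIVE[a] for a in residues if a in ("D", "E", "C", "Y")]
    positive = sum(1.0 / (1.0 + 10.0 ** (ph - pk)) for pk in pos_pk)
    negative = sum(1.0 / (1.0 + 10.0 ** (pk - ph)) for pk in neg_pk)
    return positive - negative


def isoelectric_point(residues: str, tol: float = 1e-4) -> float:
    """pH at which the modeled net charge vanishes; bisection on [0, 14].

    Net charge is strictly decreasing in pH, so plain bisection to ``tol``
    pH units suffices.
    """
    lo, hi = 0.0, 14.0
    while hi - lo > tol:
        mid = (lo + hi) / 2.0
        if net_charge(residues, mid) > 0:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2.0


# -- the assembled report ---------------------------------------------------


@dataclass(frozen=True)
class PropertyReport:
    """The twelve physicochemical descriptors of one sequence."""

    sequence_id: str
    length: int
    molecular_weight: float
    isoelectric_point: float
    negatively_charged: int  # Asp + Glu
    positively_charged: int  # Arg + Lys
    atoms: int
    extinction_cystine: int
    extinction_reduced: int
    half_life: str
    instability_index: float
    aliphatic_index: float
    gravy: float

    ROW_ORDER = (
        "length",
        "molecular_weight",
        "isoelectric_point",
        "negatively_charged",
        "positively_charged",
        "atoms",
        "extinction_cystine",
        "extinction_reduced",
        "half_life",
        "instability_index",
        "aliphatic_index",
        "gravy",
    )

    def as_dict(self) -> dict[str, float | int | str]:
        return {name: getattr(self, name) for name in self.ROW_ORDER}


def protparam_report(seq: ProteinSequence) -> PropertyReport:
    r = seq.residues
    ext_cystine, ext_reduced = extinction_coefficients(r)
    return PropertyReport(
        sequence_id=seq.id,
        length=len(r),
        molecular_weight=molecular_weight(r),
        isoelectric_point=isoelectric_point(r),
        negatively_charged=r.count("D") + r.count("E"),
        positively_charged=r.count("R") + r.count("K"),
        atoms=atom_count(r),
        extinction_cystine=ext_cystine,
        extinction_reduced=ext_reduced,
        half_life=half_life(r),
        instability_index=instability_index(r),
        aliphatic_index=aliphatic_index(r),
        gravy=gravy(r),
    )


def compare_reports(native: PropertyReport, mutant: PropertyReport) -> dict[str, dict]:
    """Signed per-metric deltas (mutant minus native) with direction notes.

    Restricted to same-length sequences: the deltas are meant for
    single-residue substitutions, not truncations.
    """
    if native.length != mutant.length:
        raise ValueError(
            f"length mismatch: {native.length} vs {mutant.length}; "
            "delta table is defined for substitutions only"
        )
    out: dict[str, dict] = {}
    for name in PropertyReport.ROW_ORDER:
        a, b = getattr(native, name), getattr(mutant, name)
        if isinstance(a, str):
            out[name] = {"native": a, "mutant": b, "delta": None, "direction": "changed" if a != b else "unchanged"}
            continue
        delta = b - a
        direction = "unchanged" if delta == 0 else ("increased" if delta > 0 else "decreased")
        out[name] = {"native": a, "mutant": b, "delta": delta, "direction": direction}
    return out
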