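"""Forward-time simulation of recessive-deafness allele dynamics.

Implements the mechanism under test in the cohort analysis: a major
recessive deafness locus (standing for DFNB1) plus optional unlinked
heterogeneity loci, non-genetic deafness, phenotypic assortative mating
(deaf preferring deaf partners), consanguinity modelled as F-inflated
autozygosity, differential fertility of deaf-by-deaf couples, and a
viability/fitness weight on the deaf phenotype whose relaxation is the
relaxed-selection scenario.

Two engines share one parameter set:

* :func:`deterministic_recursion` — an infinite-population, per-locus
  genotype-frequency recursion.  Heterogeneity loci enter a focal locus's
  update only as an independent background deafness probability; the
  cross-locus gametic disequilibrium that assortment builds is ignored here
  (the individual-based engine carries it), so the two engines coincide
  exactly only for a single locus.
* the individual-based engine (:func:`simulate_trajectory`,
  :func:`simulate_cohort`) — finite population, explicit pairs and
  children, seeded and reproducible, able to emit two-generation cohort
  files in the pedigree dialect of :mod:`dfnb1.cohort`.

Key analytic properties (asserted by the test-suite): with equal fertility
and no selection the allele frequency is a martingale for *any* assortment
strength — assortment alone reshapes genotype, not allele, frequencies —
and consanguineous offspring homozygosity is ``q^2 + F q (1 - q)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Any

import numpy as np

from .cohort import Cohort, Family, Individual
from .registry import GenotypeCall, VariantRegistry, default_registry

#: Allele label used to render the major simulated locus as a pseudo-GJB2
#: genotype so simulated cohorts flow through the same pipeline as real ones.
MAJOR_LOCUS_ALLELE = "W24X"


@dataclass(frozen=True)
class SimParams:
    """Parameters of the assortative-mating + consanguinity model.

    Defaults mirror a high-consanguinity population in which the major locus
    accounts for roughly a third of recessive deafness: major-locus allele
    frequency 2%, four minor recessive loci of equal frequency, a 20%
    non-genetic (environmental) share of deafness, strong phenotypic
    assortment, 30% consanguineous matings at first-cousin autozygosity.
    """

    population_size: int = 10_000
    generations: int = 10
    q0: float = 0.02
    het_freqs: tuple[float, ...] = (0.02, 0.02, 0.02, 0.02)
    epsilon: float = 0.2
    assortment: float = 0.9
    consanguinity: float = 0.3
    inbreeding_f: float = 1.0 / 16.0
    fertility_dd: float = 1.0
    deaf_fitness: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        probs = {
            "epsilon": self.epsilon,
            "assortment": self.assortment,
            "consanguinity": self.consanguinity,
            "inbreeding_f": self.inbreeding_f,
            "deaf_fitness": self.deaf_fitness,
        }
        for name, p in probs.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {p}")
        for name, q in [("q0", self.q0), *((f"het_freqs[{i}]", q) for i, q in enumerate(self.het_freqs))]:
            if not 0.0 < q < 1.0:
                raise ValueError(f"{name} must lie in (0, 1), got {q}")
        if self.population_size <= 1:
            raise ValueError("population_size must exceed 1")
        if self.generations < 0:
            raise ValueError("generations must be non-negative")
        if self.fertility_dd <= 0:
            raise ValueError("fertility_dd must be positive")

    @property
    def n_loci(self) -> int:
        return 1 + len(self.het_freqs)

    @property
    def locus_freqs(self) -> tuple[float, ...]:
        return (self.q0, *self.het_freqs)


@dataclass
class Trajectory:
    """Per-generation state of a recursion or simulation run.

    ``q`` has shape (G+1, L); ``genotype_freqs`` (G+1, L, 3) with the last
    axis indexing the count of deafness alleles; ``prop_dxd`` and
    ``prop_noncomplementary`` are per-generation mating-pool summaries
    (fractions of matings that are deaf-by-deaf, and of those, capable only
    of deaf offspring through same-locus homozygosity).
    """

    q: np.ndarray
    genotype_freqs: np.ndarray
    prop_dxd: np.ndarray
    prop_noncomplementary: np.ndarray

    @property
    def generations(self) -> int:
        return self.q.shape[0] - 1


# ---------------------------------------------------------------------------
# deterministic, infinite-population recursion
# ---------------------------------------------------------------------------


def _mendel_offspring(i: int, j: int) -> np.ndarray:
    """Offspring genotype distribution of an i x j cross (allele counts)."""
    pa, pb = i / 2.0, j / 2.0
    return np.array(
        [
            (1 - pa) * (1 - pb),
            pa * (1 - pb) + pb * (1 - pa),
            pa * pb,
        ]
    )


_MENDEL = np.array([[_mendel_offspring(i, j) for j in range(3)] for i in range(3)])


def _one_locus_update(
    g: np.ndarray, d_background: float, params: SimParams
) -> tuple[np.ndarray, float, float]:
    """One generation at one locus; returns (g', prop_dxd, prop_noncomp).

    ``d_background`` is the probability that an individual not homozygous at
    this locus is deaf anyway (other loci or non-genetic causes).
    """
    s, A, C, F, fdd = (
        params.deaf_fitness,
        params.assortment,
        params.consanguinity,
        params.inbreeding_f,
        params.fertility_dd,
    )
    # joint (genotype, phenotype) mass after viability weighting
    p_deaf = np.array([d_background, d_background, 1.0])
    w_deaf = g * p_deaf * s
    w_hear = g * (1.0 - p_deaf)
    mass = w_deaf.sum() + w_hear.sum()
    w_deaf, w_hear = w_deaf / mass, w_hear / mass
    m_d = w_deaf.sum()

    # deaf pool pairs off among itself with mass A*m_d; the remainder
    # (non-assorting deaf + hearing) mates at random, so every individual
    # participates in exactly one mating and allele frequency is conserved
    # whenever fertility and fitness are flat.
    pair_masses: list[tuple[float, np.ndarray, np.ndarray, bool]] = []
    if m_d > 0 and A > 0:
        dg = w_deaf / m_d
        pair_masses.append((A * m_d, dg, dg, True))
    rem_deaf = (1.0 - A) * w_deaf
    rem_mass = rem_deaf.sum() + w_hear.sum()
    if rem_mass > 0:
        rg_deaf = rem_deaf / rem_mass
        rg_hear = w_hear / rem_mass
        # mixture over phenotype combinations within the random remainder
        pair_masses.append((rem_mass, rg_deaf, rg_deaf, True))
        pair_masses.append((rem_mass, rg_deaf, rg_hear, False))
        pair_masses.append((rem_mass, rg_hear, rg_deaf, False))
        pair_masses.append((rem_mass, rg_hear, rg_hear, False))

    g_next = np.zeros(3)
    pair_total = 0.0
    dxd_mass = 0.0
    noncomp_mass = 0.0
    for mass_k, ga, gb, both_deaf in pair_masses:
        pair = mass_k * np.outer(ga, gb)
        fert = fdd if both_deaf else 1.0
        pair_total += pair.sum()
        if both_deaf:
            dxd_mass += pair.sum()
            noncomp_mass += pair[2, 2]
        weighted = fert * pair
        mend = np.tensordot(weighted, _MENDEL, axes=([0, 1], [0, 1]))
        if C > 0 and F > 0:
            # under consanguineous autozygosity the child copies one parental
            # allele: homozygous deaf with the pair's mean allele dosage
            ij = np.add.outer(np.arange(3), np.arange(3)) / 4.0
            p_auto_a = (weighted * ij).sum()
            auto = np.array([weighted.sum() - p_auto_a, 0.0, p_auto_a])
            mend = (1.0 - C * F) * mend + C * F * auto
        g_next += mend

    g_next /= g_next.sum()
    prop_dxd = dxd_mass / pair_total if pair_total > 0 else 0.0
    prop_noncomp = noncomp_mass / dxd_mass if dxd_mass > 0 else 0.0
    return g_next, prop_dxd, prop_noncomp


def deterministic_recursion(params: SimParams) -> Trajectory:
    """Iterate the infinite-population genotype recursion for G generations.

    Starts every locus at Hardy-Weinberg proportions of its initial
    frequency.  Supports any number of heterogeneity loci, each updated with
    the others folded into an independent background deafness probability;
    with no heterogeneity loci the update is exact.
    """
    L = params.n_loci
    G = params.generations
    geno = np.zeros((G + 1, L, 3))
    for l, qf in enumerate(params.locus_freqs):
        geno[0, l] = [(1 - qf) ** 2, 2 * qf * (1 - qf), qf**2]

    dxd = np.zeros(G + 1)
    noncomp = np.zeros(G + 1)
    dxd[0], noncomp[0] = _mating_pool_summary(geno[0], params)
    for t in range(G):
        for l in range(L):
            hom_other = [geno[t, m, 2] for m in range(L) if m != l]
            d_bg = 1.0 - (1.0 - params.epsilon) * float(np.prod([1.0 - h for h in hom_other]))
            geno[t + 1, l], _, _ = _one_locus_update(geno[t, l], d_bg, params)
        dxd[t + 1], noncomp[t + 1] = _mating_pool_summary(geno[t + 1], params)

    q = geno[:, :, 1] / 2.0 + geno[:, :, 2]
    return Trajectory(q=q, genotype_freqs=geno, prop_dxd=dxd, prop_noncomplementary=noncomp)


def _mating_pool_summary(geno_t: np.ndarray, params: SimParams) -> tuple[float, float]:
    """(prop DXD matings, prop of DXD matings non-complementary) for a state.

    Non-complementarity across loci is combined under the recursion's
    independence approximation.
    """
    L = geno_t.shape[0]
    hom = geno_t[:, 2]
    p_deaf = 1.0 - (1.0 - params.epsilon) * float(np.prod(1.0 - hom))
    s, A = params.deaf_fitness, params.assortment
    m_d = p_deaf * s / (p_deaf * s + (1.0 - p_deaf))
    # deaf-deaf matings: the assorted block plus random coincidences
    prop_dxd = A * m_d + (1.0 - A * m_d) * (((1.0 - A) * m_d / (1.0 - A * m_d)) ** 2 if A * m_d < 1 else 0.0)
    if m_d == 0:
        return 0.0, 0.0
    # P(partner homozygous at locus l | deaf): weight by deaf pool composition
    nc_per_locus = []
    for l in range(L):
        p_hom_given_deaf = hom[l] / p_deaf if p_deaf > 0 else 0.0
        nc_per_locus.append(p_hom_given_deaf**2)
    noncomp = 1.0 - float(np.prod([1.0 - x for x in nc_per_locus]))
    return float(prop_dxd), noncomp


# ---------------------------------------------------------------------------
# individual-based engine
# ---------------------------------------------------------------------------


@dataclass
class _MatingRecord:
    """One generation's explicit matings (for cohort emission)."""

    parent1: np.ndarray  # indices into the parental genotype array
    parent2: np.ndarray
    parent_geno: np.ndarray  # (n_pop, L) parental genotypes
    parent_deaf: np.ndarray  # (n_pop,) parental phenotypes
    consanguineous: np.ndarray  # (n_pairs,)
    child_pair: np.ndarray  # pair index per child
    child_geno: np.ndarray  # (n_children, L)
    child_deaf: np.ndarray  # (n_children,)


def _initial_population(params: SimParams, rng: np.random.Generator) -> np.ndarray:
    N, L = params.population_size, params.n_loci
    geno = np.empty((N, L), dtype=np.int8)
    for l, qf in enumerate(params.locus_freqs):
        geno[:, l] = rng.binomial(2, qf, size=N)
    return geno


def _phenotype(geno: np.ndarray, params: SimParams, rng: np.random.Generator) -> np.ndarray:
    genetic = (geno == 2).any(axis=1)
    nongenetic = rng.random(geno.shape[0]) < params.epsilon
    return genetic | nongenetic


def _one_generation(
    geno: np.ndarray, params: SimParams, rng: np.random.Generator
) -> _MatingRecord:
    N, L = geno.shape
    deaf = _phenotype(geno, params, rng)

    # viability: deaf individuals reach the mating pool with probability s
    alive = np.ones(N, dtype=bool)
    if params.deaf_fitness < 1.0:
        alive[deaf] = rng.random(int(deaf.sum())) < params.deaf_fitness

    deaf_idx = np.flatnonzero(deaf & alive)
    hear_idx = np.flatnonzero(~deaf & alive)

    assorting = deaf_idx[rng.random(deaf_idx.size) < params.assortment]
    rest = np.concatenate([np.setdiff1d(deaf_idx, assorting, assume_unique=True), hear_idx])

    assorting = rng.permutation(assorting)
    if assorting.size % 2 == 1:
        rest = np.concatenate([rest, assorting[-1:]])
        assorting = assorting[:-1]
    rest = rng.permutation(rest)
    if rest.size % 2 == 1:
        rest = rest[:-1]

    p1 = np.concatenate([assorting[0::2], rest[0::2]])
    p2 = np.concatenate([assorting[1::2], rest[1::2]])
    if p1.size == 0:
        raise RuntimeError("mating pool collapsed; increase population_size")

    both_deaf = deaf[p1] & deaf[p2]
    fert = np.where(both_deaf, params.fertility_dd, 1.0)
    children_per_pair = rng.multinomial(N, fert / fert.sum())
    child_pair = np.repeat(np.arange(p1.size), children_per_pair)

    consang = rng.random(p1.size) < params.consanguinity

    g1 = geno[p1][child_pair]
    g2 = geno[p2][child_pair]
    a1 = rng.random(g1.shape) < g1 / 2.0
    a2 = rng.random(g2.shape) < g2 / 2.0
    child = (a1.astype(np.int8) + a2.astype(np.int8))

    auto = consang[child_pair][:, None] & (rng.random(g1.shape) < params.inbreeding_f)
    if auto.any():
        pick_first = rng.random(g1.shape) < 0.5
        src = np.where(pick_first, g1, g2)
        allele = rng.random(g1.shape) < src / 2.0
        child = np.where(auto, 2 * allele.astype(np.int8), child)

    child_deaf = _phenotype(child, params, rng)
    return _MatingRecord(
        parent1=p1,
        parent2=p2,
        parent_geno=geno,
        parent_deaf=deaf,
        consanguineous=consang,
        child_pair=child_pair,
        child_geno=child,
        child_deaf=child_deaf,
    )


def simulate_trajectory(params: SimParams, seed: int | None = None) -> Trajectory:
    """Individual-based allele-frequency trajectory (seeded, reproducible)."""
    rng = np.random.default_rng(params.seed if seed is None else seed)
    geno = _initial_population(params, rng)
    G, L = params.generations, params.n_loci
    q = np.zeros((G + 1, L))
    gfreq = np.zeros((G + 1, L, 3))
    dxd = np.zeros(G + 1)
    noncomp = np.zeros(G + 1)

    def record(t: int, g: np.ndarray) -> None:
        q[t] = g.mean(axis=0) / 2.0
        for k in range(3):
            gfreq[t, :, k] = (g == k).mean(axis=0)

    record(0, geno)
    for t in range(G):
        rec = _one_generation(geno, params, rng)
        both_deaf = rec.parent_deaf[rec.parent1] & rec.parent_deaf[rec.parent2]
        dxd[t] = both_deaf.mean()
        if both_deaf.any():
            same_hom = (
                (rec.parent_geno[rec.parent1] == 2) & (rec.parent_geno[rec.parent2] == 2)
            ).any(axis=1)
            noncomp[t] = float(same_hom[both_deaf].mean())
        geno = rec.child_geno
        record(t + 1, geno)
    return Trajectory(q=q, genotype_freqs=gfreq, prop_dxd=dxd, prop_noncomplementary=noncomp)


def _render_major_locus(g: int) -> GenotypeCall:
    return GenotypeCall(gene="GJB2", alleles=(MAJOR_LOCUS_ALLELE,) * int(g))


def simulate_cohort(
    params: SimParams,
    families: int,
    seed: int | None = None,
    registry: VariantRegistry | None = None,
) -> tuple[Cohort, dict[str, Any]]:
    """Simulate and emit a two-generation cohort of assortative matings.

    Runs the individual-based engine for ``generations`` and samples
    ``families`` matings with at least one deaf partner from the final
    generation's matings: deaf-by-deaf pairs become DXD families, deaf-by-
    hearing pairs DXN.  The major locus is rendered as a pseudo-GJB2
    genotype; heterogeneity loci stay latent (untyped) and are reported only
    in the returned truth record, together with every individual's full
    genotype and phenotype.
    """
    if families <= 0:
        raise ValueError("families must be positive")
    rng = np.random.default_rng(params.seed if seed is None else seed)
    registry = registry or default_registry()
    geno = _initial_population(params, rng)
    rec = None
    for _ in range(max(params.generations, 1)):
        rec = _one_generation(geno, params, rng)
        geno = rec.child_geno
    assert rec is not None

    deaf1 = rec.parent_deaf[rec.parent1]
    deaf2 = rec.parent_deaf[rec.parent2]
    eligible = np.flatnonzero(deaf1 | deaf2)
    if eligible.size < families:
        raise RuntimeError(
            f"only {eligible.size} matings with a deaf partner available; "
            f"requested {families} (raise population_size or epsilon)"
        )
    chosen = rng.permutation(eligible)[:families]

    individuals: dict[str, Individual] = {}
    families_out: dict[str, Family] = {}
    truth: dict[str, Any] = {"params": params.__dict__ | {"het_freqs": list(params.het_freqs)}, "individuals": {}}

    for k, pair_idx in enumerate(chosen, 1):
        fid = f"SIM{k:04d}"
        pids = []
        pair_deaf = (bool(deaf1[pair_idx]), bool(deaf2[pair_idx]))
        mating_type = "DXD" if all(pair_deaf) else "DXN"
        for slot, (parent_arr, is_deaf) in enumerate(
            zip((rec.parent1, rec.parent2), pair_deaf), 1
        ):
            iid = f"{fid}-P{slot}"
            pids.append(iid)
            g = rec.parent_geno[parent_arr[pair_idx]]
            individuals[iid] = Individual(
                individual_id=iid,
                family_id=fid,
                sex="M" if slot == 1 else "F",
                hearing_status="HI" if is_deaf else "normal",
                role="mate" if is_deaf else "hearing-partner",
                parental_consanguinity="unknown",
                genotypes={
                    "GJB2": _render_major_locus(int(g[0])),
                    "GJB6": GenotypeCall(gene="GJB6", alleles=()),
                },
            )
            truth["individuals"][iid] = {"genotypes": [int(x) for x in g], "deaf": is_deaf}
        kid_rows = np.flatnonzero(rec.child_pair == pair_idx)
        kid_ids = []
        for j, row in enumerate(kid_rows, 1):
            iid = f"{fid}-O{j}"
            kid_ids.append(iid)
            g = rec.child_geno[row]
            is_deaf = bool(rec.child_deaf[row])
            individuals[iid] = Individual(
                individual_id=iid,
                family_id=fid,
                father_id=pids[0],
                mother_id=pids[1],
                sex="U",
                hearing_status="HI" if is_deaf else "normal",
                role="offspring",
                genotypes={
                    "GJB2": _render_major_locus(int(g[0])),
                    "GJB6": GenotypeCall(gene="GJB6", alleles=()),
                },
            )
            truth["individuals"][iid] = {"genotypes": [int(x) for x in g], "deaf": is_deaf}
        families_out[fid] = Family(
            family_id=fid,
            mating_type=mating_type,
            mating_consanguineous="yes" if rec.consanguineous[pair_idx] else "no",
            partner_ids=tuple(pids),
            offspring_ids=tuple(kid_ids),
        )

    cohort = Cohort(individuals=individuals, families=families_out, registry=registry)
    return cohort, truth
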