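"""Forward simulator: analytic invariants, engine agreement, determinism."""

import numpy as np
import pytest

from dfnb1 import SimParams, deterministic_recursion, simulate_cohort, simulate_trajectory, write_cohort
from dfnb1.simulate import _one_generation


def _params(**kw):
    base = dict(population_size=2000, generations=4, q0=0.1, het_freqs=(),
                epsilon=0.2, assortment=0.0, consanguinity=0.0,
                fertility_dd=1.0, deaf_fitness=1.0, seed=0)
    base.update(kw)
    return SimParams(**base)


def test_parameter_validation():
    with pytest.raises(ValueError):
        _params(q0=0.0)
    with pytest.raises(ValueError):
        _params(assortment=1.5)
    with pytest.raises(ValueError):
        _params(epsilon=-0.1)
    with pytest.raises(ValueError):
        _params(fertility_dd=0.0)
    with pytest.raises(ValueError):
        simulate_cohort(_params(), families=0)


def test_neutral_recursion_keeps_q_constant():
    tr = deterministic_recursion(_params(generations=8))
    assert np.allclose(tr.q[:, 0], 0.1, atol=1e-12)
    # genotype frequencies stay at Hardy-Weinberg and sum to one
    assert np.allclose(tr.genotype_freqs.sum(axis=2), 1.0)
    assert np.allclose(tr.genotype_freqs[-1, 0], [0.81, 0.18, 0.01], atol=1e-12)


def test_assortment_alone_reshapes_genotypes_not_alleles():
    tr = deterministic_recursion(_params(assortment=1.0, epsilon=0.0, generations=6))
    assert np.allclose(tr.q[:, 0], 0.1, atol=1e-12)
    hom = tr.genotype_freqs[:, 0, 2]
    assert np.all(np.diff(hom) > 0)  # homozygote excess grows every generation
    assert hom[-1] > 0.01  # above the Hardy-Weinberg q^2


def test_consanguinity_inflates_homozygosity_exactly():
    """One neutral generation with full consanguinity: q^2 + F q (1 - q)."""
    q, F = 0.1, 1.0 / 16.0
    tr = deterministic_recursion(_params(consanguinity=1.0, inbreeding_f=F, generations=1))
    assert tr.q[1, 0] == pytest.approx(q)
    assert tr.genotype_freqs[1, 0, 2] == pytest.approx(q**2 + F * q * (1 - q))


def test_selection_erodes_and_fertility_restores_the_allele():
    eroded = deterministic_recursion(_params(deaf_fitness=0.5, epsilon=0.0, generations=5))
    assert np.all(np.diff(eroded.q[:, 0]) < 0)
    relaxed = deterministic_recursion(
        _params(assortment=0.9, fertility_dd=1.5, epsilon=0.1, generations=5)
    )
    assert np.all(np.diff(relaxed.q[:, 0]) > 0)


def test_relaxed_selection_trajectory_non_decreasing_after_relaxation():
    """Run under selection, then hand the end state to a relaxed regime:
    the recessive-allele trajectory stops falling once selection lifts."""
    under = deterministic_recursion(_params(deaf_fitness=0.6, epsilon=0.1, generations=6))
    q_end = float(under.q[-1, 0])
    relaxed = deterministic_recursion(
        _params(q0=q_end, deaf_fitness=1.0, assortment=0.8, fertility_dd=1.0,
                epsilon=0.1, generations=6)
    )
    assert np.all(np.diff(relaxed.q[:, 0]) >= -1e-12)


def _brute_force_one_step(g, params, d_bg):
    """Independent oracle: explicit loop over the nine genotype crosses."""
    s, A, C, F, fdd = (params.deaf_fitness, params.assortment,
                       params.consanguinity, params.inbreeding_f, params.fertility_dd)
    p_deaf = [d_bg, d_bg, 1.0]
    w = {}
    for i in range(3):
        w[(i, "D")] = g[i] * p_deaf[i] * s
        w[(i, "H")] = g[i] * (1 - p_deaf[i])
    total = sum(w.values())
    w = {k: v / total for k, v in w.items()}
    m_d = sum(v for (i, ph), v in w.items() if ph == "D")

    pools = []
    if m_d > 0 and A > 0:
        deaf = {i: w[(i, "D")] / m_d for i in range(3)}
        pools.append((A * m_d, [(i, "D", deaf[i]) for i in range(3)]))
    rem = {(i, ph): (1 - A if ph == "D" else 1) * w[(i, ph)] for (i, ph) in w}
    rm = sum(rem.values())
    if rm > 0:
        pools.append((rm, [(i, ph, v / rm) for (i, ph), v in rem.items()]))

    out = np.zeros(3)
    for mass, members in pools:
        for (i, ph1, f1) in members:
            for (j, ph2, f2) in members:
                pw = mass * f1 * f2
                if ph1 == "D" and ph2 == "D":
                    pw *= fdd
                pa, pb = i / 2, j / 2
                mend = np.array([(1 - pa) * (1 - pb),
                                 pa * (1 - pb) + pb * (1 - pa), pa * pb])
                auto_a = (i + j) / 4
                auto = np.array([1 - auto_a, 0.0, auto_a])
                out += pw * ((1 - C * F) * mend + C * F * auto)
    return out / out.sum()


@pytest.mark.parametrize(
    "kw",
    [
        dict(),
        dict(assortment=0.7, fertility_dd=1.4),
        dict(assortment=1.0, deaf_fitness=0.6),
        dict(consanguinity=0.5, inbreeding_f=1 / 16, assortment=0.3),
    ],
)
def test_recursion_matches_brute_force_mating_table(kw):
    params = _params(generations=1, epsilon=0.2, **kw)
    tr = deterministic_recursion(params)
    q0 = params.q0
    g0 = np.array([(1 - q0) ** 2, 2 * q0 * (1 - q0), q0**2])
    expected = _brute_force_one_step(g0, params, params.epsilon)
    assert np.allclose(tr.genotype_freqs[1, 0], expected, atol=1e-12)


def test_seeded_determinism_byte_identical_files(tmp_path):
    params = _params(population_size=600, generations=2, assortment=0.8)
    paths = []
    for k in range(2):
        cohort, truth = simulate_cohort(params, families=20, seed=99)
        p = tmp_path / f"run{k}.tsv"
        write_cohort(cohort, p)
        paths.append(p)
    assert paths[0].read_bytes() == paths[1].read_bytes()
    different, _ = simulate_cohort(params, families=20, seed=100)
    p3 = tmp_path / "run3.tsv"
    write_cohort(different, p3)
    assert paths[0].read_bytes() != p3.read_bytes()


def test_individual_inbreeding_matches_autozygosity_formula():
    """C=1, F=1/16: offspring homozygosity is q^2 + F q (1 - q)."""
    q, F = 0.3, 1.0 / 16.0
    params = _params(population_size=60_000, generations=1, q0=q,
                     consanguinity=1.0, inbreeding_f=F, epsilon=0.0)
    rng = np.random.default_rng(7)
    from dfnb1.simulate import _initial_population

    geno = _initial_population(params, rng)
    q_parental = geno.mean() / 2
    rec = _one_generation(geno, params, rng)
    hom = (rec.child_geno[:, 0] == 2).mean()
    expected = q_parental**2 + F * q_parental * (1 - q_parental)
    # binomial Monte-Carlo tolerance at 3 sigma
    tol = 3 * np.sqrt(expected * (1 - expected) / params.population_size)
    assert abs(hom - expected) < tol


def test_complementation_between_different_loci():
    """Two deaf partners homozygous at different recessive loci produce
    only hearing (double-heterozygous) offspring."""
    params = _params(population_size=2, generations=1, het_freqs=(0.5,),
                     epsilon=0.0, assortment=1.0)
    geno = np.array([[2, 0], [0, 2]], dtype=np.int8)
    rng = np.random.default_rng(3)
    rec = _one_generation(geno, params, rng)
    assert rec.child_geno.shape[0] == 2
    assert (rec.child_geno == 1).all()
    assert not rec.child_deaf.any()


def test_monte_carlo_mean_matches_recursion():
    """The two engines agree on the mean single-locus trajectory."""
    params = _params(population_size=2000, generations=3, q0=0.1,
                     assortment=0.8, fertility_dd=1.3, deaf_fitness=0.9,
                     consanguinity=0.2, epsilon=0.2)
    det = deterministic_recursion(params).q[:, 0]
    reps = 200
    qs = np.empty((reps, params.generations + 1))
    for r in range(reps):
        qs[r] = simulate_trajectory(params, seed=4000 + r).q[:, 0]
    mean = qs.mean(axis=0)
    se = qs.std(axis=0, ddof=1) / np.sqrt(reps)
    assert np.all(np.abs(mean[1:] - det[1:]) < 3 * se[1:] + 2.0 / params.population_size)


def test_simulated_cohort_structure(sim_cohort):
    cohort, truth = sim_cohort
    assert len(cohort.families) == 50
    types = {f.mating_type for f in cohort.families.values()}
    assert types <= {"DXD", "DXN"} and types
    for fam in cohort.families.values():
        partners = cohort.partners(fam)
        n_deaf = sum(1 for p in partners if p.hearing_status == "HI")
        assert n_deaf == (2 if fam.mating_type == "DXD" else 1)
    # truth record covers every individual with latent genotypes at all loci
    assert set(truth["individuals"]) == set(cohort.individuals)
    n_loci = 1 + len(truth["params"]["het_freqs"])
    assert all(len(v["genotypes"]) == n_loci for v in truth["individuals"].values())
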