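"""Closed-form fitness: frozen examples, exact oracles, order properties."""

import itertools
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mitonuclear import (
    CrossKind,
    ModelParams,
    PopulationAlleleProfile,
    backcross_compatible_fitness,
    backcross_paternal_fitness,
    cross_fitness,
    f1_fitness,
    f2_fitness,
    fitness_curves,
    polymorphic_fitness,
)

# Per-locus genotype distributions of each cross: (probability, copies of the
# allele mismatched to the zygote's mtDNA).  Used by the exact enumeration
# oracle below, which multiplies out all locus-state combinations with
# Fraction arithmetic -- an independent path from both library methods.
LOCUS_DISTS = {
    CrossKind.F1: [(Fraction(1), 1)],
    CrossKind.F2: [(Fraction(1, 4), 0), (Fraction(1, 2), 1), (Fraction(1, 4), 2)],
    CrossKind.BC_COMPATIBLE: [(Fraction(1, 2), 0), (Fraction(1, 2), 1)],
    CrossKind.BC_PATERNAL: [(Fraction(1, 2), 1), (Fraction(1, 2), 2)],
}


def enumeration_oracle(n, s1, s2, kind):
    """Exact expected fitness by enumerating every locus-state combination."""
    w = {0: 1.0, 1: 1.0 - s1, 2: 1.0 - s2}
    total = 0.0
    for combo in itertools.product(LOCUS_DISTS[kind], repeat=n):
        prob = Fraction(1)
        fitness = 1.0
        for p, state in combo:
            prob *= p
            fitness *= w[state]
        total += float(prob) * fitness
    return total


S_GRID = [0.0, 0.05, 0.3, 0.5, 1.0]


@pytest.mark.parametrize(
    "fn,n,s1,s2,expected",
    [
        (f1_fitness, 1, 0.05, 0.0, 0.95),
        (f1_fitness, 10, 0.0, 0.0, 1.0),
        (f1_fitness, 5, 0.05, 0.0, 0.7737809375),
        (f2_fitness, 1, 0.05, 0.5, 0.85),
        (f2_fitness, 0, 0.3, 0.7, 1.0),
        (f2_fitness, 2, 0.05, 0.5, 0.7225),
        (backcross_compatible_fitness, 1, 0.05, 0.5, 0.975),
        (backcross_compatible_fitness, 3, 0.0, 0.5, 1.0),
        (backcross_compatible_fitness, 2, 0.05, 0.5, 0.950625),
        (backcross_paternal_fitness, 1, 0.05, 0.5, 0.725),
        (backcross_paternal_fitness, 2, 0.05, 0.5, 0.525625),
    ],
)
def test_closed_form_examples(fn, n, s1, s2, expected):
    fv = fn(ModelParams(n_loci=n, s1=s1, s2=s2))
    assert fv.value == pytest.approx(expected, rel=1e-12)


def test_paternal_backcross_equals_f1_when_costs_equal():
    """With s1 = s2 every paternal-backcross locus pays the same cost as F1."""
    for s in (0.05, 0.3):
        p = ModelParams(n_loci=4, s1=s, s2=s)
        assert backcross_paternal_fitness(p).value == pytest.approx(
            f1_fitness(p).value, rel=1e-12
        )


@pytest.mark.parametrize("kind", list(CrossKind))
def test_literal_sum_matches_factorized(kind):
    """The multinomial/binomial sums equal the per-locus power forms."""
    for n in range(0, 21):
        for s1, s2 in itertools.product(S_GRID, S_GRID):
            p = ModelParams(n_loci=n, s1=s1, s2=s2)
            lit = cross_fitness(p, kind, method="closed_form_sum").value
            fac = cross_fitness(p, kind, method="factorized").value
            assert lit == pytest.approx(fac, rel=1e-12, abs=1e-15)


@pytest.mark.parametrize("kind", list(CrossKind))
@pytest.mark.parametrize("n", [1, 2, 4, 8])
def test_exhaustive_enumeration_oracle(kind, n):
    """All-state enumeration with exact probabilities reproduces closed forms."""
    for s1, s2 in [(0.05, 0.5), (0.3, 0.9), (0.0, 1.0)]:
        p = ModelParams(n_loci=n, s1=s1, s2=s2)
        assert cross_fitness(p, kind).value == pytest.approx(
            enumeration_oracle(n, s1, s2, kind), rel=1e-12
        )


def test_curve_table_shape_and_reference_row():
    curves = fitness_curves(1, 0.05, 0.5)
    row = curves.iloc[0]
    assert list(curves.columns) == ["n", "W1", "W2", "W3", "W4"]
    assert (row["n"], row["W1"], row["W2"], row["W3"], row["W4"]) == pytest.approx(
        (1, 0.95, 0.85, 0.975, 0.725)
    )
    with pytest.raises(ValueError):
        fitness_curves(0, 0.05, 0.5)


def test_curves_zero_cost_all_one():
    curves = fitness_curves(5, 0.0, 0.0)
    assert (curves[["W1", "W2", "W3", "W4"]] == 1.0).all().all()


def test_curves_strictly_decreasing_in_n():
    curves = fitness_curves(20, 0.05, 0.5)
    for col in ("W1", "W2", "W3", "W4"):
        assert (np.diff(curves[col]) < 0).all()


def test_cross_ordering_at_reference_costs():
    """W3 >= W1 >= W2 >= W4 for every n at the reference costs (0.05, 0.5)."""
    curves = fitness_curves(20, 0.05, 0.5)
    assert (curves["W3"] >= curves["W1"]).all()
    assert (curves["W1"] >= curves["W2"]).all()
    assert (curves["W2"] >= curves["W4"]).all()


@given(
    s1=st.floats(0.001, 0.5),
    ratio=st.floats(2.0, 10.0),
    n=st.integers(1, 20),
)
@settings(max_examples=100, deadline=None)
def test_ordering_maintained_whenever_s2_exceeds_twice_s1(s1, ratio, n):
    s2 = min(s1 * ratio, 1.0)
    p = ModelParams(n_loci=n, s1=s1, s2=s2)
    w1 = f1_fitness(p).value
    w2 = f2_fitness(p).value
    w3 = backcross_compatible_fitness(p).value
    w4 = backcross_paternal_fitness(p).value
    assert w3 >= w1 >= w2 >= w4


@given(s1=st.floats(0, 1), s2=st.floats(0, 1), n=st.integers(0, 30))
@settings(max_examples=150, deadline=None)
def test_universal_order_relations(s1, s2, n):
    """W3 >= W1 and W2 >= W4 always; W1 >= W2 exactly when s2 >= 2*s1."""
    p = ModelParams(n_loci=n, s1=s1, s2=s2)
    w1 = f1_fitness(p).value
    w2 = f2_fitness(p).value
    w3 = backcross_compatible_fitness(p).value
    w4 = backcross_paternal_fitness(p).value
    assert w3 >= w1 - 1e-15
    assert w2 >= w4 - 1e-15
    for w in (w1, w2, w3, w4):
        assert 0.0 <= w <= 1.0
    if n >= 1:
        if s2 >= 2 * s1:
            assert w1 >= w2 - 1e-12
        else:
            assert w2 >= w1 - 1e-12


def test_fitness_non_increasing_in_each_parameter():
    for kind in CrossKind:
        base = cross_fitness(ModelParams(5, 0.1, 0.4), kind).value
        assert cross_fitness(ModelParams(6, 0.1, 0.4), kind).value <= base + 1e-15
        assert cross_fitness(ModelParams(5, 0.2, 0.4), kind).value <= base + 1e-15
        assert cross_fitness(ModelParams(5, 0.1, 0.5), kind).value <= base + 1e-15


def test_single_lethal_locus_halves_paternal_backcross_fitness():
    """At s2 = 1, one locus already costs half the paternal-backcross brood."""
    p = ModelParams(n_loci=1, s1=0.05, s2=1.0)
    assert backcross_paternal_fitness(p).value == pytest.approx((1 - 0.05) / 2)


def test_invalid_params_rejected():
    with pytest.raises(ValueError):
        ModelParams(n_loci=-1, s1=0.1)
    with pytest.raises(ValueError):
        ModelParams(n_loci=1, s1=1.5)
    with pytest.raises(ValueError):
        ModelParams(n_loci=1, s1=0.1, s2=-0.2)


# ---------------------------------------------------------------------------
# polymorphic extension


def test_polymorphic_reduces_to_fixed_forms_at_fixation():
    cases = [
        (CrossKind.F2, 1, 0.85),
        (CrossKind.F1, 3, 0.95**3),
        (CrossKind.BC_PATERNAL, 2, 0.725**2),
    ]
    for kind, n, expected in cases:
        profile = PopulationAlleleProfile(north=(1.0,) * n, south=(1.0,) * n)
        fv = polymorphic_fitness(profile, ModelParams(n, 0.05, 0.5), kind)
        assert fv.value == pytest.approx(expected, rel=1e-12)


def test_polymorphic_f2_example_half_frequencies():
    profile = PopulationAlleleProfile(north=(0.5,), south=(0.5,))
    fv = polymorphic_fitness(profile, ModelParams(1, 0.05, 0.5), CrossKind.F2)
    assert fv.value >= 0.85 - 1e-12


def test_polymorphic_f2_oracle_by_parental_enumeration():
    """Full enumeration of HWE parents, gametes and unions at one locus."""
    p_n, q_s, s1, s2 = 0.8, 0.7, 0.05, 0.5
    # gamete carrying the north-matched allele: prob = pool frequency
    g_mat, g_pat = p_n, 1 - q_s

    def hwe(p):
        return {2: p * p, 1: 2 * p * (1 - p), 0: (1 - p) * (1 - p)}

    # parent genotype with k matched copies transmits matched w.p. k/2
    def gamete_dist(pool_freq):
        out = {0: 0.0, 1: 0.0}
        for k, pk in hwe(pool_freq).items():
            out[1] += pk * k / 2
            out[0] += pk * (1 - k / 2)
        return out

    gm, gf = gamete_dist(g_mat), gamete_dist(g_pat)
    f1_gamete = {a: 0.0 for a in (0, 1)}
    for a, pa in gm.items():
        for b, pb in gf.items():
            # F1 genotype (a+b matched copies) transmits matched w.p. (a+b)/2
            f1_gamete[1] += pa * pb * (a + b) / 2
            f1_gamete[0] += pa * pb * (1 - (a + b) / 2)
    w = {2: 1.0, 1: 1 - s1, 0: 1 - s2}
    expected = sum(
        pa * pb * w[a + b]
        for a, pa in f1_gamete.items()
        for b, pb in f1_gamete.items()
    )
    profile = PopulationAlleleProfile(north=(p_n,), south=(q_s,))
    fv = polymorphic_fitness(profile, ModelParams(1, s1, s2), CrossKind.F2)
    assert fv.value == pytest.approx(expected, rel=1e-12)


@given(
    p=st.floats(0.0, 1.0),
    s1=st.floats(0.0, 1.0),
    s2=st.floats(0.0, 1.0),
    n=st.integers(1, 5),
)
@settings(max_examples=100, deadline=None)
def test_symmetric_polymorphism_softens_breakdown(p, s1, s2, n):
    """F2 and paternal-backcross fitness >= the fixed-population value.

    Holds for symmetric polymorphism (both pools carry their locally
    adapted allele at the same frequency p): the F1 gamete frequency is
    then exactly 1/2, so F2 matches the fixed case while the paternal
    backcross gains matched homozygotes.  Asymmetric pools can instead
    deepen the breakdown.
    """
    profile = PopulationAlleleProfile(north=(p,) * n, south=(p,) * n)
    params = ModelParams(n, s1, s2)
    for kind in (CrossKind.F2, CrossKind.BC_PATERNAL):
        poly = polymorphic_fitness(profile, params, kind).value
        fixed = cross_fitness(params, kind).value
        assert poly >= fixed - 1e-12


def test_polymorphic_validation():
    with pytest.raises(ValueError):
        PopulationAlleleProfile(north=(1.2,), south=(0.5,))
    with pytest.raises(ValueError):
        polymorphic_fitness(
            PopulationAlleleProfile(north=(1.0,), south=(1.0,)),
            ModelParams(2, 0.05, 0.5),
            CrossKind.F2,
        )
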