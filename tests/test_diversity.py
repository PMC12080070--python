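"""Formula oracles, algebraic identities and invariances of the twelve
diversity indices."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tcrdiv.diversity import (
    INDEX_NAMES,
    ace,
    basharin,
    chao1,
    compute_all,
    d50,
    gini_coefficient,
    gini_simpson,
    hill_number,
    inv_simpson,
    pielou,
    richness_s,
    shannon,
    summarize_abundance,
)

LN2 = math.log(2.0)
H_34 = -(0.75 * math.log(0.75) + 0.25 * math.log(0.25))  # entropy of {3,1}


def A(counts):
    return summarize_abundance(counts)


class TestAbundanceSummary:
    def test_counting(self):
        a = A([1, 1, 2])
        assert (a.S, a.N, a.n(1), a.n(2)) == (3, 4.0, 2, 1)

    def test_singleton(self):
        a = A([7])
        assert (a.S, a.N, a.n(7)) == (1, 7.0, 1)

    def test_invariants(self):
        a = A([1, 1, 2, 15])
        assert sum(i * n for i, n in a.freq_of_freqs.items()) == a.N
        assert sum(a.freq_of_freqs.values()) == a.S
        assert math.isclose(a.p.sum(), 1.0, abs_tol=1e-12)

    @pytest.mark.parametrize("bad", [[], [0, 1], [1, -2]])
    def test_rejects_invalid(self, bad):
        with pytest.raises(ValueError):
            A(bad)


# hand-computed oracle values for each index formula
HAND_CASES = [
    (richness_s, [1, 1, 2], 3.0),
    (richness_s, [7], 1.0),
    (chao1, [1, 1, 2, 2, 3], 5 + 2 * 1 / (2 * 3)),
    (chao1, [3, 3, 3], 3.0),
    (chao1, [1, 1, 1], 3 + 3 * 2 / (2 * 1)),
    (shannon, [1] * 10, math.log(10)),
    (shannon, [7], 0.0),
    (shannon, [3, 1], H_34),
    (inv_simpson, [2] * 6, 6.0),
    (inv_simpson, [7], 1.0),
    (inv_simpson, [3, 1], 1.6),
    (gini_simpson, [7], 0.0),
    (gini_simpson, [1] * 10, 0.9),
    (gini_simpson, [3, 1], 0.375),
    (gini_coefficient, [5] * 8, 0.0),
    (gini_coefficient, [3, 1], 0.25),
]


@pytest.mark.parametrize("fn,counts,expected", HAND_CASES,
                         ids=lambda v: getattr(v, "__name__", None))
def test_hand_oracles(fn, counts, expected):
    assert fn(A(counts)) == pytest.approx(expected, abs=1e-9)


class TestAce:
    def test_hand_evaluation(self):
        # C = 1 - 2/4, gamma^2 clamps to 0, ACE = 1 + 3/0.5
        value, status = ace(A([1, 1, 2, 15]))
        assert value == pytest.approx(7.0, abs=1e-9)
        assert status == "ok"

    def test_no_rare_fallback(self):
        value, status = ace(A([11, 12]))
        assert (value, status) == (2.0, "fallback")

    def test_all_singletons_undefined(self):
        value, status = ace(A([1, 1, 1, 1]))
        assert math.isnan(value) and status == "undefined"

    def test_rare_partition_threshold(self):
        a = A([1, 1, 2, 15])
        rare = a.counts[a.counts <= 10]
        assert (rare.size, int(rare.sum()), int((a.counts > 10).sum())) == (3, 4, 1)


class TestD50:
    def test_dominant_clone(self):
        assert d50([5, 1, 1, 1, 1, 1]) == pytest.approx(100 / 6, abs=1e-9)

    def test_uniform_even(self):
        assert d50([3] * 10) == pytest.approx(50.0)

    def test_at_least_boundary(self):
        assert d50([1, 1]) == pytest.approx(50.0)

    def test_fraction_flag(self):
        assert d50([5, 1, 1, 1, 1, 1], as_fraction=True) == pytest.approx(1 / 6)


class TestHill:
    def test_uniform_identity(self):
        assert hill_number(A([2] * 4), 3) == pytest.approx(4.0, abs=1e-9)
        assert hill_number(A([5, 5]), 4) == pytest.approx(2.0, abs=1e-9)

    def test_hand_q3(self):
        assert hill_number(A([3, 1]), 3) == pytest.approx(0.4375 ** -0.5, abs=1e-9)

    def test_q1_redirects(self):
        with pytest.raises(ValueError, match="[Ss]hannon"):
            hill_number(A([1, 2]), 1)


class TestEvenness:
    def test_pielou_uniform_is_one(self):
        for s in (2, 10, 100):
            v, st = pielou(A([4] * s))
            assert v == pytest.approx(1.0, abs=1e-12) and st == "ok"

    def test_pielou_hand(self):
        v, _ = pielou(A([3, 1]))
        assert v == pytest.approx(H_34 / LN2, abs=1e-9)

    def test_pielou_single_undefined(self):
        v, st = pielou(A([7]))
        assert math.isnan(v) and st == "undefined"

    def test_basharin_hand(self):
        v, _ = basharin(A([10, 10]))
        assert v == pytest.approx((LN2 - 1 / 40) / LN2, abs=1e-9)
        v, _ = basharin(A([3, 1]))
        assert v == pytest.approx((H_34 - 1 / 8) / LN2, abs=1e-9)

    def test_basharin_converges_to_pielou(self):
        # fixed relative abundances, growing N: the (S-1)/(2N) correction vanishes
        j = pielou(A([3, 1]))[0]
        gap = [abs(basharin(A([3 * m, m]))[0] - j) for m in (1, 100, 10000)]
        assert gap[2] < gap[1] < gap[0] and gap[2] < 1e-4


def test_gini_sorted_form_matches_double_sum(rng):
    for _ in range(100):
        counts = rng.integers(1, 50, size=rng.integers(2, 30))
        a = A(counts)
        brute = np.abs(a.p[:, None] - a.p[None, :]).sum() / (2 * a.S**2 * (1 / a.S))
        assert gini_coefficient(a) == pytest.approx(brute, abs=1e-12)


class TestIdentities:
    @pytest.mark.parametrize("counts", [[5, 3, 1], [1, 1, 2, 15], [9] * 7])
    def test_shannon_is_hill_limit(self, counts):
        a = A(counts)
        d1 = math.exp(shannon(a))
        for q in (1 - 1e-4, 1 + 1e-4):
            assert hill_number(a, q) == pytest.approx(d1, rel=1e-3)

    @pytest.mark.parametrize("counts", [[5, 3, 1], [1, 1, 2, 15], [2] * 10])
    def test_simpson_family(self, counts):
        a = A(counts)
        assert inv_simpson(a) == pytest.approx(hill_number(a, 2), abs=1e-12)
        assert gini_simpson(a) == pytest.approx(1 - 1 / inv_simpson(a), abs=1e-12)

    @pytest.mark.parametrize("s", [2, 10, 100])
    def test_uniform_identities(self, s):
        a = A([6] * s)
        for q in (0, 2, 3, 4):
            assert hill_number(a, q) == pytest.approx(s, rel=1e-12)
        assert pielou(a)[0] == pytest.approx(1.0)
        assert gini_coefficient(a) == pytest.approx(0.0, abs=1e-12)
        if s % 2 == 0:
            assert d50([6] * s) == pytest.approx(50.0)


def test_skew_monotonicity(rng):
    """Moving mass from the rarest to the most abundant clonotype never
    increases the entropy-family indices and never decreases Gini."""
    counts = np.sort(rng.integers(2, 40, size=12))[::-1].astype(float)
    skewed = counts.copy()
    skewed[0] += counts[-1] - 1
    skewed[-1] = 1
    a, b = A(counts), A(skewed)
    for fn in (shannon, inv_simpson, gini_simpson):
        assert fn(b) <= fn(a) + 1e-12
    for q in (3, 4):
        assert hill_number(b, q) <= hill_number(a, q) + 1e-12
    assert gini_coefficient(b) >= gini_coefficient(a) - 1e-12


# indices that are functions of the relative abundances alone; Chao1 and ACE
# read absolute singleton/doubleton structure and Basharin reads N, so none
# of those three can be scale-invariant
SCALE_FREE = ("S", "Shannon", "Inv.Simpson", "Gini.Simpson", "D3", "D4",
              "Pielou", "d50", "Gini")


@given(st.lists(st.integers(1, 1000), min_size=1, max_size=40), st.integers(2, 7))
@settings(max_examples=50, deadline=None, derandomize=True)
def test_count_scaling_invariance(counts, factor):
    """Relative-abundance indices are invariant to scaling every count by a
    positive integer; Basharin uses N and is not."""
    v1 = compute_all(counts)
    v2 = compute_all([c * factor for c in counts])
    for name in SCALE_FREE:
        x, y = v1.values[name], v2.values[name]
        assert (math.isnan(x) and math.isnan(y)) or x == pytest.approx(y, rel=1e-9)
    if len(counts) > 1:
        assert v2.values["Basharin"] > v1.values["Basharin"]  # smaller correction


class TestComputeAll:
    def test_composition(self):
        v = compute_all([1, 1, 2, 2, 3])
        assert v.values["Chao1"] == pytest.approx(5 + 1 / 3, abs=1e-9)
        assert v.values["S"] == 5

    def test_single_clonotype_boundary(self):
        v = compute_all([7])
        assert v.values["S"] == 1
        assert v.values["Shannon"] == 0
        assert v.values["Gini.Simpson"] == 0
        assert v.status["Pielou"] == "undefined"
        assert v.status["Basharin"] == "undefined"
        assert math.isnan(v.values["Pielou"])

    def test_permutation_invariance(self, rng):
        counts = rng.integers(1, 100, size=25)
        v1 = compute_all(counts)
        v2 = compute_all(rng.permutation(counts))
        for name in INDEX_NAMES:
            x, y = v1.values[name], v2.values[name]
            assert (math.isnan(x) and math.isnan(y)) or x == y

    def test_chao1_ace_bounded_below_by_richness(self, rng):
        for _ in range(50):
            counts = rng.integers(1, 30, size=rng.integers(2, 50))
            v = compute_all(counts)
            assert v.values["Chao1"] >= v.values["S"]
            if v.status["ACE"] == "ok":
                assert v.values["ACE"] >= v.values["S"] - 1e-9


def test_cross_check_against_scikit_bio(rng):
    """Independent implementations (scikit-bio) agree on the indices whose
    definitions coincide: bias-corrected Chao1, ACE, Shannon (base e),
    Pielou, inverse Simpson (ENS_PIE) and Gini-Simpson."""
    sa = pytest.importorskip("skbio.diversity.alpha")
    for _ in range(20):
        counts = rng.integers(1, 60, size=rng.integers(5, 80))
        a = A(counts)
        assert chao1(a) == pytest.approx(sa.chao1(counts, bias_corrected=True), rel=1e-9)
        assert shannon(a) == pytest.approx(sa.shannon(counts, base=math.e), rel=1e-9)
        assert inv_simpson(a) == pytest.approx(sa.enspie(counts), rel=1e-9)
        assert gini_simpson(a) == pytest.approx(sa.simpson(counts), rel=1e-9)
        assert pielou(a)[0] == pytest.approx(sa.pielou_e(counts), rel=1e-9)
        if a.n(1) < np.sum(counts <= 10):  # skbio's ACE requires C_ace > 0
            assert ace(a)[0] == pytest.approx(sa.ace(counts), rel=1e-9)
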