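"""Unit and property tests for call-string correlations and networks."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from probesim import (
    VariationCallMatrix,
    build_network,
    build_null,
    corr_anti,
    empirical_pvalue,
)
from probesim.covariation import NullDistribution, pairwise_corr_anti

call_strings = st.text(alphabet="IDN", min_size=1, max_size=50)


def brute_force_corr_anti(s1: str, s2: str):
    conc = disc = informative = 0
    for a, b in zip(s1, s2):
        if a == "N" and b == "N":
            continue
        informative += 1
        if a == b and a != "N":
            conc += 1
        elif "N" not in (a, b):
            disc += 1
    if informative == 0:
        return 0.0, 0.0, 0
    return 100.0 * conc / informative, 100.0 * disc / informative, informative


@pytest.mark.parametrize(
    "s1, s2, expected",
    [
        ("II", "II", (100.0, 0.0, 2)),
        ("IDID", "DIDI", (0.0, 100.0, 4)),
        ("IDNNI", "IDNDN", (50.0, 0.0, 4)),
        ("NN", "NN", (0.0, 0.0, 0)),
    ],
)
def test_corr_anti_worked_examples(s1, s2, expected):
    assert corr_anti(s1, s2) == expected


def test_corr_anti_rejects_bad_input():
    with pytest.raises(ValueError, match="length"):
        corr_anti("ID", "IDN")
    with pytest.raises(ValueError, match="illegal"):
        corr_anti("IX", "ID")


@settings(max_examples=200, derandomize=True)
@given(st.integers(1, 50).flatmap(
    lambda n: st.tuples(
        st.text(alphabet="IDN", min_size=n, max_size=n),
        st.text(alphabet="IDN", min_size=n, max_size=n),
    )
))
def test_corr_anti_matches_brute_force(pair):
    s1, s2 = pair
    assert corr_anti(s1, s2) == brute_force_corr_anti(s1, s2)
    c, a, _ = corr_anti(s1, s2)
    assert c + a <= 100.0 + 1e-12


@settings(max_examples=100, derandomize=True)
@given(st.integers(1, 50).flatmap(
    lambda n: st.tuples(
        st.text(alphabet="IDN", min_size=n, max_size=n),
        st.text(alphabet="IDN", min_size=n, max_size=n),
    )
))
def test_inverting_one_string_swaps_corr_and_anti(pair):
    s1, s2 = pair
    flipped = s1.translate(str.maketrans("ID", "DI"))
    c, a, n = corr_anti(s1, s2)
    c2, a2, n2 = corr_anti(flipped, s2)
    assert (c2, a2, n2) == (a, c, n)


def test_pairwise_matches_scalar():
    rng = np.random.default_rng(7)
    codes = rng.integers(-1, 2, size=(10, 40)).astype(np.int8)
    corr, anti, info = pairwise_corr_anti(codes)
    for i in range(10):
        for j in range(10):
            c, a, n = corr_anti(codes[i], codes[j])
            assert corr[i, j] == pytest.approx(c)
            assert anti[i, j] == pytest.approx(a)
            assert info[i, j] == n


class TestNull:
    def _matrix(self, strings):
        return VariationCallMatrix.from_strings(
            [f"ps{i}" for i in range(len(strings))], strings
        )

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(0)
        strings = ["".join(rng.choice(list("IDN"), 30)) for _ in range(20)]
        m = self._matrix(strings)
        n1 = build_null(m, 150, seed=42)
        n2 = build_null(m, 150, seed=42)
        assert np.array_equal(n1.corr_null, n2.corr_null)
        assert np.array_equal(n1.anti_null, n2.anti_null)

    def test_identical_strings_give_corr_100(self):
        m = self._matrix(["IDID"] * 20)
        null = build_null(m, 100, seed=0)
        assert (null.corr_null == 100.0).all()
        assert (null.anti_null == 0.0).all()

    def test_small_universe_goes_exhaustive(self):
        m = self._matrix(["IDID", "IDDD", "NIDI", "DDDD"])
        null = build_null(m, 100, seed=0)
        assert null.exhaustive
        assert null.n_samples == 6  # C(4,2)

    def test_validates_inputs(self):
        m = self._matrix(["IDID", "IDDD", "NIDI"])
        with pytest.raises(ValueError):
            build_null(m, 50, seed=0)  # n_samples too small
        with pytest.raises(ValueError):
            build_null(self._matrix(["IDID"]), 100, seed=0)


class TestEmpiricalPvalue:
    def test_value_above_all(self):
        null = np.arange(1.0, 11.0)
        assert empirical_pvalue(50.0, null) == pytest.approx(1 / 11)

    def test_value_at_or_below_min(self):
        null = np.arange(1.0, 11.0)
        assert empirical_pvalue(0.5, null) == pytest.approx(1.0)

    def test_counting_ties(self):
        null = np.arange(10.0, 101.0, 10.0)  # 10, 20, ..., 100
        assert empirical_pvalue(95.0, null) == pytest.approx(2 / 11)

    def test_empty_null_rejected(self):
        with pytest.raises(ValueError):
            empirical_pvalue(10.0, np.array([]))


class TestBuildNetwork:
    @pytest.fixture()
    def calls(self):
        rng = np.random.default_rng(3)
        strings = ["".join(rng.choice(list("IDN"), 60)) for _ in range(15)]
        return VariationCallMatrix.from_strings(
            [f"ps{i}" for i in range(15)], strings
        )

    def test_alpha_one_stores_all_nondegenerate(self, calls):
        null = build_null(calls, 100, seed=1)
        net = build_network(calls, null, alpha=1.0)
        _, _, info = pairwise_corr_anti(calls.codes)
        offdiag = ~np.eye(15, dtype=bool)
        expected = (info > 0) & offdiag
        assert np.array_equal(net.stored_corr, expected)
        assert np.array_equal(net.stored_anti, expected)

    def test_filtering_monotone_in_alpha(self, calls):
        null = build_null(calls, 100, seed=1)
        strict = build_network(calls, null, alpha=0.05)
        loose = build_network(calls, null, alpha=0.3)
        assert not (strict.stored_corr & ~loose.stored_corr).any()
        assert not (strict.stored_anti & ~loose.stored_anti).any()

    def test_symmetry(self, calls):
        null = build_null(calls, 100, seed=1)
        net = build_network(calls, null, alpha=0.2)
        assert np.array_equal(net.stored_corr, net.stored_corr.T)
        assert np.array_equal(net.corr, net.corr.T)

    def test_invalid_alpha(self, calls):
        null = build_null(calls, 100, seed=1)
        with pytest.raises(ValueError):
            build_network(calls, null, alpha=0.0)

    def test_degenerate_pairs_absent(self):
        m = VariationCallMatrix.from_strings(["a", "b", "c"], ["NN", "NN", "ID"])
        null = NullDistribution(np.zeros(100), np.zeros(100), 100, 0)
        net = build_network(m, null, alpha=1.0)
        assert not net.stored_corr[0, 1] and not net.stored_anti[0, 1]
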