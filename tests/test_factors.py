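"""Normalization-factor arithmetic: worked examples, errors and invariants."""

from fractions import Fraction

import pytest
from hypothesis import given, settings, strategies as st

from spikenorm import (
    SampleStats,
    compute_factors,
    cpm_scale_factor,
    equal_read_factors,
    input_adjusted_factors,
    spikein_factors,
)
from spikenorm.datasets import foxa1_triplicate


def stats(rows):
    return [
        SampleStats(sample_id=f"s{i+1}", unique_sample_reads=x,
                    unique_spikein_reads=s, input_dna_mass=c, spikein_mass=m)
        for i, (x, s, c, m) in enumerate(rows)
    ]


TRIPLICATE = foxa1_triplicate()
X = [4_190_041, 23_728_210, 22_990_981]
S = [142_086, 268_064, 319_773]
C = [592.0, 346.0, 712.0]  # 29.6 / 17.3 / 35.6 ng/uL x 20 uL
M = 62.5


class TestEqualRead:
    def test_triplicate_worked_example(self):
        nfs = equal_read_factors(TRIPLICATE)
        for sid, x in zip(("Rep1", "Rep2", "Rep3"), X):
            assert nfs.factors[sid] == pytest.approx(float(Fraction(min(X), x)), abs=0, rel=1e-15)
        assert nfs.reference_sample == "Rep1"

    @pytest.mark.parametrize(
        "xs,expected",
        [((100, 100), (1.0, 1.0)), ((10, 20, 40), (1.0, 0.5, 0.25))],
    )
    def test_simple_depths(self, xs, expected):
        nfs = equal_read_factors(stats([(x, 1, 1, 1) for x in xs]))
        assert tuple(nfs.factors[f"s{i+1}"] for i in range(len(xs))) == expected

    def test_retained_reads_equalized(self):
        nfs = equal_read_factors(TRIPLICATE)
        retained = nfs.expected_retained(TRIPLICATE)
        assert all(r == pytest.approx(min(X)) for r in retained.values())

    def test_errors(self):
        with pytest.raises(ValueError, match="at least 2"):
            equal_read_factors(TRIPLICATE[:1])
        with pytest.raises(ValueError, match="zero unique sample reads"):
            equal_read_factors(stats([(0, 1, 1, 1), (5, 1, 1, 1)]))


class TestSpikein:
    def test_triplicate_worked_example(self):
        nfs = spikein_factors(TRIPLICATE)
        exact = [float(Fraction(min(S), s)) for s in S]
        assert [nfs.factors[f"Rep{i+1}"] for i in range(3)] == pytest.approx(exact, rel=1e-15)
        # expected retained sample reads: X_i x factor_i
        retained = nfs.expected_retained(TRIPLICATE)
        expect = [x * Fraction(min(S), s) for x, s in zip(X, S)]
        assert [retained[f"Rep{i+1}"] for i in range(3)] == pytest.approx(
            [float(e) for e in expect])
        # the ~12.58M / ~10.22M magnitudes of the bench table
        assert retained["Rep2"] == pytest.approx(12_577_021, abs=1)
        assert retained["Rep3"] == pytest.approx(10_215_673, abs=1)

    def test_equal_recovery_is_identity(self):
        nfs = spikein_factors(stats([(10, 7, 1, 1), (20, 7, 1, 1), (30, 7, 1, 1)]))
        assert set(nfs.factors.values()) == {1.0}

    def test_zero_spikein_names_sample(self):
        with pytest.raises(ValueError, match="s2"):
            spikein_factors(stats([(10, 5, 1, 1), (10, 0, 1, 1)]))


class TestInputAdjusted:
    def test_triplicate_worked_example(self):
        nfs = input_adjusted_factors(TRIPLICATE)
        raw = [Fraction(c) / Fraction(M) / Fraction(x, s)
               for x, s, c in zip(X, S, C)]
        top = max(raw)
        assert [nfs.factors[f"Rep{i+1}"] for i in range(3)] == pytest.approx(
            [float(r / top) for r in raw], rel=1e-15)
        assert nfs.reference_sample == "Rep1"
        # raw factors match exact rational arithmetic
        assert float(raw[0]) == pytest.approx(0.321199, abs=5e-7)
        assert float(raw[1]) == pytest.approx(0.062542, abs=5e-7)
        assert float(raw[2]) == pytest.approx(0.158447, abs=5e-7)

    def test_reference_retains_all_reads(self):
        retained = input_adjusted_factors(TRIPLICATE).expected_retained(TRIPLICATE)
        assert retained["Rep1"] == X[0]
        assert retained["Rep2"] == pytest.approx(4_620_190, abs=2)
        assert retained["Rep3"] == pytest.approx(11_341_410, abs=2)

    def test_symmetric_group_is_identity(self):
        nfs = input_adjusted_factors(stats([(10, 2, 50, 5)] * 3))
        assert set(nfs.factors.values()) == {1.0}

    def test_ratio_contract(self):
        """After normalization X'_i/S_i is proportional to C_i/M_i."""
        nfs = input_adjusted_factors(TRIPLICATE)
        vals = [
            (x * nfs.factors[f"Rep{i+1}"] / s) / (c / M)
            for i, (x, s, c) in enumerate(zip(X, S, C))
        ]
        assert vals[0] == pytest.approx(vals[1], rel=1e-12)
        assert vals[1] == pytest.approx(vals[2], rel=1e-12)

    def test_equal_mass_reduction(self):
        """With equal masses the factors are proportional to S_i/X_i."""
        rows = [(100, 10, 50, 5), (200, 15, 50, 5), (150, 30, 50, 5)]
        nfs = input_adjusted_factors(stats(rows))
        ratios = [nfs.factors[f"s{i+1}"] / (s / x)
                  for i, (x, s, _, _) in enumerate(rows)]
        assert ratios[0] == pytest.approx(ratios[1], rel=1e-12)
        assert ratios[1] == pytest.approx(ratios[2], rel=1e-12)

    def test_degenerate_inputs(self):
        with pytest.raises(ValueError, match="masses"):
            input_adjusted_factors(stats([(10, 5, 0, 5), (10, 5, 3, 5)]))
        with pytest.raises(ValueError, match="read"):
            input_adjusted_factors(stats([(10, 0, 3, 5), (10, 5, 3, 5)]))


class TestCpm:
    @pytest.mark.parametrize("total,expected", [
        (1_000_000, 1.0),
        (4_190_041, 1e6 / 4_190_041),
    ])
    def test_scale(self, total, expected):
        assert cpm_scale_factor(total) == pytest.approx(expected, rel=1e-12)

    def test_scaled_window_value(self):
        assert 5 * cpm_scale_factor(2_000_000) == pytest.approx(2.5)

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            cpm_scale_factor(0)

    def test_compute_factors_cpm_is_empty(self):
        nfs = compute_factors("cpm", TRIPLICATE)
        assert nfs.factors == {}

    def test_unknown_method(self):
        with pytest.raises(ValueError, match="unknown"):
            compute_factors("loess", TRIPLICATE)


counts = st.integers(min_value=1, max_value=10**8)
masses = st.floats(min_value=1e-3, max_value=1e4, allow_nan=False)


@settings(max_examples=100, deadline=None, derandomize=True)
@given(st.lists(st.tuples(counts, counts, masses, masses), min_size=2, max_size=6))
def test_factor_invariants(rows):
    """All factors in (0,1]; products equalized; cross-ratio identity holds."""
    group = stats(rows)
    eq = equal_read_factors(group)
    sp = spikein_factors(group)
    ia = input_adjusted_factors(group)
    for nfs in (eq, sp, ia):
        assert all(0.0 < f <= 1.0 for f in nfs.factors.values())
        assert nfs.factors[nfs.reference_sample] == 1.0
    xs = [r[0] for r in rows]
    ss = [r[1] for r in rows]
    for i, s in enumerate(group):
        assert xs[i] * eq.factors[s.sample_id] == pytest.approx(min(xs), rel=1e-9)
        assert ss[i] * sp.factors[s.sample_id] == pytest.approx(min(ss), rel=1e-9)
    # cross-ratio identity of the input-adjusted method
    f = [ia.factors[s.sample_id] for s in group]
    for i in range(len(rows)):
        for j in range(i + 1, len(rows)):
            xi, si, ci, mi = rows[i]
            xj, sj, cj, mj = rows[j]
            lhs = (xi * f[i]) * sj * cj * mi
            rhs = (xj * f[j]) * si * ci * mj
            assert lhs == pytest.approx(rhs, rel=1e-9)


@settings(max_examples=50, deadline=None, derandomize=True)
@given(
    st.lists(st.tuples(counts, counts, masses), min_size=2, max_size=5),
    st.floats(min_value=1e-2, max_value=1e3),
)
def test_mass_scale_invariance(rows, k):
    """Multiplying all masses by one constant leaves the factors unchanged."""
    base = stats([(x, s, c, 7.5) for x, s, c in rows])
    scaled = stats([(x, s, c * k, 7.5 * k) for x, s, c in rows])
    f0 = input_adjusted_factors(base).factors
    f1 = input_adjusted_factors(scaled).factors
    for sid in f0:
        assert f0[sid] == pytest.approx(f1[sid], rel=1e-9)
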