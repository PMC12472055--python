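import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from neutromet import (
    BinDefinition,
    FeatureTable,
    InvariantError,
    PatternFile,
    Spectrum,
    crs_select,
    integrate_bins,
    lorentzian,
    lorentzian_area,
    pareto_scale,
    ta_normalise,
)


def flat_spectrum(value=1.0, span=(0.0, 2.0), n=2001, **meta):
    ppm = np.linspace(*span, n)
    return Spectrum(ppm, np.full_like(ppm, value), meta=meta)


def table_from_matrix(X, bins=None, state="raw", groups=None):
    X = np.asarray(X, float)
    n, p = X.shape
    if bins is None:
        bins = [
            BinDefinition(f"b{j}", 10.0 - j, 9.5 - j, f"met{j}", f"M{j}")
            for j in range(p)
        ]
    meta = pd.DataFrame({"sample_id": [f"s{i}" for i in range(n)]})
    if groups is not None:
        meta["group"] = groups
    return FeatureTable(X, meta, bins, state)


class TestIntegrateBins:
    def test_unit_rectangle_area(self):
        s = flat_spectrum(1.0)
        pat = PatternFile([BinDefinition("b1", 1.05, 0.95)])
        t = integrate_bins([s], pat)
        assert t.values[0, 0] == pytest.approx(0.100, abs=1e-9)

    def test_zero_spectrum_gives_zero_areas(self):
        s = flat_spectrum(0.0)
        pat = PatternFile([BinDefinition("b1", 1.5, 1.0), BinDefinition("b2", 0.8, 0.2)])
        t = integrate_bins([s], pat)
        assert np.all(t.values == 0)

    def test_lorentzian_matches_arctan_integral(self):
        # 0.001 ppm axis step; closed-form Lorentzian integral as oracle
        ppm = np.arange(0.0, 3.0, 0.001)
        height, fwhm, center = 5.0, 0.004, 1.5
        s = Spectrum(ppm, height * lorentzian(ppm, center, fwhm))
        pat = PatternFile([BinDefinition("b1", 1.56, 1.44)])
        t = integrate_bins([s], pat)
        expected = lorentzian_area(height, fwhm, 1.56, 1.44, center)
        assert t.values[0, 0] == pytest.approx(expected, rel=0.005)

    def test_split_bin_additivity(self):
        rng = np.random.default_rng(0)
        ppm = np.linspace(0.0, 2.0, 1501)
        s = Spectrum(ppm, rng.normal(5.0, 1.0, ppm.size))
        whole = PatternFile([BinDefinition("w", 1.30, 1.10)])
        # split point deliberately off the sampling grid
        parts = PatternFile(
            [BinDefinition("p1", 1.30, 1.2173), BinDefinition("p2", 1.2173, 1.10)]
        )
        a = integrate_bins([s], whole).values[0, 0]
        with np.errstate(all="ignore"):
            b = integrate_bins([s], parts).values[0].sum()
        assert b == pytest.approx(a, abs=1e-9)

    def test_bin_outside_axis_is_error(self):
        s = flat_spectrum(1.0, span=(0.0, 2.0))
        pat = PatternFile([BinDefinition("far", 5.0, 4.0)])
        with pytest.raises(InvariantError, match="far"):
            integrate_bins([s], pat)


class TestTaNormalise:
    def test_row_becomes_proportions(self):
        t = table_from_matrix([[2.0, 3.0, 5.0]])
        out = ta_normalise(t)
        np.testing.assert_allclose(out.values[0], [0.2, 0.3, 0.5], rtol=1e-12)
        assert out.state == "normalised"

    def test_scale_invariance(self):
        t1 = table_from_matrix([[2.0, 3.0, 5.0], [1.0, 1.0, 2.0]])
        X2 = t1.values.copy()
        X2[0] *= 7.0
        t2 = table_from_matrix(X2)
        np.testing.assert_allclose(
            ta_normalise(t1).values[0], ta_normalise(t2).values[0], rtol=1e-12
        )

    def test_zero_row_is_error(self):
        t = table_from_matrix([[0.0, 0.0], [1.0, 1.0]])
        with pytest.raises(InvariantError, match="s0"):
            ta_normalise(t)

    def test_idempotent_on_values(self):
        t = table_from_matrix([[2.0, 3.0, 5.0], [4.0, 1.0, 5.0]])
        once = ta_normalise(t)
        again = ta_normalise(table_from_matrix(once.values))
        np.testing.assert_allclose(again.values, once.values, rtol=1e-12)

    def test_row_sums_are_one(self):
        rng = np.random.default_rng(3)
        t = table_from_matrix(rng.uniform(0.1, 5.0, size=(6, 9)))
        out = ta_normalise(t)
        np.testing.assert_allclose(out.values.sum(axis=1), 1.0, atol=1e-12)


class TestParetoScale:
    def test_two_point_column(self):
        # column (1, 3): mean 2, sample SD sqrt(2), divisor 2^(1/4)
        X = np.array([[1.0, 0.5], [3.0, 0.5]])
        ft = table_from_matrix(X, state="normalised")
        out = pareto_scale(ft)
        expected = (1.0 - 2.0) / np.sqrt(np.sqrt(2.0))
        assert out.values[0, 0] == pytest.approx(expected, abs=1e-9)
        assert out.values[0, 0] == pytest.approx(-0.8409, abs=1e-4)
        assert out.values[1, 0] == pytest.approx(0.8409, abs=1e-4)

    def test_constant_column_becomes_zero(self):
        ft = table_from_matrix(
            np.array([[0.3, 0.7], [0.3, 0.7], [0.3, 0.7]]), state="normalised"
        )
        out = pareto_scale(ft)
        assert np.all(out.values[:, 0] == 0)
        assert out.state == "scaled"

    def test_columns_centred(self):
        rng = np.random.default_rng(1)
        X = rng.uniform(0.0, 1.0, size=(8, 5))
        X /= X.sum(axis=1, keepdims=True)
        out = pareto_scale(table_from_matrix(X, state="normalised"))
        np.testing.assert_allclose(out.values.mean(axis=0), 0.0, atol=1e-12)

    def test_single_sample_is_error(self):
        ft = table_from_matrix(np.array([[0.5, 0.5]]), state="normalised")
        with pytest.raises(InvariantError):
            pareto_scale(ft)


def crs_table(values, annotations, metabolite_ids):
    bins = [
        BinDefinition(f"b{j}", 10.0 - 0.6 * j, 9.6 - 0.6 * j, a, m)
        for j, (a, m) in enumerate(zip(annotations, metabolite_ids))
    ]
    return table_from_matrix(values, bins=bins, state="normalised"), PatternFile(bins)


class TestCRS:
    def test_single_candidate_kept_with_score_one(self):
        rng = np.random.default_rng(0)
        t, pat = crs_table(rng.uniform(0.1, 1, (10, 2)), ["ala", "lac"], ["M1", "M2"])
        out, res = crs_select(t, pat)
        assert out.n_bins == 2
        assert all(m.scores[m.chosen] == 1.0 for m in res.metabolites)

    def test_correlated_pair_beats_independent_noise(self):
        rng = np.random.default_rng(5)
        z = rng.normal(size=30)
        A = 1.0 + 0.5 * z
        B = 2.0 + 1.5 * z  # exact affine copy of A: corr 1
        C = rng.normal(size=30)  # independent
        t, pat = crs_table(
            np.column_stack([A, B, C]), ["ala"] * 3, ["M1"] * 3
        )
        out, res = crs_select(t, pat)
        m = res.metabolites[0]
        assert m.chosen in ("b0", "b1")
        assert m.scores["b2"] < m.scores[m.chosen]

    def test_counting_contract(self):
        """10 annotated metabolites over 24 candidate bins + 9 unknown bins
        reduce to exactly 10 columns with 9 unknowns removed."""
        rng = np.random.default_rng(2)
        candidates = [3, 2, 2, 3, 2, 3, 2, 3, 2, 2]  # sums to 24
        annotations, ids = [], []
        for i, k in enumerate(candidates):
            annotations += [f"met{i}"] * k
            ids += [f"M{i}"] * k
        annotations += ["unknown"] * 9
        ids += [""] * 9
        t, pat = crs_table(rng.uniform(0.1, 1.0, (12, 33)), annotations, ids)
        out, res = crs_select(t, pat)
        assert out.n_bins == 10
        assert len(res.removed_unknown_bins) == 9
        assert len(res.removed_candidate_bins) == 24 - 10

    def test_all_zero_variance_candidates_error(self):
        X = np.ones((6, 2)) * 0.5
        t, pat = crs_table(X, ["ala", "ala"], ["M1", "M1"])
        with pytest.raises(InvariantError):
            crs_select(t, pat)

    def test_requires_normalised_state(self, simple_table):
        pat = PatternFile(list(simple_table.bins))
        with pytest.raises(InvariantError):
            crs_select(simple_table, pat)

    def test_lowest_noise_bin_recovered(self):
        """When candidate bins share one latent concentration plus bin-specific
        noise, the least-noisy bin wins nearly always."""
        rng = np.random.default_rng(7)
        hits = trials = 0
        for _ in range(30):
            z = rng.lognormal(0.0, 1.0, size=60)
            noise_sd = [0.05, 0.6, 0.9, 1.2]
            X = np.column_stack([z + rng.normal(0, sd, 60) for sd in noise_sd])
            t, pat = crs_table(np.abs(X), ["ala"] * 4, ["M1"] * 4)
            out, res = crs_select(t, pat)
            hits += res.metabolites[0].chosen == "b0"
            trials += 1
        assert hits / trials >= 0.9

    def test_output_never_exceeds_input_columns(self):
        rng = np.random.default_rng(4)
        t, pat = crs_table(
            rng.uniform(0.1, 1.0, (8, 4)), ["a", "a", "b", "unknown"], ["M1", "M1", "M2", ""]
        )
        out, _ = crs_select(t, pat)
        assert out.n_bins == 2  # one per annotated metabolite


@settings(max_examples=25, deadline=None)
@given(st.integers(min_value=0, max_value=10_000))
def test_ta_then_pareto_invariants_hold(seed):
    """Row sums 1 after TA; column means 0 after Pareto; pipeline states."""
    rng = np.random.default_rng(seed)
    X = rng.uniform(0.05, 2.0, size=(5, 6))
    t = table_from_matrix(X)
    norm = ta_normalise(t)
    np.testing.assert_allclose(norm.values.sum(axis=1), 1.0, atol=1e-12)
    scaled = pareto_scale(norm)
    np.testing.assert_allclose(scaled.values.mean(axis=0), 0.0, atol=1e-10)
    assert scaled.state == "scaled"
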