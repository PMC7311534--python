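"""Dictionary construction, compression and inner-product matching."""

import numpy as np
import pytest

from liverperf import (
    DictionaryGrid,
    InputFunctions,
    PerfusionParams,
    build_dictionary,
    compress,
    default_grid,
    estimate_dv,
    forward_model,
    match,
)
from liverperf.dictionary import (
    Dictionary,
    DictionaryMatcher,
    MTT_EPS,
    load_dictionary,
    match_arrays,
    save_dictionary,
)


@pytest.fixture(scope="module")
def small_matcher(inputs):
    """Coarse dictionary (21 x 21 = 441 entries) for oracle comparisons."""
    grid = DictionaryGrid(
        af_values=np.linspace(0, 1, 21),
        mtt_values=np.concatenate([[MTT_EPS], np.arange(5.0, 101.0, 5.0)]),
    )
    return DictionaryMatcher(inputs=inputs, grid=grid).fit()


class TestGrid:
    def test_default_grid_dimensions(self):
        g = default_grid()
        assert g.af_values.size == 101
        assert g.mtt_values.size == 101
        assert g.n_entries == 10201

    def test_default_grid_content(self):
        g = default_grid()
        assert g.af_values[0] == 0.0 and g.af_values[-1] == 1.0
        assert g.af_values[30] == pytest.approx(0.30)
        assert g.mtt_values[0] == MTT_EPS
        assert np.array_equal(g.mtt_values[1:], np.arange(1.0, 101.0))

    def test_grid_validation(self):
        with pytest.raises(ValueError):
            DictionaryGrid(af_values=[0.5, 0.2], mtt_values=[1.0])
        with pytest.raises(ValueError):
            DictionaryGrid(af_values=[0.0, 1.5], mtt_values=[1.0])
        with pytest.raises(ValueError):
            DictionaryGrid(af_values=[0.5], mtt_values=[1.0], dv_fixed=0.5)


class TestBuild:
    def test_columns_have_unit_norm(self, matcher):
        norms = np.linalg.norm(matcher.dictionary_.entries, axis=0)
        assert norms == pytest.approx(np.ones(matcher.n_entries_), abs=1e-10)

    def test_column_equals_normalized_forward_curve(self, matcher, inputs):
        d = matcher.dictionary_
        j = 3060  # AF 0.30, MTT 30 on the default grid
        assert d.params[j] == pytest.approx([0.30, 30.0])
        curve = forward_model(PerfusionParams(0.30, 1.0, 30.0), inputs)
        assert d.norms[j] == pytest.approx(np.linalg.norm(curve), rel=1e-12)
        assert d.entries[:, j] == pytest.approx(curve / np.linalg.norm(curve), abs=1e-12)

    def test_neighboring_columns_are_distinct(self, small_matcher):
        e = small_matcher.dictionary_.entries
        gram = e.T @ e
        np.fill_diagonal(gram, 0.0)
        assert gram.max() < 1.0

    def test_zero_inputs_raise(self, times):
        silent = InputFunctions(times=times, aif=np.zeros_like(times), pvif=np.zeros_like(times))
        with pytest.raises(ValueError):
            build_dictionary(default_grid(0.5, 50.0), silent)


class TestMatch:
    def test_scaled_entry_recovered_exactly(self, matcher, inputs):
        curve = 0.3 * forward_model(PerfusionParams(0.30, 1.0, 30.0), inputs)
        res = match(curve, matcher.dictionary_)[0]
        assert res.valid
        assert res.params.af == 0.30 and res.params.mtt == 30.0
        assert res.inner_product == pytest.approx(1.0, abs=1e-12)
        assert res.params.dv == pytest.approx(0.3, rel=1e-12)

    def test_off_grid_af_snaps_to_neighbor(self, matcher, inputs):
        curve = forward_model(PerfusionParams(0.305, 1.0, 30.0), inputs)
        res = match(curve, matcher.dictionary_)[0]
        assert res.params.af in (0.30, 0.31)
        assert res.params.mtt == 30.0

    def test_negated_entry_scores_minus_one(self, small_matcher):
        d = small_matcher.dictionary_
        j = 57
        probe = -d.entries[:, j]
        assert probe @ d.entries[:, j] == pytest.approx(-1.0)
        res = match(probe, d)[0]
        assert res.column_index != j

    def test_zero_curve_flagged_not_raised(self, small_matcher, times):
        res = match(np.zeros_like(times), small_matcher.dictionary_)[0]
        assert not res.valid and res.params is None

    def test_scale_invariance(self, small_matcher, inputs):
        curve = forward_model(PerfusionParams(0.45, 0.4, 35.0), inputs)
        r1 = match(curve, small_matcher.dictionary_)[0]
        r2 = match(7.5 * curve, small_matcher.dictionary_)[0]
        assert r1.column_index == r2.column_index
        assert r2.params.dv == pytest.approx(7.5 * r1.params.dv, rel=1e-12)

    def test_results_independent_of_batch_size(self, small_matcher, rng):
        probes = rng.uniform(0, 1, size=(57, 100))
        a = match_arrays(probes, small_matcher.dictionary_, batch_size=8)
        b = match_arrays(probes, small_matcher.dictionary_, batch_size=10_000)
        assert np.array_equal(a["column"], b["column"])
        assert a["dv"] == pytest.approx(b["dv"])

    def test_tie_breaks_to_lowest_column(self, times, inputs):
        d = build_dictionary(default_grid(0.5, 50.0), inputs)
        dup = Dictionary(
            grid=d.grid,
            times=d.times,
            entries=np.repeat(d.entries[:, :1], 4, axis=1),
            norms=np.repeat(d.norms[:1], 4),
            params=d.params[:4],
        )
        res = match(dup.entries[:, 2].copy(), dup)[0]
        assert res.column_index == 0

    def test_naive_exhaustive_search_oracle(self, small_matcher, inputs, rng):
        """match() must agree with a brute-force double loop over all entries."""
        d = small_matcher.dictionary_
        assert d.n_entries <= 500
        model_curves = [
            forward_model(
                PerfusionParams(rng.uniform(0, 1), rng.uniform(0.1, 1), rng.uniform(1, 100)),
                inputs,
            )
            for _ in range(50)
        ]
        probes = np.vstack(model_curves + [rng.uniform(0, 1, d.times.size) for _ in range(50)])
        fast = match_arrays(probes, d)
        for i, probe in enumerate(probes):
            unit = probe / np.linalg.norm(probe)
            best_j, best_ip = -1, -np.inf
            for j in range(d.n_entries):
                ip = float(unit @ d.entries[:, j])
                if ip > best_ip:
                    best_j, best_ip = j, ip
            assert fast["column"][i] == best_j
            assert fast["inner_product"][i] == pytest.approx(best_ip, abs=1e-12)


class TestEstimateDv:
    def test_norm_ratio_examples(self, rng):
        entry = rng.uniform(0, 1, 50)
        assert estimate_dv(0.5 * entry, entry) == pytest.approx(0.5)
        assert estimate_dv(entry, entry) == pytest.approx(1.0)
        assert np.isnan(estimate_dv(entry, np.zeros(50)))

    def test_end_to_end_dv_recovery(self, matcher, inputs):
        curve = forward_model(PerfusionParams(0.30, 0.30, 30.0), inputs)
        res = matcher.match(curve[None, :]).iloc[0]
        assert abs(res["dv"] - 0.30) < 0.005


class TestCompression:
    def test_full_rank_matching_is_identical(self, small_matcher, rng):
        d = small_matcher.dictionary_
        cd = compress(d, rank=min(d.entries.shape))
        probes = rng.uniform(0, 1, size=(40, d.times.size))
        assert np.array_equal(
            match_arrays(probes, d)["column"], match_arrays(probes, cd)["column"]
        )

    def test_full_rank_reconstruction(self, small_matcher):
        d = small_matcher.dictionary_
        cd = compress(d, rank=min(d.entries.shape))
        assert cd.left_basis @ cd.projected == pytest.approx(d.entries, abs=1e-8)

    def test_energy_rank_agrees_on_noiseless_probes(self, matcher, inputs, rng):
        d = matcher.dictionary_
        cd = compress(d)  # smallest rank with >= 99.999% singular-value energy
        assert cd.rank < min(d.entries.shape)
        params = np.column_stack(
            [rng.uniform(0, 1, 1000), rng.uniform(0.1, 1, 1000), rng.uniform(1, 100, 1000)]
        )
        probes = np.vstack(
            [forward_model(PerfusionParams(*p), inputs) for p in params]
        )
        full = match_arrays(probes, d)["column"]
        low = match_arrays(probes, cd)["column"]
        assert np.mean(full == low) >= 0.99

    def test_rank_one_on_identical_columns(self, small_matcher):
        d = small_matcher.dictionary_
        col = d.entries[:, :1]
        dup = Dictionary(
            grid=d.grid, times=d.times,
            entries=np.repeat(col, 6, axis=1),
            norms=np.repeat(d.norms[:1], 6),
            params=d.params[:6],
        )
        cd = compress(dup, rank=1)
        assert cd.left_basis @ cd.projected == pytest.approx(dup.entries, abs=1e-10)

    def test_invalid_rank(self, small_matcher):
        with pytest.raises(ValueError):
            compress(small_matcher.dictionary_, rank=0)


class TestEstimatorApi:
    def test_sklearn_params_round_trip(self, inputs):
        m = DictionaryMatcher(inputs=inputs, af_step=0.1, mtt_step=10.0)
        params = m.get_params()
        assert params["af_step"] == 0.1
        m.set_params(mtt_step=20.0)
        assert m.mtt_step == 20.0

    def test_predict_returns_nan_for_invalid(self, small_matcher, times):
        out = small_matcher.predict(np.zeros((1, times.size)))
        assert np.isnan(out).all()

    def test_score_threshold_masks_poor_matches(self, small_matcher, rng):
        m = DictionaryMatcher(**small_matcher.get_params())
        m.set_params(score_threshold=0.999999)
        m.fit()
        noise = rng.uniform(0, 1, (5, 100))
        assert not m.match(noise)["valid"].any()

    def test_clip_dv(self, small_matcher, inputs):
        curve = 10.0 * forward_model(PerfusionParams(0.5, 1.0, 50.0), inputs)
        m = DictionaryMatcher(**{**small_matcher.get_params(), "clip_dv": True}).fit()
        assert m.match(curve[None, :])["dv"].iloc[0] <= 1.0

    def test_curve_length_mismatch(self, small_matcher):
        with pytest.raises(ValueError):
            small_matcher.predict(np.ones((2, 17)))


def test_hdf5_round_trip(small_matcher, tmp_path, rng):
    d = small_matcher.dictionary_
    path = tmp_path / "dict.h5"
    save_dictionary(d, path)
    d2 = load_dictionary(path)
    assert np.array_equal(d.entries, d2.entries)
    assert np.array_equal(d.norms, d2.norms)
    assert np.array_equal(d.params, d2.params)
    assert d2.inputs_hash == d.inputs_hash
    probes = rng.uniform(0, 1, size=(5, d.times.size))
    assert np.array_equal(
        match_arrays(probes, d)["column"], match_arrays(probes, d2)["column"]
    )
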