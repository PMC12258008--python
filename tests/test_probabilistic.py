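"""Oracle and property tests for the E[D]/Omega accumulation machinery."""

import numpy as np
import pytest
from scipy import sparse

from scenariofree import (
    PhaseAccumulator,
    ValidationError,
    accumulate,
    combine_phase_accumulators,
)
from conftest import toy_influences


def dense_weighted_covariance(mats, weights, rows):
    """Brute-force oracle: sum_s w_s Dv^T Dv - (sum_s w_s Dv)^T (sum_s w_s Dv)."""
    second = sum(
        w * (np.asarray(m.todense())[rows].T @ np.asarray(m.todense())[rows])
        for m, w in zip(mats, weights)
    )
    mean = sum(w * np.asarray(m.todense())[rows] for m, w in zip(mats, weights))
    return second - mean.T @ mean


class TestAccumulate:
    def test_omega_matches_dense_weighted_covariance_oracle(self, rng):
        stream = toy_influences(rng)
        mats = [m for m, _ in stream]
        weights = [w for _, w in stream]
        rows = np.array([0, 2, 3])
        model = accumulate(iter(stream), {"v": rows})
        oracle = dense_weighted_covariance(mats, weights, rows)
        assert np.abs(model.omega["v"] - oracle).max() < 1e-10

    def test_expected_influence_is_weighted_sum(self, rng):
        stream = toy_influences(rng)
        model = accumulate(iter(stream), {"v": np.arange(5)})
        expected = sum(w * m.toarray() for m, w in stream)
        assert np.abs(model.expected_influence.toarray() - expected).max() < 1e-14

    def test_single_scenario_gives_zero_omega(self, rng):
        m = sparse.csr_matrix(rng.uniform(size=(6, 3)))
        model = accumulate(iter([(m, 1.0)]), {"v": np.arange(6)})
        assert np.abs(model.omega["v"]).max() < 1e-12
        assert model.total_variance("v", rng.uniform(size=3)) == 0.0

    def test_duplicated_scenario_is_degenerate(self, rng):
        m = sparse.csr_matrix(rng.uniform(size=(6, 3)))
        single = accumulate(iter([(m, 1.0)]), {"v": np.arange(6)})
        double = accumulate(iter([(m, 0.5), (m, 0.5)]), {"v": np.arange(6)})
        assert np.abs(single.omega["v"] - double.omega["v"]).max() < 1e-12
        assert np.abs(
            (single.expected_influence - double.expected_influence).toarray()
        ).max() < 1e-14

    def test_weight_sum_validation(self, rng):
        m = sparse.csr_matrix(rng.uniform(size=(4, 2)))
        with pytest.raises(ValidationError):
            accumulate(iter([(m, 0.7)]), {"v": np.arange(4)})

    def test_shape_mismatch_raises(self, rng):
        a = sparse.csr_matrix(rng.uniform(size=(4, 2)))
        b = sparse.csr_matrix(rng.uniform(size=(5, 2)))
        with pytest.raises(ValidationError):
            accumulate(iter([(a, 0.5), (b, 0.5)]), {"v": np.arange(4)})

    def test_order_invariance(self, rng):
        stream = toy_influences(rng, n_scen=5, nvox=8, nb=3,
                                weights=(0.1, 0.3, 0.2, 0.25, 0.15))
        rows = np.arange(8)
        m1 = accumulate(iter(stream), {"v": rows})
        m2 = accumulate(iter(stream[::-1]), {"v": rows})
        scale = np.abs(m1.omega["v"]).max()
        assert np.abs(m1.omega["v"] - m2.omega["v"]).max() <= 1e-12 * scale
        d1 = m1.expected_influence.toarray()
        d2 = m2.expected_influence.toarray()
        assert np.abs(d1 - d2).max() <= 1e-12 * np.abs(d1).max()

    def test_stream_is_consumed_exactly_once(self, rng):
        """The accumulator works off a one-shot iterator (no revisiting)."""
        stream = toy_influences(rng)
        visits = []

        def one_shot():
            for i, (m, w) in enumerate(stream):
                assert i not in visits, "scenario revisited"
                visits.append(i)
                yield m, w

        accumulate(one_shot(), {"v": np.arange(5)})
        assert visits == [0, 1, 2]


class TestModelEvaluation:
    def test_expected_dose_matches_scenario_sum_oracle(self, rng):
        stream = toy_influences(rng)
        model = accumulate(iter(stream), {"v": np.arange(5)})
        x = rng.uniform(size=2)
        oracle = sum(w * (m @ x) for m, w in stream)
        got = model.expected_dose(x)
        assert np.abs(got - oracle).max() < 1e-10
        # linearity
        x2 = rng.uniform(size=2)
        assert np.allclose(
            model.expected_dose(x + x2),
            model.expected_dose(x) + model.expected_dose(x2),
        )
        assert np.all(model.expected_dose(np.zeros(2)) == 0.0)

    def test_total_variance_matches_voxelwise_oracle(self, rng):
        stream = toy_influences(rng)
        rows = np.array([1, 2, 4])
        model = accumulate(iter(stream), {"v": rows})
        x = rng.uniform(size=2)
        doses = [np.asarray((m @ x))[rows] for m, _ in stream]
        w = [wt for _, wt in stream]
        first = sum(wi * d for wi, d in zip(w, doses))
        second = sum(wi * d * d for wi, d in zip(w, doses))
        oracle = float(np.sum(second - first**2))
        got = model.total_variance("v", x)
        assert got == pytest.approx(oracle, rel=1e-8)

    def test_quadratic_scaling(self, rng):
        stream = toy_influences(rng)
        model = accumulate(iter(stream), {"v": np.arange(5)})
        x = rng.uniform(size=2)
        assert model.total_variance("v", 2 * x) == pytest.approx(
            4 * model.total_variance("v", x), rel=1e-12
        )

    def test_omega_symmetric_and_psd_up_to_rounding(self, rng):
        for trial in range(5):
            stream = toy_influences(
                rng, n_scen=4, nvox=10, nb=6, weights=(0.4, 0.3, 0.2, 0.1)
            )
            model = accumulate(iter(stream), {"v": np.arange(10)})
            O = model.omega["v"]
            assert np.abs(O - O.T).max() <= 1e-10 * max(np.abs(O).max(), 1e-300)
            evals = np.linalg.eigvalsh(O)
            assert evals.min() >= -1e-8 * np.trace(O)
            for _ in range(5):
                x = rng.normal(size=6)
                q = float(x @ O @ x)
                assert q >= -1e-8 * np.trace(O) * float(x @ x)

    def test_unknown_voi_raises(self, rng):
        model = accumulate(iter(toy_influences(rng)), {"v": np.arange(5)})
        with pytest.raises(KeyError):
            model.total_variance("missing", np.zeros(2))

    def test_fluence_length_validation(self, rng):
        model = accumulate(iter(toy_influences(rng)), {"v": np.arange(5)})
        with pytest.raises(ValidationError):
            model.expected_dose(np.zeros(3))


class TestPhaseCombination:
    def _accs(self, rng, identical=False):
        vois = {"v": np.arange(6)}
        accs = []
        base = toy_influences(rng, n_scen=2, nvox=6, nb=3, weights=(0.6, 0.4))
        for k in range(2):
            acc = PhaseAccumulator(vois)
            stream = base if identical or k == 0 else toy_influences(
                rng, n_scen=2, nvox=6, nb=3, weights=(0.6, 0.4)
            )
            for m, w in stream:
                acc.add(m, w)
            accs.append((acc, stream))
        return accs

    def test_identical_phases_make_modes_agree(self, rng):
        accs = self._accs(rng, identical=True)
        w = np.array([0.5, 0.5])
        pooled = combine_phase_accumulators([a for a, _ in accs], w, "pooled")
        within = combine_phase_accumulators([a for a, _ in accs], w, "within_phase")
        assert np.abs(pooled.omega["v"] - within.omega["v"]).max() < 1e-12
        assert np.abs(
            (pooled.expected_influence - within.expected_influence).toarray()
        ).max() < 1e-14

    def test_law_of_total_variance_decomposition(self, rng):
        """Omega_pooled - Omega_within = weighted covariance of phase means."""
        accs = self._accs(rng)
        w = np.array([0.7, 0.3])
        pooled = combine_phase_accumulators([a for a, _ in accs], w, "pooled")
        within = combine_phase_accumulators([a for a, _ in accs], w,
                                            "within_phase")
        means = []
        for acc, stream in accs:
            means.append(sum(wt * m.toarray() for m, wt in stream))
        grand = sum(wk * mk for wk, mk in zip(w, means))
        between = sum(
            wk * ((mk - grand).T @ (mk - grand)) for wk, mk in zip(w, means)
        )
        diff = pooled.omega["v"] - within.omega["v"]
        scale = max(np.abs(between).max(), 1e-300)
        assert np.abs(diff - between).max() <= 1e-9 * scale

    def test_expected_influence_identical_across_modes(self, rng):
        accs = self._accs(rng)
        w = np.array([0.7, 0.3])
        pooled = combine_phase_accumulators([a for a, _ in accs], w, "pooled")
        within = combine_phase_accumulators([a for a, _ in accs], w,
                                            "within_phase")
        assert np.abs(
            (pooled.expected_influence - within.expected_influence).toarray()
        ).max() < 1e-14

    def test_bad_phase_weights_raise(self, rng):
        accs = [a for a, _ in self._accs(rng)]
        with pytest.raises(ValidationError):
            combine_phase_accumulators(accs, np.array([0.7, 0.7]), "pooled")


class TestPersistence:
    def test_export_import_round_trip(self, rng, tmp_path):
        from scenariofree.io import export_model, import_model

        stream = toy_influences(rng)
        model = accumulate(iter(stream), {"v": np.array([0, 2, 3])})
        export_model(model, tmp_path / "model")
        back = import_model(tmp_path / "model")
        x = rng.uniform(size=2)
        assert back.expected_dose(x) == pytest.approx(
            model.expected_dose(x), rel=1e-12, abs=1e-300
        )
        assert back.total_variance("v", x) == pytest.approx(
            model.total_variance("v", x), rel=1e-12
        )
        assert back.n_scenarios == model.n_scenarios
        assert back.voi_sizes == model.voi_sizes

    def test_missing_files_raise_with_filename(self, tmp_path):
        from scenariofree.io import import_model

        with pytest.raises(IOError, match="manifest"):
            import_model(tmp_path / "nowhere")
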