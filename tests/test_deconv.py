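import numpy as np
import pandas as pd
import pytest

import germlayertracker as g
from germlayertracker import UnderdeterminedError, ValidationError

from conftest import make_matrix


def truth_signatures(truth):
    return [
        g.Signature(cls, cls, [g.Marker(p, o) for p, o in markers])
        for cls, markers in truth.markers.items()
    ]


def simplex_grid_oracle(R, b, step=0.01):
    """Brute-force least squares over the 2-simplex at fixed resolution."""
    best, best_f = np.inf, None
    n = int(round(1 / step))
    for i in range(n + 1):
        for j in range(n + 1 - i):
            f = np.array([i, j, n - i - j]) / n
            r = float(np.sum((R @ f - b) ** 2))
            if r < best:
                best, best_f = r, f
    return best_f, np.sqrt(best)


class TestBuildReference:
    def test_single_sample_per_class_equals_samples(self, labeled_dataset):
        matrix, labels, truth = labeled_dataset
        one_each = labels.groupby(labels).head(1)
        ref = g.build_reference(matrix[one_each.index], one_each, truth_signatures(truth))
        for cls, sample in zip(one_each.values, one_each.index):
            np.testing.assert_allclose(ref[cls], matrix.loc[ref.index, sample])

    def test_mode_shapes(self, default_panel, rng):
        probes = sorted({p for s in default_panel for p in s.probe_ids})
        m = make_matrix(rng.uniform(0, 1, (15, 10)), probes=probes)
        labels = pd.Series(
            ["PSC", "PSC", "ENDO", "ENDO", "MESO", "MESO", "ECTO", "ECTO", "ENDOMESO", "ENDOMESO"],
            index=m.columns,
        )
        full = g.build_reference(m, labels, default_panel, mode="full")
        endomeso = g.build_reference(m, labels, default_panel, mode="endomeso")
        assert full.shape == (12, 4) and list(full.columns) == ["PSC", "ENDO", "MESO", "ECTO"]
        assert endomeso.shape == (9, 3) and list(endomeso.columns) == ["PSC", "ENDOMESO", "ECTO"]

    def test_matches_groupwise_mean_oracle(self, labeled_dataset):
        matrix, labels, truth = labeled_dataset
        ref = g.build_reference(matrix, labels, truth_signatures(truth))
        for cls in ref.columns:
            expected = matrix.loc[ref.index, labels.index[labels == cls]].mean(axis=1)
            np.testing.assert_allclose(ref[cls], expected, atol=1e-12)

    def test_missing_class_errors(self, labeled_dataset):
        matrix, labels, truth = labeled_dataset
        no_ecto = labels[labels != "ECTO"]
        with pytest.raises(ValidationError, match="ECTO"):
            g.build_reference(matrix[no_ecto.index], no_ecto, truth_signatures(truth))


class TestNNLS:
    def test_identity_recovery(self):
        assert np.allclose(g.nnls_solve(np.eye(3), np.array([1.0, 0, 0])), [1, 0, 0])

    def test_exact_two_class_mixture(self, rng):
        R = rng.uniform(0, 1, (5, 2))
        b = R @ np.array([0.5, 0.5])
        np.testing.assert_allclose(g.nnls_solve(R, b), [0.5, 0.5], atol=1e-10)

    def test_missing_rows_dropped(self, rng):
        R = rng.uniform(0, 1, (6, 2))
        f = np.array([0.3, 0.7])
        b = R @ f
        b[2] = np.nan
        np.testing.assert_allclose(g.nnls_solve(R, b), f, atol=1e-10)

    def test_underdetermined_raises(self):
        R = np.ones((3, 3))
        b = np.array([np.nan, np.nan, 0.5])
        with pytest.raises(UnderdeterminedError):
            g.nnls_solve(R, b)

    def test_matches_simplex_grid_oracle(self, rng):
        """Exact simplex mixtures: active-set solution within two grid steps
        of the brute-force optimum, never with a larger residual."""
        for _ in range(5):
            R = rng.uniform(0, 1, (5, 3))
            while np.linalg.svd(R, compute_uv=False)[-1] < 0.3:
                R = rng.uniform(0, 1, (5, 3))
            f_true = rng.dirichlet(np.ones(3))
            b = R @ f_true
            coef = g.nnls_solve(R, b)
            f_grid, r_grid = simplex_grid_oracle(R, b)
            assert np.max(np.abs(coef - f_grid)) <= 0.02
            assert np.linalg.norm(R @ coef - b) <= r_grid + 1e-12
            assert np.linalg.norm(R @ coef - b) <= np.linalg.norm(b)  # beats zero vector


class TestDeconvolution:
    def test_reference_column_recovered_exactly(self, labeled_dataset):
        matrix, labels, truth = labeled_dataset
        ref = g.build_reference(matrix, labels, truth_signatures(truth))
        sample = make_matrix(ref[["ENDO"]].to_numpy(), probes=list(ref.index), samples=["E"])
        out = g.deconvolve(sample, ref)
        assert out.loc["E", "frac.ENDO"] == pytest.approx(1.0, abs=1e-9)
        assert out.loc["E", "residual"] == pytest.approx(0.0, abs=1e-9)
        assert out.loc["E", "predicted_class"] == "ENDO"

    def test_mixture_parameter_recovery(self, labeled_dataset, rng):
        matrix, labels, truth = labeled_dataset
        ref = g.build_reference(matrix, labels, truth_signatures(truth))
        fractions = g.sample_simplex(100, 4, rng)
        mix, mix_truth = g.simulate_mixtures(
            truth, fractions, noise_sd=0.03, seed=11, probes=list(ref.index)
        )
        est = g.Deconvolution(mix, ref).fit().fractions[mix_truth.fractions.columns]
        err = np.abs(est.to_numpy() - mix_truth.fractions.to_numpy())
        assert err.mean() < 0.05

    def test_batch_row_count_and_columns(self, labeled_dataset):
        matrix, labels, truth = labeled_dataset
        ref = g.build_reference(matrix, labels, truth_signatures(truth))
        out = g.deconvolve(matrix, ref)
        assert out.shape[0] == matrix.shape[1]
        for cls in ref.columns:
            assert f"raw.{cls}" in out.columns and f"frac.{cls}" in out.columns
        fr = out.filter(like="frac.").to_numpy()
        np.testing.assert_allclose(fr.sum(axis=1), 1.0, atol=1e-9)
        assert (fr >= -1e-12).all()

    def test_duplicated_marker_row_preserves_exact_solution(self, rng):
        R = rng.uniform(0, 1, (6, 3))
        f = np.array([0.2, 0.3, 0.5])
        b = R @ f
        R2, b2 = np.vstack([R, R[0]]), np.append(b, b[0])
        np.testing.assert_allclose(g.nnls_solve(R2, b2), g.nnls_solve(R, b), atol=1e-9)

    def test_degenerate_all_zero_sample_flagged_uniform(self, rng):
        # reference strictly positive, observation zero -> NNLS coefficients all zero
        ref = make_matrix(rng.uniform(0.5, 1, (4, 2)), samples=["A", "B"])
        sample = make_matrix(np.zeros((4, 1)), probes=list(ref.index), samples=["Z"])
        out = g.deconvolve(sample, ref)
        assert out.loc["Z", "frac.A"] == pytest.approx(0.5)
        assert "degenerate" in out.loc["Z", "flags"]

    def test_underdetermined_sample_not_fatal_for_batch(self, rng):
        ref = make_matrix(rng.uniform(0, 1, (4, 3)), samples=["A", "B", "C"])
        values = rng.uniform(0, 1, (4, 2))
        values[:3, 0] = np.nan  # one usable marker for 3 classes
        batch = make_matrix(values, probes=list(ref.index), samples=["bad", "good"])
        out = g.deconvolve(batch, ref)
        assert out.loc["bad", "flags"] == "underdetermined"
        assert np.isnan(out.loc["bad", "frac.A"])
        assert np.isfinite(out.loc["good", "frac.A"])

    def test_noise_degrades_error_monotonically_in_trend(self, labeled_dataset):
        matrix, labels, truth = labeled_dataset
        ref = g.build_reference(matrix, labels, truth_signatures(truth))
        medians = []
        for sd in (0.01, 0.10):
            errs = []
            for seed in range(5):
                fr = g.sample_simplex(20, 4, np.random.default_rng(100 + seed))
                mix, t = g.simulate_mixtures(truth, fr, noise_sd=sd, seed=seed, probes=list(ref.index))
                est = g.Deconvolution(mix, ref).fit().fractions[t.fractions.columns]
                errs.append(np.median(np.abs(est.to_numpy() - t.fractions.to_numpy())))
            medians.append(np.median(errs))
        assert medians[1] >= medians[0]


class TestPyroAdjustment:
    @pytest.fixture()
    def reference(self, rng):
        return make_matrix(rng.uniform(0, 1, (4, 2)), samples=["PSC", "ENDO"])

    def test_empty_pyro_set_identity(self, reference):
        empty = pd.DataFrame(index=pd.Index([], name="probe_id"), columns=[], dtype=float)
        out = g.adjust_reference_with_pyro(reference, empty, pd.Series(dtype=object))
        pd.testing.assert_frame_equal(out, reference)

    def test_single_measurement_changes_one_cell(self, reference):
        probe = reference.index[1]
        pyro = make_matrix([[0.42]], probes=[probe], samples=["P1"])
        out = g.adjust_reference_with_pyro(reference, pyro, {"P1": "ENDO"})
        assert out.loc[probe, "ENDO"] == pytest.approx(0.42)
        changed = (out != reference).to_numpy().sum()
        assert changed == 1
        assert out.attrs["pyro_adjusted_cells"] == [(probe, "ENDO")]

    def test_full_coverage_equals_pyro_class_means(self, reference, rng):
        pyro = make_matrix(
            rng.uniform(0, 1, (4, 6)), probes=list(reference.index),
            samples=[f"P{i}" for i in range(6)],
        )
        labels = {f"P{i}": ("PSC" if i < 3 else "ENDO") for i in range(6)}
        out = g.adjust_reference_with_pyro(reference, pyro, labels)
        np.testing.assert_allclose(out["PSC"], pyro.iloc[:, :3].mean(axis=1), atol=1e-12)
        np.testing.assert_allclose(out["ENDO"], pyro.iloc[:, 3:].mean(axis=1), atol=1e-12)
        assert out.attrs["provenance"].endswith("pyrosequencing")

    def test_unknown_probe_and_class_warn_and_ignored(self, reference):
        pyro = make_matrix([[0.5], [0.6]], probes=["cgUnknown", reference.index[0]], samples=["P1"])
        with pytest.warns(UserWarning, match="cgUnknown"):
            out = g.adjust_reference_with_pyro(reference, pyro, {"P1": "PSC"})
        assert out.loc[reference.index[0], "PSC"] == pytest.approx(0.6)
        with pytest.warns(UserWarning, match="classes"):
            out2 = g.adjust_reference_with_pyro(reference, pyro.iloc[1:], {"P1": "MESO"})
        pd.testing.assert_frame_equal(out2, reference)
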