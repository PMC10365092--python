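"""Preprocessing: file IO, shell handling, SH fitting, clamping,
gradient reordering and truncation."""

import nibabel as nib
import numpy as np
import pytest

import tractuq as tq
from tractuq import shbasis
from tractuq.core import DWIVolume, GradientTable
from tractuq.errors import (
    ConditioningError,
    DataError,
    FormatError,
    SelectionError,
)
from tractuq.preprocess import prefix_energy
from tractuq.rotation import fibonacci_sphere


def _write_dwi(tmp_path, data, bvals, bvecs):
    img = tmp_path / "dwi.nii.gz"
    nib.save(nib.Nifti1Image(data.astype(np.float32), np.eye(4)), str(img))
    bval = tmp_path / "dwi.bval"
    bvec = tmp_path / "dwi.bvec"
    np.savetxt(bval, np.asarray(bvals)[None], fmt="%g")
    np.savetxt(bvec, np.asarray(bvecs).T, fmt="%.8f")
    return img, bval, bvec


class TestReadDWI:
    def test_consistent_files_roundtrip(self, tmp_path, rng):
        data = rng.random((4, 4, 4, 10))
        bvals = [0.0] + [1000.0] * 9
        bvecs = np.vstack([[0, 0, 0], fibonacci_sphere(9)])
        paths = _write_dwi(tmp_path, data, bvals, bvecs)
        dwi = tq.read_dwi(*paths)
        assert dwi.gradients.n == 10
        assert np.allclose(dwi.data, data, atol=1e-6)
        # b0 frame keeps its zero direction
        assert np.all(dwi.gradients.directions[0] == 0)
        norms = np.linalg.norm(dwi.gradients.directions[1:], axis=1)
        assert np.allclose(norms, 1.0, atol=1e-6)

    def test_count_mismatch_names_file(self, tmp_path, rng):
        data = rng.random((4, 4, 4, 10))
        bvecs = np.vstack([[0, 0, 0], fibonacci_sphere(9)])
        img, bval, bvec = _write_dwi(tmp_path, data, [0.0] + [1000.0] * 8, bvecs[:9])
        with pytest.raises(FormatError, match="bval"):
            tq.read_dwi(img, bval, bvec)


def _dwi_from(bvals, data=None, rng=None):
    bvals = np.asarray(bvals, dtype=float)
    g = len(bvals)
    dirs = np.zeros((g, 3))
    dw = bvals > 50
    dirs[dw] = fibonacci_sphere(int(dw.sum()))
    if data is None:
        data = (rng or np.random.default_rng(0)).random((3, 3, 3, g)) + 0.5
    return DWIVolume(data, np.eye(4), GradientTable(dirs, bvals))


class TestExtractShell:
    def test_exact_partition(self):
        dwi = _dwi_from([0, 1000, 2000, 2000])
        shell, b0s = tq.extract_shell(dwi, 2000, 100)
        assert np.all(shell.gradients.bvalues == 2000)
        assert shell.gradients.n == 2 and b0s.gradients.n == 1
        assert np.array_equal(shell.data, dwi.data[..., [2, 3]])

    def test_tolerance_window(self):
        dwi = _dwi_from([0, 995, 1005])
        shell, _ = tq.extract_shell(dwi, 1000, 10)
        assert shell.gradients.n == 2

    def test_empty_shell_reports_available(self):
        dwi = _dwi_from([0, 3000])
        with pytest.raises(SelectionError, match="3000"):
            tq.extract_shell(dwi, 2000, 100)


class TestNormalizeByB0:
    def test_division_and_degenerate_voxel(self):
        shell = _dwi_from([2000, 2000], data=np.full((2, 2, 2, 2), 4.0))
        b0_data = np.full((2, 2, 2, 1), 2.0)
        b0_data[0, 0, 0, 0] = 0.0
        b0s = _dwi_from([0], data=b0_data)
        out = tq.normalize_by_b0(shell, b0s)
        assert out.data[1, 1, 1, 0] == pytest.approx(2.0)
        assert out.data[0, 0, 0, 0] == 0.0  # zero-b0 voxel zeroed, no error

    def test_identity_ratio(self):
        data = np.full((2, 2, 2, 3), 7.0)
        shell = _dwi_from([2000] * 3, data=data)
        b0s = _dwi_from([0], data=data[..., :1])
        assert np.allclose(tq.normalize_by_b0(shell, b0s).data, 1.0)

    def test_all_zero_b0_raises(self):
        shell = _dwi_from([2000, 2000], data=np.ones((2, 2, 2, 2)))
        b0s = _dwi_from([0], data=np.zeros((2, 2, 2, 1)))
        with pytest.raises(DataError):
            tq.normalize_by_b0(shell, b0s)


class TestFitSH:
    def test_constant_signal_is_pure_c00(self):
        dirs = fibonacci_sphere(20)
        dwi = _dwi_from([2000] * 20, data=np.full((2, 2, 2, 20), 3.0))
        sh = tq.fit_sh(dwi, lmax=4)
        assert sh.n_coeffs == 15
        assert np.allclose(sh.coeffs[..., 0], 2 * np.sqrt(np.pi) * 3.0, atol=1e-8)
        assert np.max(np.abs(sh.coeffs[..., 1:])) < 1e-8

    def test_roundtrip_recovers_coefficients(self, rng):
        # oracle: synthesize signal from known coefficients, refit
        dirs = fibonacci_sphere(60)
        c = rng.normal(size=(2, 2, 2, 15))
        signal = shbasis.synthesize(c, dirs, 4)
        dwi = DWIVolume(
            signal - signal.min() + 1.0 if False else signal,
            np.eye(4),
            GradientTable(dirs, np.full(60, 2000.0)),
        )
        sh = tq.fit_sh(dwi, lmax=4)
        assert np.max(np.abs(sh.coeffs - c)) < 1e-6

    def test_underdetermined_raises(self):
        dwi = _dwi_from([2000] * 10)
        with pytest.raises(ConditioningError):
            tq.fit_sh(dwi, lmax=4)


class TestClampOutliers:
    def _sh(self, values):
        coeffs = np.zeros((len(values), 1, 1, 15))
        coeffs[:, 0, 0, :] = np.asarray(values)[:, None]
        return tq.SHVolume(coeffs, 4, np.eye(4))

    def test_percentile_bounds_match_bruteforce(self):
        values = np.arange(1.0, 101.0)
        out = tq.clamp_outliers(self._sh(values), 5, 99)
        p5 = np.percentile(values, 5)
        p99 = np.percentile(values, 99)
        assert out.coeffs[..., 0].min() == pytest.approx(p5)
        assert out.coeffs[..., 0].max() == pytest.approx(p99)

    def test_constant_channel_unchanged(self):
        sh = self._sh(np.full(20, 3.3))
        out = tq.clamp_outliers(sh, 5, 99)
        assert np.array_equal(out.coeffs, sh.coeffs)

    def test_full_range_is_identity(self):
        sh = self._sh(np.arange(50.0))
        out = tq.clamp_outliers(sh, 0, 100)
        assert np.array_equal(out.coeffs, sh.coeffs)

    def test_near_idempotent(self, rng):
        # re-clamping moves bounds by at most the local order-statistic gap
        sh = self._sh(rng.normal(size=200))
        once = tq.clamp_outliers(sh, 5, 99)
        twice = tq.clamp_outliers(once, 5, 99)
        span = once.coeffs.max() - once.coeffs.min()
        assert np.max(np.abs(twice.coeffs - once.coeffs)) < 0.02 * span

    def test_empty_mask_raises(self):
        sh = self._sh(np.arange(10.0))
        mask = tq.BrainMask(np.zeros(sh.spatial_shape, dtype=bool))
        with pytest.raises(DataError):
            tq.clamp_outliers(sh, 5, 99, mask)


class TestReorderGradients:
    def _gtab(self, dirs, n_b0=1):
        dirs = np.asarray(dirs, dtype=float)
        all_dirs = np.vstack([np.zeros((n_b0, 3)), dirs])
        bvals = np.concatenate([np.zeros(n_b0), np.full(len(dirs), 1000.0)])
        return GradientTable(all_dirs, bvals)

    def test_output_is_permutation(self):
        gtab = self._gtab(fibonacci_sphere(12), n_b0=2)
        out, perm = tq.reorder_gradients(gtab)
        assert sorted(perm.tolist()) == list(range(14))
        assert np.allclose(np.sort(out.bvalues), np.sort(gtab.bvalues))

    def test_greedy_prefixes_beat_identity_order(self):
        # icosahedral half-sphere directions, shuffled adversarially
        phi = (1 + np.sqrt(5)) / 2
        ico = np.array(
            [[0, 1, phi], [0, -1, phi], [1, phi, 0], [-1, phi, 0], [phi, 0, 1],
             [-phi, 0, 1]],
            dtype=float,
        )
        ico /= np.linalg.norm(ico, axis=1, keepdims=True)
        # adversarial order: two nearly-parallel first
        order = [0, 1, 2, 3, 4, 5]
        gtab = self._gtab(ico[order], n_b0=0)
        out, _ = tq.reorder_gradients(gtab)
        for k in range(2, 7):
            assert prefix_energy(out.directions, k) <= prefix_energy(
                gtab.directions, k
            ) + 1e-9

    def test_duplicate_directions_warn(self):
        d = fibonacci_sphere(4)
        dirs = np.vstack([d, -d[0]])  # antipodal duplicate
        gtab = self._gtab(dirs, n_b0=0)
        with pytest.warns(UserWarning, match="duplicate"):
            tq.reorder_gradients(gtab)


class TestTruncateGradients:
    def test_truncation_to_45(self, rng):
        bvals = np.concatenate([np.zeros(10), np.full(90, 1000.0)])
        dirs = np.vstack([np.zeros((10, 3)), fibonacci_sphere(90)])
        data = rng.random((2, 2, 2, 100))
        dwi = DWIVolume(data, np.eye(4), GradientTable(dirs, bvals))
        out = tq.truncate_gradients(dwi, 45)
        assert int((~out.gradients.b0_mask).sum()) == 45
        assert out.data.shape[3] == out.gradients.n

    def test_keep_all_is_identity(self):
        dwi = _dwi_from([0, 1000, 1000, 1000])
        out = tq.truncate_gradients(dwi, 3)
        assert np.array_equal(out.data, dwi.data)

    @pytest.mark.parametrize("n", [0, 99])
    def test_degenerate_counts_raise(self, n):
        dwi = _dwi_from([0, 1000, 1000, 1000])
        with pytest.raises(SelectionError):
            tq.truncate_gradients(dwi, n)
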