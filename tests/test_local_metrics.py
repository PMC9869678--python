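"""Brute-force oracles for every local metric, plus analytic limits."""

import numpy as np
import pytest
from scipy.stats import rankdata

from restpipe.core import BoldSeries, TissueMask
from restpipe.local_metrics import (
    DEFAULT_STANDARDIZATION,
    compute_local_metrics,
    degree_centrality,
    falff,
    fcs,
    reho,
    standardize_map,
    symmetrize_mask,
    vmhc,
)


def _bold(data, tr=2.0):
    return BoldSeries(np.asarray(data, dtype=float), tr=tr, affine=np.eye(4))


def _sinusoid_bold(freq, T=170, tr=2.0, shape=(2, 2, 2)):
    t = np.arange(T) * tr
    return _bold(np.tile(np.sin(2 * np.pi * freq * t), shape + (1,)), tr)


# ---------------------------------------------------------------- oracles


def falff_oracle(series, tr, low=(0.01, 0.08), full=(0.0, 0.25)):
    """Direct FFT amplitude-ratio computation for one series."""
    T = len(series)
    amp = np.abs(np.fft.rfft(series))
    f = np.fft.rfftfreq(T, tr)
    eps = 1e-12
    num = amp[(f >= low[0] - eps) & (f <= low[1] + eps) & (f > 0)].sum()
    den = amp[(f > full[0]) & (f <= full[1] + eps)].sum()
    return 0.0 if den == 0 else num / den


def kcc_oracle(series_matrix):
    """Kendall concordance of m series (rows) over n time points."""
    m, n = series_matrix.shape
    ranks = np.array([rankdata(s) for s in series_matrix])
    R = ranks.sum(axis=0)  # cross-series rank sum per time point
    Rbar = R.mean()
    S = ((R - Rbar) ** 2).sum()
    return 12.0 * S / (m**2 * (n**3 - n))


def dc_oracle(series, r_thr=0.25):
    n = series.shape[0]
    out = np.zeros(n)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            r = np.corrcoef(series[i], series[j])[0, 1]
            if r > r_thr:
                out[i] += r
    return out

def fcs_oracle(series, r0=0.2):
    n = series.shape[0]
    out = np.zeros(n)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            r = np.corrcoef(series[i], series[j])[0, 1]
            if r > r0:
                out[i] += np.arctanh(r)
    return out / (n - 1)


# ----------------------------------------------------------------- fALFF


class TestFalff:
    def test_pure_low_band_sinusoid(self):
        m = falff(_sinusoid_bold(0.05), TissueMask(np.ones((2, 2, 2), bool)))
        assert m.data[0, 0, 0] >= 0.95

    def test_pure_high_band_sinusoid(self):
        m = falff(_sinusoid_bold(0.15), TissueMask(np.ones((2, 2, 2), bool)))
        assert m.data[0, 0, 0] <= 0.05

    def test_white_noise_bin_count_ratio(self, rng):
        T = 170
        bold = _bold(rng.standard_normal((10, 10, 10, T)))
        m = falff(bold, TissueMask(np.ones((10, 10, 10), bool)))
        f = np.fft.rfftfreq(T, 2.0)
        expected = (
            ((f >= 0.01) & (f <= 0.08)).sum() / ((f > 0) & (f <= 0.25 + 1e-9)).sum()
        )
        assert m.data.mean() == pytest.approx(expected, abs=0.01)

    def test_matches_oracle(self, rng):
        data = rng.standard_normal((4, 4, 3, 64))
        mask = TissueMask(np.ones((4, 4, 3), bool))
        m = falff(_bold(data), mask)
        for idx in [(0, 0, 0), (1, 2, 1), (3, 3, 2)]:
            assert m.data[idx] == pytest.approx(
                falff_oracle(data[idx], 2.0), abs=1e-12
            )

    def test_all_zero_series_warns(self):
        data = np.zeros((2, 2, 2, 64))
        with pytest.warns(UserWarning, match="all-zero"):
            m = falff(_bold(data), TissueMask(np.ones((2, 2, 2), bool)))
        assert np.all(m.data == 0)

    def test_range(self, rng):
        m = falff(
            _bold(rng.standard_normal((5, 5, 4, 64))),
            TissueMask(np.ones((5, 5, 4), bool)),
        )
        assert m.data.min() >= 0 and m.data.max() <= 1


# ------------------------------------------------------------------ ReHo


class TestReho:
    def test_identical_series_full_concordance(self, rng):
        sig = rng.standard_normal(40)
        b = _bold(np.tile(sig, (3, 3, 3, 1)))
        w = reho(b, TissueMask(np.ones((3, 3, 3), bool)))
        assert w.data[1, 1, 1] == pytest.approx(1.0, abs=1e-12)

    def test_monotone_transform_invariance(self, rng):
        sig = rng.standard_normal(40)
        data = np.tile(sig, (3, 3, 3, 1)).copy()
        data[0, 0, 0] = sig**3 + 2.0  # strictly monotone transform
        data[2, 2, 2] = np.exp(sig)
        w = reho(_bold(data), TissueMask(np.ones((3, 3, 3), bool)))
        assert w.data[1, 1, 1] == pytest.approx(1.0, abs=1e-12)

    def test_matches_oracle_center_voxel(self, rng):
        data = rng.standard_normal((3, 3, 3, 20))
        w = reho(_bold(data), TissueMask(np.ones((3, 3, 3), bool)))
        assert w.data[1, 1, 1] == pytest.approx(
            kcc_oracle(data.reshape(27, 20)), abs=1e-12
        )

    def test_matches_oracle_edge_voxel(self, rng):
        """Corner voxel uses its 8-voxel in-mask neighborhood with adjusted m."""
        data = rng.standard_normal((3, 3, 3, 20))
        w = reho(_bold(data), TissueMask(np.ones((3, 3, 3), bool)))
        corner = data[:2, :2, :2].reshape(8, 20)
        assert w.data[0, 0, 0] == pytest.approx(kcc_oracle(corner), abs=1e-12)

    def test_range_and_constant_series(self, rng):
        data = rng.standard_normal((4, 4, 3, 25))
        data[0, 0, 0, :] = 5.0  # constant voxel
        with pytest.warns(UserWarning, match="constant"):
            w = reho(_bold(data), TissueMask(np.ones((4, 4, 3), bool)))
        assert w.data[0, 0, 0] == 0.0
        assert np.all(w.data >= 0) and np.all(w.data <= 1)


# -------------------------------------------------------------------- DC


class TestDegreeCentrality:
    def _corr_series(self, rng, rs, T=4000):
        """Build series with roughly prescribed pairwise correlations to a base."""
        base = rng.standard_normal(T)
        out = [base]
        for r in rs:
            out.append(r * base + np.sqrt(1 - r**2) * rng.standard_normal(T))
        return np.array(out)

    def test_three_voxel_hand_sum(self):
        """r12=0.9, r13=0.3, r23=0.1 -> DC = (1.2, 0.9, 0.3) with threshold 0.25."""
        # exact construction: demeaned orthonormal basis x Cholesky factor
        G = np.array([[1.0, 0.9, 0.3], [0.9, 1.0, 0.1], [0.3, 0.1, 1.0]])
        L = np.linalg.cholesky(G)
        T = 12
        basis = np.linalg.qr(np.random.default_rng(0).standard_normal((T, 3)))[0].T
        basis -= basis.mean(axis=1, keepdims=True)
        # re-orthonormalize after demeaning
        basis = np.linalg.qr(basis.T)[0].T
        series = L @ basis
        data = series.reshape(3, 1, 1, T)
        dc = degree_centrality(
            _bold(data), TissueMask(np.ones((3, 1, 1), bool)), r_threshold=0.25
        )
        assert np.allclose(dc.data.ravel(), [1.2, 0.9, 0.3], atol=1e-8)

    def test_uncorrelated_voxel_zero(self, rng):
        series = self._corr_series(rng, [0.05, 0.1])
        # voxel 0 correlates weakly with all others
        data = series[[1, 0, 2]].reshape(3, 1, 1, -1)
        dc = degree_centrality(_bold(data), TissueMask(np.ones((3, 1, 1), bool)))
        # middle voxel (base) may or may not pass; first voxel (r~0.05) must not
        assert dc.data[0, 0, 0] <= dc.data[1, 0, 0]

    def test_matches_brute_force_200_voxels(self, rng):
        data = rng.standard_normal((10, 10, 2, 30))
        mask = TissueMask(np.ones((10, 10, 2), bool))
        dc = degree_centrality(_bold(data), mask)
        oracle = dc_oracle(data.reshape(200, 30))
        assert np.allclose(dc.data.ravel(), oracle, atol=1e-10)

    def test_zero_variance_voxel_excluded(self, rng):
        data = rng.standard_normal((3, 3, 1, 30))
        data[0, 0, 0] = 1.0
        dc = degree_centrality(_bold(data), TissueMask(np.ones((3, 3, 1), bool)))
        assert dc.data[0, 0, 0] == 0.0

    def test_binary_mode_counts(self, rng):
        data = rng.standard_normal((4, 4, 2, 30))
        mask = TissueMask(np.ones((4, 4, 2), bool))
        dcb = degree_centrality(_bold(data), mask, weighted=False)
        series = data.reshape(32, 30)
        counts = np.zeros(32)
        for i in range(32):
            for j in range(32):
                if i != j and np.corrcoef(series[i], series[j])[0, 1] > 0.25:
                    counts[i] += 1
        assert np.allclose(dcb.data.ravel(), counts, atol=1e-10)


# ------------------------------------------------------------------ VMHC


class TestVmhc:
    def test_duplicated_hemispheres_symmetric(self, rng):
        half = rng.standard_normal((3, 6, 4, 30))
        data = np.concatenate([half, half[::-1]], axis=0)
        data += 0.5 * rng.standard_normal(data.shape)  # independent noise
        m = vmhc(_bold(data), TissueMask(np.ones((6, 6, 4), bool)))
        assert np.max(np.abs(m.data - m.data[::-1])) == 0.0

    def test_independent_hemispheres_near_zero(self, rng):
        T = 100
        data = rng.standard_normal((6, 6, 4, T))
        m = vmhc(_bold(data), TissueMask(np.ones((6, 6, 4), bool)))
        se = 1.0 / np.sqrt(T - 3)
        assert abs(np.arctanh(m.data).mean()) <= 3 * se / np.sqrt(m.data.size / 2)

    def test_identical_mirrored_series_clipped(self, rng):
        half = rng.standard_normal((3, 4, 2, 30))
        data = np.concatenate([half, half[::-1]], axis=0)
        m = vmhc(_bold(data), TissueMask(np.ones((6, 4, 2), bool)))
        mask = TissueMask(np.ones((6, 4, 2), bool))
        with pytest.warns(UserWarning, match="clipped"):
            z = standardize_map(m, "fisher_z", mask)
        assert np.all(np.isfinite(z.data))
        assert z.data.max() == pytest.approx(np.arctanh(1 - 1e-7), rel=1e-3)

    def test_mask_symmetrization(self):
        mask = np.zeros((6, 4, 2), dtype=bool)
        mask[0, :, :] = True  # no mirror partner for most
        mask[5, 0, 0] = True  # mirror of (0, 0, 0)
        sym = symmetrize_mask(TissueMask(mask))
        assert sym.n_voxels == 2

    def test_matches_voxel_loop_oracle(self, rng):
        data = rng.standard_normal((4, 3, 3, 25))
        mask = TissueMask(np.ones((4, 3, 3), bool))
        m = vmhc(_bold(data), mask)
        for i in range(4):
            for j in range(3):
                for k in range(3):
                    r = np.corrcoef(data[i, j, k], data[3 - i, j, k])[0, 1]
                    assert m.data[i, j, k] == pytest.approx(r, abs=1e-10)


# ------------------------------------------------------------------- FCS


class TestFcs:
    def test_no_suprathreshold_zero_map(self, rng):
        # two exactly anti-correlated voxels: r = -1 < r0
        T = 20
        a = rng.standard_normal(T)
        data = np.stack([a, -a]).reshape(2, 1, 1, T)
        m = fcs(_bold(data), TissueMask(np.ones((2, 1, 1), bool)))
        assert np.all(m.data == 0)

    def test_three_voxel_hand_values(self):
        G = np.array([[1.0, 0.5, 0.1], [0.5, 1.0, 0.3], [0.1, 0.3, 1.0]])
        L = np.linalg.cholesky(G)
        T = 12
        basis = np.linalg.qr(np.random.default_rng(1).standard_normal((T, 3)))[0].T
        basis -= basis.mean(axis=1, keepdims=True)
        basis = np.linalg.qr(basis.T)[0].T
        series = L @ basis
        m = fcs(
            _bold(series.reshape(3, 1, 1, T)),
            TissueMask(np.ones((3, 1, 1), bool)),
            r0=0.2,
        )
        expected = [
            np.arctanh(0.5) / 2,
            (np.arctanh(0.5) + np.arctanh(0.3)) / 2,
            np.arctanh(0.3) / 2,
        ]
        assert np.allclose(m.data.ravel(), expected, atol=1e-8)

    def test_matches_brute_force_200_voxels(self, rng):
        data = rng.standard_normal((10, 10, 2, 30))
        mask = TissueMask(np.ones((10, 10, 2), bool))
        m = fcs(_bold(data), mask)
        assert np.allclose(m.data.ravel(), fcs_oracle(data.reshape(200, 30)), atol=1e-10)


# -------------------------------------------------------- standardization


class TestStandardizeMap:
    def test_fisher_z_zero(self):
        from restpipe.core import MetricMap

        mask = TissueMask(np.ones((2, 2, 2), bool))
        m = MetricMap(np.zeros((2, 2, 2)), metric="VMHC")
        assert np.all(standardize_map(m, "fisher_z", mask).data == 0)

    def test_fisher_z_half(self):
        from restpipe.core import MetricMap

        mask = TissueMask(np.ones((2, 2, 2), bool))
        m = MetricMap(np.full((2, 2, 2), 0.5), metric="VMHC")
        z = standardize_map(m, "fisher_z", mask)
        assert z.data[0, 0, 0] == pytest.approx(0.5493, abs=1e-4)

    def test_zscore_normalization(self, rng):
        from restpipe.core import MetricMap

        mask = TissueMask(np.ones((5, 5, 4), bool))
        m = MetricMap(rng.random((5, 5, 4)), metric="fALFF")
        z = standardize_map(m, "zscore", mask)
        assert z.data.mean() == pytest.approx(0.0, abs=1e-10)
        assert z.data.std() == pytest.approx(1.0, abs=1e-10)

    def test_zero_sd_errors(self):
        from restpipe.core import MetricMap

        mask = TissueMask(np.ones((2, 2, 2), bool))
        m = MetricMap(np.full((2, 2, 2), 0.3), metric="fALFF")
        with pytest.raises(ValueError, match="variance"):
            standardize_map(m, "zscore", mask)


class TestSmoothingOrder:
    def test_orders_recorded(self, rng):
        data = rng.standard_normal((6, 6, 4, 64))
        bold = _bold(data)
        mask = TissueMask(np.ones((6, 6, 4), bool))
        maps = compute_local_metrics(bold, bold, mask, (3.0, 3.0, 3.0), fwhm_mm=6.0)
        assert set(maps) == {"fALFF", "ReHo", "DC", "VMHC", "FCS"}
        assert "smooth_before" in maps["fALFF"].processing_log
        for name in ("ReHo", "DC", "VMHC", "FCS"):
            log = maps[name].processing_log
            assert log.index("smooth_after") > log.index(
                f"standardize({DEFAULT_STANDARDIZATION[name]})"
            )
        for m in maps.values():
            assert m.smoothed
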