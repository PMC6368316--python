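import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from nodtex.errors import NoPairsError, UndefinedMomentError
from nodtex.features_intensity import (
    OFFSETS_13,
    GLCMMatrix,
    first_order,
    glcm,
    glcm_features,
    quantize,
)

from .conftest import make_segment


class TestFirstOrder:
    def test_constant_values_have_undefined_skewness(self):
        seg = make_segment(np.zeros((1, 1, 3)))
        with pytest.raises(UndefinedMomentError):
            first_order(seg)

    def test_hand_computed_three_values(self):
        """{-100, 0, 100}: mean 0, sample SD 100, skew 0, excess kurtosis -1.5."""
        seg = make_segment(np.array([[[-100.0, 0.0, 100.0]]]))
        fo = first_order(seg)
        assert fo.mean_attenuation == pytest.approx(0.0)
        assert fo.attenuation_sd == pytest.approx(100.0)
        assert fo.attenuation_variance == pytest.approx(10_000.0)
        assert fo.skewness == pytest.approx(0.0, abs=1e-12)
        assert fo.kurtosis == pytest.approx(-1.5)

    def test_variance_is_sd_squared(self, rng):
        seg = make_segment(rng.normal(size=(4, 5, 6)) * 100)
        fo = first_order(seg)
        assert fo.attenuation_variance == pytest.approx(fo.attenuation_sd**2, rel=1e-10)

    def test_matches_scipy_oracle(self, rng):
        """Independent route: numpy/scipy biased-moment implementations."""
        x = rng.normal(-100, 80, size=(3, 4, 5))
        fo = first_order(make_segment(x))
        flat = x.ravel()
        assert fo.mean_attenuation == pytest.approx(flat.mean(), rel=1e-12)
        assert fo.attenuation_sd == pytest.approx(flat.std(ddof=1), rel=1e-12)
        assert fo.skewness == pytest.approx(stats.skew(flat, bias=True), rel=1e-10)
        assert fo.kurtosis == pytest.approx(stats.kurtosis(flat, bias=True), rel=1e-10)

    def test_large_sample_recovers_generator_mean(self, rng):
        """N(-116.5, 91.8) draws: sample mean within 3 HU at n=1e4."""
        x = rng.normal(-116.5, 91.8, size=(22, 22, 22))
        fo = first_order(make_segment(x))
        assert fo.mean_attenuation == pytest.approx(-116.5, abs=3.0)


class TestQuantize:
    def test_unit_bins_are_hu_offsets(self):
        seg = make_segment(np.array([[[-500.0, -499.0, 0.0]]]))
        q = quantize(seg, 1.0)
        got = sorted(q.levels[q.levels >= 0])
        assert got == [0, 1, 500]

    def test_bin_boundaries_at_floor_multiples(self):
        seg = make_segment(np.array([[[-500.0, -476.0, -475.0]]]))
        q = quantize(seg, 25.0)
        assert sorted(q.levels[q.levels >= 0]) == [0, 0, 1]

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(
        hu=st.lists(st.floats(-1000, 2000, allow_nan=False), min_size=2, max_size=30),
        bin_width=st.floats(0.1, 100.0),
    )
    def test_reconstruction_bounded_by_half_bin(self, hu, bin_width):
        """Property: bin centers reconstruct HU to within half a bin width."""
        seg = make_segment(np.array(hu, dtype=float).reshape(1, 1, -1))
        q = quantize(seg, bin_width)
        centers = q.bin_center(q.levels[tuple(seg.coords.T)])
        assert np.abs(centers - seg.hu).max() <= bin_width / 2 + 1e-6 * bin_width

    def test_bin_center_reconstruction(self, rng):
        seg = make_segment(rng.uniform(-500, 500, size=(5, 5, 5)))
        for bw in (1.0, 10.0, 37.5):
            q = quantize(seg, bw)
            centers = q.bin_center(q.levels[tuple(seg.coords.T)])
            assert np.abs(centers - seg.hu).max() <= bw / 2 + 1e-9


def _brute_glcm(levels, offsets, symmetric):
    """Exhaustive pair enumeration oracle."""
    counts = {}
    nz, ny, nx = levels.shape
    for off in offsets:
        for z in range(nz):
            for y in range(ny):
                for x in range(nx):
                    z2, y2, x2 = z + off[0], y + off[1], x + off[2]
                    if not (0 <= z2 < nz and 0 <= y2 < ny and 0 <= x2 < nx):
                        continue
                    a, b = levels[z, y, x], levels[z2, y2, x2]
                    if a < 0 or b < 0:
                        continue
                    counts[(a, b)] = counts.get((a, b), 0) + 1
                    if symmetric:
                        counts[(b, a)] = counts.get((b, a), 0) + 1
    total = sum(counts.values())
    return {k: v / total for k, v in counts.items()}


class TestGLCM:
    def test_constant_segment_single_cell(self):
        seg = make_segment(np.full((1, 2, 2), 40.0))
        m = glcm(quantize(seg), offsets=((0, 0, 1),))
        assert len(m.p) == 1
        assert m.p[0] == pytest.approx(1.0)
        assert m.i[0] == m.j[0] == 0

    def test_alternating_line(self):
        """[0,1,0,1] with offset (0,0,1), symmetric: off-diagonal halves."""
        seg = make_segment(np.array([[[0.0, 1.0, 0.0, 1.0]]]))
        m = glcm(quantize(seg), offsets=((0, 0, 1),), symmetric=True)
        dense = m.to_dense()
        assert dense[0, 1] == pytest.approx(0.5)
        assert dense[1, 0] == pytest.approx(0.5)
        assert dense[0, 0] == dense[1, 1] == 0.0

    def test_single_voxel_has_no_pairs(self):
        seg = make_segment(np.array([[[7.0]]]))
        with pytest.raises(NoPairsError):
            glcm(quantize(seg))

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(data=st.data())
    def test_normalization_property(self, data):
        """Property: GLCM entries are non-negative and sum to one."""
        shape = data.draw(
            st.tuples(*(st.integers(1, 4),) * 3).filter(lambda s: np.prod(s) >= 2)
        )
        n = int(np.prod(shape))
        vals = data.draw(st.lists(st.integers(0, 6), min_size=n, max_size=n))
        seg = make_segment(np.array(vals, dtype=float).reshape(shape))
        m = glcm(quantize(seg))
        assert (m.p >= 0).all()
        assert m.p.sum() == pytest.approx(1.0, abs=1e-9)

    @pytest.mark.parametrize("symmetric", [True, False])
    def test_matches_brute_force(self, rng, symmetric):
        hu = np.round(rng.uniform(0, 5, size=(4, 4, 4)))
        mask = rng.random((4, 4, 4)) < 0.8
        mask[0, 0, 0] = mask[0, 0, 1] = True
        seg = make_segment(hu, mask=mask)
        q = quantize(seg)
        m = glcm(q, OFFSETS_13, symmetric=symmetric)
        assert m.p.sum() == pytest.approx(1.0, abs=1e-9)
        oracle = _brute_glcm(q.levels, OFFSETS_13, symmetric)
        got = {(i, j): p for i, j, p in zip(m.i, m.j, m.p)}
        assert set(got) == set(oracle)
        for k in oracle:
            assert got[k] == pytest.approx(oracle[k], abs=1e-12)

    def test_symmetry_flag(self, rng):
        hu = np.round(rng.uniform(0, 4, size=(3, 3, 3)))
        m = glcm(quantize(make_segment(hu)), symmetric=True)
        dense = m.to_dense()
        np.testing.assert_allclose(dense, dense.T, atol=1e-12)


class TestGLCMFeatures:
    def test_single_cell_identities(self):
        """Constant image: ASM=1, IDM=1, contrast=0, entropy=0, moments=0."""
        m = GLCMMatrix(
            i=np.array([0]), j=np.array([0]), p=np.array([1.0]),
            n_levels=1, bin_width=1.0, offsets=((0, 0, 1),), symmetric=True,
        )
        f = glcm_features(m)
        assert f.glcm_asm == pytest.approx(1.0)
        assert f.glcm_idm == pytest.approx(1.0)
        assert f.glcm_contrast == pytest.approx(0.0)
        assert f.glcm_entropy == pytest.approx(0.0)
        assert f.glcm_moments == pytest.approx(0.0)

    def test_two_cell_hand_values(self):
        """P(0,1)=P(1,0)=0.5: ASM 0.5, IDM 0.5, contrast 1, entropy ln2, moments 1."""
        m = GLCMMatrix(
            i=np.array([0, 1]), j=np.array([1, 0]), p=np.array([0.5, 0.5]),
            n_levels=2, bin_width=1.0, offsets=((0, 0, 1),), symmetric=True,
        )
        f = glcm_features(m)
        assert f.glcm_asm == pytest.approx(0.5)
        assert f.glcm_idm == pytest.approx(0.5)  # 0.5/2 + 0.5/2, direct evaluation
        assert f.glcm_contrast == pytest.approx(1.0)
        assert f.glcm_entropy == pytest.approx(math.log(2))
        assert f.glcm_moments == pytest.approx(1.0)

    @pytest.mark.parametrize("k", [2, 5])
    def test_uniform_matrix_maximum_entropy(self, k):
        i, j = np.meshgrid(np.arange(k), np.arange(k), indexing="ij")
        m = GLCMMatrix(
            i=i.ravel(), j=j.ravel(), p=np.full(k * k, 1.0 / k**2),
            n_levels=k, bin_width=1.0, offsets=((0, 0, 1),), symmetric=True,
        )
        f = glcm_features(m)
        assert f.glcm_entropy == pytest.approx(2 * math.log(k))
        assert f.glcm_asm == pytest.approx(1.0 / k**2)

    def test_entropy_base_two(self):
        m = GLCMMatrix(
            i=np.array([0, 1]), j=np.array([1, 0]), p=np.array([0.5, 0.5]),
            n_levels=2, bin_width=1.0, offsets=((0, 0, 1),), symmetric=True,
        )
        assert glcm_features(m, entropy_base=2.0).glcm_entropy == pytest.approx(1.0)

    def test_shift_invariance(self, rng):
        """Adding a constant HU shift divisible by the bin width changes nothing."""
        hu = np.round(rng.uniform(-100, 100, size=(4, 4, 4)))
        f1 = glcm_features(glcm(quantize(make_segment(hu), 5.0)))
        f2 = glcm_features(glcm(quantize(make_segment(hu + 25.0), 5.0)))
        for name in ("glcm_asm", "glcm_idm", "glcm_contrast", "glcm_entropy", "glcm_moments"):
            assert getattr(f1, name) == pytest.approx(getattr(f2, name), rel=1e-12)

    def test_entropy_asm_antitone_under_concentration(self):
        """Uniform matrix: max entropy / min ASM; single cell: the reverse."""
        k = 4
        i, j = np.meshgrid(np.arange(k), np.arange(k), indexing="ij")
        uni = GLCMMatrix(i.ravel(), j.ravel(), np.full(k * k, 1 / k**2),
                         k, 1.0, ((0, 0, 1),), True)
        single = GLCMMatrix(np.array([0]), np.array([0]), np.array([1.0]),
                            k, 1.0, ((0, 0, 1),), True)
        fu, fs = glcm_features(uni), glcm_features(single)
        assert fu.glcm_entropy > fs.glcm_entropy
        assert fu.glcm_asm < fs.glcm_asm
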