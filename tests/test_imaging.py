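"""Image encoders versus naive double-loop oracles and hand values."""

import numpy as np
import pytest

from ecgrpm.imaging import (EncoderConfig, encode, gasf_matrix, mtf_matrix,
                            paa, render, rp_matrix, rpm_matrix, to_gray,
                            zscore)
from ecgrpm.preprocessing import Segment, SegmentKind


# --------------------------- naive oracles ---------------------------------

def rpm_oracle(x):
    m = len(x)
    out = np.empty((m, m))
    for i in range(m):
        for j in range(m):
            out[i, j] = x[j] - x[i]
    return out


def gasf_oracle(x):
    lo, hi = min(x), max(x)
    r = [0.0] * len(x) if hi == lo else [2 * (v - lo) / (hi - lo) - 1 for v in x]
    phi = [np.arccos(min(max(v, -1.0), 1.0)) for v in r]
    m = len(x)
    out = np.empty((m, m))
    for i in range(m):
        for j in range(m):
            out[i, j] = np.cos(phi[i] + phi[j])
    return out


def rp_oracle(x, q):
    m = len(x)
    d = np.empty((m, m))
    for i in range(m):
        for j in range(m):
            d[i, j] = abs(x[i] - x[j])
    off = [d[i, j] for i in range(m) for j in range(m) if i != j]
    eps = np.quantile(off, q)
    return (d <= eps).astype(float)


def mtf_oracle(x, n_bins):
    x = np.asarray(x, dtype=float)
    q = min(n_bins, len(np.unique(x)))
    edges = np.quantile(x, np.linspace(0, 1, q + 1)[1:-1]) if q > 1 else []
    bins = []
    for v in x:
        b = 0
        for e in edges:
            if v > e:
                b += 1
        bins.append(b)
    w = np.zeros((q, q))
    for a, b in zip(bins[:-1], bins[1:]):
        w[a, b] += 1
    for r in range(q):
        s = w[r].sum()
        if s > 0:
            w[r] /= s
    m = len(x)
    out = np.empty((m, m))
    for i in range(m):
        for j in range(m):
            out[i, j] = w[bins[i], bins[j]]
    return out


# --------------------------- basic transforms ------------------------------

class TestZscore:
    def test_hand_example_population_sigma(self):
        out = zscore([1, 2, 3])
        np.testing.assert_allclose(out, [-1.224744871391589, 0.0,
                                         1.224744871391589])

    def test_constant_maps_to_zero(self):
        np.testing.assert_array_equal(zscore([5, 5, 5, 5]), np.zeros(4))

    def test_defining_property(self, rng):
        x = rng.standard_normal(777)
        out = zscore(x)
        assert abs(out.mean()) < 1e-10
        assert abs(out.std() - 1) < 1e-10

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            zscore([])


class TestPaa:
    def test_block_means(self):
        np.testing.assert_allclose(paa([1, 2, 3, 4], 2), [1.5, 3.5])

    def test_identity_when_m_equals_n(self, rng):
        x = rng.standard_normal(57)
        np.testing.assert_array_equal(paa(x, 57), x)

    def test_mean_preserved_for_divisible_frames(self, rng):
        x = rng.standard_normal(1800)
        out = paa(x, 300)
        assert out.shape == (300,)
        assert abs(out.mean() - x.mean()) < 1e-10

    def test_uneven_frames_match_definition(self):
        # n=5, m=2: frames [0,1] (floor(0*5/2)=0..floor(1*5/2)=2) and [2,3,4]
        np.testing.assert_allclose(paa([1, 2, 3, 4, 5], 2), [1.5, 4.0])

    def test_m_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            paa([1, 2, 3], 4)
        with pytest.raises(ValueError):
            paa([1, 2, 3], 1)


class TestRpmMatrix:
    def test_hand_example(self):
        np.testing.assert_array_equal(
            rpm_matrix([-1, 0, 1]),
            [[0, 1, 2], [-1, 0, 1], [-2, -1, 0]])

    def test_constant_gives_zero_matrix(self):
        np.testing.assert_array_equal(rpm_matrix([0, 0, 0]), np.zeros((3, 3)))

    def test_antisymmetry_and_zero_trace(self, rng):
        for _ in range(20):
            x = rng.standard_normal(rng.integers(3, 64))
            m = rpm_matrix(x)
            np.testing.assert_array_equal(m + m.T, np.zeros_like(m))
            assert np.trace(m) == 0.0


class TestToGray:
    def test_half_up_rounding(self):
        np.testing.assert_array_equal(
            to_gray(np.array([[0.0, 1.0], [-1.0, 0.0]])),
            [[128, 255], [0, 128]])

    def test_constant_matrix_is_zeros(self):
        np.testing.assert_array_equal(to_gray(np.full((3, 3), 7.0)),
                                      np.zeros((3, 3), dtype=np.uint8))

    def test_antisymmetric_diagonal_is_128(self, rng):
        for _ in range(20):
            m = rpm_matrix(rng.standard_normal(rng.integers(3, 64)))
            if m.max() == m.min():
                continue
            g = to_gray(m)
            assert np.all(np.diag(g) == 128)
            assert g.min() == 0 and g.max() == 255


# --------------------------- encoders --------------------------------------

class TestEncoderExamples:
    def test_gasf_three_point(self):
        np.testing.assert_allclose(
            gasf_matrix([1.0, 0.0, -1.0]),
            [[1, 0, -1], [0, -1, 0], [-1, 0, 1]], atol=1e-12)

    def test_rp_recurrent_pairs(self):
        x = np.array([0.0, 0.0, 1.0])
        d = rp_matrix(x, 0.5, binarize=False)
        rec = d <= 0.5
        expected = {(0, 0), (1, 1), (2, 2), (0, 1), (1, 0)}
        got = {(i, j) for i in range(3) for j in range(3) if rec[i, j]}
        assert got == expected

    def test_mtf_two_bin_transition(self):
        t = mtf_matrix([0.0, 0.0, 1.0, 1.0], n_bins=2)
        assert t[0, 3] == pytest.approx(0.5)
        assert t[0, 0] == pytest.approx(0.5)
        assert t[2, 2] == pytest.approx(1.0)

    def test_mtf_rows_of_transition_matrix_sum_to_one(self, rng):
        x = rng.standard_normal(50)
        t = mtf_matrix(x, 8)
        # every value's outgoing row either sums to 1 over the bins it can
        # reach, which shows up as each matrix row summing to a constant
        # multiple of visited-bin probabilities; check via the definition:
        q = 8
        edges = np.quantile(x, np.linspace(0, 1, q + 1)[1:-1])
        bins = np.searchsorted(edges, x, side="left")
        w = np.zeros((q, q))
        np.add.at(w, (bins[:-1], bins[1:]), 1.0)
        visited = w.sum(axis=1) > 0
        wn = np.where(visited[:, None], w / np.where(visited, w.sum(axis=1),
                                                     1.0)[:, None], 0.0)
        assert np.allclose(wn.sum(axis=1)[visited], 1.0)
        np.testing.assert_allclose(t, wn[np.ix_(bins, bins)])


@pytest.mark.parametrize("encoder", ["RPM", "GASF", "RP", "MTF"])
def test_oracle_equivalence(encoder, rng):
    """Vectorized encoders equal naive double-loop oracles on random series."""
    for seed in range(20):
        r = np.random.default_rng(seed)
        x = zscore(r.standard_normal(int(r.integers(8, 65))))
        if encoder == "RPM":
            np.testing.assert_array_equal(rpm_matrix(x), rpm_oracle(x))
        elif encoder == "GASF":
            np.testing.assert_allclose(gasf_matrix(x), gasf_oracle(x),
                                       atol=1e-10)
        elif encoder == "RP":
            np.testing.assert_array_equal(rp_matrix(x, 0.10),
                                          rp_oracle(x, 0.10))
        else:
            np.testing.assert_allclose(mtf_matrix(x, 8), mtf_oracle(x, 8),
                                       atol=1e-10)


def _segment(samples, kind=SegmentKind.SINGLE_BEAT, label="N"):
    return Segment(samples=samples, label=label, kind=kind,
                   source_record="t", anchor_index=99)


class TestEncodePipeline:
    def test_rpm_affine_invariance(self, rng):
        x = rng.standard_normal(300)
        cfg = EncoderConfig(encoder="RPM", render_px=64)
        base = encode(_segment(x), cfg)
        shifted = encode(_segment(3.7 * x + 11.0), cfg)
        np.testing.assert_array_equal(base.matrix, shifted.matrix)
        np.testing.assert_array_equal(base.rendered, shifted.rendered)

    @pytest.mark.parametrize("encoder", ["RPM", "GASF", "MTF"])
    def test_full_gray_range(self, encoder, rng):
        x = rng.standard_normal(300)
        img = encode(_segment(x), EncoderConfig(encoder=encoder, render_px=64))
        assert img.matrix.min() == 0 and img.matrix.max() == 255

    def test_matrix_is_square_at_native_or_paa_length(self, rng):
        beat = encode(_segment(rng.standard_normal(300)),
                      EncoderConfig(encoder="RPM", render_px=64))
        assert beat.matrix.shape == (300, 300)
        window = encode(
            _segment(rng.standard_normal(1800), SegmentKind.FIVE_SECOND),
            EncoderConfig(encoder="RPM", render_px=64))
        assert window.matrix.shape == (300, 300)

    def test_rp_black_means_similar(self, rng):
        x = rng.standard_normal(100)
        img = encode(_segment(np.concatenate([x, x, x])),
                     EncoderConfig(encoder="RP", render_px=64))
        assert set(np.unique(img.matrix)) <= {0, 255}
        assert np.all(np.diag(img.matrix) == 0)   # self-similarity is black

    def test_unknown_encoder_rejected(self):
        with pytest.raises(ValueError):
            EncoderConfig(encoder="SPECTROGRAM")


class TestRender:
    def test_identity_resize(self, rng):
        m = rng.integers(0, 256, size=(224, 224)).astype(np.uint8)
        np.testing.assert_array_equal(render(m, 224), m)

    def test_constant_stays_constant(self):
        m = np.full((300, 300), 77, dtype=np.uint8)
        out = render(m, 224)
        assert out.shape == (224, 224)
        assert np.all(out == 77)

    def test_checker_range_and_shape(self):
        m = (np.indices((300, 300)).sum(axis=0) % 2 * 255).astype(np.uint8)
        out = render(m, 224)
        assert out.shape == (224, 224)
        assert out.min() >= 0 and out.max() <= 255
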