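"""Category selection (CSM) and gland-masked self-attention (AKGM):
algebraic identities and loop-based oracle equivalence."""

import numpy as np
import pytest

from ctgnet.backbone import SharedFeatures
from ctgnet.cls_unit import ClassPrediction
from ctgnet.coarse_seg import init_decoder
from ctgnet.fine_seg import akgm, csm, fine_segment, fuse, init_akgm, init_csm


def _pred(rng, d1, C):
    logits = rng.normal(size=C)
    h = np.exp(logits - logits.max())
    h /= h.sum()
    return ClassPrediction(g_global=rng.normal(size=(d1, C)), h_score=h,
                           logits=logits)


def csm_reference(f_vals, g_global, h_score, params):
    """Naive loop evaluation of the category-attention product."""
    d, H, W = f_vals.shape
    d1, C = g_global.shape
    wg = params["wg"]["W"] @ g_global + params["wg"]["b"][:, None]
    p = np.zeros((C, H, W))
    for c in range(C):
        for i in range(d):
            p[c] += params["proj"]["W"][c, i, 0, 0] * f_vals[i]
        p[c] += params["proj"]["b"][c]
    out = np.zeros((d1, H * W))
    for j in range(d1):
        for n in range(H * W):
            out[j, n] = sum(wg[j, c] * h_score[c] * p.reshape(C, -1)[c, n]
                            for c in range(C))
    return out.reshape(d1, H, W)


def akgm_reference(f_vals, mask, params):
    """Naive per-position evaluation of gland-masked self-attention."""
    d, H, W = f_vals.shape
    N = H * W
    flat = f_vals.reshape(d, N)
    conv1 = lambda layer: (layer["W"][:, :, 0, 0] @ flat
                           + layer["b"][:, None])
    q, k, v = conv1(params["q"]), conv1(params["k"]), conv1(params["v"])
    mf = mask.reshape(N)
    qm, km = q * mf, k * mf
    s = np.zeros((N, N))
    for j in range(N):
        logits = np.array([qm[:, j] @ km[:, i] for i in range(N)])
        e = np.exp(logits - logits.max())
        s[j] = e / e.sum()
    out = np.zeros((d, N))
    for j in range(N):
        for i in range(N):
            out[:, j] += s[j, i] * v[:, i]
    return (float(params["alpha"]) * out + flat).reshape(d, H, W)


class TestCsm:
    @pytest.mark.parametrize("d,hw,C", [(3, 2, 2), (4, 4, 3)])
    def test_matches_loop_oracle(self, d, hw, C):
        rng = np.random.default_rng(d * 10 + hw + C)
        d1 = 3
        params = init_csm(d, d1, C, rng, dtype=np.float64)
        f = SharedFeatures(values=rng.normal(size=(d, hw, hw)), stride=8)
        pred = _pred(rng, d1, C)
        got = np.asarray(csm(f, pred, params))
        want = csm_reference(f.values, pred.g_global, pred.h_score, params)
        np.testing.assert_allclose(got, want, atol=1e-6)

    def test_zero_scores_zero_the_output(self, rng):
        params = init_csm(4, 3, 2, rng, dtype=np.float64)
        f = SharedFeatures(values=rng.normal(size=(4, 2, 2)), stride=8)
        pred = ClassPrediction(g_global=rng.normal(size=(3, 2)),
                               h_score=np.zeros(2), logits=np.zeros(2))
        np.testing.assert_allclose(np.asarray(csm(f, pred, params)), 0.0,
                                   atol=1e-12)

    def test_one_hot_scores_keep_only_that_class(self, rng):
        # h = (1, 0): output is the outer product of W_g column 0 with the
        # class-0 projection of F'
        d, d1, C = 3, 4, 2
        params = init_csm(d, d1, C, rng, dtype=np.float64)
        f = SharedFeatures(values=rng.normal(size=(d, 2, 2)), stride=8)
        g = rng.normal(size=(d1, C))
        pred = ClassPrediction(g_global=g, h_score=np.array([1.0, 0.0]),
                               logits=np.zeros(2))
        wg = params["wg"]["W"] @ g + params["wg"]["b"][:, None]
        p0 = (np.tensordot(params["proj"]["W"][0, :, 0, 0], f.values, axes=1)
              + params["proj"]["b"][0])
        want = np.einsum("j,hw->jhw", wg[:, 0], p0)
        np.testing.assert_allclose(np.asarray(csm(f, pred, params)), want,
                                   atol=1e-10)

    def test_duplicate_classes_collapse_to_single_class_result(self, rng):
        d, d1 = 3, 4
        params = init_csm(d, d1, 2, rng, dtype=np.float64)
        # make the projection rows identical so P has equal class rows
        params["proj"]["W"][1] = params["proj"]["W"][0]
        params["proj"]["b"][1] = params["proj"]["b"][0]
        f = SharedFeatures(values=rng.normal(size=(d, 2, 2)), stride=8)
        col = rng.normal(size=d1)
        g = np.stack([col, col], axis=1)
        duplicated = csm(f, ClassPrediction(g_global=g,
                                            h_score=np.array([0.5, 0.5]),
                                            logits=np.zeros(2)), params)
        single = csm(f, ClassPrediction(g_global=g,
                                        h_score=np.array([1.0, 0.0]),
                                        logits=np.zeros(2)), params)
        np.testing.assert_allclose(np.asarray(duplicated),
                                   np.asarray(single), atol=1e-10)

    def test_class_count_mismatch_is_reported(self, rng):
        params = init_csm(4, 3, 2, rng, dtype=np.float64)
        f = SharedFeatures(values=rng.normal(size=(4, 2, 2)), stride=8)
        with pytest.raises(ValueError, match="class-count"):
            csm(f, _pred(rng, 3, 3), params)


class TestAkgm:
    def test_identity_at_alpha_zero(self, rng):
        params = init_akgm(6, rng, dtype=np.float64)
        assert float(params["alpha"]) == 0.0
        f = SharedFeatures(values=rng.normal(size=(6, 4, 4)), stride=8)
        mask = rng.uniform(size=(4, 4))
        out = np.asarray(akgm(f, mask, params))
        assert np.array_equal(out, f.values)  # bit-exact

    @pytest.mark.parametrize("d,hw", [(3, 2), (4, 4)])
    def test_matches_loop_oracle(self, d, hw):
        rng = np.random.default_rng(d + hw)
        params = init_akgm(d, rng, qk_channels=2, dtype=np.float64)
        params["alpha"] = np.array(0.6)
        f = SharedFeatures(values=rng.normal(size=(d, hw, hw)), stride=8)
        mask = rng.uniform(size=(hw, hw))
        got = np.asarray(akgm(f, mask, params))
        want = akgm_reference(f.values, mask, params)
        np.testing.assert_allclose(got, want, atol=1e-6)

    def test_attention_rows_are_stochastic(self, rng):
        params = init_akgm(5, rng, dtype=np.float64)
        f = SharedFeatures(values=rng.normal(size=(5, 3, 3)), stride=8)
        _, state = akgm(f, rng.uniform(size=(3, 3)), params, return_state=True)
        np.testing.assert_allclose(state.s.sum(axis=1), 1.0, atol=1e-5)

    def test_zero_mask_attends_uniformly(self, rng):
        # masked-out gland: S is uniform, every position gets the mean of V
        d, hw = 4, 2
        params = init_akgm(d, rng, dtype=np.float64)
        params["alpha"] = np.array(0.8)
        f = SharedFeatures(values=rng.normal(size=(d, hw, hw)), stride=8)
        out, state = akgm(f, np.zeros((hw, hw)), params, return_state=True)
        np.testing.assert_allclose(state.s, 0.25, atol=1e-12)
        vbar = state.v.mean(axis=1)
        want = 0.8 * vbar[:, None, None] + f.values
        np.testing.assert_allclose(np.asarray(out), want, atol=1e-10)


class TestFineDecode:
    def test_fusion_concatenates_along_channels(self, rng):
        a = rng.normal(size=(3, 2, 2))
        b = rng.normal(size=(5, 2, 2))
        ff = fuse(a, b, stride=8)
        assert ff.f_fine.shape == (8, 2, 2)
        np.testing.assert_array_equal(ff.f_fine[:3], a)
        np.testing.assert_array_equal(ff.f_fine[3:], b)
        assert fuse(a, None, 8).f_fine.shape == (3, 2, 2)
        assert fuse(None, b, 8).f_fine.shape == (5, 2, 2)
        with pytest.raises(ValueError):
            fuse(None, None, 8)

    def test_probabilities_normalized_and_shaped(self, rng):
        params = init_decoder(6, (4, 4, 4, 4), 2, rng, dtype=np.float64)
        ff = fuse(rng.normal(size=(2, 8, 8)), rng.normal(size=(4, 8, 8)), 8)
        probs = np.asarray(fine_segment(ff, params))
        assert probs.shape == (2, 64, 64)
        np.testing.assert_allclose(probs.sum(axis=0), 1.0, atol=1e-5)

    def test_zero_head_gives_even_odds(self, rng):
        params = init_decoder(4, (4, 4, 4, 4), 2, rng, dtype=np.float64)
        params["head"]["W"][:] = 0.0
        ff = fuse(None, rng.normal(size=(4, 4, 4)), 8)
        np.testing.assert_allclose(np.asarray(fine_segment(ff, params)), 0.5,
                                   atol=1e-12)
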