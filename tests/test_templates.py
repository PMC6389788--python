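import numpy as np
import pytest

from neurokws import dsp
from neurokws import templates as tpl
from neurokws.features import FeatureStream
from neurokws.recording_io import SYLLABLES


def make_stream(z, frame_rate=62.5, roi=None):
    z = np.asarray(z, dtype=float)
    return FeatureStream(
        z=z,
        frame_times=0.127 + np.arange(z.shape[1]) / frame_rate,
        frame_rate=frame_rate,
        channel_labels=[f"c{i}" for i in range(z.shape[0])],
        roi=np.array(["vSMC"] * z.shape[0] if roi is None else roi, dtype=object),
        baseline_frames=np.arange(min(20, z.shape[1])),
    )


def brute_force_pearson(z, template, mask):
    """Independent oracle: double-loop Pearson over unmasked entries."""
    C, L = template.shape
    F = z.shape[1]
    out = np.zeros(F)
    tv = template[mask]
    for t in range(L - 1, F):
        wv = z[:, t - L + 1 : t + 1][mask]
        tc = tv - tv.mean()
        wc = wv - wv.mean()
        denom = np.sqrt((tc**2).sum() * (wc**2).sum())
        out[t] = (tc * wc).sum() / denom if denom > 1e-12 else 0.0
    return out


class TestContrastDefinitions:
    def test_nineteen_contrasts(self):
        d = tpl.contrast_definitions()
        assert len(d) == 19
        assert d["bilabial"] == {"/ba/", "/pa/", "/bi/", "/pi/"}
        assert d["voiced"] == {"/ba/", "/da/", "/ga/", "/bi/", "/di/", "/gi/"}
        assert d["/a/"] == {"/ba/", "/da/", "/ga/", "/pa/", "/ta/", "/ka/"}
        for s in SYLLABLES:
            assert d[s] == {s}


class TestBuildTemplates:
    def _epochs(self, rng, n=24, c=3, L=63):
        labels = np.array([SYLLABLES[i % 12] for i in range(n)], dtype=object)
        return rng.standard_normal((n, c, L)), labels

    def test_identical_trials_zero_discrimination(self):
        epochs = np.tile(np.arange(63.0), (24, 2, 1))
        labels = np.array([SYLLABLES[i % 12] for i in range(24)], dtype=object)
        ts = tpl.build_templates(epochs, labels, np.array(["vSMC", "vSMC"], dtype=object))
        for name in ts.contrasts:
            np.testing.assert_allclose(ts.discrimination[name], 0.0, atol=1e-12)

    def test_toy_oracle(self):
        # 2 channels, 5 frames, 2 conditions with hand-computable means
        L, fr = 5, 62.5
        a = np.zeros((2, L)); a[0] = 4.0
        b = np.zeros((2, L)); b[1] = 4.0
        epochs = np.stack([a] * 6 + [b] * 6)
        labels = np.array(["/ba/"] * 6 + ["/da/"] * 6, dtype=object)
        with pytest.warns(UserWarning):
            ts = tpl.build_templates(epochs, labels,
                                     np.array(["vSMC", "vSMC"], dtype=object),
                                     frame_rate=fr)
        response = epochs.mean(0)
        kernel = dsp.hamming_kernel(0.1, fr)
        from scipy.signal import lfilter
        cond = a
        mask = cond * np.sqrt(6) >= 3.0
        expected = np.where(mask, lfilter(kernel, [1.0], cond - response, axis=-1), 0.0)
        np.testing.assert_allclose(ts.discrimination["/ba/"], expected, atol=1e-12)

    def test_mask_zeroes_subthreshold_elements(self):
        # condition-mean z of 2.9 must be zeroed, 3.1 kept
        n = 16
        L = 5
        epochs = np.zeros((2 * n, 1, L))
        epochs[:n, 0, 1] = 2.9 / np.sqrt(n)
        epochs[:n, 0, 3] = 3.1 / np.sqrt(n)
        labels = np.array(["/ba/"] * n + ["/da/"] * n, dtype=object)
        with pytest.warns(UserWarning):
            ts = tpl.build_templates(epochs, labels, np.array(["vSMC"], dtype=object))
        assert not ts.masks["/ba/"][0, 1]
        assert ts.masks["/ba/"][0, 3]
        assert ts.discrimination["/ba/"][0, 1] == 0.0

    def test_vad_excludes_stg(self, rng):
        epochs, labels = self._epochs(rng, c=4)
        roi = np.array(["vSMC", "STG", "vSMC", "STG"], dtype=object)
        ts = tpl.build_templates(epochs, labels, roi)
        assert ts.vad.shape[0] == 2
        np.testing.assert_array_equal(ts.vad_channels, [0, 2])
        np.testing.assert_allclose(ts.vad, ts.response[[0, 2]])

    def test_empty_contrast_warns_and_omits(self, rng):
        epochs = rng.standard_normal((8, 2, 63))
        labels = np.array(["/ba/"] * 4 + ["/da/"] * 4, dtype=object)
        with pytest.warns(UserWarning, match="no trials"):
            ts = tpl.build_templates(epochs, labels, np.array(["vSMC", "vSMC"], dtype=object))
        assert "/ki/" not in ts.discrimination
        assert "/ba/" in ts.discrimination

    def test_single_condition_rejected(self, rng):
        epochs = rng.standard_normal((4, 2, 63))
        labels = np.array(["/ba/"] * 4, dtype=object)
        with pytest.raises(ValueError, match="two conditions"):
            tpl.build_templates(epochs, labels, np.array(["vSMC", "vSMC"], dtype=object))

    def test_masked_entries_exactly_zero(self, pipeline):
        ts = pipeline.templates
        for name in ts.contrasts:
            assert np.all(ts.discrimination[name][~ts.masks[name]] == 0.0)
        assert len(ts.contrasts) == 19
        assert np.all(ts.roi[ts.vad_channels] == "vSMC")


class TestMatchedFilter:
    def test_exact_copy_peaks_at_one(self, rng):
        L, C, F = 63, 3, 300
        template = rng.standard_normal((C, L))
        z = np.zeros((C, F))
        z[:, 100 : 100 + L] = 2.0 * template + 1.0  # scaled/shifted copy
        mask = np.ones((C, L), dtype=bool)
        r = tpl._sliding_pearson(z, template, mask)
        peak = 100 + L - 1
        assert r[peak] == pytest.approx(1.0, abs=1e-12)
        assert np.argmax(r) == peak

    def test_oracle_equivalence_random(self, rng):
        C, F, L = 4, 200, 63
        z = rng.standard_normal((C, F))
        template = rng.standard_normal((C, L))
        mask = rng.random((C, L)) > 0.3
        ours = tpl._sliding_pearson(z, template, mask)
        ref = brute_force_pearson(z, template, mask)
        np.testing.assert_allclose(ours, ref, atol=1e-10, rtol=1e-10)

    def test_vad_nonnegative_and_causal(self, rng):
        z = rng.standard_normal((4, 400))
        stream = make_stream(z)
        labels = np.array([SYLLABLES[i % 12] for i in range(24)], dtype=object)
        epochs = rng.standard_normal((24, 4, 63))
        ts = tpl.build_templates(epochs, labels, stream.roi)
        out = tpl.matched_filter(stream, ts)
        assert np.all(out.v >= 0)
        # causality: perturbing the future never changes the past
        z2 = z.copy()
        z2[:, 250:] += 10 * rng.standard_normal((4, 150))
        out2 = tpl.matched_filter(make_stream(z2), ts)
        np.testing.assert_allclose(out.y[:, :250], out2.y[:, :250], atol=1e-10)
        np.testing.assert_allclose(out.v[:250], out2.v[:250], atol=1e-10)
        assert not np.allclose(out.v[250:], out2.v[250:])

    def test_stream_too_short(self, rng):
        stream = make_stream(rng.standard_normal((2, 30)))
        labels = np.array(["/ba/"] * 4 + ["/da/"] * 4, dtype=object)
        with pytest.warns(UserWarning):
            ts = tpl.build_templates(rng.standard_normal((8, 2, 63)), labels, stream.roi)
        with pytest.raises(ValueError, match="shorter"):
            tpl.matched_filter(stream, ts)

    def test_ablation_is_boxcar(self, rng):
        z = rng.standard_normal((3, 200))
        stream = make_stream(z)
        labels = np.array([SYLLABLES[i % 12] for i in range(24)], dtype=object)
        ts = tpl.build_templates(rng.standard_normal((24, 3, 63)), labels, stream.roi)
        out = tpl.matched_filter(stream, ts, ablate_rectangular=True)
        # every contrast collapses to the same rectangular smoothing
        for i in range(1, out.y.shape[0]):
            np.testing.assert_allclose(out.y[i], out.y[0], atol=1e-12)
        L = ts.length
        expected = z[:, :L].mean()
        raw = tpl._sliding_boxcar(z, (3, L))
        assert raw[L - 1] == pytest.approx(expected)

    def test_delays_metadata(self, pipeline):
        out = pipeline.train.outputs
        assert out.y_delay_s == pytest.approx((31 + 7.5) * 0.016)
        assert out.v_delay_s == pytest.approx((31 + 31) * 0.016)


class TestPersistence:
    def test_round_trip(self, tmp_path, pipeline):
        path = tmp_path / "t.h5"
        tpl.save_templates(pipeline.templates, path)
        back = tpl.load_templates(path)
        assert set(back.contrasts) == set(pipeline.templates.contrasts)
        for name in pipeline.templates.contrasts:
            np.testing.assert_allclose(back.discrimination[name],
                                       pipeline.templates.discrimination[name])
            np.testing.assert_array_equal(back.masks[name], pipeline.templates.masks[name])
        np.testing.assert_allclose(back.vad, pipeline.templates.vad)
        assert back.channel_labels == pipeline.templates.channel_labels
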