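"""Feature extraction: Hilbert analytic signal, PLI, band power,
differential entropy, dPAC/AAC, and the subject-level feature matrix."""

import cmath
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from bdeeg.core import BANDS, MONTAGE_19
from bdeeg.features import (
    aac,
    analytic,
    build_feature_matrix,
    differential_entropy,
    dpac,
    feature_columns,
    pli_from_phases,
    pli_matrix,
    psd_band_power,
)
from bdeeg.preprocess import band_filter, epoch, filter_broadband
from bdeeg.stats import feature_ttests
from bdeeg.synthetic import CohortSpec, GroupParams, generate_cohort

from conftest import FS, make_recording, montage_noise_recording, tone


def brute_force_pli(phase):
    """Independent per-sample evaluation of |1/M sum sgn(wrapped dphi)|."""
    n_ep, n_ch, n_s = phase.shape
    mat = np.zeros((n_ch, n_ch))
    for a in range(n_ch):
        for b in range(n_ch):
            if a == b:
                continue
            epoch_means = []
            for m in range(n_ep):
                total = 0.0
                for t in range(n_s):
                    d = phase[m, a, t] - phase[m, b, t]
                    wrapped = cmath.phase(cmath.exp(1j * d))
                    total += (0.0 if wrapped == 0 else math.copysign(1.0, wrapped))
                epoch_means.append(total / n_s)
            mat[a, b] = abs(sum(epoch_means) / n_ep)
    return mat


class TestAnalytic:
    def test_tone_amplitude_and_phase_rate(self):
        es = epoch(make_recording([tone(10.0, duration=30.0)] * 2,
                                  labels=["O1", "O2"]))
        an = analytic(band_filter(es, BANDS["alpha"]))
        core = an.amplitude[1:-1, 0, 200:-200]
        assert np.abs(core - 1.0).max() < 0.02
        dphi = np.diff(np.unwrap(an.phase[1, 0, 200:-200]))
        assert np.allclose(dphi, 2 * np.pi * 10 / FS, rtol=0.02)

    def test_amplitude_linear_in_scale(self):
        rec = montage_noise_recording(seed=1, duration=12.0)
        es = band_filter(epoch(rec), BANDS["alpha"])
        es3 = band_filter(epoch(rec.copy_with(data=3.0 * rec.data)),
                          BANDS["alpha"])
        assert np.allclose(analytic(es3).amplitude, 3 * analytic(es).amplitude)

    def test_sign_flip_shifts_phase_by_pi(self):
        rec = montage_noise_recording(seed=2, duration=12.0)
        es = band_filter(epoch(rec), BANDS["alpha"])
        neg = band_filter(epoch(rec.copy_with(data=-rec.data)), BANDS["alpha"])
        d = np.angle(np.exp(1j * (analytic(neg).phase - analytic(es).phase)))
        assert np.allclose(np.abs(d), np.pi, atol=1e-8)

    def test_broadband_rejected(self):
        with pytest.raises(ValueError):
            analytic(epoch(montage_noise_recording(duration=12.0)))


class TestPLI:
    def test_identical_channels_give_zero(self):
        phase = np.random.default_rng(0).uniform(-np.pi, np.pi, (3, 1, 500))
        phase = np.repeat(phase, 2, axis=1)
        assert np.all(pli_from_phases(phase) == 0)

    def test_constant_lag_gives_one(self):
        base = np.random.default_rng(1).uniform(-np.pi, np.pi, (3, 1, 500))
        phase = np.concatenate([base, base - np.pi / 4], axis=1)
        m = pli_from_phases(phase)
        assert m[0, 1] == 1.0

    def test_uniform_null_bound(self):
        """|PLI| <= 0.04 for N=9000 iid uniform phase differences in >=95%
        of 200 draws (3.8-sigma bound on the sign mean)."""
        rng = np.random.default_rng(42)
        hits = 0
        for _ in range(200):
            phase = rng.uniform(-np.pi, np.pi, (1, 2, 9000))
            if pli_from_phases(phase)[0, 1] <= 0.04:
                hits += 1
        assert hits >= 190

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(5):
            phase = rng.uniform(-np.pi, np.pi, (2, 3, 50))
            assert np.abs(pli_from_phases(phase)
                          - brute_force_pli(phase)).max() < 1e-12

    def test_single_channel_rejected(self):
        with pytest.raises(ValueError):
            pli_from_phases(np.zeros((2, 1, 10)))

    @settings(deadline=None, max_examples=25)
    @given(hnp.arrays(np.float64, (2, 4, 30),
                      elements=st.floats(-np.pi, np.pi, width=64)))
    def test_fuzz_symmetric_bounded(self, phase):
        m = pli_from_phases(phase)
        assert np.allclose(m, m.T)
        assert np.all(np.diag(m) == 0)
        assert np.all((m >= 0) & (m <= 1))

    def test_channel_permutation_equivariance(self):
        rng = np.random.default_rng(4)
        phase = rng.uniform(-np.pi, np.pi, (2, 5, 100))
        perm = rng.permutation(5)
        m = pli_from_phases(phase)
        mp = pli_from_phases(phase[:, perm, :])
        assert np.allclose(mp, m[np.ix_(perm, perm)], atol=1e-12)


class TestBandPower:
    def test_unit_tone_half_watt_in_alpha(self):
        es = epoch(make_recording([tone(10.0, duration=60.0)] * 2,
                                  labels=["O1", "O2"]))
        alpha = psd_band_power(es, BANDS["alpha"])
        assert np.abs(alpha - 0.5).max() < 0.01
        for other in ("delta", "theta", "beta", "gamma"):
            assert psd_band_power(es, BANDS[other]).max() < 0.005

    def test_white_noise_partition(self, rng):
        sigma = 2.0
        es = epoch(make_recording(
            sigma * rng.standard_normal((2, int(60 * FS))), labels=["O1", "O2"]))
        total = sum(psd_band_power(es, BANDS[b]).mean()
                    for b in ("delta", "theta", "alpha", "beta", "gamma"))
        expected = sigma ** 2 * (48.0 / 125.0)  # in-band fraction of flat spectrum
        assert abs(total / expected - 1) < 0.05

    def test_zero_signal(self):
        es = epoch(make_recording(np.zeros((2, 3000)), labels=["O1", "O2"]))
        assert np.all(psd_band_power(es, BANDS["alpha"]) == 0)

    def test_banded_input_rejected(self):
        es = band_filter(epoch(montage_noise_recording(duration=12.0)),
                         BANDS["alpha"])
        with pytest.raises(ValueError):
            psd_band_power(es, BANDS["alpha"])


class TestDifferentialEntropy:
    def test_unit_variance_gaussian_closed_form(self, rng):
        es = band_filter(epoch(montage_noise_recording(seed=6, duration=60.0)),
                         BANDS["alpha"])
        scaled = es.epochs / es.epochs.std(axis=-1, keepdims=True)
        from bdeeg.core import EpochSet
        unit = EpochSet(scaled, es.fs, es.channel_labels, es.band)
        de = differential_entropy(unit)
        assert np.abs(de - 0.5 * np.log(2 * np.pi * np.e)).max() < 0.05

    def test_scaling_shifts_by_log_c(self):
        es = band_filter(epoch(montage_noise_recording(seed=7, duration=12.0)),
                         BANDS["beta"])
        from bdeeg.core import EpochSet
        scaled = EpochSet(5.0 * es.epochs, es.fs, es.channel_labels, es.band)
        assert np.allclose(differential_entropy(scaled),
                           differential_entropy(es) + np.log(5.0))

    def test_zero_variance_rejected(self):
        from bdeeg.core import EpochSet
        es = EpochSet(np.zeros((1, 2, 100)), FS, ("O1", "O2"), BANDS["alpha"])
        with pytest.raises(ValueError):
            differential_entropy(es)

    def test_monotone_with_log_power(self, rng):
        """DE and log band power rank subjects identically on Gaussian data."""
        de_vals, lp_vals = [], []
        for s in range(12):
            rec = montage_noise_recording(seed=100 + s, duration=12.0,
                                          scale=float(rng.uniform(2, 40)))
            es = epoch(filter_broadband(rec))
            lp_vals.append(np.log(psd_band_power(es, BANDS["alpha"]).mean()))
            de_vals.append(differential_entropy(
                band_filter(es, BANDS["alpha"])).mean())
        from scipy.stats import spearmanr
        assert spearmanr(de_vals, lp_vals).statistic > 0.95


def _analytic_from(phase, amplitude):
    from bdeeg.core import AnalyticSignal
    n_ch = phase.shape[1]
    return AnalyticSignal(phase=phase, amplitude=amplitude, fs=FS,
                          channel_labels=MONTAGE_19[:n_ch],
                          band=BANDS["delta"])


class TestDPAC:
    def test_uniform_phase_null(self, rng):
        n = 9000
        phi = rng.uniform(-np.pi, np.pi, (1, 1, n))
        amp = np.full((1, 1, n), 2.0)
        d = dpac(_analytic_from(phi, amp), _analytic_from(phi, amp))
        assert d[0] <= 3 * 2.0 / np.sqrt(n)

    def test_cosine_modulation_recovers_half_kappa(self, rng):
        phi = rng.uniform(-np.pi, np.pi, (1, 1, 100000))
        amp = 1 + 0.9 * np.cos(phi)
        d = dpac(_analytic_from(phi, np.ones_like(phi)),
                 _analytic_from(phi, amp))
        assert abs(d[0] - 0.45) < 0.02

    def test_global_phase_rotation_invariance(self, rng):
        phi = rng.uniform(-np.pi, np.pi, (2, 3, 500))
        amp = rng.uniform(0.5, 2.0, phi.shape)
        d1 = dpac(_analytic_from(phi, amp), _analytic_from(phi, amp))
        d2 = dpac(_analytic_from(phi + 1.3, amp), _analytic_from(phi, amp))
        assert np.allclose(d1, d2, atol=1e-12)

    def test_misaligned_rejected(self, rng):
        phi = rng.uniform(-np.pi, np.pi, (1, 2, 100))
        with pytest.raises(ValueError):
            dpac(_analytic_from(phi, np.ones_like(phi)),
                 _analytic_from(phi[:, :, :50], np.ones((1, 2, 50))))


class TestAAC:
    def test_affine_envelopes_perfectly_correlated(self, rng):
        a = rng.uniform(0.5, 3.0, (2, 2, 400))
        phi = np.zeros_like(a)
        up = aac(_analytic_from(phi, a), _analytic_from(phi, 2 * a + 1))
        down = aac(_analytic_from(phi, a), _analytic_from(phi, -a + 10))
        assert np.allclose(up, 1.0)
        assert np.allclose(down, -1.0)

    def test_independent_envelopes_null(self, rng):
        hits = 0
        for _ in range(100):
            a = rng.uniform(0.5, 3.0, (1, 1, 9000))
            b = rng.uniform(0.5, 3.0, (1, 1, 9000))
            phi = np.zeros_like(a)
            if abs(aac(_analytic_from(phi, a), _analytic_from(phi, b))[0]) <= 0.04:
                hits += 1
        assert hits >= 95

    def test_constant_envelope_rejected(self):
        a = np.ones((1, 1, 100))
        phi = np.zeros_like(a)
        with pytest.raises(ValueError):
            aac(_analytic_from(phi, a), _analytic_from(phi, a))


class TestFeatureMatrix:
    def test_shape_and_determinism(self, tiny_spec):
        recs, meta, _ = generate_cohort(tiny_spec, paradigms=["eyes_closed"])
        fm1 = build_feature_matrix(recs["eyes_closed"], metadata=meta)
        fm2 = build_feature_matrix(recs["eyes_closed"], metadata=meta)
        feats = feature_columns(MONTAGE_19)
        assert len(feats) == 228
        assert fm1.shape[0] == 8
        assert list(fm1.columns[-228:]) == feats
        assert fm1.equals(fm2)

    def test_pac_contrast_detected(self):
        """BD pac_depth 0.8 vs HC 0.0 raises the mean dPAC column in BD."""
        def grp(kappa):
            return GroupParams({"delta": 8.0, "beta": 5.0}, (), kappa)
        spec = CohortSpec(
            n_bd=6, n_hc=6, duration=30.0, seed=11, one_over_f_scale=2.0,
            params={"eyes_closed": {"BD": grp(0.8), "HC": grp(0.0)}})
        recs, meta, _ = generate_cohort(spec)
        fm = build_feature_matrix(recs["eyes_closed"], metadata=meta)
        tt = feature_ttests(fm)
        dp = tt[tt["feature"] == "dpac"]
        assert dp["significant"].mean() > 0.5
        cols = [c for c in fm.columns if c.startswith("dpac__")]
        assert (fm[fm.group == "BD"][cols].mean().mean()
                > fm[fm.group == "HC"][cols].mean().mean())
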