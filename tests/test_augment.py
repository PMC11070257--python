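"""Augmentation contracts: identity limits, peak-relative levels, chain frequencies."""

import numpy as np
import pytest

from katydet.augment import (
    alter_distance,
    background_infuse,
    build_chain,
    echo,
    gaussian_noise,
    variable_noise_floor,
    volume_ramp,
)

RATE = 96_000


@pytest.fixture
def tone():
    t = np.arange(76_800) / RATE
    return 0.8 * np.sin(2 * np.pi * 12_000 * t)


class TestEcho:
    def test_impulse_response(self):
        x = np.zeros(1000)
        x[0] = 1.0
        out = echo(x, l_db=-20.0, t_ms=1.0, rate=RATE)
        assert out[0] == 1.0
        assert out[96] == pytest.approx(0.1)  # 10^(-20/20)
        assert np.count_nonzero(out) == 2

    def test_large_attenuation_approaches_identity(self, tone):
        out = echo(tone, l_db=-300.0, t_ms=2.0, rate=RATE)
        np.testing.assert_allclose(out, tone, atol=1e-12)

    def test_zero_input_zero_output(self):
        assert not echo(np.zeros(500), -15.0, 1.0, RATE).any()

    def test_length_unchanged_and_delay_validated(self, tone):
        assert len(echo(tone, -18.0, 6.0, RATE)) == len(tone)
        with pytest.raises(ValueError):
            echo(np.zeros(10), -18.0, 6.0, RATE)  # delay beyond segment


class TestVolumeRamp:
    def test_zero_db_is_identity(self, tone):
        np.testing.assert_array_equal(volume_ramp(tone, 0.0), tone)

    def test_endpoint_attenuation(self):
        out = volume_ramp(np.ones(1001), 6.0, attenuated_end="last")
        assert out[0] == 1.0
        assert out[-1] == pytest.approx(10 ** (-6 / 20), abs=1e-9)  # ~0.5012
        # midpoint follows from linearity
        assert out[500] == pytest.approx((1 + 10 ** (-6 / 20)) / 2, abs=1e-9)

    def test_first_end_attenuated(self):
        out = volume_ramp(np.ones(100), 6.0, attenuated_end="first")
        assert out[0] == pytest.approx(10 ** (-6 / 20))
        assert out[-1] == 1.0

    def test_negative_level_rejected(self, tone):
        with pytest.raises(ValueError):
            volume_ramp(tone, -1.0)


class TestBackgroundInfuse:
    def test_noise_peak_scaled_relative_to_signal(self, tone):
        rng = np.random.default_rng(0)
        noise = rng.normal(size=len(tone))
        out = background_infuse(tone, noise, ramp_db=0.0, atten_db=-12.0)
        added = out - tone
        target = 10 ** (-12 / 20) * np.max(np.abs(tone))
        assert np.max(np.abs(added)) == pytest.approx(target, rel=10 ** (0.1 / 20) - 1)

    def test_zero_noise_is_identity(self, tone):
        np.testing.assert_array_equal(background_infuse(tone, np.zeros_like(tone), 3.0, -15.0), tone)

    def test_huge_attenuation_approaches_identity(self, tone):
        out = background_infuse(tone, np.ones_like(tone), 0.0, -300.0)
        np.testing.assert_allclose(out, tone, atol=1e-12)

    def test_zero_signal_rejected(self, tone):
        with pytest.raises(ValueError):
            background_infuse(np.zeros_like(tone), tone, 0.0, -12.0)

    def test_signal_remains_dominant(self, tone):
        rng = np.random.default_rng(1)
        out = background_infuse(tone, rng.normal(size=len(tone)), 9.0, -12.0)
        assert 20 * np.log10(np.max(np.abs(out)) / np.max(np.abs(tone))) <= 3.0


class TestGaussianNoise:
    def test_realized_peak_exact(self, tone):
        rng = np.random.default_rng(0)
        out = gaussian_noise(tone, l_db=-20.0, rng=rng)
        peak = np.max(np.abs(out - tone))
        assert peak == pytest.approx(0.1 * np.max(np.abs(tone)), rel=1e-6)

    def test_seeded_determinism(self, tone):
        a = gaussian_noise(tone, -18.0, np.random.default_rng(42))
        b = gaussian_noise(tone, -18.0, np.random.default_rng(42))
        np.testing.assert_array_equal(a, b)

    def test_zero_input_rejected(self):
        with pytest.raises(ValueError):
            gaussian_noise(np.zeros(100), -20.0)


class TestVariableNoiseFloor:
    def test_all_zero_psd_gives_constant_floor(self):
        out = variable_noise_floor(np.zeros((204, 319)), -100.0)
        np.testing.assert_allclose(out, -100.0)

    def test_epsilon_inversion(self):
        # floor -85 dB corresponds to eps = 10^-8.5
        out = variable_noise_floor(np.zeros((4, 4)), -85.0)
        np.testing.assert_allclose(out, -85.0)
        np.testing.assert_allclose(10 ** (out / 10), 10**-8.5)

    def test_strong_cell_unaffected_by_floor(self):
        for floor in (-105.0, -85.0):
            out = variable_noise_floor(np.array([[1.0]]), floor)
            assert out[0, 0] == pytest.approx(0.0, abs=0.001)

    def test_positive_floor_rejected(self):
        with pytest.raises(ValueError):
            variable_noise_floor(np.zeros((2, 2)), 3.0)


class TestAlterDistance:
    def test_zero_tilt_is_identity(self):
        spec = np.random.default_rng(0).normal(size=(10, 7))
        np.testing.assert_array_equal(alter_distance(spec, 0.0), spec)

    def test_linear_tilt_endpoints(self):
        spec = np.zeros((11, 5))
        out = alter_distance(spec, -6.0)
        np.testing.assert_allclose(out[0], 0.0)
        np.testing.assert_allclose(out[-1], -6.0)
        np.testing.assert_allclose(out[5], -3.0)  # middle row = l/2

    def test_same_offset_every_frame(self):
        out = alter_distance(np.zeros((6, 9)), 4.0)
        assert np.all(out == out[:, :1])


class TestChain:
    def test_non_focal_never_echo_or_infuse(self):
        chain = build_chain("non-focal", seed=3)
        kinds = {s.kind for s in chain.specs}
        assert "echo" not in kinds and "background_infuse" not in kinds

    def test_noise_floor_always_applied(self):
        for prov in ("focal", "non-focal"):
            chain = build_chain(prov, seed=5)
            plans = [chain.draw_plan() for _ in range(500)]
            assert all("variable_noise_floor" in p for p in plans)

    def test_unknown_provenance_rejected(self):
        with pytest.raises(ValueError):
            build_chain("studio")

    def test_focal_application_frequencies(self):
        # Monte-Carlo frequency oracle over 10 000 seeded draws
        chain = build_chain("focal", seed=11)
        n = 10_000
        counts = {k: 0 for k in ("echo", "volume_ramp", "background_infuse",
                                 "gaussian_noise", "alter_distance")}
        gauss_given_not_infused = [0, 0]
        for _ in range(n):
            plan = chain.draw_plan()
            for k in counts:
                counts[k] += k in plan
            if "background_infuse" not in plan:
                gauss_given_not_infused[1] += 1
                gauss_given_not_infused[0] += "gaussian_noise" in plan
        assert counts["echo"] / n == pytest.approx(0.20, abs=0.02)
        assert counts["volume_ramp"] / n == pytest.approx(0.33, abs=0.02)
        assert counts["background_infuse"] / n == pytest.approx(0.67, abs=0.02)
        assert counts["alter_distance"] / n == pytest.approx(0.33, abs=0.02)
        # conditional Gaussian noise: 25% of the non-infused inputs, never infused ones
        assert gauss_given_not_infused[0] / gauss_given_not_infused[1] == pytest.approx(0.25, abs=0.02)
        assert counts["gaussian_noise"] / n == pytest.approx(0.25 * 0.33, abs=0.02)

    def test_non_focal_frequencies(self):
        chain = build_chain("non-focal", seed=13)
        n = 10_000
        gauss = ramp = alter = 0
        for _ in range(n):
            plan = chain.draw_plan()
            gauss += "gaussian_noise" in plan
            ramp += "volume_ramp" in plan
            alter += "alter_distance" in plan
        assert gauss / n == pytest.approx(0.75, abs=0.02)
        assert ramp / n == pytest.approx(0.33, abs=0.02)
        assert alter / n == pytest.approx(0.25, abs=0.02)

    def test_chain_determinism(self, tone):
        pool = [np.random.default_rng(9).normal(size=len(tone))]
        a = build_chain("focal", seed=21).process(tone, RATE, pool)
        b = build_chain("focal", seed=21).process(tone, RATE, pool)
        np.testing.assert_array_equal(a, b)
        assert a.shape == (204, 319)

    def test_parameters_drawn_within_ranges(self):
        chain = build_chain("focal", seed=17)
        for _ in range(300):
            plan = chain.draw_plan()
            if "echo" in plan:
                assert -24 <= plan["echo"]["l_db"] <= -15
                assert 1 <= plan["echo"]["t_ms"] <= 6
            if "gaussian_noise" in plan:
                assert -24 <= plan["gaussian_noise"]["l_db"] <= -15
            assert -105 <= plan["variable_noise_floor"]["floor_db"] <= -85
            if "alter_distance" in plan:
                assert -6 <= plan["alter_distance"]["l_db"] <= -3
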