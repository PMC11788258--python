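"""Scene layer: motion waveform, phantom geometry and WET line integrals."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pbtrack import scene


# ---------------------------------------------------------------------------
# motion waveform
# ---------------------------------------------------------------------------


class TestDisplacement:
    def test_as_printed_literal_values(self):
        m = scene.MotionModel(20.0, 24.0, "as_printed")
        assert scene.displacement(0.0, m) == pytest.approx(-20.0)
        assert scene.displacement(6.0, m) == pytest.approx(60.0)

    def test_peak_to_peak_endpoints(self):
        m = scene.MotionModel(20.0, 24.0, "peak_to_peak")
        assert scene.displacement(0.0, m) == pytest.approx(0.0)
        assert scene.displacement(12.0, m) == pytest.approx(20.0)

    def test_peak_to_peak_range_and_mean(self):
        m = scene.MotionModel(20.0, 24.0)
        t = np.linspace(0, 24, 4801)
        y = scene.displacement(t, m)
        assert y.min() >= 0.0 and y.max() <= 20.0
        assert m.mean_displacement == pytest.approx(10.0)
        assert np.trapezoid(y, t) / 24.0 == pytest.approx(10.0, abs=1e-6)

    @settings(derandomize=True, max_examples=60)
    @given(
        t=st.floats(-100, 100),
        amp=st.floats(0, 50),
        period=st.floats(0.5, 60),
        variant=st.sampled_from(["as_printed", "peak_to_peak"]),
    )
    def test_periodicity(self, t, amp, period, variant):
        """displacement(t) == displacement(t + P) with P the variant's
        fundamental period (T/2 for the literal waveform, T otherwise)."""
        m = scene.MotionModel(amp, period, variant)
        y0 = scene.displacement(t, m)
        y1 = scene.displacement(t + m.fundamental_period, m)
        assert abs(y0 - y1) < 1e-9 * max(1.0, amp)

    def test_nonfinite_time_rejected(self):
        m = scene.MotionModel(20.0, 24.0)
        with pytest.raises(ValueError):
            scene.displacement(np.nan, m)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            scene.MotionModel(20.0, 0.0)
        with pytest.raises(ValueError):
            scene.MotionModel(-1.0, 24.0)
        with pytest.raises(ValueError):
            scene.MotionModel(1.0, 1.0, "sawtooth")


# ---------------------------------------------------------------------------
# phantoms and WET integrals
# ---------------------------------------------------------------------------


def ray_march_wet(phantom, origin, direction, step=0.01, length=600.0):
    """Independent oracle: fine-step numerical ray marching with the same
    later-primitive-wins overlap rule."""
    direction = np.asarray(direction, float)
    direction = direction / np.linalg.norm(direction)
    ts = np.arange(0.0, length, step) + step / 2.0
    pts = np.asarray(origin, float)[None, :] + ts[:, None] * direction[None, :]
    rsp = np.full(ts.shape, phantom.background.rsp)
    for p in phantom.primitives:
        rsp[p.contains(pts)] = p.material.rsp
    return float(rsp.sum() * step)


class TestSlabPhantom:
    def test_central_ray_wet(self, slab_phantom):
        wet = scene.wet_line_integral(slab_phantom, (0, 0, -500), (0, 0, 1))
        assert wet == pytest.approx(110 * 1.16 + 30.0)

    def test_off_center_sphere_chord(self, slab_phantom):
        wet = scene.wet_line_integral(slab_phantom, (10, 0, -500), (0, 0, 1))
        chord = 2 * np.sqrt(15.0**2 - 10.0**2)
        assert wet == pytest.approx(110 * 1.16 + chord, abs=1e-9)

    def test_ray_missing_sphere(self, slab_phantom):
        wet = scene.wet_line_integral(slab_phantom, (20, 0, -500), (0, 0, 1))
        assert wet == pytest.approx(110 * 1.16)

    def test_empty_phantom_is_zero(self):
        dummy = scene.Primitive("d", "sphere", scene.AIR, dict(center=[0, 0, 0], radius=1.0), moving=True)
        ph = scene.PhantomModel([dummy], "d")
        assert scene.wet_line_integral(ph, (50, 50, -100), (0, 0, 1)) == 0.0

    def test_homogeneous_slab_any_parallel_ray(self):
        slab = scene.Primitive("s", "slab", scene.PMMA, dict(lo=[-50, -50, 0], hi=[50, 50, 110]))
        dummy = scene.Primitive("d", "sphere", scene.AIR, dict(center=[0, 0, 900], radius=1.0), moving=True)
        ph = scene.PhantomModel([slab, dummy], "d")
        for x, y in [(0, 0), (-30, 10), (49, -49)]:
            assert scene.wet_line_integral(ph, (x, y, -10), (0, 0, 1)) == pytest.approx(110 * 1.16)


class TestThoraxPhantom:
    def test_insert_contrast_is_chord_times_rsp_difference(self, thorax_phantom):
        """A ray through the insert centre exceeds a parallel lung-only ray
        (same vertical level) by the sphere chord times the lung-insert RSP
        contrast."""
        wet_insert = scene.wet_line_integral(thorax_phantom, (0, 0, -500), (0, 0, 1))
        wet_lung = scene.wet_line_integral(thorax_phantom, (60, 0, -500), (0, 0, 1))
        assert wet_insert - wet_lung == pytest.approx(30.0 * (1.00 - 0.21), abs=1e-9)

    def test_invariants(self):
        ph = scene.build_thorax_phantom(10.0)
        assert sum(p.moving for p in ph.primitives) == 1
        assert ph.moving_primitive.name == ph.moving_primitive_id
        assert all(p.material.rsp >= 0 and np.isfinite(p.material.rsp) for p in ph.primitives)

    def test_displaced_sphere_leaves_original_ray(self, thorax_phantom):
        shifted = thorax_phantom.translated_moving(40.0)
        wet0 = scene.wet_line_integral(thorax_phantom, (0, 0, -500), (0, 0, 1))
        wet1 = scene.wet_line_integral(shifted, (0, 0, -500), (0, 0, 1))
        assert wet1 == pytest.approx(wet0 - 30.0 * (1.00 - 0.21), abs=1e-9)

    def test_nonpositive_diameter_rejected(self):
        with pytest.raises(ValueError):
            scene.build_thorax_phantom(0.0)

    def test_matches_ray_marching_oracle(self, thorax_phantom):
        """Exact integrator vs 0.01 mm ray-marching on random rays."""
        rng = np.random.default_rng(42)
        for _ in range(40):
            origin = np.array([rng.uniform(-60, 60), rng.uniform(-60, 60), -300.0])
            d = np.array([rng.uniform(-0.2, 0.2), rng.uniform(-0.2, 0.2), 1.0])
            exact = scene.wet_line_integral(thorax_phantom, origin, d)
            marched = ray_march_wet(thorax_phantom, origin, d)
            assert exact == pytest.approx(marched, abs=0.05)

    def test_fast_parallel_path_matches_general_integrator(self, thorax_phantom):
        motion = scene.MotionModel(20.0, 24.0)
        rng = np.random.default_rng(1)
        xs = rng.uniform(-60, 60, 50)
        ys = rng.uniform(-40, 40, 50)
        ts = rng.uniform(0, 24, 50)
        fast = scene.wet_parallel_rays(thorax_phantom, xs, ys, ts, motion)
        for i in range(50):
            gen = scene.wet_line_integral(thorax_phantom, (xs[i], ys[i], -500), (0, 0, 1), ts[i], motion)
            assert fast[i] == pytest.approx(gen, abs=1e-8)


class TestWetProperties:
    @settings(derandomize=True, max_examples=30)
    @given(x=st.floats(-40, 40), y=st.floats(-40, 40))
    def test_additivity_over_disjoint_materials(self, x, y):
        """WET of slabs + sphere equals WET(slabs) + WET(sphere): the line
        integral is additive over disjoint segments."""
        full = scene.build_slab_phantom()
        slabs_only = scene.PhantomModel(
            [p for p in full.primitives if p.shape == "slab"]
            + [scene.Primitive("d", "sphere", scene.AIR, dict(center=[0, 0, 900], radius=1.0), moving=True)],
            "d",
        )
        sphere_only = scene.PhantomModel([full.get("insert")], "insert")
        o, d = (x, y, -500), (0, 0, 1)
        assert scene.wet_line_integral(full, o, d) == pytest.approx(
            scene.wet_line_integral(slabs_only, o, d) + scene.wet_line_integral(sphere_only, o, d),
            abs=1e-9,
        )

    def test_translation_consistency(self, slab_phantom):
        """Integral with the sphere displaced by d equals the static integral
        along the ray shifted by -d (lateral rays)."""
        motion = scene.MotionModel(20.0, 24.0)
        t = 5.3
        d = scene.displacement(t, motion)
        for x in np.linspace(-20, 20, 9):
            moved = scene.wet_line_integral(slab_phantom, (x, 0, -500), (0, 0, 1), t, motion)
            static = scene.wet_line_integral(slab_phantom, (x - d, 0, -500), (0, 0, 1))
            assert moved == pytest.approx(static, abs=1e-9)

    def test_degenerate_ray_rejected(self, slab_phantom):
        with pytest.raises(ValueError):
            scene.wet_line_integral(slab_phantom, (0, 0, 0), (0, 0, 0))


class TestSerialisation:
    def test_json_round_trip(self, thorax_phantom):
        ph = scene.phantom_from_json(scene.phantom_to_json(thorax_phantom))
        assert [p.name for p in ph.primitives] == [p.name for p in thorax_phantom.primitives]
        w0 = scene.wet_line_integral(thorax_phantom, (0, 5, -500), (0, 0, 1))
        w1 = scene.wet_line_integral(ph, (0, 5, -500), (0, 0, 1))
        assert w0 == pytest.approx(w1)

    def test_builder_dict(self):
        ph = scene.phantom_from_dict({"builder": "thorax", "insert_diameter": 20})
        assert ph.moving_primitive.params["radius"] == 10.0

    def test_motion_dict_round_trip(self):
        m = scene.MotionModel(15.0, 12.0, "as_printed", phase_offset=1.5)
        m2 = scene.motion_from_dict(scene.motion_to_dict(m))
        assert m2 == m
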