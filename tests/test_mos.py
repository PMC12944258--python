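"""Margin-of-stability reference computation: closed forms and pipeline."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import gaitmos as g
from gaitmos.errors import DataError, DetectionError
from gaitmos.types import MarkerFrameSeries


def _static_markers(n=100, dt=0.005, com=(0.0, 0.0, 0.9), toe_y=0.3):
    time = np.arange(n) * dt
    cx, cy, cz = com
    mk = lambda x, y, z: np.tile([x, y, z], (n, 1))
    return MarkerFrameSeries(
        time=time,
        positions={
            "ASIS_L": mk(cx - 0.1, cy, cz),
            "ASIS_R": mk(cx + 0.1, cy, cz),
            "TOE_L": mk(-0.1, toe_y, 0.0),
            "TOE_R": mk(0.1, toe_y, 0.0),
        },
    )


class TestComFromAsis:
    @pytest.mark.parametrize(
        "left,right,expected",
        [
            ((-0.1, 0, 0.9), (0.1, 0, 0.9), (0, 0, 0.9)),
            ((0.2, 0.1, 0.8), (0.2, 0.1, 0.8), (0.2, 0.1, 0.8)),
            ((0, 0.02, 0.88), (0.2, 0.04, 0.90), (0.1, 0.03, 0.89)),
        ],
    )
    def test_midpoint(self, left, right, expected):
        n = 10
        time = np.arange(n) * 0.005
        markers = MarkerFrameSeries(
            time=time,
            positions={
                "ASIS_L": np.tile(left, (n, 1)),
                "ASIS_R": np.tile(right, (n, 1)),
                "TOE_L": np.tile([0, 0.3, 0], (n, 1)),
                "TOE_R": np.tile([0, 0.3, 0], (n, 1)),
            },
        )
        com = g.com_from_asis(markers)
        np.testing.assert_allclose(com, np.tile(expected, (n, 1)), atol=1e-15)

    def test_missing_marker_rejected(self):
        with pytest.raises(g.SchemaError, match="ASIS_R"):
            MarkerFrameSeries(
                time=np.arange(5) * 0.01,
                positions={
                    "ASIS_L": np.zeros((5, 3)),
                    "TOE_L": np.zeros((5, 3)),
                    "TOE_R": np.zeros((5, 3)),
                },
            )


class TestComVelocity:
    def test_linear_position_gives_constant_velocity(self):
        t = np.arange(50) * 0.01
        pos = np.column_stack([np.zeros(50), 0.5 * t, np.zeros(50)])
        v = g.com_velocity(pos, 0.01)
        np.testing.assert_allclose(v[:, 1], 0.5, atol=1e-12)
        np.testing.assert_allclose(v[:, 0], 0.0, atol=1e-12)

    def test_constant_position_gives_zero(self):
        v = g.com_velocity(np.ones((20, 3)), 0.01)
        np.testing.assert_allclose(v, 0.0, atol=1e-15)

    def test_central_difference_exact_on_quadratic(self):
        dt = 0.01
        t = np.arange(0, 2, dt)
        pos = np.column_stack([t**2, t**2, t**2])
        v = g.com_velocity(pos, dt)
        i = int(round(1.0 / dt))  # interior point t = 1
        np.testing.assert_allclose(v[i], 2.0, rtol=1e-12)

    def test_too_few_samples(self):
        with pytest.raises(DataError):
            g.com_velocity(np.zeros((2, 3)), 0.01)


class TestNaturalFrequency:
    def test_values(self):
        assert g.natural_frequency(9.81) == pytest.approx(1.0)
        assert g.natural_frequency(1.0) == pytest.approx(np.sqrt(9.81))

    def test_nonpositive_height(self):
        with pytest.raises(DataError):
            g.natural_frequency(0.0)


class TestExtrapolatedCom:
    def test_velocity_extrapolation(self):
        out = g.extrapolated_com(
            np.array([0.0, 0.0]), np.array([0.1, 0.2]), omega=2.0
        )
        np.testing.assert_allclose(out, [0.05, 0.10])

    def test_identity_limit(self):
        x = np.array([0.3, -0.2])
        out = g.extrapolated_com(x, np.zeros(2), omega=2.0, belt_speed=0.0)
        np.testing.assert_allclose(out, x)

    def test_belt_speed_added_to_anterior(self):
        out = g.extrapolated_com(
            np.zeros(2), np.zeros(2), omega=2.0, belt_speed=3.0 / 3.6
        )
        np.testing.assert_allclose(out, [0.0, 0.41666667], atol=1e-6)

    def test_bad_omega(self):
        with pytest.raises(DataError):
            g.extrapolated_com(np.zeros(2), np.zeros(2), omega=0.0)


class TestMargins:
    @pytest.mark.parametrize(
        "bos,xcom,expected", [(0.30, 0.25, 0.05), (0.2, 0.2, 0.0), (0.20, 0.26, -0.06)]
    )
    def test_anterior_signed(self, bos, xcom, expected):
        assert g.anterior_mos(bos, xcom) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "bos,xcom,expected", [(0.10, 0.02, 0.08), (0.02, 0.10, 0.08), (0.5, 0.5, 0.0)]
    )
    def test_mediolateral_absolute(self, bos, xcom, expected):
        assert g.mediolateral_mos(bos, xcom) == pytest.approx(expected)

    @settings(derandomize=True, max_examples=50)
    @given(
        a=st.floats(-10, 10, allow_nan=False),
        b=st.floats(-10, 10, allow_nan=False),
    )
    def test_mediolateral_nonnegative_and_symmetric(self, a, b):
        assert g.mediolateral_mos(a, b) >= 0
        assert g.mediolateral_mos(a, b) == g.mediolateral_mos(b, a)


class TestHeelContactDetection:
    def test_constant_toes_rejected(self):
        with pytest.raises(DetectionError):
            g.detect_heel_contacts(_static_markers(), belt_speed=0.8)

    def test_antiphase_sinusoids_alternate_at_half_period(self):
        # toe anterior position a pure sinusoid, feet phase-shifted by T/2:
        # peaks (heel contacts) alternate every T/2
        dt, T = 0.005, 1.2
        t = np.arange(0, 6, dt)
        n = t.size
        mk = lambda y: np.column_stack([np.zeros(n), y, np.zeros(n)])
        markers = MarkerFrameSeries(
            time=t,
            positions={
                "ASIS_L": np.tile([-0.1, 0, 0.9], (n, 1)),
                "ASIS_R": np.tile([0.1, 0, 0.9], (n, 1)),
                "TOE_L": mk(0.3 + 0.1 * np.sin(2 * np.pi * t / T)),
                "TOE_R": mk(0.3 + 0.1 * np.sin(2 * np.pi * (t - T / 2) / T)),
            },
        )
        events = g.detect_heel_contacts(markers, belt_speed=0.8)
        gaps = np.diff(events.times)
        np.testing.assert_allclose(gaps, T / 2, atol=2 * dt)
        assert all(
            events.feet[i] != events.feet[i + 1]
            for i in range(len(events) - 1)
        )

    def test_recovers_generator_events_within_one_sample(self, trial):
        detected = g.detect_heel_contacts(
            trial.markers, belt_speed=trial.speed_kmh / 3.6
        )
        dt = trial.markers.dt
        for t_true, foot in zip(trial.events.times, trial.events.feet):
            mask = np.array([f == foot for f in detected.feet])
            err = np.min(np.abs(detected.times[mask] - t_true))
            assert err <= dt + 1e-12


class TestMosSeries:
    def test_static_posture_constant_anterior_margin(self):
        markers = _static_markers(toe_y=0.3)
        events = g.HeelContactSeries(times=[0.0], feet=["left"])
        series = g.mos_series(markers, belt_speed=0.0, events=events)
        # v = 0, belt = 0: XCoM = CoM, so margin is just bos_y - com_y
        np.testing.assert_allclose(series.anterior, 0.3, atol=1e-12)

    def test_anterior_margin_strictly_decreasing_in_belt_speed(self):
        markers = _static_markers()
        events = g.HeelContactSeries(times=[0.0], feet=["left"])
        prev = g.mos_series(markers, 0.0, events).anterior
        for belt in (0.3, 0.6, 1.2):
            cur = g.mos_series(markers, belt, events).anterior
            assert np.all(cur < prev)
            prev = cur

    def test_mirror_symmetry_of_mediolateral_margin(self, trial):
        """Swapping left/right markers and negating x leaves |ML MoS| unchanged."""
        m = trial.markers
        belt = trial.speed_kmh / 3.6
        flipped_positions = {}
        swap = {
            "ASIS_L": "ASIS_R",
            "ASIS_R": "ASIS_L",
            "TOE_L": "TOE_R",
            "TOE_R": "TOE_L",
        }
        for name, other in swap.items():
            p = m.positions[other].copy()
            p[:, 0] = -p[:, 0]
            flipped_positions[name] = p
        flipped = MarkerFrameSeries(time=m.time, positions=flipped_positions)
        ev_flip = g.HeelContactSeries(
            times=trial.events.times,
            feet=np.array(
                ["left" if f == "right" else "right" for f in trial.events.feet],
                dtype=object,
            ),
        )
        a = g.mos_series(m, belt, trial.events)
        b = g.mos_series(flipped, belt, ev_flip)
        np.testing.assert_allclose(b.mediolateral, a.mediolateral, atol=1e-12)
        np.testing.assert_allclose(b.anterior, a.anterior, atol=1e-12)


class TestMinMosPerStep:
    def _series(self, anterior, ml=None, dt=0.01):
        n = len(anterior)
        t = np.arange(n) * dt
        ml = np.full(n, 0.05) if ml is None else ml
        return g.MosSeries(time=t, anterior=np.asarray(anterior), mediolateral=ml)

    def test_constant_series(self):
        series = self._series(np.full(100, 0.02))
        events = g.HeelContactSeries(
            times=[0.0, 0.4, 0.8], feet=["left", "right", "left"]
        )
        labels = g.min_mos_per_step(series, events)
        assert len(labels) == 2
        for lab in labels:
            assert lab.min_anterior_mm == pytest.approx(20.0)
            assert lab.min_mediolateral_mm == pytest.approx(50.0)
        assert labels[0].support_foot == "left"
        assert labels[1].support_foot == "right"

    def test_single_dip_located(self):
        ant = np.full(100, 0.02)
        ant[30] = -0.0154  # dip inside the first step
        series = self._series(ant)
        events = g.HeelContactSeries(
            times=[0.0, 0.5, 0.99], feet=["left", "right", "left"]
        )
        labels = g.min_mos_per_step(series, events)
        assert labels[0].min_anterior_mm == pytest.approx(-15.4)
        assert labels[1].min_anterior_mm == pytest.approx(20.0)

    def test_too_few_events(self):
        series = self._series(np.zeros(10))
        with pytest.raises(DataError):
            g.min_mos_per_step(
                series, g.HeelContactSeries(times=[0.0], feet=["left"])
            )


class TestPipelineConsistency:
    def test_marker_pipeline_reproduces_generator_truth(self, trial):
        """Full marker -> label path matches the analytic truth to 1e-6 m."""
        labels, _, _ = g.reference_labels(
            trial.markers,
            trial.speed_kmh / 3.6,
            events=trial.events,
            participant=trial.participant,
            speed_kmh=trial.speed_kmh,
        )
        assert len(labels) == len(trial.truth)
        ant = np.array([l.min_anterior_mm for l in labels])
        ml = np.array([l.min_mediolateral_mm for l in labels])
        np.testing.assert_allclose(
            ant, trial.truth["min_anterior_mm"].to_numpy(), atol=1e-3
        )
        np.testing.assert_allclose(
            ml, trial.truth["min_mediolateral_mm"].to_numpy(), atol=1e-3
        )
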