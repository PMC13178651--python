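"""Bead-track I/O, drift correction and GLT displacement metrics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from airglt import simulate, tracks
from conftest import make_linear_track


class TestReadWriteTracks:
    def test_round_trip(self, tmp_path):
        originals = [
            make_linear_track("0", velocity=(1.0, 0.5)),
            make_linear_track("1", velocity=(-0.5, 0.2), origin=(10, 10)),
        ]
        path = tracks.write_tracks(originals, tmp_path / "tracks.csv")
        loaded = tracks.read_tracks(path)
        assert len(loaded) == 2
        for orig, back in zip(originals, loaded):
            assert len(back) == len(orig)
            np.testing.assert_allclose(back.x, orig.x)
            np.testing.assert_allclose(back.y, orig.y)
            np.testing.assert_allclose(back.t, orig.t)

    def test_trackmate_extra_header_rows_tolerated(self, tmp_path):
        # TrackMate spots exports carry label/units rows under the header
        path = tmp_path / "spots.csv"
        path.write_text(
            "TRACK_ID,FRAME,POSITION_X,POSITION_Y,POSITION_T\n"
            "Track ID,Frame,X,Y,T\n"
            ",,(micron),(micron),(sec)\n"
            "0,0,1.0,2.0,0.0\n"
            "0,1,1.5,2.5,0.01\n"
        )
        loaded = tracks.read_tracks(path)
        assert len(loaded) == 1 and len(loaded[0]) == 2

    def test_missing_column_named_in_error(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("TRACK_ID,FRAME,POSITION_X\n0,0,1.0\n")
        with pytest.raises(tracks.FormatError, match="POSITION_Y"):
            tracks.read_tracks(path, frame_rate=100.0)

    def test_duplicate_frame_rejected(self, tmp_path):
        path = tmp_path / "dup.csv"
        path.write_text(
            "TRACK_ID,FRAME,POSITION_X,POSITION_Y,POSITION_T\n"
            "0,0,1.0,2.0,0.0\n0,0,1.1,2.1,0.0\n"
        )
        with pytest.raises(tracks.FormatError, match="duplicate"):
            tracks.read_tracks(path)

    def test_frame_rate_fallback_without_time_column(self, tmp_path):
        path = tmp_path / "nt.csv"
        path.write_text("TRACK_ID,FRAME,POSITION_X,POSITION_Y\n0,0,1,1\n0,5,2,2\n")
        (tr,) = tracks.read_tracks(
            path,
            column_map={"track_id": "TRACK_ID", "frame": "FRAME",
                        "x": "POSITION_X", "y": "POSITION_Y"},
            frame_rate=100.0,
        )
        assert tr.t[-1] == pytest.approx(0.05)

    def test_simulator_output_reads_back_identically(self, tmp_path, noiseless_track_params):
        table, _ = simulate.simulate_tracks(noiseless_track_params)
        path = tmp_path / "sim.csv"
        table.to_csv(path, index=False)
        loaded = tracks.read_tracks(path)
        assert len(loaded) == noiseless_track_params.n_beads
        first = table[table["TRACK_ID"] == 0]
        np.testing.assert_allclose(loaded[0].x, first["POSITION_X"].to_numpy())


class TestCompletenessFilter:
    def test_full_span_kept_truncated_excluded(self, protocol):
        full = make_linear_track("full", t_start=0.0, t_end=15.0)
        short = make_linear_track("short", t_start=0.0, t_end=9.0)
        late = make_linear_track("late", t_start=2.0, t_end=15.0)
        kept, excluded = tracks.filter_complete_tracks([full, short, late], protocol)
        assert [tr.track_id for tr in kept] == ["full"]
        assert {tr.track_id for tr, _ in excluded} == {"short", "late"}
        assert len(kept) + len(excluded) == 3

    def test_one_frame_slack_allowed(self, protocol):
        almost = make_linear_track("a", t_start=0.05, t_end=14.95, frame_rate=10.0)
        kept, excluded = tracks.filter_complete_tracks([almost], protocol)
        assert len(kept) == 1 and not excluded

    def test_empty_input(self, protocol):
        assert tracks.filter_complete_tracks([], protocol) == ([], [])


class TestDriftEstimation:
    def test_stationary_beads_zero_drift(self, protocol):
        field = [make_linear_track(str(i), origin=(i, i)) for i in range(12)]
        drift = tracks.estimate_ciliary_drift(field, protocol=protocol)
        assert drift.vx == drift.vy == 0.0
        assert drift.n_particles == 12

    def test_uniform_translation_recovered_exactly(self, protocol):
        field = [
            make_linear_track(str(i), velocity=(1.0, 2.0), origin=(i, 0))
            for i in range(15)
        ]
        drift = tracks.estimate_ciliary_drift(field, protocol=protocol)
        assert drift.vx == pytest.approx(1.0)
        assert drift.vy == pytest.approx(2.0)

    def test_noisy_drift_within_three_se(self, protocol):
        """Monte-Carlo: drift (0.5, -0.3) um/s + 0.05 um noise, 15 beads."""
        params = simulate.TrackSimParams(
            n_beads=15, drift=(0.5, -0.3), localization_noise_sd=0.05, seed=7,
            protocol=protocol,
        )
        table, truth = simulate.simulate_tracks(params)
        loaded = _tracks_from_table(table)
        drift = tracks.estimate_ciliary_drift(loaded, protocol=protocol)
        # SE of an endpoint-difference velocity over the 5 s window
        se = np.sqrt(2) * 0.05 / 5.0 / np.sqrt(15)
        assert abs(drift.vx - 0.5) < 3 * se
        assert abs(drift.vy - (-0.3)) < 3 * se

    def test_insufficient_window_data_raises(self, protocol):
        tr = make_linear_track("0", t_start=6.0, t_end=15.0)
        with pytest.raises(tracks.InsufficientDataError):
            tracks.estimate_ciliary_drift([tr], protocol=protocol)

    def test_field_size_warning(self):
        with pytest.warns(UserWarning, match="particles"):
            tracks.DriftEstimate(vx=0.0, vy=0.0, n_particles=3)


class TestSubtractDrift:
    def test_zero_drift_identity(self):
        tr = make_linear_track("0", velocity=(1.0, -1.0))
        out = tracks.subtract_drift(tr, tracks.ZERO_DRIFT)
        np.testing.assert_array_equal(out.x, tr.x)

    def test_pure_drift_becomes_stationary(self):
        tr = make_linear_track("0", velocity=(0.7, -0.2), origin=(5.0, 5.0))
        out = tracks.subtract_drift(tr, tracks.DriftEstimate(0.7, -0.2, 15))
        np.testing.assert_allclose(out.x, 5.0, atol=1e-9)
        np.testing.assert_allclose(out.y, 5.0, atol=1e-9)

    def test_subtract_then_add_inverts(self):
        tr = make_linear_track("0", velocity=(0.3, 0.9))
        drift = tracks.DriftEstimate(0.3, 0.9, 15)
        neg = tracks.DriftEstimate(-0.3, -0.9, 15)
        back = tracks.subtract_drift(tracks.subtract_drift(tr, drift), neg)
        np.testing.assert_allclose(back.x, tr.x, atol=1e-9)
        np.testing.assert_allclose(back.y, tr.y, atol=1e-9)


class TestInstantaneousVelocities:
    def test_uniform_motion_constant_speed(self):
        tr = make_linear_track("0", velocity=(10.0, 0.0), t_end=1.0, frame_rate=100.0)
        vel = tracks.instantaneous_velocities(tr)
        np.testing.assert_allclose(vel["speed"], 10.0, rtol=1e-9)

    def test_stationary_zero_speed(self):
        tr = make_linear_track("0")
        assert tracks.instantaneous_velocities(tr)["speed"].max() == 0.0

    def test_peak_speed_falls_in_pulse_window(self, protocol, noiseless_track_params):
        table, _ = simulate.simulate_tracks(noiseless_track_params)
        tr = _tracks_from_table(table)[0]
        vel = tracks.instantaneous_velocities(tr)
        t_peak = vel.loc[vel["speed"].idxmax(), "t"]
        assert protocol.t_pulse_start <= t_peak <= protocol.t_pulse_end


def _tracks_from_table(table: pd.DataFrame) -> list:
    out = []
    for tid, grp in table.groupby("TRACK_ID"):
        out.append(
            tracks.Track(
                track_id=str(tid),
                frame=grp["FRAME"].to_numpy(),
                t=grp["POSITION_T"].to_numpy(),
                x=grp["POSITION_X"].to_numpy(),
                y=grp["POSITION_Y"].to_numpy(),
            )
        )
    return out


def _step_track(pulse_step=20.0, recoil_step=-5.0, protocol=None):
    """Piecewise-linear along-x track: +pulse_step during pulse, recoil after."""
    protocol = protocol or tracks.PulseProtocol()
    t = np.arange(0.0, 15.01, 0.1)
    x = np.zeros_like(t)
    pulse = (t >= protocol.t_pulse_start) & (t <= protocol.t_pulse_end)
    x[pulse] = pulse_step * (t[pulse] - protocol.t_pulse_start) / 5.0
    after = t > protocol.t_pulse_end
    x[after] = pulse_step + recoil_step * (t[after] - protocol.t_pulse_end) / 5.0
    return tracks.Track(
        track_id="0", frame=np.arange(len(t)), t=t, x=x, y=np.zeros_like(t)
    )


class TestPulseMetrics:
    def test_forced_example(self, protocol):
        """+20 um during pulse, -5 um recoil -> net 15, recovery 25%."""
        m = tracks.pulse_metrics(_step_track(20.0, -5.0), protocol)
        assert m.pulse_displacement == pytest.approx(20.0)
        assert m.recoil_distance == pytest.approx(-5.0)
        assert m.net_displacement == pytest.approx(15.0)
        assert m.percent_recovery == pytest.approx(25.0)

    def test_no_motion_all_zero(self, protocol):
        m = tracks.pulse_metrics(make_linear_track("0"), protocol)
        assert m.pulse_displacement == m.net_displacement == 0.0
        assert m.percent_recovery == 0.0

    def test_incomplete_track_rejected(self, protocol):
        import dataclasses
        tr = dataclasses.replace(make_linear_track("0"), complete=False)
        with pytest.raises(ValueError, match="incomplete"):
            tracks.pulse_metrics(tr, protocol)

    def test_signed_additivity(self, protocol):
        """net = pulse + recoil for arbitrary shaped tracks."""
        for pulse_step, recoil_step in [(20, -5), (-8, 3), (12, 0), (0.5, -0.4)]:
            m = tracks.pulse_metrics(_step_track(pulse_step, recoil_step), protocol)
            assert m.net_displacement == pytest.approx(
                m.pulse_displacement + m.recoil_distance, abs=1e-9
            )

    @given(
        vx=st.floats(-2.0, 2.0, allow_nan=False),
        vy=st.floats(-2.0, 2.0, allow_nan=False),
    )
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_drift_invariance_noiseless(self, vx, vy):
        """Adding any constant drift leaves drift-corrected metrics unchanged
        when the estimator sees noiseless data."""
        protocol = tracks.PulseProtocol()
        base = _step_track(20.0, -5.0)
        m_base = tracks.pulse_metrics(base, protocol)
        drifted = tracks.Track(
            track_id="0", frame=base.frame, t=base.t,
            x=base.x + vx * base.t, y=base.y + vy * base.t,
        )
        est = tracks.estimate_ciliary_drift(
            [drifted] * 10, protocol=protocol
        )
        m = tracks.pulse_metrics(drifted, protocol, est)
        assert m.pulse_displacement == pytest.approx(m_base.pulse_displacement, abs=1e-7)
        assert m.net_displacement == pytest.approx(m_base.net_displacement, abs=1e-7)

    def test_axis_rotation_consistency(self, protocol):
        """Rotating coordinates and axis together leaves metrics unchanged."""
        theta = 0.7
        c, s = np.cos(theta), np.sin(theta)
        base = _step_track(20.0, -5.0)
        rotated = tracks.Track(
            track_id="0", frame=base.frame, t=base.t,
            x=c * base.x - s * base.y, y=s * base.x + c * base.y,
        )
        proto_rot = tracks.PulseProtocol(airflow_axis=(c, s))
        m0 = tracks.pulse_metrics(base, protocol)
        m1 = tracks.pulse_metrics(rotated, proto_rot)
        assert m1.pulse_displacement == pytest.approx(m0.pulse_displacement, abs=1e-9)
        assert m1.recoil_distance == pytest.approx(m0.recoil_distance, abs=1e-9)
        assert m1.net_displacement == pytest.approx(m0.net_displacement, abs=1e-9)


class TestEnsembleMetrics:
    def _metrics(self, net):
        return tracks.TrackMetrics(
            track_id="x", pulse_displacement=net, recoil_distance=0.0,
            net_displacement=net, percent_recovery=0.0, peak_velocity=1.0,
        )

    def test_identical_tracks_sd_zero(self):
        ens = tracks.ensemble_metrics([self._metrics(7.0)] * 5)
        assert ens.mean["net_displacement"] == 7.0
        assert ens.sd["net_displacement"] == 0.0
        assert ens.n_tracks == 5

    def test_two_values_mean(self):
        ens = tracks.ensemble_metrics([self._metrics(10.0), self._metrics(14.0)])
        assert ens.mean["net_displacement"] == pytest.approx(12.0)

    def test_single_track_warns(self):
        with pytest.warns(UserWarning, match="single track"):
            ens = tracks.ensemble_metrics([self._metrics(3.0)])
        assert ens.sd["net_displacement"] == 0.0

    def test_empty_rejected(self):
        with pytest.raises(tracks.InsufficientDataError):
            tracks.ensemble_metrics([])


class TestAnalyzePipeline:
    def test_exclusion_conservation(self, protocol):
        full = [make_linear_track(str(i), origin=(i, 0)) for i in range(11)]
        truncated = [make_linear_track("t1", t_end=8.0), make_linear_track("t2", t_start=3.0)]
        per_track, ensemble, _, excluded = tracks.analyze_tracks(full + truncated, protocol)
        assert ensemble.n_tracks + ensemble.n_excluded == 13
        excluded_ids = {tr.track_id for tr, _ in excluded}
        assert excluded_ids == {"t1", "t2"}
        assert not excluded_ids & {m.track_id for m in per_track}
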