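import numpy as np
import pytest

from zfsentinel.core_io import CalibrationInfo, GroupRecording, LandmarkSet, Trajectory


def make_group(
    positions_px,
    px_per_mm=1.0,
    frame_rate=30.0,
    arena=(308.0, 340.0),
    site="siteA",
    tank_id="tank1",
    duration_s=None,
):
    """GroupRecording from an (n_fish, n_frames, 2) array of pixel
    positions (NaN marks excluded frames)."""
    positions_px = np.asarray(positions_px, dtype=float)
    n_fish, n_frames, _ = positions_px.shape
    times = np.arange(n_frames) / frame_rate
    cal = CalibrationInfo(
        px_per_mm=px_per_mm,
        frame_rate=frame_rate,
        arena_width_mm=arena[0],
        arena_height_mm=arena[1],
    )
    trajectories = [
        Trajectory(fish_id=f"fish{i + 1}", times_s=times, positions_px=positions_px[i])
        for i in range(n_fish)
    ]
    return GroupRecording(
        site=site,
        tank_id=tank_id,
        trajectories=trajectories,
        calibration=cal,
        sample_duration_s=duration_s if duration_s is not None else n_frames / frame_rate,
    )


def make_landmark_set(coords, fish_id="f1", site="siteA", sex="male"):
    return LandmarkSet(fish_id=fish_id, site=site, sex=sex, landmarks_mm=np.asarray(coords, float))


@pytest.fixture
def rng():
    return np.random.default_rng(20210712)


@pytest.fixture
def seven_landmarks(rng):
    """A non-degenerate 7-landmark configuration in mm."""
    from zfsentinel.synthetic_data import load_template

    return load_template() * 20.0 + np.array([50.0, 60.0])
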