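import numpy as np
import pytest

from pawflux.trajectory_io import TrajectorySet, write_dlc_csv

SEVEN_PARTS = [
    "snout",
    "front_left",
    "front_right",
    "midpoint",
    "hind_left",
    "hind_right",
    "tail_base",
]


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def make_traj(rng):
    """Factory for small random TrajectorySets."""

    def _make(parts=None, n=100, fps=30.0, animal_id="a0", seed=None):
        parts = list(parts) if parts is not None else list(SEVEN_PARTS)
        r = np.random.default_rng(seed) if seed is not None else rng
        xy = r.normal(loc=100.0, scale=10.0, size=(len(parts), n, 2))
        return TrajectorySet(animal_id=animal_id, fps=fps, parts=parts, xy=xy)

    return _make


@pytest.fixture
def dlc_csv(tmp_path, make_traj):
    """Write a fully-observed 7-part, 100-frame fixture CSV; returns path."""

    def _write(traj=None, name="fixture.csv", likelihood=0.99):
        traj = traj if traj is not None else make_traj()
        path = tmp_path / name
        write_dlc_csv(traj, path)
        if likelihood != 1.0:
            text = path.read_text().splitlines()
            coords = text[2].split(",")
            out = text[:3]
            for line in text[3:]:
                cells = line.split(",")
                cells = [
                    str(likelihood) if coords[i] == "likelihood" else c
                    for i, c in enumerate(cells)
                ]
                out.append(",".join(cells))
            path.write_text("\n".join(out) + "\n")
        return path

    return _write
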