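"""Reading, validation and preprocessing of body-part trajectory tables.

The on-disk dialect is the DeepLabCut CSV layout: three header rows
(``scorer`` / ``bodyparts`` / ``coords``) and one ``x``, ``y``,
``likelihood`` triplet of columns per tracked body part.  Preprocessing
follows the recording pipeline: frames whose detection likelihood falls
below a threshold are treated as missing, gaps are filled from the
nearest previous observation (nearest following one for a missing
prefix), and a short running median filter suppresses jitter and
marker-swap anomalies.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import (
    EmptyInputError,
    FormatError,
    ParameterError,
    UnusablePartError,
)

__all__ = [
    "TrajectorySet",
    "LikelihoodSeries",
    "PROV_OBSERVED",
    "PROV_GAP_FILLED",
    "PROV_FILTERED",
    "read_dlc_csv",
    "write_dlc_csv",
    "fill_gaps",
    "median_filter",
    "preprocess",
    "as_series_matrix",
]

#: provenance codes stored per (part, frame)
PROV_OBSERVED = 0
PROV_GAP_FILLED = 1
PROV_FILTERED = 2

_HEADER_ROWS = ("scorer", "bodyparts", "coords")


@dataclass
class TrajectorySet:
    """Time-indexed 2-D positions for the tracked body parts of one animal.

    Parameters
    ----------
    animal_id : str
        Identifier of the recording / animal.
    fps : float
        Sampling rate in frames per second (> 0).
    parts : list of str
        Ordered, unique body-part labels.
    xy : ndarray, shape (m, N, 2)
        Positions per part and frame; NaN marks missing samples.
    provenance : ndarray of uint8, shape (m, N)
        Per-sample provenance flag (observed / gap-filled / filtered).
    """

    animal_id: str
    fps: float
    parts: list[str]
    xy: np.ndarray
    provenance: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.xy = np.asarray(self.xy, dtype=float)
        if self.xy.ndim != 3 or self.xy.shape[2] != 2:
            raise ParameterError(
                f"xy must have shape (m, N, 2), got {self.xy.shape}"
            )
        m, n, _ = self.xy.shape
        if m != len(self.parts):
            raise ParameterError(
                f"{len(self.parts)} part labels but {m} trajectories"
            )
        if m == 0:
            raise EmptyInputError("trajectory set has no body parts")
        if n < 1:
            raise EmptyInputError("trajectory set has zero frames")
        if len(set(self.parts)) != len(self.parts):
            raise ParameterError(f"duplicate part labels in {self.parts}")
        if not self.fps > 0:
            raise ParameterError(f"fps must be positive, got {self.fps}")
        if self.provenance is None:
            self.provenance = np.zeros((m, n), dtype=np.uint8)
        else:
            self.provenance = np.asarray(self.provenance, dtype=np.uint8)
            if self.provenance.shape != (m, n):
                raise ParameterError("provenance shape mismatch")

    @property
    def n_frames(self) -> int:
        return self.xy.shape[1]

    @property
    def n_parts(self) -> int:
        return self.xy.shape[0]

    @property
    def missing(self) -> np.ndarray:
        """Boolean mask (m, N): True where a sample is missing (NaN)."""
        return np.isnan(self.xy).any(axis=2)

    @property
    def duration_seconds(self) -> float:
        return self.n_frames / self.fps

    def part_index(self, part: str) -> int:
        try:
            return self.parts.index(part)
        except ValueError:
            raise ParameterError(
                f"unknown part {part!r}; available: {self.parts}"
            ) from None

    def replace(self, **kwargs) -> "TrajectorySet":
        return dataclasses.replace(self, **kwargs)

    def slice_frames(self, start: int, stop: int) -> "TrajectorySet":
        """Return the sub-recording covering frames [start, stop)."""
        return self.replace(
            xy=self.xy[:, start:stop].copy(),
            provenance=self.provenance[:, start:stop].copy(),
        )


@dataclass
class LikelihoodSeries:
    """Detection confidence in [0, 1] per part and frame."""

    parts: list[str]
    values: np.ndarray  # (m, N)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != len(self.parts):
            raise ParameterError("likelihood array shape mismatch")
        finite = self.values[np.isfinite(self.values)]
        if finite.size and (finite.min() < 0 or finite.max() > 1):
            raise ParameterError("likelihood values must lie in [0, 1]")


def read_dlc_csv(
    path,
    likelihood_threshold: float = 0.6,
    fps: float = 30.0,
    animal_id: str | None = None,
) -> tuple[TrajectorySet, LikelihoodSeries]:
    """Read a DeepLabCut-dialect CSV trajectory table.

    Frames whose likelihood is below ``likelihood_threshold`` (or whose
    coordinates are empty/NaN) are marked missing; call :func:`fill_gaps`
    to obtain a gap-free set.
    """
    if not 0 <= likelihood_threshold <= 1:
        raise ParameterError(
            f"likelihood_threshold must be in [0, 1], got {likelihood_threshold}"
        )
    try:
        df = pd.read_csv(path, header=[0, 1, 2], index_col=0)
    except (pd.errors.ParserError, ValueError) as exc:
        raise FormatError(f"{path}: cannot parse DLC CSV ({exc})") from exc
    except pd.errors.EmptyDataError as exc:
        raise EmptyInputError(f"{path}: file is empty") from exc

    if df.columns.nlevels != 3:
        raise FormatError(
            f"{path}: expected 3 header rows (scorer/bodyparts/coords), "
            f"found {df.columns.nlevels}"
        )
    names = [n.lower() if isinstance(n, str) else "" for n in df.columns.names]
    for row_i, expected in enumerate(_HEADER_ROWS):
        if names[row_i] != expected:
            raise FormatError(
                f"{path}: header row {row_i + 1} should be labelled "
                f"{expected!r}, found {df.columns.names[row_i]!r}"
            )
    if len(df) == 0:
        raise EmptyInputError(f"{path}: table contains no frames")

    parts = list(dict.fromkeys(df.columns.get_level_values(1)))
    n = len(df)
    xy = np.full((len(parts), n, 2), np.nan)
    lik = np.ones((len(parts), n))
    for pi, part in enumerate(parts):
        sub = df.xs(part, axis=1, level=1)
        cols = [c.lower() for c in sub.columns.get_level_values(-1)]
        if "x" not in cols or "y" not in cols:
            raise FormatError(
                f"{path}: part {part!r} lacks x/y columns (coords row has {cols})"
            )
        xy[pi, :, 0] = pd.to_numeric(
            sub.iloc[:, cols.index("x")], errors="coerce"
        ).to_numpy()
        xy[pi, :, 1] = pd.to_numeric(
            sub.iloc[:, cols.index("y")], errors="coerce"
        ).to_numpy()
        if "likelihood" in cols:
            lik[pi] = pd.to_numeric(
                sub.iloc[:, cols.index("likelihood")], errors="coerce"
            ).to_numpy()
    # gate undetected frames: likelihood below threshold counts as missing
    low = lik < likelihood_threshold
    xy[low] = np.nan

    if animal_id is None:
        animal_id = _stem(path)
    traj = TrajectorySet(animal_id=animal_id, fps=fps, parts=parts, xy=xy)
    return traj, LikelihoodSeries(parts=parts, values=lik)


def write_dlc_csv(traj: TrajectorySet, path, scorer: str = "pawflux") -> None:
    """Write a TrajectorySet in the same three-header-row CSV dialect.

    The likelihood column is emitted as 1.0 everywhere (synthetic data
    carries no detector confidence).
    """
    if traj.n_parts == 0:  # unreachable via constructor, kept for safety
        raise EmptyInputError("cannot write a trajectory set without parts")
    columns = pd.MultiIndex.from_tuples(
        [
            (scorer, part, coord)
            for part in traj.parts
            for coord in ("x", "y", "likelihood")
        ],
        names=list(_HEADER_ROWS),
    )
    data = np.empty((traj.n_frames, 3 * traj.n_parts))
    for pi in range(traj.n_parts):
        data[:, 3 * pi] = traj.xy[pi, :, 0]
        data[:, 3 * pi + 1] = traj.xy[pi, :, 1]
        data[:, 3 * pi + 2] = 1.0
    frame = pd.DataFrame(data, columns=columns)
    frame.to_csv(path, index=True)  # default float repr round-trips exactly


def fill_gaps(traj: TrajectorySet) -> TrajectorySet:
    """Replace missing samples with the previous observed value.

    A missing prefix is filled with the first observed value (the nearest
    neighbour in that case).  Idempotent; raises
    :class:`~pawflux.errors.UnusablePartError` if a part was never
    observed.
    """
    xy = traj.xy.copy()
    prov = traj.provenance.copy()
    for pi, part in enumerate(traj.parts):
        miss = np.isnan(xy[pi]).any(axis=1)
        if miss.all():
            raise UnusablePartError(
                f"part {part!r} has no observed samples at all"
            )
        if not miss.any():
            continue
        obs_idx = np.flatnonzero(~miss)
        # index of the previous observed sample for every frame
        prev = np.searchsorted(obs_idx, np.arange(traj.n_frames), side="right") - 1
        prev = obs_idx[np.clip(prev, 0, None)]  # prefix -> first observation
        xy[pi] = xy[pi, prev]
        prov[pi, miss] = PROV_GAP_FILLED
    return traj.replace(xy=xy, provenance=prov)


def median_filter(traj: TrajectorySet, window: int = 5) -> TrajectorySet:
    """Running median over a centred window of ``window`` frames.

    Edge frames use symmetrically shrunken windows so the length is
    preserved without inventing data.  ``window`` must be odd and at most
    the number of frames; gaps must have been filled first.
    """
    if window % 2 == 0 or window < 1:
        raise ParameterError(f"median window must be odd and >= 1, got {window}")
    if window > traj.n_frames:
        raise ParameterError(
            f"median window {window} exceeds recording length {traj.n_frames}"
        )
    if window == 1:
        return traj.replace(xy=traj.xy.copy(), provenance=traj.provenance.copy())
    half = window // 2
    xy = np.empty_like(traj.xy)
    n = traj.n_frames
    # interior: vectorized median over full windows
    if n >= window:
        view = np.lib.stride_tricks.sliding_window_view(traj.xy, window, axis=1)
        xy[:, half : n - half] = np.median(view, axis=-1)
    # edges: symmetrically shrunken centred windows
    for i in list(range(half)) + list(range(n - half, n)):
        h = min(i, n - 1 - i, half)
        xy[:, i] = np.median(traj.xy[:, i - h : i + h + 1], axis=1)
    prov = traj.provenance.copy()
    changed = np.any(xy != traj.xy, axis=2)
    prov[changed] = PROV_FILTERED
    return traj.replace(xy=xy, provenance=prov)


def preprocess(traj: TrajectorySet, median_window: int = 5) -> TrajectorySet:
    """Full preprocessing chain: gap filling followed by median filtering."""
    return median_filter(fill_gaps(traj), window=median_window)


def as_series_matrix(
    traj: TrajectorySet,
    parts: list[str] | None = None,
    axes: str = "xy",
) -> tuple[list[str], np.ndarray]:
    """Flatten a TrajectorySet into labelled 1-D data series.

    Returns ``(labels, series)`` where ``series`` has shape
    ``(len(parts) * len(axes), N)`` and labels look like ``"snout:x"``.
    Axis order is part-major (all requested axes of the first part come
    first).
    """
    if parts is None:
        parts = traj.parts
    axis_idx = {"x": 0, "y": 1}
    for ax in axes:
        if ax not in axis_idx:
            raise ParameterError(f"unknown axis {ax!r}")
    labels: list[str] = []
    rows: list[np.ndarray] = []
    for part in parts:
        pi = traj.part_index(part)
        for ax in axes:
            labels.append(f"{part}:{ax}")
            rows.append(traj.xy[pi, :, axis_idx[ax]])
    return labels, np.asarray(rows)


def _stem(path) -> str:
    import os

    return os.path.splitext(os.path.basename(str(path)))[0]
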