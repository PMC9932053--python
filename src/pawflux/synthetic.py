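"""Synthetic trajectory generation for testing and calibration.

Spectral (Fourier) synthesis of Gaussian series whose detrended
fluctuation functions follow prescribed power laws: a series with DFA
exponent ``alpha`` is synthesized with power spectrum S(f) ~ f**-beta,
beta = 2 * alpha - 1.  Two-regime series use a piecewise spectrum that
is continuous at an internal knee frequency; the knee is placed so that
the *measured* DFA crossover (rotated-curve maximum) lands at the
requested scale — DFA smears spectral crossovers toward larger scales,
so the knee sits above 1/s_x by a fixed calibration factor.

Whole animals are emulated as a body-midpoint trajectory (one two-regime
series per axis) plus body parts that mix a delayed copy of the midpoint
with an independent same-law component:

    part = rho * midpoint(t - d) + sqrt(1 - rho**2) * independent + noise

so the pairwise part-midpoint correlation is ~rho at every scale, the
midpoint leads by d frames, and rho = 1, d = 0 degenerates to an exact
copy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ParameterError
from .trajectory_io import TrajectorySet

__all__ = [
    "DEFAULT_PARTS",
    "MIDPOINT",
    "Coupling",
    "SyntheticConfig",
    "gen_power_law_series",
    "gen_crossover_series",
    "gen_animal",
    "gen_group_study",
]

#: the seven tracked points of the open-field recordings
DEFAULT_PARTS = [
    "snout",
    "front_left",
    "front_right",
    "midpoint",
    "hind_left",
    "hind_right",
    "tail_base",
]
MIDPOINT = "midpoint"

#: DFA rotated-curve crossovers sit above the spectral knee time by roughly
#: this factor (measured on the (2, 1/2) regime pair, order-2 detrending);
#: the knee is placed at CROSSOVER_CALIBRATION / s_x so that the requested
#: s_x is what the estimator recovers.
CROSSOVER_CALIBRATION = 1.26


@dataclass
class Coupling:
    """Pairwise coupling of a body part to the midpoint."""

    rho: float = 0.8
    delay: int = 0  # frames; > 0 means the midpoint leads the part


@dataclass
class SyntheticConfig:
    """Parameters of one synthetic animal / cohort member."""

    n_frames: int = 8192
    fps: float = 30.0
    crossover_seconds: float = 8.0
    small_scale_alpha: float = 2.0
    large_scale_alpha: float = 0.5
    parts: list[str] = field(default_factory=lambda: list(DEFAULT_PARTS))
    coupling: dict[str, Coupling] = field(default_factory=dict)
    #: crossover of the part-relative movement component; None means the
    #: relative component follows the same law as the midpoint.  A short
    #: fixed value reproduces the rise of part-midpoint correlations
    #: toward 1 at large scales (relative movements are bounded while the
    #: walking trajectory keeps growing).
    rel_crossover_seconds: float | None = 1.0
    noise_sd: float = 0.0
    amplitude: float = 25.0  # spatial units (px) per unit series std
    origin: tuple[float, float] = (200.0, 150.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames < 64:
            raise ParameterError(f"n_frames must be >= 64, got {self.n_frames}")
        if not self.fps > 0:
            raise ParameterError("fps must be positive")
        max_sx = self.n_frames / (4 * self.fps)
        if not 0 < self.crossover_seconds < max_sx:
            raise ParameterError(
                f"crossover_seconds must lie in (0, {max_sx:g}) for "
                f"N={self.n_frames}, fps={self.fps}"
            )
        for name, alpha in (
            ("small_scale_alpha", self.small_scale_alpha),
            ("large_scale_alpha", self.large_scale_alpha),
        ):
            if not 0 < alpha < 3:
                raise ParameterError(f"{name} must lie in (0, 3), got {alpha}")
        if MIDPOINT not in self.parts:
            raise ParameterError(f"parts must include {MIDPOINT!r}")
        for part, cp in self.coupling.items():
            if part not in self.parts:
                raise ParameterError(f"coupling refers to unknown part {part!r}")
            if part == MIDPOINT:
                raise ParameterError("midpoint cannot be coupled to itself")
            if not -1 <= cp.rho <= 1:
                raise ParameterError(f"|rho| <= 1 required, got {cp.rho}")
            if abs(cp.delay) >= self.n_frames / 4:
                raise ParameterError(f"|delay| must be < N/4, got {cp.delay}")
        if self.rel_crossover_seconds is not None and not (
            0 < self.rel_crossover_seconds < max_sx
        ):
            raise ParameterError(
                f"rel_crossover_seconds must lie in (0, {max_sx:g}) or be None"
            )
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be >= 0")

    def coupling_for(self, part: str) -> Coupling:
        return self.coupling.get(part, Coupling())


# ---------------------------------------------------------------------------
# spectral synthesis primitives

def _analytic_std(amp: np.ndarray, n: int) -> float:
    """Expected std of the synthesized series for given spectral amplitudes."""
    var = 4.0 * np.sum(amp[1:-1] ** 2)
    if n % 2 == 0:
        var += amp[-1] ** 2
    else:
        var += 4.0 * amp[-1] ** 2
    return float(np.sqrt(var) / n)


def _spectral_series(n: int, amplitude_of_f, rng, reference_of_f=None) -> np.ndarray:
    """Real Gaussian series with per-frequency spectral amplitudes.

    ``amplitude_of_f`` maps the positive rfft frequencies (cycles/frame)
    to spectral amplitudes; the zero-frequency amplitude is 0 (zero-mean
    output).  By default the result is normalized to unit realized
    standard deviation; if ``reference_of_f`` is given, the series is
    instead divided by the *analytic* std of that reference spectrum, so
    the normalization does not depend on the shape of the actual
    spectrum (this keeps small-scale amplitudes comparable across
    different crossover placements).
    """
    freqs = np.fft.rfftfreq(n)
    amp = np.zeros(freqs.shape)
    amp[1:] = amplitude_of_f(freqs[1:])
    z = amp * (
        rng.standard_normal(freqs.shape) + 1j * rng.standard_normal(freqs.shape)
    )
    z[0] = 0.0
    if n % 2 == 0:
        z[-1] = z[-1].real
    x = np.fft.irfft(z, n=n)
    if reference_of_f is None:
        sd = x.std()
    else:
        ref = np.zeros(freqs.shape)
        ref[1:] = reference_of_f(freqs[1:])
        sd = _analytic_std(ref, n)
    if sd == 0:
        raise ParameterError("degenerate spectrum produced a constant series")
    return x / sd


def gen_power_law_series(n: int, alpha: float, seed) -> np.ndarray:
    """Series whose DFA exponent (order-2 detrending) is ``alpha``.

    Synthesized with spectrum S(f) ~ f**-(2 alpha - 1) and random phases;
    a given seed always reproduces the same series.
    """
    if not 0 < alpha < 3:
        raise ParameterError(f"alpha must lie in (0, 3), got {alpha}")
    if n < 8:
        raise ParameterError(f"n must be >= 8, got {n}")
    rng = _as_rng(seed)
    beta = 2 * alpha - 1
    return _spectral_series(n, lambda f: f ** (-beta / 2), rng)


def gen_crossover_series(
    cfg: SyntheticConfig | None = None,
    rng=None,
    *,
    n: int | None = None,
    fps: float | None = None,
    crossover_seconds: float | None = None,
    small_scale_alpha: float | None = None,
    large_scale_alpha: float | None = None,
    seed=None,
) -> np.ndarray:
    """Two-regime series with a tunable DFA crossover.

    The spectrum falls as f**-(2*small_alpha - 1) above the knee
    frequency and as f**-(2*large_alpha - 1) below it, continuous at the
    joint; the knee is calibrated so the rotated-curve crossover estimate
    recovers ``crossover_seconds``.  Either pass a
    :class:`SyntheticConfig` or the individual keyword parameters.
    """
    if cfg is not None:
        n = cfg.n_frames if n is None else n
        fps = cfg.fps if fps is None else fps
        crossover_seconds = (
            cfg.crossover_seconds if crossover_seconds is None else crossover_seconds
        )
        small_scale_alpha = (
            cfg.small_scale_alpha if small_scale_alpha is None else small_scale_alpha
        )
        large_scale_alpha = (
            cfg.large_scale_alpha if large_scale_alpha is None else large_scale_alpha
        )
        if rng is None and seed is None:
            seed = cfg.seed
    if None in (n, fps, crossover_seconds, small_scale_alpha, large_scale_alpha):
        raise ParameterError("incomplete crossover-series specification")
    if not 0 < crossover_seconds < n / (4 * fps):
        raise ParameterError(
            f"crossover_seconds must lie in (0, N/(4 fps)) = "
            f"(0, {n / (4 * fps):g}), got {crossover_seconds}"
        )
    rng = _as_rng(seed) if rng is None else rng
    s_frames = crossover_seconds * fps
    f_knee = CROSSOVER_CALIBRATION / s_frames
    beta_s = 2 * small_scale_alpha - 1
    beta_l = 2 * large_scale_alpha - 1

    def amplitude(f):
        amp = np.where(
            f >= f_knee,
            f ** (-beta_s / 2),
            f_knee ** (-beta_s / 2) * (f / f_knee) ** (-beta_l / 2),
        )
        return amp

    # normalization via the pure small-scale reference spectrum: the
    # small-scale fluctuation amplitude then does not depend on where the
    # crossover sits, so cohorts differing only in s_x share small-scale
    # statistics
    return _spectral_series(
        n, amplitude, rng, reference_of_f=lambda f: f ** (-beta_s / 2)
    )


# ---------------------------------------------------------------------------
# whole animals and cohorts

def gen_animal(cfg: SyntheticConfig, animal_id: str = "synthetic") -> TrajectorySet:
    """Generate one animal's TrajectorySet under the coupling model.

    Per axis, the midpoint follows an independent two-regime series; each
    other part mixes a ``delay``-shifted copy of the midpoint (weight
    rho) with an independent series of the same law (weight
    sqrt(1 - rho**2)) plus white measurement noise.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_frames
    pad = max(
        (abs(cfg.coupling_for(p).delay) for p in cfg.parts if p != MIDPOINT),
        default=0,
    )
    n_ext = n + 2 * pad
    xy = np.empty((len(cfg.parts), n, 2))
    mid_i = cfg.parts.index(MIDPOINT)
    for ax in range(2):
        mid_ext = gen_crossover_series(cfg, rng=rng, n=n_ext)
        mid = mid_ext[pad : pad + n]
        xy[mid_i, :, ax] = mid
        for pi, part in enumerate(cfg.parts):
            if part == MIDPOINT:
                continue
            cp = cfg.coupling_for(part)
            shifted = mid_ext[pad - cp.delay : pad - cp.delay + n]
            rel_sx = (
                cfg.crossover_seconds
                if cfg.rel_crossover_seconds is None
                else cfg.rel_crossover_seconds
            )
            own = gen_crossover_series(
                cfg, rng=rng, n=n, crossover_seconds=rel_sx
            )
            series = cp.rho * shifted + np.sqrt(1 - cp.rho**2) * own
            if cfg.noise_sd > 0:
                series = series + cfg.noise_sd * rng.standard_normal(n)
            xy[pi, :, ax] = series
    xy *= cfg.amplitude
    xy[:, :, 0] += cfg.origin[0]
    xy[:, :, 1] += cfg.origin[1]
    return TrajectorySet(
        animal_id=animal_id, fps=cfg.fps, parts=list(cfg.parts), xy=xy
    )


def gen_group_study(
    n_per_group: int,
    cfg_control: SyntheticConfig,
    cfg_test: SyntheticConfig,
    seed: int = 0,
) -> list[tuple[str, TrajectorySet]]:
    """Reproducible two-cohort study: [(group_label, TrajectorySet), ...].

    Per-animal seeds are spawned deterministically from ``seed``; animal
    ids encode group and index (``control_00`` ...).
    """
    if n_per_group < 1:
        raise ParameterError("n_per_group must be >= 1")
    import dataclasses as _dc

    out: list[tuple[str, TrajectorySet]] = []
    child_seeds = np.random.SeedSequence(seed).generate_state(2 * n_per_group)
    k = 0
    for label, cfg in (("control", cfg_control), ("test", cfg_test)):
        for i in range(n_per_group):
            cfg_i = _dc.replace(cfg, seed=int(child_seeds[k]))
            k += 1
            out.append((label, gen_animal(cfg_i, animal_id=f"{label}_{i:02d}")))
    return out


def _as_rng(seed):
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)
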