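"""Two-class Raman spectrum simulator.

Generates datasets of "normal" and "abnormal" spectra on a normalized
spectral axis [0, 1].  Both classes are sums of three Gaussian bands plus
i.i.d. additive Gaussian noise; the abnormal class has one band translated
by a configurable peak shift.  The noise standard deviation is set to
(maximum clean-signal amplitude) / SNR, matching the usual experimental
SNR estimate of peak amplitude over noise standard deviation.

An optional per-spectrum random smooth background (a low-order polynomial
baseline stand-in) can be added on top.

The study grid covers 7 peak shifts x 9 SNR levels = 63 cases of 200
spectra each (100 per class, 1024 points).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, asdict, replace

import numpy as np

__all__ = [
    "SHIFT_GRID",
    "SNR_GRID",
    "DEFAULT_PEAKS",
    "SimulationConfig",
    "SpectraMatrix",
    "clean_signal",
    "simulate_dataset",
    "simulate_components",
    "paper_grid",
    "add_background",
    "estimate_snr",
]

#: Peak-shift values of the study grid (on the normalized axis).
SHIFT_GRID: tuple[float, ...] = (0.001, 0.003, 0.005, 0.01, 0.02, 0.025, 0.05)
#: Signal-to-noise ratios of the study grid.
SNR_GRID: tuple[float, ...] = (0.5, 1, 2, 3, 5, 10, 30, 50, 100)

#: Default (position, width, amplitude) of the three Gaussian bands.
DEFAULT_PEAKS: tuple[tuple[float, float, float], ...] = (
    (0.25, 0.010, 1.0),
    (0.50, 0.015, 0.8),
    (0.75, 0.010, 0.6),
)


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of one simulated two-class dataset."""

    n_per_class: int = 100
    n_points: int = 1024
    domain: tuple[float, float] = (0.0, 1.0)
    peaks: tuple[tuple[float, float, float], ...] = DEFAULT_PEAKS
    shifted_peak_index: int = 1
    shift: float = 0.05
    snr: float = 30.0
    background: bool = False
    #: background maximum is uniform on [lo, hi] x tallest peak amplitude
    background_scale: tuple[float, float] = (0.5, 2.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_class < 1 or self.n_points < 2:
            raise ValueError("need n_per_class >= 1 and n_points >= 2")
        if self.snr <= 0:
            raise ValueError(f"snr must be positive, got {self.snr}")
        if self.shift < 0:
            raise ValueError(f"shift must be >= 0, got {self.shift}")
        lo, hi = self.domain
        for pos, width, amp in self.peaks:
            if width <= 0 or amp <= 0:
                raise ValueError("peak widths and amplitudes must be positive")
            if not lo <= pos <= hi:
                raise ValueError(f"peak position {pos} outside domain")
        pos = self.peaks[self.shifted_peak_index][0]
        if not lo <= pos + self.shift <= hi:
            raise ValueError(
                f"shifted peak at {pos} + {self.shift} leaves the domain [{lo}, {hi}]"
            )


@dataclass
class SpectraMatrix:
    """N discrete spectra on a shared grid, with class labels.

    ``intensities`` is N x p, ``grid`` is the p ascending axis values,
    ``labels`` the N class labels and ``batches`` optional batch labels.
    """

    intensities: np.ndarray
    grid: np.ndarray
    labels: np.ndarray
    batches: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.intensities = np.atleast_2d(np.asarray(self.intensities, dtype=float))
        self.grid = np.asarray(self.grid, dtype=float)
        self.labels = np.asarray(self.labels)
        n, p = self.intensities.shape
        if p < 2 or n < 1:
            raise ValueError("need N >= 1 spectra of p >= 2 points")
        if len(self.grid) != p:
            raise ValueError(f"grid length {len(self.grid)} != p = {p}")
        if np.any(np.diff(self.grid) <= 0):
            raise ValueError("grid must be strictly increasing")
        if len(self.labels) != n:
            raise ValueError(f"labels length {len(self.labels)} != N = {n}")
        if self.batches is not None:
            self.batches = np.asarray(self.batches)
            if len(self.batches) != n:
                raise ValueError("batches length must equal N")
        if not np.all(np.isfinite(self.intensities)):
            raise ValueError("intensities must be finite")

    @property
    def n_spectra(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_points(self) -> int:
        return self.intensities.shape[1]

    def subset(self, idx) -> "SpectraMatrix":
        return SpectraMatrix(
            intensities=self.intensities[idx],
            grid=self.grid,
            labels=self.labels[idx],
            batches=None if self.batches is None else self.batches[idx],
        )


def _gaussian(t: np.ndarray, pos: float, width: float, amp: float) -> np.ndarray:
    return amp * np.exp(-((t - pos) ** 2) / (2.0 * width**2))


def clean_signal(config: SimulationConfig, shifted: bool) -> np.ndarray:
    """Noise- and background-free class signal on the config grid."""
    t = np.linspace(*config.domain, config.n_points)
    out = np.zeros_like(t)
    for i, (pos, width, amp) in enumerate(config.peaks):
        if shifted and i == config.shifted_peak_index:
            pos = pos + config.shift
        out += _gaussian(t, pos, width, amp)
    return out


def _draw_backgrounds(
    config: SimulationConfig, rng: np.random.Generator, n: int
) -> np.ndarray:
    """n random quadratic baselines b0 + b1 t + b2 t^2, non-negative on the domain.

    Coefficients are drawn uniformly non-negative (so the polynomial is
    non-negative for t >= 0) and rescaled so each spectrum's background
    maximum is uniform on ``background_scale`` x tallest peak amplitude.
    """
    t = np.linspace(*config.domain, config.n_points)
    amax = max(a for _, _, a in config.peaks)
    lo, hi = config.background_scale
    coeff = rng.uniform(0.0, 1.0, size=(n, 3))
    target_max = rng.uniform(lo * amax, hi * amax, size=n)
    bg = coeff[:, [0]] + coeff[:, [1]] * t + coeff[:, [2]] * t**2
    cur_max = bg.max(axis=1)
    cur_max[cur_max == 0] = 1.0
    return bg * (target_max / cur_max)[:, None]


def simulate_components(config: SimulationConfig) -> tuple[SpectraMatrix, dict]:
    """Like :func:`simulate_dataset` but also return the generative parts.

    The second element maps "clean" (per-spectrum noise-free target,
    class signal plus that spectrum's background), "noise", "background"
    (zeros when backgrounds are off) and "noise_sd" to arrays.
    """
    rng = np.random.default_rng(config.seed)
    t = np.linspace(*config.domain, config.n_points)
    normal = clean_signal(config, shifted=False)
    abnormal = clean_signal(config, shifted=True)
    sigma = max(normal.max(), abnormal.max()) / config.snr

    n = config.n_per_class
    clean = np.empty((2 * n, config.n_points))
    clean[:n] = normal
    clean[n:] = abnormal
    noise = rng.normal(0.0, sigma, size=clean.shape)
    if config.background:
        bg = _draw_backgrounds(config, rng, 2 * n)
    else:
        bg = np.zeros_like(clean)
    clean = clean + bg
    labels = np.array(["normal"] * n + ["abnormal"] * n)
    spectra = SpectraMatrix(intensities=clean + noise, grid=t, labels=labels)
    return spectra, {
        "clean": clean,
        "noise": noise,
        "background": bg,
        "noise_sd": sigma,
    }


def simulate_dataset(config: SimulationConfig) -> SpectraMatrix:
    """Generate the two-class dataset defined by ``config``.

    Returns 2 * n_per_class spectra labelled "normal"/"abnormal".  Noise is
    i.i.d. Gaussian per point with sd = (max clean amplitude) / snr; the
    whole RNG stream is determined by ``config.seed``.
    """
    return simulate_components(config)[0]


def paper_grid(
    seed: int, background: bool = False, **overrides
) -> list[SimulationConfig]:
    """The 63-case study design: every (shift, snr) pair of the grids.

    Per-case sub-seeds are derived deterministically from ``seed`` via
    ``SeedSequence(seed, spawn_key=(case_index,))``, so cases are
    independent and reproducible in any order.
    """
    configs = []
    for i, (shift, snr) in enumerate(itertools.product(SHIFT_GRID, SNR_GRID)):
        sub = int(np.random.SeedSequence(seed, spawn_key=(i,)).generate_state(1)[0])
        sub %= 2**31
        configs.append(
            SimulationConfig(
                shift=shift, snr=snr, background=background, seed=sub, **overrides
            )
        )
    return configs


def add_background(
    spectra: SpectraMatrix,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> SpectraMatrix:
    """Add an independent smooth random background to each spectrum."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    lo, hi = config.background_scale
    if lo == hi == 0:
        return spectra
    cfg = replace(
        config,
        n_points=spectra.n_points,
        domain=(float(spectra.grid[0]), float(spectra.grid[-1])),
    )
    bg = _draw_backgrounds(cfg, rng, spectra.n_spectra)
    return SpectraMatrix(
        intensities=spectra.intensities + bg,
        grid=spectra.grid,
        labels=spectra.labels,
        batches=spectra.batches,
    )


def estimate_snr(
    spectrum: np.ndarray,
    grid: np.ndarray,
    peak_position: float,
    silent_region: tuple[float, float],
) -> float:
    """Experimental SNR estimate: peak amplitude over silent-region noise sd.

    Returns the intensity at the grid point nearest ``peak_position``
    divided by the sample standard deviation over the points of
    ``silent_region`` (a signal-free axis interval with >= 3 points).
    """
    spectrum = np.asarray(spectrum, dtype=float)
    grid = np.asarray(grid, dtype=float)
    lo, hi = silent_region
    mask = (grid >= lo) & (grid <= hi)
    if mask.sum() < 3:
        raise ValueError(
            f"silent region [{lo}, {hi}] must contain >= 3 grid points"
        )
    if not grid[0] <= peak_position <= grid[-1]:
        raise ValueError(f"peak position {peak_position} outside the grid")
    sd = float(np.std(spectrum[mask], ddof=1))
    if sd == 0.0:
        raise ValueError("silent region has zero standard deviation")
    peak = float(spectrum[np.argmin(np.abs(grid - peak_position))])
    return peak / sd


# re-export used by dataclass serialization helpers
config_to_dict = asdict
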