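"""Dipolar EPR forward model.

The elementary observable in a DEER (double electron-electron resonance)
experiment is the time-domain signal of an ensemble of spin pairs.  For an
isolated pair at distance ``r`` the dipolar coupling frequency is

    omega(r) = 2 pi D / r^3,     D = 52.04 MHz nm^3  (free-electron g),

and after averaging over the isotropic orientation distribution the
normalized pair signal is the Pake kernel

    K(t, r) = integral_0^1 cos[(3 x^2 - 1) omega(r) t] dx,

which has the closed Fresnel-integral form used here.  A measured trace is
the kernel averaged over a distance distribution P(r), diluted by the
modulation depth Delta (the fraction of detected spins that actually have a
coupled partner within the excitation bandwidth) and multiplied by an
intermolecular background decay:

    V(t) = [(1 - Delta) + Delta * (K P)(t)] * exp(-k t^(d/3)),

with d = 3 (homogeneous 3D background) by default.

The module also maps per-dimer ligand occupancy states to the two spin
observables the experiment yields: the modulation depth and the bound-spin
signal per dimer.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import fresnel

from .errors import InvalidInputError, UndefinedQuantityError

#: Dipolar coupling constant for two free electrons, MHz nm^3.
DIPOLAR_CONSTANT_MHZ_NM3 = 52.04


def _as_1d(values, name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1 or arr.size == 0:
        raise InvalidInputError(f"{name} must be a non-empty 1-D array")
    if not np.all(np.isfinite(arr)):
        raise InvalidInputError(f"{name} contains non-finite values")
    return arr


@dataclass(frozen=True)
class TimeAxis:
    """Uniform dipolar evolution time axis in microseconds, starting at 0."""

    values: np.ndarray

    def __post_init__(self):
        arr = _as_1d(self.values, "time axis")
        if arr[0] != 0.0:
            raise InvalidInputError("time axis must start at exactly 0")
        if arr.size > 1:
            steps = np.diff(arr)
            if np.any(steps <= 0):
                raise InvalidInputError("time axis must be strictly increasing")
            if np.ptp(steps) > 1e-9:
                raise InvalidInputError("time axis must be uniformly spaced")
        object.__setattr__(self, "values", arr)

    @classmethod
    def regular(cls, t_max: float, dt: float) -> "TimeAxis":
        n = int(round(t_max / dt)) + 1
        return cls(np.linspace(0.0, t_max, n))

    @property
    def t_max(self) -> float:
        return float(self.values[-1])

    def __len__(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class DistanceGrid:
    """Uniform inter-spin distance grid in nanometres (1-8 nm window)."""

    values: np.ndarray

    def __post_init__(self):
        arr = _as_1d(self.values, "distance grid")
        steps = np.diff(arr)
        if arr.size < 2 or np.any(steps <= 0) or np.ptp(steps) > 1e-9:
            raise InvalidInputError("distance grid must be strictly increasing and uniform")
        if arr[0] < 1.0 or arr[-1] > 8.0:
            raise InvalidInputError("distance grid must lie within [1, 8] nm")
        object.__setattr__(self, "values", arr)

    @classmethod
    def regular(cls, r_min: float = 1.0, r_max: float = 6.0, dr: float = 0.025) -> "DistanceGrid":
        n = int(round((r_max - r_min) / dr)) + 1
        return cls(np.linspace(r_min, r_max, n))

    @property
    def dr(self) -> float:
        return float(self.values[1] - self.values[0])

    def __len__(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class DistanceDistribution:
    """Probability density P(r) over a distance grid, unit trapezoidal integral."""

    grid: DistanceGrid
    density: np.ndarray

    def __post_init__(self):
        dens = _as_1d(self.density, "density")
        if dens.size != len(self.grid):
            raise InvalidInputError("density and grid lengths differ")
        if np.any(dens < 0):
            raise InvalidInputError("density must be non-negative")
        total = np.trapezoid(dens, self.grid.values)
        if abs(total - 1.0) > 1e-6:
            raise InvalidInputError(f"density must integrate to 1 (got {total:.6g})")
        object.__setattr__(self, "density", dens)

    @classmethod
    def from_unnormalized(cls, grid: DistanceGrid, weights) -> "DistanceDistribution":
        w = np.clip(np.asarray(weights, dtype=float), 0.0, None)
        total = np.trapezoid(w, grid.values)
        if total <= 0:
            raise InvalidInputError("cannot normalize an all-zero density")
        return cls(grid, w / total)

    @classmethod
    def gaussian(cls, grid: DistanceGrid, mean: float, sd: float) -> "DistanceDistribution":
        """Gaussian truncated to the grid and renormalized."""
        if sd <= 0:
            raise InvalidInputError("sd must be positive")
        w = np.exp(-0.5 * ((grid.values - mean) / sd) ** 2)
        return cls.from_unnormalized(grid, w)

    @classmethod
    def spike(cls, grid: DistanceGrid, r: float) -> "DistanceDistribution":
        """All mass on the grid point closest to ``r``."""
        w = np.zeros(len(grid))
        w[int(np.argmin(np.abs(grid.values - r)))] = 1.0
        return cls.from_unnormalized(grid, w)

    def mean(self) -> float:
        return float(np.trapezoid(self.grid.values * self.density, self.grid.values))


@dataclass(frozen=True)
class DipolarTrace:
    """Time-domain DEER signal, normalized to V(0) = 1 for noiseless data."""

    time: TimeAxis
    signal: np.ndarray
    noise_sd: float = 0.0

    def __post_init__(self):
        sig = _as_1d(self.signal, "signal")
        if sig.size != len(self.time):
            raise InvalidInputError("signal and time axis lengths differ")
        if self.noise_sd < 0:
            raise InvalidInputError("noise_sd must be >= 0")
        object.__setattr__(self, "signal", sig)


@dataclass(frozen=True)
class TraceModel:
    """Forward model: modulation depth, background rate and P(r).

    ``background_dim`` is the effective dimensionality d of the
    intermolecular background exp(-k t^(d/3)); d = 3 gives the homogeneous
    exponential.
    """

    depth: float
    background_rate: float
    distribution: DistanceDistribution
    background_dim: float = 3.0

    def __post_init__(self):
        if not 0.0 <= self.depth <= 1.0:
            raise InvalidInputError("depth must lie in [0, 1]")
        if self.background_rate < 0:
            raise InvalidInputError("background_rate must be >= 0")
        if self.background_dim <= 0:
            raise InvalidInputError("background_dim must be positive")

    def background(self, time: TimeAxis) -> np.ndarray:
        t = time.values
        return np.exp(-self.background_rate * t ** (self.background_dim / 3.0))

    def form_factor(self, time: TimeAxis) -> np.ndarray:
        """Intramolecular part (1 - Delta) + Delta * (K P)(t)."""
        K = dipolar_kernel(time, self.distribution.grid)
        kp = K @ self.distribution.density * self.distribution.grid.dr
        return (1.0 - self.depth) + self.depth * kp

    def signal(self, time: TimeAxis) -> np.ndarray:
        return self.form_factor(time) * self.background(time)


@dataclass(frozen=True)
class LabelingModel:
    """Spectroscopic label model.

    ``inversion_efficiency`` (lambda) is the probability that the partner
    spin of a detected spin is flipped by the pump pulse; it caps the
    modulation depth.  ``spin_survival`` is the fraction of nitroxide labels
    still paramagnetic at measurement time (reduced below 1 in the cytoplasm).
    """

    inversion_efficiency: float = 0.4
    spin_survival: float = 1.0

    def __post_init__(self):
        if not 0.0 < self.inversion_efficiency <= 1.0:
            raise InvalidInputError("inversion_efficiency must lie in (0, 1]")
        if not 0.0 <= self.spin_survival <= 1.0:
            raise InvalidInputError("spin_survival must lie in [0, 1]")


def dipolar_kernel(time: TimeAxis, grid: DistanceGrid) -> np.ndarray:
    """Pake kernel matrix K[t, r] by the closed Fresnel form.

    K(t, r) = Re{ e^{-i phi} integral } reduces for the isotropic powder
    average to

        K = sqrt(pi / (6 phi)) [cos(phi) C(z) + sin(phi) S(z)],
        phi = omega(r) t,  z = sqrt(6 phi / pi),

    with C, S the Fresnel cosine/sine integrals; K(0, r) = 1.
    """
    t = time.values[:, None]
    omega = 2.0 * np.pi * DIPOLAR_CONSTANT_MHZ_NM3 / grid.values[None, :] ** 3
    phi = omega * t
    K = np.ones_like(phi)
    nz = phi > 0
    z = np.sqrt(6.0 * phi[nz] / np.pi)
    S, C = fresnel(z)
    K[nz] = (np.cos(phi[nz]) * C + np.sin(phi[nz]) * S) / z
    return K


def simulate_trace(
    model: TraceModel,
    time: TimeAxis,
    noise_sd: float = 0.0,
    seed: int | None = 0,
) -> DipolarTrace:
    """Synthesize a trace from the forward model plus white Gaussian noise."""
    if noise_sd < 0:
        raise InvalidInputError("noise_sd must be >= 0")
    signal = model.signal(time)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        signal = signal + rng.normal(0.0, noise_sd, size=signal.shape)
    return DipolarTrace(time, signal, noise_sd=noise_sd)


def pair_fraction(state) -> float:
    """Fraction q of bound spins whose dimer carries a second bound spin.

    q = 2 f2 / (f1 + 2 f2); undefined when no spins are bound.
    """
    denom = state.f1 + 2.0 * state.f2
    if denom <= 0:
        raise UndefinedQuantityError("pair fraction undefined: no bound spins")
    return 2.0 * state.f2 / denom


def observables_from_state(state, labels: LabelingModel) -> tuple[float, float]:
    """Map an occupancy state to (modulation depth, bound-spin signal).

    Spin survival is applied first (each label survives independently with
    probability s); the surviving state determines the pair fraction q and
    the per-dimer bound-spin count m = f1' + 2 f2'.  Depth = lambda * q.
    Inverse of :func:`dimerdeer.occupancy.infer_occupancy` at s = 1.
    """
    from .occupancy import apply_spin_reduction  # local import avoids a cycle

    surviving = apply_spin_reduction(state, labels.spin_survival)
    m = surviving.f1 + 2.0 * surviving.f2
    if m <= 0:
        return 0.0, 0.0
    q = pair_fraction(surviving)
    return labels.inversion_efficiency * q, m
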