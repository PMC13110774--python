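"""Two-component unmixing of continuous-wave nitroxide spectra.

A room-temperature CW EPR spectrum of a nitroxide ligand in the presence of
a binding partner is a superposition of a sharp three-line component from
free, fast-tumbling ligand and a broad, powder-like component from ligand
rigidly bound to the (slowly tumbling) protein.  Because CW spectra are
recorded as field derivatives, sharp lines dominate the raw amplitude;
spin counts are instead proportional to the *double integral* (the area of
the absorption spectrum).  Templates are therefore normalized to unit
absorption area, so the non-negative least-squares weights of the two
derivative templates are directly proportional to the number of spins in
each motional state, and the free fraction is w_free / (w_free + w_bound).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize
from scipy.stats import norm

from .errors import DegenerateFitError, InvalidInputError

DEFAULT_FIELD_MT = (328.0, 343.0, 1024)
DEFAULT_CENTER_MT = 335.5
DEFAULT_HYPERFINE_MT = 1.6
DEFAULT_FREE_LINEWIDTH_MT = 0.15
DEFAULT_OUTER_SPLITTING_MT = 7.0
DEFAULT_BOUND_LINEWIDTH_MT = 0.4


@dataclass(frozen=True)
class CWSpectrum:
    """First-derivative CW spectrum on a uniform magnetic-field axis (mT)."""

    field: np.ndarray
    amplitude: np.ndarray

    def __post_init__(self):
        field = np.asarray(self.field, dtype=float)
        amp = np.asarray(self.amplitude, dtype=float)
        if field.ndim != 1 or field.size < 8 or amp.shape != field.shape:
            raise InvalidInputError("field and amplitude must be matching 1-D arrays")
        steps = np.diff(field)
        if np.any(steps <= 0) or np.ptp(steps) > 1e-9 * np.mean(steps):
            raise InvalidInputError("field axis must be strictly increasing and uniform")
        if not np.all(np.isfinite(amp)):
            raise InvalidInputError("amplitude must be finite")
        object.__setattr__(self, "field", field)
        object.__setattr__(self, "amplitude", amp)

    def absorption(self) -> np.ndarray:
        """Cumulative integral of the derivative spectrum."""
        from scipy.integrate import cumulative_trapezoid

        return cumulative_trapezoid(self.amplitude, self.field, initial=0.0)

    def double_integral(self) -> float:
        """Absorption area — proportional to the number of spins."""
        return float(np.trapezoid(self.absorption(), self.field))


@dataclass(frozen=True)
class ComponentTemplates:
    """Free/bound template pair on a common axis, unit double integral each."""

    free: CWSpectrum
    bound: CWSpectrum

    def __post_init__(self):
        if not np.array_equal(self.free.field, self.bound.field):
            raise InvalidInputError("templates must share the field axis")
        for name, tpl in (("free", self.free), ("bound", self.bound)):
            if abs(tpl.double_integral() - 1.0) > 1e-6:
                raise InvalidInputError(f"{name} template double integral != 1")


def default_field_axis() -> np.ndarray:
    lo, hi, n = DEFAULT_FIELD_MT
    return np.linspace(lo, hi, n)


def _derivative_from_absorption(field: np.ndarray, absorption: np.ndarray) -> CWSpectrum:
    """Differentiate to the CW convention and normalize to unit double integral.

    Normalization uses the double integral of the derivative itself so the
    spin-count convention is exact for the discretized template.
    """
    raw = CWSpectrum(field, np.gradient(absorption, field))
    area = raw.double_integral()
    if area <= 0:
        raise InvalidInputError("template absorption has no area on this axis")
    return CWSpectrum(field, raw.amplitude / area)


def make_free_template(
    field: np.ndarray | None = None,
    center: float = DEFAULT_CENTER_MT,
    hyperfine: float = DEFAULT_HYPERFINE_MT,
    linewidth: float = DEFAULT_FREE_LINEWIDTH_MT,
) -> CWSpectrum:
    """Fast-motion nitroxide template: three equal Lorentzian lines.

    Lines sit at center - A, center, center + A (A = the 14N hyperfine
    splitting); ``linewidth`` is the Lorentzian half-width at half-maximum
    of the absorption lines.
    """
    if linewidth <= 0 or hyperfine <= 0:
        raise InvalidInputError("linewidth and hyperfine must be positive")
    field = default_field_axis() if field is None else np.asarray(field, dtype=float)
    span = hyperfine + 5.0 * linewidth
    if field[0] > center - span or field[-1] < center + span:
        raise InvalidInputError("field axis does not cover the three-line pattern")
    absorption = np.zeros_like(field)
    for pos in (center - hyperfine, center, center + hyperfine):
        absorption += linewidth / np.pi / ((field - pos) ** 2 + linewidth**2)
    return _derivative_from_absorption(field, absorption)


def make_bound_template(
    field: np.ndarray | None = None,
    center: float = DEFAULT_CENTER_MT,
    outer_splitting: float = DEFAULT_OUTER_SPLITTING_MT,
    linewidth: float = DEFAULT_BOUND_LINEWIDTH_MT,
) -> CWSpectrum:
    """Rigid-limit surrogate: uniform line-position density of total width
    ``outer_splitting`` convolved with a Gaussian of sd ``linewidth``."""
    if outer_splitting <= 0 or linewidth <= 0:
        raise InvalidInputError("outer_splitting and linewidth must be positive")
    field = default_field_axis() if field is None else np.asarray(field, dtype=float)
    half = outer_splitting / 2.0
    span = half + 5.0 * linewidth
    if field[0] > center - span or field[-1] < center + span:
        raise InvalidInputError("field axis does not cover the powder pattern")
    x = field - center
    absorption = (norm.cdf((x + half) / linewidth) - norm.cdf((x - half) / linewidth)) / outer_splitting
    return _derivative_from_absorption(field, absorption)


def default_templates(field: np.ndarray | None = None) -> ComponentTemplates:
    field = default_field_axis() if field is None else np.asarray(field, dtype=float)
    return ComponentTemplates(make_free_template(field), make_bound_template(field))


def mix_spectrum(
    templates: ComponentTemplates,
    free_fraction: float,
    snr: float = np.inf,
    seed: int | None = 0,
) -> CWSpectrum:
    """Synthesize free_fraction * free + (1 - free_fraction) * bound, with
    white noise at ``snr`` = max|amplitude| / noise_sd."""
    if not 0.0 <= free_fraction <= 1.0:
        raise InvalidInputError("free_fraction must lie in [0, 1]")
    amp = free_fraction * templates.free.amplitude + (1.0 - free_fraction) * templates.bound.amplitude
    if np.isfinite(snr):
        if snr <= 0:
            raise InvalidInputError("snr must be positive")
        rng = np.random.default_rng(seed)
        amp = amp + rng.normal(0.0, np.max(np.abs(amp)) / snr, size=amp.shape)
    return CWSpectrum(templates.free.field, amp)


def unmix(spectrum: CWSpectrum, templates: ComponentTemplates) -> tuple[float, float]:
    """Non-negative two-component decomposition.

    Returns (free_fraction, residual_norm).  Scale-invariant in the input
    spectrum amplitude; fractions are spin-count fractions because both
    templates carry unit double integral.
    """
    if not np.array_equal(spectrum.field, templates.free.field):
        raise InvalidInputError("spectrum must be sampled on the template axis")
    A = np.column_stack([templates.free.amplitude, templates.bound.amplitude])
    w, rnorm = optimize.nnls(A, spectrum.amplitude)
    if w.sum() <= 0:
        raise DegenerateFitError("both component weights are zero")
    return float(w[0] / w.sum()), float(rnorm)
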