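"""Per-dimer ligand occupancy inference and cooperativity testing.

A homodimer population is summarized by the fractions (f0, f1, f2) of
dimers carrying 0, 1 or 2 paramagnetic ligands.  Two EPR observables
constrain these fractions: the DEER modulation depth Delta (which counts
spin *pairs* through Delta = lambda * q, with q the fraction of bound spins
sitting in a doubly occupied dimer and lambda the pump inversion
efficiency) and the bound-spin signal m = f1 + 2 f2 (spins per dimer, from
integrated signal intensity).  Inverting these two numbers yields the
occupancy split.

Cooperativity is judged against the random-binding null: a binomial
distribution of ligands over dimers at the same mean load, under which
f2_random = p^2 with p the per-site occupancy probability.  An excess of
doubly occupied dimers over that expectation indicates cooperative binding.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .deer import LabelingModel, pair_fraction
from .errors import InfeasibleObservablesError, InvalidInputError


@dataclass(frozen=True)
class OccupancyState:
    """Fractions of dimers with 0, 1, 2 bound paramagnetic ligands."""

    f0: float
    f1: float
    f2: float

    def __post_init__(self):
        for name, val in (("f0", self.f0), ("f1", self.f1), ("f2", self.f2)):
            if not -1e-9 <= val <= 1.0 + 1e-9:
                raise InvalidInputError(f"{name}={val} outside [0, 1]")
        if abs(self.f0 + self.f1 + self.f2 - 1.0) > 1e-9:
            raise InvalidInputError("occupancy fractions must sum to 1")

    @property
    def mean_load(self) -> float:
        """Mean number of bound ligands per dimer, f1 + 2 f2."""
        return self.f1 + 2.0 * self.f2

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.f0, self.f1, self.f2)


@dataclass(frozen=True)
class CooperativityReport:
    """Observed vs random-binding-null doubly-occupied fraction."""

    observed_f2: float
    expected_f2_random: float
    ratio: float
    ci_lo: float
    ci_hi: float
    verdict: str  # cooperative | anti-cooperative | indistinguishable


def infer_occupancy(depth: float, bound_signal: float, labels: LabelingModel) -> OccupancyState:
    """Invert (modulation depth, bound-spin signal) to occupancy fractions.

    q = depth / lambda (clipped to [0, 1] with a warning, since noise can
    push the measured depth slightly past the lambda ceiling), then
    f2 = q m / 2, f1 = m (1 - q), f0 = 1 - f1 - f2.  Exact inverse of
    :func:`dimerdeer.deer.observables_from_state` at spin survival 1.
    """
    lam = labels.inversion_efficiency
    if depth < 0 or depth > lam + 1e-9:
        raise InvalidInputError(f"depth must lie in [0, lambda={lam}]")
    if not 0.0 <= bound_signal <= 2.0:
        raise InvalidInputError("bound_signal must lie in [0, 2]")
    q = depth / lam
    if q > 1.0 or q < 0.0:
        warnings.warn("pair fraction clipped to [0, 1]", stacklevel=2)
        q = float(np.clip(q, 0.0, 1.0))
    f2 = q * bound_signal / 2.0
    f1 = bound_signal * (1.0 - q)
    f0 = 1.0 - f1 - f2
    if f0 < -1e-9:
        raise InfeasibleObservablesError(
            f"observables imply f0={f0:.4g} < 0: depth and bound_signal inconsistent"
        )
    return OccupancyState(max(f0, 0.0), f1, f2)


def apply_spin_reduction(state: OccupancyState, s: float) -> OccupancyState:
    """Occupancy of *paramagnetic* ligands after independent label survival s.

    Each label stays paramagnetic with probability s, so a doubly occupied
    dimer contributes s^2 to f2' and 2 s (1-s) to f1' (binomial thinning).
    """
    if not 0.0 <= s <= 1.0:
        raise InvalidInputError("spin survival must lie in [0, 1]")
    f2 = state.f2 * s * s
    f1 = state.f1 * s + 2.0 * state.f2 * s * (1.0 - s)
    return OccupancyState(1.0 - f1 - f2, f1, f2)


def random_binding_null(state: OccupancyState) -> OccupancyState:
    """Binomial occupancy at the same mean ligand load, independent sites.

    p = (f1 + 2 f2)/2 per site; returns ((1-p)^2, 2p(1-p), p^2).
    """
    p = state.mean_load / 2.0
    return OccupancyState((1.0 - p) ** 2, 2.0 * p * (1.0 - p), p * p)


def cooperativity_test(
    state: OccupancyState,
    n_dimers: int = 5000,
    n_boot: int = 1000,
    seed: int = 0,
) -> CooperativityReport:
    """Test the doubly-occupied excess over the random-binding null.

    The ratio f2 / f2_random is resampled by a multinomial parametric
    bootstrap of ``n_dimers`` dimers; the verdict is "cooperative" when the
    95% CI of the ratio lies above 1, "anti-cooperative" when below, and
    "indistinguishable" otherwise.
    """
    if n_dimers < 100:
        raise InvalidInputError("n_dimers must be >= 100")
    null = random_binding_null(state)
    if null.f2 <= 0:
        if state.f2 > 0:
            return CooperativityReport(state.f2, 0.0, np.inf, np.inf, np.inf, "cooperative")
        return CooperativityReport(0.0, 0.0, 1.0, 1.0, 1.0, "indistinguishable")
    ratio = state.f2 / null.f2

    rng = np.random.default_rng(seed)
    counts = rng.multinomial(n_dimers, state.as_tuple(), size=n_boot)
    f1_b = counts[:, 1] / n_dimers
    f2_b = counts[:, 2] / n_dimers
    p_b = (f1_b + 2.0 * f2_b) / 2.0
    with np.errstate(divide="ignore", invalid="ignore"):
        ratios = np.where(p_b > 0, f2_b / np.maximum(p_b * p_b, 1e-300), 1.0)
    ci_lo, ci_hi = np.percentile(ratios, [2.5, 97.5])
    if ci_lo > 1.0:
        verdict = "cooperative"
    elif ci_hi < 1.0:
        verdict = "anti-cooperative"
    else:
        verdict = "indistinguishable"
    return CooperativityReport(state.f2, null.f2, ratio, float(ci_lo), float(ci_hi), verdict)


__all__ = [
    "OccupancyState",
    "CooperativityReport",
    "infer_occupancy",
    "apply_spin_reduction",
    "random_binding_null",
    "cooperativity_test",
    "pair_fraction",
]
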