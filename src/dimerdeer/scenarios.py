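"""Synthetic scenario generator.

Emulates the two experiments the analysis chain is built for: an in vitro
DEER + CW measurement of a spin-labelled ligand binding to a homodimer,
and its in-cell counterpart (shorter dipolar evolution time, partial
nitroxide reduction, lower SNR).

A scenario starts from a binding model for the dimer population:

* ``independent(p)`` — each catalytic site is occupied i.i.d. with
  probability p (secondary sites stay empty); the binomial null.
* ``gated(load, gate_strength)`` — the mechanistic model: a first ligand
  binds a catalytic site, which opens the secondary site of the *other*
  monomer for the second ligand.  Allowed dimer states are {empty, one
  catalytic, catalytic + opposite secondary}; both catalytic sites are
  never occupied simultaneously.  ``load`` is the mean number of bound
  ligands per dimer and ``gate_strength`` the fraction of bound ligands
  that sit in a doubly occupied dimer (the pair fraction q), so
  f2 = gate_strength * load / 2 and f1 = load * (1 - gate_strength).

Doubly occupied dimers contribute an inter-label distance drawn from the
Gaussian pair model of their occupied site pair; the population of draws
is assembled into the ground-truth P(r), the occupancy state is mapped to
(depth, bound signal) through the labelling model, and a noisy dipolar
trace plus a two-component CW spectrum are synthesized.  Everything is
reproducible from the configured seeds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from . import io
from .cw import CWSpectrum, default_templates, mix_spectrum
from .deer import (
    DipolarTrace,
    DistanceDistribution,
    DistanceGrid,
    LabelingModel,
    TimeAxis,
    TraceModel,
    observables_from_state,
    simulate_trace,
)
from .errors import BundleIOError, InvalidConfigError
from .hypotheses import SiteGeometry, canonical_pair
from .occupancy import OccupancyState

logger = logging.getLogger(__name__)

#: Dimer states of the gated (mechanism-constrained) model.
GATED_DOUBLE_STATES = (("a1", "b2"), ("b1", "a2"))
GATED_SINGLE_STATES = (("a1",), ("b1",))


@dataclass(frozen=True)
class IndependentBinding:
    """Each catalytic site occupied i.i.d. with probability p."""

    p: float

    def __post_init__(self):
        if not 0.0 <= self.p <= 1.0:
            raise InvalidConfigError("p must lie in [0, 1]")

    @property
    def model_fractions(self) -> OccupancyState:
        p = self.p
        return OccupancyState((1 - p) ** 2, 2 * p * (1 - p), p * p)


@dataclass(frozen=True)
class GatedBinding:
    """Mechanism-constrained binding: no simultaneous double-catalytic occupancy."""

    load: float
    gate_strength: float

    def __post_init__(self):
        if not 0.0 <= self.gate_strength <= 1.0:
            raise InvalidConfigError("gate_strength must lie in [0, 1]")
        if not 0.0 <= self.load <= 2.0:
            raise InvalidConfigError("load must lie in [0, 2]")
        f1 = self.load * (1.0 - self.gate_strength)
        f2 = self.gate_strength * self.load / 2.0
        if f1 + f2 > 1.0 + 1e-12:
            raise InvalidConfigError(
                f"unachievable load: f1+f2 = {f1 + f2:.4g} > 1 for load={self.load}, "
                f"gate_strength={self.gate_strength}"
            )

    @classmethod
    def from_fractions(cls, state: OccupancyState) -> "GatedBinding":
        load = state.mean_load
        if load <= 0:
            return cls(0.0, 0.0)
        return cls(load, 2.0 * state.f2 / load)

    @property
    def model_fractions(self) -> OccupancyState:
        f1 = self.load * (1.0 - self.gate_strength)
        f2 = self.gate_strength * self.load / 2.0
        return OccupancyState(1.0 - f1 - f2, f1, f2)


@dataclass(frozen=True)
class TraceSettings:
    t_max: float = 2.0          # us
    dt: float = 0.008           # us
    background_rate: float = 0.05  # 1/us
    snr: float = 50.0           # depth / noise_sd
    seed: int = 1

    def __post_init__(self):
        if self.t_max <= 0 or self.dt <= 0 or self.dt > self.t_max / 50.0:
            raise InvalidConfigError("require 0 < dt <= t_max/50")
        if self.snr <= 0:
            raise InvalidConfigError("snr must be positive")


@dataclass(frozen=True)
class CWSettings:
    free_fraction: float = 0.09
    snr: float = 100.0          # max|amplitude| / noise_sd
    seed: int = 7

    def __post_init__(self):
        if not 0.0 <= self.free_fraction <= 1.0:
            raise InvalidConfigError("free_fraction must lie in [0, 1]")
        if self.snr <= 0:
            raise InvalidConfigError("snr must be positive")


@dataclass(frozen=True)
class ScenarioConfig:
    binding: IndependentBinding | GatedBinding
    geometry: SiteGeometry = field(default_factory=lambda: SiteGeometry.with_sigma(0.1))
    labels: LabelingModel = field(default_factory=LabelingModel)
    trace: TraceSettings = field(default_factory=TraceSettings)
    cw: CWSettings = field(default_factory=CWSettings)
    n_dimers: int = 20000
    grid: DistanceGrid = field(default_factory=DistanceGrid.regular)
    population_seed: int = 0

    def __post_init__(self):
        if self.n_dimers < 1:
            raise InvalidConfigError("n_dimers must be >= 1")


@dataclass(frozen=True)
class ScenarioTruth:
    """Ground truth saved with every bundle for recovery tests."""

    state: OccupancyState            # empirical sampled fractions
    model_state: OccupancyState      # configured model fractions
    pair_counts: dict
    pair_draws: np.ndarray           # nm, one per doubly occupied dimer
    distribution: DistanceDistribution | None
    depth: float
    bound_signal: float
    free_fraction: float


@dataclass(frozen=True)
class ScenarioBundle:
    trace: DipolarTrace
    cw: CWSpectrum
    truth: ScenarioTruth


def sample_population(
    model: IndependentBinding | GatedBinding,
    geometry: SiteGeometry,
    n_dimers: int,
    seed: int = 0,
) -> list[tuple[str, ...]]:
    """Draw per-dimer occupied-site tuples from the binding model.

    Under the gated model the count of dimers with both catalytic sites
    occupied is zero by construction; singly occupied dimers hold their
    ligand in a catalytic site (a1 or b1 with equal probability).
    """
    if n_dimers < 1:
        raise InvalidConfigError("n_dimers must be >= 1")
    rng = np.random.default_rng(seed)
    if isinstance(model, IndependentBinding):
        occ = rng.random((n_dimers, 2)) < model.p
        pop = []
        for a1, b1 in occ:
            sites = tuple(s for s, on in zip(("a1", "b1"), (a1, b1)) if on)
            pop.append(sites)
        return pop
    fr = model.model_fractions
    probs = [fr.f0, fr.f1 / 2, fr.f1 / 2, fr.f2 / 2, fr.f2 / 2]
    states = [(), *GATED_SINGLE_STATES, *GATED_DOUBLE_STATES]
    idx = rng.choice(len(states), size=n_dimers, p=np.array(probs) / np.sum(probs))
    return [states[i] for i in idx]


def distribution_from_draws(
    draws: np.ndarray, grid: DistanceGrid, bandwidth: float = 0.05
) -> DistanceDistribution:
    """Gaussian-kernel density estimate of distance draws on the grid."""
    draws = np.asarray(draws, dtype=float)
    if draws.size == 0:
        raise InvalidConfigError("no distance draws to assemble")
    diff = grid.values[:, None] - draws[None, :]
    dens = np.exp(-0.5 * (diff / bandwidth) ** 2).sum(axis=1)
    return DistanceDistribution.from_unnormalized(grid, dens)


def generate_scenario(config: ScenarioConfig) -> ScenarioBundle:
    """Synthesize one full scenario bundle with its ground truth."""
    population = sample_population(
        config.binding, config.geometry, config.n_dimers, config.population_seed
    )
    counts = np.bincount([len(sites) for sites in population], minlength=3)
    state = OccupancyState(*(counts / config.n_dimers))

    rng = np.random.default_rng(config.trace.seed)
    pair_counts: dict[str, int] = {}
    draws = []
    for sites in population:
        if len(sites) == 2:
            pair = canonical_pair(f"{sites[0]}-{sites[1]}")
            pair_counts[pair] = pair_counts.get(pair, 0) + 1
            mu, sd = config.geometry.pairs[pair]
            draws.append(rng.normal(mu, sd))
    draws = np.clip(np.asarray(draws), config.grid.values[0], config.grid.values[-1])

    depth, bound_signal = observables_from_state(state, config.labels)
    if draws.size == 0 or depth <= 0:
        logger.warning("scenario has no modulation (no doubly occupied spin pairs)")
        dist = None
        pr = DistanceDistribution.from_unnormalized(config.grid, np.ones(len(config.grid)))
        depth = 0.0
    else:
        dist = distribution_from_draws(draws, config.grid)
        pr = dist

    time = TimeAxis.regular(config.trace.t_max, config.trace.dt)
    noise_sd = depth / config.trace.snr if depth > 0 else 1.0 / config.trace.snr
    model = TraceModel(depth, config.trace.background_rate, pr)
    trace = simulate_trace(model, time, noise_sd=noise_sd, seed=config.trace.seed)

    cw = mix_spectrum(default_templates(), config.cw.free_fraction,
                      snr=config.cw.snr, seed=config.cw.seed)

    model_state = config.binding.model_fractions
    truth = ScenarioTruth(
        state=state,
        model_state=model_state,
        pair_counts=pair_counts,
        pair_draws=draws,
        distribution=dist,
        depth=depth,
        bound_signal=bound_signal,
        free_fraction=config.cw.free_fraction,
    )
    return ScenarioBundle(trace=trace, cw=cw, truth=truth)


def invitro_config(**overrides) -> ScenarioConfig:
    """The in vitro preset: gated binding at the 70/21/9 occupancy split,
    cross-pairing geometry, 2 us trace at SNR 50, CW free fraction 9%."""
    base = ScenarioConfig(
        binding=GatedBinding.from_fractions(OccupancyState(0.70, 0.21, 0.09)),
        labels=LabelingModel(inversion_efficiency=0.4, spin_survival=1.0),
        trace=TraceSettings(t_max=2.0, dt=0.008, background_rate=0.05, snr=50.0, seed=1),
        cw=CWSettings(free_fraction=0.09, snr=100.0, seed=7),
    )
    return replace(base, **overrides) if overrides else base


def incell_config(**overrides) -> ScenarioConfig:
    """The in-cell preset: same binding pattern, 1.5 us trace, spin survival
    0.5 (nitroxide reduction) and SNR 30."""
    base = ScenarioConfig(
        binding=GatedBinding.from_fractions(OccupancyState(0.70, 0.21, 0.09)),
        labels=LabelingModel(inversion_efficiency=0.4, spin_survival=0.5),
        trace=TraceSettings(t_max=1.5, dt=0.008, background_rate=0.05, snr=30.0, seed=2),
        cw=CWSettings(free_fraction=0.09, snr=100.0, seed=7),
    )
    return replace(base, **overrides) if overrides else base


PRESETS = {"invitro": invitro_config, "incell": incell_config}


def write_bundle(bundle: ScenarioBundle, directory) -> None:
    """Write trace, spectrum, truth P(r), draws and truth key-values."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    io.write_trace(directory / "trace.dat", bundle.trace)
    io.write_spectrum(directory / "cw.dat", bundle.cw)
    t = bundle.truth
    if t.distribution is not None:
        io.write_distribution(directory / "pr_truth.dat", t.distribution)
    if t.pair_draws.size:
        io.write_xy(directory / "draws.dat", np.arange(t.pair_draws.size), t.pair_draws,
                    header="pair distance draws: index, r (nm)")
    kv = {
        "f0": t.state.f0, "f1": t.state.f1, "f2": t.state.f2,
        "model_f0": t.model_state.f0, "model_f1": t.model_state.f1, "model_f2": t.model_state.f2,
        "depth": t.depth, "bound_signal": t.bound_signal,
        "free_fraction": t.free_fraction,
        "noise_sd": bundle.trace.noise_sd,
    }
    for pair, n in sorted(t.pair_counts.items()):
        kv[f"pairs_{pair}"] = n
    io.write_keyvalues(directory / "truth.txt", kv, header="scenario ground truth")


def read_bundle(directory) -> ScenarioBundle:
    directory = Path(directory)
    kv = io.read_keyvalues(directory / "truth.txt")
    trace = io.read_trace(directory / "trace.dat", noise_sd=float(kv["noise_sd"]))
    cw = io.read_spectrum(directory / "cw.dat")
    pr_path = directory / "pr_truth.dat"
    dist = io.read_distribution(pr_path) if pr_path.exists() else None
    draws_path = directory / "draws.dat"
    draws = io.read_xy(draws_path)[1] if draws_path.exists() else np.array([])
    pair_counts = {
        key.removeprefix("pairs_"): int(val)
        for key, val in kv.items() if key.startswith("pairs_")
    }
    truth = ScenarioTruth(
        state=OccupancyState(float(kv["f0"]), float(kv["f1"]), float(kv["f2"])),
        model_state=OccupancyState(
            float(kv["model_f0"]), float(kv["model_f1"]), float(kv["model_f2"])
        ),
        pair_counts=pair_counts,
        pair_draws=draws,
        distribution=dist,
        depth=float(kv["depth"]),
        bound_signal=float(kv["bound_signal"]),
        free_fraction=float(kv["free_fraction"]),
    )
    return ScenarioBundle(trace=trace, cw=cw, truth=truth)
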