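"""Binding-site geometry and pairing-hypothesis discrimination.

The homodimer carries four candidate ligand sites: a catalytic pocket in
each monomer (a1, b1) and a secondary interface site in each monomer
(a2, b2).  Dimer (C2) symmetry makes the inter-label distances pairwise
equivalent: a1-a2 = b1-b2 (intra-monomer) and a1-b2 = b1-a2 (cross
pairing).  Each doubly-occupied pairing predicts an inter-nitroxide
distance distribution; a pairing hypothesis is a weighted mixture of such
pair distributions, and hypotheses are scored against a recovered P(r) by
the overlap coefficient restricted to the distance window the experiment
can actually resolve (below the reliability limit).
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd

from .deer import DistanceDistribution, DistanceGrid
from .errors import InvalidInputError, UndefinedScoreError

#: Canonical site-pair names under dimer symmetry.
PAIR_NAMES = ("a1-b1", "a1-a2", "a1-b2", "a2-b2")

#: Aliases mapped to canonical pairs by C2 symmetry.
_PAIR_ALIASES = {
    "a1-b1": "a1-b1", "b1-a1": "a1-b1",
    "a1-a2": "a1-a2", "a2-a1": "a1-a2", "b1-b2": "a1-a2", "b2-b1": "a1-a2",
    "a1-b2": "a1-b2", "b2-a1": "a1-b2", "b1-a2": "a1-b2", "a2-b1": "a1-b2",
    "a2-b2": "a2-b2", "b2-a2": "a2-b2",
}

SCORE_CONSISTENT = 0.5
SCORE_EXCLUDED = 0.1


def canonical_pair(pair: str) -> str:
    key = pair.strip().lower().replace(".", "").replace("_", "-")
    if key not in _PAIR_ALIASES:
        raise InvalidInputError(f"unknown site pair {pair!r}; expected one of {PAIR_NAMES}")
    return _PAIR_ALIASES[key]


@dataclass(frozen=True)
class SiteGeometry:
    """Gaussian pair-distance models (mean, sd in nm) for the four pairings.

    Defaults: both-catalytic 4.1 nm, intra-monomer 3.0 nm, cross 2.5 nm,
    secondary-secondary 2.5 nm (not constrained by any default hypothesis).
    """

    pairs: dict = dc_field(default_factory=lambda: {
        "a1-b1": (4.1, 0.15),
        "a1-a2": (3.0, 0.15),
        "a1-b2": (2.5, 0.15),
        "a2-b2": (2.5, 0.15),
    })

    def __post_init__(self):
        canon = {}
        for pair, (mu, sd) in self.pairs.items():
            if mu <= 0 or sd <= 0:
                raise InvalidInputError(f"pair {pair}: mean and sd must be positive")
            canon[canonical_pair(pair)] = (float(mu), float(sd))
        for name in PAIR_NAMES:
            if name not in canon:
                raise InvalidInputError(f"geometry missing pair {name}")
        object.__setattr__(self, "pairs", canon)

    @classmethod
    def with_sigma(cls, sigma: float) -> "SiteGeometry":
        base = cls()
        return cls({k: (mu, sigma) for k, (mu, _) in base.pairs.items()})

    def mean(self, pair: str) -> float:
        return self.pairs[canonical_pair(pair)][0]

    def sd(self, pair: str) -> float:
        return self.pairs[canonical_pair(pair)][1]


@dataclass(frozen=True)
class PairingHypothesis:
    """Named weighted mixture of pair distributions with its predicted P(r)."""

    name: str
    components: tuple
    predicted: DistanceDistribution


@dataclass(frozen=True)
class ResidenceWeights:
    """Non-negative per-source weights (e.g. per MD run), normalized to 1."""

    weights: np.ndarray

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 1 or w.size == 0 or np.any(w < 0) or w.sum() <= 0:
            raise InvalidInputError("weights must be non-negative with positive sum")
        object.__setattr__(self, "weights", w / w.sum())


def pair_distribution(geometry: SiteGeometry, pair: str, grid: DistanceGrid) -> DistanceDistribution:
    """Gaussian pair-distance distribution on the grid (truncated, renormalized)."""
    mu, sd = geometry.pairs[canonical_pair(pair)]
    return DistanceDistribution.gaussian(grid, mu, sd)


def empirical_pair_distribution(
    frames: pd.DataFrame,
    grid: DistanceGrid,
    weights: ResidenceWeights | None = None,
    smoothing: float = 0.05,
) -> DistanceDistribution:
    """P(r) from a coordinate ensemble of label positions.

    ``frames`` columns: frame, source, ax, ay, az, bx, by, bz (nm); one
    point per label (N-O midpoint), conformer spread enters via frames.
    Per-frame distances are histogrammed on the grid, weighted by the
    residence weight of their source, and Gaussian-smoothed
    (default bandwidth 0.05 nm).
    """
    required = ["frame", "source", "ax", "ay", "az", "bx", "by", "bz"]
    missing = [c for c in required if c not in frames.columns]
    if missing:
        raise InvalidInputError(f"coordinate table missing columns {missing}")
    if len(frames) == 0:
        raise InvalidInputError("coordinate table has no frames")
    a = frames[["ax", "ay", "az"]].to_numpy(dtype=float)
    b = frames[["bx", "by", "bz"]].to_numpy(dtype=float)
    bad = ~np.isfinite(a).all(axis=1) | ~np.isfinite(b).all(axis=1)
    if bad.any():
        row = int(np.flatnonzero(bad)[0])
        raise InvalidInputError(f"malformed coordinates at table row {row}")
    dists = np.linalg.norm(a - b, axis=1)

    sources = pd.unique(frames["source"])
    if weights is None:
        w_map = {s: 1.0 / len(sources) for s in sources}
    else:
        if len(weights.weights) != len(sources):
            raise InvalidInputError("one residence weight per source required")
        w_map = dict(zip(sources, weights.weights))
    frame_w = frames["source"].map(w_map).to_numpy(dtype=float)
    # per-source normalization so each source contributes its weight
    counts = frames.groupby("source")["frame"].transform("size").to_numpy(dtype=float)
    frame_w = frame_w / counts

    edges = np.concatenate([
        grid.values - grid.dr / 2.0, [grid.values[-1] + grid.dr / 2.0]
    ])
    hist, _ = np.histogram(np.clip(dists, grid.values[0], grid.values[-1]), bins=edges, weights=frame_w)
    if smoothing > 0:
        half = int(np.ceil(4 * smoothing / grid.dr))
        x = np.arange(-half, half + 1) * grid.dr
        kern = np.exp(-0.5 * (x / smoothing) ** 2)
        hist = np.convolve(hist, kern / kern.sum(), mode="same")
    return DistanceDistribution.from_unnormalized(grid, hist)


def compose_hypothesis(name: str, parts: list[tuple[DistanceDistribution, float]]) -> PairingHypothesis:
    """Weighted superposition of component distributions."""
    if len(parts) == 0:
        raise InvalidInputError("hypothesis needs at least one component")
    weights = np.array([w for _, w in parts], dtype=float)
    if np.any(weights < 0) or weights.sum() <= 0:
        raise InvalidInputError("weights must be non-negative, not all zero")
    weights = weights / weights.sum()
    grid = parts[0][0].grid
    mix = np.zeros(len(grid))
    for (dist, _), w in zip(parts, weights):
        if not np.array_equal(dist.grid.values, grid.values):
            raise InvalidInputError("all components must share one grid")
        mix += w * dist.density
    predicted = DistanceDistribution.from_unnormalized(grid, mix)
    comps = tuple((f"component-{i}", float(w)) for i, w in enumerate(weights))
    return PairingHypothesis(name, comps, predicted)


def default_hypotheses(geometry: SiteGeometry, grid: DistanceGrid) -> list[PairingHypothesis]:
    """The three pairings the experiment discriminates among.

    cross — one catalytic site plus the secondary site of the *other*
    monomer (a1+b2 or b1+a2; symmetric superposition is a single peak);
    both-catalytic — a1+b1; intra-monomer — a1+a2 or b1+b2.  Exclusive
    occupation of both secondary sites is deliberately not a default.
    """
    cross = pair_distribution(geometry, "a1-b2", grid)
    return [
        compose_hypothesis("cross", [(cross, 0.5), (cross, 0.5)]),
        compose_hypothesis("both-catalytic", [(pair_distribution(geometry, "a1-b1", grid), 1.0)]),
        compose_hypothesis("intra-monomer", [(pair_distribution(geometry, "a1-a2", grid), 1.0)]),
    ]


def score_hypothesis(
    recovered: DistanceDistribution,
    hypothesis: PairingHypothesis,
    r_limit: float = np.inf,
) -> float:
    """Overlap coefficient of recovered and predicted P(r) below r_limit.

    Both curves are renormalized on the window r <= r_limit; the score is
    the integral of the pointwise minimum (1 = identical, 0 = disjoint).
    """
    grid = recovered.grid
    if not np.array_equal(grid.values, hypothesis.predicted.grid.values):
        raise InvalidInputError("recovered and predicted must share one grid")
    window = grid.values <= r_limit
    if window.sum() < 2:
        raise UndefinedScoreError("distance window below r_limit is empty")
    r = grid.values[window]
    a = recovered.density[window]
    b = hypothesis.predicted.density[window]
    norm_a, norm_b = np.trapezoid(a, r), np.trapezoid(b, r)
    if norm_a <= 1e-12 or norm_b <= 1e-12:
        raise UndefinedScoreError(
            f"no mass below r_limit={r_limit} nm for hypothesis {hypothesis.name!r}"
        )
    return float(np.trapezoid(np.minimum(a / norm_a, b / norm_b), r))


def rank_hypotheses(
    recovered: DistanceDistribution,
    hypotheses: list[PairingHypothesis],
    r_limit: float = np.inf,
    consistent_threshold: float = SCORE_CONSISTENT,
    excluded_threshold: float = SCORE_EXCLUDED,
) -> list[tuple[str, float, str]]:
    """Score and sort hypotheses; call each consistent/inconclusive/excluded.

    Returns (name, score, call) triples sorted by descending score, ties
    broken alphabetically by name.
    """
    if len(hypotheses) < 2:
        raise InvalidInputError("need at least 2 hypotheses to rank")
    rows = []
    for hyp in hypotheses:
        score = score_hypothesis(recovered, hyp, r_limit)
        if score >= consistent_threshold:
            call = "consistent"
        elif score <= excluded_threshold:
            call = "excluded"
        else:
            call = "inconclusive"
        rows.append((hyp.name, score, call))
    rows.sort(key=lambda row: (-row[1], row[0]))
    return rows
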