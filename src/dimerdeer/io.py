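"""Plain-text readers/writers for traces, spectra and distributions.

All files are two-column whitespace- or comma-separated tables; lines
starting with '#' are headers.  Traces: time (us), amplitude.  Spectra:
field (mT), amplitude.  Distributions: distance (nm), density (1/nm).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .cw import CWSpectrum
from .deer import DipolarTrace, DistanceDistribution, DistanceGrid, TimeAxis
from .errors import BundleIOError


def read_xy(path) -> tuple[np.ndarray, np.ndarray]:
    path = Path(path)
    if not path.exists():
        raise BundleIOError(f"missing file: {path}")
    xs, ys = [], []
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.replace(",", " ").split()
        if len(parts) != 2:
            raise BundleIOError(f"{path}:{lineno}: expected 2 columns, got {len(parts)}")
        try:
            xs.append(float(parts[0]))
            ys.append(float(parts[1]))
        except ValueError as exc:
            raise BundleIOError(f"{path}:{lineno}: non-numeric value") from exc
    if not xs:
        raise BundleIOError(f"{path}: no data rows")
    return np.array(xs), np.array(ys)


def write_xy(path, x, y, header: str = "") -> None:
    path = Path(path)
    lines = [f"# {h}" for h in header.splitlines() if h]
    lines += [f"{xi:.17g} {yi:.17g}" for xi, yi in zip(x, y)]
    path.write_text("\n".join(lines) + "\n")


def read_trace(path, noise_sd: float = 0.0) -> DipolarTrace:
    t, v = read_xy(path)
    return DipolarTrace(TimeAxis(t), v, noise_sd=noise_sd)


def write_trace(path, trace: DipolarTrace) -> None:
    write_xy(path, trace.time.values, trace.signal,
             header=f"dipolar trace: time (us), amplitude; noise_sd={trace.noise_sd:.12g}")


def read_spectrum(path) -> CWSpectrum:
    b, a = read_xy(path)
    return CWSpectrum(b, a)


def write_spectrum(path, spectrum: CWSpectrum) -> None:
    write_xy(path, spectrum.field, spectrum.amplitude, header="cw spectrum: field (mT), amplitude")


def read_distribution(path) -> DistanceDistribution:
    r, p = read_xy(path)
    return DistanceDistribution.from_unnormalized(DistanceGrid(r), p)


def write_distribution(path, dist: DistanceDistribution) -> None:
    write_xy(path, dist.grid.values, dist.density,
             header="distance distribution: r (nm), P(r) (1/nm)")


def read_keyvalues(path) -> dict:
    path = Path(path)
    if not path.exists():
        raise BundleIOError(f"missing file: {path}")
    out = {}
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise BundleIOError(f"{path}:{lineno}: expected key=value")
        key, _, val = line.partition("=")
        out[key.strip()] = val.strip()
    return out


def write_keyvalues(path, mapping: dict, header: str = "") -> None:
    lines = [f"# {h}" for h in header.splitlines() if h]
    for key, val in mapping.items():
        if isinstance(val, float):
            val = f"{val:.12g}"
        lines.append(f"{key} = {val}")
    Path(path).write_text("\n".join(lines) + "\n")
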