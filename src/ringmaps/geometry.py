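"""Correlated ring maps, morph sequences and circular-geometry utilities.

Two circular maps A and B are generated from a "middle" map coordinate
``theta_mid`` (uniform on the circle) and an auxiliary distance coordinate
``phi`` (uniform on the symmetric interval ``[-PHI_HALF_WIDTH, +PHI_HALF_WIDTH]``):

    theta_A = theta_mid + d * phi
    theta_B = theta_mid - d * phi      (mod 2*pi)

``d`` in [0, 1] sets the distance between the maps: ``d = 0`` makes them
identical, ``d = 1`` makes them statistically independent (the pair
``(theta_A, theta_B)`` is then uniform on the torus).  Each map cannot differ
from the middle map by more than ``d * PHI_HALF_WIDTH``, so the two maps never
differ by more than ``d * pi`` along the circle.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

TWO_PI = 2.0 * np.pi

#: Half-width of the admissible interval of the distance coordinate ``phi``.
#: With this value the d=1 limit yields exactly uncorrelated maps.
PHI_HALF_WIDTH = np.pi / 2.0

CONVENTION_VERSION = 1


class MapDistanceError(ValueError):
    """Raised when a map-distance parameter lies outside [0, 1]."""


class InconsistentLabelsError(ValueError):
    """Raised when labels cannot have been produced by the forward transform."""


def wrap_angle(theta):
    """Wrap angles to the canonical interval [0, 2*pi)."""
    return np.mod(theta, TWO_PI)


def signed_arc(a, b):
    """Signed shortest arc from angle ``a`` to angle ``b``, in (-pi, pi].

    The branch cut sits at exactly pi: antipodal pairs resolve to +pi, i.e.
    ties are broken toward the counter-clockwise arc.
    """
    delta = np.mod(np.asarray(b, dtype=float) - np.asarray(a, dtype=float), TWO_PI)
    return np.where(delta > np.pi, delta - TWO_PI, delta)


def circ_dist(a, b):
    """Circular distance: length of the shorter arc between two angles."""
    return np.abs(signed_arc(a, b))


def map_distance_bound(d: float) -> float:
    """Maximum circular distance between theta_A and theta_B at distance ``d``."""
    _check_d(d)
    return min(d * np.pi, np.pi)


def circular_correlation(a, b) -> float:
    """Fisher-Lee circular correlation coefficient between two angle samples."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    da = np.angle(np.exp(1j * a) / np.mean(np.exp(1j * a)))
    db = np.angle(np.exp(1j * b) / np.mean(np.exp(1j * b)))
    num = np.sum(np.sin(da) * np.sin(db))
    den = np.sqrt(np.sum(np.sin(da) ** 2) * np.sum(np.sin(db) ** 2))
    return float(num / den)


def _check_d(d: float) -> None:
    if not (0.0 <= d <= 1.0):
        raise MapDistanceError(f"map distance d={d!r} outside [0, 1]")


@dataclass(frozen=True)
class NeuronLabels:
    """Per-neuron coordinates: middle map, distance coordinate, maps A and B."""

    theta_mid: np.ndarray
    phi: np.ndarray
    theta_A: np.ndarray
    theta_B: np.ndarray
    d: float

    def __post_init__(self):
        n = len(self.theta_mid)
        for name in ("phi", "theta_A", "theta_B"):
            if len(getattr(self, name)) != n:
                raise InconsistentLabelsError(f"label array {name!r} has wrong length")

    def __len__(self) -> int:
        return len(self.theta_mid)

    @property
    def n(self) -> int:
        return len(self.theta_mid)

    @classmethod
    def from_mid(cls, theta_mid, phi, d: float) -> "NeuronLabels":
        _check_d(d)
        theta_mid = wrap_angle(np.asarray(theta_mid, dtype=float))
        phi = np.asarray(phi, dtype=float)
        if np.any(np.abs(phi) > PHI_HALF_WIDTH + 1e-12):
            raise InconsistentLabelsError("phi outside its admissible interval")
        theta_a, theta_b = forward_transform(theta_mid, phi, d)
        return cls(theta_mid=theta_mid, phi=phi, theta_A=theta_a, theta_B=theta_b, d=d)


def forward_transform(theta_mid, phi, d: float):
    """Map (theta_mid, phi) to the per-map angles (theta_A, theta_B)."""
    _check_d(d)
    theta_mid = np.asarray(theta_mid, dtype=float)
    phi = np.asarray(phi, dtype=float)
    return wrap_angle(theta_mid + d * phi), wrap_angle(theta_mid - d * phi)


def inverse_transform(theta_A, theta_B, d: float, *, atol: float = 1e-9):
    """Recover (theta_mid, phi) from the per-map angles.

    The difference theta_B - theta_A is reduced to the shortest arc (branch
    cut at pi, ties toward the counter-clockwise arc) before dividing by
    ``2 d``, so the returned ``phi`` always lies in the admissible interval
    whenever the input pair is admissible.
    """
    _check_d(d)
    theta_A = np.asarray(theta_A, dtype=float)
    theta_B = np.asarray(theta_B, dtype=float)
    delta = signed_arc(theta_A, theta_B)  # shortest arc from A to B
    if d == 0.0:
        if np.any(np.abs(delta) > atol):
            raise InconsistentLabelsError(
                "theta_A != theta_B is inconsistent with d=0"
            )
        return wrap_angle(theta_A), np.zeros_like(np.asarray(delta, dtype=float))
    phi = -delta / (2.0 * d)
    theta_mid = wrap_angle(theta_A + delta / 2.0)
    return theta_mid, phi


def sample_correlated_maps(n_neurons: int, d: float, seed) -> NeuronLabels:
    """Draw ``n_neurons`` random labels for a pair of maps at distance ``d``.

    ``seed`` may be an integer or a ``numpy.random.Generator``.
    """
    if n_neurons < 1:
        raise ValueError(f"n_neurons must be >= 1, got {n_neurons}")
    _check_d(d)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    theta_mid = rng.uniform(0.0, TWO_PI, size=n_neurons)
    phi = rng.uniform(-PHI_HALF_WIDTH, PHI_HALF_WIDTH, size=n_neurons)
    return NeuronLabels.from_mid(theta_mid, phi, d)


def morph_coordinates(labels: NeuronLabels, t: float) -> np.ndarray:
    """Angle of each neuron on the morph map with index ``t`` in [0, 1].

    Each neuron travels from its map-A angle (t=0) to its map-B angle (t=1)
    linearly in arc length along the shortest arc.
    """
    if not (0.0 <= t <= 1.0):
        raise ValueError(f"morph index t={t!r} outside [0, 1]")
    arc = signed_arc(labels.theta_A, labels.theta_B)
    return wrap_angle(labels.theta_A + t * arc)


@dataclass(frozen=True)
class MorphSequence:
    """A discrete family of maps interpolating between maps A and B."""

    labels: NeuronLabels
    index_grid: np.ndarray  # morph indices in [0, 1]
    coords: np.ndarray      # (n_maps, n_neurons) angles

    @property
    def n_maps(self) -> int:
        return len(self.index_grid)


def build_morph_sequence(labels: NeuronLabels, n_maps: int) -> MorphSequence:
    """Equally spaced morph maps from map A (index 0) to map B (index 1)."""
    if n_maps < 2:
        raise ValueError("a morph sequence needs at least 2 maps")
    index_grid = np.linspace(0.0, 1.0, n_maps)
    coords = np.stack([morph_coordinates(labels, t) for t in index_grid])
    return MorphSequence(labels=labels, index_grid=index_grid, coords=coords)


def labels_to_csv(labels: NeuronLabels, path, *, seed=None) -> None:
    """Write labels to CSV with a JSON sidecar recording the convention."""
    path = Path(path)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["theta_mid", "phi", "theta_A", "theta_B"])
        for row in zip(labels.theta_mid, labels.phi, labels.theta_A, labels.theta_B):
            writer.writerow([f"{x:.17g}" for x in row])
    sidecar = {
        "n_neurons": labels.n,
        "d": labels.d,
        "seed": seed,
        "convention_version": CONVENTION_VERSION,
        "phi_half_width": PHI_HALF_WIDTH,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2))


def labels_from_csv(path) -> NeuronLabels:
    path = Path(path)
    sidecar = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    data = np.genfromtxt(path, delimiter=",", names=True)
    return NeuronLabels(
        theta_mid=np.atleast_1d(data["theta_mid"]),
        phi=np.atleast_1d(data["phi"]),
        theta_A=np.atleast_1d(data["theta_A"]),
        theta_B=np.atleast_1d(data["theta_B"]),
        d=float(sidecar["d"]),
    )
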