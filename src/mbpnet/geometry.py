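"""Retinotopic tuning properties on the unit torus.

Each neuron carries four tuning properties ``(x, y, u, v)``: the center of its
spatial receptive field on the unit torus ``[0, 1)^2`` and its preferred
velocity vector (space-units per second).  Receptive-field centers are laid
out on a hexagonal grid so the population tiles visual space without
boundary effects; preferred speeds are log-spaced (a Weber-law spacing that
favors slow speeds in linear density) and crossed with uniformly spaced
directions.  The lattice is then dispersed with Gaussian jitter to emulate
the natural scatter of cortical maps.

Both spatial dimensions are periodic ("pac-man" topology), so all distances
and displacements here use the minimal periodic image.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GridSpec",
    "TuningProperties",
    "wrap",
    "torus_displacement",
    "torus_distance",
    "build_hex_grid",
    "sample_preferred_velocities",
    "assemble_population",
]


# ---------------------------------------------------------------------------
# torus metric
# ---------------------------------------------------------------------------

def wrap(p):
    """Wrap coordinates onto the unit torus [0, 1).  Idempotent.

    The double modulo guards against round-up at the seam: for a tiny
    negative ``p`` the first ``% 1.0`` can return exactly 1.0.
    """
    return np.asarray(p, dtype=float) % 1.0 % 1.0


def torus_displacement(a, b):
    """Minimal-image displacement from ``a`` to ``b``.

    Each component lies in ``[-0.5, 0.5)``.  Broadcasts over leading axes;
    the last axis holds the coordinates.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    return (b - a + 0.5) % 1.0 - 0.5


def torus_distance(a, b):
    """Euclidean length of the minimal-image displacement from a to b."""
    d = torus_displacement(a, b)
    return np.sqrt(np.sum(d * d, axis=-1))


# ---------------------------------------------------------------------------
# population specification
# ---------------------------------------------------------------------------

@dataclass
class GridSpec:
    """Layout of the tuning-property lattice before dispersal.

    Parameters
    ----------
    n_cells
        Number of hexagonal grid cells tiling the unit torus (default 100).
    n_speeds, n_angles
        Preferred speeds (log-spaced on ``[v_min, v_max]``) and directions
        (uniform on ``[0, 2pi)``) per grid cell; their product is the number
        of distinct preferred velocities per cell.
    v_min, v_max
        Speed range in space-units per second.  ``v_min`` must be positive
        because connection latencies divide by the preferred speed.
    jitter_x
        Standard deviation of the Gaussian positional dispersal
        (space units, applied per coordinate, positions re-wrapped).
    jitter_v
        Relative velocity dispersal: each velocity component receives
        Gaussian noise with standard deviation ``jitter_v * speed``.
    """

    n_cells: int = 100
    n_speeds: int = 10
    n_angles: int = 10
    v_max: float = 4.0
    v_min: float = 0.1
    jitter_x: float = 0.01
    jitter_v: float = 0.05

    def __post_init__(self):
        if self.n_cells < 1 or self.n_speeds < 1 or self.n_angles < 1:
            raise ValueError("n_cells, n_speeds and n_angles must be >= 1")
        if not 0.0 < self.v_min < self.v_max:
            raise ValueError("require 0 < v_min < v_max")
        if self.jitter_x < 0 or self.jitter_v < 0:
            raise ValueError("jitters must be non-negative")

    @property
    def n_combinations(self) -> int:
        return self.n_cells * self.n_speeds * self.n_angles


@dataclass
class TuningProperties:
    """Per-neuron tuning table: receptive-field centers and preferred velocities.

    ``x, y`` lie in ``[0, 1)``; ``u, v`` are unbounded velocity components
    with ``0 < speed <= v_max``.  ``beta_x``/``beta_v`` are the (shared)
    spatial and velocity tuning widths used by the stimulus envelope.
    """

    x: np.ndarray
    y: np.ndarray
    u: np.ndarray
    v: np.ndarray
    beta_x: float = 0.15
    beta_v: float = 0.15
    v_max: float = 4.0

    def __post_init__(self):
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.u = np.asarray(self.u, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        if not (len(self.x) == len(self.y) == len(self.u) == len(self.v)):
            raise ValueError("tuning columns must have equal length")
        if self.beta_x <= 0 or self.beta_v <= 0:
            raise ValueError("tuning widths must be positive")

    @property
    def n(self) -> int:
        return len(self.x)

    @property
    def positions(self) -> np.ndarray:
        """(n, 2) receptive-field centers."""
        return np.column_stack([self.x, self.y])

    @property
    def velocities(self) -> np.ndarray:
        """(n, 2) preferred velocities."""
        return np.column_stack([self.u, self.v])

    @property
    def speeds(self) -> np.ndarray:
        return np.hypot(self.u, self.v)

    def validate(self) -> None:
        if np.any((self.x < 0) | (self.x >= 1) | (self.y < 0) | (self.y >= 1)):
            raise ValueError("positions must lie in [0, 1)")
        sp = self.speeds
        if np.any(sp <= 0) or np.any(sp > self.v_max * (1 + 1e-12)):
            raise ValueError("preferred speeds must satisfy 0 < speed <= v_max")

    # -- serialization ------------------------------------------------------

    def to_frame(self, population: str = "E") -> pd.DataFrame:
        return pd.DataFrame(
            {
                "neuron_id": np.arange(self.n),
                "population": population,
                "x": self.x,
                "y": self.y,
                "u": self.u,
                "v": self.v,
            }
        )

    def to_csv(self, path, population: str = "E") -> None:
        self.to_frame(population).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, beta_x: float = 0.15, beta_v: float = 0.15,
                 v_max: float = 4.0) -> "TuningProperties":
        df = pd.read_csv(path)
        tp = cls(df["x"].to_numpy(), df["y"].to_numpy(),
                 df["u"].to_numpy(), df["v"].to_numpy(),
                 beta_x=beta_x, beta_v=beta_v, v_max=v_max)
        tp.validate()
        return tp

    def to_hdf5(self, group) -> None:
        for name in ("x", "y", "u", "v"):
            group.create_dataset(name, data=getattr(self, name))
        group.attrs["beta_x"] = self.beta_x
        group.attrs["beta_v"] = self.beta_v
        group.attrs["v_max"] = self.v_max

    @classmethod
    def from_hdf5(cls, group) -> "TuningProperties":
        return cls(group["x"][:], group["y"][:], group["u"][:], group["v"][:],
                   beta_x=float(group.attrs["beta_x"]),
                   beta_v=float(group.attrs["beta_v"]),
                   v_max=float(group.attrs["v_max"]))


# ---------------------------------------------------------------------------
# lattice construction
# ---------------------------------------------------------------------------

def _factor_grid(n_cells: int) -> tuple[int, int]:
    """Most-square (rows, cols) factorization of ``n_cells``.

    A 1 x n strip (prime counts above 3) does not form an offset hexagonal
    layout and is rejected.
    """
    best = None
    for rows in range(1, int(np.sqrt(n_cells)) + 1):
        if n_cells % rows == 0:
            best = (rows, n_cells // rows)
    if best is None or (best[0] == 1 and n_cells > 3):
        raise ValueError(
            f"n_cells={n_cells} cannot be arranged as a rows x cols hexagonal "
            "offset grid; choose a composite cell count (e.g. 100 = 10 x 10)"
        )
    return best


def build_hex_grid(n_cells: int, rows: int | None = None,
                   cols: int | None = None) -> np.ndarray:
    """Centers of ``n_cells`` hexagonal grid cells tiling the unit torus.

    Rows are spaced ``1/rows`` apart vertically and odd rows are shifted by
    half a column spacing, giving the offset ("honeycomb") layout.  The
    vertical spacing is chosen so the pattern is exactly periodic on the
    torus, at the cost of slightly distorted hexagons.

    Returns an ``(n_cells, 2)`` array of centers in ``[0, 1)^2``.
    """
    if rows is None or cols is None:
        rows, cols = _factor_grid(n_cells)
    if rows * cols != n_cells:
        raise ValueError("rows * cols must equal n_cells")
    r, c = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    x = (c + 0.5 * (r % 2)) / cols
    y = r / rows
    return wrap(np.column_stack([x.ravel(), y.ravel()]))


def sample_preferred_velocities(n_speeds: int, n_angles: int,
                                v_min: float = 0.1,
                                v_max: float = 4.0) -> np.ndarray:
    """Cross log-spaced speeds with uniformly spaced directions.

    Speeds form a geometric progression from ``v_min`` to ``v_max``
    (equal neuron counts per speed mean linear-speed density falls off as
    1/speed, favoring slow motion); angles are ``2*pi*k / n_angles``.

    Returns an ``(n_speeds * n_angles, 2)`` array of (u, v) vectors.
    """
    if v_min <= 0:
        raise ValueError("v_min must be positive (log spacing undefined at 0)")
    if v_min >= v_max:
        raise ValueError("require v_min < v_max")
    speeds = np.geomspace(v_min, v_max, n_speeds)
    angles = 2.0 * np.pi * np.arange(n_angles) / n_angles
    s, a = np.meshgrid(speeds, angles, indexing="ij")
    return np.column_stack([(s * np.cos(a)).ravel(), (s * np.sin(a)).ravel()])


def assemble_population(spec: GridSpec, n_target: int,
                        rng: np.random.Generator,
                        beta_x: float = 0.15,
                        beta_v: float = 0.15) -> TuningProperties:
    """Assign every (cell, velocity) lattice combination to neurons and disperse.

    Combinations are replicated round-robin (cell index varying fastest)
    until ``n_target`` neurons are assigned, so each combination is used
    ``floor`` or ``ceil`` of ``n_target / n_combinations`` times.  When
    ``n_target`` is smaller than the lattice, the first ``n_target``
    combinations in that order are used (all cells are covered first).

    Each replicate is independently jittered: positions by
    ``Normal(0, jitter_x)`` per coordinate (then re-wrapped), velocity
    components by ``Normal(0, jitter_v * speed)``.  Jittered speeds are
    clamped into ``(0, v_max]`` by radial rescaling so the population
    invariants survive dispersal.
    """
    centers = build_hex_grid(spec.n_cells)
    vels = sample_preferred_velocities(spec.n_speeds, spec.n_angles,
                                       spec.v_min, spec.v_max)
    # combination index ordered so the cell index varies fastest
    idx = np.arange(n_target) % spec.n_combinations
    cell_idx = idx % spec.n_cells
    vel_idx = idx // spec.n_cells

    pos = centers[cell_idx]
    vel = vels[vel_idx]

    if spec.jitter_x > 0:
        pos = pos + rng.normal(0.0, spec.jitter_x, size=pos.shape)
    pos = wrap(pos)
    if spec.jitter_v > 0:
        speed = np.linalg.norm(vel, axis=1, keepdims=True)
        vel = vel + rng.normal(0.0, 1.0, size=vel.shape) * spec.jitter_v * speed

    # clamp speeds into (0, v_max]
    speed = np.linalg.norm(vel, axis=1)
    too_fast = speed > spec.v_max
    if np.any(too_fast):
        vel[too_fast] *= (spec.v_max / speed[too_fast])[:, None]
    too_slow = speed < spec.v_min * 1e-6
    if np.any(too_slow):  # essentially measure-zero; restore lattice velocity
        vel[too_slow] = vels[vel_idx[too_slow]]

    tp = TuningProperties(pos[:, 0], pos[:, 1], vel[:, 0], vel[:, 1],
                          beta_x=beta_x, beta_v=beta_v, v_max=spec.v_max)
    tp.validate()
    return tp
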