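"""Population-vector readout of the excitatory spike trains.

Spikes are counted in fixed time bins (50 ms by default) and converted to
per-neuron confidence weights

    p_i(t) = n_i(t) / sum_j n_j(t),

the neuron's share of the population's belief in that bin.  Position is
decoded as the confidence-weighted *circular* mean of the receptive-field
centers: positions are mapped to angles on the unit circle
(``theta = 2 pi x - pi``), the weighted mean resultant vector is computed,
and its angle is mapped back to ``[0, 1)``.  The circular mean is required
because space is a torus; it reduces to the arithmetic mean when the
activity stays away from the wrap seam.  Velocity components are decoded
the same way with the mapping ``theta = pi v / v_scale``.

The decoded trajectory is scored against the true dot trajectory with
squared minimal-image (torus) distances.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geometry import TuningProperties, torus_displacement
from .records import SpikeRecord
from .stimulus import StimulusProtocol, stimulus_position

__all__ = [
    "bin_spikes",
    "confidence",
    "decode_position",
    "decode_direction",
    "confidence_map",
    "DecodedTrajectory",
    "decode_trajectory",
    "prediction_error",
]

DEFAULT_BIN_MS = 50.0


def bin_spikes(spikes: SpikeRecord, n_neurons: int, duration_ms: float,
               bin_width_ms: float = DEFAULT_BIN_MS) -> np.ndarray:
    """Per-bin, per-neuron spike counts, shape (n_bins, n_neurons).

    Bins are ``[k*w, (k+1)*w)``; every spike in ``[0, duration)`` lands in
    exactly one bin.
    """
    if bin_width_ms <= 0:
        raise ValueError("bin width must be positive")
    n_bins = int(np.ceil(duration_ms / bin_width_ms)) if duration_ms > 0 else 0
    counts = np.zeros((n_bins, n_neurons), dtype=np.int64)
    if len(spikes) == 0 or n_bins == 0:
        return counts
    b = np.floor(spikes.times / bin_width_ms).astype(np.int64)
    keep = (b >= 0) & (b < n_bins)
    np.add.at(counts, (b[keep], spikes.neuron_ids[keep]), 1)
    return counts


def confidence(counts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Normalize counts to per-bin weights; returns (p, valid).

    Bins without any spike are flagged invalid and carry all-zero weights.
    """
    counts = np.asarray(counts, dtype=float)
    totals = counts.sum(axis=-1, keepdims=True)
    valid = totals[..., 0] > 0
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(totals > 0, counts / totals, 0.0)
    return p, valid


def _circular_mean_unit(p: np.ndarray, values: np.ndarray,
                        literal: bool = False) -> np.ndarray:
    """Weighted circular mean of values with period 1, result in [0, 1).

    ``literal=True`` reproduces the additive constant 1 of the printed
    readout formula (which shifts point masses by half a period); the
    default uses the constant 1/2, i.e. the true inverse of the angle map,
    so decoding a single active neuron returns its own tuning center.
    """
    theta = 2.0 * np.pi * values - np.pi
    s = p @ np.sin(theta)
    c = p @ np.cos(theta)
    ang = np.arctan2(s, c)
    const = 1.0 if literal else 0.5
    return (const + ang / (2.0 * np.pi)) % 1.0


def decode_position(p: np.ndarray, tuning: TuningProperties,
                    literal: bool = False) -> np.ndarray:
    """Circular confidence-weighted mean receptive-field center, shape (..., 2)."""
    x = _circular_mean_unit(np.atleast_2d(p), tuning.x, literal)
    y = _circular_mean_unit(np.atleast_2d(p), tuning.y, literal)
    out = np.stack([x, y], axis=-1)
    return out[0] if np.ndim(p) == 1 else out


def decode_direction(p: np.ndarray, tuning: TuningProperties,
                     v_scale: float = 1.0) -> np.ndarray:
    """Circular confidence-weighted mean preferred velocity, shape (..., 2).

    Components are mapped to angles by ``pi * v / v_scale``; with the
    printed formula's ``v_scale = 1`` components outside (-1, 1) alias,
    so ``v_scale = v_max`` makes the decoding unambiguous.
    """
    p2 = np.atleast_2d(p)
    out = []
    for comp in (tuning.u, tuning.v):
        theta = np.pi * comp / v_scale
        ang = np.arctan2(p2 @ np.sin(theta), p2 @ np.cos(theta))
        out.append(v_scale * ang / np.pi)
    res = np.stack(out, axis=-1)
    return res[0] if np.ndim(p) == 1 else res


def confidence_map(p: np.ndarray, tuning: TuningProperties, dimension: str,
                   n_bins: int = 50,
                   value_range: tuple[float, float] | None = None
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Accumulate confidence along one tuning dimension per time bin.

    Returns ``(hist, edges)`` with ``hist`` of shape (n_time_bins, n_bins);
    each row sums to the bin's total confidence (1 for valid bins).
    """
    values = {"x": tuning.x, "y": tuning.y,
              "u": tuning.u, "v": tuning.v}[dimension]
    if value_range is None:
        value_range = (0.0, 1.0) if dimension in ("x", "y") else \
            (float(values.min()), float(values.max()) + 1e-9)
    edges = np.linspace(value_range[0], value_range[1], n_bins + 1)
    which = np.clip(np.searchsorted(edges, values, side="right") - 1,
                    0, n_bins - 1)
    p2 = np.atleast_2d(p)
    hist = np.zeros((p2.shape[0], n_bins))
    for b in range(n_bins):
        mask = which == b
        if mask.any():
            hist[:, b] = p2[:, mask].sum(axis=1)
    return hist, edges


@dataclass
class DecodedTrajectory:
    """Per-bin decoded state and its error against the true trajectory."""

    bin_edges: np.ndarray          # (n_bins + 1,) ms
    position: np.ndarray           # (n_bins, 2), wrapped; zeros where invalid
    direction: np.ndarray          # (n_bins, 2)
    valid: np.ndarray              # (n_bins,) bool
    sq_error: np.ndarray | None = None  # (n_bins,), NaN where invalid

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "bin_start_ms": self.bin_edges[:-1],
            "x_pred": self.position[:, 0], "y_pred": self.position[:, 1],
            "u_pred": self.direction[:, 0], "v_pred": self.direction[:, 1],
            "valid": self.valid,
            "sq_err": (self.sq_error if self.sq_error is not None
                       else np.full(len(self.valid), np.nan)),
        })

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def decode_trajectory(spikes_e: SpikeRecord, tuning: TuningProperties,
                      duration_ms: float,
                      bin_width_ms: float = DEFAULT_BIN_MS,
                      v_scale: float = 1.0,
                      literal: bool = False) -> DecodedTrajectory:
    """Full pipeline: bin, normalize, decode position and direction."""
    counts = bin_spikes(spikes_e, tuning.n, duration_ms, bin_width_ms)
    p, valid = confidence(counts)
    pos = decode_position(p, tuning, literal=literal)
    vel = decode_direction(p, tuning, v_scale=v_scale)
    pos[~valid] = 0.0
    vel[~valid] = 0.0
    edges = np.arange(counts.shape[0] + 1) * bin_width_ms
    return DecodedTrajectory(edges, pos, vel, valid)


def prediction_error(decoded: DecodedTrajectory, protocol: StimulusProtocol,
                     intervals: dict[str, tuple[float, float]] | None = None
                     ) -> tuple[np.ndarray, dict[str, float]]:
    """Squared torus distance to the true dot position per bin, plus MSEs.

    The truth is evaluated at bin centers.  ``intervals`` maps names to
    (t_start, t_end) windows; the returned dict holds the MSE over the
    *valid* bins whose centers fall in each window (NaN when none do).
    Fills ``decoded.sq_error`` as a side effect.
    """
    centers = decoded.bin_centers
    truth = stimulus_position(protocol, centers)
    diff = torus_displacement(decoded.position, truth)
    sq = np.sum(diff * diff, axis=-1)
    sq = np.where(decoded.valid, sq, np.nan)
    decoded.sq_error = sq

    mses: dict[str, float] = {}
    if intervals:
        for name, (lo, hi) in intervals.items():
            mask = (centers >= lo) & (centers < hi) & decoded.valid
            mses[name] = float(np.mean(sq[mask])) if mask.any() else float("nan")
    return sq, mses
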