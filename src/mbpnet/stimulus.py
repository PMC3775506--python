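"""Moving-dot input encoding: inhomogeneous Poisson spikes with blank phases.

The stimulus is a single dot moving on a straight, constant-velocity
trajectory across the unit torus.  Each excitatory neuron sees the dot
through a Gaussian envelope over its tuning properties,

    L_i(t) = exp(-||x_stim(t) - x_i||^2 / (2 beta_x^2)
                 - ||v_stim - v_i||^2 / (2 beta_v^2)),

which scales an inhomogeneous Poisson process with peak rate ``f_max``
(5 kHz when L_i = 1) sampled at a 0.1 ms step.  During *blank* phases the
envelope vector is randomly permuted across the whole population at every
step: the summed input rate is preserved but its selectivity is destroyed,
emulating an occluder or a blink.  The dot keeps moving invisibly, so the
envelope statistics during the blank match those of the visible stimulus.

All neurons additionally receive homogeneous Poisson background noise on
one excitatory and one inhibitory synapse, standing in for drive from
unmodeled networks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import TuningProperties, torus_displacement, wrap
from .records import SpikeRecord

__all__ = [
    "Phase",
    "StimulusProtocol",
    "InputParams",
    "stimulus_position",
    "stimulus_velocity",
    "envelope",
    "blank_shuffle",
    "generate_input_spiketrains",
    "generate_noise_spiketrains",
    "default_protocol",
]


@dataclass(frozen=True)
class Phase:
    kind: str          # "blank" or "stimulus"
    t_start: float     # ms, inclusive
    t_end: float       # ms, exclusive

    def __post_init__(self):
        if self.kind not in ("blank", "stimulus"):
            raise ValueError(f"unknown phase kind {self.kind!r}")
        if self.t_end < self.t_start:
            raise ValueError("phase must have t_end >= t_start")


@dataclass
class StimulusProtocol:
    """Dot trajectory and blank/stimulus schedule.

    Defaults follow the blanking experiment: the dot starts at (0.1, 0.5)
    moving rightward at 0.5 space-units/s; the input is blanked for the
    first 200 ms, visible 200-600 ms, blanked 600-800 ms and visible again
    until 1000 ms.
    """

    x0: tuple[float, float] = (0.1, 0.5)
    v_stim: tuple[float, float] = (0.5, 0.0)
    phases: tuple[Phase, ...] = (
        Phase("blank", 0.0, 200.0),
        Phase("stimulus", 200.0, 600.0),
        Phase("blank", 600.0, 800.0),
        Phase("stimulus", 800.0, 1000.0),
    )
    f_max: float = 5000.0   # Hz at envelope 1
    dt: float = 0.1         # ms

    def __post_init__(self):
        self.phases = tuple(self.phases)
        if not self.phases:
            raise ValueError("protocol needs at least one phase")
        if abs(self.phases[0].t_start) > 1e-12:
            raise ValueError("phases must start at 0")
        for a, b in zip(self.phases[:-1], self.phases[1:]):
            if abs(a.t_end - b.t_start) > 1e-12:
                raise ValueError("phases must be contiguous and non-overlapping")
        if self.f_max * self.dt > 1000.0:
            raise ValueError("f_max * dt must not exceed 1000 (per-step p <= 1)")

    @property
    def duration(self) -> float:
        return self.phases[-1].t_end

    @property
    def n_steps(self) -> int:
        return int(round(self.duration / self.dt))

    def blank_mask(self) -> np.ndarray:
        """Boolean per-step mask, True where the step falls in a blank phase."""
        t = (np.arange(self.n_steps) + 0.5) * self.dt
        mask = np.zeros(self.n_steps, dtype=bool)
        for ph in self.phases:
            if ph.kind == "blank":
                mask |= (t >= ph.t_start) & (t < ph.t_end)
        return mask

    def phase_window(self, kind: str, occurrence: int = 0) -> tuple[float, float]:
        """(t_start, t_end) of the n-th phase of the given kind (0-based)."""
        hits = [ph for ph in self.phases if ph.kind == kind]
        return (hits[occurrence].t_start, hits[occurrence].t_end)


@dataclass
class InputParams:
    """Synaptic interface of the external drive (weights in nS)."""

    w_input: float = 5.0     # nS, stimulus synapse onto each excitatory neuron
    f_noise: float = 2000.0  # Hz, background Poisson rate per train
    w_noise: float = 4.0     # nS, noise synapse weight (both polarities)

    def __post_init__(self):
        if min(self.w_input, self.f_noise, self.w_noise) < 0:
            raise ValueError("input parameters must be non-negative")


def default_protocol(**kwargs) -> StimulusProtocol:
    return StimulusProtocol(**kwargs)


def stimulus_position(protocol: StimulusProtocol, t_ms) -> np.ndarray:
    """Dot position at time ``t_ms`` (ms), wrapped to the torus.

    Accepts scalars or arrays; returns shape ``t.shape + (2,)``.
    """
    t = np.asarray(t_ms, dtype=float)
    x0 = np.asarray(protocol.x0, dtype=float)
    v = np.asarray(protocol.v_stim, dtype=float)
    return wrap(x0 + v * (t[..., None] / 1000.0))


def stimulus_velocity(protocol: StimulusProtocol) -> np.ndarray:
    return np.asarray(protocol.v_stim, dtype=float)


def envelope(tuning: TuningProperties, t_ms: float,
             protocol: StimulusProtocol) -> np.ndarray:
    """Per-neuron envelope L_i(t) in (0, 1].

    The spatial term uses the torus (minimal-image) distance between the dot
    and the receptive-field center; the velocity term is a plain Euclidean
    distance in the unbounded velocity plane.  L_i = 1 iff both match exactly.
    """
    xs = stimulus_position(protocol, t_ms)
    dx = torus_displacement(tuning.positions, xs)
    d2 = np.sum(dx * dx, axis=-1)
    dv = stimulus_velocity(protocol) - tuning.velocities
    dv2 = np.sum(dv * dv, axis=-1)
    return np.exp(-d2 / (2.0 * tuning.beta_x ** 2)
                  - dv2 / (2.0 * tuning.beta_v ** 2))


def blank_shuffle(envelope_vector: np.ndarray,
                  rng: np.random.Generator) -> np.ndarray:
    """Uniform random permutation of the envelope vector (one blank step)."""
    return rng.permutation(envelope_vector)


def generate_input_spiketrains(tuning: TuningProperties,
                               protocol: StimulusProtocol,
                               rng: np.random.Generator) -> SpikeRecord:
    """Stimulus-driven input spikes for the excitatory population.

    Per 0.1 ms step, neuron ``i`` fires with probability
    ``L_i(t) * f_max * dt / 1000`` (Bernoulli thinning of the envelope).
    During blank steps the envelope vector is permuted across the population
    before drawing.  Spike times are step-aligned (multiples of ``dt``).
    """
    n = tuning.n
    p_scale = protocol.f_max * protocol.dt / 1000.0
    blank = protocol.blank_mask()
    ids_chunks, t_chunks = [], []
    for step in range(protocol.n_steps):
        t = step * protocol.dt
        L = envelope(tuning, t, protocol)
        if blank[step]:
            L = blank_shuffle(L, rng)
        fired = np.nonzero(rng.random(n) < L * p_scale)[0]
        if fired.size:
            ids_chunks.append(fired)
            t_chunks.append(np.full(fired.size, t))
    if not ids_chunks:
        return SpikeRecord.empty("stimulus")
    return SpikeRecord(np.concatenate(ids_chunks), np.concatenate(t_chunks),
                       label="stimulus")


def _homogeneous_poisson(n_neurons: int, duration_ms: float, rate_hz: float,
                         rng: np.random.Generator, label: str) -> SpikeRecord:
    # Poisson counts + uniform order statistics == homogeneous Poisson process
    counts = rng.poisson(rate_hz * duration_ms / 1000.0, size=n_neurons)
    total = int(counts.sum())
    if total == 0:
        return SpikeRecord.empty(label)
    ids = np.repeat(np.arange(n_neurons), counts)
    times = rng.uniform(0.0, duration_ms, size=total)
    order = np.lexsort((ids, times))
    return SpikeRecord(ids[order], times[order], label=label)


def generate_noise_spiketrains(n_neurons: int, duration_ms: float,
                               params: InputParams,
                               rng: np.random.Generator
                               ) -> tuple[SpikeRecord, SpikeRecord]:
    """Background noise: one excitatory- and one inhibitory-synapse Poisson
    train per neuron, each at ``f_noise``.

    Times are continuous (exponential inter-spike intervals); the simulator
    bins them onto its integration grid at delivery.
    """
    exc = _homogeneous_poisson(n_neurons, duration_ms, params.f_noise, rng,
                               "noise_exc")
    inh = _homogeneous_poisson(n_neurons, duration_ms, params.f_noise, rng,
                               "noise_inh")
    return exc, inh
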