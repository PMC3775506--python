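"""Conductance-based leaky integrate-and-fire network integration.

Membrane dynamics per neuron k:

    C_m dV_k/dt = g_l (E_l - V_k) + sum_j [ g_{jk,E} (E_E - V_k)
                                          + g_{jk,I} (E_I - V_k) ]

Synaptic conductances decay exponentially (``g(t) = w * exp(-(t - t_spike)
/ tau_p)``) and synapses of one polarity share their time constant, so the
per-neuron state reduces to two summed conductances ``g_E`` and ``g_I``.
Each step: (1) decay the conductances; (2) add the weights of all spikes
whose emission time plus delay lands in the step (recurrent spikes through
a ring buffer, external stimulus/noise spikes through pre-binned event
lists); (3) advance V with the exponential update using each conductance's
exact average over the step, ``g * (tau_p / dt) * (1 - exp(-dt / tau_p))``,
which removes the O(dt / tau_p) bias of freezing the start-of-step value;
(4) neurons at or above threshold and out of refractoriness spike, reset to
``V_reset`` and are clamped for ``tau_refrac``.

Because V is always a convex combination of the reversal potentials and the
initial condition, the scheme is unconditionally stable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .connectivity import SynapseTable
from .geometry import TuningProperties
from .records import SpikeRecord

__all__ = [
    "NeuronParams",
    "SimulatorConfig",
    "SimulationResult",
    "exponential_step",
    "schedule_delivery",
    "integrate",
]


@dataclass
class NeuronParams:
    """Cell and synapse constants (same values for both populations).

    Units: capacitance nF, conductance uS, potentials mV, times ms.  The
    membrane time constant is ``tau_m = C_m / g_l`` (10 ms at the defaults).
    """

    c_m: float = 1.0        # nF
    g_l: float = 0.1        # uS
    e_l: float = -70.0      # mV
    e_e: float = 0.0        # mV
    e_i: float = -70.0      # mV
    tau_e: float = 5.0      # ms
    tau_i: float = 10.0     # ms
    v_thresh: float = -50.0  # mV
    v_reset: float = -70.0  # mV
    tau_refrac: float = 1.0  # ms

    def __post_init__(self):
        if min(self.c_m, self.g_l, self.tau_e, self.tau_i) <= 0:
            raise ValueError("C_m, g_l and synaptic time constants must be > 0")
        if not (self.e_i <= self.v_reset <= self.v_thresh < self.e_e):
            raise ValueError("require E_I <= V_reset <= V_thresh < E_E")

    @property
    def tau_m(self) -> float:
        return self.c_m / self.g_l


@dataclass
class SimulatorConfig:
    dt: float = 0.1            # ms
    duration: float = 1000.0   # ms
    v_init_mean: float = -65.0  # mV
    v_init_sd: float = 10.0    # mV
    record_v: np.ndarray | None = None  # global neuron indices to trace

    def __post_init__(self):
        if self.dt <= 0 or self.duration < 0:
            raise ValueError("dt must be > 0 and duration >= 0")

    @property
    def n_steps(self) -> int:
        return int(round(self.duration / self.dt))


@dataclass
class SimulationResult:
    spikes: SpikeRecord          # global neuron ids, population via n_exc split
    n_exc: int
    n_inh: int
    v_traces: np.ndarray | None = None   # (len(record_v), n_steps)
    v_trace_ids: np.ndarray | None = None

    def excitatory_spikes(self) -> SpikeRecord:
        keep = self.spikes.neuron_ids < self.n_exc
        return SpikeRecord(self.spikes.neuron_ids[keep],
                           self.spikes.times[keep], label="E")

    def inhibitory_spikes(self) -> SpikeRecord:
        keep = self.spikes.neuron_ids >= self.n_exc
        return SpikeRecord(self.spikes.neuron_ids[keep] - self.n_exc,
                           self.spikes.times[keep], label="I")


def exponential_step(v, g_e, g_i, params: NeuronParams, dt: float):
    """One exponential-integrator step with conductances frozen.

    ``V' = V_inf + (V - V_inf) * exp(-dt * g_tot / C_m)`` where
    ``g_tot = g_l + g_E + g_I`` and ``V_inf`` is the conductance-weighted
    mixture of the reversal potentials.  Maps ``[E_I, E_E]`` into itself.
    """
    g_tot = params.g_l + g_e + g_i
    v_inf = (params.g_l * params.e_l + g_e * params.e_e
             + g_i * params.e_i) / g_tot
    return v_inf + (v - v_inf) * np.exp(-dt * g_tot / params.c_m)


def schedule_delivery(emission_step: int, delay_ms: float, dt: float) -> int:
    """Delivery step for a spike: emission + round(delay/dt), at least +1."""
    return emission_step + max(1, int(round(delay_ms / dt)))


def _event_csr(records: list[tuple[SpikeRecord, float]], n_steps: int,
               dt: float):
    """Pre-bin external spike events by integration step.

    Returns (ptr, targets, weights): events of step ``s`` occupy
    ``targets[ptr[s]:ptr[s+1]]``.  Event times are floored onto the grid;
    events outside [0, duration) are dropped.
    """
    ids_all, w_all, step_all = [], [], []
    for rec, weight_uS in records:
        if len(rec) == 0 or weight_uS == 0.0:
            continue
        steps = np.floor(rec.times / dt).astype(np.int64)
        keep = (steps >= 0) & (steps < n_steps)
        ids_all.append(rec.neuron_ids[keep])
        step_all.append(steps[keep])
        w_all.append(np.full(keep.sum(), weight_uS))
    if not ids_all:
        ptr = np.zeros(n_steps + 1, dtype=np.int64)
        return ptr, np.empty(0, np.int64), np.empty(0)
    ids = np.concatenate(ids_all)
    steps = np.concatenate(step_all)
    w = np.concatenate(w_all)
    order = np.argsort(steps, kind="stable")
    ids, steps, w = ids[order], steps[order], w[order]
    ptr = np.zeros(n_steps + 1, dtype=np.int64)
    np.cumsum(np.bincount(steps, minlength=n_steps), out=ptr[1:])
    return ptr, ids, w


def _outgoing_csr(tables: dict[str, SynapseTable], n_exc: int, n_inh: int,
                  dt: float):
    """Flatten all pathways into per-global-source synapse lists.

    Global indexing: excitatory neurons 0..n_exc-1, inhibitory neurons
    n_exc..n_exc+n_inh-1.  Returns (ptr, targets, weights, delay_steps);
    the polarity of a synapse is that of its global source index.
    """
    n = n_exc + n_inh
    offs = {"E": 0, "I": n_exc}
    s_all, t_all, w_all, d_all = [], [], [], []
    for name, tab in tables.items():
        if len(tab) == 0:
            continue
        s_all.append(tab.source + offs[name[0]])
        t_all.append(tab.target + offs[name[1]])
        w_all.append(tab.weight)
        d_all.append(np.maximum(1, np.round(tab.delay / dt).astype(np.int64)))
    if not s_all:
        return (np.zeros(n + 1, np.int64), np.empty(0, np.int64),
                np.empty(0), np.empty(0, np.int64))
    s = np.concatenate(s_all)
    order = np.argsort(s, kind="stable")
    s = s[order]
    t = np.concatenate(t_all)[order]
    w = np.concatenate(w_all)[order]
    d = np.concatenate(d_all)[order]
    ptr = np.zeros(n + 1, dtype=np.int64)
    np.cumsum(np.bincount(s, minlength=n), out=ptr[1:])
    return ptr, t, w, d


def integrate(n_exc: int, n_inh: int,
              synapse_tables: dict[str, SynapseTable],
              input_spikes: SpikeRecord,
              noise_exc: SpikeRecord, noise_inh: SpikeRecord,
              neuron_params: NeuronParams,
              config: SimulatorConfig,
              rng: np.random.Generator,
              w_input_uS: float = 0.005,
              w_noise_uS: float = 0.004) -> SimulationResult:
    """Run the network and return the complete spike record.

    ``input_spikes`` target excitatory neurons (indices < n_exc) through an
    excitatory synapse of ``w_input_uS``; the two noise records target all
    neurons (global indices) through excitatory / inhibitory synapses of
    ``w_noise_uS``.  Given identical inputs and rng state the result is
    bit-identical across runs.
    """
    p = neuron_params
    n = n_exc + n_inh
    n_steps = config.n_steps
    dt = config.dt

    # initial potentials: normal draw, re-drawn above threshold
    v = rng.normal(config.v_init_mean, config.v_init_sd, size=n)
    bad = v >= p.v_thresh
    while np.any(bad):
        v[bad] = rng.normal(config.v_init_mean, config.v_init_sd,
                            size=int(bad.sum()))
        bad = v >= p.v_thresh

    ptr, syn_tgt, syn_w, syn_d = _outgoing_csr(synapse_tables, n_exc, n_inh, dt)
    max_delay = int(syn_d.max()) if len(syn_d) else 1
    L = max_delay + 1
    buf_e = np.zeros((L, n))
    buf_i = np.zeros((L, n))

    ev_ptr_e, ev_tgt_e, ev_w_e = _event_csr(
        [(input_spikes, w_input_uS), (noise_exc, w_noise_uS)], n_steps, dt)
    ev_ptr_i, ev_tgt_i, ev_w_i = _event_csr(
        [(noise_inh, w_noise_uS)], n_steps, dt)

    g_e = np.zeros(n)
    g_i = np.zeros(n)
    dec_e = np.exp(-dt / p.tau_e)
    dec_i = np.exp(-dt / p.tau_i)
    # exact average of g(t) = g0 * exp(-t/tau) over one step, as a factor
    avg_e = p.tau_e / dt * (1.0 - dec_e)
    avg_i = p.tau_i / dt * (1.0 - dec_i)
    refrac_steps = max(1, int(round(p.tau_refrac / dt)))
    refrac_until = np.zeros(n, dtype=np.int64)

    spike_ids, spike_steps = [], []
    trace_ids = None
    traces = None
    if config.record_v is not None and len(config.record_v):
        trace_ids = np.asarray(config.record_v, dtype=np.int64)
        traces = np.zeros((len(trace_ids), n_steps))

    src_is_e = np.arange(n) < n_exc

    for step in range(n_steps):
        g_e *= dec_e
        g_i *= dec_i
        slot = step % L
        g_e += buf_e[slot]
        g_i += buf_i[slot]
        buf_e[slot] = 0.0
        buf_i[slot] = 0.0
        a, b = ev_ptr_e[step], ev_ptr_e[step + 1]
        if b > a:
            np.add.at(g_e, ev_tgt_e[a:b], ev_w_e[a:b])
        a, b = ev_ptr_i[step], ev_ptr_i[step + 1]
        if b > a:
            np.add.at(g_i, ev_tgt_i[a:b], ev_w_i[a:b])

        v = exponential_step(v, g_e * avg_e, g_i * avg_i, p, dt)

        clamped = refrac_until > step
        v[clamped] = p.v_reset
        spiking = np.nonzero(~clamped & (v >= p.v_thresh))[0]
        if spiking.size:
            v[spiking] = p.v_reset
            refrac_until[spiking] = step + refrac_steps
            spike_ids.append(spiking)
            spike_steps.append(np.full(spiking.size, step))
            # recurrent delivery through the ring buffer
            for s in spiking:
                a, b = ptr[s], ptr[s + 1]
                if b == a:
                    continue
                slots = (step + syn_d[a:b]) % L
                buf = buf_e if src_is_e[s] else buf_i
                np.add.at(buf, (slots, syn_tgt[a:b]), syn_w[a:b])
        if traces is not None:
            traces[:, step] = v[trace_ids]
        if step % 1000 == 999 and not np.all(np.isfinite(v)):
            raise FloatingPointError(f"non-finite membrane potential at step {step}")

    if spike_ids:
        ids = np.concatenate(spike_ids)
        times = np.concatenate(spike_steps) * dt
    else:
        ids = np.empty(0, dtype=np.int64)
        times = np.empty(0)
    return SimulationResult(SpikeRecord(ids, times, label="net"),
                            n_exc=n_exc, n_inh=n_inh,
                            v_traces=traces, v_trace_ids=trace_ids)
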