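"""Lateral connectivity rules: random, isotropic, and anisotropic wiring.

The network has four pathways (E->E, E->I, I->E, I->I).  The recurrent
excitatory pathway can be wired under three rules:

* **isotropic / random** - the connection probability depends only on the
  torus distance between receptive-field centers,
  ``p_ij = p_max * exp(-d_ij^2 / (2 sigma_x^2))``; a very large ``sigma_x``
  yields the completely random (uniform) limit.  Weights and delays are
  drawn from normal distributions.

* **motion-based** - the source neuron projects to targets lying where its
  preferred motion predicts the stimulus to be after the inter-neuron
  latency ``tau_ij = d_ij / speed_i``, and whose preferred velocity matches
  its own:
  ``p_ij = exp(-||x*_ij - x_j||^2 / (2 sigma_x^2))
          * exp(-||v_i - v_j||^2 / (2 sigma_v^2))`` with
  ``x*_ij = x_i + v_i * tau_ij``.  The latency itself becomes the synaptic
  delay, so spikes travel across the map at the source's preferred speed.

* **direction-based** - a speed-free variant using von Mises kernels on the
  angle between the source->target displacement and the source's preferred
  direction, and on the angle between the two preferred directions.  Only
  pairs within radius ``r_conn`` or with latency below ``tau_max_db`` are
  eligible, keeping connections local and delays short.

For the anisotropic rules each target deterministically receives the
``round(k_frac * N_source)`` highest-probability sources and those
probabilities are converted to weights summing exactly to the pathway
target ``w_kl``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .geometry import TuningProperties, torus_displacement, torus_distance, wrap

__all__ = [
    "ConnectivityParams",
    "SynapseTable",
    "default_connectivity",
    "isotropic_probability",
    "latency",
    "predicted_position",
    "motion_based_probability",
    "direction_based_probability",
    "select_incoming",
    "normalize_weights",
    "draw_isotropic_weights",
    "assign_delays",
    "build_network",
    "anisotropy_statistic",
]

SCHEMES = ("random", "isotropic", "motion_based", "direction_based")


def _round_half_up(x: float) -> int:
    """round() with exact halves going up (0.005 * 1300 -> 7, not 6)."""
    return int(np.floor(x + 0.5))


@dataclass
class ConnectivityParams:
    """Wiring parameters for all four pathways.

    ``sigma_x`` / ``sigma_v`` parameterize the E->E rule selected by
    ``scheme`` (space units and space-units/s for the Gaussian rules,
    approximately radians for the von Mises rule).  ``sigma_x_iso`` is the
    spatial width used for the always-isotropic E->I, I->E and I->I
    pathways.  Weights are in uS, delays in ms.
    """

    scheme: str = "motion_based"
    sigma_x: float = 1.0
    sigma_v: float = 1.0
    # overall pathway connection probabilities
    p_ee: float = 0.005
    p_ei: float = 0.02
    p_ie: float = 0.02
    p_ii: float = 0.01
    # per-target sums of incoming weights (uS)
    w_ee: float = 0.20
    w_ei: float = 1.8
    w_ie: float = 0.8
    w_ii: float = 0.15
    # isotropic pathway shape and delay distribution
    sigma_x_iso: float = 0.2
    delay_mean: float = 3.0
    delay_sd: float = 1.0
    # anisotropic constraints
    r_conn: float = 0.10        # eligibility radius, direction-based rule
    tau_max_mb: float = 400.0   # ms, delay cap for the motion-based rule
    tau_max_db: float = 100.0   # ms, latency gate and delay cap, direction-based
    dt: float = 0.1             # ms, minimum representable delay

    def __post_init__(self):
        if self.scheme not in SCHEMES:
            raise ValueError(f"scheme must be one of {SCHEMES}")
        if self.sigma_x <= 0 or self.sigma_v <= 0 or self.sigma_x_iso <= 0:
            raise ValueError("selectivity widths must be positive")
        for p in (self.p_ee, self.p_ei, self.p_ie, self.p_ii):
            if not 0.0 < p <= 1.0:
                raise ValueError("pathway probabilities must lie in (0, 1]")
        for w in (self.w_ee, self.w_ei, self.w_ie, self.w_ii):
            if w < 0:
                raise ValueError("weight targets must be non-negative")
        if self.r_conn <= 0 or self.tau_max_mb < self.dt or self.tau_max_db < self.dt:
            raise ValueError("invalid r_conn / delay caps")


def default_connectivity(scheme: str, **overrides) -> ConnectivityParams:
    """Per-scheme defaults: selectivity widths and the E->E weight budget."""
    presets = {
        "motion_based": dict(sigma_x=1.0, sigma_v=1.0, w_ee=0.20),
        "direction_based": dict(sigma_x=0.5, sigma_v=0.5, w_ee=0.25),
        "isotropic": dict(sigma_x=0.2, sigma_v=1.0, w_ee=0.3),
        "random": dict(sigma_x=10.0, sigma_v=1.0, w_ee=0.3),
    }
    kw = presets[scheme] | overrides
    return ConnectivityParams(scheme=scheme, **kw)


# ---------------------------------------------------------------------------
# synapse tables
# ---------------------------------------------------------------------------

@dataclass
class SynapseTable:
    """Directed synapses of one pathway: (source, target, weight uS, delay ms)."""

    source: np.ndarray
    target: np.ndarray
    weight: np.ndarray
    delay: np.ndarray
    pathway: str = "EE"

    def __post_init__(self):
        self.source = np.asarray(self.source, dtype=np.int64)
        self.target = np.asarray(self.target, dtype=np.int64)
        self.weight = np.asarray(self.weight, dtype=float)
        self.delay = np.asarray(self.delay, dtype=float)
        if not (len(self.source) == len(self.target)
                == len(self.weight) == len(self.delay)):
            raise ValueError("synapse columns must have equal length")
        if self.pathway not in ("EE", "EI", "IE", "II"):
            raise ValueError("pathway must be one of EE, EI, IE, II")

    def __len__(self) -> int:
        return len(self.source)

    @property
    def same_population(self) -> bool:
        return self.pathway in ("EE", "II")

    def validate(self, n_source: int, n_target: int, dt: float = 0.1) -> None:
        if len(self) == 0:
            return
        if self.source.min() < 0 or self.source.max() >= n_source:
            raise ValueError("source index out of range")
        if self.target.min() < 0 or self.target.max() >= n_target:
            raise ValueError("target index out of range")
        if self.same_population and np.any(self.source == self.target):
            raise ValueError("self-connections are not allowed")
        if np.any(self.weight < 0):
            raise ValueError("negative weight")
        if np.any(self.delay < dt - 1e-12):
            raise ValueError("delay below the integration step")

    def in_degrees(self, n_target: int) -> np.ndarray:
        return np.bincount(self.target, minlength=n_target)

    def incoming_weight_sums(self, n_target: int) -> np.ndarray:
        return np.bincount(self.target, weights=self.weight,
                           minlength=n_target)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"source_id": self.source, "target_id": self.target,
                             "pathway": self.pathway, "weight_uS": self.weight,
                             "delay_ms": self.delay})

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, n_source: int | None = None,
                 n_target: int | None = None, dt: float = 0.1) -> "SynapseTable":
        df = pd.read_csv(path)
        pathway = str(df["pathway"].iloc[0]) if len(df) else "EE"
        table = cls(df["source_id"].to_numpy(), df["target_id"].to_numpy(),
                    df["weight_uS"].to_numpy(), df["delay_ms"].to_numpy(),
                    pathway=pathway)
        if n_source is not None and n_target is not None:
            table.validate(n_source, n_target, dt)
        return table

    def to_hdf5(self, group) -> None:
        for name in ("source", "target", "weight", "delay"):
            group.create_dataset(name, data=getattr(self, name))
        group.attrs["pathway"] = self.pathway


# ---------------------------------------------------------------------------
# elementary rules
# ---------------------------------------------------------------------------

def isotropic_probability(d, sigma_x: float, p_max: float):
    """Distance-dependent probability ``p_max * exp(-d^2 / (2 sigma_x^2))``."""
    d = np.asarray(d, dtype=float)
    return p_max * np.exp(-(d * d) / (2.0 * sigma_x ** 2))


def latency(distance, source_speed):
    """Travel time (s) implied by the source's preferred speed: d / speed."""
    distance = np.asarray(distance, dtype=float)
    source_speed = np.asarray(source_speed, dtype=float)
    if np.any(source_speed <= 0):
        raise ValueError("latency undefined for non-positive source speed")
    return distance / source_speed


def predicted_position(source_pos, source_vel, tau):
    """Source position advanced along its preferred velocity for ``tau`` s,
    wrapped to the torus."""
    source_pos = np.asarray(source_pos, dtype=float)
    source_vel = np.asarray(source_vel, dtype=float)
    tau = np.asarray(tau, dtype=float)
    return wrap(source_pos + source_vel * tau[..., None])


def motion_based_probability(source_pos, source_vel, target_pos, target_vel,
                             sigma_x: float, sigma_v: float,
                             p_max: float = 1.0):
    """Smooth-trajectory likelihood of a source->target connection.

    Broadcasts elementwise over paired source/target rows.  Asymmetric in
    general: the probability is high when the *target* sits where the
    *source's* motion predicts the stimulus after the latency, and when
    both prefer similar velocities.
    """
    d = torus_distance(source_pos, target_pos)
    speed = np.linalg.norm(np.asarray(source_vel, dtype=float), axis=-1)
    tau = latency(d, speed)
    x_star = predicted_position(source_pos, source_vel, tau)
    miss = torus_distance(x_star, target_pos)
    dv = np.asarray(source_vel, dtype=float) - np.asarray(target_vel, dtype=float)
    dv2 = np.sum(dv * dv, axis=-1)
    return (p_max * np.exp(-(miss * miss) / (2.0 * sigma_x ** 2))
            * np.exp(-dv2 / (2.0 * sigma_v ** 2)))


def direction_based_probability(source_pos, source_vel, target_pos, target_vel,
                                sigma_x: float, sigma_v: float,
                                p_max: float = 1.0,
                                r_conn: float = 0.10,
                                tau_max_ms: float = 100.0):
    """Speed-independent von Mises variant of the wiring rule.

    ``p = p_max * exp(cos(angle(x_j - x_i, v_i)) / sigma_x^2)
              * exp(cos(angle(v_i, v_j)) / sigma_v^2)``

    Pairs are eligible when they lie within ``r_conn`` of each other *and*
    their latency ``d / speed_i`` is shorter than ``tau_max_ms``; all other
    pairs (and coincident positions, where the displacement angle is
    undefined) get probability 0.  The conjunction keeps every synaptic
    delay equal to its true inter-neuron latency, so the diffused activity
    stays aligned with the trajectory it predicts.
    """
    source_pos = np.asarray(source_pos, dtype=float)
    source_vel = np.asarray(source_vel, dtype=float)
    target_pos = np.asarray(target_pos, dtype=float)
    target_vel = np.asarray(target_vel, dtype=float)

    disp = torus_displacement(source_pos, target_pos)
    d = np.sqrt(np.sum(disp * disp, axis=-1))
    speed_i = np.linalg.norm(source_vel, axis=-1)
    speed_j = np.linalg.norm(target_vel, axis=-1)

    with np.errstate(invalid="ignore", divide="ignore"):
        cos_disp = np.sum(disp * source_vel, axis=-1) / (d * speed_i)
        cos_dir = (np.sum(source_vel * target_vel, axis=-1)
                   / (speed_i * speed_j))
    cos_disp = np.clip(cos_disp, -1.0, 1.0)
    cos_dir = np.clip(cos_dir, -1.0, 1.0)

    p = (p_max * np.exp(cos_disp / sigma_x ** 2)
         * np.exp(cos_dir / sigma_v ** 2))
    lat_ms = np.where(d > 0, 1000.0 * d / speed_i, 0.0)
    eligible = (d > 0) & (d <= r_conn) & (lat_ms < tau_max_ms)
    return np.where(eligible, p, 0.0)


# ---------------------------------------------------------------------------
# selection, weights and delays
# ---------------------------------------------------------------------------

def select_incoming(probabilities: np.ndarray, k_frac: float,
                    exclude: int | None = None) -> np.ndarray:
    """Indices of the top ``round(k_frac * n)`` sources for one target.

    Ties are broken by ascending source index (stable sort), making the
    selection deterministic.  Sources with probability 0 are never
    selected; if fewer than k carry positive probability, all of them are
    taken and a warning is emitted.
    """
    p = np.asarray(probabilities, dtype=float).copy()
    n = len(p)
    if not 0.0 < k_frac <= 1.0:
        raise ValueError("k_frac must lie in (0, 1]")
    if exclude is not None:
        p[exclude] = -1.0
    k = _round_half_up(k_frac * n)
    order = np.argsort(-p, kind="stable")
    sel = order[:k]
    sel = sel[p[sel] > 0]
    if len(sel) < k:
        warnings.warn(f"only {len(sel)} of {k} requested sources have "
                      "positive probability")
    return sel


def normalize_weights(selected_probabilities: np.ndarray,
                      w_sum: float) -> np.ndarray:
    """Convert selected probabilities to weights summing exactly to w_sum."""
    p = np.asarray(selected_probabilities, dtype=float)
    total = p.sum()
    if total <= 0:
        raise ValueError("cannot normalize all-zero probabilities")
    return w_sum * p / total


def draw_isotropic_weights(n_incoming: int, w_sum: float, n_expected: float,
                           rng: np.random.Generator) -> np.ndarray:
    """Normal weight draws for isotropic pathways, truncated at 0.

    Mean ``w_sum / n_expected`` with 20% relative standard deviation, so the
    *expected* incoming sum (with the expected in-degree ``n_expected``)
    equals ``w_sum``.
    """
    mu = w_sum / n_expected
    w = rng.normal(mu, 0.2 * mu, size=n_incoming)
    return np.clip(w, 0.0, None)


def assign_delays(distances: np.ndarray, source_speeds: np.ndarray,
                  scheme: str, params: ConnectivityParams,
                  rng: np.random.Generator | None = None) -> np.ndarray:
    """Synaptic delays (ms) for already-selected pairs.

    Isotropic/random pairs draw from ``Normal(delay_mean, delay_sd)``;
    anisotropic pairs use the inter-neuron latency ``1000 * d / speed_i``.
    All delays are clipped to ``[dt, cap]`` with the scheme's cap.
    """
    if scheme in ("random", "isotropic"):
        if rng is None:
            raise ValueError("isotropic delays require an rng")
        d = rng.normal(params.delay_mean, params.delay_sd,
                       size=len(np.atleast_1d(distances)))
        return np.clip(d, params.dt, params.tau_max_mb)
    lat_ms = 1000.0 * latency(distances, source_speeds)
    cap = params.tau_max_mb if scheme == "motion_based" else params.tau_max_db
    return np.clip(lat_ms, params.dt, cap)


# ---------------------------------------------------------------------------
# pathway builders
# ---------------------------------------------------------------------------

def _mean_isotropic_kernel(src_pos: np.ndarray, tgt_pos: np.ndarray,
                           sigma_x: float, same_population: bool,
                           chunk: int = 512) -> float:
    """Mean of exp(-d^2 / 2 sigma^2) over all valid (non-self) pairs."""
    n_src, n_tgt = len(src_pos), len(tgt_pos)
    acc = 0.0
    for lo in range(0, n_tgt, chunk):
        hi = min(lo + chunk, n_tgt)
        d = torus_distance(src_pos[:, None, :], tgt_pos[None, lo:hi, :])
        k = np.exp(-(d * d) / (2.0 * sigma_x ** 2))
        if same_population:
            rows = np.arange(lo, hi)
            k[rows, rows - lo] = 0.0
        acc += k.sum()
    n_pairs = n_src * n_tgt - (n_src if same_population else 0)
    return acc / n_pairs


def _build_isotropic_pathway(src: TuningProperties, tgt: TuningProperties,
                             p_kl: float, w_kl: float, sigma_x: float,
                             pathway: str, params: ConnectivityParams,
                             rng: np.random.Generator,
                             chunk: int = 512) -> SynapseTable:
    same_pop = pathway in ("EE", "II")
    m = _mean_isotropic_kernel(src.positions, tgt.positions, sigma_x, same_pop,
                               chunk)
    p_max = p_kl / m
    n_expected = p_kl * src.n

    src_chunks, tgt_chunks = [], []
    for lo in range(0, tgt.n, chunk):
        hi = min(lo + chunk, tgt.n)
        d = torus_distance(src.positions[:, None, :],
                           tgt.positions[None, lo:hi, :])
        p = np.minimum(isotropic_probability(d, sigma_x, p_max), 1.0)
        if same_pop:
            rows = np.arange(lo, hi)
            p[rows, rows - lo] = 0.0
        hit_s, hit_t = np.nonzero(rng.random(p.shape) < p)
        src_chunks.append(hit_s)
        tgt_chunks.append(hit_t + lo)
    source = np.concatenate(src_chunks) if src_chunks else np.empty(0, int)
    target = np.concatenate(tgt_chunks) if tgt_chunks else np.empty(0, int)
    weight = draw_isotropic_weights(len(source), w_kl, n_expected, rng)
    delay = assign_delays(np.zeros(len(source)), np.ones(len(source)),
                          "isotropic", params, rng)
    return SynapseTable(source, target, weight, delay, pathway=pathway)


def _build_anisotropic_ee(tuning: TuningProperties,
                          params: ConnectivityParams,
                          chunk: int = 256) -> SynapseTable:
    """Deterministic top-k wiring of the recurrent excitatory pathway."""
    n = tuning.n
    pos, vel = tuning.positions, tuning.velocities
    speeds = tuning.speeds
    k = _round_half_up(params.p_ee * n)

    src_chunks, tgt_chunks, w_chunks, d_chunks = [], [], [], []
    for lo in range(0, n, chunk):
        hi = min(lo + chunk, n)
        tgt_pos = pos[None, lo:hi, :]
        tgt_vel = vel[None, lo:hi, :]
        src_pos = pos[:, None, :]
        src_vel = vel[:, None, :]
        if params.scheme == "motion_based":
            p = motion_based_probability(src_pos, src_vel, tgt_pos, tgt_vel,
                                         params.sigma_x, params.sigma_v)
        else:
            p = direction_based_probability(src_pos, src_vel, tgt_pos, tgt_vel,
                                            params.sigma_x, params.sigma_v,
                                            r_conn=params.r_conn,
                                            tau_max_ms=params.tau_max_db)
        rows = np.arange(lo, hi)
        p[rows, rows - lo] = 0.0  # no self-connections

        # top-k per target, ties by ascending source index
        order = np.argsort(-p, axis=0, kind="stable")
        sel = order[:k, :]                     # (k, n_chunk)
        p_sel = np.take_along_axis(p, sel, axis=0)
        valid = p_sel > 0
        if not valid.all():
            short = int(valid.sum(axis=0).min())
            warnings.warn(f"some targets have only {short} positive-probability "
                          f"sources (requested {k})")
        totals = np.where(valid, p_sel, 0.0).sum(axis=0)
        if np.any(totals <= 0):
            raise ValueError("a target neuron has no positive-probability source")
        w_sel = params.w_ee * np.where(valid, p_sel, 0.0) / totals

        tgt_idx = np.broadcast_to(np.arange(lo, hi), sel.shape)
        s = sel[valid]
        t = tgt_idx[valid]
        dist = torus_distance(pos[s], pos[t])
        delays = assign_delays(dist, speeds[s], params.scheme, params)
        src_chunks.append(s)
        tgt_chunks.append(t)
        w_chunks.append(w_sel[valid])
        d_chunks.append(delays)

    return SynapseTable(np.concatenate(src_chunks), np.concatenate(tgt_chunks),
                        np.concatenate(w_chunks), np.concatenate(d_chunks),
                        pathway="EE")


def build_network(tuning_e: TuningProperties, tuning_i: TuningProperties,
                  params: ConnectivityParams,
                  rng: np.random.Generator) -> dict[str, SynapseTable]:
    """Build all four pathway tables.

    The E->E pathway follows ``params.scheme``; E->I, I->E and I->I are
    always isotropic (width ``sigma_x_iso``).  Anisotropic E->E tables are
    deterministic functions of the tuning tables; isotropic tables are
    reproducible under the given rng.
    """
    if params.scheme in ("random", "isotropic"):
        ee = _build_isotropic_pathway(tuning_e, tuning_e, params.p_ee,
                                      params.w_ee, params.sigma_x, "EE",
                                      params, rng)
    else:
        ee = _build_anisotropic_ee(tuning_e, params)
    ei = _build_isotropic_pathway(tuning_e, tuning_i, params.p_ei, params.w_ei,
                                  params.sigma_x_iso, "EI", params, rng)
    ie = _build_isotropic_pathway(tuning_i, tuning_e, params.p_ie, params.w_ie,
                                  params.sigma_x_iso, "IE", params, rng)
    ii = _build_isotropic_pathway(tuning_i, tuning_i, params.p_ii, params.w_ii,
                                  params.sigma_x_iso, "II", params, rng)
    tables = {"EE": ee, "EI": ei, "IE": ie, "II": ii}
    sizes = {"E": tuning_e.n, "I": tuning_i.n}
    for name, table in tables.items():
        table.validate(sizes[name[0]], sizes[name[1]], params.dt)
    return tables


# ---------------------------------------------------------------------------
# diagnostics
# ---------------------------------------------------------------------------

def anisotropy_statistic(table: SynapseTable,
                         tuning_src: TuningProperties,
                         tuning_tgt: TuningProperties | None = None) -> float:
    """Mean outgoing displacement projected on the source's preferred direction.

    For each source neuron with outgoing connections, average the torus
    displacement to its targets and project it on the source's unit
    preferred-direction vector; return the population mean.  Near 0 for
    isotropic wiring, clearly positive when connections run ahead of the
    source's preferred motion.
    """
    if tuning_tgt is None:
        tuning_tgt = tuning_src
    if len(table) == 0:
        return 0.0
    disp = torus_displacement(tuning_src.positions[table.source],
                              tuning_tgt.positions[table.target])
    vhat = tuning_src.velocities[table.source]
    vhat = vhat / np.linalg.norm(vhat, axis=1, keepdims=True)
    proj = np.sum(disp * vhat, axis=1)
    # per-source mean, then population mean over sources with any outgoing
    sums = np.bincount(table.source, weights=proj, minlength=tuning_src.n)
    counts = np.bincount(table.source, minlength=tuning_src.n)
    has = counts > 0
    return float(np.mean(sums[has] / counts[has]))
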