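"""Figure rendering: rasters, confidence maps, readout traces, fan plots."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg", force=False)

import matplotlib.pyplot as plt
import numpy as np

from .connectivity import SynapseTable, anisotropy_statistic
from .decoder import confidence, confidence_map, bin_spikes
from .geometry import TuningProperties, torus_displacement
from .records import SpikeRecord
from .stimulus import StimulusProtocol, stimulus_position

__all__ = ["plot_raster", "plot_confidence_maps", "plot_readout",
           "plot_connectivity_fan", "render_outputs"]


def _phase_lines(ax, protocol: StimulusProtocol):
    for ph in protocol.phases[1:]:
        ax.axvline(ph.t_start, color="k", ls="--", lw=0.6)


def plot_raster(input_spikes: SpikeRecord, output_spikes: SpikeRecord,
                tuning: TuningProperties, protocol: StimulusProtocol,
                ax=None):
    """Raster of input (blue) and network (black) spikes, neurons ordered by
    x position."""
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4))
    order = np.argsort(tuning.x)
    rank = np.empty(tuning.n, dtype=int)
    rank[order] = np.arange(tuning.n)
    if len(input_spikes):
        ax.plot(input_spikes.times, rank[input_spikes.neuron_ids], ".",
                ms=1, color="tab:blue", alpha=0.3, rasterized=True)
    if len(output_spikes):
        ax.plot(output_spikes.times, rank[output_spikes.neuron_ids], ".",
                ms=2, color="k", rasterized=True)
    _phase_lines(ax, protocol)
    ax.set_xlabel("time (ms)")
    ax.set_ylabel("neuron (sorted by x)")
    return ax


def plot_confidence_maps(spikes_e: SpikeRecord, tuning: TuningProperties,
                         protocol: StimulusProtocol,
                         bin_width_ms: float = 50.0, n_bins: int = 40,
                         fig=None):
    """4-panel accumulated-confidence maps over x, y, u and v."""
    counts = bin_spikes(spikes_e, tuning.n, protocol.duration, bin_width_ms)
    p, _ = confidence(counts)
    if fig is None:
        fig, axes = plt.subplots(2, 2, figsize=(9, 6), sharex=True)
    else:
        axes = np.array(fig.subplots(2, 2, sharex=True))
    for ax, dim in zip(axes.ravel(), ("u", "v", "x", "y")):
        hist, edges = confidence_map(p, tuning, dim, n_bins=n_bins)
        ax.imshow(hist.T, origin="lower", aspect="auto",
                  extent=(0, protocol.duration, edges[0], edges[-1]),
                  cmap="viridis")
        ax.set_ylabel(dim)
        _phase_lines(ax, protocol)
    for ax in axes[-1]:
        ax.set_xlabel("time (ms)")
    fig.tight_layout()
    return fig


def plot_readout(decoded, protocol: StimulusProtocol, fig=None):
    """Decoded position/direction vs. the true trajectory, plus squared error."""
    if fig is None:
        fig, axes = plt.subplots(3, 1, figsize=(7, 7), sharex=True)
    else:
        axes = fig.subplots(3, 1, sharex=True)
    t = decoded.bin_centers
    truth = stimulus_position(protocol, t)
    ok = decoded.valid
    axes[0].plot(t, truth[:, 0], "k-", label="x true")
    axes[0].plot(t[ok], decoded.position[ok, 0], "o-", ms=3, label="x decoded")
    axes[0].set_ylabel("x")
    axes[1].plot(t, truth[:, 1], "k-", label="y true")
    axes[1].plot(t[ok], decoded.position[ok, 1], "o-", ms=3, label="y decoded")
    axes[1].set_ylabel("y")
    if decoded.sq_error is not None:
        axes[2].plot(t[ok], decoded.sq_error[ok], "o-", ms=3)
    axes[2].set_ylabel("squared error")
    axes[2].set_xlabel("time (ms)")
    for ax in axes:
        _phase_lines(ax, protocol)
    axes[0].legend(loc="upper left", fontsize=8)
    fig.tight_layout()
    return fig


def plot_connectivity_fan(table: SynapseTable, tuning: TuningProperties,
                          neuron: int, ax=None):
    """Outgoing (circles) and incoming (triangles) connections of one neuron,
    delay color-coded, with the population anisotropy statistic annotated."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    x0 = tuning.positions[neuron]
    out = table.source == neuron
    inc = table.target == neuron
    for mask, marker in ((out, "o"), (inc, "^")):
        if not mask.any():
            continue
        other = table.target[mask] if marker == "o" else table.source[mask]
        disp = torus_displacement(x0, tuning.positions[other])
        sc = ax.scatter(x0[0] + disp[:, 0], x0[1] + disp[:, 1],
                        c=table.delay[mask], s=200 * table.weight[mask] /
                        max(table.weight.max(), 1e-12) + 5,
                        marker=marker, cmap="plasma")
    v = tuning.velocities[neuron]
    v = 0.1 * v / max(np.linalg.norm(v), 1e-12)
    ax.annotate("", xy=tuple(x0 + v), xytext=tuple(x0),
                arrowprops=dict(color="gold", width=2, headwidth=8))
    ax.plot(*x0, "D", color="gold", ms=10, mec="k")
    stat = anisotropy_statistic(table, tuning)
    ax.set_title(f"{table.pathway}: anisotropy = {stat:.3f}")
    ax.set_xlabel("x")
    ax.set_ylabel("y")
    try:
        plt.colorbar(sc, ax=ax, label="delay (ms)")
    except (NameError, UnboundLocalError):
        pass
    return ax


def render_outputs(result, outdir) -> list[Path]:
    """Render the standard figure set for one experiment result."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []

    ax = plot_raster(result.input_spikes, result.sim.excitatory_spikes(),
                     result.tuning_e, result.config.protocol)
    path = outdir / "raster.png"
    ax.figure.savefig(path, dpi=120)
    plt.close(ax.figure)
    written.append(path)

    fig = plot_confidence_maps(result.sim.excitatory_spikes(),
                               result.tuning_e, result.config.protocol,
                               result.config.bin_width_ms)
    path = outdir / "confidence_maps.png"
    fig.savefig(path, dpi=120)
    plt.close(fig)
    written.append(path)

    fig = plot_readout(result.decoded, result.config.protocol)
    path = outdir / "readout.png"
    fig.savefig(path, dpi=120)
    plt.close(fig)
    written.append(path)

    ee = result.tables["EE"]
    if len(ee):
        # pick a neuron with outgoing connections near the map center
        src = int(np.bincount(ee.source,
                              minlength=result.tuning_e.n).argmax())
        ax = plot_connectivity_fan(ee, result.tuning_e, src)
        path = outdir / "connectivity_fan.png"
        ax.figure.savefig(path, dpi=120)
        plt.close(ax.figure)
        written.append(path)
    return written
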