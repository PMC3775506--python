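# mbpnet — motion-based prediction in a spiking network

When a moving object disappears behind an occluder — or you blink — the
visual system keeps a running estimate of where it is and where it is
going. `mbpnet` is a simulation package for studying one candidate
mechanism for this *motion extrapolation*: **anisotropic lateral
connectivity** in a recurrent network of spiking neurons. It is aimed at
computational neuroscientists who want a self-contained, deterministic
testbed for tuning-dependent wiring rules, with no external data
dependencies.

## The model in brief

A retinotopic sheet of conductance-based leaky integrate-and-fire neurons
(13 000 excitatory, 2 520 inhibitory at reference scale) lives on the unit
torus. Each neuron *i* carries tuning properties
(x<sub>i</sub>, y<sub>i</sub>, u<sub>i</sub>, v<sub>i</sub>): a
receptive-field center and a preferred velocity. A dot moving at
**v**<sub>stim</sub> = (0.5, 0) /s drives neuron *i* as an inhomogeneous
Poisson process (peak 5 kHz) with envelope

L<sub>i</sub>(t) = exp( −‖**x**<sub>stim</sub>(t) − **x**<sub>i</sub>‖² / 2β<sub>X</sub>² − ‖**v**<sub>stim</sub> − **v**<sub>i</sub>‖² / 2β<sub>V</sub>² ).

During *blank* phases the input vector is randomly permuted across the
population every 0.1 ms — same total drive, zero selectivity.

The recurrent excitatory pathway is wired under one of three rules:

- **isotropic / random** — p<sub>ij</sub> ∝ exp(−d<sub>ij</sub>²/2σ<sub>X</sub>²), a pure distance kernel (control);
- **motion-based** — the source connects to targets sitting where its
  preferred motion predicts the stimulus after the latency
  τ<sub>ij</sub> = d<sub>ij</sub>/‖**v**<sub>i</sub>‖, and the latency
  itself becomes the synaptic delay, so spikes travel across the map at
  the source's preferred speed;
- **direction-based** — a speed-free von Mises variant on the displacement
  and direction angles, restricted to a local radius with sub-100 ms
  latencies.

Excitatory spikes are read out in 50 ms bins as confidence weights
p<sub>i</sub> = n<sub>i</sub>/Σn<sub>j</sub> and decoded by a circular
population-vector average into a time-continuous estimate of target
position and velocity; prediction error is the squared torus distance to
the true trajectory. The claim under test: anisotropic wiring — and only
anisotropic wiring — carries the estimate through the blank.

See `docs/methods.md` for the full model description, parameter table
rationale, and numerical choices.

## Worked example

Run the blanking experiment (blank 0–200 ms, stimulus 200–600 ms, blank
600–800 ms, stimulus 800–1000 ms) on the quarter-scale network with
motion-based wiring:

```bash
mbpnet simulate --scheme motion_based --scale 0.25 --seed 1 --out out/
```

prints (abridged):

```json
{
  "scheme": "motion_based",
  "n_exc": 3250,
  "mse": {
    "blank1": 0.1752,
    "stimulus1": 0.00068,
    "blank2": 0.0310,
    "stimulus2": 0.0090
  },
  "exc_rate_hz": {"blank1": 0.032, "stimulus1": 0.335,
                  "blank2": 0.342, "stimulus2": 0.606},
  "active_exc_stimulus_rate_hz": 11.57
}
```

Reading this: before stimulus onset (`blank1`) the decode is noise
(MSE ≈ 0.18, i.e. chance on the torus); under the stimulus the decode
locks onto the dot (MSE ≈ 7·10⁻⁴, about 0.03 space units of error);
during the second blank the estimate *keeps tracking the invisible dot*
(MSE ≈ 0.03) because the ~1% of neurons recruited into the traveling
packet keep firing at 25–35 Hz and hand activity forward along the
trajectory. The same command with `--scheme isotropic` returns the blank
to chance (MSE ≈ 0.11): distance-only wiring cannot route the prediction.

Compare all three schemes against literally identical input spikes:

```bash
mbpnet compare --scale 0.25 --seeds 1,2,3 --out out/
```

Blank-phase (600–800 ms) position MSE per seed, from `out/comparison.csv`:

| scheme          | seed 1 | seed 2 | seed 3 |
|-----------------|-------:|-------:|-------:|
| isotropic       | 0.110  | 0.130  | 0.106  |
| motion_based    | 0.031  | 0.034  | 0.022  |
| direction_based | 0.009  | 0.035  | 0.011  |

Both anisotropic rules beat the isotropic control in every seed, and the
motion-based decoded x-position advances monotonically through the blank
(Spearman ρ vs. time ≈ 1.0 across seeds) while the isotropic decode
wanders. `mbpnet render` writes the position-ordered raster, the
confidence maps over (x, y, u, v), readout-vs-truth traces and a
connectivity fan plot for a single neuron.

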