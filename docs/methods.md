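# Methods

`mbpnet` simulates motion extrapolation in a recurrent spiking network: a
moving dot drives a retinotopic sheet of conductance-based
integrate-and-fire neurons, the dot is transiently blanked, and the
question is whether the lateral wiring alone can carry the trajectory
estimate through the blank. This note documents the model, the parameters
that matter, the numerical choices, and what the scaled-down test
conditions do and do not show.

## Model

### Neurons

Both populations use leaky integrate-and-fire dynamics with
conductance-based exponential synapses:

    C_m dV/dt = g_l (E_l - V) + g_E (E_E - V) + g_I (E_I - V)

with C_m = 1 nF, g_l = 0.1 uS (tau_m = 10 ms), E_l = E_I = -70 mV,
E_E = 0 mV, tau_E = 5 ms, tau_I = 10 ms. A spike is emitted at
V >= -50 mV, V resets to -70 mV and is clamped for 1 ms. Initial
potentials are drawn from N(-65, 10) mV, re-drawn if above threshold (the
untruncated draw would make ~7% of neurons fire spuriously at t = 0; the
original treatment of this tail is not documented, so the re-draw is our
choice).

### Tuning properties

Each neuron carries (x, y, u, v): a receptive-field center on the unit
torus and a preferred velocity. Centers sit on an offset ("honeycomb")
grid — 10 x 10 cells for the reference excitatory population, with
vertical spacing 1/rows so the pattern tiles the torus exactly at the cost
of slightly distorted hexagons. Each cell hosts 10 log-spaced speeds
(0.1 to 4.0 space-units/s; equal counts per log-spaced speed means linear
density ~ 1/speed, favoring slow motion) crossed with 10 uniform
directions. The 13000 excitatory neurons are mapped round-robin onto the
10000 (cell, velocity) combinations and each replicate is independently
dispersed: positional jitter sd 0.01 (re-wrapped), velocity jitter sd
0.05 x speed per component, with speeds clamped back into (0, v_max] so
population invariants survive. The jitter magnitudes are our choice (the
reference only states that properties "get dispersed"); v_min = 0.1 is
our choice (only v_max ~ 4 is stated) and matters because connection
latencies divide by the source speed. The inhibitory population (2520
neurons, 16.2% of the total) uses a coarser 6 x 6 grid; because its
lattice (3600 combinations) exceeds the population, the round-robin order
iterates cells fastest so every cell is covered and only velocities are
subsampled — only inhibitory positions matter under the default isotropic
inhibitory pathways.

### Stimulus

The dot follows x(t) = x0 + v t with v = (0.5, 0)/s from (0.1, 0.5). Each
excitatory neuron sees it through

    L_i(t) = exp(-||x_stim - x_i||^2 / 2 beta_x^2
                 - ||v_stim - v_i||^2 / 2 beta_v^2),

beta_x = beta_v = 0.15 (torus distance for space, plain Euclidean for
velocity), scaling a Poisson process with peak 5 kHz sampled by per-step
Bernoulli thinning at dt = 0.1 ms (p <= 0.5; thinning bias < 1.3%,
accepted because the envelope is defined stepwise anyway). Input spikes
arrive on one 5 nS excitatory synapse per neuron. During blank phases the
envelope vector is permuted across the whole excitatory population every
step: the dot keeps moving invisibly, the summed input rate is conserved
exactly per step, but selectivity is destroyed. All neurons additionally
receive 2 kHz Poisson noise on one excitatory and one inhibitory 4 nS
synapse. Noise spike times are continuous (uniform order statistics, hence
exactly exponential intervals); envelope-driven spikes are step-aligned.

### Connectivity

Four pathways (E-E, E-I, I-E, I-I). E-I, I-E, I-I are always isotropic;
E-E follows one of three rules.

*Isotropic / random*: p_ij = p_max exp(-d_ij^2 / 2 sigma_x^2) with p_max
solved so the mean pairwise probability equals the pathway budget
(p_EE = 0.5%, p_EI = p_IE = 2%, p_II = 1%). sigma_x = 0.2 for the
isotropic pathways (unstated in the reference; fixed once) and 10 for the
"random" limit, where the kernel is flat to < 0.3%. Weights are normal
with 20% relative sd and mean w_kl / (p_kl N_src), truncated at zero
(w_EE = 0.3, w_EI = 1.8, w_IE = 0.8, w_II = 0.15 uS); delays are
N(3, 1) ms clipped below at dt.

*Motion-based*: the source's preferred motion predicts where the stimulus
it codes for will be after the inter-neuron latency tau_ij = d_ij /
|v_i|; the connection probability is a Gaussian in the miss distance of
that prediction times a Gaussian in the preferred-velocity difference
(sigma_x = sigma_v = 1.0 by default; the reference states 0.1, 0.3 and
1.0 in different places — we measured 0.3 vs 1.0 at fixture scale and saw
no material difference in rates or blank tracking, so the exposed defaults
follow the results section). Each target deterministically receives its
round(0.5% x N) highest-probability sources (ties broken by ascending
index), probabilities are converted to weights summing exactly to
w_EE = 0.20 uS, and the latency itself becomes the synaptic delay
(clipped to [dt, 400 ms]; slow sources otherwise imply delays of seconds).
Spikes therefore travel across the map at the source's preferred speed —
the wiring is a wave medium matched to smooth trajectories.

*Direction-based*: a speed-free variant with von Mises kernels on (a) the
angle between the source-to-target displacement and the source's preferred
direction, and (b) the angle between the two preferred directions
(sigma_x = sigma_v = 0.5, w_EE = 0.25 uS). Pairs are eligible only if
d <= r_conn = 0.10 *and* latency < 100 ms, so every delay equals its true
latency. We also examined the disjunctive gate (radius OR latency): it
admits slow-source local pairs whose latencies must be clipped to the cap,
and those incoherent early arrivals destroy blank-phase propagation
entirely — the conjunctive gate is the reading under which the rule does
what it is for. With the 100 ms gate, hops longer than 0.05 require
source speeds above the dot's; direction-based tracking therefore leans on
short forward hops and local recurrence, and is visibly less accurate than
the motion-based rule, matching its billing as an approximation.

Self-connections are excluded everywhere. Anisotropic tables are
deterministic functions of the tuning tables; isotropic tables are
reproducible under a seed.

### Readout

Excitatory spikes are counted in 50 ms bins and normalized to confidence
weights p_i = n_i / sum n_j. Position is decoded per dimension as the
confidence-weighted circular mean: x -> theta = 2 pi x - pi, average the
unit vectors, map the resultant angle back. The printed readout formula
adds 1 to the recovered fraction, which shifts a point mass by half a
period (a neuron at x = 0.25 would decode to 0.75); we use the additive
constant 1/2 — the true inverse of the angle map, under which decoding a
single active neuron returns its own center — and keep the literal variant
behind a flag for comparison. Velocity components are decoded the same way
with theta = pi v / v_scale; the printed v_scale = 1 aliases speeds beyond
1, so the experiment pipeline uses v_scale = v_max = 4 by default while
the printed form remains available. Bins without spikes yield no estimate
(nothing is carried forward). Errors against the true trajectory use
squared minimal-image (torus) distances at bin centers.

## Numerical choices

- Exponential integrator, dt = 0.1 ms (matching the input step),
  unconditionally stable: V is always a convex combination of reversal
  potentials. The voltage update uses each conductance's *exact average*
  over the step, g (tau/dt)(1 - e^(-dt/tau)), instead of the frozen
  start-of-step value; freezing overestimates EPSP amplitudes by
  ~dt/2tau_E = 1%, while the average matches a 100x-finer reference to
  ~0.05%. Halving dt changes the spike count of a driven test network by
  ~0.3%.
- Spike delivery: delays round to the nearest step (minimum one); recurrent
  spikes travel through a ring buffer sized by the longest delay; external
  spikes are pre-binned per step. Spikes are timestamped at the end of the
  threshold-crossing step, without sub-step interpolation.
- Conductances of one polarity share their time constant, so per-neuron
  state is two summed conductances — mathematically identical to
  per-synapse exponentials.
- Half-up rounding for in-degrees (round(0.005 x 1300) = 7).
- Determinism: a master seed spawns independent child streams per stage
  (tuning E/I, input, noise, simulator, connectivity), so identical seeds
  give bit-identical runs, and all schemes in a comparison consume
  literally the same input and noise realizations.

## Scaled test conditions

The reference network (13000/2520 neurons) is exercised in tests and in
the acceptance script at quarter scale: neuron counts, grid cells and
in-degrees shrink by the scale factor while per-target incoming weight
budgets, noise, stimulus parameters and all spatial constants stay fixed,
so single-neuron operating points match the full model. Quarter scale
(3250/630 neurons, 5 x 5 excitatory grid) is the smallest scale at which
the grid still covers the dot's path at the 0.15 tuning width; the
comparison suite runs three schemes x three seeds in ~90 s on one CPU.

What transfers across scale, measured: single-neuron statistics
(stimulus-driven peaks ~225 Hz, blank-packet neurons ~25-35 Hz firing
5-10 spikes per blank, active-neuron stimulus means 11-17 Hz) and the
qualitative separation between schemes (anisotropic wiring tracks through
the blank, isotropic wiring does not, in every seed). What does not: the
*global* population-average rates, which are proportional to the fraction
of neurons recruited into the blank packet (~1% here, scale-invariant from
1300 to 6500 neurons in our measurements); the reference reports larger
global averages, consistent with a broader packet under its final
hand-tuned weights — its connection weights are described as fine-tuned,
size-dependent example values, and we deliberately keep the printed ones
rather than re-tune. With the printed noise parameters the free membrane
potential sits at -57.3 +/- 1.9 mV (3.9 sd below threshold), so
background activity is near-silent by construction; pre-onset decoding is
still defined in every 50 ms bin because a handful of noise-driven spikes
suffice.

The synthetic stimulus is a single rectilinear dot with stepwise-constant
statistics; passing tests show that the wiring rules transport a coherent
activity packet under exactly these conditions. They do not speak to
multiple objects, curved or accelerating trajectories, looming motion,
contrast dynamics, or realistic V1/MT response statistics — all outside
the model.

## Known limitations

- Motion-based delays reach the 400 ms cap for roughly half the synapses
  (slow sources at long range); these deliver late, weakly coherent input.
  The cap value is our choice; the underlying long-delay problem is
  intrinsic to the rule and is the stated motivation for the
  direction-based variant.
- Direction-based wiring at coarse fixture grids is dominated by
  within-cell pairs (the pinned r_conn = 0.10 is smaller than the coarse
  grid spacing); scaling r_conn with the spacing restores cross-cell reach
  but measurably worsens blank tracking, so the pinned value is kept.
- Velocity decoding with the printed v_scale = 1 aliases; position MSE,
  the quantity compared across schemes, is unaffected.
- The decoded position tends to run slightly ahead of the target during
  blanks (excitation spreads along the predicted path), an overshoot the
  reference also describes.
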