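# Methods

## The model

`calwave` simulates intercellular calcium waves on patterned networks of
endothelial cells. Each cell `i` carries one state variable, its cytosolic
calcium concentration `C_i` (dimensionless), evolving under

* **calcium-induced calcium release (CICR)** inside the cell, and
* **gap-junction diffusion** between neighbouring cells.

The intracellular reaction is `f(C) = -k(C)·C` with a piecewise-constant
rate constant switched on two thresholds:

| regime | condition | rate constant | effect |
|---|---|---|---|
| intake | `C < UC1` | `k1 = 0.03` | ER absorbs cytosolic calcium |
| release | `UC1 ≤ C ≤ UC2` | `k2 = -0.025` | CICR: concentration grows |
| refractory | `C > UC2` ever reached | `k3 = 0.0045` | slow re-uptake, **permanent** |

A concentration exactly at a threshold belongs to the release regime
(measure-zero choice, fixed for bit-reproducibility). The refractory lock
engages the first time a cell's pre-step concentration strictly exceeds
`UC2` and never releases — this single mechanism produces both the finite
pulse width and the annihilation of colliding waves. Real cells recover
after tens of seconds; on the ~30 s horizon of one wave passage the
permanent lock is an adequate idealization, but the model cannot describe
repeated firing of the same cell.

Diffusion is a graph Laplacian: cell `i` receives
`Σ_j w_ij (C_j - C_i)` over its coupled neighbours. On a chain all
couplings are *edge* contacts with coefficient `d_edge = 0.6`. On the
branched ("T") network, cells are unit squares; orthogonally adjacent cells
couple through edges (`d_edge`), diagonally adjacent cells in the junction
cluster couple through *vertex* contacts with a smaller coefficient `dv`
(longer diagonal path, fewer gap junctions in a corner contact).

### Time stepping and the scaling convention

The update is synchronous and explicit; every right-hand-side term is
evaluated at the previous step, concentrations are clamped at zero from
below (clamp events are counted; none occur under default parameters).

The tabulated coefficients are dimensionless, and how they scale with the
step `dt = 0.01` is fixed empirically by requiring the calibrated wave to
cross one cell per 0.87 dimensionless time units:

* diffusion coefficients are rates per unit dimensionless time: each link
  contributes `coeff · dt · (C_j - C_i)` per step;
* the rate constants are per-step increments: the reaction contributes
  `-k·C` per step with no extra `dt`.

The two obvious uniform alternatives both fail qualitatively: treating the
diffusion coefficient as a per-step weight makes the explicit scheme
unstable (per-neighbour weight 0.6 exceeds the stability bound), while
scaling the rate constants by `dt` as well makes CICR ~100× slower than
diffusion, so no cell ever reaches `UC2` and the wave dies within a few
cells. The mixed convention reproduces the 0.87 cell-to-cell time (measured
0.8611) and yields a physical diffusion coefficient of 2.8·10⁻¹⁰ m²/s,
the same order as measured cytosolic free-Ca²⁺ diffusion — both checks
fail by orders of magnitude under the alternatives. Both scaling flags are
exposed on `SimulationSettings` (`diffusion_per_step`, `reaction_per_step`)
for numerical experiments.

With the default parameters the travelling pulse has amplitude ~3.0, a
steady width of 7–9 cells above `UC1`, and each pulse consists of a fast
rise (~1 time unit) and a slow refractory decay (~5 units). A discreteness
artifact appears in the **stimulated** cell's tail: when its neighbours
peak, back-diffusion makes its concentration rise again briefly (peak rate
~25% of its main rise). Downstream cells only slow their decline; their
rate of change never turns positive again. This matters for crossing
detection (below).

## Network architectures

* `build_chain(n, d_edge)` — a single-file chain, labels `1..n`.
* `build_t_structure(d_edge, dv)` — a 61-cell backbone (row 0), a 30-cell
  side branch `1s..30s` rising from backbone cell 31, and two cluster
  cells `1'` at (30, 1) and `2'` at (32, 1) flanking `1s`, mimicking the
  multi-cell cluster that forms where patterned branches meet. All
  orthogonal contacts are edges; the vertex (diagonal) pairs are, by
  default (`vertex_rule="cluster"`), the four junction-cluster diagonals
  `1s–30`, `1s–32`, `1'–31`, `2'–31`.

The default vertex wiring was a genuinely open design point: the lattice
admits four more diagonal pairs (`1'–29`, `2'–33`, `1'–2s`, `2'–2s`;
available via `vertex_rule="all_diagonals"`). The uniform all-diagonals
rule was rejected because it changes the physics at the junction: the
`29–1'` diagonal makes backbone cell 29 the first to fail, and the single-
and dual-stimulation blocking thresholds coincide — no dual advantage.
With the cluster-only wiring the first failure sits at backbone cell 30
(drained through its shared diagonal into the branch) and dual stimulation
sustains propagation to distinctly larger `dv`, which is the behaviour the
junction model exists to capture.

Boundaries are zero-flux: terminal cells simply have fewer couplings.

## Protocols and classification

Four canonical in-silico experiments (stimulus = initial concentration
`C0 = 2.0` in the probed cell(s), everything else at 0):

1. chain, single stimulus at the middle cell (31 of 61);
2. chain, simultaneous dual stimulus, separation 7 (cells 28/35,
   relabelled 1–8 in outputs);
3. T structure, single stimulus at backbone cell 28;
4. T structure, simultaneous dual stimulus at cells 28 and 34.

A run is classified by which cells entered the refractory regime within
the horizon (default 15 000 steps = 150 time units, ≳1.5× the time a wave
needs to traverse the whole T structure). Side-branch propagation is
judged by a mid-branch sentinel cell (`15s`): far enough from the junction
to exclude partial leakage, far enough from the tip to exclude edge
effects. "Full structure" excludes the terminal (single-coupling) cells,
which may legitimately fail from edge effects. If any cell activates in
the last 5% of the horizon the classification is flagged inconclusive
rather than trusted.

`sweep_dv` classifies one run per grid value (0.01 resolution, matching
the two significant figures of the reported coefficients) and reports the
largest propagating / smallest blocked value, plus whether propagation
holds on a contiguous prefix of the grid (it does, in every sweep run
here).

### Junction thresholds: a reproduction caveat

Under the default (calibrated) parameters this reconstruction blocks
single-stimulus side-branch propagation from `dv = 0.37` (last propagating
0.36) and dual-stimulus propagation from `dv = 0.49` (last propagating
0.48). The originally reported transition values for this geometry are
substantially smaller (0.16/0.17 single, 0.23 dual). The exact junction
equations of the original were published only in supplementary material
unavailable here; no uniform reconstruction we tried (alternative diagonal
pair sets, per-step vs per-time vertex flux, flux multiplicity) reproduces
both printed thresholds, because the dual/single threshold ratio is pinned
near 1.3 by the dynamics whenever the failure site matches the reported
one (cell 30). The qualitative structure — existence of a finite blocking
threshold, failure at cell 30 with everything beyond blocked, and a
strictly larger dual-stimulation threshold — is fully reproduced and is
asserted in the test suite.

## Wave metrics and calibration

The response time of a cell is the time its trace attains its maximum
positive rate of change (first differences of recorded samples, stamped at
the trailing sample, earliest-wins on ties within 1e-9) — the same
fiducial used on measured fluorescence, so simulated and experimental
propagation times compare like for like. A threshold-crossing fiducial is
available; on a steady travelling wave both give identical cell-to-cell
differences, so the max-rate definition is the shipped default.

Spatial extent is the maximum over recorded times of the longest
contiguous run of cells above a threshold (default `UC1`). Measured over
the whole chain this counts the two still-merged nascent pulses around the
stimulated cell (17 cells at launch); the extent *of the pulse* is
measured on one side of the stimulus (maximum 9 cells, steady 7–8).

Crossing detection (dual-stimulus chains) looks, in every cell on the far
side of a stimulated cell, for a second distinct activation episode: a
second local maximum of the positive rate, separated from the first by a
decaying phase and exceeding 10% of that cell's first-pulse peak rate.
The floor is conservative: scanned (non-stimulated) cells show no positive
tail rate at all, and the stimulated cells' tail humps are excluded by
construction. With default parameters no crossing is ever detected, and a
planted second pulse is.

Calibration maps model units to physical ones by matching cell-to-cell
times: `time_conversion = 1.8 s / 0.87 = 2.07 s` per dimensionless unit,
giving an effective integration step of 0.0207 s, a wave speed of
31.2 µm / 1.8 s ≈ 17 µm/s, and a physical diffusion coefficient
`d_edge · Δx² / time_conversion ≈ 2.8·10⁻¹⁰ m²/s` (logged with a warning
if it leaves the order-of-magnitude band around the literature cytosolic
value 2.2·10⁻¹⁰ m²/s).

## Trace analysis

The experimental pipeline is reimplemented so the same metrics run on
measured-style data: background subtraction and normalization by the
initial corrected sample (traces with non-positive initial intensity are
flagged unusable rather than aborting the set), response calling, and
directional propagation statistics.

A cell is called a responder when its trace shows the pulse shape —
irrespective of absolute magnitude. Operationally (all parameters
configurable):

* geometry is assessed on a 3-sample centered smooth of the trace; the
  noise sd is estimated robustly (MAD) from the first differences of the
  raw trace;
* the peak prominence over the baseline (25th percentile of the smoothed
  trace) must exceed 3× the noise sd and an absolute floor of 0.25
  normalized units (sub-threshold diffusive bumps in simulated data reach
  at most ~0.15); the peak height uses a two-sample mean so smoothing
  attenuation does not penalize narrow pulses;
* fast-rise/slow-decline shape: the smoothed trace must spend more samples
  above the return level (10% of prominence above baseline, kept out of
  the smoothed noise band) after the peak than before it.

The response time is the maximum positive first difference of the raw
trace — or, for weak signals, of its 4-interval trailing running average
(uncertainty one full sampling interval instead of half) — with the search
confined to the detected pulse's rise, so a noise spike elsewhere in the
trace can never be reported as the response. The weak-signal switch is
caller-controlled, mirroring the per-cell strong/weak labelling of the
experimental procedure; the running average is trailing (a centered
variant would shift all timestamps by half a window, cancelling in
differences).

Propagation statistics pair consecutive responders along the chain
(pairs spanning non-responders are excluded and counted), orient each pair
along its wave's direction of travel, and report per-direction means and
SDs; in dual layouts the pair where the waves merge is labelled `meeting`
and excluded from directional means.

## Synthetic data

The generator emulates dye-based recordings on patterned chains: unit
baseline plus a pulse per responding cell (piecewise-linear rise, default
3 s, to amplitude 1.0; exponential decay with time constant
`decay_time/3`, default decay 12 s, so the pulse is ≳95% decayed 12 s
after its peak and the full width matches the observed 10–15 s), onsets
spreading outward from the stimulated cell with independent per-pair lags,
a finite propagation range (Gaussian, mean 4.7 cells, sd 1.1, per
direction), per-cell arbitrary intensity scale, constant background
offset, additive Gaussian noise on the normalized scale, 1.2 s sampling.
Per-pair lags are uniform on `mean_lag·[2/(1+d), 2d/(1+d)]` with
dispersion `d = 2`: mean exactly `mean_lag` (1.8 s) and extreme lags
differing by the factor `d`, the minimal model of the observed
cell-to-cell variability. All randomness flows through one seeded
generator; a fixed seed reproduces the set bit for bit. The true response
time of a responder is defined as the midpoint of its linear rise, where
the sampled rate of change peaks in expectation.

`from_simulation` bridges model output to experiment-style data:
calibrated resampling at 1.2 s, the affine intensity map `I = 1 + C/C0`, a
6 s resting baseline prepended (recordings start before probing, and every
trace then starts at intensity 1), and noise on the normalized scale.

What the generator does **not** emulate: photobleaching, dye saturation,
amplitude attenuation with distance, spontaneous single-cell firing,
heavy-tailed noise, or non-uniform sampling. Passing recovery tests
therefore show that the analysis pipeline is correct and robust to
Gaussian noise at the stated SNR on pulses of the assumed shape — not that
it is robust to every pathology of real recordings.

## Numerical choices and problem sizes

* Horizon 15 000 steps; recording stride 1 for chain metrics, 50 for
  classification sweeps (classification uses exact activation times
  tracked at full resolution regardless of stride).
* Vertex sweeps run on a 0.00–0.60 grid at 0.01 (61 classified runs per
  mode, ~30 s each mode on one core) so the actual transition is inside
  the grid; the spec-scale 0.00–0.30 grid is used where only the presence
  of propagation matters.
* Parameter recovery: 200 seeded replicates of a 9-cell chain at SNR 5
  (amplitude 1.0, noise sd 0.2); success = mean-lag estimate within one
  sampling interval (1.2 s) of the generating mean. Measured: 99.5% with
  the running-average method.
* Explicit-scheme instability (non-finite concentration) raises an error
  naming the step; it is reachable only under non-default scaling flags.

## Known limitations

* Permanent refractory lock: no repeated firing, no recovery.
* No amplitude attenuation along the chain (contrary to some experiments).
* The junction thresholds are reconstruction-dependent (see the caveat
  above); only their qualitative structure should be trusted.
* Single-variable CICR: no IP₃ dynamics, no store depletion, no
  stochastic channel gating.
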