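# Methods

`pmspace` characterizes brain states from parcellated BOLD time series as
probabilistic metastable substate (PMS) spaces, fits a coupled Stuart-Landau
(Hopf) whole-brain model to each state, and searches in silico for localized
perturbations that force transitions between states. This note documents the
models, the numerical choices, and what the packaged synthetic study does and
does not establish.

## Model-free stage: leading-eigenvector dynamics

Each parcel's signal is demeaned and band-pass filtered to 0.04–0.07 Hz with a
second-order Butterworth applied forward–backward (`scipy.signal.filtfilt`),
so the filter has zero phase and does not bias the subsequent Hilbert phases.
The instantaneous phase θ_n(t) is the angle of the analytic signal. At each
TR the phase-coherence matrix

    dFC_np(t) = cos(θ_n(t) − θ_p(t))

is symmetric with unit diagonal; aligned parcels give 1, orthogonal parcels 0,
anti-phase −1. Each matrix is reduced to its leading eigenvector V₁(t). Since
dFC(t) = c cᵀ + s sᵀ with c = cos θ(t), s = sin θ(t), the matrix has exact
rank 2 and V₁ lies in span{c, s}; the pipeline solves the corresponding 2×2
eigenproblem per TR, which is exact and O(N) instead of O(N³). Tests verify
agreement with a dense symmetric eigensolver to 1e-10.

**Eigenvector sign convention.** V₁ is oriented so that strictly more than
half of its entries are nonpositive; when neither orientation has a strict
majority, the largest-magnitude entry is forced negative. The convention is
idempotent and makes the all-aligned pattern the all-negative uniform vector.

**Substates.** Eigenvectors pooled over all subjects, TRs and conditions are
clustered with Euclidean K-means (k-means++ initialization, 50 restarts by
default, fixed seed; best inertia kept). Centroids are reordered by descending
pooled occupancy, ties by first occurrence, so substate labels are stable. The
PMS of a condition is the occupancy fraction of each substate over that
condition's TRs. k is scanned (2–8 at full scale) and chosen as the smallest k
maximizing the fraction of substates with an FDR-significant condition
difference; if nothing is significant at any k, the smallest k is returned
with a warning.

**Statistics.** Group differences per substate use a permutation test on the
Wilcoxon rank-sum statistic (1,000 relabelings by default; a signed-rank/
sign-flip variant is provided for paired designs), with the add-one estimator
p = (1 + #{|T_perm| ≥ |T_obs|})/(1 + n_perm) so p is never zero, followed by
Benjamini–Hochberg correction across substates (statsmodels). Hilbert edge
trimming is available (`edge_trim`) but defaults to 0 so that the pooled count
of phase-coherence matrices equals subjects × TRs × conditions exactly.

## Model-based stage: coupled Hopf oscillators

Each parcel n is a Stuart-Landau oscillator at the normal form of a
supercritical Hopf bifurcation, coupled diffusively through a connectome C:

    dx_n/dt = (a_n − x_n² − y_n²) x_n − ω_n y_n + G Σ_p C_np (x_p − x_n) + β η_n(t)
    dy_n/dt = (a_n − x_n² − y_n²) y_n + ω_n x_n + G Σ_p C_np (y_p − y_n) + β η_n(t)

Defaults: a_n = −0.02 (just below the bifurcation, where noise-driven
fluctuations are structured), β = 0.01 (noise standard deviation), node
frequencies f_n = ω_n/2π estimated per node as the peak of the
subject-averaged periodogram of the band-passed data, clamped to 0.04–0.07 Hz
(flat spectra fall back to the 0.055 Hz midpoint with a warning).

**Integration.** A splitting scheme with step dt = 0.1 s: the radial, coupling
and noise terms advance by Euler–Maruyama (diffusion β·√dt per component, so
stationary statistics are dt-invariant), then the rotation is applied exactly
as a rotation by ω_n·dt. A plain explicit Euler rotation inflates the
limit-cycle radius by O(dt·ω²) (≈2.7% at dt = 0.1, f = 0.05 Hz); the splitting
removes this, and the noise-free uncoupled radius matches the closed form √a
to better than 1% with < 1% change under dt halving (both tested). The first
300 s are discarded as transient and the output is sampled every TR = 2 s.
States with |x| > 1e6 raise a divergence error naming the coupling at fault;
in ensemble sweeps the affected replicate is recorded and the sweep continues.
Many replicates are integrated in one vectorized pass, and the bifurcation
vector, coupling and frequencies may vary per replicate — this is what makes
grid sweeps tractable on one CPU.

**Fitting.** The simulated PMS is computed by pushing each simulated run
through the *same* LEiDA chain and assigning each eigenvector to the nearest
empirical centroid (Euclidean; verified against brute force). The objective is
the symmetrized Kullback–Leibler distance

    KL(P, Q) = ½ [ Σ_i P_i ln(P_i/Q_i) + Σ_i Q_i ln(Q_i/P_i) ],

with zero probabilities floored at 1/(10·n_observations) of the respective
distribution followed by renormalization — the floor keeps the objective
finite while preserving ordering, and shrinks as the number of pooled TRs
grows. G is swept over a grid (0–0.3 step 0.01 at full scale; 200 pooled
repetitions per G; 0–0.15 with 20 repetitions at desk scale).

**Effective connectivity.** For each G the coupling matrix starts at the
structural connectome (symmetrized, max-normalized to 0.2) and is refined by
gradient descent on the grand-average phase-coherence matrix
FC_ij = ⟨cos(φ_j(t) − φ_i(t))⟩_t:

    C_ij ← C_ij + ε (FC_emp_ij − FC_sim_ij),  ε = 0.01,

on off-diagonal entries, re-symmetrized and clamped to [0, 0.2], until the
mean absolute off-diagonal difference drops below 0.001 or a 300-iteration cap
(the cap guarantees termination; a warning fires if the discrepancy rises
three iterations in a row). Updates are allowed on all off-diagonal pairs so
connections missing from tractography can appear. Setting `max_ec_iters=0`
gives a pure coupling sweep on the raw connectome (`fit_global_coupling`),
which is what the parameter-recovery experiment uses; each G runs an
independent EC loop rather than warm-starting from the previous G.

## Perturbation stage

A fitted source-state model is perturbed one node at a time: the node's
bifurcation parameter is swept from the working point −0.02 up to 0.18
(synchronization protocol, toward self-sustained oscillation) or down to
−0.22 (noise protocol, toward a noise-dominated fixed point), in steps of
0.01 — 21 intensities per protocol, the first being the unperturbed baseline.
Each cell is simulated 3 times (350 TRs per repetition, matching the fitting
stage) and the repetitions' eigenvector assignments are pooled into one
perturbed PMS (pooling rather than averaging per-repetition PMS vectors:
equivalent in expectation, lower variance). The cell score is the symmetrized
KL distance to the target state's empirical PMS; diverged cells are recorded
as +inf and the sweep continues. The optimal transition is the global argmin
(ties: lower node index, then intensity closest to baseline); nodes are ranked
by their per-node minimum. The baseline KL reported alongside is the mean of
the first grid column, i.e. repeated Monte-Carlo estimates of the unperturbed
model's distance to the target. All three repetitions share the fitted
effective connectivity; refitting per cell would multiply the cost by the EC
loop length with no mechanistic rationale.

## Synthetic study conditions

Because the pipeline is validated without any external data, the generator
produces the study's dimensions from the model itself: 116 parcels (100
cortical across the seven canonical resting-state networks in two hemispheres
+ 16 subcortical structures), 20 subjects × 2 conditions × 350 TRs at
TR = 2 s. Node frequencies are drawn uniformly in 0.04–0.07 Hz per subject
(a subject trait, shared across that subject's conditions; inter-subject
variability is a modeling choice, as no empirical distribution is available).
Subject noise streams use seed = sim_seed + 1000·condition_index +
subject_index. The condition contrast is induced by global coupling alone:
rest-like G = 0.04 and meditation-like G = 0.09 (ΔG = 0.05, inside the fitted
sweep range); per-node bifurcation offsets per condition are supported but
default to zero.

**Connectome.** The stand-in connectome is block-modular (4 modules,
within/between weights 0.1/0.02) with a rich-club core: 20% of parcels, spread
evenly across modules, are hubs whose mutual edges get weight 1.0 before
lognormal jitter (σ = 0.5, emulating the heavy tail of streamline counts),
symmetrization and max-normalization to 0.2. The hub core concentrates the
network's spectral radius in few nodes, so global coupling drives
synchronization through the core — making the PMS sensitive to G in the
0–0.15 range — while the majority of parcels keep a low coupling load and
their noise-driven oscillations stay narrow-band: band-pass filtering retains
roughly 60–70% of the raw signal variance. A homogeneous dense graph cannot
do both at once: its mean coupling load broadens every node's spectral line at
exactly the coupling strengths that make the substate structure informative.
Rich-club organization is also a documented feature of real tractography
connectomes.

**What the generator does not emulate.** No hemodynamic (Balloon–Windkessel)
forward model, no measurement noise beyond the model's own stochasticity, no
head motion, no spatial autocorrelation of parcels, no inter-subject
connectome variability. Passing tests therefore establish internal
consistency of the method — ground-truth recovery, calibration, directional
efficacy — on model-generated data, not claims about real brains.

## Validation experiments and problem sizes

All experiments run on one CPU at "desk" scale; the desk preset only reduces
repetition counts and grid sizes, never formulas.

- **Parameter recovery:** a single-condition study at G = 0.05 (study
  dimensions otherwise) is generated, clustered at k = 3, and swept over
  G ∈ [0, 0.15] with 20 repetitions per value; the recovered optimum falls
  within ±0.02 of the truth. The KL curve is steep below the synchronization
  onset and shallow above it, so the ±0.02 band is an honest resolution limit
  rather than a formality.
- **Null calibration:** 20 reduced null studies (20 parcels, 10 subjects,
  120 TRs, identical G in both conditions) are pushed through the full chain;
  the fraction of seeds with any FDR rejection at α = 0.05 is required to stay
  ≤ 0.10.
- **Directional efficacy:** on the packaged two-condition study, the
  synchronization protocol applied to the rest-like model (G = 0.04, its
  generating working point) lowers the KL to the meditation-like PMS below
  baseline, and the noise protocol does the same in the reverse direction, on
  a reduced node set of 6 parcels spanning hubs and periphery.

## Known limitations

- The perturbation working point uses the generating coupling of the source
  condition in the packaged experiments; with empirical data it would be the
  fitted g_best (the pipeline wires it that way).
- The KL floor makes distances between near-degenerate distributions depend
  mildly on the pooled observation count; comparisons are only made between
  quantities computed with the same pooling.
- K-means with Euclidean distance on unit-norm eigenvectors is the
  conventional choice for this analysis, not a claim of optimality; no
  alternative clusterings are implemented.
- At coupling values far above the fitted range the simulated dynamics can
  leave the regime where the band-pass/Hilbert chain is informative; the grid
  is capped at 0.3 for this reason.
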