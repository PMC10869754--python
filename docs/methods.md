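# Methods

## Setting

The package targets conformational transitions that are too slow for
brute-force equilibrium simulation but can be covered by many short
trajectories started from a non-equilibrium spread of initial conditions —
the prototypical case being activation of a voltage-sensing domain, where
the S4 helix translocates and rotates between a "down" (resting) and "up"
(active) arrangement while its arginines exchange salt-bridge partners.
All estimators assume only that the dynamics are Markovian on the chosen
lag time.

## Estimators

**Committor.** For reactant A and product B, the committor q₊(x) is the
probability of reaching B before A. It satisfies a fixed-point equation
under the stopped transition operator (dynamics killed on first entry into
A ∪ B). Expanding q₊ = γ + Σ vᵢφᵢ with basis functions that vanish on
A ∪ B and a guess γ obeying the boundary conditions, Galerkin projection
against the sampled distribution μ gives `(C_t − C_0)v = −(r_t − r_0)` with
`C_t[i,j]` the empirical correlation of φᵢ at a trajectory start with φⱼ at
the stopped endpoint, and r the analogous vectors with γ. The linear solve
uses least squares with a singular-value cutoff (1e-10 relative) because a
whitened basis can still be rank-deficient on finite data; the condition
number is reported. Reconstructed values are clipped to [0, 1] before any
downstream use and pinned exactly to 0/1 on labeled frames. With an
indicator (one-hot cluster) basis the estimator is algebraically identical
to a Markov state model with absorbing boundary — a property the tests
assert to 1e-10.

**Weights.** The equilibrium weight w = π/μ is the fixed point of the
μ-weighted adjoint transition operator. With an indicator basis this
reduces to: build the cluster transition matrix from unstopped (t, t+lag)
pairs, take its stationary distribution, and set w per frame to stationary
probability over empirical cluster frequency. Weights are normalized to
frame-mean 1 (PMFs are invariant to this choice). If the empirical matrix
is reducible the largest closed communicating class is used and frames
outside it get weight 0, with a warning.

**Mean first-passage time.** Stopping on B only and accumulating elapsed
time gives the Feynman–Kac system `(C_t − C_0)v = −τ̄` with
`τ̄[i] = ⟨φᵢ(X(0)) · (t ∧ T_B)⟩`; reconstructed times are floored at 0 and
zero on B. Times are reported in physical units (frames × save interval).

**Stopped-process bookkeeping.** Frames already inside a stopping state
stop at their own index — the correct convention for the committor/MFPT
correlation matrices. Flux estimators instead need transitions *leaving*
the reactant, so `stop_times` also offers `boundary_starts="evolve"`, which
stops at the first entry strictly after the start frame. The reactive
current requires the latter.

**Reactive current.** Each (start, stopped-end) pair deposits the
antisymmetrized reactive displacement
`(w/2)[q₋(start)q₊(end) − q₊(start)q₋(end)] · (ξ(end) − ξ(start))/lag`,
split half/half between the start and end bins of the 2-D collective
variable grid, averaged over pairs, and smoothed with a Gaussian kernel of
one bin. The backward committor defaults to 1 − q₊, valid for reversible
equilibrium dynamics (the zero-voltage setting); a time-reversed solve is
available as a cross-check. The estimator is validated against exact
transition-path-theory currents of Markov chains: interior bin values match
the reactive rate on a 1-D chain, and the two-channel flux split of a
reversible network matches the exact edge decomposition.

**Bases.** The committor basis multiplies (standardized) features by the
boundary factor h = d_A d_B/(d_A + d_B)², with guess γ = d_A²/(d_A² + d_B²);
both vanish identically on labeled frames by construction. d_A/d_B are
either Euclidean distances to the nearest A-/B-labeled frame in z-scored
feature space (default; exact zeros on members) or distances to the state
ellipse boundaries in the translocation/rotation plane
(`ellipse_boundary_distances`) — the pipeline uses the latter since exact
nearest-neighbour queries on ~3·10⁵ frames in 20 dimensions dominate
runtime without changing the boundary properties. Columns are SVD-whitened
(empirical Gram = identity; singular values below 1e-8 of the maximum
dropped). The weight basis is k-means (k = 200, mini-batch for large data,
10 restarts, one reseeded retry on an empty cluster) on a 10-dimensional
slow-mode projection of the features.

**Slow modes (lag-integrated variational analysis).** The integrated
time-lagged covariance Σ_{τ=min}^{max} C(τ) (forward/transpose symmetrized
so the spectrum is real) is diagonalized against C(0) on mean-centered
features; centering removes the trivial constant mode and constant columns
are dropped. C(0) receives a ridge of 1e-10 × trace/p only when its
condition number exceeds 1e12. On a two-state chain the leading eigenvalue
equals the relaxation eigenvalue at a single lag and its geometric sum over
a lag window — both asserted in the tests. Subspace validation bins frames
by the first coordinate and reports the Spearman correlation between bin
index and mean committor.

**Sparse committor models.** Transition-region points are sampled with
replacement ∝ w·q₊(1 − q₊) (boundary frames never drawn; 100 000 samples by
default). The data are split at q₊ = 0.5 and each branch is mapped to the
real line with ln[2q/(1−2q)] (lower) or ln[(2q−1)/(2−2q)] (upper) — exact
mirror images — so back-transformed predictions stay inside (0, 0.5) or
(0.5, 1). The LASSO objective is Σ(βᵀx − y)² + λ‖β‖₁ on features
standardized to zero mean and unit variance (scikit-learn's `alpha` is
λ/2n); λ = 0 falls back to ordinary least squares. Defaults λ = 0.02
(lower) and 0.03 (upper); the full λ-path of nonzero sets is available
because the sparsity/accuracy trade-off is a judgement call. R² is reported
both on the transformed fitting scale and on back-transformed committor
values, since the two differ and either may be wanted.

**TPT observables.** PMFs are −kT·ln of the weighted histogram, min-shifted
to zero over occupied bins, with empty bins masked (NaN) rather than set to
a sentinel. Voltage tilts add Q_d·V with 1 e·mV = 0.0230605 kcal/mol. The
default kT for molecular data is 0.5961 kcal/mol (300 K); the surrogate
pipeline works in thermal units (kT = 1). The equilibrium time-correlation
function is ⟨w·O(0)O(τ)⟩/⟨w⟩ normalized by C(0), no stopping; the
biexponential fit a₁e^{−t/τ₁} + (1−a₁)e^{−t/τ₂} uses multi-start nonlinear
least squares with decade-spaced log-parameterized time constants, orders
τ₁ ≥ τ₂, and flags degenerate (single-exponential) fits. The sensing charge
is the weighted mean displacement charge in the up state minus the down
state.

**Structural collective variables.** Units are Å, degrees (reported in
(−180°, 180°]) and elementary charge. Alignment is Kabsch superposition
(proper rotation enforced). Translocation is the projection of the COM
displacement of the mobile selection onto an axis, defaulting to the
principal inertia axis (long axis) of the reference selection; rotation is
the closed-form spin angle θ = atan2(Σm(r′⊥ × r⊥)·ê, Σm r′⊥·r⊥), the
RMSD-minimizing rotation about the axis, positive for right-handed rotation
about the axis oriented toward positive z (extracellular). The displacement
charge uses unwrapped z-coordinates; wrapped input is rejected rather than
silently accepted because wrapping makes Q_d discontinuous. Hydrogen bonds
use donor–acceptor heavy-atom distance ≤ 3.5 Å and donor–hydrogen–acceptor
angle ≥ 120° (the angle vertex is a documented, configurable choice).
Masses for COM are inferred from atom names with standard atomic masses.
Salt-bridge targets may be single atoms or mass-weighted groups; the default
committor feature set is the 60 distances from five sensing arginines to
six acidic partners — all inter-group Cα–Cα pairs plus guanidinium-Cζ to
carboxylate-Cγ/Cδ pairs.

## The synthetic test bed

**Markov-chain oracles.** Committor, stationary distribution, MFPT and TPT
currents come from direct linear solves; the backward committor uses the
time-reversed chain π_j P_ji/π_i, so the net current is divergence-free on
interior states and its flux through every A/B-separating cut equals the
reactive rate (asserted to 1e-10). These oracles are the ground truth for
every estimator test.

**Langevin dynamics.** Euler–Maruyama in the overdamped limit,
x ← x − ∇U·(D/kT)·dt + √(2D·dt)·η, with analytic or central-difference
gradients, NaN-force detection, and a warning when the potential changes by
more than kT per step at the starting points. Any Markovian surrogate is a
valid test bed because the estimators assume nothing about the dynamics
beyond Markovianity at the lag.

**Five-basin voltage-sensor surrogate.** The slow space is the
(translocation d, rotation θ) plane with θ compressed by 12°/Å so the two
coordinates carry comparable diffusive distances. Five inverted Gaussian
basins (widths 0.35 Å isotropic in scaled units; interior depth 2.3 kT, end
depth 3.3 kT so the end states are most stable; barriers of roughly 2–3 kT,
matching the shallow landscapes reported for voltage-sensor activation) lie
along a bent path — rotation relaxes first at nearly fixed translocation,
then translocation proceeds — with a quadratic confinement of 2 kT per
squared scaled unit off the path. Basin arc positions were calibrated once,
at design time, against an exact fine-grid finite-volume committor solve of
this landscape so the three interior basins sit at q₊ ≈ 0.25/0.50/0.75
between the two state ellipses (uncalibrated equal spacing puts them at
0.32/0.52/0.65 because the end gaps are shortened by the absorbing ellipse
radii and the bend lets paths cut the corner). Features are 20 noisy
distance-like observables of the path progress — most monotone, at least a
quarter V-shaped (dip-and-recover, as a side chain crossing a hydrophobic
plug produces) — with Gaussian noise of 0.25 Å. The charge observable is a
smoothed two-level step ("click") of 0.9 e between −4.2 e and −3.3 e,
switching on the barrier between the third and fourth basins. Starting
points are uniform along the path with 0.15 scaled-unit jitter, emulating
seeding spread across the transition region rather than equilibrium
sampling.

What the surrogate does *not* emulate: real molecular data have thousands
of correlated features, multiple competing pathways, non-Markovian memory
at short lags, force-field errors, and state definitions that may truncate
basins. Passing tests on the surrogate demonstrates estimator correctness
under the stated assumptions, not robustness to those failure modes.

## Pipeline defaults and problem sizes

The end-to-end run uses 900 trajectories × 300 frames (270 000 frames; save
interval 25 steps of dt 2e-4, so each trajectory spans ~1.5 natural time
units, about one barrier-escape time), DGA lag 10 frames, 28 bins per PMF
axis, k = 200 clusters on a 10-dimensional slow-mode projection (lag window
1–5), and 100 000 transition-region samples for the sparse fits. These
sizes give committor errors well inside the test tolerances while a full
pipeline completes in well under a minute on one CPU; they scale up
linearly if sharper PMFs are wanted. The lag is configurable and reported
with results: it must exceed the intra-basin relaxation (~6 frames here)
for the Markov assumption to hold at the resolution of the basis.

Minima of PMF grids are counted by topological persistence: occupied bins
are swept in order of increasing free energy and merged via union-find;
a basin counts if its prominence (death minus birth free energy) is at
least 0.75 kT and its floor lies below 3 kT. Strict stencil minima are not
stable at realistic bin occupancy — a basin straddling a bin boundary
splits in two, and 0.1-kT noise dips register — while persistence is
insensitive to the prominence threshold anywhere in 0.5–1.0 kT on the
default problem size. The "interior" count restricts births to committor
bins in (0.08, 0.93), excluding the end-state populations pinned at exactly
0 and 1.

## Numerical choices and degenerate inputs

- Linear solves: `scipy.linalg.lstsq` with relative singular-value cutoff
  1e-10; singular systems raise with a suggestion to relax the whitening
  tolerance or increase the lag.
- Indicator bases drop all-zero columns after boundary masking (clusters
  fully inside A ∪ B), which keeps the system nonsingular without changing
  the reconstruction.
- Ellipse membership wraps angular differences into (−180°, 180°], so
  labels are invariant under θ → θ + 360°. Overlapping state definitions
  are rejected by a numerical containment scan.
- Ties in nearest-labeled-frame distances are broken by lowest frame index
  (inherited from the neighbour search); the labeled frames themselves are
  set to exactly zero distance.
- Biexponential fits on non-decaying series raise; single-exponential
  inputs converge with a degeneracy flag rather than an error.
- Empty PMF bins serialize as NaN (masked), never ±inf.
- Random numbers: one named `numpy.random.Generator` per operation, seeded
  explicitly; no global state. Repeated runs with the same configuration
  are byte-identical, which the tests assert.

## Known limitations

- The backward committor defaults to 1 − q₊; for irreversible dynamics the
  time-reversed solve must be used explicitly, and the reactive-current
  oracle tests are therefore built on reversible chains.
- No non-Markovian memory corrections: lag-time robustness must be checked
  by the user (the tests do so on chain data where it holds exactly).
- Weight estimation inherits MSM discretization bias; with too-coarse
  clustering the stationary distribution of the cluster chain differs from
  the true marginal.
- No block-bootstrap error bars on PMFs or currents; sampling noise must be
  judged by seed variation.
- The coordinate reader does not unwrap periodic trajectories; displacement
  charge requires unwrapped z-coordinates supplied by the caller.
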