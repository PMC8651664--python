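# Methods

## Scope and model

`qdrlart` implements a model-based reinforcement-learning framework for
adapting the dose per fraction in the last third of an NSCLC
radiotherapy course. The environment ("artificial radiotherapy
environment") composes three maps applied once per adaptation period:

1. **Transition.** The biomarkers IP10 and GLSZM-ZSV evolve through a
   dense net (2 hidden tanh layers of width 32) trained on longitudinal
   records (5-feature pre state + dose per fraction → post biomarkers).
   The gEUD features instead follow the process-driven monotone prior

       g(t_n) = g(t_{n-1}) + kappa * dt * d * (1 + d / (alpha/beta)),

   a discretised proportionality between gEUD accrual and dose
   fractionation weighted by tissue radiosensitivity. The constant of
   proportionality is not fixed by the relationship itself, so each
   tissue carries an explicit `kappa` (default 1.0 Gy per (Gy/frac) per
   week); `dt` defaults to one 2-week adaptation period. With the
   defaults, one period at 2 Gy/frac adds 4.8 Gy tumor gEUD.
2. **Outcome estimator.** Each endpoint (local control on tumor gEUD,
   grade-2+ pneumonitis on lung gEUD) is a logistic
   `p = 1/(1+exp((g - mu)/T))` whose patient-specific `mu` and `T` are
   the outputs of two small nets (one hidden tanh layer, width 16) over
   the dose-independent covariates (IP10, ZSV, genotype). The two nets
   are tuned alternately — mu-net with T-net frozen, then swapped —
   until the binary cross-entropy changes by less than 1e-5 or 25 rounds
   elapse. `T` is parametrised as `-(0.5 + softplus(raw) * sd(g))`, i.e.
   strictly negative, so both probabilities are nondecreasing in
   accumulated dose; this keeps the printed logistic form while
   enforcing the clinically observed monotone dose-risk relationship.
   A weight decay of 1e-2 on the net weights shrinks spurious
   patient-to-patient variation in (mu, T); without it the nets memorise
   label noise (on a 2000-patient check against a known logistic, decay
   reduces the sd of fitted mu from 3.2 Gy to under 0.5 Gy).
3. **Reward.** `R = P+ + bonus` with `P+ = p_LC (1 - p_RP2)`. The three
   printed bonus boxes leave gaps in the unit square, so the rule is
   evaluated top-down: +10 if `p_LC > 0.7 and p_RP2 < 0.172` (clinical
   region, also the episode-terminating condition), else +5 if
   `p_LC > 0.5 and p_RP2 < 0.5`, else -1. All inequalities are strict as
   printed; the rule is total on [0,1]^2 and bounded in [-1, 11].

Episodes start from the week-4 (mid-treatment) state and run for at most
10 dose decisions — the step cap used throughout — terminating early
when the outcome estimate enters the clinical region. Multi-step
episodes reuse the same per-period transition; the framework does not
model calendar time past week 6, so later steps are counterfactual
continuations of the same adaptation dynamics.

## Quantum decision layer

Doses live on an evenly spaced grid of 2^n levels indexed by the
computational basis of an n-qubit register (default n = 5 over 1.0-4.1
Gy/frac, spacing 0.1). Selection amplifies the greedy eigen-dose and
measures:

* **Controller circuit** (default): 2n qubits split into control and
  main. Pre-control X gates prepare the marked bitstring on the control;
  the main register is flipped to |1...1>, entangled through per-pair
  CNOTs, and flipped back. The noiseless measurement equals the marked
  string with probability 1 (a double-complement identity), and the
  depth is 4 gate layers regardless of n — the property that makes the
  construction viable on hardware whose coherence length Grover circuits
  exceed. Substituting CU3(theta, phi, lambda) for the CNOTs makes each
  marked bit assert only with probability sin^2(theta/2), a tunable
  stochasticity hook; the angles may be supplied per call (e.g. on an
  episode schedule), and no specific schedule is prescribed.
* **Grover amplification**: the closed-form state after k iterations
  (marked amplitude sin((2k+1) arcsin(1/sqrt(N))), unmarked amplitudes
  equal); the default schedule is floor(pi/4 sqrt(N)) iterations. Tests
  cross-check the closed form against an explicit oracle+diffusion
  operator iteration to 1e-9.

Bit convention: character 0 of a bitstring is the most significant bit
of the dose index. Measurement ties break toward the lowest index.
Circuits export to OpenQASM 2.0 text and re-import exactly; the
`external` backend forwards QASM to a user-supplied runner and consumes
its counts, with no vendor coupling.

## Agent

The deep Q-net maps the standardized 5-feature state to one q-value per
eigen-dose (3 hidden ReLU layers of width 64). Training uses uniform
replay (capacity 10^4, batch 64), the double-Q target
`r + gamma * Q_target[argmax Q_online]` with gamma = 0.99, Adam at 1e-3,
target sync every 100 updates, and epsilon-greedy exploration annealed
linearly 1.0 → 0.05 over episodes. None of these are claimed from prior
work; they are desk-scale choices recorded in the config and hashed into
every artifact. Recommendations are reported as the mean greedy dose of
an ensemble of 5 identically configured, independently seeded members
with SEM = sd/sqrt(m) (defined as 0 for a single member) and each
member's greedy q-value as a confidence indicator.

## Synthetic cohort

Real adaptive-trial records are restricted, so the generator emulates
the schema: IP10 and ZSV are log-normal (positive-support biomarkers),
gEUDs truncated normal (tumor 30 +/- 4 Gy, lung 10 +/- 3 Gy accumulated
by week 4), genotype Binomial(2, 0.3), and the clinical dose per
fraction normal (2.2 +/- 0.6, clipped to the 1.0-4.1 Gy/frac grid).
Mid-treatment biomarkers respond linearly to dose intensity (IP10 slope
+0.08/Gy·frac⁻¹, ZSV -0.05, 5% log-normal noise) and gEUDs accrue via
the transition prior. Outcomes are Bernoulli draws from logistic curves
on the week-6 gEUDs (LC: mu 45 Gy, T -5 Gy on tumor; RP2: mu 32 Gy, T -5
Gy on lung), which makes P(LC=1) and P(RP2=1) increase with dose — the
monotone assumption the self-evaluation scheme encodes — and produces
all four outcome classes. The generator reproduces none of the real
trials' covariance structure, measurement error, dropout or imputation;
green tests demonstrate mechanistic and statistical correctness of the
pipeline, not clinical performance.

### GLSZM zone-size variance

ZSV is computed as the variance of the zone size j under the normalized
zone probabilities p(i,j): `sum p(i,j) (j - mu)^2` with
`mu = sum j p(i,j)`. A literal transcription of the commonly printed
form, `(1/(Ng*Lz)) sum (j p(i,j) - mu)^2`, is available as
`variant="printed"` for comparison; it is not the variance of any
distribution for non-uniform matrices, which is why the probability-
normalized reading is the default. ZSV is invariant to zero-padding and
to the gray-level axis entirely.

## Augmentation

A WGAN-GP learns the joint distribution of the 12-column tabular records
(min-max scaled to [-1,1]) and emits 4000 synthetic rows by default.
Critic and generator are dense nets (2x64; ReLU critic, tanh generator);
lambda = 10, 5 critic iterations per generator step, Adam(0.5, 0.9) with
critic lr 2e-3 and generator lr one tenth of that (the two-timescale
ratio was needed for stable convergence on toy Gaussians). Because the
critic is piecewise linear, the gradient of the penalty
`lambda E[(||grad f(x_hat)|| - 1)^2]` with respect to the critic weights
has a closed form (backprop with the activation masks held fixed, exact
almost everywhere), verified against finite differences; bias gradients
of the penalty vanish identically. Post-processing snaps genotype to
{0,1,2}, binarizes outcomes at 0.5, and clips continuous fields to the
training support. Whether to augment full records or states only is a
config flag (`states_only`); the default augments full records so the
fitted environment and agent can consume them directly.

## Evaluation

The similarity score is the RMSE between ensemble-averaged
recommendations and clinical doses. The self-evaluation scheme tags each
recommendation from the outcome pair and Delta = AI - clinical:
(0,0): Good iff Delta > 0; (0,1): Good iff Delta < -0.1 (the 0.1 Gy/frac
cushion reflects that toxicity caps the deliverable dose); (1,0): Good
iff |Delta| <= 0.5, Unsure otherwise (the desirable outcome cannot be
improved upon, only matched); (1,1): Good iff Delta < 0. The clinical
baseline is scored on outcomes alone — Good iff (LC=1, RP2=0) — an
interpretation, since only the outcome information is available to score
the clinic against itself. Percentages are reported at full precision
with a rounded convenience copy.

## Numerical and engineering choices

* All networks are numpy dense nets with manual backprop and Adam;
  checkpoints are JSON (text), stamped with the config hash and seed.
* Deterministic seeding throughout (`numpy.random.default_rng`); under
  the noiseless controller backend the entire pipeline is bitwise
  reproducible for a fixed (config, seed).
* Degenerate inputs fail loudly: all-zero GLSZM, single-class outcome
  labels, empty cohorts/ensembles, non-binary outcomes, unnormalized
  voxel volumes, zero dose under a negative gEUD exponent, T = 0.
* Cohort CSVs are written at 17 significant digits and read with
  pandas' round-trip float parser, so write-read is bit-exact.
* Statevector simulation asserts unit norm after every gate (1e-9).

## Problem sizes

Tests and the reference scripts run at desk scale on one CPU: cohorts of
60-2000 patients, 3000 one-step episodes for the optimal-dose recovery
check (against a 32-dose enumeration oracle, >= 95% within one grid
step), a 2-state/2-action tabular check against value iteration (1e-3),
and a 2-D Gaussian WGAN-GP check (3000 generator steps, means within 0.1
sd). The full default pipeline (200 patients, 4000 augmented rows,
5-member ensemble) runs in a few minutes.

## Known limitations

The gEUD transition operates on scalar gEUD state; full voxel-level gEUD
is exposed only as the standalone `compute_geud` utility. No DICOM/PET
image handling or GLSZM extraction from images. The IBMQ-style hardware
path is an interface only. Policy-gradient methods, multimodal treatment
environments and patient-specific alpha/beta ratios are out of scope.
The synthetic cohort's arbitrary biomarker scales are configurable but
not calibrated to any trial.
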