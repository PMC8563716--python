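# Methods

`hipporpe` simulates rule-plus-exception (RPE) category learning with a
rate-coded model of the hippocampal circuit and reimplements the full
analysis chain around it: Luce-choice accuracy readout, representational
similarity analysis (RSA) of the hidden subfields, the category
representational difference (CRD) statistic, Sammon/Procrustes
representational trajectories, and mixed-effects models for both
simulated and (synthetic) behavioral trial data.  This note documents
the model, its assumptions, the parameters that matter, and the design
choices made where the design was genuinely open.

## Task structure

Ten flower stimuli live on four binary features (outer petal colour,
outer petal shape, inner petal shape, central disc colour) plus a binary
category label.  Features 1–3 are diagnostic and follow the
Shepard–Hovland–Jenkins Type III assignment: four prototypes (two per
category, one per value of the nondiagnostic fourth feature), four
rule-followers at diagnostic distance 1 from their prototype, and one
exception per category at distance 2 from its own prototype but
distance 1 from the opposite one.  No single diagnostic dimension
separates the categories (asserted by exhaustive enumeration).

The exact diagnostic triples and nondiagnostic values beyond the
category-A prototype are underdetermined; the default
(`stimuli.DEFAULT_STRUCTURE`) is one canonical Type III isomorph chosen
so that the category-A exception (EA) shares its nondiagnostic value
with its diagnostically nearest own-category rule-follower and prototype
variant while the category-B exception (EB) does not.  This builds in
the asymmetry that makes EA behave like a rule-follower and EB like a
true exception, and it is validated by a structural invariant (EA's
summed within-category distance over d4-sharing members is strictly
smaller than EB's).  Both maps are config-overridable; invalid
assignments are rejected.

Encodings are padded: five unit pairs, one-hot per dimension, value 0 ↦
`10`, so the all-zero category-A prototype encodes `1010101010`.

## Sequences

Both conditions run 144 learning trials in three 48-trial blocks at a
2:1:1 prototype:rule-follower:exception ratio (72/36/36 total), with a
prototype-only prefix of 8 trials.  Early: every block is 24 P / 12 R /
12 E.  Delayed: block 1 is 32 P / 16 R and blocks 2–3 are 20 P / 10 R /
18 E, preserving totals — the minimal deviation from the early
composition that moves all exception exposure past trial 48.  Within a
role, items appear equally often (±1, remainders rotated across
blocks), so role effects are not confounded with item frequency.  The
test sequence is 48 trials, 16 per role, identical across conditions.
Networks are probed at fixed checkpoints (early: 12, 36, 48, 72, 96,
120, 144; delayed: 24, 48, 60, 72, 84, 96, 120, 144 — denser around the
introduction of the exceptions).

## Network model

Five layers: `EC_in` (10 units) feeds the trisynaptic pathway
EC_in→DG→CA3→CA1 and the monosynaptic pathway EC_in→CA1; CA1 drives
`EC_out` (10), which feeds back to CA1 and — big-loop recurrence — to
EC_in.  Defaults: DG 400 units / 4 winners, CA3 80 / 6, CA1 100 / 25,
an order-of-magnitude match to the standard hippocampal model family
with the activity-fraction ordering DG < CA3 < CA1 enforced.

Each projection's drive is normalized by its source layer's expected
activity and mixed with a relative weight (all 1.0 except EC_out→CA1 at
0.3, so the feedforward cue dominates CA1).  DG and CA3 apply a hard
k-winners-take-all ramp (units below the k-th/k+1-th midpoint silenced,
winners saturating); CA1 uses a *soft* graded competition (logistic
around the same threshold) reflecting its lower inhibition — this is
what keeps CA1's code dense, distributed and overlapping, and it is
essential for the similarity structure: with a hard ramp CA1
orthogonalizes completely and the intercategory-similarity phenomena
disappear.  EC_out applies a logistic squash (threshold 0.3, gain
0.05).  Activations relax toward their targets with step 0.5 for up to
80 cycles (convergence tolerance 1e-4).

**Learning** is two-phase per trial.  The *expectation* phase presents
the cue exactly as at test: feature units of EC_in clamped, the
category pair left free and filled in by big-loop recurrence from
EC_out — the network settles on its own guess.  The *outcome* phase
clamps EC_in and EC_out to the full true pattern.  Weights change by

    Δw = lr · [ (plus coproduct − minus coproduct) + hebbian term ]

clipped to [0, 1].  The contrastive term is classic error-driven
learning; the Hebbian term operates on the duration-weighted mean
activity of the two phases (60 expectation + 20 outcome cycles), i.e.
on what the network actually settled into during the trial, including
wrong big-loop guesses.  Into DG/CA3 the Hebbian term is competitive
(each active receiver moves its weight vector toward the sending
pattern, fraction 0.05) so sparse winners specialize slowly; into
CA1/EC_out it is associative and soft-bounded (fraction 0.4) so
co-active features bind while weights saturate.  TSP projections learn
at 0.3, MSP/output at 0.05 (the TSP > MSP contract); the big loop is a
fixed identity.

Two of these choices were pivotal and deserve emphasis, because the
directional condition effects hinge on them.  First, running the
expectation phase on the *cue* (rather than the full pattern) makes the
big loop active during training, so early-learning category confusion
is re-entered and transiently bound into the hidden codes.  Second,
binding the whole-trial activity Hebbianly means that confusion leaves
a persistent trace.  Together they produce the blurring asymmetry: in
the early condition exceptions keep the network confused throughout
CA1's formative period, yielding higher intercategory similarity at the
end of learning, whereas the delayed condition lets the rule structure
crystallize first.

**Testing** presents each stimulus with the category pair blanked (only
big-loop feedback can fill it), settles 80 cycles with no weight
change, and records DG/CA3/CA1/EC_out activations; the ten stimuli are
settled in parallel.  Accuracy is the Luce ratio of cosine similarities
between EC_out's category pair and the target versus nontarget one-hot,
which for nonnegative readouts reduces to x_t/(x_t + x_nt); a
dead-zero readout raises rather than silently scoring 0.5.

**Ensembles.** A batch is one network trained on one seeded sequence;
batch *b* of a run uses seed `base_seed + b` for both weight
initialization and sequence shuffling.  The reference computation uses
500 batches per condition; the test suite uses 50 (directional checks)
and 100 (reference targets) to stay within a practical runtime, sizes
chosen as the smallest at which the respective quantities are stable —
below ~100 batches the ensemble-mean similarity matrices retain enough
sampling noise to push the worst-case Sammon stress above its
full-scale value.

## Analyses

*RSA.* A subfield's representation is the 10×10 Pearson correlation
matrix over stimulus activation rows (canonical order: category A then
B, each P,P,R,R,E).  Constant rows (possible in an untrained sparse
layer) give NaN cells with a warning and are excluded from means, never
zero-filled.  Per-batch matrices feed all statistics; ensemble-level
displays and the trajectory maps use the elementwise mean across
batches.  Intercategory similarity is the mean of the 25 A×B cells; the
CRD of an exception is ((1+ρ_intra) − (1+ρ_inter)) / ((1+ρ_intra) +
(1+ρ_inter)) with the self-correlation excluded from ρ_intra.
Condition comparisons of per-batch scalars use the two-sided Wilcoxon
rank-sum test, statistic on the Mann–Whitney U convention.

*Embedding.* Correlations become dissimilarities via d = 1 − r
(bounded, monotone, the standard choice for correlation RSA).  Sammon
stress is minimized from a classical-scaling initialization plus three
seeded random restarts, refined by Sammon's diagonal-Newton step with
step-halving, so stress is non-increasing and the map deterministic
under a seed.  Checkpoint configurations are aligned to the
end-of-learning map by similarity Procrustes (translation, isotropic
scale, rotation, reflection); alignment never changes stress.  Zero
off-diagonal dissimilarities are either rejected or floored, per
config.

*Mixed models.* End-of-learning accuracies are analyzed with a linear
mixed model (batch random intercept) on the accuracy scale — the
contrasts of interest are small mean shifts of a bounded continuous
outcome, and the reference coefficients are on that scale; a
logit-outcome sensitivity fit is available behind a flag.  Reference
levels are exception/early (so `condition[delayed]` is the exception
condition effect) and category-B/early in the exceptions-only model (so
the interaction is the A-minus-B difference of condition effects).
Behavioral trial tables are fit with a binomial logistic GLMM
(participant random intercept) by marginal maximum likelihood with
25-node Gauss–Hermite quadrature — the per-participant likelihood
factorizes, so one-dimensional quadrature is accurate — with Wald
CIs/p-values from the numerical Hessian and BIC from the marginal
log-likelihood.  Quasi-separation is detected and warned, never
silent.  Preprocessing excludes participants who never exceed 0.75
accuracy for any stimulus type in any block, or whose out-of-range
([0.15 s, 2 s]) reaction-time fraction exceeds 20%; surviving
out-of-range trials are dropped, and learning-phase analyses keep the
first 36 repetitions per role.  Preprocessing is idempotent and returns
an explicit exclusion report.

## Synthetic behavior

The generator emulates the trial-level layout of deposited behavioral
data so the preprocessing/GLME stages are testable without a download:
per-participant Bernoulli correctness with a role × condition intercept
and repetition slope plus a Normal participant intercept (logits capped
at ±10), and truncated log-normal reaction times that exist only to
exercise the exclusion rules.  Defaults qualitatively mimic the
empirical pattern (prototype > rule-follower > exception; a delayed
advantage for exceptions carried by the intercept and slope) and are
illustrative, not a calibration.  `inject_exclusion_cases` plants
tagged rule violators so filter output can be checked exactly.  What
the generator does *not* emulate: item-level difficulty within a role,
response-time/accuracy coupling, learning curves beyond a linear logit
slope, or session effects — so green tests certify the statistical
machinery, not fidelity to any particular empirical dataset.

## Known limitations

* The learning rule is a documented stand-in (contrastive two-phase +
  Hebbian), not a port of theta-phase Leabra/XCAL.  All headline
  *directions* replicate under the defaults — delayed advantage for EB,
  early advantage for EA, negative category × condition interaction,
  higher early-condition CA1 intercategory similarity (rank-sum
  p < 0.001), intra > inter in every subfield, CA1 > CA3/DG mean
  similarity, DG < CA3 < CA1 sparsity, Sammon stress under 0.035 at the
  full ensemble scale — but effect *magnitudes* are roughly an order of
  magnitude smaller than the reference implementation's (e.g. EB
  condition effect ≈ 0.02 vs 0.181 on the accuracy scale), and CA1
  intercategory similarity sits near 0.48/0.40 (early/delayed) rather
  than 0.718/0.619, with the same condition gap (≈ 0.08–0.12).
* In the 2-D trajectory, both exceptions' CRDs migrate toward their own
  category across learning, but the EB-*specific* large displacement is
  not reproduced: EA and EB move comparable distances under the
  stand-in rule.
* Prototype feature reconstruction (settled EC_out vs input cosine on
  the eight feature units) has a median of ≈ 0.90: the CA1 code
  abstracts the category and carries the nondiagnostic central-disc
  dimension weakly, so its pair settles near 0.5/0.5.  The package's
  memorization contract is stated (and tested) at 0.85.
* Connectivity-scaling parameters for lesion studies are exposed
  (`strength_scale` on CA3→CA1 and EC_in→CA1) but untested beyond the
  fully connected defaults.
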