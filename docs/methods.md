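# Methods

## The model

`topsec` labels every residue of an α-helical membrane protein with one of
four merged structure classes: membrane-spanning helix **M**, non-membrane
helix **H**, non-membrane strand **E**, and non-membrane coil **C**.
Coarser views are projections of the 4-class string: topology (Q2;
M → T, everything else → N) and secondary structure (Q3; {M, H} → H).

The sequence model is a **class hidden Markov model (class HMM)**: a hidden
Markov chain in which every emitting state belongs to exactly one class, so
supervision at the class level constrains the hidden path without fixing
it.  The default state graph has 12 states: silent `Begin`/`End`, a
(begin, interior, end) triple for each of M, H and E — the interior
self-loops, so each of those segments is at least three residues long —
and a single self-looping C state.  Segment grammar is encoded in the
allowed-transition mask: `Begin` feeds the four sub-model entries, each
sub-model exit feeds the other sub-models' entries, C, or `End`.  The
topology is an ordinary data object (loadable from YAML), so alternative
wirings can be evaluated without touching the dynamic programs.

Emission scores are **pluggable**.  The dynamic programs consume a
positions × emitting-states table of non-negative scores and do not care
where it came from:

* *tabular* — per-class residue distributions, which turns the hybrid
  model into a classical HMM.  Used as the testing oracle and by the
  synthetic generator;
* *softmax network* — a window classifier producing a probability vector
  over the 10 emitting states per residue (separate-training regime);
* *per-state sigmoid regressors* — independent (0, 1) outputs per state
  (joint-training regime).

## Input encoding

Each residue is a 52-dimensional vector: 20 one-hot columns (alphabetical
over the standard amino acids, A=0 … Y=19), one NoSeq flag, 30
evolutionary-profile values squashed into (0, 1) by
`f(t) = 1 / (1 + exp(−t/2000))`, and a second NoSeq flag.  Missing
profiles leave the 30 columns at zero; `*` entries in `.hhm` files map to a
−40000 sentinel, which squashes to ≈0.  The network sees a sliding window
of 19 residues centred on the position being classified (the window length
is a parameter; 19 is the default); positions beyond either terminus are
padding rows that are all-zero except the two NoSeq flags.

## The emission network

A compact neural network implemented directly in numpy (float64
throughout, driven by one seeded generator, so training is
bit-reproducible): a stack of same-padded 1-D convolutions over the window
(default one layer of 32 filters, width 3), a bidirectional LSTM (default
16 units per direction), additive attention pooling over window positions
(`score_t = v·tanh(W h_t + b)`, softmax weights, weighted sum), two fully
connected ReLU layers (32, 16), and the head.  Forward and backward passes
are hand-derived and verified against central finite differences in the
test suite (relative error ≲ 1e-5 at step 1e-5).  Optimisation is Adam
(default rate 2e-3, batch 64) with save-best weights and early stopping
after 10 epochs without validation-loss improvement.  The layer sizes are
deliberately small: the synthetic task saturates well below this capacity
and training stays in the minutes range on one CPU.

Supervised targets distribute each residue's class mass uniformly over the
class's states (1/3 per M/H/E state, 1 for C); a class-tied mode (4
outputs broadcast to same-class states) exists as a config option.  The
joint regime instead uses 0/1 label-consistency indicators per state.  The
per-state regressor family shares a trunk with 10 independent sigmoid
heads; this keeps the "one regressor per state" semantics of the loss
while remaining desk-scale.

## Training

**Conditional maximum likelihood (CML).**  With emissions fixed, the
transition matrix θ is trained to maximise P(y | x, θ) =
P(x, y | θ) / P(x | θ).  Each iteration runs two forward–backward passes
per sequence: a *free-running* phase over all paths (giving
Lf = −log P(x|θ)) and a *clamped* phase restricted at every position to
states of the labelled class (giving Lc = −log P(x,y|θ)); the loss is
L = Lc − Lf ≥ 0.  The gradient is the difference of posterior expected
edge counts between the two phases: ∂L/∂θij = −(Cc,ij − Cf,ij)/θij, with
the analogous per-position expression for emission parameters.  θ is
parameterised by unconstrained logits mapped to the simplex by row-wise
softmax over allowed edges, so gradient steps can never leave the simplex
or touch a forbidden edge.  Descent is safeguarded: a fixed step (default
0.01) is halved and retried whenever the summed loss would increase, so
the loss trace is non-increasing; fitting stops at a relative improvement
below 1e-6 or 500 iterations.

Pipelines initialise θ from *supervised expected counts*: one clamped
forward–backward under uniform transitions, normalised with a pseudocount
of 1 per allowed edge.  With per-residue labels available this is the
standard initialisation and is already close to the generative optimum;
CML then refines the discriminatively identifiable directions.  A caveat
documented here because it shapes what parameter-recovery experiments can
show: directions of θ that barely affect P(y|x) (e.g. the Begin row when
emissions are informative) carry little conditional Fisher information,
so long CML runs drift along them without harming predictions.  The
conservative step schedule and counts initialisation bound that drift.

**Separate regime.**  Train the softmax emission network supervised;
freeze it; compute its posteriors on the training set; fit θ by CML.  At
decode time the posteriors are used directly as emission scores
(configurable: `rescale=True` divides them by marginal state priors,
the scaled-likelihood convention for hybrid models).

**Joint regime.**  Alternating rounds: (1) the regressor outputs
e_k(s_i; w) seed the emission parameters E_k; (2) one full-dataset CML
step updates θ and one gradient step updates E_k ← E_k − η ∂L/∂E_k
(η default 0.1, values clipped to (1e-6, 1−1e-6)); (3) the combined
residual ERROR = (T_k − E_k) + (T_k − e_k) against the 0/1 targets T_k
defines the loss L2 = mean(ERROR²), and the regressors train one epoch on
it; (4) validation accuracy (full Viterbi decoding) drives save-best and
patience-10 stopping.  The square is taken of the *sum* of the two
residuals; with everything in agreement (E_k = T_k = e_k) the loss is
exactly 0.

## Decoding

Viterbi over the allowed graph in natural-log space, with Begin-row scores
as initialisation and End-column scores as termination; ties break toward
the lower state id.  The decoded state path projects to the 4-class label
string; Q2/Q3 are projections of that.  All dynamic programming is
log-space with log-sum-exp (no probability-space scaling), which is
accurate and fast for sequences up to the few-thousand range.

## Synthetic data

The generator is a generative class HMM with a known transition matrix θ\*
and known class-conditional residue distributions, standing in for a real
membrane-protein corpus so that every stage is testable without downloads:

* θ\*: interior/coil self-transitions 0.9 (geometric mean run length 10);
  segment exits favour coil; termination mass 0.05 from M/H/E exits and
  0.01 from C.  Sequence lengths are drawn uniformly from the requested
  range (default 60–200, minimum 30, mirroring the usual short-chain
  filter) and the state path is sampled *exactly conditioned on that
  length* using backward survival weights — no rejection loops, fully
  seed-deterministic.
* class alphabets: M is enriched in hydrophobic residues (AFILMVWY), H in
  charged/polar ones (DEKNQR), E in CGHST, C in the classic turn formers
  (DGNPS).  A `separation` knob (default 0.8) is the probability mass
  concentrated on the class set; at the default the minimum pairwise
  Jensen–Shannon divergence between classes is 0.37 bits.
* pseudo-profiles: per residue, the first 20 columns are the logit (on the
  sigmoid's raw scale) of a residue/class mixture plus Gaussian noise
  (sd 300 raw units); the last 10 columns are noise.  They carry label
  signal the way evolutionary profiles do, and they round-trip through the
  `.hhm` writer/reader bit-exactly.

What the generator does **not** emulate: within-class residue
autocorrelation (residues are i.i.d. given the state), realistic segment
length distributions beyond geometric, MSA-derived profile structure, and
class imbalance as extreme as real corpora.  Consequences for
interpretation: a window classifier approaches the per-position Bayes
optimum on this data more easily than on real proteins, which compresses
the headroom that Viterbi decoding has over per-position argmax (decoding
mainly repairs segment-level validity — minimum lengths, segment counts —
rather than raw per-position accuracy).  Passing tests demonstrate
correctness of the machinery and recoverability under known conditions,
not benchmark performance on real membrane proteins.

## Evaluation

Q2/Q3/Q4 are per-position accuracies on the respective alphabets.  MCC is
the textbook binary formula on two-letter alphabets and the Gorodkin R_K
contingency-table generalisation otherwise (zero denominators give 0).
SOV follows the SOV'99 definition: per-class maximal segments; each
overlapping true/predicted pair contributes
(minov + δ)/maxov · len(S1) with δ = min(maxov−minov, minov,
⌊len(S1)/2⌋, ⌊len(S2)/2⌋); unmatched true segments enlarge only the
normaliser; dataset-level SOV joins proteins with a separator so segments
never merge across chains.  Per-class recall/precision/specificity/F1 are
one-vs-rest; classes absent from both strings are reported as NaN rather
than 0 so macro-averages cannot be silently deflated.  TM-segment
correctness counts proteins whose number of maximal M-runs is exactly
right (no minimum segment length by default; an option exists).

## Numerical choices and degenerate inputs

* −inf encodes impossible states/edges throughout; an infeasible clamped
  labelling yields +inf loss (reported, not silently clipped).
* Viterbi raises on sequences with no feasible Begin→End path.
* Emission gradients at positions with zero posterior mass in both phases
  are defined as 0.
* MCC with a zero denominator is 0 by convention; undefined per-class
  statistics are NaN markers.
* All randomness flows through `numpy.random.default_rng(seed)`; every
  training entry point is a pure function of (data, config including
  seed).

## Problem sizes used in the shipped tests

The acceptance suite runs the DP-vs-enumeration check on 200 random
instances (≤5 emitting states, length ≤6), the gradient check on 50
instances, transition recovery on 200 sequences of length 100 at three
seeds, and both training pipelines on a 300-sequence corpus (lengths
60–200, ~36k residues) with a 25-epoch network budget and 60 CML
iterations — sizes chosen so the full suite completes comfortably on a
single CPU while every claim is still exercised at meaningful scale.

## Known limitations

* Transition parameters that the conditional likelihood barely constrains
  are recovered only as well as the supervised count initialisation allows
  (see the CML caveat above); reporting recovery as mean per-row L1
  reflects this.
* On this generator, per-position accuracy of Viterbi decoding sits
  within noise of — and often slightly below — the emission network's own
  argmax, because window posteriors already approximate smoothed
  marginals; the decoder's contribution shows in segment-level metrics.
* The joint regime inherits the known imbalance sensitivity of per-state
  regression training; it is provided as a reference implementation of the
  alternating scheme, not as the recommended predictor.
* β-barrel membrane proteins and signal peptides are out of scope of the
  default topology.
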