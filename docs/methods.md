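# Methods

## Model and procedure

The package optimizes the input features of a frozen fold-confidence
predictor rather than the predictor itself. The manipulated feature is the
MSA cluster profile `P ∈ R^{L×22}` (per-column frequencies over
`ARNDCQEGHILKMFPSTWYVX-`; ambiguity codes B/Z/J/U/O map to X, `*` is
stripped). An unconstrained additive bias `B`, initialized to zeros with
the shape of `P`, is learned by minimizing `1/RC` with
`RC = 0.8·iptm + 0.2·ptm`, using Adam with bias-corrected moments. Features
enter the backend as the raw sum `P + B`: no clamping or renormalization,
matching the reading that the perturbation acts on the raw feature tensor.
Gradients are taken only at the backend's final internal pass, never across
recycles; the optimizer state persists across the per-iteration MSA
resampling. The output of a run is the full per-iteration trajectory plus
the final bias; the *selected* model is the highest-confidence record, ties
going to the earliest iteration.

Two stochasticity sources are modeled at the interface we control:
per-iteration cluster resampling (fresh uniform sample of rows, query
always first, default 128 cluster centers capped at the row count) and
backend-internal noise (in the surrogate, each internal pass evaluates a
random 80% column subset). Both flow from a single master seed via
`SeedSequence`-style derivation `(master_seed, iteration, stream)`, so
stochastic runs are bit-reproducible.

## The surrogate backend

The surrogate exists to make the machinery testable against known ground
truth; it makes no claim of fidelity to a real predictor's confidence
landscape. A problem plants a sharp profile `P*` (per column, a Dirichlet
draw with concentration 10.0 on one of the 20 standard amino acids and 0.1
elsewhere, ≈0.83 expected mass on the planted residue), blurs it by adding
N(0, σ²) noise and projecting back onto the simplex (Euclidean projection),
and samples an observed MSA i.i.d. per column from the blurred profile,
with the planted consensus as the gap-free query row. Confidence is

    d    = mean over evaluated columns of ||f_col − P*_col||²
    iptm = exp(−k_i·d),  ptm = exp(−k_p·d),  RC = 0.8·iptm + 0.2·ptm

averaged over `n_recycles + 1` passes (recycling here only reduces
subset-sampling variance). The gradient is defined at the final pass only:
`dRC/df = (0.8·k_i·iptm + 0.2·k_p·ptm)·(−2/L')·(f − P*)` on that pass's
columns and zero elsewhere, so forward and gradient calls must replay the
same noise stream — the optimizer passes generators seeded identically for
the pair. The objective is smooth and convex in the features, so descent
and parameter recovery are provable properties of a correct implementation,
which is the point.

Defaults define the study conditions and were chosen once: L=50, 200 MSA
rows, σ=0.1, k_i=5, k_p=3 (so iptm < ptm at moderate distance, loosely
echoing interface vs. global score behavior), 80% column subsets as the
single noise knob.

What the surrogate does not emulate: real covariation structure, chain
geometry, pLDDT/PAE, the non-convexity of a learned network's confidence
surface, or any relationship between MSA depth and difficulty. Passing
tests therefore certify the optimization/selection machinery, not
structure-prediction accuracy on real complexes.

## Multimer featurization

Species pairing uses header taxa (`OX=`/`TaxID=`): for each species present
in every chain, the highest-identity-to-query row per chain is concatenated
(identity = fraction of matching non-gap query positions; ties to the
lowest row index). Gene-distance pairing is not reproducible without
genomic coordinates, so identity is the deterministic stand-in. Rows
without a parsable taxon are unpairable. Block diagonalization emits each
chain's non-query rows padded with gaps outside the chain's column span;
it returns an MSA fragment without a query row (`query_index=None`), and
`build_multimer_msa` stacks query + paired + block rows into the final
alignment. This resolves the tension between "one output row per non-query
row" and a representation that must always carry a query: the fragment is
an intermediate, the stacked alignment is the consumable object.

## Numerical choices

- Profile validity: rows sum to 1 within 1e-9; TSV/JSON serialization at 12
  significant digits round-trips well inside that tolerance.
- Deletion counts attach to the match column following the insertion run;
  trailing insertions (no following match column) are dropped. A3M writing
  emits insertions as lowercase `x` runs, since inserted residue identities
  are not retained — counts, rows, headers and species round-trip exactly.
- Adam: standard bias-corrected recurrence; ε=1e-8 inside the square-root
  denominator. The update is checked against a written-out scalar recurrence
  to 1e-12.
- Finite-difference gradient checks use central differences with h=1e-6 and
  a 1e-10 absolute floor: the cancellation error of a central difference on
  an O(1) function at h=1e-6 is ~1e-10, so below that level the comparison
  would measure FD roundoff, not gradient error.
- Confidence ≤ 0 from a backend raises immediately (degenerate output)
  rather than producing an infinite loss.
- Spearman on a constant vector is reported as NaN, an explicit
  not-a-value flag — trajectories can plateau, and silently reporting 0
  would masquerade as "no association".
- Outcome thresholds (accuracy 0.75, confidence 0.8) are strict
  inequalities; boundary values do not clear a threshold.
- `select_best` ties break to the earliest iteration, making selection
  deterministic on plateaus.

## Validation design

Planted-problem recovery is the module's reason to exist: starting from the
observed profile with zero bias, the deterministic setting (no resampling,
lr 1e-2, 100 steps) must reduce the mean squared distance to `P*` by ≥90%
(measured at the selected best-by-confidence record, i.e. the model the
method actually outputs — the last Adam iterate can oscillate at the step
scale). Alongside it: trajectory-wise Spearman(confidence, accuracy proxy)
≥ 0.9 in deterministic runs; confidence collapse below 50% of the observed
level under uniform-simplex profile randomization; monotone degradation of
initial confidence in σ; and exact agreement of the evaluation statistics
with brute-force oracles (pairwise concordance for ROC-AUC, hand-ranked
examples for Spearman, group-by for running means).

Problem sizes in the test and acceptance runs (L between 10 and 200, MSA
depth ≤ 200 rows, 7-target batches) are the package's desk-scale study
conditions; record accounting (targets × iterations) is independent of
problem size.

## Known limitations

- The runnable backend is synthetic; no adapter to a real predictor is
  included beyond the documented stub surface.
- The learning-rate default 1e-4 (configurable, with the 1e-4..1e-2 range
  exposed) is kept for fidelity to the standard setting even though the
  convex surrogate tolerates — and the recovery tests use — the faster
  1e-2.
- Pairing quality depends entirely on header taxa; no gene-distance or
  cross-database merging logic is attempted, and a single pre-merged MSA
  per chain is assumed.
- No early stopping: runs always use the full iteration budget.
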