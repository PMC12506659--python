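# Methods

This note documents the models, procedures, defaults, and design
choices behind `ecaudit`, and what the synthetic-data experiments do and
do not establish about real data.

## EC numbers and hierarchical comparison

An EC number is stored as up to four levels, each a positive integer or
an unspecified marker; unspecified levels occur only as a contiguous
suffix (partial codes are prefixes — there are no internal wildcards,
matching how partial ECs appear in annotation databases). `2.7.1` and
`2.7.1.-` normalize to the same code. Comparison is on integers, so
leading zeros are harmless.

The relation of a predicted to a reference EC is: *identical* (same
specified depth, all levels equal), *specializes* (reference is a proper
prefix of the prediction), *generalizes* (the converse), or
*divergent at level k* (first level where both are specified and
disagree). Reference entries can carry several ECs; the rubric needs a
single verdict, so the best relation is chosen with precedence
identical > specializes > generalizes > divergent, and among divergent
relations the deepest divergence (largest shared prefix) is reported as
the most informative. This precedence is a package decision — curation
practice for multi-EC entries is not standardized — and is surfaced in
the call's rationale code rather than hidden.

## The audit rubric

Evidence per prediction is a set of curation judgements encoded as
boolean flags (same function annotated without an EC, family supports
the predicted activity, activity already assigned to another gene,
same-family paralog holds the activity, pathway absent from the
organism, literature refutes / supports-but-uncaptured, family known to
contain non-isofunctional paralogs). Flags are inputs, not computed
from text: deciding whether two free-text function descriptions denote
the same activity is a curation judgement we deliberately do not
automate.

Classification is a fixed decision tree, evaluated in order:

1. identical EC, or same function without an EC, or same function under
   a partial EC the prediction specializes → **CNN** (CS 2);
2. prediction generalizes the reference → **LSP** (CS 2);
3. literature supports an activity the reference database missed →
   **COR** (CS 2);
4. any refuting evidence (absent pathway, activity owned by another
   gene, refuting literature): if the prediction was flagged as a
   replication → **REP** (CS 0); else if the owning gene is a
   same-family paralog, or the family is known non-isofunctional and
   the codes diverge only at the serial (4th) level → **PLI** (CS 0);
   otherwise → **NPI** (CS 0);
5. otherwise → **UNC** (CS 1).

The confidence score is a pure function of the category. Every record
receives exactly one category, so tallies always partition the input.
REP takes precedence over PLI/NPI among refuted records: replication is
treated as its own failure mode because it indicates a property of the
model (echoing common labels) rather than of the protein.

**Repetition detection.** A locus is flagged when its full predicted EC
occurs at least `min_count` times (default 3) across the prediction set,
its own family does not support the activity, and the record is not
already supported under rules 1–3. Supported or family-backed records
are exempt from flagging but still count toward the occurrence tally —
replication is a property of the EC, exemption a property of the record.

**Tallies.** Percent-correct is 100·(CNN+LSP+COR)/n and
percent-inconsistent 100·(PLI+NPI+REP)/n, reported both at one decimal
and at integer precision (summaries in the field mix both styles).
Empty inputs tally to zeros with a warning.

**Macro-F1** is computed per full-EC class over the union of classes in
truth and predictions (absent classes score 0 via the zero-division
rule) and averaged unweighted; `scikit-learn` does the per-class
precision/recall arithmetic, and the tests pin it to a hand-computed
example.

**Frequency dependence** is the Spearman correlation between per-EC
prediction counts and training-label frequencies over the union of ECs
(absent = 0), undefined (reported as such) below 3 distinct ECs. A
predictor that echoes its training distribution scores near +1; a
sequence-driven predictor on a frequency-unrelated label mix scores
near 0. Because a single family contributes only as many rank points as
it has labels, the near-zero regime is estimated as the mean over
independent replicate families (10 by default) rather than from one
draw whose sampling noise (sd ≈ 0.23 at 20 labels) would dominate.

## Sequence similarity networks

Meta-nodes collapse sequences by single-linkage at ≥ 70% pairwise
identity (the conventional representative-node rule). The alignment
score of an edge is AS = min(−log10 E-value, 200), with E = 0 capped at
200 to avoid infinities; cross-meta-node scores are aggregated by
maximum (most permissive; mean is available) and an edge survives only
when the aggregate is **strictly** greater than the threshold. Raising
the threshold therefore never adds an edge, and component counts are
non-decreasing — a property the tests check against a brute-force
depth-first-search oracle.

The sweep raises the threshold from `as_start` in steps of 5 AS units
and stops at the first threshold where at least 90% of clusters holding
at least 5 sequences reach label purity ≥ 0.9 ("most clusters
homogeneous", quantified; all three constants are configurable). If no
cluster reaches the size floor the state is treated as vacuously
homogeneous; if the network runs out of edges first, the last threshold
with edges is returned with a not-converged flag.

For synthetic equal-length sequences the package uses ungapped column
identity and the monotone surrogate AS = identity × L / 2; real data
should supply BLAST tabular scores, which the reader converts (pident →
fraction, E-value → AS, reciprocal hits collapsed keeping the best).

Gene-neighborhood signatures report, per cluster, the fraction of
member sequences whose ±window (default 5) context contains each
neighboring gene family; families at ≥ 0.5 form the dominant signature,
and members without context are tallied separately rather than
diluting the denominator.

## Residue-importance explanation

The explainer is a LIME-style local surrogate adapted to multilabel
sigmoid outputs: explanations isolate one label's score at a time, and
by default only the top-scoring label of each sequence is explained
(ties break to the first label and are flagged).

Perturbation masks each position independently with probability
`mask_rate` (default 0.3) using the token `X`; the unperturbed row is
always sample 1. Per-residue masking is the finest-grained choice; a
contiguous-segment mode (`segment_length`) is provided as an option. An
exhaustive mode enumerates all 2^L masks for small L, which the tests
use to compare against a closed-form least-squares oracle.

The surrogate is ridge-penalized weighted least squares of the label
score on the binary keep/mask design: weights exp(−d²/kernel_width²)
with d the masked fraction (simpler and monotone where a cosine kernel
would be an alternative), kernel_width 0.25, ridge 1e-3, n_samples 1000
by default. With exhaustive masks, infinite kernel width, and zero
ridge the coefficients equal the ordinary least-squares solution to
numerical precision. Note the sampled surrogate converges to the
projection under its own sampling distribution: at mask_rate 0.5 that
limit coincides with the uniform exhaustive design, which is what the
fidelity tests exploit.

Batch explanation draws a uniform subsample without replacement of up
to `max_explained` (default 500) sequences; the rest receive the
explained subset's global mean binned profile interpolated to their own
length, marked `estimated`. Extrapolating by the aggregate profile is a
package decision; nothing finer is identifiable without explaining the
sequence itself.

Profiles are compared across sequences of different lengths by
resampling each importance vector to `n_bins` (default 100) relative
positions — averaging positions per bin, or linear interpolation when
the sequence is shorter than the bin count. Stratified profiles divide
importances by the category-wide maximum absolute value (normalizing to
[−1, 1]) before binning and report per-bin mean ± sd. For the
peaked-vs-flat contrast between supported and replication-type
predictions, both groups are normalized against the supported group's
scale, so "flat" is measured in units of the informative signal.

## Synthetic data

The generators produce data with exactly the structure the analysis
assumes — no more.

**Superfamilies.** One random ancestor; subgroup ancestors diverge from
it, and members from their subgroup ancestor, by substitution-only
mutation (uniform over the 19 alternative residues, never silent).
Substitution rates are solved numerically from the identity targets
using the exact two-lineage match probabilities (a position matches
with probability s² + (1−s)²/19, where s is the per-lineage
root-retention probability). Mutations hit exactly round(rate·L)
positions rather than Bernoulli draws: same expectation, much smaller
variance, so small families land on their targets (realized means are
within ±0.05 of the targets; defaults within 0.8, between 0.45,
L = 120). Each subgroup carries a planted signature: 3 fixed,
subgroup-specific residues at positions disjoint across subgroups; the
identity targets are adjusted for these overwritten columns. True ECs
come from a fictitious series (`9.9.9.k`) that cannot collide with real
codes. Substitution-only mutation means no indels, equal lengths, and a
well-defined ungapped identity — deliberately unrealistic evolution,
because the audit logic depends only on the identity structure.

**Neighborhoods.** Each subgroup has a designated partner family placed
adjacent (offset +1) with probability `colocal_prob` (default 0.9);
remaining slots within ±5 draw uniformly from 30 decoy families.

**Toy classifiers.** *Motif* mode scores each label by
sigmoid(sharpness·(signature matches − (n_sig − 0.5))) — a model that
reads localized residues. *Frequency* mode carries no biological
signal: per-label base scores are a fixed monotone transform of the
training-label frequencies, and the top label is drawn per sequence by
inverse-CDF sampling of those frequencies from a CRC32 content hash —
deterministic given (sequence, seed), insensitive to the planted
signatures, and producing prediction counts that mirror the training
distribution, which is the defining behaviour of frequency-dependent
prediction. *Hybrid* mixes the two score vectors convexly (weight 0 =
pure frequency). A frequency mode with literally constant scores was
considered and rejected: it collapses every prediction onto the single
most frequent label, which neither reproduces frequency-matched
prediction counts nor admits a meaningful rank-correlation test.

**Audit fixtures.** Evidence records whose flags force each intended
category, with replication groups of configurable ECs (each at least
`min_count` strong — a REP total of 1 or 2 is infeasible under the
rubric and is rejected rather than silently mis-generated). The
full-scale fixture mirrors the audited 453-prediction set: counts
CNN 136 (121 identical-EC + 15 same-function), LSP 27, COR 3, UNC 42,
PLI 42, NPI 77, REP 126, including 12 replicated histidine-kinase
predictions (`2.7.13.3`) and 15 PTS predictions (`2.7.1.69`) of which 4
carry family support and are therefore exempt from flagging.

**What passing tests show — and don't.** The synthetic superfamilies
have uniform substitution, no indels, no length variation, no
alignment ambiguity; the similarity surrogate is monotone in identity
by construction; evidence flags are internally consistent by
construction. Green tests therefore establish that the *logic* of each
stage is correct under its stated assumptions, not that real curation
data is this clean: real evidence tables contain judgement calls the
flag encoding compresses away, and real BLAST scores are noisier than
the surrogate.

## Numerical and reporting choices

Positions are 1-based in all user-facing tables, 0-based internally.
Tabular outputs are sorted by locus/sequence id with floats at 6
significant digits, so repeated runs diff cleanly; every run directory
embeds the config, its SHA-256 hash (first 16 hex digits), the seed,
and per-stage record counts in the log. All randomness flows from
explicit seeds through `numpy` generators (child seeds via
`SeedSequence.spawn`); CRC32 content hashing keeps the frequency-mode
classifier deterministic across processes. Degenerate cases are
explicit: empty tallies warn and report zeros, an all-identical
perturbation design is an error advising a larger sample budget, an
empty stratification category is omitted with a warning.

## Problem sizes

The test suite and the reproduction script run at desk scale, chosen so
each statistic is stable at its decision threshold: the rubric fixture
at its natural 453 records; sweeps on 200-sequence families (4
subgroups × 50); signature recovery on 10 subgroups × 5 sequences with
1000-sample surrogates; the frequency-dependence contrast at 5000
sequences / 10 labels (frequency regime) and 10 replicate families of
3000 sequences / 20 labels (sequence-driven regime); batch-explanation
bounds at 600 sequences against the 500-explanation budget.

## Known limitations

Multi-EC reference precedence and the REP-before-PLI/NPI ordering are
package decisions where curation practice is unstated. The explainer's
"aggregate statistics" extrapolation assigns unexplained sequences a
profile that ignores their individual content. The neighborhood
signature treats gene families as exchangeable tokens (no synteny order
beyond the window, no strand). The generators make no attempt at
phylogenetic realism, and identity targets are enforced in expectation
per family, not per pair.
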