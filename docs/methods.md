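# Methods

This note records the modelling choices, defaults, and numerical details of
defenscan, and what its synthetic validation does and does not establish.

## Problem setting

Given a prokaryotic genome (or pre-called proteins), annotate genes belonging
to ten antiviral defense ("Doron") systems and assemble them into multi-gene
cassettes. The setting is open-set: almost all genes in a genome belong to no
training class, so per-gene decisions must include a reject option, and a
band of "almost confident" predictions is surfaced as CANDIDATE calls for
potentially novel subtypes.

## Encodings

Sequences are sanitized to a 21-letter alphabet (20 canonical residues plus
X; B→D, Z→E, J→L, U→C, O→K, anything else→X — lossless on canonical data and
total on real-world FASTA). One-hot matrices are truncated at the C-terminus
to `l_max` (default 1,000; desk-scale studies use the generator's maximum
length) and zero-padded with an explicit mask.

Twelve descriptors accompany each sequence: length, molecular weight,
instability index, isoelectric point, aromaticity, GRAVY, net charge at
pH 7, fractions of positively (K, R) and negatively (D, E) charged residues,
and helix/turn/sheet propensity fractions. All but the length are computed
with Biopython's ProtParam on the X-stripped sequence; degenerate inputs
(e.g. all-X) yield 0.0, never NaN. The exact 12-feature set used by the
original study is not printed in its text, so this documented, standard,
exactly-12 set stands in for it. Descriptors are z-scored with statistics
from the training split only, stored in the checkpoint.

## Architecture

One 1-D convolution (kernel 7, stride 5) over the one-hot axis, ReLU, two
bidirectional GRU layers, and three linear layers; a small head processes
the 12 descriptors and its output is concatenated with the final GRU states
(forward state at the last valid step, reversed state at position 0) before
the linear stack. Padded positions never influence hidden states: recurrent
updates are gated by a per-timestep mask, so states freeze at the end of
each sequence's valid region.

Layer widths were tuned but not published by the original authors; defaults
here (conv 64 channels, GRU hidden 128, head [32], linear [256, 64, k]) are
configurable, and the desk-scale studies use smaller widths (48/48/[16]/
[64, 32]) chosen for one-CPU runtimes.

The network core is a compact NumPy implementation: a reverse-mode autodiff
engine over float64 arrays plus a fused GRU scan whose backward pass is
hand-derived backpropagation through time. Gradients of every layer and all
four losses are validated against central finite differences (relative error
≲ 1e-4 in the test suite), and the fused scan is tested for exact agreement
with a step-by-step reference recurrence.

## Training

Adam (lr 0.001), up to 150 epochs, multi-step decay ×0.9 after epochs
{3, 12, 22, …, 92} (the published phrase "after 3, 12, and then every other
10 epochs up to 100" is read literally as every 10; configurable), batch 64
(32 in the motif study, where the fixed epoch budget otherwise delivers too
few gradient updates at n = 900), shuffled each epoch under the run seed.
Early stopping on validation loss arms after ⌈epochs/3⌉ epochs with patience
20 and restores the best-validation weights; ties keep the earlier epoch.
Samples are weighted by their class's N/(n_c·k).

Losses: weighted cross-entropy; label smoothing q′(i) = (1−ε)δ_{y,i} + εμ(i)
with uniform μ (default ε 0.1); confidence penalty as an entropy hinge
added to the cross-entropy, β·max(0, Ω − H(p̂)) (defaults β 0.1,
Ω = 0.5·ln k) — written with the sign under which it penalizes confident
(low-entropy) outputs, which is the stated purpose of the method; and the
DOC sum of k binary log-losses on sigmoid outputs. Log-probabilities are
computed from logits with max-subtraction; probabilities fed to logs are
floored at 1e-12. At β = 0, ε = 0, or Ω = 0 each regime reduces exactly to
weighted cross-entropy (asserted to 1e-9).

Stratified splits follow the convention that uniquely reproduces the
published sizes for N = 21,196: test = ⌊0.1·N⌋, validation = round of
0.1·(N − test), train = remainder, each class within ±1 sample of its global
proportion in every part. Classes with fewer members than folds are flagged,
not dropped.

## Calibration and rejection

Temperature scaling fits T > 0 by validation NLL (bounded scalar
minimization on log T, tolerance 1e-6); vector/matrix scaling fit W, b by
L-BFGS on validation cross-entropy with analytic gradients, starting from
the identity, returning the best iterate with a convergence flag if the
iteration cap (500) is hit. Scalers are fitted on the in-distribution
validation set (the fitting objective on unrelated data is unspecified in
the source methodology); the unrelated set is evaluated only through the
mean-distance metric. For sigmoid-head models the scaled logits pass through
the sigmoid instead of the softmax.

DOC thresholds: per class, the probabilities of correctly classified
validation samples are mirrored about their mean (a config switch mirrors
about 1.0 instead, matching the original DOC publication), σᵢ is the
population standard deviation of the combined set, and
tᵢ = max(0.5, 1 − α·σᵢ). The candidate bar at α = 4 reuses the same fitted
μᵢ/σᵢ — only α changes. Classes with no correct predictions get tᵢ = 0.5 and
a flag. Rejection: REJECT iff every pᵢ < tᵢ, else argmax (ties to the lowest
class index). Applying DOC thresholds to calibrated softmax outputs is
supported as a documented extension so the benchmark can cross every method
with every scaling.

## Ensembles and the benchmark

Ensembles (default 3 members, independent seeds) average member
probabilities and take the argmax; the reported certainty is the minimum
member probability among members whose own argmax agrees with the ensemble
class, or the averaged probability if none agrees (the averaged argmax need
not match any member). "Confidence" of a sample is always the probability
of its predicted class, which keeps the unrelated set's confidence defined
without labels.

The benchmark crosses {softmax, DOC, smoothing, penalize} × {unscaled,
temperature, vector, matrix} × {single, ensemble} and scores mean distance =
mean related-test confidence − mean unrelated confidence (can be negative),
plus accuracy on the related test set only, averaged over CV folds with SDs.
Temperature scaling provably preserves each single model's predicted class;
in ensemble mode, averaging temperature-scaled members can in principle
reorder the average, so accuracy equality is asserted only in single mode.

## Synthetic data

Class c is a random-background sequence (uniform over the 20 canonical
residues by default) with a class-specific 6–12-residue motif implanted at a
random position with probability 1.0; the unrelated class has no motif. Toy
genomes lay planted cassette genes and background genes along one replicon,
back-translated with a fixed one-codon-per-residue table (determinism over
codon-usage realism) so the nucleotide and protein paths agree exactly;
truth labels and cassette spans are emitted as GFF3.

What this emulates: class-specific local sequence signal in otherwise
unrelated sequence, class imbalance handling, and defense-island gene
clustering. What it does not: homology structure within and between real
Doron families, real length and composition distributions, overlapping genes
and strand effects, or HMM-comparable profiles. Passing the synthetic suites
therefore validates the machinery (losses, calibration, rejection, chaining)
and the qualitative open-set behaviour, not real-genome accuracy.

### Study conditions (frozen in `defenscan.studies`)

* Open-set benchmark: 4 Zorya-like subclasses + unrelated background,
  300 proteins/class, lengths 40–70, motif length 8; model 48/48/[16]/[64,32];
  60-epoch budget, patience 12, batch 64; 2-fold CV with a 20% test split.
  One seeded replicate runs in ≈6 minutes on one CPU.
* Schedule study: 3 motif classes × 300, lengths 50–90; the full published
  schedule (150-epoch budget, early stopping armed at 50, patience 20);
  3-member ensemble reaches ≥0.90 held-out accuracy.

These problem sizes are the package's desk-scale choices; the 2-fold CV and
single-replicate defaults keep the validation suite and the reproduction
script inside one-CPU runtimes while leaving every qualitative comparison
(DOC+temperature ensemble vs. unscaled single softmax, ensemble vs. single
accuracy) intact.

## Cassette pipeline

Stage 1 passes a gene iff the ensemble certainty of the immune class is
≥ 0.3 — deliberately permissive, because stage 3's chaining requirement
suppresses isolated false positives. Stage 2 applies the three-way rule with
the α = 3 and α = 4 threshold sets (t(4) ≤ t(3) classwise, so CANDIDATE is
the band between the bars; candidates are evaluated only for proteins
already failing the α = 3 bar). Stage 3 chains KNOWN genes per system:
"distance ≤ 2 genes" counts intervening gene calls (ordinal gap − 1), which
is translation-invariant; an optional nucleotide-distance cap exists.
Chains with ≥ 2 KNOWN members (per-system overrides allowed via rules.yaml)
become cassettes; CANDIDATE genes inside a cassette's span are attached but
never counted toward the minimum; Shedu is annotated per-gene but excluded
from chaining; strand is recorded but ignored. Chaining is verified
exhaustively against a connected-component enumeration on all gene lists up
to length 8 over three systems.

Outputs: GFF3 (one `defense_cassette` feature per call, child `gene`
features per member; 1-based inclusive coordinates when available, ordinal
coordinates otherwise) and a per-gene TSV with status, subclass, system, and
both stage probabilities.

## Known limitations

* Desk-scale models leak some unrelated proteins through both stages (the
  worked example shows two adjacent background genes forming a false pair);
  the published full-scale setting trains on ~21k labeled proteins.
* The naive ORF fallback finds spurious reverse-strand ORFs on synthetic
  genomes; prodigal mode is preferred for real genomes.
* Vector/matrix scaling can destabilize accuracy (expected — the same
  pattern appears in the published benchmark tables); matrix scaling of
  small validation sets may overfit.
* The 12-descriptor set is a documented stand-in for the original
  supplementary list.
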