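# Methods

This note documents the models and procedures implemented in `tcrlatent`,
the choices made where the design was genuinely open, and what the bundled
synthetic data can and cannot establish.

## Physicochemical encoding

Each of the 20 standard amino acids is described by 7 physicochemical
descriptors, z-scored over the 20 residues (mean 0, sample s.d. 1 per
column), plus an eighth gap-indicator coordinate that is 1 for the gap
symbol `-` and 0 otherwise.  The gap vector is zero on all descriptor
coordinates, keeping padding orthogonal to chemistry.  A sequence of
length L becomes an `L_max x 8` array, padded at the end with gap vectors.

The bundled default descriptor set is the 7-parameter table of Meiler et
al. (2001) — steric parameter, polarizability, volume, hydrophobicity,
isoelectric point, helix and sheet propensity.  Nothing downstream depends
on this particular table: `build_feature_table` accepts any 20x7 numeric
table, and all metrics are defined through the z-scored space.

Decoded (real-valued) arrays are projected back to position weight
matrices with the inverse-L1 kernel `delta(f, f_a) = 1/(||f - f_a||_1 +
eps)`, `eps = 1e-6`, normalized per position over the 21 candidates (20
residues + gap).  An exactly matching residue receives `delta = 1e6` and
therefore essentially all probability mass, which is why encoding →
PWM → consensus round-trips losslessly.  Consensus ties break to the
alphabetically first residue, with the gap ordered last, so consensus
calling is deterministic.

## AIRR preparation

Records follow the AIRR rearrangement schema with 1-based inclusive
nucleotide coordinates.  QC retains records that are productive, in
frame, stop-codon-free, whose junction is 7–23 residues, starts with C,
ends with F and contains no X/*/U, and whose `v_call` resolves to exactly
one V gene (multiple alleles of one gene are allowed and collapsed to the
gene; all alleles are treated as *01).  CDR1/CDR2 come from a
user-supplied germline lookup table rather than on-the-fly IMGT
numbering; a toy germline ships with the simulator.

The insert region is the set of CDR3 codons (consecutive triplets from
`cdr3_start`) containing at least one nucleotide position p with
`v_sequence_end < p < j_start` — strictly inside the open interval, i.e.
not templated by either germline segment.  Feature strings join the
selected CDRs with `-` in the order CDR1–CDR2–CDR3; per chain they must
be shorter than 28 characters (CDR3 and CDR2+3 formats) or 35
(CDR1+2+3).  Splits are 80/10/10 after exact-duplicate removal, with
floor rounding for validation/test and the remainder to train, drawn by a
seeded shuffle.

## Synthetic repertoires

The generator emulates beta-chain V(D)J recombination: a sampled V gene
contributes CDR1/CDR2 and a conserved C-initial CDR3 tail, a J gene a
conserved F-terminal suffix, and between them a non-templated insert of
uniform-random residues whose length is binomially distributed between a
configurable minimum and maximum (default 0–10 residues, mean 4,
consistent with the few-residue non-templated regions of real beta
chains).  Insert nucleotides are sampled at the codon level from the
standard genetic code, so every record translates cleanly and passes QC
by construction; nucleotide coordinates are laid out so that the insert
extractor provably recovers the sampled insert.  D genes, allele-level
CDR variation, biased insert composition, and realistic gene-usage
frequencies are *not* modeled: passing tests on this data demonstrates
correctness of the machinery and qualitative model behavior, not
performance on real repertoires.

The labeled-cluster generator assigns each antigen a fixed V gene and a
CDR3 motif (pairwise Hamming separation >= 3 by default) and perturbs
members by at most a configurable number of substitutions — an idealized
picture of antigen-driven convergent recombination.  Spiked-in irrelevant
TCRs receive unique labels (`spike_<replicate>_<i>`), so they can never
form pure clusters and count against the purity of any cluster they
join.

## Capacity-controlled VAE

Encoder: three stride-1 1-D convolutions along the sequence axis
(channels 32/64/128, kernels 5/3/3, He initialization), each followed by
batch normalization and leaky ReLU (slope 0.2, configurable); the
flattened output feeds two parallel dense heads for the posterior mean
and log-variance (width `n_latent`, default 16).  Decoder: dense ReLU to
an `L_max x 128` array, three length-preserving transposed convolutions
(channels 128/64/32, kernels 3/3/5; at stride 1 with same padding a
transposed convolution is itself a convolution, which is how it is
implemented), each with batch norm + leaky ReLU, then an 8-channel
kernel-1 projection with no activation.  Padding is the length-preserving
choice — the only one consistent with a 28x128 pre-decoder array and a
28x8 output.

The loss is `L = L_recon + beta * |L_KL - n_latent * C|` with
`L_recon` the per-sample mean squared error (one posterior sample per
input per step) and `L_KL` the closed-form Gaussian KL divergence to the
standard normal, summed over latent dimensions and averaged over the
batch.  The capacity `C` (nats per latent dimension) is fixed during
training rather than annealed; `beta` defaults to 1, and to 10 when
`C = 1`, where a stronger weight is needed to actually reach the
capacity.  `beta = 0` is accepted as the plain-autoencoder limit used as
a continuity/disentanglement baseline: sampling and the KL penalty are
disabled and the code is the deterministic posterior mean.

Training uses Adam (lr 1e-3), shuffled mini-batches (default 512; the
scaled-down study runs below use 64, which at a fixed wall-clock budget
yields substantially more optimizer steps and therefore better
reconstruction), and early stopping on the validation loss with
configurable patience, restoring the weights of the best validation
epoch.  Validation decodes the deterministic posterior mean, which
removes sampling noise from the early-stopping signal; the capacity
penalty still fluctuates epoch to epoch, so the restored optimum tends
to sit where the realized KL is closest to the target `n_latent * C`.
The log-variance head bias is initialized at -3 (posterior s.d. ~0.22)
so that early decoder gradients are not swamped by sampling noise; the
capacity penalty re-balances the posterior scale within a few epochs.
Convergence is strongly step-count limited: the capacity penalty plus
per-step posterior sampling slows reconstruction learning by an order of
magnitude relative to the beta = 0 autoencoder, whose smooth validation
loss converges in a fraction of the epochs (which is why the bundled
studies give the autoencoder baseline a smaller epoch cap — it reaches
*better* reconstruction than the capacity model within it, so
continuity comparisons are not confounded by baseline undertraining).
Within the bundled studies' budgets the capacity model reconstructs
germline-templated regions near-perfectly while the quasi-random insert
region remains the hard residual; see the limitations below.

The networks run on an in-repo numpy reverse-mode autodiff stack
(`tcrlatent.nn`) with im2col convolutions, fused batch-norm backward and
Adam; gradient correctness is pinned against central finite differences
in the test suite.

Reconstruction accuracy is reported as the fraction of matching positions
between the input feature string and the consensus of the decoded PWM,
over the true (unpadded) string length — gap padding positions are
excluded so the number is not inflated by trivially predictable padding.

## Continuity metrics

Two TCRs with identical CDR3 and different (equal-length) CDR2 are
embedded; the straight line between the posterior means is decoded at N
points (`z_i = i/(N-1) z1 + (N-1-i)/(N-1) z2`, so the printed convention
places the *second* TCR at i = 0).  The decoded arrays are split into
CDR2/CDR3 regions by the fixed feature-string layout of the endpoints (no
re-alignment; both endpoints share the layout by construction).  The
distance d between arrays is the sum over positions of per-position L1
feature distances.

Per point, `D_i,cdr2` is the distance of the decoded CDR2 region to the
*nearest* germline CDR2 of matching length (proximity to the data
manifold) and `D_i,cdr3` the distance to the encoding of the true shared
CDR3.  Trajectory summaries: `mean_d_cdr2` is the plain average; the CDR3
metric is normalized by the endpoint reconstruction errors,
`(1/N) * 2/(D_0 + D_{N-1}) * sum_i D_i`, so models with different
reconstruction accuracy are comparable (a constant-error trajectory
scores exactly 1; error confined to the endpoints scores 2/N).  The
denominator uses the two trajectory endpoints; the summation index does
not enter it.

The Monte Carlo protocol samples 31 distinct test-set CDR3s and, for
each, 10 random pairs of length-6 germline CDR2s — 310 traversals of
N = 100 points by default; all counts are parameters.

## Disentanglement

Random-forest predictors map latent coordinates to the three generative
factors: V gene and J gene (classifiers, scored by weighted one-vs-rest
AUROC under stratified 5-fold CV) and mean insert physicochemistry (the
7-descriptor average over insert residues; a multi-output regressor
scored by R², with empty-insert records excluded).  The forest
hyperparameters (trees {100}, depth {None, 8, 16}) are selected by CV and
the forest is refit on the full sample (capped at 100k records).
Impurity-based feature importances form the `n_latent x 3` matrix R.

The score normalizes each latent dimension's row to a probability vector,
takes one minus its entropy (log base = number of factors), and averages
with weights proportional to row mass.  It is 1 when every informative
dimension loads on exactly one factor, 0 when all rows are uniform, and
invariant to global rescaling of R.  Dimensions with zero total
importance contribute nothing.  The completeness/informativeness
components of the full Eastwood–Williams framework are deliberately out
of scope; a single disentangling score is reported.

## Clustering evaluation

DBSCAN (Euclidean, `min_samples = 2`) clusters any embedding table over a
radius grid; size filtering (default: clusters of >= 3) is applied post
hoc rather than through the density core size, matching the post-hoc
cluster-size analysis convention.  A retained cluster is pure iff its
modal antigen label covers strictly more than 90% of members.  Members of
pure clusters count as c-TP, of retained impure clusters as c-FP, and
everything else — noise and members of size-filtered clusters — as c-FN,
which conserves c-TP + c-FP + c-FN = n (the CSI denominator is all TCRs,
so filtered clusters cannot simply vanish).  c-Precision is defined as 0
when nothing is clustered.  The multi-assignment correction for tools
that place a TCR in several clusters keeps only the largest cluster per
TCR (ties to the lowest cluster id) and unclusters the members of
clusters thereby reduced to singletons.

Spike-in robustness follows folds 0–5x with 10 replicates per fold;
each replicate is embedded, swept over eps, and summarized at the eps
maximizing c-CSI.

## Uncertainty-aware classification

The classifier is dropout(25%) → dense(128, ReLU) → dropout(40%) →
dense(128, ReLU) → dropout(40%) → dense(softmax).  The "25%/40%
retention" figures are read as *drop rates* by default (keep 0.75/0.60),
matching the Keras `Dropout(p)` convention in which p is the fraction
dropped; the literal keep-probability reading
(`retention_is_keep_prob=True`) is also implemented, but dropping 75% of
a 16-dimensional input prevents the classifier from learning the ID
classes at small scale — the cross-entropy never falls, the uniformity
term dominates, and predictions collapse to uniform — so the drop-rate
reading is the default.  Batches
pair 32 labeled with 512 unlabeled examples; the loss adds to the
class-weighted cross-entropy an `alpha`-weighted KL divergence *from the
uniform distribution to the prediction* on unlabeled samples (the
standard form of the uniformity auxiliary; it vanishes exactly at the
uniform output).  Class weights are `n_total/(n_classes * n_c)`.
Evaluation uses 10 Monte Carlo stratified 75/12.5/12.5 splits with early
stopping (patience 5) on a validation loss that includes the auxiliary
term on a fixed unlabeled batch.

Confidence is `N max(P)/(N-1)` exactly as defined, although it exceeds 1
at `max(P) = 1`; every use here is rank-based (ROC), which the affine map
does not affect.  OOD AUROC treats ID as positive with ties at 0.5.
Model comparisons over the Monte Carlo splits use the two-sided
Mann–Whitney U test — exact for small tie-free samples, tie-corrected
normal approximation otherwise — with common-language effect size
`U/(n1 n2)` (hence `U/100` for 10-vs-10 comparisons).

## Problem sizes in the bundled studies

The test suite and the acceptance script run everything end to end on
synthetic repertoires: VAE studies train on ~5,000 unique CDR2+3 feature
strings (16 latent dimensions, C = 2), continuity comparisons use >= 30
traversals against a beta = 0 autoencoder of identical architecture, the
spike-in study uses folds 0–5 x 10 replicates over a fixed labeled
fixture, and the OOD study uses 8 Gaussian-separated ID classes with a
shifted OOD component over 5 seeds.  These sizes are the package's own
scaled-down study design; the pipelines accept arbitrarily larger inputs.

## Known limitations

- The synthetic insert is uniform over residues; real inserts are biased
  and shorter-tailed, so absolute reconstruction numbers on real data
  will differ.  Uniform inserts are also the hardest-to-compress
  composition: at the bundled study scale (~5k sequences, minutes of
  single-CPU training) the capacity-2 model reconstructs germline
  regions at ~98–99% but insert residues far less well, leaving overall
  held-out consensus accuracy in the low-to-mid 80s (%); closing the
  remainder is a matter of training steps, not model capacity (the
  32-nat budget comfortably exceeds the ~8.5 nats needed to index the
  training set).
- Germline CDR lookup requires the user's table for real data; no IMGT
  numbering is performed.
- The autodiff stack is CPU-only and single-threaded BLAS-bound; it is
  sized for the bundled studies, not for multi-million-sequence corpora.
- The c-FN attribution of size-filtered cluster members is a convention
  choice (documented above); alternative conventions change c-CSI by at
  most the mass of such clusters.
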