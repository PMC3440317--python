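# Methods

## Model

`tripitope` predicts linear B-cell epitopes at the level of fixed-length
peptide windows (L ∈ {10, 12, 14, 16, 18, 20}, default 20). Every peptide is
mapped to the 8000-dimensional tri-peptide attribute space; a binary
RBF-kernel SVM trained on balanced epitope/non-epitope peptides supplies a
real-valued decision score, and a window with positive score is called a
putative epitope. The method assumes (i) that linear epitopes can be
represented by fixed-length windows around their experimentally annotated
span, and (ii) that the discriminative signal lives in tri-peptide-level
sequence statistics rather than structure.

### Encoding

For attribute *i* with representative tri-peptide Φ(i), the similarity
component is

    T(i) = Σⱼ [ s(Φ(i)₁, Ωⱼ₁) + s(Φ(i)₂, Ωⱼ₂) + s(Φ(i)₃, Ωⱼ₃) ],

the sum over all windows Ωⱼ of the peptide of three position-wise
substitution-matrix scores. Windows are contiguous tri-peptides (pattern
`AAA`) or gapped projections of 4-residue windows (`A_AA`, `AA_A`), so the
attribute space is 20³ in every case. Matrices: the published BLOSUM62 and
PAM160 integer tables, bundled as NCBI-format text and restricted to the 20
canonical residues. Attribute order is lexicographic over
`ACDEFGHIKLMNPQRSTVWY` for determinism; all operations are covariant under a
permutation of that order (property-tested).

The propensity of attribute *i* is

    P(i) = (f(i) + ε) / (F(i) + ε),

where f is the tri-peptide frequency over all windows of the positive
(epitope) peptides, F the frequency over a large background protein pool
(both normalised to sum to 1), and ε a pseudocount defaulting to 1/(total
windows counted). The ratio is the standard propensity-scale construction;
the smoothing keeps P finite and positive for tri-peptides absent from the
background, and P ≡ 1 when f ≡ F. Tables serialise to TSV with 17
significant digits, which round-trips float64 bit-exactly.

Encoding modes:

* `combined` (default): K(i) = T(i) · P(i), elementwise. "Similarity
  modulated by propensity" is read as a product — the minimal combination
  consistent with a with/without-propensity ablation; it is a configuration
  option, not hard-wired.
* `similarity_only`: K(i) = T(i).
* `propensity_only`: K(i) = (occurrence count of tri-peptide i among the
  peptide's windows) · P(i) — the minimal encoding that uses propensity but
  no substitution matrix.

Non-standard residues (B, Z, X, U, `*`) are rejected with the offending
position named: the 20³ space has no slot for ambiguity codes, and silent
coercion would corrupt propensity estimates. Dataset construction and the
sliding-window predictor skip (and log) affected records/windows; the
encoder itself raises.

**A structural property worth knowing.** Because each term of T scores only
same-position residue pairs, T factorises: T = A · c where c is the 3×20
table of window-position residue counts and A a fixed linear map. Every
T-based encoding (combined included) is therefore a deterministic function
of the peptide's position-marginal composition — it cannot distinguish two
peptides with identical residue counts, and multiplying by P(i) re-weights
coordinates without adding information. Consequences: (1) the SVM learns a
(kernelised) composition classifier; (2) the combined-vs-similarity-only
contrast is a feature-conditioning effect, not an information gain — it is
measurably positive in weak-signal, capacity-limited regimes (≈ +0.015 AUC
at n = 500/class, C ≤ 0.5) and noise-level (|Δ| < 0.001, unstable sign) at
benchmark scale with C = 32. The per-position reading of the kernel is taken
literally and enforced against a brute-force oracle; a per-window
multiplicative or match-based similarity would carry joint occurrence
information, but is a different kernel. Only `propensity_only` mode sees
actual tri-peptide occurrences.

### SVM

`sklearn.svm.SVC` with an RBF kernel; hyper-parameters (c, g, p) with
defaults c = 32, g = 0.05, p = 0.5 and a standard grid c = 2⁻¹⁰..2⁻¹,
g = 2⁻¹²..2⁻³, p = 2⁻⁵..2⁻² (powers of two, optionally extended with the
default optimum). `p` is an epsilon-style parameter of some SVM packages; it
is recorded for configuration fidelity but not consumed by the
classification backend, whose decision values provide the real-valued scores
the method thresholds. Encoded vectors are **L2-normalised** before the
kernel: raw kernel sums grow with window count and peptide composition, and
unit-norm scaling (the usual convention for string/spectrum kernels) puts
squared distances in [0, 4], where the stated gamma range is meaningful.
Cross-validation precomputes fold kernels from one squared-distance matrix,
so grid points differing only in (c, g) reuse it.

## Datasets

* **Annotation ingestion** — epitopes arrive as a TSV
  (`epitope_id, antigen_id, epitope_seq, start, end, is_tcell_related`,
  1-based inclusive coordinates) validated against an antigen FASTA. Spans
  are checked or, when absent, located by exact unique substring search;
  T-cell-flagged, unresolvable, ambiguous or non-standard records are
  rejected and logged; identical epitope sequences collapse to one.
  Coordinates are 0-based half-open internally and 1-based inclusive in
  human-readable output.
* **Length normalisation** — epitopes longer than L are trimmed
  symmetrically about their centre, shorter ones extended symmetrically into
  the antigen; odd leftovers resolve toward the N-terminus; the window
  slides inward at antigen ends and the record is dropped if the antigen is
  shorter than L.
* **Redundancy reduction** — single-linkage clustering of pairs with
  identity ≥ 30%, one representative (first in deterministic id order) per
  cluster. Identity is the exact-match fraction of an ungapped global
  comparison of the equal-length peptides (identical positions / L) — an
  alignment-free stand-in for a BLAST-style similarity; transitive chaining
  can link pairs below the ceiling (single-linkage caveat).
* **Negatives** — equal in number to the positives, drawn uniformly
  (seeded) from length-L windows with zero overlap with any annotated
  epitope span of the source antigen; duplicates and windows with
  non-standard residues excluded.
* **Folds** — single-linkage clusters at identity > 20% stay within one
  fold; clusters are dealt largest-first to the currently smallest fold, and
  a verification pass asserts the cross-fold ceiling. A cluster holding more
  than half the data triggers an imbalance warning.

**Limitation of the identity stand-in.** For 20-mers the chance identity
between unrelated peptides has mean ≈ 6% and heavy enough a tail that
P(pair ≥ 30%) ≈ 10⁻³ and P(pair > 20%) ≈ 6×10⁻³ under realistic
compositions. Single-linkage clustering therefore percolates once a few
thousand peptides are pooled: the 30% reduction caps the retained set and
the 20% fold rule produces one giant cluster — an artefact of exact-position
identity, which links chance matches that an alignment-significance measure
would ignore. The identity-threshold operations are used (and tested) at
corpus scale where they behave; the large synthetic benchmark instead
deduplicates exactly and groups folds **by source antigen**, which removes
the leak channel that matters for window peptides (overlapping windows of
one protein) by provenance rather than by threshold.

## Training and evaluation protocol

Five-fold cross-validation over the similarity-aware folds. Inside every
round the propensity table is recomputed from the training folds' positives
only (the background pool is a fixed external sample); a
`leak_free_propensity=False` flag reproduces the global-table variant for
comparison. Grid search evaluates every (c, g, p) triplet by the mean max-F
over test folds and returns the argmax.

ROC curves are built by a threshold sweep over unique scores (ties
grouped); AUC is the trapezoidal area, which equals the Mann–Whitney
statistic (property-tested against exhaustive pair counting). Sensitivity
and precision are reported at the threshold maximising F = 2·Sn·P/(Sn+P) on
the test scores — note this operating point is chosen on the test
distribution, an optimistic reporting convention adopted deliberately.
Confidence intervals are mean ± t₀.₉₇₅,ₖ₋₁ · sd/√k over the k folds. ROC
differences between two methods scored on the same instances use the paired
DeLong test (two-sided normal p-value from the structural-components
variance estimate; a degenerate variance yields p = 1 for a zero difference
and NaN otherwise, never a fake zero). The implementation is verified
against an independent reference implementation on a frozen example.

Attribute weights are read out as w = Σᵢ αᵢxᵢ over the support vectors
(dual coefficients times encoded vectors) — a linear proxy under the RBF
kernel, used for ranking attributes, not as an exact primal weight. The
tendency screen scores two disjoint equal-length pools together, ranks by
score with ties broken by stable input order (documented because top-N
compositions depend on it), and reports per-N pool composition.

## Synthetic data generator

The generator emulates the pipeline's real-world inputs: antigens carrying
annotated linear epitopes, plus background protein pools. Antigens and
background proteins are i.i.d. residues from a fixed composition (default:
the average composition of known proteins). Planted epitopes are drawn from
a tri-peptide-tilted distribution by window-level rejection: a candidate
residue extending the last two residues (a, b) is accepted with probability
mult(abc)/max-mult, so the realised next-residue law is ∝ composition(c) ·
mult(abc). This keeps planted segments sequence-like (no motif
concatenation) at the cost of bounding achievable enrichment — the realised
frequency ratio for a multiplier-10 motif is ≈ 7–8.

Defaults are fixed study conditions: 300 antigens of 150–400 residues, 2
epitopes per antigen of 12–30 residues, background pool of 200 proteins, and
a planted family of **all tri-peptides containing glutamine or proline**
(2168 motifs, ≈ 24% of background window mass) at multiplier 10. The family
mirrors the domain observation that epitope-propensity scales are dominated
by Q/P-built tri-peptides, and it is broad enough that a planted epitope
carries several enriched windows — necessary because the encoding is
composition-limited (above); a handful of rare motifs at multiplier 10
shifts composition by ~0.04 windows per peptide and is unrecoverable by any
classifier on these features.

The standard benchmark (`benchmark_dataset`) oversamples a corpus, exactly
deduplicates, truncates to n-per-class positives in deterministic id order,
draws matched negatives from the same antigens, and assigns antigen-grouped
folds. At n = 2000 per class the combined encoding reaches five-fold CV AUC
≈ 0.95 and the planted family fills 100% of the top decile of attribute
weights; with permuted labels the CV AUC sits at 0.49–0.52.

What the generator does **not** emulate: real protein composition structure
(domains, repeats, disorder), antibody binding physics, epitope length and
positional biases of curated databases, and homology families (each antigen
is independent). Passing tests therefore demonstrate pipeline correctness
and recoverability of a planted composition-level signal — not expected
performance on curated epitope data.

## Numerical choices and problem sizes

* Seeds: every stochastic step (generator, negative sampling, fold dealing,
  label permutation) takes an explicit integer seed; identical inputs and
  seeds give byte-identical output files and model archives.
* Ties: ranking and fold-dealing tie-breaks are stable/deterministic;
  redundancy representatives are first-by-input-order.
* Degenerate inputs: single-class training data, empty peptide collections,
  empty grids, exhausted negative pools and oversized top-N requests raise
  with explicit messages rather than degrading silently.
* Test problem sizes: unit tests run at a few hundred peptides; the
  heavyweight validations use the 2000-per-class benchmark (three seeds),
  a 1000-per-class permuted-label null, and a 300-antigen end-to-end
  pipeline run — together a few minutes on one CPU.

## Known limitations

* The literal per-position similarity kernel is composition-limited (see
  above); the combined/similarity-only ablation is accordingly a small
  conditioning effect at benchmark scale rather than the large contrast a
  per-window multiplicative kernel would show.
* Exact-position identity percolates at scale; alignment-based redundancy
  measures can be plugged in where that matters.
* The max-F operating point is selected on test scores (optimistic).
* `propensity_only` mode is a minimal construction for ablation, not a
  tuned baseline.
* Discontinuous (conformational) epitopes, k ≠ 3 kernels and structural
  features are out of scope.
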