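# Methods

## Signatures

A genomic signature is the canonical k-mer frequency vector of one 500 kbp
representative fragment per assembly, 1 ≤ k ≤ 6.

**Fragment selection.** Contigs are sorted by length, longest first, with a
stable sort so equal-length ties preserve input order. If the longest
contig holds at least `target_len` non-N bases, a window is cut at a
uniformly random offset drawn from a seeded generator (the seed is recorded
in the fragment's provenance). The offset and span are taken in *non-N
coordinates*: the window covers exactly `target_len` informative bases even
when the source contig contains N runs, which is the only way the
effective-length contract can hold on gapped contigs. Otherwise, sorted
contigs are concatenated with a single `N` separator between pieces —
preventing spurious k-mers across joins — and the last contig is truncated
to its prefix so the non-N length is exactly `target_len`. Inserted Ns
never count toward the effective length. Lowercase input is uppercased;
IUPAC ambiguity codes other than N are mapped to N with a logged warning.

**Counting.** A sliding window of width k and step 1; windows containing N
contribute nothing. Counts are accumulated over the fragment and its
reverse complement and then collapsed onto canonical k-mers (the
alphabetically smaller member of each reverse-complement pair; palindromes,
which exist only for even k, appear once). Count totals therefore equal
twice the number of valid windows; frequencies are counts normalized to sum
to one. There are 4^k/2 canonical k-mers for odd k and (4^k + 4^(k/2))/2
for even k. A sequence with no valid window yields an all-zero, flagged
signature. At k = 1 the C-bucket frequency equals the G+C fraction of the
non-N positions.

**fCGR.** Corner convention A bottom-left, C top-left, G top-right, T
bottom-right; the pixel of a k-mer is built by successive corner-halving
from its first character outward. Values indexed by canonical k-mers are
written at both paired pixels; values indexed by all 4^k k-mers are written
one per pixel (in that mode a grid filled from the per-k-mer symmetrized
count vector sums to twice the window count). The grid is invariant under
the pixel involution induced by reverse complementation. Plotting is a
thin optional layer; the palette is not part of the contract.

## Labels and folds

Temperature categories from optimal growth temperature use half-open-left
boundaries: psychrophile < 20 °C, mesophile [20, 45), thermophile [45, 80],
hyperthermophile > 80 °C (the literature's "45–80" range overlaps both
neighbours, so the boundary policy is declared rather than inferred). pH:
acidophile < 5, alkaliphile > 9. For challenge experiments, thermophile and
hyperthermophile merge into one "high-temperature" category, applied
symmetrically to training and evaluation.

Random pseudo-labels are i.i.d. uniform over c classes by default (the
control scenario); an empirical mode draws from the dataset's
environment-category proportions instead.

Standard folds use stratified shuffled 10-fold CV. Genus-restricted folds
keep all samples of a genus in one fold while approximating global label
proportions: genera are processed in decreasing size order, each assigned
to the fold minimizing a squared divergence of fold label proportions from
the global proportions plus a penalty for overshooting the target fold size
(weights 1 and 4; both exposed as knobs since their balance is a genuinely
open choice); empty folds are seeded first, and a local-refinement pass
then moves single genera between folds while the global objective
improves. On symmetric instances this attains the balanced optimum; on
random instances its stratification is at least as good as a random
genus-to-fold assignment essentially always.

## Classifiers

Backends: `svm_rbf` (features z-scored on the training folds only — RBF
kernels are scale-sensitive), `random_forest_gini` (scale-free, no
standardization), `distance_based` (1-nearest-neighbour over a
user-supplied pairwise distance; default (1 − Pearson r)/2, the contract
through which signal-processing-style pipelines plug in), and `ann`
(512- and 64-unit ReLU hidden layers with dropout 0.5; requires torch,
which is an optional extra — the core package carries no deep-learning
dependency and all shipped analyses use the other backends). Features are
frequencies, not counts. Hyperparameters not fixed by the method (SVM
C = 1, gamma = "scale"; forest size 100; ANN schedule) are frozen, seeded
defaults recorded in `DEFAULT_HYPERPARAMETERS`: the claims of interest are
qualitative accuracy orderings, so reproducibility is preferred over
tuning. CV accuracy is the mean of per-fold accuracies, in percent.

## Relevance

One-vs-all binary relabelling per environment category; a Random Forest is
trained per stratified fold and MDI importances are averaged over folds
into a descending ranking (MDI is preferred over permutation importance
because k-mer features are strongly correlated). The minimal relevant
subset is the shortest ranking prefix whose CV accuracy, on the *same* fold
plan and seed as the full-feature run (isolating the feature-subset
effect), is within a tolerance of the full-feature accuracy. Default
tolerance 0.5 percentage points: CV accuracy is stochastic, so exact
equality is ill-posed; the value is declared, not inferred. The search
doubles the prefix length, then bisects; prefix-accuracy monotonicity is
not assumed — a linear-scan reference implementation exists and the two are
checked for agreement on small instances. If classification is no better
than the majority baseline the size-1 result carries a `degenerate` flag.
Deviation profiles are category mean frequency minus dataset mean, in
percentage points; their size-weighted sum is identically zero per k-mer.

## Clustering evaluation

ACC maps cluster labels to true labels optimally: injectively via
rectangular assignment when #clusters ≤ #classes, by cluster-majority class
otherwise (an injective map cannot meaningfully score many clusters against
two classes; the majority extension is standard). Both modes are exposed;
`mode="auto"` switches on the cluster/class count. Noise labels (−1) from
density-based backends never match and are excluded from quality clusters.

Completeness of a cluster = occurrences of its most common genus divided by
that genus's total count in the dataset. Contamination = the fraction of
the cluster *outside* its most common genus (1 − purity): the literal
"most-common-genus count over cluster size" reading would score a perfectly
pure cluster as 100 % contaminated, contradicting the "at most 50 %
contaminated" quality criterion, so the 1 − purity reading is used.
Qualifying clusters have completeness ≥ 0.5 and contamination ≤ 0.5
(thresholds are parameters); genus-recovery counts consider only genera
with more than two sequences.

Built-in parametric backends: k-means and Gaussian mixture (scikit-learn)
and a hand-written PAM-style k-medoids (farthest-point seeded init,
alternating assignment/medoid update) since no installed library provides
one; deep or density-based methods plug in through `register_backend`.

Consensus pairs: a cross-domain pair is a candidate when co-clustered
(same non-noise label) in at least a strict majority of the supplied
assignments — the threshold and the per-pair (rather than
connected-component) reading are declared defaults.

## Challenge experiments

For a candidate, the challenge training set contains every opposite-domain
sample plus same-domain samples of a different merged environment category;
the candidate is excluded and no training sample shares both its domain and
its environment. Experiment (i) trains on merged environment labels and
asks whether the candidate's category is still predicted correctly;
experiment (ii) trains on domain labels and asks whether the candidate is
"fooled" into the opposite domain. A candidate is confirmed when a strict
majority of backends passes (i) and a strict majority is fooled in (ii);
ties count as not confirmed (conservative). Each registered backend gets
one vote. Candidates carrying both a temperature and a pH label can be
challenged once per axis.

## Synthetic data

Genomes are sampled from an order-2 Markov chain (uniform base transitions)
— the smallest model in which 3-mer probabilities are directly
controllable; analyses at higher k inherit the signal through 3-mer
composition. Effects are multiplicative tilts on transition cells, always
applied jointly to a 3-mer and its reverse complement so planted signal
survives strand symmetrization:

| knob | meaning | default |
|------|---------|---------|
| `tau` | domain tilt on 4 canonical 3-mers per domain | 1.25 |
| `epsilon` | environment tilt on 3 canonical 3-mers per category | 1.07 |
| `genus_sigma` | per-genus log-normal field on all cells | 0.045 |
| `sample_sigma` | per-sample log-normal field on all cells | 0.03 |
| `genome_length` | sequence per genome (1–5 contigs, rare N runs) | 520 000 |

Planted sets are mutually disjoint, so the environmental effect is
orthogonal to taxonomy by construction; the genus and sample fields supply
within-taxon variation. Default plan: 2 domains x 15 genera x 4 samples
(120 genomes), environment categories assigned round-robin within each
genus (orthogonal to genus); `by_genus` assignment makes genus and
environment fully correlated for restriction-penalty studies, and
`samples_per_genus=20` gives the 600-genome scale used for pseudo-label
baselines. Optimal growth temperatures are drawn inside each category's
interval so the OGT-to-category mapping round-trips.

The tilt magnitudes were fixed by a single calibration run (seeds 0–4) so
that, at k = 6, taxonomy CV accuracy > environment CV accuracy > the 1/c
random baseline — the qualitative regime the analyses probe. The
planted-subset recovery analyses use a sparser, noisier configuration
(`epsilon=1.15, sample_sigma=0.10, kmers_per_category=2, genus_sigma=0.02`)
in which one-vs-all accuracy sits near 80–90 % and no single planted k-mer
suffices, so the minimal subset genuinely needs the planted set.

Convergent organisms keep their true metadata (own domain, high-temperature
category) but their *composition* copies the opposite domain's
high-temperature tilt while their own domain tilt and genus field are
attenuated (factor 0.15) — modelling an organism whose environmental
component overrides its taxonomic one, as the challenge experiments demand.

Desk-scale genome length (520 kbp in 1–5 contigs, exercising both
fragment-selection branches) is the default; it is a modelling choice that
keeps whole-pipeline studies fast while leaving every contract identical to
full-length genomes, which remain available by raising `genome_length`.

**What the generator does not emulate:** gene structure, codon usage, GC
skew, repeats, horizontal transfer, or realistic genome sizes and
assembly-quality artifacts. Passing tests therefore demonstrate
correctness of the pipeline and recoverability of planted compositional
effects — not that real extremophile genomes carry such effects, nor the
specific accuracies attainable on real data.

## Numerical notes and limitations

- All randomness flows from named, spawned generator streams; datasets and
  fold plans are byte-reproducible from (config, seed).
- Chain sampling is JIT-compiled (numba); k-mer counting is vectorized
  (stride tricks + bincount). A 600-genome study builds in under a minute.
- Degenerate inputs: all-N fragments yield flagged zero signatures;
  single-class training folds log a warning; fewer genera than folds
  reduces the fold count with a warning; empty challenge training classes
  raise.
- ACC with all-noise assignments is 0; the [1/n, 1] range assumes at least
  one non-noise cluster.
- Hungarian ACC brute-force checks are exhaustive only up to 6x6
  cluster/class contingencies; beyond that the assignment solver is trusted.
- Accuracies reported in the literature for curated NCBI extremophile
  datasets are not reproducible at desk scale: they depend on hundreds of
  real assemblies, unrecorded random fragment offsets, and unreported
  hyperparameters. This package reproduces the *procedure* and its
  qualitative behaviour on ground-truthed synthetic data.
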