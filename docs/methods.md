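# Methods

This note records the models and procedures `herbscreen` implements, the
defaults and why, what the synthetic generator does and does not emulate,
and the numerical choices made where the design was open.

## Compound-level model

### Kennard–Stone splitting

The train/test split is deterministic and space-filling: within each
activity class, features are standardized (zero mean, unit variance per
column), the two mutually most distant points (Euclidean) seed the training
set, and points are added by the max–min criterion until the per-class
train fraction (default 0.8, i.e. 4:1) is reached. Standardization is
applied because raw 2D descriptors span wildly different scales and
unstandardized Euclidean distance would be dominated by a few columns.
Stratification keeps both classes at the target ratio (within one
compound). Ties — identical points or equal max–min distances — are broken
by lowest input index, which makes the split reproducible and
permutation-stable whenever all pairwise distances are distinct.

### Descriptors and feature selection

Descriptor computation is a provider contract: any callable mapping a
parsed molecule to a fixed-length named numeric vector. The shipped
default is the full RDKit 2D descriptor set (~210 physicochemical,
electrotopological and fragment-count descriptors); a 2-descriptor toy
provider supports tests. Sporadic descriptor failures are median-imputed
(logged per feature); compounds failing entirely join the rejects list.

Relevance selection is a shadow-feature scheme: each round appends a
permuted copy of every column, fits a random forest (500 trees by default;
`max_features=None` so every split sees every candidate, which stops
chance-correlated noise columns from accumulating importance the planted
features would otherwise share), and scores a hit for every real feature
whose importance exceeds the best shadow importance. A two-sided binomial
test on the hit count (p = 0.5) decides: features winning significantly
more often than chance are confirmed — with a Bonferroni correction across
features, since one lucky noise column among hundreds would otherwise be
confirmed — and features losing significantly are rejected at the raw
alpha. Features still tentative at `max_iter` (default 100) are resolved by
comparing their median importance to the median best-shadow importance.
The selector is deliberately conservative: on a weak, highly correlated
descriptor signal it may confirm very few features, which is the honest
answer for such data.

Correlation pruning then enforces pairwise |Pearson r| ≤ 0.90 among kept
features, dropping the lower-importance member of each offending pair
(ties by name). Zero-variance features, for which r is undefined, are
dropped first. Every feature ends in exactly one provenance class:
`kept-by-relevance`, `dropped-shadow`, `dropped-zero-variance` or
`dropped-correlated-with X`.

### Learners and evaluation

Seven base learners and a voting meta-learner. The classic WEKA algorithms
are replaced by functional analogues, not clones: a Gaussian naive Bayes;
a CART decision tree whose `confidence` knob maps a pruning-confidence
value onto cost-complexity pruning (lower confidence → heavier pruning);
plain k-NN; a distance-weighted k-NN with an exponential kernel
`exp(-d / mean neighbour distance)` as an entropy-motivated nearest-
neighbour analogue (K-star proper defines an instance-transformation
entropy; the exponential kernel reproduces its qualitative behaviour —
smooth, distance-decaying vote weights over a wide neighbourhood);
a random forest; bagged k-NN; and AdaBoost over depth-3 trees.
Distance-based learners are wrapped with feature standardization.

The voting model averages the base models' active-class probabilities with
equal weights and predicts active at score ≥ 0.5 (boundary counted as
active). Cross-validation is stratified k-fold (default 5) with one
confusion matrix pooled over out-of-fold predictions — not per-fold metric
averaging — and AUC computed as the Mann–Whitney pair statistic on pooled
out-of-fold scores (ties count one half). Class imbalance is reported
through SE/SP rather than corrected by reweighting. Grid parameter search
maximizes pooled CV accuracy, breaking ties toward simpler models (fewer
neighbours, then shallower/smaller ensembles, then grid order).

## Structural-alert mining

Fragments are generated from the active molecules by recursively cutting
acyclic single bonds (rings stay intact — standard practice for alert
mining, since opening rings produces chemically meaningless valence
patterns), deduplicated by canonical SMILES, and bounded to 2–18 heavy
atoms by default to keep enumeration desk-scale. A compound contributes at
most one count to tp or fp regardless of match multiplicity.

Rules failing LR ≥ `min_lr` (default 10) or tp ≥ `min_freq` (default 10)
are discarded. Infinite-LR rules (fp = 0) rank above all finite ones and
among themselves by descending tp; finite rules by descending LR, then tp,
then fewer atoms, then canonical-form order. Two extraction modes:
`score_all` (default) keeps every passing rule except those whose
matched-active set is a subset of an already-accepted rule's (redundancy
filter); `iterative_cover` repeatedly accepts the best rule and removes
the actives it covers, in the set-cover style of classic alert extractors.

## Herb-level statistics

### Property encoding and contrast

The 24-term vocabulary (5 natures, 7 flavors, 12 channels) is fixed in
order; a herb's property vector sets bit i iff term i is present. Herbs
without any channel term are retained but flagged not clusterable.

The chi-squared contrast has two modes. The omnibus mode tests homogeneity
of the 2 × 24 per-term possession-count table. Because a herb possesses
several terms, the columns are not mutually exclusive and the table is not
a true multinomial contingency table; empirically the test is conservative
under the null (p-values lean toward 1, never pile up near 0), so a small
omnibus p is trustworthy evidence of profile difference while the exact
null distribution is not chi-squared. The per-feature mode runs 24
individual 2 × 2 tests with Benjamini–Hochberg adjusted p-values reported
alongside the raw ones. Continuity correction is off by default (flag
available); low expected cells attach a warning rather than failing.

### Association rules

Apriori with the consequent fixed to hepatoprotection: antecedent itemsets
over the 24 property terms are expanded level-wise, pruning any itemset
whose joint support P(antecedent ∧ hepatoprotective) falls below
`min_support` (anti-monotone, so pruning is exact). Rules must pass
support ≥ 5 %, confidence ≥ 65 % and lift > 1 by default, with antecedents
of at most 3 items (the deepest regime of interest); output is sorted by
confidence then support, both descending. The identities
support ≤ confidence and lift · prior = confidence hold exactly.

### Cluster-branch classification

Candidates are clustered jointly with the labeled references on Euclidean
distance over the 24-bit vectors; the tree is cut into `k_cut` branches
(default 2). Ward linkage is the default because on binary vectors it
produces compact, balanced branches and is stable under input order; both
linkage and `k_cut` are configurable. A candidate's verdict is
hepatoprotective-like iff the fraction of hepatoprotective references in
its branch strictly exceeds the global reference prior — this generalizes
"same branch as the hepatoprotective herbs" to mixed branches. A branch
containing no references yields a non-hepatoprotective-like verdict, since
enrichment cannot be established. Candidates are clustered jointly with
the references (not projected onto a fixed reference tree); with
well-separated populations the two coincide.

## Network screen

Edges are restricted to known-active ingredients; herbs already labeled
hepatoprotective form one network and all others the "undetermined"
network. A herb's candidate degree is its number of distinct active
ingredients. The degree threshold is inclusive (≥ 15 by default): the
reference regime lists herbs at exactly the threshold as candidates, so
the boundary belongs inside. The final screen intersects the degree filter
with the cluster verdict; matched association rules are reported as
supporting evidence only and never gate the decision, and herbs lacking
channel information are reported unassessable rather than dropped. Reports
are rendered deterministically (byte-identical for identical inputs) with
every threshold in a provenance header.

## Synthetic data: what it emulates and what it does not

The generator's defaults state the world the pipeline is tested in:
~700 active / 200 inactive compounds with one planted nitroaromatic alert
(penetrance 2/7, zero leak); ~250 reference herbs at a ~0.48
hepatoprotective prior carrying a planted sour → hepatoprotection rule at
confidence 0.714; 25 undetermined candidates, 12 with the
hepatoprotective-like property profile, all enriched to ≥ 15 active
ingredients against a sparse (1 %) background.

Compounds are assembled from a small SMILES grammar (rings, chains, common
substituents chained by concatenation with per-piece ring-closure digits),
with motifs appended at the stated penetrance/leak; every emitted SMILES
is verified to parse. Herb statuses follow the planted rules — a herb
matching a planted antecedent is hepatoprotective with that rule's
confidence (most specific antecedent wins), otherwise with the base rate —
so empirical confidences converge to their targets by the law of large
numbers. Separately, status-linked profile bits *outside* every planted
antecedent (sweet/warm/liver/kidney for the hepatoprotective side;
cold/bitter/pungent/large-intestine/spleen for the other) are force-set
with probability `profile_shift` (default 0.85), giving the cluster model
a recoverable two-population geometry without disturbing the planted
confidences. All sampling flows from the spec seed; identical seeds give
byte-identical outputs.

Limitations: the generated molecules are chemically valid but
pharmacologically meaningless, and the strong profile shift makes
property–status associations far denser than in real herb data (many
near-saturated rules), so a green cluster-recovery test establishes that
the machinery recovers planted structure, not that real herbs separate
this cleanly. Scales in tests are reduced (hundreds of compounds, not
~900; forests of 100–200 trees, not 500) to keep the suite fast; the
statistical structure is unchanged.

## Numerical choices and degenerate inputs

* LR with fp = 0 is +∞ and sorts above all finite LRs; a fragment matching
  nothing gets an undefined (NaN) LR and is never emitted.
* Report percentages are rounded to 2 dp for display; internal arithmetic
  is unrounded.
* The voting threshold is fixed at 0.5, boundary inclusive toward active.
* Unparseable structures, unknown labels and unknown property terms are
  collected (compound rejects) or raised with the offending term and row
  (herb tables) — never silently dropped.
* Duplicate edge pairs collapse; edges whose ingredient is not in the
  active registry are dropped with a logged count.
* Seeds derived from a user seed stay below 2^31.
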