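# Methods

This note documents the statistical model, the procedure, the tunable
parameters, the synthetic study conditions, and the design choices made
where the design was genuinely open.

## Model

A relational table **R** holds N entities by M mixed-mode attributes. After
discretization every cell is a categorical event; an *attribute value* (AV)
is one (attribute, value) pair with marginal count `n` and an EID set (the
entities carrying it). The null model throughout is mutual independence of
attributes. The deviation of an AV set {a₁…a_k} from that null is the
adjusted standardized residual

    d = (o − e) / √e / √(Π_i (1 − n_i/N)),    e = N · Π_i (n_i/N),

where `o` is the size of the set's EID intersection. `d` is asymptotically
standard normal under independence, so the default threshold 1.96 is a
two-sided 95% bound. Two properties matter for the method's claims:
`d` grows with coherence relative to the *expected* count, so small,
coherent groups reach large residuals (rare-class sensitivity without
resampling); and the normalization makes residuals comparable across AV
pairs with very different marginals, which is what allows a single global
threshold.

No continuity correction is applied and expected counts below 1 are
permitted (logged, not rejected): at the table sizes this package targets
(tens to hundreds of entities) a small-expected-count guard would silence
exactly the rare patterns the method exists to find. The type-I cost of
that choice is measured, not assumed — on independent-attribute null tables
(N=1000) the observed fraction of |d| ≥ 1.96 entries stays near the nominal
5% (the acceptance suite bounds it at 10%).

## Disentanglement

The SR matrix S collects the pairwise residuals of all cross-attribute AV
pairs; same-attribute pairs are mutually exclusive events and are fixed at
0 (keeping S symmetric and eigendecomposable rather than injecting
arbitrary large negatives). S is eigendecomposed without centering — it is
already a deviation-from-independence representation, so its eigenvectors
separate *sources of association*, not directions of raw variance.

Each eigenpair (λ, v) defines a disentangled space whose re-projected
residual space (RSRV) is the rank-one matrix λ·v·vᵀ; the RSRVs sum back to
S exactly, so each space carries an additive share of every pairwise
association. Spaces are ranked by |λ| (ties, at float tolerance, prefer the
positive member of a ± pair, then the original position).

Three further rules make the decomposition usable as a source model:

- **Dominant-space AV ownership.** Each AV belongs to the positive-λ space
  maximizing its energy λ·v[i]², and contributes significant structure only
  there. Without this rule the leading eigenvector of a multi-source table
  lumps several sources on one side of the PC, every same-side rank-one
  entry is positive, and the sources fuse into one SubPG; with it, each
  source claims its AVs exactly once and AVs genuinely shared by two
  sources resolve to the space explaining them best.
- **Negative eigenvalues own nothing.** A symmetric matrix with zero
  diagonal blocks necessarily has negative eigenvalues; they encode the
  *exclusion* structure between sources (classes are mutually exclusive, so
  their AV blocks repel). No positive co-occurrence pattern can live there,
  so they never claim AVs — and consequently are never retained.
- **Re-projection of orphans.** An AV whose dominant space fails retention
  is reassigned to the retained positive space where it carries the most
  energy. Otherwise a source AV narrowly claimed by a weak echo space would
  silently vanish from the knowledge base.

Retention: a space is kept iff its RSRV has at least one cross-attribute
entry with |entry| ≥ threshold and at least two significant owned AVs
spanning two attributes. Retention is evaluated per space, so non-contiguous
selections (DS4 dropped while DS5 is kept) are normal.

Within a retained space, significant AVs split by loading sign into two
pattern groups (the eigenvector sign is fixed so the largest-|loading|
entry is positive, making PG numbering deterministic); each PG splits into
SubPGs as connected components of the graph with an edge where the RSRV
entry is ≥ +threshold. Components are ordered by size, then smallest AV
index. Each nonempty SubPG is addressed by its DSU code `[ds pg subpg]`.

**Known failure mode.** When two sources have near-degenerate eigenvalues,
per-AV argmax ownership can split one planted block across two spaces. The
entity-level clustering repairs this downstream (the two units cover the
same entities and merge), but the strict SubPG-level AV partition on such
seeds scores ARI ≈ 0.8 rather than 1.0. This is intrinsic to assigning AVs
through an eigenbasis and is left visible rather than patched.

## Patterns and the knowledge base

Patterns are grown levelwise inside each SubPG: a candidate AV set (one AV
per attribute) is extended only while its EID intersection is non-empty —
support is anti-monotone — but significance never prunes supersets, because
it is not anti-monotone. Every qualifying subset is kept (the comprehensive
view), not only maximal ones: the per-entity pattern *counts* in the
Summary KB are the entity-cluster signal, and they require all members.
Restricting candidates to within-SubPG AVs is precisely the disentanglement
payoff: it is what shrinks hundreds of entangled association rules to a
dozen interpretable patterns. Defaults: `min_occurrence = 2` (a pattern
seen once has no intersection evidence), `max_order = 8` (a logged
truncation guard; the target tables have ≤ 13 attributes). Repulsive sets
(d ≤ −1.96) are recorded separately and excluded from the KB.

Class labels never enter quantization, the SR matrix, the decomposition or
pattern growth. When present they are placed back as references: each
pattern is associated to the majority class of its covered labeled
entities, with the majority fraction as confidence (ties break
lexicographically and are flagged).

The knowledge base has two interlocked sections: Summary (one row per DSU:
union of its patterns' AVs, per-entity pattern counts) and Comprehensive
(one row per pattern: 0/1 entity flags). The invariant `summary count =
number of flags` is enforced at construction. Entities with no pattern
remain as all-zero columns — outlier detection reads the KB, so an empty
column must stay visible. Row order (DSU code, then significance
descending) and column order (input entity order) are fixed for diffable
exports.

## Entity analytics

- **Clustering:** each covered entity goes to the DSU holding most of its
  patterns (ties to the lower code); DSU clusters whose covered-entity
  Jaccard overlap ≥ `merge_overlap` (default 0.5) merge transitively.
  Zero-count entities are unassigned.
- **Outliers** are exactly the all-zero-column entities. **Mislabeled**
  entities match at least one pattern, but every matched pattern's class
  differs from their own label; the inferred class is the
  significance-weighted majority over matched patterns. The two sets are
  disjoint by construction.
- **Classifier:** fit = run the full pipeline on training rows (the
  quantization scheme is fit on training data and re-applied to test rows);
  score(c) = Σ over matched patterns associated to c of significance ×
  confidence; zero matches → abstain to the training-majority class
  (reported separately). The scoring rule is a design choice — the
  knowledge base determines *which* patterns vote, and
  significance × confidence is the simplest weighting that respects both
  statistical strength and label purity.
- **Evaluation:** clusters map to classes by the optimal one-to-one
  assignment (Hungarian algorithm on the contingency table); accuracy is
  the matched fraction with unassigned entities counted as errors;
  per-class precision/recall under that mapping, macro-F as their harmonic
  mean. "Repeated validation with variance" is realized as 10 repeated
  stratified 80/20 splits (the split fractions are explicit in the
  protocol; literal 10-fold CV would contradict them), with per-repeat
  records and identical splits under a fixed seed so that
  with/without-removal comparisons are exactly paired.

## Synthetic study conditions

The generator plants one AV block per class; a class member shows the
block's value at each blocked attribute with probability `fidelity`, else a
uniform other value; non-blocked attributes are uniform. On top: background
cell noise, all-uniform noise entities recorded under a random class label,
planted mislabels (recorded label flipped, truth kept in a sidecar), and
transition groups taking the target class's AV per attribute with a stated
fraction. Each component draws from its own seed-split stream, so changing
one rate never perturbs another's draws — essential for paired experiments.
Numeric attributes realize a latent level k as a jittered value in
[k+0.05, k+0.95], so equal-width binning at the level count recovers the
levels.

Fixed conditions (chosen once, as the package's study conditions):

- `apc1_like` — 80 entities, 9 categorical site attributes, classes
  30/25/20/5, blocks of 7 attributes for the three major classes and 4 for
  the rare one, exactly two AVs deliberately shared between class blocks
  (S1=L between the two largest, S6=E between first and third), fidelity
  0.9. This is the imbalanced, entangled, rare-class condition.
- `cancer_transition_like` — two major classes (447/235, nine attributes,
  opposite extreme blocks) plus two 30-entity transition groups with
  complementary per-attribute interpolation fractions (0.9/0.1 on the first
  four attributes and the reverse), fidelity 0.9.
- `heart_like` — 270 entities, 13 mixed-mode attributes (5 numeric, 8
  categorical), classes 150/120, fidelity 0.85.
- `two_class_mislabel` — 500 entities, two balanced classes with disjoint
  6-attribute blocks, fidelity 0.9, 5% planted mislabels: the mislabel
  *detection* condition.
- `entangled_mislabel` — 120 entities, two balanced classes whose blocks
  share two AVs, fidelity 0.65, 10% planted mislabels: the anomaly-removal
  *experiment* condition. The low volume, low fidelity and shared AVs are
  deliberate: labels never enter discovery, so mislabels can only harm a
  model through pattern-class associations, and associations only flip when
  pattern coverages are small and mixed. On clean high-fidelity disjoint
  blocks the with/without-removal delta is structurally zero; the benefit
  of removing detected anomalies before training is a property of noisy,
  entangled, low-volume data — which is the regime the method targets.

What the generator does *not* emulate: real marginal distributions,
correlated backgrounds, attribute dependence under the null within a class,
or measurement error structure. Passing tests therefore demonstrate
correctness of the machinery and the claimed qualitative behaviors
(rare-group recovery, type-I control, mislabel detection, removal benefit),
not performance on any particular real dataset.

## Numerical choices

Eigendecomposition is `numpy.linalg.eigh` (full, dense — catalogs are at
most a few hundred AVs; no sparse or randomized solvers). Interval edges
are `min + k·(max−min)/bins`; intervals are left-closed/right-open with the
last bin closed; equal-frequency edges collapse duplicates with a warning
rather than failing. Out-of-range values at scheme re-application clip into
the end bins. Constant attributes (marginal = N) are dropped from the
catalog with a warning — their residual variance is zero. Missing values
form a reserved non-category excluded from all statistics. All tie-breaks
(eigenvalue order, PG numbering, SubPG order, class association,
clustering assignment, classification) are deterministic and documented at
the definition site; two runs on the same input are byte-identical.

## Problem sizes used in the validation suite

Oracle checks run on 100 random tables (N ≤ 50, M ≤ 5) for the residual
and reconstruction properties and 200 small catalogs (≤ 12 AVs) for
pattern-search completeness; recovery, type-I, mislabel and
anomaly-removal checks use 20 seeds of their respective presets, with the
removal experiment at 10 paired splits per seed. These sizes give stable
statistics while keeping the whole suite and the acceptance script each
under a minute on one CPU.

## Limitations

- The residual's normal approximation is asymptotic; at very small N the
  1.96 threshold is nominal, not exact.
- One planted source can split across near-degenerate eigendirections (see
  above); AV-level recovery is then partial even though entity-level
  clustering is intact.
- The pattern search is exponential in SubPG size in the worst case; the
  `max_order` cap bounds it at the cost of completeness beyond that order.
- Cross-SubPG patterns are out of scope by design — that restriction *is*
  the disentanglement, but it means associations spanning two sources are
  only visible through the exclusion (negative) structure, which is
  recorded but not mined.
- The anomaly-removal benefit is condition-dependent (see
  `entangled_mislabel` above); on clean, well-separated data the procedure
  is a no-op, and removal can slightly hurt when false-positive flags
  shrink an already small training set.
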