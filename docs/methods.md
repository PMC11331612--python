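# Methods

This note documents the models and procedures implemented in `mtclades`,
the parameter choices that matter, and what the synthetic data generator
does and does not emulate.

## Haplogroup name grammar and irregularity flags

The strict cladistic convention for human mtDNA haplogroup names is a
single capital letter followed by digit blocks alternating with single
lowercase letters. We encode it as the regular expression

```
^[A-Z]([0-9]+([a-z][0-9]+)*[a-z]?)?$
```

applied to the *core* of a label, allowing names to end on either a digit
block (`C1d1`) or a letter (`L0d`). Before parsing, labels are trimmed,
internal whitespace and digit-group commas are removed (`D5a2a1 + @16,172`
→ `D5a2a1+@16172`), and the core is obtained by cutting at the first `+`,
`@` or `*`: those characters begin mutation modifiers, which annotate
extra or absent mutations rather than clade identity. The stripped text
still sets the `has_symbols` flag, computed over the full label against
the symbol set `*()@+"`.

Four irregularity flags are reported: two adjacent capitals
(`JT`-style merged names), two adjacent lowercase letters (`H3ag1`),
symbols, and apostrophe merges (`M9a'b`). `strict_cladistic` is true iff
the core matches the grammar and no flag is set. Classification summaries
report percentages rounded half-up to one decimal. Names are
case-sensitive. A name that fails the grammar without raising any flag
(e.g. a lowercase letter directly after the capital) is simply non-strict.

Apostrophe-merged names are kept whole: SC and SCL use only leading
characters, and hierarchy lookups resolve them by exact label match. No
splitting heuristic is attempted, since composed names are legitimate
clade names in the notation.

## Groupings

* **SC** returns the first letter.
* **SCL** returns `L<digit>` for names starting with `L`, the first letter
  otherwise. A bare `L` is an error rather than a silent `L` group:
  there is no haplogroup L, and emitting one would manufacture exactly the
  polyphyletic pseudo-group the scheme is criticised for.
* **custom** groupings match the core against a user-supplied prefix → label
  map, longest prefix winning (so `HV` can coexist with `H`), with an
  optional default label.

MRCA queries run on a `HaplogroupHierarchy`, a rooted tree of unique names
built from child/parent edges or labeled Newick. The MRCA is the deepest
node on the common prefix of the root-ward paths; the test suite checks it
against an independent ancestor-set-intersection oracle. A compact
schematic hierarchy (rooted at `mt-MRCA`, with `M`/`N` inside `L3`, `R`
inside `N`, and representative chains down to `B4a1a1b`, `J2b1a`,
`L0d2c1a1`) is packaged for tests and demonstrations; it is not a
substitute for a full reference phylogeny, which users supply themselves.

## Max-clade clustering

Given a rooted tree with non-negative branch lengths, the partition at
threshold *t* consists of maximal clades whose leaf-pair path-distance
diameter is ≤ *t*. A post-order pass computes, per node, the maximum leaf
depth through each child and the clade diameter (best pair of child depth
sums, or a child's internal diameter); a pre-order pass emits a cluster at
every highest valid node. This is linear in the number of nodes, and is
checked in the tests against exhaustive clade enumeration. The comparison
is inclusive with an absolute tolerance of 1e-12 against summation noise.

Every leaf receives a real cluster id — singletons get their own ids —
because addresses require a total assignment at every level. Ids are dense
integers numbered by each cluster's first leaf in the canonical
left-to-right traversal, making outputs deterministic across runs and
platforms. Internal node labels and support values in Newick input are
parsed and ignored; no support-based collapsing is performed. Explicitly
unrooted trees (`[&U]`) are rejected, since clades are undefined without a
root; mtDNA trees are conventionally rooted on an RSRS outgroup.

Because the validity constraint is monotone in *t* and clades are nested
or disjoint, partitions along a strictly decreasing threshold ladder are
nested refinements: cluster counts are non-decreasing as *t* decreases,
and every finer cluster sits inside exactly one coarser cluster.

## mtHg-addresses and named levels

An address lists a sample's cluster ids along the ladder, rendered with
dots. Refinement makes addresses prefix-consistent, and
`finest_shared_threshold` returns the threshold at the end of the longest
equal prefix (or none if the coarsest components already differ). With a
final threshold of 0, two samples share a full address iff their tree
distance is 0, which is the precise sense in which the scheme excludes
polyphyletic pseudo-groups.

Defaults: ladder `0.008 … 0.001, 0` (nine values) and level thresholds
macro = 0.006, meso = 0.005, micro = 0.004. Both are illustrative and
configurable — appropriate thresholds for a production standard would have
to be calibrated once on the full reference phylogeny, which is out of
scope here. Address components are per-level ids, not globally unique
ones, matching the dotted-number rendering where small integers recur
across levels.

Clusters are named by the MRCA haplogroup of their members' labels; a
cluster whose members all carry one identical label is named by that label
without a hierarchy lookup, which avoids spurious failures when a partial
hierarchy lacks a leaf-level name. Level naming is monotone: the macro
name is an ancestor-or-self of the meso name, and so on, whenever the
level thresholds are ordered.

## Sequence distances

Alignments are read from FASTA over `{A, C, G, T, N, -}`; other ambiguity
codes are conservatively mapped to `N` and excluded pairwise rather than
scored. The default mask removes the two poly-C regions (rCRS 303–315 and
16183–16194), expressed in reference coordinates and mapped through the
non-gap positions of a designated reference row; columns where the
reference is gapped carry no reference coordinate and are kept. Masked
alignments remember their original coordinate frames, so re-applying a
mask is a no-op. Spacer conventions (rCRS 3107, RSRS 523–524) are input
preprocessing concerns; the masking operation handles any such range the
user supplies.

Distances are mismatch counts or p-distances under pairwise deletion. No
multiple-hit correction is applied: the downstream uses (MDS, within-group
spread summaries) are rank-driven, and the uncorrected proportion is the
simplest defensible choice. A pair with zero comparable sites is an
explicit error, never a silent zero.

## Ordination

Correspondence analysis follows the standard SVD construction: with
`P = N/n`, row masses `r` and column masses `c`, the standardized
residuals `S = D_r^{-1/2}(P − r cᵀ)D_c^{-1/2}` are decomposed and
principal coordinates are the mass-rescaled singular vectors times
singular values. Total inertia equals `χ²/n` (verified to 1e-10 against an
independent χ² computation). Zero rows/columns are pruned first; singular
values below 1e-12 are dropped, so an exactly independent table retains
zero dimensions. CA is scale-invariant, so counts and relative frequencies
give identical coordinates; axis signs are not identifiable.

Classical MDS is Torgerson scaling: eigendecomposition of
`B = −½ J D∘D J`. Coordinates use the top-k non-negative eigenpairs;
negative eigenvalues — expected for non-Euclidean inputs such as
non-ultrametric tree metrics — are reported unmodified and never used for
coordinates, and no additive-constant correction is applied. Euclidean
inputs are reconstructed to numerical precision.

## Synthetic data generator

The generator emulates the shape of an mtDNA population survey: defaults
are 7 populations, ~100 samples, a tree diameter of 0.01
substitutions/site (placing the 0.001–0.008 ladder in its informative
range), and a 2 kb alignment. Sizes in the test and acceptance runs are
chosen at this scale so the full suite exercises every property in
seconds.

* **Trees**: Yule or Kingman topologies and waiting times via dendropy's
  simulators, branch lengths rescaled uniformly to an exact target
  diameter, leaves relabeled deterministically. The 2-leaf Yule case is a
  direct cherry, as the only 2-leaf shape.
* **Labels**: internal nodes down to a configurable depth are named by
  extending the parent's name with alternating tokens, so names are
  clade-consistent by construction and the emitted hierarchy mirrors the
  tree. Irregularities are injected at configurable per-event rates
  (defaults echo reported reference-phylogeny rates: 1.8% merged capitals,
  2.8% double lowercase, 19% mutation modifiers; apostrophe merges are
  common but unquantified, so 5% is used), with bookkeeping that records
  every affected leaf independently of the parser — the recovery tests
  compare parser counts against this record exactly.
* **Populations**: per-population group frequencies are symmetric
  Dirichlet draws. Populations can be assigned in proportion to those
  frequencies given leaf clade labels (distinct profiles), or leaves can be
  split evenly with group labels sampled from each population's vector, in
  which case the Dirichlet draw is the exact sampling law used by the
  calibration tests.
* **Alignments**: Jukes–Cantor evolution with the exact per-branch
  substitution probability `(3/4)(1 − e^(−4ℓ/3))`, no indels, no rate
  heterogeneity. A cherry's p-distance therefore matches the closed form
  in expectation, which the calibration test checks within 3 standard
  errors at 10,000 sites.

What the generator does *not* emulate: human mtDNA mutation spectra,
hypervariable hotspots, heteroplasmy, indels/alignment error, and real
haplogroup nomenclature depth. Passing tests therefore demonstrate
algorithmic correctness on well-formed inputs, not robustness to the
pathologies of real alignments.

All randomness in a bundle flows from one seed through
`numpy.random.SeedSequence`; identical seeds give byte-identical outputs.

## Numerical and degenerate-input choices

* Threshold and ladder validation is strict (non-negative, strictly
  decreasing); level thresholds must be ladder members, compared with a
  1e-15 absolute tolerance.
* Distance-matrix inputs to MDS must be symmetric with a zero diagonal
  (1e-9 tolerance); `k` is truncated with a warning when fewer
  non-negative eigenpairs exist.
* A mask that removes every column yields a zero-length alignment with an
  explicit warning; a fully masked pair of sequences is an error at
  distance time.
* Missing branch lengths are rejected unless a default is supplied
  explicitly; negative lengths are always rejected.

## Known limitations

* The packaged hierarchy is schematic; MRCA naming on real data requires a
  user-supplied reference hierarchy, and names absent from it raise
  lookup errors (by design).
* Only max-clade clustering is implemented; other criteria (single
  linkage, sum-length) are out of scope.
* Reproducing published name statistics for full reference phylogenies, or
  group counts on real 1000 Genomes data, requires external downloads,
  haplogroup calling and tree inference, and is deliberately not part of
  the test surface; the deterministic worked examples above are.
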