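# Methods

## Model and procedure

The package treats target selection as monotone submodular maximization on a
tree. Given a rooted phylogeny T with non-negative branch lengths and leaf set
L, the PD of S ⊆ L is the total length of the edges spanned by S: in **rooted**
mode the union of root-to-member paths; in **unrooted** mode the minimal
Steiner subtree of S (0 for |S| ≤ 1). Coverage of S is PD(S)/PD(L); PD(L)
equals the total branch length in both modes, so coverage fractions are
invariant under uniform rescaling of branch lengths.

A selection run partitions the leaves using the record table:

1. **preselected** — strains whose genome project status is in
   `exclude_statuses` (default `{ongoing, complete}`). Their PD counts as
   already covered. They are *not* deleted from the tree: deletion would
   shrink the coverage denominator and inflate the marginal gains of their
   relatives.
2. **excluded** — strains failing `require_type_strain` or `require_growable`
   (each exclusion carries a named reason). Already-sequenced status takes
   precedence over these flags: a sequenced non-growable strain is covered
   diversity, not an exclusion. Leaves without a matching record are likewise
   unselectable but keep contributing to total PD.
3. **eligible** — everything else.

Greedy selection then adds, at each step, the eligible leaf with the largest
marginal PD gain given everything covered so far, breaking ties
lexicographically by taxon name. The backup list is the continuation of the
same greedy run (next-best scorers, intended as drop-in substitutes), so
primary + backup equals one greedy run of size `n_primary + n_backup`.

## Correctness anchors

On rooted trees, stepwise greedy PD selection is optimal at every intermediate
size. The implementation never relies on that theorem for correctness of its
own bookkeeping; instead `brute_force_select` enumerates all k-subsets
(refusing pools above 20 leaves) and the test suite checks greedy cumulative
PD against the enumerated optimum at every k over 200 seeded random trees with
random preselected sets. An independent whole-edge-classification PD oracle
(an edge is spanned iff its subtree contains a member, and, unrooted, some
member lies outside) cross-checks the path-walking PD implementation in the
property tests.

## Numerical and algorithmic choices

* **Lazy greedy.** Gains are held in a max-heap of upper bounds and
  re-evaluated on pop; submodularity guarantees a popped, still-fresh gain is
  the true maximum. Gain evaluation walks the leaf's root path until the first
  covered edge (O(depth)), so a 1,000-pick run on an 8,029-leaf tree takes
  ~10 ms. All gains flow through one routine so stored and recomputed values
  use identical summation order.
* **Unrooted seeding.** Every singleton unrooted PD is 0, so the first pick
  from an empty selection is the lexicographic tie-break; it seeds the Steiner
  tree, after which gains are positive and non-increasing. This is the one
  step exempt from the non-increasing-gains invariant. The pipeline default is
  rooted mode, where the first pick is already well defined; unrooted mode is
  retained because "overall distance on a tree" can legitimately denote the
  spanning length without the root path.
* **Strict parsing.** Trees without branch lengths are rejected rather than
  defaulted (a silent ℓ = 1 would corrupt every score); zero-length branches
  are accepted; labels are compared exactly after trimming surrounding
  whitespace and unquoting; underscores are literal. Duplicate or empty leaf
  labels, unary nodes, and a root of out-degree < 2 are validation errors.
* **Rounding.** Percentages are computed at full precision and rounded
  half-up to one decimal only for presentation (half-even would print 56.2
  where published tables print 56.3). Machine outputs (TSV/JSON) carry full
  float precision; rounding and digit grouping appear only in the
  human-readable summary.
* **Determinism.** Lexicographic tie-breaks everywhere; all simulation
  randomness flows from one integer seed through per-stage
  `numpy.random.SeedSequence` streams; re-running any stage with the same
  inputs and seed yields byte-identical output files.

## Ledger arithmetic

Per-phylum summaries count: type strains (rows flagged as such),
species/subspecies names (distinct nomenclatural ids; homotypic synonyms make
names outnumber strains), % synonyms = (names − type strains)/names,
type-genome and non-type-genome project counts, genome coverage =
type genomes / type strains, and proposed targets. The totals row recomputes
percentages from summed counts and additionally reports a clearly labelled
coverage variant that counts non-type genome sequences in the numerator; the
two variants genuinely differ (13.4% vs 14.2% on the packaged mid-2011
census) and neither is silently preferred. The packaged census stores only
raw counts; every derived cell is recomputed.

## Synthetic data: what it does and does not emulate

`simulate_yule_tree` grows a rooted binary pure-birth tree: two crown
lineages, each extant lineage splitting at rate λ (`birth_rate`), branch
lengths equal to inter-event exposure times, growth stopping at the event that
would create n + 1 lineages. Expected total branch length is (n − 1)/λ —
each stage with j lineages lasts Exp(jλ) and exposes j branches — which the
tests check against simulation at 3 standard errors. Defaults mirror the
mid-2011 study scale: n = 8,029 leaves, 13% of strains with a genome project
(7% complete, 6% ongoing), 33 phyla. `frac_nongrowable = 0.10` is a package
choice: no census of hard-to-grow type strains exists, and a ~10%
failure-to-grow allowance is a realistic planning figure for collection-held
strains.

Phyla are assigned by cutting the tree into `n_phyla` monophyletic clades
(largest clade split first) so per-phylum PD summaries remain interpretable.

The generator does **not** emulate: 16S rate heterogeneity or non-clock
branch-length structure, taxon-sampling bias toward cultivable clades,
synonym-bearing record structure (every synthetic leaf is a distinct type
strain), or correlations between growability and phylogeny. Passing tests
therefore demonstrate the selection machinery's correctness and its behavior
at realistic scale, not that any particular real-data coverage number (such as
a specific coverage fraction of a curated 16S tree) is reproduced; that number
depends on the actual tree and the actual already-sequenced list.

## Problem sizes used in checks

The packaged per-phylum census expands to 11,846 records. The oracle
comparison uses 200 Yule trees of 5–12 leaves with random preselected sets
(every k checked exhaustively). The scaled selection experiment uses 20
replicates of 8,029-leaf trees, 1,000 greedy picks each, compared with 1,000
uniformly random eligible picks per replicate.

## Known limitations

* Unrooted-mode greedy is not guaranteed optimal from an empty start (the
  classical unrooted algorithm seeds with the farthest leaf *pair*; this
  implementation seeds with the lexicographic tie-break to honor the uniform
  tie rule). Rooted mode, the default, carries the optimality guarantee.
* Backups are a global greedy continuation; per-phylum quotas are not
  implemented.
* Growability is a boolean input; real culture-condition screening is manual
  and out of scope, as are sequencing, assembly and annotation.
* Name matching between tree and records is exact (after trimming); no fuzzy
  nomenclature resolution.
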