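# Methods

## Similarity model

Pairwise similarity between two aligned sequences is the fraction of
identical columns. Three gap conventions are exposed:

- `all` (default): every column counts; identity is pure character equality,
  so a gap–gap column and an N–N column are matches. This mirrors a
  keep-gaps similarity matrix on a concatenated supermatrix, where a shared
  missing gene appears as matching gap runs. Whether the upstream tools that
  popularized keep-gaps matrices count gap–gap columns as matches is not
  documented anywhere we could verify, so the rule here is a stated
  convention, switchable by mode.
- `exclude_either`: columns gapped in either sequence are dropped — the
  usual choice when gap runs encode missing data rather than indels.
- `exclude_both`: only columns gapped in both are dropped.

Similarities are stored as fractions in [0, 1] at full precision; rendering
as percentages (2 decimals) happens once, in the report layer. An identity
whose denominator is empty (e.g. two all-gap sequences under
`exclude_either`) is undefined and propagates as NaN; downstream stages
treat undefined entries as "too far" (no cluster edge) and log them.

Descriptive statistics follow the pandas `describe` conventions: sample
(n−1) standard deviation, undefined for a single gene, and
linear-interpolation quantiles. Cross-group statistics (one strain group
against another) include per-row maxima — each strain's best match in the
other group — whose mode is taken after rounding to two decimals in percent,
ties broken toward the smaller value; without a rounding grid the mode of
continuous values is meaningless.

## Supermatrix construction

Per-gene alignments are concatenated by sequence id, genes in lexicographic
order so the result is independent of filesystem enumeration. Coordinates in
the partition map are 0-based half-open. Strains missing a gene are padded
with gaps by default (`pad_gaps`) rather than dropped, because real ortholog
recovery is incomplete and discarding a strain over one missing gene wastes
the other 49; `drop_strain` is available when complete matrices are
required. The alphabet is normalized to `{A,C,G,T,N,-}` on input; anything
else (including U and non-N IUPAC ambiguity codes) becomes N with a logged
count, keeping identity semantics exact over a six-letter alphabet.

## Lineage clustering

Byte-identical concatenated sequences are collapsed first (representative =
lexicographically smallest id; deterministic and idempotent). Remaining
strains are clustered by single linkage on the similarity graph with an edge
wherever divergence `1 − s < θ` (strict), default `θ = 0.0002` (0.02%).
Single linkage is the right notion here because a lineage is a clade of
mutually near-identical strains connected through chains of closeness, not a
centroid-shaped cluster; at thresholds this tight the graph components
coincide with phylogenetic clades. One representative per lineage is then
drawn uniformly with a seeded generator — the draw is random by design (any
member represents the lineage equally well), but reproducible per seed.

The threshold is a proportion of sites (0.0002), not 2%; the flag
`--max-divergence` exposes it for users who want a coarser grouping.

## Classification

The label of a strain pair is a pure function of the two per-gene mean
identities and two thresholds (`symb_min_similarity = 0.93`,
`host_max_similarity = 0.80`). The `uninformative` label exists because for
closely related hosts neither high nor low symbiont similarity discriminates
transmission routes — hybrid introgression and recent codivergence both
predict similar symbionts. Defaults are read from the narrative ranges of
published host-shift analyses (symbiont identities of shifted pairs 93–99.9%
against host identities of 60–80% and below) and are reported in every
output; classification never uses the bootstrap intervals or per-gene
spread, which are reported as evidence context only.

A proportional clock model (`ratio_c` = symbiont divergence per unit host
divergence) can be calibrated as the median ratio over user-designated
codiverging reference pairs; the codivergence expectation
`max(0, 1 − c·h_div)` is then attached to each call for inspection. The
median is used rather than a regression because reference sets are small and
occasionally contain a mislabeled shifted pair.

`hs_host_fraction` — the share of host species appearing in at least one
host-shift call — is defined operationally over the call set and reported in
percent with one decimal.

## Trees and incongruence

Distance trees are built by canonical neighbor joining on `1 − s`. Q-matrix
ties break toward the smallest index pair in the current agglomeration
order, and negative branch-length estimates are clamped to zero with the
deficit logged, so reconstruction is deterministic. NJ is used deliberately
instead of maximum likelihood: on the tightly constrained distances this
pipeline produces it is consistent (exact recovery of additive distances is
part of the test suite), runs in milliseconds, and keeps the artifact free
of external inference tools; users with an ML tree supply it as Newick.

Incongruence is quantified with the unrooted Robinson–Foulds distance
(symmetric difference of non-trivial bipartitions), normalized by `2(n−3)`,
defined as 0 for n ≤ 3. Strain leaves are translated to host species through
the strain–host map before comparison. Newick serialization canonicalizes
child order by smallest descendant leaf label and writes branch lengths at 6
decimals, making tree output byte-stable.

## Simulator

The generator produces the statistical structure the inference assumes, with
known truth, and nothing more:

- **Host tree**: Yule pure-birth process; waiting times exponential with
  rate k·birth_rate for k extant lineages, root split at time 0, one extra
  waiting time beyond the n-th lineage, then height normalized to 1. All
  rates in the simulator are therefore per unit tree height.
- **Cophylogeny**: the symbiont tree starts as an exact copy of the host
  tree (strict codivergence). Host-shift events arrive as a Poisson process
  with rate λ per unit branch length, measured on the host tree (equal to
  the initial symbiont tree; the replacement surgery below shortens the
  realized symbiont tree, so the initial copy is the well-defined measure).
  Each event picks its edge proportionally to length and a donor uniformly
  among the other lineages extant at that time. The event grafts the
  recipient's symbiont subtree onto the donor's lineage at the event time,
  replacing the recipient's prior symbiont ancestry — shifted strains are
  thereby near-identical to the donor's strain, the defining signature. An
  event between lineages whose symbionts already share their ancestry at
  that time (after earlier shifts) is genealogically a no-op; it stays in
  the event log but changes nothing. The surgery keeps the original root
  fixed and leaves internal unifurcations in place: path lengths,
  bipartitions and sequence evolution are all unaffected by them, and
  re-rooting edge cases disappear. Emptied ancestors of repeatedly detached
  sibling lineages are pruned so no phantom leaves arise.
- **Sequences**: independent genes under Jukes–Cantor with no indels, so the
  true alignment is positional identity and the inference is isolated from
  alignment error. Per branch of length t, each site is retained with
  probability `1/4 + (3/4)e^(−4·rate·t/3)`, otherwise replaced uniformly by
  one of the other three bases. Symbiont genes evolve on the symbiont tree
  at `clock_ratio_c × host_subst_rate`.
- **Dropout**: each (strain, gene) record is removed with probability
  `gene_dropout`, emulating incomplete single-copy ortholog recovery.

Defaults (chosen once, as the package's standing study conditions): 10
hosts, 50 genes × 900 bp, `host_subst_rate = 0.45` (distant host pairs land
near ~48% identity under the JC closed form, matching the host identities
the method is designed to contrast), `clock_ratio_c = 0.5` (a codiverging
symbiont pair at any host depth stays below the 0.93 call threshold — at
this ratio the region where symbiont identity ≥ 0.93 lies entirely inside
the uninformative zone `h̄ > 0.80`, so the classifier has no analytic
false-positive band), `hs_rate_lambda = 0.5` (no empirical estimate of the
shift rate exists; this yields a few events per simulated clade), and
`gene_dropout = 0.02` (mean recovered genes 49 of 50, matching typical
ortholog-recovery completeness).

The ground-truth scenario builder for recovery experiments
(`forced_shift_scenario`) searches seeded host trees for three disjoint
donor/recipient pairs with pairwise MRCA time ≤ 0.5 and pendant branches
starting by time 0.75, then plants shifts at t = 0.95. These constraints,
pushed through the JC closed form at the default rates, guarantee host
identity < 0.80 for every forced pair (expected ≈ 0.66) and symbiont
identity < 0.93 for every non-shifted pair including pairs that interact
with a donor's relatives (expected ≤ 0.90), with margins of many standard
errors at 50 × 900 sites — which is why recovery is expected to be perfect
in nearly every replicate.

## What the simulations do and do not show

Passing the recovery tests shows the pipeline detects the pattern it
formalizes — replacement-style transfers under a proportional JC clock with
correct alignments. Real data differ in ways the simulator deliberately
omits: alignment and assembly error, recombination between symbiont strains,
rate heterogeneity across sites and lineages, multiple infections per host,
host-tree extinction, and GC/codon structure. Results on real datasets
therefore depend on upstream ortholog identification and alignment quality
in ways these tests cannot certify.

## Numerical and testing choices

Problem sizes in the test suite and acceptance script (e.g. 20–50 replicates
per condition, 10-host trees, 50 × 900-site gene panels) were set as the
smallest sizes at which the statistical checks have comfortable margins
(3-standard-error bands, 10% ratio tolerance); all randomness flows from
explicit seeds, and hypothesis-based property tests run derandomized.
Bootstrap intervals are percentile-based over seeded resamples. The
acceptance script derives every sub-seed from its single `--seed` argument,
so its JSON is reproducible run to run.
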