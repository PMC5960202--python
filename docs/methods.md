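# Methods

## The protocol

`foldbridge` assigns SCOP-style structural folds to protein sequence
families using nothing but sequence information. Its premise is that
fold space is sparsely sampled by natural sequences: two families of the
same fold can be so diverged that no search reaches one from the other,
yet the region of sequence space *between* them is perfectly protein-like.
The method populates that region with designed sequences and lets an
iterative profile search use them as intermediates.

The pipeline stages and their contracts:

**Family profiles** (`profiles`). An alignment with `n ≥ 2` rows becomes
per-column residue distributions. Sequences are weighted with the
Henikoff position-based scheme (gap characters count as their own symbol
class, so fragmentary rows are not over-weighted). Observed frequencies
are mixed with a fixed amino-acid background (Robinson–Robinson) through
a per-column admixture `α = min(1, c/n_eff)`, where `n_eff` is the
number of distinct residues in the column and `c` (default 0.1) is the
pseudocount weight. Unknown residues (`X`) contribute background-shaped
counts; an all-gap column is an error naming the column.

**Profile–profile alignment.** Columns are compared by
`s(p, q) = 1 − 2·JSD₂(p, q)` (base-2 Jensen–Shannon divergence, so
`s ∈ [−1, 1]` with identical columns at +1). Before the alignment the
whole similarity matrix is centred to mean 0: for unrelated profiles
every column pair is effectively a random pair, so after centring an
unrelated match is cost-neutral and the affine gap penalties
(`gap_open = 3.0`, `gap_extend = 0.3`, in column-score units; a run of
length k costs `open + k·extend`) alone decide gap placement. Without
centring, sharp unrelated columns score near −1 and the aligner
degenerates into gap-hopping between spuriously similar columns, which
turns the combined model into a concatenation of the two family
consensi rather than a position-wise mixture. The global
dynamic program breaks ties deterministically (match over gap-in-second
over gap-in-first); on profiles of length ≤ 6 it is tested against
exhaustive enumeration of all global alignments.

**Combined model and linker design** (`linker_design`). At a paired
position the merged distribution is `w·f_A + (1−w)·f_B` renormalized
(`w = 0.5` by default: no reason to prefer either family); at a
position present in only one profile it is that profile's distribution.
A position whose combined gap fraction (an absent profile counting as
fully gapped) exceeds ½ is kept but not emitted. Sampling is a literal
roulette wheel: per emitted position, one uniform variate against the
cumulative merged frequencies. Sequence *k* of a batch uses seed
`seed + k − 1`, so parallel generation is reproducible. Designed
records are named `DS_<fold>_<famA>_<famB>_<serial>` and carry their
fold and parent families in the fold map; downstream they count toward
normalized fold frequency exactly like natural sequences — that is the
point of the design.

**Iterative search** (`search_engine`). The engine preserves the
protocol that defines the original search procedure — at most 5
iterations, an E-value threshold of 10⁻⁴ used both for reporting and
for profile inclusion (the protocol states a single filter), profile
re-estimation after every round, and the anti-drift rule that the
original query is a row of every round's profile — while the scoring
machinery is a deliberately lightweight PSSM stand-in rather than a
profile HMM: targets are aligned to a position-specific log₂-odds
matrix by Smith–Waterman with affine gaps, and E-values come from a
maximum-likelihood Gumbel fit to the scores of 200 shuffled decoys
drawn from the database (seeded). For a bare query the PSSM columns are
one-hot distributions smoothed with background admixture `α = 0.25`,
which plays the role of a substitution-matrix prior; the implied
break-even identity (~33% for the default gap costs
`gap_open = 6 bits`, `gap_extend = 1.5 bits`) keeps local alignments
from either fragmenting at homologous identity levels or tunnelling
through non-homologous regions with cheap gaps. Profiles for later
rounds are rebuilt on the original query's coordinates from the aligned
residues of all included targets. Per-domain tables from real jackhmmer
runs can be ingested through `read_domtblout` instead; the per-domain
independent E-value is used throughout because filtering and coverage
are per-domain notions.

**Assignment** (`fold_assignment`). Filtering is strict on both stated
boundaries: E-value "better than 10⁻⁴" is `E < 1e-4`, coverage "better
than 60%" is `cov > 0.6`; coverage is the query span of the best
(lowest-E) domain per target sequence. Normalized fold frequency for
fold *i* is the fraction of qualifying target sequences from that fold;
ties in nff break by higher best coverage, then lower best E-value,
then fold id. The label rules are ordered: a single fold is
`NO_AMBIGUITY`; otherwise the top-nff fold is `CONFIDENT_STAR` if it
has a hit at ≥ 95% query coverage, `CONFIDENT` if it also provides the
best coverage, else `CONFLICT`. `nff ≥ 0.8` additionally marks the call
high-confidence. Hits pooled over several representatives of one family
are assigned exactly as their concatenation. Clan extension copies a
non-`CONFLICT` fold call to unassigned clan members
(`inferred_via_clan = true`); clans whose direct calls disagree are
flagged and left alone, and a direct call is never overwritten.

**Assessment** (`assessment`). Confusion counts are per retrieved
candidate: among the best domains per target retrieved by the search,
true-fold candidates passing the filters are TP, true-fold failures FN,
other-fold passes FP, other-fold failures TN. Candidates never
retrieved at any E-value are not counted, so TN is search-scoped.
For this to be informative the pipeline's retrieval keeps weak
candidates up to `candidate_evalue = 10` (the customary reporting
default of the underlying search tools) and applies the 10⁻⁴/coverage
protocol filter downstream; assignment results are unaffected because
the assignment stage filters at 10⁻⁴ regardless. Metrics are the exact
formula evaluations (percent scale; MCC in [−1, 1]); a zero denominator
flags the component undefined rather than zero, and medians across
families ignore undefined entries.

## The synthetic corpus

The generator (`synthetic_data`) emulates the structure the method
assumes, at desk scale. A fold is an ancestor sequence (length 120,
background residue usage); family founders diverge from it by
`between_div` substitutions/site (uniform replacement: a mutated site is
redrawn uniformly over the 20 residues, so retained identity per site is
`1 − 19/20·d`); members diverge from their founder by `within_div`,
plus geometric-length indel events at `indel_rate` per site. Alignments
are exact by construction (founder coordinates), so profile building is
not confounded by alignment error.

The last family of each fold is a **recombinant intermediate**: its
founder takes its N-terminal half from the first family's founder and
its C-terminal half from the second's. This emulates the continuity of
real fold space — a family can lie between two structurally
characterized families, sharing different parts of its domain with each.
It is the regime in which designed linkers matter: each characterized
family matches only ~half of such a query (failing the > 60% coverage
filter), while a designed linker between the two database families is
alignable over the query's full length. It also feeds the iteration:
once linkers enter the profile, they supply bridging residues across the
whole query, after which even the natural remote members align at high
coverage.

The benchmark builder has two holdout modes. `representative` holds out
cluster representatives (greedy single-linkage at 60% identity and 90%
mutual length coverage, emulating blastclust's published thresholds)
and leaves the rest of the family in the database — the mode for
count contracts and for transitivity fixtures. `family` (the pipeline
default) removes the recombinant family entirely and uses its members
as queries — the realistic regime of a query family with no sequenced
relative in the database, matching the corpus the method was built for,
where query families and the structure-bearing database are disjoint
sequence sets. If more queries are requested than clusters exist,
additional members top up the query set.

Default operating point: `within_div = 0.10`, `between_div = 0.65`,
`indel_rate = 0.005`, 3 folds × 3 families × 20 members × length 120,
50 linkers per family pair, 5 queries per held-out family. These place
query-to-database identities at remote-homology levels (~15% to the
other fold half, ~45% to a designed linker, ~80% within a family) so
that direct search fails for most queries while the linker route is
reliable. At this operating point, across seeds, plain search assigns
the correct fold to 0–50% of held-out queries and the enriched database
raises recovery to ~100%.

What the generator does **not** emulate: site-rate heterogeneity and
substitution biases (a BLOSUM-flavoured replacement model is not
included), phylogenetic tree structure within families, multi-domain
architectures, compositional bias, and alignment uncertainty. Passing
tests therefore demonstrate the protocol's internal correctness and its
central mechanism under controlled divergence — not performance on real
Pfam/SCOP corpora, whose headline statistics require the real databases.

## Numerical choices

- Roulette wheel: cumulative frequencies with the final entry clamped
  to 1.0, sampled by `searchsorted`; a degenerate column emits its
  single residue deterministically.
- Gumbel fit: `scipy.stats.gumbel_r.fit` (MLE) on decoy scores; the
  scale is floored at 10⁻⁶; E = database size × upper-tail probability,
  floored at 10⁻³⁰⁰ so extreme self-hits remain representable.
- All alignment coordinates are stored 1-based inclusive (the
  per-domain table convention); conversions to half-open happen only
  inside coverage arithmetic.
- Determinism: every stochastic step (simulation, decoys, sampling)
  derives its generator from explicit seeds, with string-dependent
  stream separation via CRC32 (stable across processes); identical
  seeds give byte-identical FASTA/TSV outputs.
- Reported search hits are sorted by (E-value, target id); database
  order never affects results.

## Limitations

- The search engine is a PSSM approximation of a profile HMM; its
  E-values are calibrated empirically per query and are not comparable
  with HMMER's analytic statistics (ingest real jackhmmer domtblout
  files where that matters).
- One fold call per query; queries spanning multiple structural
  domains with different folds are out of scope.
- Clan extension propagates a single fold per clan and flags
  disagreements instead of arbitrating them.
- The recombinant query family construction is the simplest geometry
  that places a query between two database families; real intermediacy
  is higher-dimensional.
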