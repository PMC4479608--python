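# Methods

## Problem and model

`taxores` measures how well a marker gene region separates taxonomic ranks.
The observable is the distribution of pairwise percent identities within
five pair categories — intra-species (S), inter-species intra-genus (G),
inter-genus intra-family (F), inter-family intra-order (O), inter-order
(I). Two statistics are derived from those distributions:

* **Best threshold (balanced success).** For a boundary between adjacent
  ranks (S/G, G/F, F/O, O/I), plot the cumulative fraction of the finer
  category's values at or above a threshold (positive curve) and the
  cumulative fraction of the coarser category's values at or below it
  (negative curve). The curves cross at the threshold that balances the two
  error directions; the common curve value at the crossing is the success
  rate. Values equal to a grid threshold count toward *both* curves by
  default (`tie_rule="both"`); this makes both curves conservative and is
  switchable to `"strict"`.
* **Lowest threshold (guaranteed accuracy).** The probability that a query
  matching a reference at similarity S ≥ n truly belongs to the reference's
  rank is modelled from the confusable categories' cumulative frequencies
  at S ≥ n (ICP, OCP, FCP, GCP): `OP = 1 − ICP`, `FP = OP·(1 − OCP)`,
  `GP = FP·(1 − FCP)`, `SP = GP·(1 − GCP)`. By construction SP ≤ GP ≤ FP ≤
  OP at every n, and all four are non-decreasing in n. The lowest threshold
  for a rank is the smallest grid n whose probability meets the accuracy
  floor (default 0.95); when no threshold qualifies the result is `none`
  rather than a weakened floor.

Assumptions worth keeping in mind: the pair categories are treated as
samples from fixed distributions (no phylogenetic correlation correction);
the taxonomy labels are taken as ground truth; and percent identity comes
from *local* alignment, so divergent pairs are scored on their best-aligned
segment, not genome-wide divergence.

## Numerical choices

* **Grid.** Thresholds are evaluated on a 0.1% grid from `floor(min)` to
  100. The crossing is refined by linear interpolation between the
  bracketing grid points; an exact-equality plateau yields its midpoint.
  Perfectly separated categories (no overlap at all) are reported as
  success 100 with `separated=True` and the threshold at the midpoint of
  the empty overlap interval.
* **Coordinates.** 0-based half-open internally; 1-based inclusive in every
  report, log and config file.
* **Entropy.** Column entropy is Shannon entropy (bits) over unambiguous
  A/C/G/T frequencies; gaps and ambiguity codes carry no weight, and a
  column with no unambiguous base reports entropy 0 with an `empty` flag.
  The variability trend is the mean entropy of successive non-overlapping
  windows (default 20 columns), the trailing partial window averaged over
  its actual width.
* **Site classes.** Within an interval, a column with ≥ 2 unambiguous
  states is variable (Nv), exactly 1 conserved (Nc), and
  parsimony-informative (PI) when ≥ 2 states each occur in ≥ 2 rows.
  Columns with no unambiguous state count toward the interval total Nt but
  neither class, so Nv + Nc ≤ Nt; the difference is reported explicitly as
  a remainder column.
* **p-distance.** Uncorrected proportion of differing sites under pairwise
  deletion (columns with a gap or ambiguity in either row are skipped); a
  pair with zero comparable sites raises an undefined-distance signal and
  is excluded (and counted) by the per-region summary. SD uses ddof = 1.

## Local alignment

Two interchangeable engines produce the 12-column tabular report:

* `blast`: `makeblastdb` + `blastn` with `-outfmt 6`, task `blastn`
  (11-bp words) by default. The megablast task's 28-bp seed fails to find
  any hit between strongly diverged pairs (inter-order pairs at ~70%
  identity), which would silently empty the I category, so the classic
  word size is the default; callers can pass `task="megablast"` for
  close-in data.
* `native`: an affine-gap Smith–Waterman (match +2, mismatch −3, gap open
  5, gap extend 2 — megablast-like scores) vectorised row-wise in numpy,
  with the horizontal-gap state computed by a prefix-max scan. It reports
  the single best local alignment per ordered pair. Bit scores use
  Karlin–Altschul parameters appropriate to the score system (λ = 0.625,
  K = 0.41); they only need to rank hits consistently for pair collapse.

Spurious hits (short high-identity segments between non-homologous
stretches) are removed by alignment length. The `SORTED_GAP` policy sorts
hit lengths and cuts at the largest gap whose lower side is below 50% of
the median length — a deterministic version of eyeballing the sorted
list — and *requires* that 100% of expected pairs survive; when short hits
grade continuously into valid ones it refuses and instructs an explicit
`FIXED_CUTOFF`, mirroring how short variable sections must be handled in
practice. `ResolutionModel.from_sequences` falls back automatically to a
cutoff at half the shortest section sequence. Per unordered pair, the
surviving hit with the highest bit score (ties: higher identity) supplies
the pair's percent identity.

## Uncertain identifications

Records may be identified only to a rank above species (token
`sp_uncertain`). A pair whose deciding rank is uncertain has no category,
so datasets are filtered first: within each genus, uncertain-species
records are dropped when a species-confirmed record exists, otherwise
exactly one is retained; the same rule applies one level up for records
uncertain at genus or higher. The retained representative is the
lexicographically smallest accession — a documented convention chosen to
make the filter deterministic and idempotent. Taxonomies are validated for
tree consistency at load time (a genus under two families is a hard
error).

## Synthetic data generator

The simulator emulates the statistical structure of a curated rRNA
dataset, not its biology:

* a balanced taxonomy (default 4 orders × 2 families × 2 genera × 3
  species × 4 sequences = 192 records) evolved from a uniform-random root
  (default 1800 bp, the length scale of a full 18S gene);
* per rank edge, each site is substituted with probability
  `rank_divergence[edge] × regional multiplier`, the new base uniform over
  the other three (Jukes–Cantor-like; adequate because the analysis
  consumes identities, not model-based distances). Defaults are 0.12 /
  0.06 / 0.03 / 0.01 / 0.001 for order / family / genus / species / intra
  edges — strictly ordered, which is exactly the condition for the
  S > G > F > O > I similarity structure. Divergence accrues along shared
  ancestry (same-genus species share their genus ancestor), which is what
  produces nested similarity rather than independently sampled categories;
* the region layout is an 18S-like mosaic of nine variable regions in
  conserved linkers, with multipliers normalised to a length-weighted mean
  of 1 so that rank divergences read as genome-wide per-site expectations;
* the optional indel-prone region implements *deletions only*: the root
  carries the longest variant and lineages delete runs (up to
  `max_indel_length`, with per-edge probability `indel_rate`). This keeps
  the true alignment a fixed column set — no insertion propagation — while
  still producing the length variability that characterises hypervariable
  segments such as the copepod V7;
* one `numpy` Generator seeded from `config.seed` drives everything; equal
  seeds give byte-identical outputs.

The closed-form expected identity between two sequences joined by edges
with substitution probabilities `p_1..p_k` is
`1/4 + 3/4·Π(1 − 4 p_i/3)` per site, averaged over the region layout;
tests use it as an independent oracle for the generator.

What the generator does **not** emulate: unbalanced taxon sampling,
base-composition skew, rate variation beyond the region multipliers,
insertions, sequencing error, or misidentified reference labels. Passing
tests therefore demonstrate that the estimators recover the structure they
assume, not that any particular real dataset satisfies those assumptions.

## Problem sizes

The test suite runs the full pipeline at root length 500 bp with 192
sequences (18 336 pairs, ≥ 200 pairs in every category) over 10 seeds for
the stochastic parameter-recovery check, using the `blast` engine; unit
and property tests use the `native` engine on sequences ≤ 400 bp. The
acceptance script runs one full-length (1800 bp) pipeline per invocation.

## Known limitations

* Absolute percent identities from local alignment depend on the engine's
  task/word size; cross-engine agreement is asserted to ±1 point on
  moderately diverged pairs, not to the last decimal.
* The accuracy model ignores sampling error in the cumulative frequencies;
  with few pairs in a category the lowest thresholds inherit that noise.
* The sorted-gap filter assumes the valid-hit length distribution is
  unimodal; heavily length-polymorphic sections should use explicit
  cutoffs.
* `best_threshold` requires both categories non-empty; boundaries without
  data are reported as NaN rows rather than inferred.
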