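# Methods

## Problem and model

A clonal panel is a set of accessions (clones) of one species, each
measured by one or more marker systems. The pipeline treats every marker
system the same way once its output is expressed as a rectangular
samples × characters state matrix over the alphabet

* homozygous: `a c g t`
* ambiguous: the IUPAC two-or-more-base codes `r y s w k m b d h v`,
  unknown `n`, alignment gap `-`, missing `?`.

Fragment-length (presence/absence) characters are recoded `0 → c`,
`1 → a` so that one distance implementation serves both marker families.
Ambiguity is defined as *any non-homozygous call*: heterozygous codes
and gaps are what sequencing-based methods actually produce at
uncertain sites, and unknowns (`n`, `?`) are folded in because they are
equally unusable for a strict homozygous-site comparison. This strict
treatment avoids any phasing assumption, at the cost of discarding
genuinely informative heterozygous differences — a deliberate trade-off.

### Distances

For samples *i, j*: `L_ij` = number of sites where both calls are
homozygous, `m_ij` = mismatches among them, `p_ij = m_ij / L_ij`
(uncorrected p-distance). Sites are excluded *pairwise* (only for the
pairs they affect), not listwise: this maximizes compared sites and
makes the replicate-pair error estimate use every site the pair can
support. A pair with `L_ij = 0` has an undefined distance; it is flagged
as NaN and clustering/resolution refuse to run over it rather than
treating it as 0. No substitution-model correction is applied:
intraspecific p-distances here are ≪ 0.05, where multiple substitutions
per site are negligible.

Note that under pairwise deletion a monomorphic column still enters
`L_ij`, so adding or removing monomorphic characters rescales `p`
(never `m`); genotype counts at a fixed *proportional* threshold are
insensitive to this only insofar as the threshold is derived from the
same matrix, which is how the error-based thresholds are defined.

### Error estimation

Replicate runs of the same DNA extract should agree everywhere; their
p-distance is the per-character error rate of the method. Per panel the
estimator reports the per-pair rates, their mean and maximum, and the
pooled rate (Σ mismatches / Σ compared). Mean-of-rates and pooled rate
coincide when all pairs compare equally many sites; both are exposed
because published tables rarely say which was used. Zero replicate
pairs yield an explicit *not determined* (n.d.) state — never a silent
0 — and resolution then runs at threshold 0 only.

### Genotype resolution

Clones are nodes; every pair with `p ≤ t` (inclusive) is an edge;
genotypes are connected components. The inclusive comparison makes
`t = 0` merge exactly the identical clones. Replicate samples are
removed before counting: they estimate error, they are not extra
clones. Components equal the single-linkage dendrogram cut at `t`
(tested as a property), so the dendrogram visualizes the same decision
the counter makes. Chaining is intentional and tested: under pairwise
deletion, "indistinguishable at p ≤ t" is not transitive, and a triple
A~B, B~C with A≁C is merged into one genotype — the operational reading
is "no method-level evidence separates these clones into more groups".

### Single linkage and Newick export

Agglomeration is implemented directly (O(n³), panels are tens of
samples): at each step the cluster pair with minimal single-linkage
distance merges; exact ties resolve to the pair whose
lexicographically-smallest members are smallest, making merge order
reproducible. `scipy`'s single-linkage serves as an independent
cross-check in the tests, not as the implementation. In the Newick
export a node sits at *half* its merge height, so the path length
between two leaves equals the p-distance at which they merged
(cophenetic convention); branch length = parent height − child height;
trees are round-trip checked with an external Newick parser.

## Fragment scoring

The peak-table scorer makes two pre-processing steps explicit:

* **Gap binning** (`bin_peaks`, default `max_gap = 0.5` nt): per locus,
  distinct sizes are sorted and a new size class opens when the gap to
  the previous size exceeds the tolerance. This is order-independent
  and deterministic. The documented caveat is chaining: a ladder of
  sizes each ≤ 0.5 nt apart forms one bin whose span exceeds the
  tolerance. Binning is per locus; with global binning, co-migrating
  fragments from different loci would be merged.
* **Lattice rounding** (`lattice_round`): microsatellite alleles at a
  locus with repeat unit `u` are snapped onto the lattice
  `{φ + k·u}`, with the offset φ chosen on a 0.01-nt grid to minimize
  the total absolute deviation (smallest optimal φ on ties). This
  removes the systematic sub-repeat drift of capillary sizing while
  preserving repeat-number differences.

Each bin becomes one character; a cell is 1 if the sample has ≥ 1 peak
in the bin. Identical duplicate rows (two dyes, re-runs) collapse to
presence. Monomorphic characters are retained — they contribute no
mismatches and document the panel's information content honestly.

## Synthetic panels

`simulate_panel` emulates a clonal genotyping study:

| parameter | default | meaning |
|---|---|---|
| `n_genotypes` / `clones_per_genotype` | 21 over 23 clones (one triple) | true partition |
| `n_characters` | 1292 | SNP characters |
| `divergence` | 0.02 | P(two distinct genotypes differ at a character) |
| `heterozygosity` | 0.29 | per-cell ambiguity probability (SNP only) |
| `error_rate` | 0.0 | expected replicate-pair mismatch rate |
| `replicate_clones` | first 3 clones | replicate runs emitted as `<id>r` |

Defaults portray a low-diversity clonal panel: 23 clones with four-digit
codes, a shared-genotype triple, and expected pairwise p-distances of a
few percent. Generation: a root haplotype is drawn uniformly; each
genotype prototype mutates each character with probability `q(divergence)`
(closed-form calibrated so two *distinct* prototypes differ at the stated
rate); clones copy their genotype's prototype; ambiguity is injected
per clone (80% heterozygosity codes, 10% `n`, 10% `-`) and shared by a
clone's replicates, since both runs measure the same extract;
measurement error is then applied independently per emitted sample to
homozygous cells only. The per-copy flip probability is calibrated
(again closed form) so that the *expected mismatch rate between two
independent measurements* equals `error_rate` — naive independent
flipping at rate *e* would make replicate pairs differ at ≈ 2*e*.
A single seeded `numpy` generator drives all draws; a fixed seed gives
byte-identical panels.

What the simulator does **not** model: linkage between characters,
locus-specific ambiguity structure (real short-read panels concentrate
heterozygosity in specific columns, which makes the per-sample
ambiguity SD several-fold larger than the binomial SD the simulator
produces), allele dropout correlated with fragment size, or geographic
population structure. Passing recovery tests therefore demonstrates the
pipeline arithmetic — error calibration, ambiguity accounting,
partition recovery — not realism of any particular marker chemistry.

`recovery_report` scores inference against truth with the adjusted Rand
index of the genotype partitions plus the bias of the estimated error
rate. A documented failure mode, exercised in the tests: when true
divergence falls below the error-derived threshold, distinct genotypes
collapse and the count is an undercount.

## Numerical and degenerate-input choices

* Sample standard deviation (n − 1) throughout; SD of a single sample
  is reported as 0.
* Percent ambiguity is kept as a float; display columns round to the
  integer / two-decimal conventions of comparison tables.
* Undefined distances: NaN + refusal, never 0 (see above).
* Empty inputs, ragged alignments, out-of-alphabet symbols, non-binary
  cells, dangling replicate pointers and double recoding all raise typed
  errors with coordinates where applicable; the CLI maps computational
  refusals to exit 1 and usage/IO problems to exit 2.
* Acceptance-scale runs use panels of 23 clones with 13–10 000
  characters; every stage is O(n² · L) or better, so the whole suite
  runs in seconds on one CPU.

## Known limitations

* The binning tolerance is a gap rule, not a bin-width rule; datasets
  scored with a ±0.5 *bin-center* convention can differ on ladders of
  closely spaced fragments.
* Thresholds are compared on proportions; converting a published
  percentage threshold back to a proportion is the caller's duty
  (`ReplicateErrorEstimate` exposes both).
* The component construction gives one operational genotype count; it
  does not attribute residual clone differences to somatic mutation
  versus scoring error, and it provides no confidence interval on the
  count.
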