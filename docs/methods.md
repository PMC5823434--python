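# Methods

## Model

A domain family is observed through one paralog alignment (all members in
the reference species) and one ortholog alignment per member (the member
plus its direct relatives across species, the member's row serving as the
reference for canonical numbering). Conservation is always measured at the
level of six amino-acid equivalency groups (AVLIMC, FWYH, STNQ, KR, DE, GP):
substitutions within a group are treated as neutral, so the statistics see
physicochemical change, not raw identity.

The positional entropy exp(−Σ pᵢ ln pᵢ) is the exponential of the Shannon
entropy of group frequencies, i.e. the perplexity or effective number of
groups, ranging from 1 to the number of groups. The specific conservation
of a canonical position is the ratio of the paralog-alignment entropy to
the ortholog-alignment entropy. The implicit model is that a specificity
determinant is under divergent selection between paralogs and purifying
selection within each ortholog lineage; a housekeeping (fold) residue is
purified everywhere (SC ≈ 1 with both entropies near 1); an unconstrained
residue drifts everywhere (SC ≈ 1 with both entropies high).

## Numerical and convention choices

- **Entropy fractions.** pᵢ is taken over *counted* residues — gaps and
  ambiguity letters (X, B, Z, U, O) are excluded from numerator and
  denominator — so Σ pᵢ = 1 and the entropy is well defined whenever any
  residue is counted. The 0·ln 0 limit is 0.
- **Gap threshold.** An entropy is reported only when the non-gap fraction
  of the column is ≥ 0.64 (inclusive; on 29 rows the minimal passing count
  is 19). The same rule applies to both alignments; a position failing it on
  either side has undefined SC. Ambiguity letters count as gaps here too,
  since they contribute nothing downstream.
- **Boundaries.** The high-SC flag is inclusive (average SC ≥ 1.7, with a
  1-part-in-10¹² tolerance so that a region of exactly-1.7 values is not
  lost to floating-point rounding of the mean); the conserved-insertion
  cutoff is inclusive (ortholog entropy ≤ 3.3); the intensity sum filter is
  inclusive (≥ 1000 units retained); the specificity call is strict
  (BF > 0.5), which guarantees at most one call per peptide and species.
- **Rounding.** Tables carry full precision plus a 1-decimal display
  column. Ratios are formed from unrounded entropies, so a displayed pair
  4.5/1.2 can legitimately print alongside an SC of 3.8 (= 3.75 rounded)
  rather than 3.7.
- **Canonical numbering.** The user supplies the domain span in ungapped
  reference coordinates; reference-gap columns inside the span are labelled
  as insertions anchored to the canonical position on their left (14a, 14b,
  …), columns outside the span as N-/C-terminal flanks. Insertions are
  assigned to loops by their anchor: RT-loop 11–19, N-Src loop 29–35,
  distal loop 42–48 (configurable; the loop boundaries are a convention of
  this package).
- **PSSMs and clustering.** PSSMs count grouped residues at canonical
  columns only; all-gap positions keep zero-frequency rows so every
  domain's flattened vector shares one 360-column frame, ordered
  position-major. k-means uses 50 seeded restarts (scikit-learn); because a
  flat partition cannot draw a dendrogram, hierarchical clustering
  (average linkage, Euclidean metric) is produced alongside it, with
  Newick export and a cophenetic-distance table for comparing surface
  divergence. k defaults to 4 for both surfaces.
- **Binding summaries.** Paralog merge columns are arithmetic means. The
  best peptide of a domain maximises mean BF over species with data, ties
  broken by lexicographic peptide id; a species lacking that peptide (e.g.
  filtered there) is dropped from both numbers of the "x/y species" pair.
  Missing domains are absent columns, never zeros.

## The synthetic generator

`synthetic_data` emulates the statistical structure the pipeline detects,
not sequence evolution. Defaults mirror the study conditions: 28 paralogs,
29 orthologs per member, 60 canonical positions; housekeeping positions
planted on SI and specificity on SII (so surface-level contrasts are
testable), the rest variable. Housekeeping positions share one family-wide
group with a 2 % switch rate; specificity positions draw an independent
group per member, held within orthologs up to a 5 % switch; variable
positions redraw uniformly with probability 0.65; gaps are sprinkled at 2 %
on non-reference rows. Residues are sampled uniformly *within* a chosen
group, since every statistic in scope is group-level. These rates place
housekeeping/variable SC near 1 and specificity SC near 4–5, straddling the
1.7 line so threshold behaviour is exercised.

The binding generator plants, per domain, a uniform 0–50 specific peptides
(assigned greedily from a ~300-peptide pool until it is exhausted), sets
each planted intensity so the peptide's binding fraction sits at 0.7 with
log-normal jitter on the odds (σ = 0.1), draws background intensities
log-normal (median 120 units, σ = 1, so typical 24-domain row sums clear
the 1000-unit filter), and rescales 10 peptides below the filter. All
randomness flows from one `numpy` PCG64 generator per call, so outputs are
bit-reproducible given the seed.

What passing tests show — and do not. Recovery of planted truth
(sensitivity/specificity ≥ 0.9 for SC at 1.7; ≥ 95 % of planted binders
called) demonstrates the statistics and thresholds behave as designed under
their intended signal model. Real alignments add phylogenetic correlation
between rows, alignment error, and compositional bias; real SPOT data adds
spatially correlated noise and non-specific stickiness. None of these are
modelled, so synthetic performance bounds are not field performance claims.

## Problem sizes

Tests and examples run the full default family (28 × 29 × 60) once as a
shared fixture and smaller families (6–12 members) elsewhere; these sizes
already saturate the statistics being checked, since every estimator here
is a per-column frequency computation.

## Known limitations

- Alignment construction, ortholog retrieval and manual alignment curation
  are out of scope: alignments are inputs, and canonical maps derived from
  re-aligned data may differ from hand-curated ones.
- No significance testing is attached to SC; 1.7 and 3.3 are fixed
  heuristic cutoffs.
- Dendrogram topology depends on the (configurable) linkage choice; only
  the qualitative SI-vs-SII divergence ordering is asserted.
- Structure-based cluster interpretation and peptide motif discovery are
  not implemented.
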