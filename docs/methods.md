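# Methods

`preyid` implements a fecal DNA metabarcoding workflow for identifying the
prey of a predator — the motivating case is an endangered estuarine
elasmobranch whose diet cannot be studied by stomach-content analysis — from
amplicon sequencing of marker genes (mitochondrial 12S and 16S rRNA for
species-level fish identification; nuclear 18S rRNA for broad, class-level
screening). This note records the model and procedure, the parameters that
matter, the numerical choices, what the synthetic-data generator does and does
not emulate, and known limitations.

## Pipeline model

Per sample and marker the pipeline runs:

1. **Read merging.** Overlapping mates are merged by a maximum-score overlap
   search: the reverse read is reverse-complemented and every overlap of at
   least `min_overlap` (default 10 bp) is scored as matches − mismatches. The
   best-scoring overlap is accepted if its mismatch fraction is ≤
   `max_mismatch_frac` (default 0.1); within the overlap the higher-quality
   base wins, with the forward base breaking ties. Ties in score prefer the
   longer overlap, then the smaller start offset, so merging is deterministic.
   N bases never count as matches, and all-N reads fail (not raise). No
   statistical overlap test is performed; on amplicon data with a designed
   overlap the maximum-score criterion recovers the fragment.

2. **OTU clustering.** Merged reads are dereplicated and clustered greedily at
   fixed identity θ_c (default 0.97, applied as ≥). Unique sequences are
   processed in (abundance desc, length desc, lexicographic) order; each joins
   the *first* existing centroid at identity ≥ θ_c or founds a new OTU
   (`best_centroid=True` joins the best-matching centroid instead). This gives
   two exact guarantees checked by the tests: every member is within θ_c of
   its centroid, and every later centroid is below θ_c to *all* earlier
   centroids. Multiplicities are carried as weights, so member counts are
   conserved. OTUs with fewer than `min_otu_size` (default 5) reads are
   dropped as inconsequential, with the omitted read fraction logged.

3. **Identity definition.** Percent identity between two sequences is
   1 − Levenshtein distance / max(length). This is symmetric, lies in [0, 1],
   reduces to the familiar matches/length on equal-length sequences (50 bp
   with one mismatch → 0.98), and — because it is a function of the edit
   distance alone, not of one particular optimal alignment — is exactly
   checkable against an independent dynamic-programming oracle. Definitions
   of the form matches/alignment-columns depend on which co-optimal alignment
   a tool reports and were avoided for that reason. Threshold comparisons are
   made on the integer edit distance (d ≤ ⌊(1−θ)·L⌋ with a 1e-9 guard) so
   boundary cases like 1 edit in 50 bp at θ = 0.98 are decided exactly.

4. **Reference search.** Each retained centroid is compared against every
   same-marker reference, taking the better of the two strand orientations.
   Hits are sorted by identity (rounded to 4 decimals for tie stability) with
   `record_id` as the deterministic tie-break. No heuristic prefilter is
   enabled by default: reference sets at this scale (tens to a few hundred
   sequences) make exhaustive search cheap, and the alignment backend is C.

5. **Error calibration.** The per-base sequencing error is estimated from
   OTUs identified as the *host*, whose reference sequence is known:
   e = 1 − (member-count-weighted mean identity of host centroids to the host
   reference), and the identification threshold is θ_id = 1 − e exactly. For
   an unbiased estimate the calibration is applied to **dereplicated** host
   amplicons (every distinct sequence its own centroid, weighted by
   multiplicity; `estimate_error_from_reads`). Applying it to 97%-clustered
   OTUs instead collapses nearly all erroneous reads into a dominant
   error-free centroid and biases e toward zero; the pipeline therefore
   reports that coarser estimate in its log but identifies at the configured
   θ_id (default 0.98, the operating point at a 2% error rate) unless
   `derive_threshold=True` is set, which re-dereplicates the host reads.
   Weighting by member count (rather than unweighted centroids) makes e a
   read-level error rate. With ≥ 2,000 host reads the estimator recovers
   simulated substitution rates of 0.005–0.02 within ±0.005.

6. **Identification cascade** (12S/16S), per non-host OTU, exactly one branch:
   - unique top hit (tied hits of the *same* species count as unique) at
     identity ≥ θ_id → **similarity**, species level;
   - tied top hits of distinct species ≥ θ_id → signature-tag rescue; a
     single exact tag match → **tag**, species level; conflicting or no
     match → **lca**, the lowest taxon shared by the tied lineages;
   - top hit below θ_id → tag rescue as above, else **unidentified**;
   - any species-level call not plausible at the sampling location per the
     occurrence table is **occurrence_relegated**: the rank walk (genus →
     family → order → class → kingdom) stops at the first taxon containing a
     locally known species. If no rank qualifies the OTU becomes
     unidentified; in practice relegation stops at genus.
   Host OTUs are flagged before the cascade: an OTU is host when the host
   species appears among its tied top hits (conservative). The 18S mode skips
   the cascade and assigns the class of the single best hit, ascending to the
   next present rank when class is absent — that marker's resolution does not
   support species calls.

7. **Profiles.** Identified counts are rescaled to a fixed depth T (default
   10,000) by largest-remainder rounding, which preserves zeros and sums to T
   exactly (ties in remainder break by taxon name). The mitochondrial mode
   removes host reads first and normalizes prey counts, matching tables
   reported "after removal of host sequences"; the 18S mode normalizes
   everything and then removes host entries. Unidentified OTUs stay in the
   logs but never enter profiles. Genus-level entries are labelled
   "Genus sp.", coarser ranks "Name (rank)".

8. **Community statistics.** Bray–Curtis similarity
   s = 2·Σmin(xᵢ, yᵢ)/(Σxᵢ + Σyᵢ) on normalized counts (scale-invariant, so
   counts vs proportions is immaterial); samples without detected prey are
   removed first, and zero-total vectors are an error. Hierarchical clustering
   is agglomerative on 1 − s with average linkage (UPGMA, the
   community-ecology default; complete/single available via `method=`),
   delegated to `scipy.cluster.hierarchy.linkage`, with Newick export through
   scikit-bio. Marker concordance classifies each (sample, taxon) cell as
   both / 12S-only / 16S-only / neither and counts corroborated
   identification instances per marker.

## Signature tags

A signature tag is a length-L window (default L = 40) of a species' reference
that occurs — on either strand — in no other species' same-marker reference.
All windows of all of a species' references are tested by exhaustive
comparison against every same-length window (forward and reverse-complement)
of every other species. Among diagnostic windows the selection maximizes the
minimum Hamming distance to the closest foreign window, tie-broken leftmost:
the most mismatch-buffered tag is the one most robust to sequencing error
under exact-substring matching. If no length-40 window is diagnostic, lengths
36–44 are swept outward from 40. Species can be tagless (e.g., identical
references); that is a reported outcome, not an error. `verify_specificity`
re-scans derived (or imported) tags by plain substring search and flags any
cross-species occurrence; matching against centroids is exact (0 mismatches),
both strands, and multiple distinct matched species is a conflict with no
identification. The window-by-window distance matrices are materialized with
NumPy; for databases beyond a few hundred references per marker the scan
should be chunked (a known, unexercised limit at desk scale).

## Synthetic data

The generator provides the study conditions with known ground truth:

- **Reference databases.** Sequences are the marker amplicon region itself
  (12S-like 250 bp, 16S-like 280 bp, 18S-like 400 bp), generated by mutating
  a random per-marker root along the taxonomy tree with *exact* per-branch
  substitution counts. Branch fractions are chosen additively so that target
  pairwise divergences are met: within-genus 0.05, within-family 0.12,
  within-order 0.20 by default (divergences typical of congeneric vs
  confamilial fish marker sequences). Sibling species mutate *disjoint* site
  sets, pinning within-genus divergence at its target rather than letting
  site collisions erode it below the identifiability floor 2·(1 − θ_id);
  realized divergences are verified within ±30% (relative) of targets and
  generation fails loudly otherwise, or up front if the requested within-genus
  divergence is ≤ the floor. A host (elasmobranch-like lineage, ~30% diverged)
  and optionally an out-of-class contaminant (penaeid-shrimp-like lineage,
  for the scavenged-bait pathway) are added; both lineages are synthetic
  stand-ins. Genera are grouped pairwise into families so that within-genus,
  within-family, and within-order pairs all exist.
- **Samples.** Read counts are multinomial over (host_fraction, prey
  fractions); defaults emulate host-dominated feces (host fraction 0.5,
  5,000 reads, ε = 0.01). Substitutions at rate ε are applied once per
  molecule and both mates are cut from the mutated fragment with an exact
  `overlap` (default 50 bp), so mates agree in the overlap and the merged
  read's per-base error is exactly ε. Qualities are constant high ("I");
  quality modelling is out of scope. Truth tables count exactly the emitted
  reads, and read order is shuffled so it carries no signal. Everything is
  deterministic given the seed.
- **Bait contamination** replaces each prey read independently with
  probability f by a read drawn from the out-of-class reference, updating the
  truth table, to exercise the 18S class-level pathway.

Not emulated: PCR/primer bias (per-marker capture differences are left as a
free experiment parameter rather than asserted), chimeras, indel sequencing
error (substitution-only by default), length variation among amplicons, and
cross-contamination. Passing tests on this generator therefore demonstrate
the *pipeline logic* — clustering guarantees, threshold calibration, cascade
behaviour, profile arithmetic — not robustness to those real-data artifacts.

## Test and acceptance problem sizes

The test suite exercises the estimator at 2,000 host reads × 20 seeds per
error rate, and end-to-end recovery on 12-species communities (3 orders × 2
genera × 2 species) at 5,000 reads × 20 seeds; `scripts/acceptance.py` uses
10 replicates per marker plus a 10-database tag-specificity scan. These sizes
give stable statistics (binomial bounds at 3 SD; ±0.005 error tolerance) while
keeping a full run in minutes on one CPU.

## Known limitations

- Greedy first-match clustering is order-dependent by design (the order is
  fixed and documented); it is not a denoiser, and ASV-style resolution is out
  of scope, as is chimera detection.
- Global identity assumes reference sequences span the amplicon region;
  identities against much longer references are not meaningful. References
  should be trimmed to the amplified locus.
- The occurrence relegation walk requires occurrence species to be present in
  the reference taxonomy; unknown species are ignored in the plausibility
  check.
- Secondary predation (prey-of-prey DNA) is indistinguishable from primary
  prey, as in any metabarcoding diet analysis.
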