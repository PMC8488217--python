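# Methods

## Problem setting

Circulating tumor cells (CTCs) sampled from peripheral blood carry the
genomes of disseminating tumor clones. Comparing the somatic mutation
profile of pooled 10-cell CTC tubes against a patient's primary tumor (PM)
and progressive lesions (PG: lung tumor re-biopsy, lymph node, or malignant
pleural effusion / hydrothorax) asks which lesion the blood-borne clone
resembles. The measurement is hard because 10-cell input requires
whole-genome amplification (WGA) before exome capture, which introduces
allelic dropout (false-negative calls), amplification false positives,
and uneven coverage. The package implements the full decision procedure
that turns per-sample variant calls plus read counts into comparable
somatic mutation sets, and the set analytics on top of them.

## Bulk somatic filter (tumor vs WBC)

A tumor variant is somatic when all of the following hold, with thresholds
as strict inequalities:

* protein-altering effect (nonsynonymous SNV, stop gain/loss, frameshift
  or in-frame indel, splicing) and VAF > `vaf_min` (default 0.03), relaxed
  to VAF > `hotspot_vaf_min` (default 0.01) at sites on a user-supplied
  cancer-hotspot list;
* tumor/normal VAF ratio > `vaf_ratio_min` (default 5). "Normal" is the
  matched WBC control; a normal VAF of zero, or a site never called in the
  normal, counts as an infinite ratio. An alternative reading of the
  ratio — alt reads over ref reads within the tumor — is available as
  `ratio_definition: alt_over_ref_in_tumor`;
* Fisher exact test of (alt, ref) reads tumor-vs-WBC with
  p < `fisher_p_max` (default 0.01), two-sided by default
  (`fisher_sidedness: one_sided` switches to greater-in-tumor). When the
  normal sample did not call the variant but assayed the site, its
  (ref, alt) read counts come from the readcount matrix; a site the
  normal never assayed skips the test (infinite-ratio convention).

TMB is the count of protein-altering somatic variants divided by
`coding_region_mb`. The denominator is not derivable from a variant table;
it defaults to 35 Mb (a common whole-exome coding footprint) and is
configurable and echoed into every report.

## CTC cascade

Replicate 10-cell tubes are first merged — union of calls by default
(`ctc_replicate_merge`: union / intersection / majority), keeping for each
variant the replicate call with the most alt reads. The merged calls then
pass the protein-altering effect filter and (by default,
`apply_vaf_rule_to_ctc: true`) the same VAF rule as bulk samples, then
four subtractive/concordance filters in a fixed order, each audited with
input/removed/output counts:

1. drop variants present in the population polymorphism site list
   (1000 Genomes / ExAC-style membership, exact chrom,pos,ref,alt match);
2. drop variants inside blacklisted genomic regions (BED, 0-based
   half-open; variants are 1-based and the conversion happens in exactly
   one function);
3. drop variants called in any WBC control of any type (pooled 10-cell
   oligo-WBC or bulk WBC);
4. keep only variants present in the union of the patient's PM/PG somatic
   sets (patients without a primary sample use PG alone).

Steps 1–3 are commuting set subtractions; the fixed order exists only so
audit counts are comparable across patients.

### Rescue of missing tumor variants

Tumor variants absent from the merged CTC call set are re-examined in the
CTC read counts (the BAM-derived evidence, pooled across replicate tubes).
Each receives exactly one verdict:

* `not_assayed` — no CTC tube covered the site (absent from the readcount
  matrix, which distinguishes "not assayed" from "assayed, zero alt");
* `rescued` — alt reads ≥ `rescue_min_alt_reads` (4) and Fisher
  p < `rescue_keep_p_max` (0.01): accepted as a true CTC mutation;
* `dropped_low_coverage` — p > `rescue_drop_p_min` (0.05): the absence is
  compatible with coverage, the variant is removed;
* `indeterminate` — everything between, including strong p with fewer
  than 4 reads. Indeterminate variants are excluded from the final set
  but reported, so ambiguous evidence is never silently promoted.

The 2×2 contrast for the rescue test is configurable. The default
(`rescue_contrast: wbc_background`) tests the CTC (alt, ref) counts
against the pooled oligo-WBC counts at the same site — a
presence-above-background test under which "keep if p small" is coherent.
The literal alternative (`tumor_literal`) contrasts CTCs against the
pooled tumor samples; it is provided because the procedure is sometimes
described that way, but a small p then indicates *discordance* with the
tumor, which sits awkwardly with a keep-if-significant rule, so it is not
the default. If the contrast site was never assayed, the test falls back
to a zero-alt background with the same total reads as the CTC entry
(matched-depth null); this case cannot arise when WBC readcounts cover
the queried sites, as the simulator guarantees.

The final CTC somatic set is (surviving calls) ∪ (rescued variants); the
two parts are disjoint by construction.

## Fisher exact test

Implemented by direct summation over the hypergeometric support in log
space (gammaln), so cells up to ~10^6 reads neither overflow nor lose the
exactness that matters: on every table with both row sums ≤ 25 the p-value
agrees with exact integer enumeration to ≤ 1e-9 (the test suite checks
this exhaustively). The two-sided p sums all tables whose point
probability is ≤ the observed one with relative tie tolerance 1e-7, and
the input table is canonicalized under row/column swaps first so the
p-value's swap symmetry holds bit-exactly. Confidence intervals on
fractions are exact Clopper–Pearson via beta quantiles.

## Concordance analytics

* 7-region Venn partition of (PM, PG, CTC) sets, computed at variant
  identity level and, separately, at gene-symbol level (recurrently
  published Venn counts are often gene-level; both units are always
  reported and stamped).
* Shared proportions |A∩B|/|denominator| are reported under **both**
  denominators for every pair, because a "shared proportion" is ambiguous
  until its denominator is fixed; nothing downstream guesses.
* The cohort triple-overlap summary pools counts
  (Σ|PM∩PG∩CTC| / Σ|PM|, and /Σ|PG|) rather than averaging ratios;
  patients missing a set are excluded from that pool.
* TMB trajectory is the sign of TMB(PG) − TMB(PM), exact equality mapping
  to "unchanged".
* The recurrence matrix ranks genes by the number of (patient, sample
  role) cells carrying a mutation, ties broken lexicographically.

## Screening

Gene-symbol-level (case-insensitive) matching of the final variant sets
against three resources: a PharmGKB-shaped drug–gene association table, a
catalogue of 10 oncogenic signaling and 10 DNA-damage-repair pathway gene
lists, and a free-text annotation table searched for "stem cell" keywords
(lowercased, hyphens collapsed to spaces, whitespace normalized, so
"Stem-cell" matches). Bundled lists are small illustrative defaults —
enough to exercise every code path and cover the genes a lung-cancer
cohort plausibly recurs in; real resource releases are drop-in TSV inputs
and are never downloaded at build or test time. Stem hits are flagged
"candidate": the literature-curation step that would confirm them is a
manual process outside the package.

## Synthetic cohort generator

The generator is the package's study-conditions definition, not a test
convenience dial. Per patient (one independent RNG stream per
(seed, patient index), so cohorts extend without perturbing existing
patients):

* PM truth: `n_truth_variants` (default 200) variants with VAF drawn
  uniformly from `tumor_vaf_range` (default 0.05–0.6); a
  `hotspot_fraction` (default 0.02) of truth variants instead get VAF in
  0.015–0.03 and a hotspot flag, so the relaxed hotspot rule is load-bearing.
* PG truth: each PM variant enters PG with probability `pm_pg_overlap`
  (default 0.4, inside the 16.7–76.9% per-patient overlap range such
  cohorts show), topped up with fresh private variants to the same size.
* CTC truth: each PG variant with probability `ctc_from_pg`, each
  PM-private variant with probability `ctc_from_pm` (default 0.05), plus
  Poisson(`ctc_private`·n) fresh private variants. Because PM-private and
  PG draws are disjoint, `ctc_from_pg` **is** the expected |CTC∩PG|/|PG| —
  the quantity the pipeline estimates.
* Observation model: depth per (sample, site) is negative binomial
  (per-role means, default 250 for tumors, 100 for CTC tubes, 150/200 for
  oligo/bulk WBC; dispersion 5 — a two-parameter model chosen as the
  simplest mechanism that yields genuinely uncovered sites for the rescue
  path). Alt reads are binomial(depth, VAF); absent alleles sample the
  sequencing error rate (1e-3). Zero depth ⇒ the site is absent from the
  readcount matrix ("not assayed").
* WGA artifacts, CTC tubes only: per-site-per-tube allelic dropout with
  probability `wga_dropout` (default 0.1 — a 10-cell pool attenuates the
  much higher single-cell dropout), Poisson(`wga_fp_rate`, default 10)
  false-positive variants per tube, a fixed 20% of which also leak into
  the oligo-WBC control (same amplification chemistry). Germline leakage
  (`germline_rate` 0.05) appears in every sample at VAF 0.5 and is listed
  in the emitted population database; alignment artifacts
  (`blacklist_rate` 0.02) appear in CTC tubes at positions covered by the
  emitted blacklist BED.
* Caller model: a variant is called when alt ≥ 2 and alt/depth ≥ 0.02;
  CTC calls additionally survive with probability `caller_sensitivity`
  (default 0.9). The sensitivity term is what makes the rescue step
  exercisable at all — a variant can be missing from the call set while
  its reads sit in the readcount matrix, exactly the situation the rescue
  rule re-examines. Error-level read support is emitted as calls only in
  WBC samples (labelled artifacts); bulk tumor callers are assumed to
  suppress it.

Every observed call carries one truth label (true_somatic, germline_leak,
blacklist_artifact, wga_false_positive, wbc_artifact), so filter
performance is measurable exactly. What the generator does **not**
emulate: mutational signatures, clonal phylogenies, copy number, FFPE
deamination damage, mappability-correlated coverage, or read-level data.
Passing tests therefore demonstrate that the decision procedure is
implemented correctly and behaves as designed under a faithful error
*structure*, not that the thresholds are optimal for any particular real
data set.

## Numerical and design choices

* Variant identity is literal (chrom, pos, ref, alt); indels are
  VCF-style left-anchored and no normalization is applied, keeping
  identity reproducible without a reference genome.
* Set filters and reports are pure functions of their inputs; every
  writer sorts rows (patient, then genomic coordinate), so identical
  inputs give byte-identical files.
* The effect vocabulary is closed at 8 classes; upstream annotator
  strings map through a shipped, overridable table.
* Degenerate inputs fail loudly: all-zero Fisher tables, empty
  denominators, unknown roles/classes and malformed rows (reported with
  line numbers) raise typed errors; an empty WBC control list is allowed
  for the WBC filter itself (identity, with a warning path at the
  pipeline level) but a patient without any WBC control cannot be run.

## Problem sizes used in the checks

The verification suite runs cohorts of 6–20 patients with 120–200 truth
variants per patient (seconds per cohort on one core): exhaustive Fisher
oracle comparison over all ~123k tables with row sums ≤ 25; exact
end-to-end recovery in the noise-free limit (all artifact rates zero,
depth 500); recovery of configured sharing fractions (0.30
hydrothorax-like vs 0.05 lymph-like) within ±0.05 under default noise;
and rescue-rate agreement with a 10,000-draw Monte-Carlo oracle at depth
80 / dropout 0.2 with single CTC tubes (single tubes make caller misses
observable; with triplicate tubes a simultaneous miss is ~10^-3 and the
rescue path almost never fires, which is why the default cohort's audit
shows zero rescues).

## Known limitations

* The rescue contrast ambiguity is resolved by configuration, not by
  evidence; both readings are implemented and logged.
* Gene-level screening ignores allele-level drug annotations unless an
  allele-resolved database is supplied.
* The pooled-tube model treats 10 cells as one homogeneous DNA source;
  within-tube clonal heterogeneity is not modelled.
* Cohort-level inputs (population database, blacklist) are taken as
  given; the package never attempts to re-derive them.
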