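# Methods

## The assay model

The package models a two-marker PCR-RFLP identification assay for
freshwater eels on a linear DNA molecule with 0-based, half-open
coordinates (a cut at position *i* separates `[0, i)` from `[i, len)`;
user-facing reports are 1-based).

**Amplification.** Primer binding sites are found by IUPAC-compatible
string matching (two codes are compatible when their base sets intersect);
the reverse primer, written 5'→3' on the opposite strand, binds where its
reverse complement occurs on the template top strand. The product spans
from the first base of the forward site to the last base of the reverse
site, primers included; when several pairings exist the shortest product is
taken, mimicking the dominant PCR product. Mismatch tolerance defaults to
zero (configurable per primer pair); products longer than
`max_product_length` (default 5000 bp) are rejected. No thermodynamics:
annealing temperature, efficiency and multi-product competition are out of
scope.

**Digestion.** Every recognition-site window contributes exactly one
double-strand cut: a window matching the motif in forward orientation cuts
at `start + cut_offset`; a window matching only in reverse orientation cuts
at `start + len(motif) − cut_offset`. This one-cut-per-window rule matters:
both default motifs (HinfI `GANTC`, PauI `GCGCGC`) are their own IUPAC
reverse complements, so naively scanning both strands with the forward rule
would report every site twice at two different offsets and corrupt every
fragment profile. Reverse-orientation scanning is on by default and only
affects asymmetric user-defined motifs. Overlapping occurrences are all
reported; cuts at the molecule ends are no-ops and dropped.

**The gel.** Two parameters model scoring bands on a 2% agarose gel:

| parameter | default | units | rationale |
|---|---|---|---|
| `visibility_threshold` | 100 | bp | the diagnostic profiles imply a 70 bp fragment that is never scored and a 117 bp fragment that always is; 100 bp sits between them and matches the smallest ladder rung |
| `band_tolerance` | 0.05 | relative | gel sizes are read off a ladder to roughly ±5%; observed and expected bands match when every size pair agrees within this fraction, compared in descending order with equal cardinality |

Enzyme definitions (REBASE motifs), primers and both gel parameters live in
an editable YAML configuration, not in code.

## Classification

Per-marker band profiles are matched against the canonical patterns
(cytb: {350}, {280}, {164,117}; 18S: {412}, {245,167}) within the band
tolerance; anything else is `OTHER`. The two marker states combine through
an exhaustive 4×3 decision table; concordant patterns yield a species,
`CUT_280`/`UNCUT_412` yields "saltwater eel or hybrid" (the two are
indistinguishable on the gel), `UNCUT_350`/`CUT_167_245` yields "putative
introgressed hybrid" (European mtDNA over an American nuclear background),
and any `OTHER` — including the biologically unexpected Japanese-mtDNA /
American-nucleus combination, and putative heterozygous three-band 18S
patterns — maps to `UNRESOLVED`. Every call except a positive
*A. rostrata* carries `SEQUENCING_REQUIRED`.

**Sequence confirmation** replaces a remote BLAST search with
nearest-reference assignment against a local panel: percent identity is the
fraction of matching positions, computed ungapped for equal-length
sequences and over an end-gap-free global alignment otherwise (internal
indel columns count as mismatches; dangling ends are ignored). A flagged
call is confirmed when the best panel taxon agrees with the RFLP call at
identity ≥ 0.98 (configurable); a saltwater-or-hybrid call is resolved to
saltwater only by a non-*Anguilla* best hit and is never silently
relabelled when the hit is *A. rostrata*.

## Survey statistics

The denominator is always the freshwater-labelled subset; a label
containing "anago" or "saltwater" marks a sample as saltwater-labelled and
excludes it. On the bundled manifest this gives 134 of 137 samples, and a
grocery denominator of 24 (three of the 27 grocery samples are
saltwater-labelled).

* **Bootstrap SD**: resampling n binary indicators with replacement makes
  each replicate success count Binomial(n, k/n), so replicates are drawn
  from that distribution directly; the statistic is the sample SD (ddof=1)
  of B = 1000 replicate proportions, as a percentage. Deterministic given
  the seed; the seed is recorded in every estimate.
* **Wald interval**: margin = z·100·√(p̂(1−p̂)/n) with z(0.95) = 1.959964.
  Reported percentages are rounded to one decimal, and the interval
  endpoints are formed from the *rounded* point estimate and margin
  (5.2 − 3.8 = 1.4) so that printed values are self-consistent; full
  precision is kept internally (`p_exact`). A bootstrap-percentile interval
  can be formed from the replicates if preferred.
* **GLM**: binomial (logit) models fit by IRLS via statsmodels; the test
  statistic is the deviance difference between the intercept-only and
  single-predictor fits on (levels − 1) degrees of freedom. Four states
  with 1–3 samples each (IL, NV, NY, TX) are excluded for *both* predictors
  so the two tests see the same N. On the bundled manifest that N is 124;
  the survey's published analysis reports N = 123 with X² = 3.70 (state)
  and 1.69 (retail type), a one-record discrepancy that cannot be
  reconciled from the published table, so the package asserts the
  qualitative conclusion (both predictors non-significant; we obtain
  X² = 3.11, p = 0.54 and X² = 1.67, p = 0.43) rather than those exact
  statistics.

**Trade check.** The legally-permitted fraction is
100 × Σ(permitted kg)/Σ(imported kg) over an inclusive year range (default
2019–2021; study-period aggregates 265,500 / 16,795,248 kg = 1.6% ship as
constants, with CSV schemas for full ledgers). Consistency means the
fraction lies inside the survey's CI, endpoints included.

## Synthetic data

The generator's defaults *are* the study conditions. Reference "sequences"
are uniformly random A/C/G/T (GC fraction configurable) of the published
amplicon lengths — 350 bp cytb, 412 bp 18S (the published text once says
417 bp for 18S; 412 matches its own table and PCR description and is
adopted) — with exact primer sites at both ends, recognition sites planted
to reproduce each taxon's diagnostic fragment multiset exactly
({280,70}, {117,164,69}, {350}; {167,245}, {412}; the saltwater outgroup
mirrors its observed gel behaviour: cytb cut to a visible ~280 band, 18S
uncut), and all unintended occurrences of either motif, both orientations,
scrubbed by bounded resampling. Real primer sequences are not published
(names only), so verified motif-free synthetic 20-mers stand in via the
config. Generation is deterministic given the seed; the generator refuses
to emit a sequence whose rescanned cut positions differ from the plan.

Surveys draw species per stratum from a known mixture; hybrids take cytb
bands from the maternal parent and 18S bands from the nuclear parent. Band
sizes are perturbed multiplicatively with Gaussian noise (default SD 2%,
truncated at ±3 SD, rounded to integer bp) to emulate ladder-based sizing
error; near-threshold bands can optionally drop out. The left-to-right
fragment order within an amplicon is not asserted anywhere — only the
multiset — since the published material fixes only the sizes.

What the synthetic data does *not* emulate: real sequence divergence
between taxa follows a phylogeny, whereas panel sequences are independent
random draws (inter-taxon identity ≈ 75%, far below real congeners); there
is no partial digestion, star activity, heteroplasmy, or chromatogram
noise. Passing tests therefore demonstrate the correctness of the
scanning/digestion/classification/statistics machinery under the assay's
idealised band model, not robustness to real sequencing artefacts.

## Numerical and design choices

* Percentages print at one decimal; internal arithmetic is double
  precision. Band lists compare in descending order.
* All randomness flows through `numpy.random.default_rng`; stratified
  reports derive per-stratum seeds deterministically from one master seed,
  and JSON reports embed the configuration hash and seed, so identical
  inputs give byte-identical reports.
* Parameter-recovery checks (200 simulated surveys at n = 134, true
  frequency 5.2%) run noiseless: they validate the estimator and interval
  coverage; noise robustness is exercised separately. Problem sizes in the
  test suite (200-replicate oracle sweeps, 10⁵-replicate bootstrap
  convergence) were chosen to make the checks statistically meaningful
  while keeping the suite quick.
* Degenerate inputs fail loudly: empty strata, zero import mass,
  unclassified records, constant GLM predictors, non-converging fits and
  fixture checksum mismatches all raise typed errors rather than returning
  defaults.

## Known limitations

* The classifier's `OTHER` catch-all treats any novel band pattern —
  including a genuine F1 hybrid's putative three-band 18S profile — as
  unresolved; it never guesses beyond the decision table.
* Wald intervals undercover for very small k; the bootstrap-percentile
  alternative mitigates but does not eliminate this at k ≤ 2.
* The trade comparison treats import and permit masses as commensurable
  totals; storage lag between import and retail is only approximated by
  widening the year range.
* Enzyme scanning is exhaustive O(n·m) per window class; adequate for
  amplicon-scale inputs, not optimised for genomes.
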