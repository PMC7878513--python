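# Methods

`beecaste` implements the three statistical analyses used to compare
nurse and forager workers across eusocial bee species — cross-species
overlap of differentially expressed (DE) gene sets, taxonomic-conservation
classification of orthogroups, and context-resolved gene-body DNA
methylation — together with the minimal Gene Ontology machinery those
analyses need and synthetic-data generators that reproduce the statistical
structure of the real inputs. This note records the models, the defaults
and why, the numerical choices, and what the synthetic conditions do and do
not establish about real data.

## Cross-species DE overlap (`beecaste.overlap`)

**Model.** Species are compared through free-text protein annotations, not
sequence: each species contributes the set of *normalized, unique,
non-redundant* annotation terms of its DE superTranscripts, and a term
universe — the normalized annotations of its full annotated transcriptome.
Normalization lowercases, collapses whitespace, deduplicates, and removes
empty strings and any annotation containing "uncharacterized protein"
(placeholder hits carry no cross-species information). The observed statistic
is the size of the term-set intersection. The null redraws each species' DE
set size uniformly without replacement from that species' own universe
(`universe_mode="per-species"`, the default; `"shared"` draws both sets from
the union universe and makes the null exactly hypergeometric, which the test
suite uses as a closed-form oracle). The empirical one-sided p-value is
`(#{draws >= observed} + 1) / (reps + 1)`, so it is never 0; with the
default `reps = 10,000` the smallest reportable p is ~1e-4.

**Curation.** Reported shared-term lists are additionally filtered by an
editable list of literal substring patterns (shipped defaults:
"transposase", "transporter", "cytochrome c oxidase subunit") that flag
partial or redundant annotation matches. Curation affects only the reported
list; the resampling statistic always uses the uncurated computational
overlap. Term matching is exact string equality after normalization — the
curation pattern list is the explicit, reproducible stand-in for manual
review, and no fuzzy matching is attempted.

**Calibration and discreteness.** The overlap statistic is integer-valued,
so the `(+1)/(reps+1)` convention with a `>=` tail is conservative by
construction (under a null comparison the mean reported p is slightly above
0.5). `OverlapResult` therefore also carries `p_value_randomized`, the
standard tie-randomized empirical p, which is exactly Uniform(0,1) under an
exchangeable null. It exists for calibration diagnostics — the test suite
KS-checks its uniformity over 500 null comparisons and verifies the reported
p is never anti-conservative — and is never used to declare significance.

**Stratification.** `stratified_overlap` runs the test for the full DE
sets and separately for the nurse-biased and forager-biased subsets, with
per-stratum seeds derived from the caller's seed. Direction of bias is fixed
at table-reading time from the declared logFC orientation (default:
positive logFC = forager-biased) and stored on every record, so downstream
code never re-infers sign conventions.

**Open choice.** Whether the original universes were all superTranscripts
or only annotated ones is not derivable; normalization drops unannotated
entries, so universes here are annotated-only.

## Taxonomic-conservation classifier (`beecaste.txr`)

**Model.** Orthogroups inferred over 11 datasets — nine NCBI proteomes
(*A. cerana*, *A. mellifera*, *B. impatiens*, *B. terrestris*,
*E. dilemma*, *E. mexicana*, *F. varia*, *M. quadrifasciata*, plus the
*H. laboriosa* outgroup) and the two study transcriptomes (*B. terrestris*,
*T. angustula*) — are assigned to conservation categories purely from their
presence/absence pattern. Rules are data: an ordered list of predicates
over datasets and named clades, evaluated first-match-wins with a guaranteed
`other` catch-all, so every pattern maps to exactly one category and the
contested class boundaries can be edited in a TOML file without touching
code (`examples/config/rules.toml` reproduces the shipped defaults).

**Shipped interpretation.** Most-conserved rules first: `apinae` requires
presence in all 11 datasets; `corbiculates` presence in at least one member
of each of the four corbiculate clades with the outgroup absent;
`social_corbiculates` likewise over bumblebees, honeybees and stingless
bees with orchid bees and the outgroup absent. The species-level classes
are exclusive (absent everywhere their predicates do not reference):
`bumblebees` = *B. impatiens* plus at least one *B. terrestris* dataset;
`stingless_bees_f` = all three stingless-bee datasets;
`stingless_bees` = *M. quadrifasciata* + *T. angustula* with *F. varia*
ignored; `bterrestris_g` = both *B. terrestris* datasets;
`species_specific_*` = exactly one focal transcriptome. The published
verbal definitions of `bterrestris (G)` and `species-specific` overlap
("may or may not occur in the proteome" vs "only in the B. terrestris
datasets"); the shipped rules make them disjoint by requiring the proteome
present for `bterrestris_g`. This is this package's interpretation, not an
assertion of the original authors' intent — edit the rule file to explore
the alternative reading.

**Unassigned genes.** Genes the orthology inference left unassigned are
treated as probable assembly/annotation artifacts: `exclude_unassigned`
removes them from focal gene lists with an audit line (counts and
percentages), and `category_proportions` reports two proportion vectors
(whole matrix vs focal orthogroups), each summing to 1 within 1e-12.

## Methylation analysis (`beecaste.methylation`)

**Space and units.** All statistics live in transcript space (bisulfite
reads mapped to superTranscripts, not a genome), with 1-based CGmap
coordinates. Cytosine dinucleotides are collapsed to CG, CW (= CA or CT)
and CC; the three classes partition all defined C sites, so compositions
close to 100%.

**Pipeline.** Sites under the coverage threshold (default 10x) are dropped
first and never reach any statistic. The *context census* counts C sites on
both strands of the reference: a plus-strand C at position i is classified
by the base at i+1; a plus-strand G is a minus-strand C classified by the
complement of the base at i-1; sites whose partner base is N/ambiguous or
off the sequence end go to an "undefined" bucket excluded from the
denominator. A site is called *methylated* when it has at least one
methylated read (the simplest reading of "methylated cytosines reported");
an alternative one-sided binomial call against a bisulfite non-conversion
error rate (default 0.005, alpha 0.01) is available behind a flag.

**Per-transcript mC.** `mean_mC` is the unweighted arithmetic mean of site
levels (in percent) over all covered C sites of a transcript — the
coverage-weighted alternative `weighted_mC` (total methylated reads over
total coverage) is always computed alongside, since the two can differ
sharply when coverage is uneven and the original choice is not stated.
Set-level means average `mean_mC` over transcripts.

**Tests.** `cg_enrichment_test` draws, per replicate, the observed number
of methylated sites from the census context distribution and records the CG
fraction; the one-sided empirical p uses the same `(+1)/(reps+1)`
convention as the overlap test. `subset_mean_ztest` treats the
transcriptome-wide per-transcript `mean_mC` distribution as the population
(known mu and sigma): z = (x̄_sub − mu)/(sigma/√n), one-tailed normal p,
95% CI on the subset mean, and the percent difference from the global mean.
The default tail (`auto`) follows the sign of the observed difference,
matching how "significantly different from the global mean" is used in
practice; note this sign-picked rule is a two-sided procedure of size
2·alpha, so calibration checks fix the tail. A Welch two-sample t-test is
not offered — the population-reference z is the procedure being modeled.
`methylation_expression_correlation` computes Spearman's r_s (average
ranks on ties, via scipy) between per-transcript context mean mC and the
supplied normalized read counts, separately for CG and CW, over the whole
transcriptome or a designated subset, with listwise NA removal and n >= 3
required.

## GO tools (`beecaste.go_tools`)

Only `is_a` edges are traversed. Annotation propagation is the true-path
ancestor closure (idempotent; roots included). Enrichment is the classic
one-sided Fisher test — the hypergeometric tail P(X >= k) for the study
set against the transcriptome background — reported as raw p-values with
a p < 0.01 convention and **no multiple-testing correction**, mirroring how
such scans are conventionally reported; weighted/decorrelated variants are
out of scope. Term depth counts the root as level 1 and uses the shortest
is_a path by default (`longest` available), a documented convention since
"GO level" is otherwise ambiguous. `rollup_level` summarizes all terms at a
given depth with (gene count, mean logFC), assigning a gene to every
level-k term in its closure (not a single best one). `induced_subgraph`
returns the ancestor-closed node set and its is_a edges; closure makes it
stable under re-induction, which is what lets enriched-term subgraphs of
different species be compared on shared parents.

## Synthetic data (`beecaste.synthetic`)

Every generator is a pure function of (params, seed): identical seeds give
byte-identical outputs, and every generator emits a truth table sufficient
to score the estimator it feeds.

**Methylome.** C sites are planted as unambiguous dinucleotide tiles
separated by A/T spacers (no cytosine on either strand of a spacer), so the
realized both-strand context census equals one global multinomial draw over
all planted sites; CG sites are palindromic pairs, as in real DNA, so the
drawn CG count is rounded to even (a <=1-site perturbation in ~25,000). The
default context mix plants 23.14% CG (the bumblebee availability;
a 15.44% stingless-bee preset is provided), with the non-CG mass split
40/20/40 over CA/CC/CT — an AT-rich insect transcriptome. Methylation is
sparse and CG-enriched: per-context site methylation probabilities default
to CG 0.15, CW 0.02, CC 0.01, scaled per transcript by independent
Gamma(4, 1/4) propensities (mean 1) for CG and for non-CG, which create the
between-transcript variance that expression can couple to. A methylated
site's level is Beta(5,1) (high — gene-body mC is bimodal); unmethylated
sites emit zero methylated reads. Coverage is negative binomial (mean 30,
dispersion 0.3, i.e. variance = mean + 0.3·mean²), making the 10x filter
consequential (~8% of sites drop at the defaults). Methylated read counts
are Binomial(coverage, level) and the printed level is the rounded ratio,
exactly as an upstream caller would emit. Normalized expression is
log-normal with slope 1 on the standardized CG propensity and unit log-noise
— a positive CG coupling and no CW coupling, the sign pattern reported for
real worker methylomes.

**What the methylome generator does not model:** read-level bisulfite
conversion, non-conversion error (unmethylated sites report exactly zero),
sequence composition beyond dinucleotide tiles, spatial clustering of mC
along a transcript, and batch structure. Passing recovery tests therefore
shows the *statistics* are computed correctly at realistic signal levels,
not that the pipeline is robust to alignment or conversion artifacts.

**DE pair.** Two annotated DE tables over partially shared term universes
(defaults: universes of 1,000 terms sharing 600; DE sets of 100 and 50
terms) with an exactly planted overlap (default 15, matching the scale of
the published bumblebee/stingless-bee comparison) whose subcaste bias is
identical in both species, so stratified overlaps are exact by
construction. Planted and filler terms are drawn so the pair is an exact
draw from the conditional null given the overlap — drawing the planted k
from the hypergeometric null therefore reproduces the null exactly, which
is what the calibration suite does. DESeq2-style count simulation is out of
scope; tables are simulated at the results level, without batch effects.

**Orthogroups.** Presence patterns are generated per requested category
from recipes that satisfy the shipped rules by construction (the
`corbiculates` recipe randomly thins one clade to a single member to
exercise the any-of-each reading), with 1–2 genes per present cell and
configurable per-dataset unassigned gene lists. Default counts plant all
nine categories.

**Ontology.** A layered is_a tree (4 levels, branching 3), genes annotated
to 1–3 random leaves, and a study set drawn without replacement with weight
`enrichment_odds` (default 8) on genes under one planted level-3 term; odds
of 1 yield an exact null draw used for type-I calibration.

## Pipeline and reproducibility (`beecaste.pipeline`, CLI)

One global seed is expanded into per-stage streams with
`numpy.random.SeedSequence(entropy=seed, spawn_key=(stage,))`, so adding or
removing a stage never perturbs another stage's draws; all derived seeds
stay below 2^31. Every report embeds its seed, rep count and thresholds;
the run manifest records the config snapshot, SHA-256 input digests,
per-stage outputs and the package version, and identical manifest inputs
reproduce byte-identical reports. The `beecaste` CLI is a thin wrapper over
these functions (exit codes: 0 ok, 2 validation error, 3 data error).

## Problem sizes used in the test suite

The suites run at deliberately modest sizes chosen to make every
statistical check sharp: methylome recovery uses 500 transcripts (~25,000 C
sites, giving a 99% binomial band of about ±0.7 percentage points on the
census); overlap calibration uses 500 null comparisons over a 1,500-term
shared universe with 300-term DE sets and 300 resampling draws; z-test
calibration uses 1,000 subsets of 30 from a 2,000-transcript population;
Fisher oracles enumerate hypergeometric tails exactly up to N = 200. These
are the package's standing study conditions, not tuning knobs: the
generator defaults were fixed first and the acceptance surfaces measure
recovery under them.

## Known limitations

- Annotation-text matching across species inherits every bias of the
  underlying annotation databases; orthology-aware matching is deliberately
  out of scope for the overlap test (the published comparison is
  annotation-based).
- The reported empirical p cannot be below 1/(reps+1); published tables that
  print "p = 0" correspond here to p = 1e-4 at the default reps.
- The conservation classifier encodes one defensible reading of verbally
  ambiguous category definitions; alternative readings are a rule-file edit
  away but change the category counts.
- The z-test treats the transcriptome distribution as a known population;
  with small global sets this understates uncertainty.
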