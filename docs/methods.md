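# Methods

## Seed model

A seed window is a 1-based, inclusive interval on the mature miRNA read
5'→3': `(start=2, length=6)` is the minimal "2–7" seed, `(2,7)` the "2–8"
and `(1,8)` the "1–8" window. Sequences are uppercased and T→U normalized
at ingest, because public FASTA files mix DNA and RNA conventions; any
character outside `{A,C,G,U}` is an error in a miRNA and a non-matching
position in a transcript (ambiguity codes such as N never match —
deliberately conservative).

A *site* for a seed is a transcript window of the same length that pairs
antiparallel: seed position `i` faces window position `L−i+1`. Every
position must pair Watson–Crick, except that in wobble mode up to
`max_wobbles` positions may form the G:U pair (seed G opposite site U, or
seed U opposite site G). With wobbles disabled the unique accepted window
is the seed's reverse complement, and the scanner reduces to substring
search. This orientation of the wobble rule gives the sequence-level
theorem the tests exercise: substituting C→U (or A→G) in a seed turns every
exact site into a one-wobble site, which is exactly the miR-147b → miR-147a
relation (U instead of C at seed position 5).

Site coordinates are region-local, 1-based and closed. `distance_to_stop`
is `start − 1` for 3'UTR sites (position 1 = first base after the stop) and
`−(region_length − start + 1)` for CDS sites. Overlapping sites are
reported separately, but predicted target sets are set-valued: one
membership per transcript regardless of site count (enrichment is
set-based). Scanning each seed class independently can double-report a 2–7
site inside a 2–8 site; `longest_class_only` merges class tables keeping
the longest class per covered window, for callers that want one class per
pair. A TargetScan-style requirement of an A opposite miRNA position 1 is
available (`require_t1a`) but off by default — the default search is plain
complementary matching.

### Pairing extent and 3'-supplementary pairing

Given a matched site, pairing is extended outward position by position in
the register fixed by the seed (miRNA position `m` faces region position
`site.start + seed_end − m`), stopping at the first non-pairing position on
each side; wobbles extend the duplex only when explicitly allowed. The
miRNA 5'-terminal nucleotide is sequestered by Argonaute's MID pocket and
is never counted as paired unless it lies inside the seed window itself, so
a perfectly complementary context still reports an extent starting at
position 2 for a 2–7 seed. Supplementary pairing is reported as the longest
contiguous Watson–Crick run the miRNA 3' region (positions ≥ 13) can form
against the 30 nt of mRNA immediately 5'-ward (upstream) of the site — the
side the miRNA 3' end faces in an antiparallel duplex — computed over all
alignment offsets so that bulges between seed and supplementary segments do
not mask the run.

## Census and family concordance

The catalog maps each extracted seed to the miRNAs carrying it. Identical
mature sequences deposited under different names (paralogous loci) count as
distinct miRNAs by default, because public seed tables are keyed by miRNA
name; `collapse_identical_sequences=True` counts them once. The census
reports distinct/unique/shared seed counts and a histogram of carriers per
seed; concordance reports, for each sharing level `k ≥ 2`, how many shared
seeds have all carriers in one annotated family. miRNAs without a family
label are treated as singleton families, which can only *lower* concordance
— an unannotated pair never counts as a same-family match. Percentages are
rounded half-up to one decimal, matching how such tables are conventionally
printed. Arms are parsed from `-5p`/`-3p` id suffixes only; arm inference
from hairpin structure is out of scope.

## Differential-expression classification and enrichment

A DE record carries `A` (log2 average expression), `M` (log2 fold change
versus the negative control) and raw/adjusted p-values. The universe is the
expressed set `A > a_min` (default 8); down = universe ∩ {`M < −0.5`,
`adjP < 0.05`}, up symmetric. Testing against all probes instead of the
expressed set is available (`universe_mode="all"`) but inflates the carrier
count `K` with transcripts that could never respond; absolute folds differ
between the two modes. Probe-level tables collapse to one row per
transcript keeping the smallest adjP, and RefSeq-style version suffixes are
stripped before joining namespaces (switchable).

Enrichment uses the inclusive upper tail `P(X ≥ k)` of
Hypergeometric(N, K, n) — `scipy.stats.hypergeom.sf(k−1, …)` — with
Benjamini–Hochberg correction (statsmodels) applied across miRNAs within
one (source, category) family; `K = 0` rows are reported but excluded from
the BH family, since the hypothesis is untestable. Fold enrichment is
`(k/n)/(K/N)`; an odds-ratio variant was considered and rejected as the
default because the ratio of category and universe target fractions is what
enrichment plots conventionally display. Rows are ranked by adjP, then fold
(descending), then miRNA id. The regional profile recomputes target sets
per 3'UTR `distance_to_stop` bin (default width 200 nt, configurable;
5'UTR and CDS as whole regions) and tests each bin the same way. Pairwise
target-set overlap reports Venn partition counts, Jaccard, and percent
overlap defined as `|A∩B| / min(|A|,|B|)`.

## Synthetic data generator

The generator emulates a transfection microarray study: one miRNA
overexpressed against a negative control, three biological replicates per
arm, repression read out as negative log2 ratios.

*Catalog*: seeds are drawn uniformly without replacement (a plan is
infeasible once it needs more distinct seeds than `4^length`); each
sharing-plan group contributes `count` seeds carried by `k` miRNAs, either
all in one synthetic family or in `k` distinct ones, so the census and
concordance of the output equal the plan by construction — an exact oracle
for the census code.

*Transcriptome*: 3'UTR lengths are Normal(1000, 300) truncated at 100 nt,
base composition uniform (a GC-skew option stresses incidental matching);
`⌈target_fraction · n⌉` transcripts receive 1–3 non-overlapping exact
sites for the planted miRNA's seed at uniform positions (optionally capped
at a maximum distance from the stop codon, used by the positional
analyses). Incidental background matches arise freely and are picked up on
rescan, as in real UTRs, where a random hexamer match sits in roughly a
fifth of kilobase-scale UTRs.

*Expression*: replicate log-ratios are Normal(−μ·target, σ) with defaults
μ = 2, σ = 0.25; `M` is the replicate mean. The per-transcript p-value
comes from a one-sample location test whose variance is pooled across all
transcripts: the noise model is homoscedastic, so pooling is the natural
estimator, and it plays the role that variance moderation plays in real
array pipelines — with three replicates a strictly per-transcript t-test
(df = 2) cannot reach BH-adjusted significance over thousands of
transcripts at any realistic effect size. Under the null the pooled
statistic is N(0,1) to within pooling error, so type-I calibration is
preserved; with σ = 0 the table degenerates exactly (M = −μ, p = 0).
Repression is a fixed shift regardless of site count by default
(`repression_per_site` scales by min(sites, 3)). `A` is Normal(10, 1)
truncated above the expression cut for all but a 10% unexpressed fraction.
The generator does **not** model probe-level intensities, dye bias,
normalization artifacts, correlated transcripts or secondary (indirect)
regulation — so passing recovery tests demonstrate the inference machinery,
not robustness to those real-data features.

*Recovery*: each run draws a fresh transcriptome, DE table and 50 decoy
miRNAs with seeds distinct from the planted seed (optionally plus one
co-seeded decoy), runs scan → classify → enrich, and records the planted
miRNA's rank and the decoy rate at adjP < 0.05. For exact (wobble-free)
scans the target sets are computed by substring containment of the reverse
complement, verified in tests to equal the full site-table scan. Default
problem sizes (5000 transcripts, 200 runs) keep a full recovery study
around three minutes on one CPU.

## Numerical and interface choices

- All randomness flows through `numpy.random.Generator`; every simulation
  accepts a seed or generator and is bit-reproducible from it. Child seeds
  are spawned below 2^31.
- Ties in enrichment rankings break by miRNA id after adjP and fold, so
  output order is deterministic.
- Tables are TSV with header, `.` for missing values, UTF-8; FASTA ids are
  the first whitespace-delimited header token. miFam-style family records
  (AC/ID/MI lines) annotate precursor names, so family lookup for a mature
  id falls back from the exact id to the arm-stripped and `miR`→`mir`
  precursor forms.
- The pipeline writes a manifest with config echo and SHA-256 checksums of
  inputs and outputs; no timestamps, so reruns are byte-comparable.

## Known limitations

Site scoring is purely combinatorial: no thermodynamics, site
accessibility, conservation filtering or full duplex folding. Conserved or
non-conserved prediction lists are consumed as external pair lists, not
computed. The seed-sharing census is name-keyed and depends on the catalog
release used; family concordance depends on the completeness of the family
annotation file. The DE side consumes pre-computed adjusted p-values from
real experiments — array normalization and moderated test statistics are
explicitly upstream of this package.
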