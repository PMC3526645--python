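# Methods

## The matching problem

A bite mark transfers a sample of the biter's dental plaque — dominated
by streptococci — onto the skin. Swabs of the bite mark and of a
suspect's teeth are amplified with streptococcus-specific fusion primers
at up to four loci (16S rRNA, the 16S–23S intergenic spacer, *rnpB* and
*rpoB*), sequenced bidirectionally, and compared at 100 % sequence
identity. The package treats the comparison as a binary classification
problem: does a bite/teeth pair come from the same mouth?

## Read filtering

Three levels, in order, per sample:

1. **Length + demultiplex.** Raw reads shorter than 220 bp
   (`min_raw_length`) are discarded. Survivors are assigned to the
   unique locus whose fusion-primer prefix they carry — adapter A +
   forward primer for forward reads, adapter B + reverse primer for
   reverse reads — with IUPAC-aware exact prefix matching
   (`max_primer_mismatches`, default 0: stringency can only reduce false
   locus assignment). Reverse reads are reverse-complemented so both
   sequencing directions of one template collapse to the same string;
   without this the 100 %-identity comparison would systematically miss
   cross-direction matches. Unassignable reads are discarded and
   counted. The 220 bp threshold is measured on the raw read, adapters
   included.
2. **Trim + truncate.** The 5' adapter (when present — canonicalized
   reverse reads begin directly at the forward primer) and the forward
   primer are stripped; the read is truncated immediately before the
   first base with Phred < 20 (`min_quality`) or outside {A,C,G,T};
   then the reverse-complemented reverse primer and everything after it
   are removed from the 3' end, including end-truncated primer fragments
   of at least 6 bp. Truncation keeps the prefix strictly before the
   first failing position — excising interior bases would create
   chimeric strings that break exact-identity matching. The 3' step runs
   after the quality cut and iterates to a fixpoint, making the whole
   trim idempotent even when the quality cut lands inside the primer
   tail. Degenerate (even empty) outputs survive to level 3, where the
   length filter removes them.
3. **Dereplicate.** Trimmed reads shorter than 180 bp
   (`min_trimmed_length`) are discarded; the rest are grouped by exact
   full-string equality; groups smaller than `min_frequency` (2) —
   singletons — are discarded, removing most one-off sequencing-error
   variants. Each surviving group becomes one unique read annotated with
   its frequency (identical members make the consensus trivial). Unique
   reads are written as FASTA with the common dereplication header
   dialect `id;size=N`.

A sample needs at least `min_unique_reads` (10) unique reads at a locus
to enter comparative analyses. Per the comparative-table convention, a
sample failing the rule at any retained locus is excluded from analyses
at **all** loci; a locus failing it for nearly all samples (fewer than
`min_participants_per_locus` complete pairs) is excluded as a locus
instead, without taking its participants down with it. Audit counts are
kept at every level and reconcile exactly with the raw read count.

## The statistic and best-match rule

For bite unique-read set *B* and teeth set *T*:
`p = |B ∩ T| / |B|` — deliberately asymmetric, with the bite sample
(the smaller, dropout-affected set) in the denominator. The denominator
counts **unique** reads: the filtered data sets consist of unique reads
only, and the published diagnostic table reproduces exactly under this
reading (a frequency-weighted variant is available behind
`weighted=True` for sensitivity analysis). An empty bite set is an
error, not a zero. Matrices are oriented teeth rows × bite columns;
internal values are full precision and rounding to two decimals happens
only on export.

Best match = column maximum; ties go to the teeth data set with the
fewest unique reads, then to the smallest label. The packaged
tie-break count fixture is a synthetic stand-in (the real per-sample
counts were published only as bar charts) whose ordering encodes the
documented tie-break outcomes; it is labelled synthetic in its filename
and header.

## Matching evaluation

- **Labeling:** every (teeth, bite) cell is a pair; outcome 1 iff the
  participants match. The published modelling subset is the
  pooled-library participants {1, 3–10}: 81 pairs, 9 positive.
- **Threshold rule:** predicted match iff proportion ≥ threshold. The
  comparison is inclusive: corresponding pairs printed exactly at the
  optimum (16S 0.20, ITS 0.25) would otherwise be false negatives and
  the published sensitivities of 100 % would be irreproducible.
- **ROC:** candidate thresholds are the distinct observed proportions.
  AUC is the rank-sum (Mann–Whitney) probability with ties counting one
  half. The optimum proportion maximizes Youden's J
  (sensitivity + specificity − 1), ties resolved toward the **largest**
  threshold — the most stringent among equally good cutoffs. This
  selection returns 0.20 / 0.25 / 0.20 on the packaged matrices.
- **Logistic model:** single-predictor fit via maximum likelihood
  (statsmodels). The model p-value is the likelihood-ratio test against
  the intercept-only model, which remains well defined near perfect
  separation; the Wald p is reported alongside. Pseudo-R² is McFadden's
  1 − ℓ/ℓ₀; goodness of fit is a decile-grouped Hosmer–Lemeshow test.
  Perfect separation (min positive proportion > max negative, as at
  *rpoB*) is detected and flagged; no penalized refit is attempted,
  since every reported diagnostic derives from the threshold analysis,
  which needs no converged model. A constant predictor skips the model
  with an explanation.
- **Intervals:** sensitivity/specificity/PPV/NPV are binomial
  proportions; both asymptotic-normal (Wald, z·√(p(1−p)/n), clipped)
  and exact Clopper–Pearson 95 % intervals are reported. The published
  parenthesized intervals match neither method throughout (e.g.
  (55–100) for 9/9), so intervals here are labelled by method rather
  than matched to the print.

## Synthetic data generator

What it emulates: per-participant strain repertoires per locus, built by
filling `strains_per_participant_per_locus` (30) slots either from a
shared background pool of `background_pool_size` (8) sequences — with
per-locus probability `sharing_rate_per_locus` — or with private random
sequences; insert lengths follow each locus's published amplicon range
minus primers. Teeth samples draw reads uniformly from the full
repertoire; bite samples from a per-sample subset retained with
probability `bite_transfer_fraction` (0.7 — the transfer process is
unquantified in the source data, so this is a documented free
parameter); skin controls contain no streptococcal primer and vanish at
demultiplexing. Reads carry adapter + primer (+ reverse-primer tail),
random direction, substitution errors (rate 0.001/base, the order of
the platform's post-filter error), indels (0.0005/base, plus
0.002/base extra inside homopolymer runs ≥ 3 — the platform's dominant
error mode and the motivation for the stringent filtering), Phred
scores declining from 38 by 0.03/base with noise, collapsed to < 20 at
substituted/inserted bases, and a `singleton_contaminant_rate` (0.02)
of one-off random-template reads destined for the singleton filter.
Pooled mode splits `reads_per_sample` (400) across the four loci;
single-locus mode gives each locus the full count, reproducing the
deeper per-locus coverage of the singly sequenced samples.

Sharing-rate defaults (16S 0.55, ITS 0.63, *rnpB* 0.45, *rpoB* 0.30)
were calibrated by simulation so the realized fraction of a
participant's strains common to **all** eight participants lands near
the observed levels — ≈ 11 % (16S), ≈ 20 % (ITS) and ≈ 1.6 % (*rpoB*).
Commonality-to-all decays steeply with the number of participants, so
the draw probabilities are much closer together than the commonality
levels they generate, and the *rpoB* value is small but not zero.
`simulate.common_to_all_fraction` and `mean_pairwise_overlap` measure
the realized values for any configuration.

What it does **not** model: real streptococcal alleles or phylogeny
(strains are random DNA — the analysis depends only on string-identity
structure), chimeras, abundance skew within a repertoire,
quality-score miscalibration, or temporal drift of strain carriage.
Passing tests therefore demonstrate the pipeline's correctness and the
statistic's behaviour under controlled identity structure, not
performance on real flowgram data.

Reproducibility: every sample's reads derive from an independent stream
seeded by (study seed, sample id), so studies are byte-identical across
runs and samples are reproducible in isolation.

## Problem sizes and numerical choices

The default synthetic study uses 8 participants × 400 reads × 4 loci
(pooled), which the full pipeline processes in a few seconds; the
statistical reproduction from the packaged matrices is instantaneous.
Ties in dereplication output are ordered by (frequency desc, sequence);
matrices order rows/columns by participant id; all tie-breaks are
deterministic, so identical inputs give identical outputs regardless of
input order. Thresholds are compared with exact float equality only on
values read from two-decimal fixtures; recomputed statistics are
compared in tests at explicit tolerances.

## Known limitations

- The filter assumes Sanger Phred+33 FASTQ; legacy +64 input is
  rejected rather than auto-detected.
- Primer matching at 0 mismatches discards reads with any error in the
  fusion-primer region (≈ 4 % at default error rates); this mirrors the
  stringency-first design but understates recoverable reads.
- No sub-100 %-identity clustering, chimera detection or denoising: a
  double error duplicated across two reads can create a spurious unique
  read, though at default rates this is vanishingly rare.
- The logistic model's coefficient estimates are meaningless under
  perfect separation (flagged); only the threshold-analysis diagnostics
  should be quoted there.
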