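# Methods

## Scope

`panelcnv` implements the depth-based CNV caller, the known-site
Alu-insertion detector, and the validation statistics of a targeted
36-gene hereditary-cancer sequencing assay, together with a simulator
that generates every input the pipeline consumes. Alignment, SNV/indel
calling, variant classification and wet-lab QC are out of scope; the
caller starts from a per-target × per-sample integer depth matrix and a
panel definition.

## Panel model

Targets are 0-based half-open intervals carrying a gene symbol and an
exon label. The builtin `counsyl36` panel stores the assay's published
per-gene reportable ROI sizes (34 genes; total exactly 124,245 bp) and
sequenced exon ranges; PMS2 exons 11–15 (pseudogene homology) and RET
exon 1 (GC content) are absent by design. Because the assay's capture
coordinates are not public, the fixture's intervals are **synthetic**:
each gene's exons are evenly sized blocks that sum exactly to the
printed ROI, separated by fixed 2-kb introns, with genes on a shared
chromosome spaced 1 Mb apart. The GREM1 promoter-duplication intervals
are the three published GRCh37 coordinates (they mutually overlap, so
the non-overlap invariant applies only to genes with an SNV/indel ROI).
EPCAM (single exon-9 target, deletions only) and GREM1 (duplications
only) carry restrictive reporting rules; every other gene reports all
events.

## Depth normalization and emission model

For one batch (the samples sequenced together in a flowcell lane):

- $\mu_i$ = median over samples of $d_{i,j}$ — the median, not the
  mean, so CNV carriers in the batch do not shift the diploid
  reference;
- $\mu_j$ = median over targets of $d_{i,j}/\mu_i$ (targets with
  $\mu_i = 0$ are masked: excluded from the median and emitted with
  state-uninformative likelihoods);
- expected depth at copy number $c$ is $(c/2)\,\mu_i\,\mu_j$, so the
  diploid state matches the observed median exactly. Copy 0 uses a
  residual fraction $\varepsilon_0 = 0.01$ of the diploid expectation
  (mismapping background; a zero-mean NB is degenerate).

Dispersion is moment-matched: $r_i = \mu_i^2 / (\mathrm{Var}_j[d_{i,j}]
- \mu_i)$, capped at $R_{\max} = 10^8$ (numerically Poisson) when the
variance does not exceed the mean, and defaulting to $10^4$ when the
batch has fewer than two samples. The *fitted* model applies two
refinements to this estimator, both exposed as options on
`estimate_dispersion`:

1. **Scale correction** — variance is taken on $d_{i,j}/\mu_j$.
   Without it, per-sample depth spread (a ~10% lognormal in realistic
   batches) masquerades as target overdispersion and collapses $r_i$
   from $10^4$ to order $10^2$ everywhere.
2. **Robust scale** — a MAD-based variance
   $(1.4826\cdot\mathrm{MAD})^2$ replaces the unbiased sample variance.
   A CNV-carrying sample sits many standard deviations from the batch
   median at exactly the targets it affects; with 16 samples it
   inflates the raw variance enough to cost roughly half of all
   duplications. The MAD ignores a single outlying sample entirely.

The plain estimator (raw counts, $n-1$ variance) remains the default
code path of `estimate_dispersion` for transparency and testing.

The NB log-pmf is evaluated in a numerically stable form:
$\log\Gamma(d+r) - \log\Gamma(r) - d\log r$ is computed by a power-sum
series when $r \gg d$ (direct lgamma differencing loses
$\sim|\log\Gamma(r)|\,\varepsilon \approx 2\times10^{-7}$ absolute at
$r = 10^8$, and scipy's `nbinom.logpmf` shows ~$4\times10^{-6}$ noise
there). The exact Poisson-limit behaviour is
$\log p_{NB} - \log p_{Poi} = ((d-\mu)^2 - d)/(2r) + O(r^{-2})$:
at $\mu = 650$ and $r = 10^8$ the two distributions agree to better
than $10^{-7}$ in probability at every count, although the *log*-pmf
still differs by a few $10^{-6}$ near the mode — the cap is
"indistinguishable from Poisson" on the probability scale, which is
what decoding consumes.

## Transition model

Copy number evolves per base pair as a two-macro-state chain: wild-type
(diploid) and CNV, with exit rate $b = p_{CNV\to WT} = 1/6{,}200$ per
bp (matching the mean CNV length observed in the human population) and
entry rate $a = p_{CNV}\,b$ with $p_{CNV} = 10^{-3}$. The $g$-bp
advancement has the exact closed form

$$P_{WT\to CNV}(g) = \frac{a}{a+b}\left(1 - (1-a-b)^g\right),$$

computed with `expm1`/`log1p` so the $g = 1$ matrix is exact to 1 ulp.
The CNV macro-state splits equally over the non-diploid copy numbers
{0, 1, 3}; there are no direct transitions between different CNV states
(a deletion cannot become a duplication without intervening diploid
sequence), which makes the per-state closed form exact as well: mass
that never exits stays in its own state with probability $(1-b)^g$, and
re-entered mass is uniform over CNV states. Copy numbers above 3 are
reported as state 3 ("≥3"); all 36 panel genes are autosomal, so no
sex-chromosome ploidy handling exists.

Each gene is an independent decoding block restarted at the stationary
distribution ($P(CNV) = p_{CNV}/(1+p_{CNV})$). Gaps are distances
between consecutive target midpoints, clamped to 1 Mb (beyond which the
chain has effectively mixed anyway); masked targets are skipped with
gaps bridged across them.

## Decoding, segmentation and calling policy

Viterbi decoding (log space) gives the MAP copy-number path; ties break
toward diploid, then toward the lower copy number, so output is
deterministic. Posteriors come from a scaled forward–backward pass.
Maximal runs of one non-diploid state become calls. Because the sum of
per-target posteriors is not a probability for multi-target events, a
call's confidence is the **mean** of $P(c_{i,j} \neq 2)$ over its run
(the minimum is retained as a diagnostic). Status: `confident` at
confidence ≥ 0.99, `retest` in [0.5, 0.99), `no_call` below — the
production thresholds are unpublished; these defaults are configurable
and the retest status stands in for the re-extraction/re-sequencing
policy. Batches of one sample are rejected (no cross-sample
normalization is possible); normalization never crosses batches.

Sample-level QC gates mirror the assay's printed thresholds:
contamination < 5%, per-base minimum depth ≥ 20× (inclusive), mean
depth > 250× (strict), ROI coverage 100%.

## Alu-insertion detection

Call-by-list only: each site carries a chromosome, a between-base
insertion coordinate and a junction sequence. Soft clips (leading or
trailing CIGAR `S` segments, ≥ 10 bp) whose boundary falls within 5 bp
of the site are collected; duplicates are removed on the key
(aligned start, clip side, clip sequence) — a PCR-duplicate proxy in
the absence of mate information; a clip matches if its ungapped prefix
overlap with the junction sequence is ≥ 10 bp at ≥ 90% identity (clips
are compared in reference orientation; aligners emit reads that way).
A site is positive with ≥ 3 unique matching reads. The builtin site
table carries the four unique validated variants (ATM intron 54–55,
BRCA2 exon 3 c.156_157insAlu, BRCA2 exon 25 c.930_931insAlu, MSH6
intron 2–3) with **synthetic** junction sequences built from the AluY
consensus prefix, anchored to the synthetic panel coordinates.

## Validation statistics

TP/FP/FN follow call-level comparison (payload text must match when
both sides carry one; a payload mismatch at a truth-variant locus
counts as both FP and FN). No-call pairs are censored before counting.
True negatives are restricted to informative loci: in `site` mode, loci
polymorphic in at least one sample; in `gene` mode, sample×gene pairs
in genes with at least one true positive in the cohort. Confidence
intervals are exact Clopper–Pearson Beta-quantile bounds ($x = n$ gives
a lower bound of $(\alpha/2)^{1/n}$); replicate concordance is pooled
pairwise agreement over aligned call lists.

## Simulator

The generator realizes exactly the caller's model, with truth
manifests:

- per-target baselines lognormal around 650× (σ = 0.3, emulating
  capture-efficiency spread; the assay publishes only the mean);
- per-sample scale factors lognormal with σ = 0.1 (typical within-lane
  library imbalance);
- NB counts via the Gamma–Poisson mixture, so the mean/size
  parameterization is exact in distribution; default $r = 10^4$;
- spiked events scale expected depth by $c/2$ (copy 0 keeps the 1%
  residual);
- Alu read sets with matching clips (junction prefixes of varying
  length), exact duplicates and random-sequence distractors;
- validation cohorts with exact configured TP/FP/FN/no-call counts.

What it does **not** emulate: GC bias, mappability artifacts, batch
effects, pseudogene cross-mapping, breakpoints inside targets, mosaic
fractions, or read-level sequence for the CNV path (depth-level only).
Passing tests therefore demonstrate correctness of the statistical
machinery under the stated model, not robustness to every artifact of
real capture data.

Problem sizes used by the test suite and acceptance script — 16-sample
batches on the 547-target panel, 50 spiked events, 1,000 random
HMM blocks of ≤ 6 targets against exhaustive enumeration — run in
seconds on one CPU and were chosen as the smallest sizes that exercise
every code path meaningfully.

## Known limitations

- The synthetic panel coordinates are not the assay's real design; any
  analysis keyed to true genomic positions needs a user-supplied BED.
- The dispersion estimator's robustness relies on at most a minority of
  batch samples carrying an event at any one target.
- Confidence calibration (0.99/0.5 thresholds) was not tuned against
  patient data; the published thresholds are unknown.
- Alu matching is ungapped and orientation-fixed; a junction sequence
  diverging > 10% from its catalogue entry would be missed.
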