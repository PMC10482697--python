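# Methods

## Coordinate conventions

All reference positions are 0-based; intervals are half-open. A cut site
is a between-base offset: a blunt cut between positions `c-1` and `c` is
encoded as `c`. This removes ±1 ambiguity between the window logic, the
indel calls and the simulator. Cut sites are supplied by the user;
deriving them from the protospacer and enzyme (Cas9 vs Cas12a offset
rules, paired nicking geometry) is deliberately out of scope.

## Read merging

Paired 2×150 bp amplicon reads whose insert is shorter than 300 bp are
merged from their 3′ overlap: read 2 is reverse-complemented, every
candidate overlap length `k ≥ min_overlap` (default 20) is scored, and
among overlaps with mismatch fraction ≤ 0.1 the one with the most
matching bases wins (ties prefer the longer overlap). At a disagreement
inside the overlap the base with the higher Phred quality is kept, ties
going to read 1. This is a deterministic maximum-matching merger, not a
probabilistic model of adapter read-through; pre-merged input from a
dedicated merger is accepted via `--merged` and is the recommended path
for real libraries. Bases called N never count as matches, here or
anywhere downstream.

## Alignment

Reads are aligned to the amplicon with Biopython's `PairwiseAligner`
under an affine-gap scheme: match +5, mismatch −4, gap open −20, each
additional gapped base −1 (so a length-L gap costs 20 + (L−1)). These
are needle-class parameters of the kind amplicon quantifiers use; they
strongly prefer one long gap over scattered short ones, which is the
right prior for nuclease-induced indels. Terminal gaps are free at both
sequence ends, making the alignment tolerant of residual primer/adapter
length differences at either terminus; identity is computed as
matches / columns over the non-terminal columns only, so the statistic is
unaffected by the overhang convention. An `N` scores 0 against any base.

The first optimal traceback is taken; any ambiguity in gap placement is
then removed by canonical **left alignment** of every indel (the
variant-normalisation convention): a deletion shifts left while the base
before it equals its last base, an insertion rotates its sequence while
shifting. Left alignment is idempotent and yields the unique leftmost
representation, which makes microhomology computation and read
deduplication deterministic.

## Classification

Thresholds (all configurable on `ClassifyThresholds`):

| parameter             | default | meaning                                   |
|-----------------------|---------|-------------------------------------------|
| `min_read_similarity` | 0.70    | retention filter (vs WT *or* HDR allele)   |
| `hdr_similarity`      | 0.95    | minimum identity to HDR allele for HDR     |
| `window_radius`       | 20 bp   | quantification window half-width per cut   |
| `mmej_min_mh`         | 2 bp    | minimum deletion MH for MMEJ attribution   |

The retention filter compares each read to **both** alleles and keeps it
if either identity reaches 0.70: in a high-efficiency HDR sample,
filtering against the wild type alone would be biased against edited
reads (negligibly for a single substitution, but the dual comparison is
the safe generalisation and costs nothing).

Decision sequence per retained read:

1. no in-window indel → **HDR** if every donor substitution is present
   *and* identity to the HDR allele ≥ 0.95 (requires at least one donor
   edit to be defined — with zero edits the condition would be vacuous);
   **PARTIAL_HDR** for a proper non-empty subset of multiple donor
   edits; otherwise **WT**;
2. in-window indel present → **IMPERFECT_HDR** if any donor substitution
   is present; else **MMEJ** if the read has no in-window insertion and
   its maximum deletion MH ≥ `mmej_min_mh`; else **NHEJ**.

Any insertion forces NHEJ because templated-insertion MMEJ signatures
are not modelled; multiple deletions are represented by the maximum MH.
Substitutions away from donor positions are recorded but never change
the category — they are indistinguishable from sequencing errors at the
per-read level — while still reducing the identity used by the 0.70/0.95
filters.

An insertion occupies no reference interval; it is counted in-window
when either flanking position lies in the window.

Microhomology is computed on the left-aligned placement as the match
length of the deleted prefix against the retained suffix, bounded only
by the reference end — so for a contraction of a long tandem repeat the
MH can exceed the deletion length, and such deletions are reported
as-is (they populate the open-ended top bin of the MH spectrum).

## Sample metrics

Fractions use retained (non-discarded) reads as the denominator; the
discarded count is reported separately. Outcome purity is
`HDR / (HDR + PARTIAL_HDR + IMPERFECT_HDR + NHEJ + MMEJ)` — the
numerator is pure HDR only, the denominator every read that differs from
wild type; both choices are exposed (`purity_numerator`). Purity is
undefined (None) when no editing events exist. The MH spectrum bins each
deletion-bearing retained read once, by its maximum deletion MH, into
bins 0/1/2/3/≥4 (configurable) — chosen to straddle the 2 bp MMEJ
threshold. Replicate aggregation reports mean and s.e.m.
(sample SD with n−1 / √n; exactly 0 for identical replicates, None for
n = 1).

## ddPCR copy number

λ = −ln(negative/total) per channel; SE(λ) = √((1−p)/(n·p)) by the delta
method on the binomial negative fraction. Copy number
`cn = 2·λ_t/λ_r` (reference gene assumed diploid);
SE(ln cn)² = SE(λ_t)²/λ_t² + SE(λ_r)²/λ_r², and the 95% CI is
`cn·exp(∓1.96·SE(ln cn))`. The log-normal construction keeps the CI
positive and is the standard treatment for digital-PCR concentration
ratios; instrument vendors' proprietary CIs are not reproduced —
simulation shows nominal coverage (≈95% at 20,000 droplets, λ_r = 1).
Saturated wells (zero negative droplets) are an error, near-saturated
wells carry a large SE; totals under 1,000 droplets trigger a warning.
Droplet volume is not modelled: all quantities are per-droplet
concentrations, which suffice for ratios.

Clone calls: 1 predominant target-site sequence → apparent homozygous,
2 → apparent heterozygous, more → rejected as possible polyclonality.
Genotype strings pool NHEJ/MMEJ as "EJ" and count any donor-carrying
sequence as HDR; `pure_hdr` marks homozygous clones whose single
sequence is exclusively the intended substitution. Copy loss is flagged
when the CI **upper bound** is below 1.5 (the midpoint between one and
two copies) — a whole-error-bar criterion, deliberately stricter than a
point-estimate cutoff. An indel overlapping a user-supplied primer/probe
interval sets `primer_site_indel`, since such clones can lose one
chromosome's amplification and mimic copy loss.

## The simulator

The generator emulates an amplicon editing experiment with known truth:

* default amplicon: 250 bp random sequence (50% GC), one cut at the
  midpoint, one donor substitution 4 bp 5′ of the cut (the blocking
  mutation position of a typical single-stranded donor);
* default outcome proportions 60% HDR, 15% NHEJ, 15% MMEJ, 5% imperfect
  HDR, 5% WT — an efficient-HDR condition in which every category is
  still well represented; category counts are multinomial;
* deletions are drawn from an enumerated set of cut-proximal candidates
  (midpoint within ±3 bp of a cut, lengths 1–20) whose left-aligned MH
  is re-verified with the same statistic the classifier uses: MMEJ
  candidates need MH in 2–6 bp, NHEJ deletions MH < 2. If a reference
  offers no MMEJ-compatible deletion, a flanking repeat is engineered
  into it (and the modified reference is returned and reported);
* insertions (1–5 bp, random sequence) are placed at the cut ±3 bp. A
  randomly drawn insertion can occasionally admit a score-equivalent
  alignment that absorbs an adjacent donor base into the gap; the
  generator classifies each insertion-bearing read once at construction
  time and redraws the insertion if the label would be ambiguous. This
  biases simulated insertions slightly toward unambiguous ones, which is
  the point: truth labels are guaranteed consistent with the calling
  rules;
* sequencing error is substitution-only at 0.1% per base (Illumina
  amplicon scale), so truth labels remain exact; indel sequencing errors,
  per-cycle quality profiles, PCR chimeras and jackpot duplicates are
  not modelled — passing recovery tests therefore demonstrates the
  correctness of the calling logic, not robustness to every real-data
  artifact;
* optional 2×150 bp fragmentation produces overlapping pairs for the
  merger; droplet counts are per-droplet Poisson draws at known λ.

All randomness flows through one seeded NumPy PCG64 generator, so every
artifact is reproducible bit-for-bit per seed.

## Problem sizes and tolerances

The test suite and the acceptance script use 10,000-read samples for
recovery and composition checks (binomial 3-SD bands), 1,000 random
instances for the microhomology-oracle comparison (exact equality), and
500 wells × 20,000 droplets for ddPCR calibration (mean within 0.02 of
2.0; CI coverage in [0.93, 0.97]) — sizes at which the expected
statistical fluctuations are well inside the asserted bands while a full
run stays comfortably desk-scale.

## Known limitations

* The retention/HDR identity thresholds reproduce the standard amplicon
  quantification convention; whether the HDR identity should be computed
  over the whole alignment or only the window is convention-dependent —
  whole-alignment identity is used here.
* MMEJ attribution is rule-based: a deletion with ≥2 bp junction MH can
  still arise from NHEJ by chance, so per-read attribution is an upper
  bound on true MMEJ, exactly as in the rule it implements. No attempt
  is made to model chance MH.
* Donor-programmed insertions/deletions are not supported (substitution
  donors only); SSA is not called separately but appears as long-MH
  deletions in the spectrum.
* The overlap merger is not a replacement for a Bayesian read merger on
  low-quality real data.
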