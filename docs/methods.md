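# Methods

## Model

`bcpseq` treats a chromosome's ChIP-seq signal as a sequence of integer
observations y_1, ..., y_n, one per *block*, and models it with an
infinite-state change-point process:

* the expected read density λ_t is piecewise constant along the
  chromosome; block 1 always opens a segment, and each subsequent block
  boundary carries an independent Bernoulli(p) change indicator;
* when a change occurs, the new level is drawn from a Gamma(α, β) prior
  (shape/rate; prior mean α/β).  The continuous state space is what
  distinguishes the model from finite-state HMM segmenters: levels are
  never quantised into a fixed alphabet;
* y_t | λ_t ~ Poisson(λ_t), independent given the levels.  Marginally
  each count is negative binomial, which captures the over-dispersion of
  real ChIP-seq counts.

Conjugacy gives every segment [i, j] a closed-form posterior
Gamma(α + Σy, β + L) and evidence m(i, j).  The posterior probability
that the segment containing block t spans [i, j] factorises as

    w_ij ∝ a_i · (1 − p)^(j−i) · m(i, j) · c_{j+1}

where a_i is the evidence of the prefix ending with a change at i and
c_{j+1} that of the suffix opening with a change at j+1; both are read
off the forward and backward filter normalisers.  The reported statistic
is the posterior mean λ̂_t = Σ w_ij (α_ij/β_ij) over all segments
containing t — effectively a scan statistic in which every window size
participates with a data-driven weight.  All recursions run in log
space; counts up to 1e6 and chromosome-scale n pose no overflow risk.

Correctness is anchored by a brute-force oracle: for n ≤ 8 the test
suite enumerates all 2^(n−1) change configurations and compares filter
weights, posterior means and marginal likelihood; the recursive
implementation agrees to ~1e-14 relative.

## Bounded-complexity mixture (BCMIX)

The exact filter carries one hypothesis per candidate change location,
making a full pass O(n²) (the package's `--exact` mode, implemented by
accumulating all segment weights through a difference array).  The
default mode caps the mixture at k_total = 20 components per step,
always retaining the m_recent = 10 most recent candidates plus the
largest-weight older ones, renormalising after each prune; smoothing
then combines the pruned forward and backward supports per block with
the evidence-ratio coupling w_ij(t) ∝ F_it G_jt m(i,j)/(m(i,t) m(t,j)).
With k_total ≥ n this path reproduces the exact smoother to machine
precision (the two algorithms differ in summation order, so agreement is
asserted at 1e-12 relative rather than bitwise).

Truncation fidelity is regime-dependent, and one aspect deserves
honesty: when segment levels sit near the prior mean α/β, splitting a
homogeneous segment is barely penalised by the evidence, so the filter
posterior over the most-recent-change index develops a long, flat tail
— at some positions the top 20 hypotheses hold only ~85–92% of the
mass.  The discarded diffuse hypotheses are short segments whose
posterior means are shrunk toward the prior, so truncation biases λ̂_t
slightly toward the local level and away from the prior.  Measured on
model-generated tracks (n = 5000, α = 2, β = 1, p = 0.001) the maximum
relative deviation from the exact smoother is ~2e-2–7e-2 (median
~1e-3), concentrated at change-point-adjacent and low-level blocks, and
it shrinks only slowly with k (k = 200 still leaves ~1e-3–8e-3).  This
is intrinsic to hard truncation, not an implementation artefact.  For
calling it is immaterial — thresholds are integer quantiles and
enriched levels sit far from them — but users needing exact posterior
means on modest inputs should pass `--exact`.

## Hyperparameters

(α, β) come from the method of moments on the pooled genome-wide block
counts: m = α/β, v = m + m/β with the sample mean and unbiased sample
variance, requiring over-dispersion v > m.  Under-dispersed input (it
occurs for near-uniform controls, whose TF blocks are almost Bernoulli)
falls back to a unit-variance prior (α = m², β = m) with a warning.
The change probability p maximises the filtering log-likelihood over
the logarithmic grid {j·10^−i} ∩ (0, 0.5]; chromosome log-likelihoods
add.  Estimation is genome-wide (pooled), applied per chromosome.

Recovery accuracy is bounded by the number of segments, not the number
of blocks: a track of 2e5 blocks at p = 0.01 holds ~2000 level draws
from Gamma(2, 1), whose sample variance carries ~5% relative error
(excess kurtosis 3), so the moment estimates inherit ~5% sampling error
per realisation; at p = 0.001 that grows to ~16%.  The acceptance test
therefore asserts the 10% recovery band on a three-seed average, where
it is a ~3σ statement rather than a coin flip.

## Data transformation

* **TF mode.**  Duplicate reads (identical chrom/start/end/strand) are
  collapsed.  The fragment shift is estimated from the bimodal strand
  profile: both strands' 5′-end densities are boxcar-smoothed (21 bp),
  and each of the top plus-strand local maxima (plateau-aware: a flat
  run counts once, at its centre) is paired with the highest-density
  minus-strand maximum within 500 bp downstream; the shift is half the
  median pair distance, rounded half away from zero.  Pairing to the
  strongest rather than the nearest maximum avoids a downward bias of
  half the site jitter; smoothing keeps isolated background reads from
  ranking as maxima after deduplication flattens true pile-ups to
  density 1.  Reads are then shifted ±shift toward the fragment centre
  and per-base coverage is blocked into maximal equal-count runs —
  variable-width, data-driven blocks.
* **HM mode.**  Reads are extended from their 5′ end to the expected
  fragment length (default 200 bp), and coverage is averaged over fixed
  200 bp windows (about one nucleosome unit), rounded half away from
  zero.
* The chromosome span defaults to the maximum (extended) read end, so
  no genome file is needed; uniqueness of read mapping is the caller's
  upstream responsibility (BED carries no mapping quality).

## Calling and validation

The cut line C is the q-quantile of Poisson(ȳ), with ȳ the global mean
block count (q = 0.90 for HM, 0.99 for TF — punctate peaks warrant the
stricter tail).  C is floored at 1: with a near-empty background ȳ → 0
the quantile degenerates to 0, and the strictly positive posterior mean
would make the whole chromosome one candidate.  HM candidates are
maximal runs of blocks with λ̂_t > C.  TF candidates additionally carry
a summit (midpoint of the block with the largest λ̂, leftmost on ties)
and a sub-area grown from that block while adjacent posterior means
differ by strictly less than one.

Validation against the input control is a one-sided upper-tail Poisson
test.  The null rate λ0 is the control read density (by read midpoint)
in the matched region — for TF, the larger of the sub-area density and
the mean density over summit-centred windows spanning one to five
candidate widths — multiplied by the library-size ratio and the
candidate length.  Zero local control density falls back to the
genome-wide control density so empty control windows cannot produce
p = 0.  Candidates with p < 1e-3 (default) are reported with score
−log10 p, capped at 1000 when p underflows.  In TF mode both samples
are first moved into the shifted coordinate frame, since the candidates
live there.

The empirical FDR swaps the two samples: peaks called with the control
as "test" are negatives, and FDR = negatives/tests, with a rank curve
FDR(r) = (#negatives scoring ≥ the rank-r score)/r.

## Synthetic data

`simulate_track` draws directly from the generative model and is the
reference for inference-recovery tests.  `simulate_reads` draws
fragment start positions from a piecewise-constant density profile,
assigns strands fairly, and reports the first/last 36 bp of each
fragment as the read — reproducing the plus/minus 5′ offset of one
fragment length that shift estimation relies on.  Default profiles:

* **HM**: 2 Mb chromosome, 10 enriched segments of 5–50 kb at 5×
  background, background 0.005 fragments/bp (mean window count ≈ 1 at
  fragment length 200) — the broad-domain regime of marks like
  H3K27me3/H3K36me3.  Matched controls are uniform at background
  density.
* **TF**: 50 point sources of 50 expected fragments each with ±10 bp
  positional jitter over a sparse uniform background (0.001
  fragments/bp) — the punctate CTCF-like regime.

What the simulator does *not* emulate: mappability holes, GC bias,
PCR-duplicate towers, chromatin-accessibility structure in the input,
or fragment-length dispersion.  Passing tests therefore demonstrate
correctness of the inference and calling machinery under the model's
own assumptions plus idealised read sampling, not robustness to every
real-data artefact; the clean separation between 5× enrichment and
background also makes the recovery rates (≥90% of enriched bases,
≤5% background) easier than on borderline real marks.

## Numerical and design choices

* Gamma prior parameterised by shape and rate, so a segment update adds
  the segment count sum to the shape and the segment length to the rate.
* Rounding of window means: half away from zero.
* Weight ties during pruning keep the more recent index (better for
  detecting fresh changes); equal posterior-mean maxima take the
  leftmost block.
* Unbiased (n−1) sample variance in the moment equations; immaterial at
  genomic n but fixed for determinism.
* Chromosomes are processed independently in lexicographic order, and
  all resolved parameters are echoed to the run log, so a run is fully
  reconstructible from its log.
* One integer seed drives each simulation via numpy's default
  generator; identical seeds give byte-identical BED output.
* Problem sizes in the test and acceptance suites (50–200 oracle
  tracks, n = 5000 exact-vs-BCMIX comparison, n = 2e5 recovery tracks,
  2 Mb read simulations) were chosen as the smallest sizes at which the
  checked statistics are stable.

## Known limitations

* No mappability or GC-bias correction; reads on unplaced contigs are
  treated like any chromosome.
* p-values are per-candidate and uncorrected (a fixed cutoff, not an
  FDR adjustment, selects candidates; the empirical FDR is reported
  separately).
* BCMIX posterior means carry the percent-level truncation bias
  described above in low-count regimes.
* BED input only; BAM/SAM ingestion and bigWig output are out of scope.
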