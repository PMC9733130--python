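# Methods

## Model and assumptions

The package treats a transcript's expression profile as a real-valued time
series `E_n = E(t_n)` sampled at `N` equally spaced times `t_n = nΔt`
spanning `T = NΔt` hours. The default design is `N = 12`, `Δt = 4 h`,
`T = 48 h`: two full light-dark cycles, which places the 24-hour period at
frequency index `k = 2` and resolves the period grid
{48, 24, 16, 12, 9.6, 8} h up to the Nyquist index `N/2 = 6`. The method
assumes entrained (light-dark) data with stable oscillations across the two
sampled cycles; decaying rhythms (e.g. free-running constant-darkness data)
leak power into long-period bins and depress the score, so the method is not
appropriate there. Equal spacing is enforced; there is no Lomb-Scargle
fallback, no detrending, and no period estimation off the discrete grid.

The DFT uses the negative-exponent convention `Ê_k = Σ E_n e^(−2πikn/N)`
(numpy's convention; verified against an O(N²) direct summation in the
tests). The folded one-sided power spectrum satisfies Parseval
(`Σ_k P(T_k) = mean(E_n²)`), with `P(T_0)` the squared mean and the non-DC
powers summing to the population variance.

## Scores

- **RP24** = `P(24) / Σ_{k∉{0,k24}} P(T_k)`. Ratio scale: 0 when no 24-h
  power, 1 when the 24-h component carries half the variance, `+inf` for a
  noise-free sinusoid. A constant profile is 0/0; it receives an undefined
  (NaN) score, p = 1, and can never be classified rhythmic. `+inf` is kept
  as a real value: it sorts above all finite scores and the logistic display
  transform maps it to 1.
- **RPT_k** generalizes RP24 to any grid period `T_k` (k = 1..N/2).
- **F24** = `P(24) / ⟨P(24)⟩_rand`, the mean taken over seeded uniform
  shuffles of the profile's values across time points. The same permutation
  ensemble backs both F24 and the p-value; since both statistics are
  monotone functions of P(24) given the shuffle-invariant total power, this
  sharing changes nothing about either.
- **Phase** = `−12·arg(Ê_k24)/π mod 24`, the peak time of the fitted 24-h
  cosine on the ZT clock. When the time axis does not start at 0 the sample
  start time is added back, so the phase is always absolute clock time.

Scores are computed on raw FPKM by default; `log_transform` scores
`log2(FPKM + 1)` instead. Replicates at the same time point are collapsed
by mean (configurable to median) before any spectral computation.

## Permutation significance

`p = (1 + #{null ≥ observed}) / (1 + n_perm)`, computed on P(24) (rank
equivalence with RP24 and F24 makes this exact, and it is the cheapest of
the three). Ties count toward the numerator and the +1 pseudocount avoids
p = 0, making the test slightly conservative; the minimum achievable p is
`1/(n_perm + 1)`. The library default is `n_perm = 10 000` (with ~10⁴
transcripts, BH at q ≤ 0.05 needs resolution well below 5 × 10⁻³); the
bundled experiments use 2 000 permutations, which gives p-resolution
5 × 10⁻⁴ — ample for ~10³-transcript simulations. Permutations are drawn
uniformly with replacement from the N! orderings; exhaustive enumeration is
provided only for N ≤ 8 (used as the oracle in tests). Benjamini-Hochberg
q-values are computed per condition across all scored transcripts.

## Classification

q ≤ 0.05 is rhythmic, q ≥ 0.075 arrhythmic; the open band between them is
indeterminate and removed. "Detectable" means max/min fold change ≥ 1.5 and
median expression ≥ 1 FPKM; a profile touching 0 has infinite fold and
passes any fold rule (an all-zero profile is undefined and fails). ELC
requires rhythmic + detectable in young and arrhythmic in old (no expression
requirement in the arrhythmic age — detectability is defined for rhythmic
transcripts); LLC is the mirror image. RLC requires rhythmic in both ages,
detectable at 1.5-fold in at least one, with the other age allowed the
relaxed 1.4-fold; the 1 FPKM median rule applies to both ages (the
conservative reading; configurable via the thresholds object).

## Staccato screening

Profiles that spike at one time point per 24-h cycle
(`E_n = E0 + ΔE` at `n ∈ {φ, φ+N/2}`, baseline elsewhere) have Fourier
coefficients `2ΔE·e^(−2πikφ/N)` at even k ≠ 0 and exactly 0 at odd k, which
puts their folded powers at k = 2, 4, 6 in ratio 2:2:1 and fixes
RP24 = 2/3 regardless of ΔE. Three scores screen them out:

- **SP** (spectral parity) = `log(Σ_{k even} P / Σ_{k odd} P)` over non-DC
  k ≤ N/2. Large for spike trains, but also for clean sinusoids, so SP never
  acts alone.
- **PVEC** (phase variance of even coefficients): the arguments of the even
  coefficients are first aligned by multiplying `Ê_k` by `e^(+2πikφ̂/N)`,
  with `φ̂` the spike-position estimate (argmax of the profile modulo N/2);
  for an ideal spike train the aligned arguments coincide for every φ, giving
  PVEC = 0 exactly. Dispersion is measured as the circular variance
  (1 − mean resultant length), not the linear variance of angles, which
  would be discontinuous at ±π. Zero-magnitude coefficients are excluded;
  fewer than two usable coefficients (e.g. a pure cosine) → undefined, and
  undefined never flags.
- **Spike variance fraction**: the share of profile variance explained by
  the best-fitting two-spike model over all spike positions. A pure 24-h
  cosine caps at 0.4 on the 12-point grid; an ideal spike train is 1.

A profile is flagged when SP ≥ 1.5 AND PVEC ≤ 0.15 AND spike fraction
≥ 0.75. These cutoffs were calibrated once on 500 simulated noisy spike
trains (ΔE = 10, additive noise SD up to 1.0 — all flagged) against 2 500
noisy sinusoids across SNR 0.5–15 and pure-noise profiles (≤ 0.2% falsely
flagged), then frozen. A transcript flagged in either age is excluded from
all named classes.

## Phase geometry

For display, RP24 is squashed by `σ(RP24) = RP24/(1+RP24)` (equivalently the
base-2 logistic in `S = log2 RP24`) and the state is the complex point
`z = σ(RP24)·e^(iθ)` with `θ = π/2 − Phase·π/12`: ZT0 up, ZT12 down,
clockwise clock. Circular histograms use half-open 30-minute bins (48 per
circle). Phase changes between ages use the shortest signed arc in
(−12, 12] h, positive = delay; an exact 12-h change tie-breaks to delay.
Medians of phase samples are circular medians (the sample point minimizing
total circular distance), since linear medians are meaningless across the
midnight wrap. Dot-and-arrow figures are emitted together with a plain-text
coordinate table so the geometry is testable without image comparison.

## Simulator

`simulate_sinusoid` draws `E(t) = A·cos(ωt + φ) + B + ε`, `ε ~ N(0, σ²)`,
`σ = A/√SNR`, with A = 1, ω = 2π/24 h⁻¹, SNR spanning 0.01–15 and baseline
B up to 300. Values may be negative at low B; an FPKM-emulation option clips
at zero (introducing a small upward bias near zero, documented here rather
than hidden). The time grid is configurable through `n_points`/`dt` but must
have an even number of points: a 7-point 0–24 h grid that includes both
endpoints samples the same clock phase twice and is incompatible with the
even-N power-spectrum fold, so phase-accuracy experiments run on the
12-point/48-h design used for the expression data.

`simulate_dataset` plants ELC/RLC/LLC/NR/staccato classes in a paired
young/old matrix: rhythmic ages get unit-amplitude sinusoids with uniform
random phases, arrhythmic ages get baseline + Gaussian noise with the same
σ, spike trains appear in both ages. Baselines are drawn U[2, 5] so that a
unit-amplitude rhythm is detectable under the 1.5-fold / 1 FPKM rules
(fold (B+1)/(B−1) ∈ [1.5, 3] over that range); the planted-class default is
SNR = 10 with 200 transcripts per class. What the simulator does *not*
emulate: count noise (no negative binomial), transcript-length or depth
effects, replicate structure beyond simple averaging, and correlated noise
across time points — so passing recovery tests demonstrate the statistical
machinery, not robustness to every artifact of real RNA-seq.

`phase_recovery_experiment` reports, per SNR, the mean RP24 and the mean
absolute/signed circular phase error over uniformly random true phases; the
error is exactly 0 in the noise-free limit and shrinks monotonically with
SNR (the directional claim the tests assert; bundled runs use 250
replicates per SNR point).

## Enrichment

Promoters are the up-to-6000-nt region upstream of the annotated TSS
(transcript 5′ end, strand-aware, clipped at the contig boundary) plus the
first intron in transcript order, joined with a 20-N linker so no motif can
span the junction; single-exon transcripts contribute the upstream segment
only. Overlap with neighboring genes is not masked. FIMO occurrence tables
are filtered at occurrence p ≤ 5 × 10⁻⁵ and collapsed to per-promoter
presence/absence. Enrichment of a cluster is the upper-tail hypergeometric
probability `P(X ≥ k)` with universe all promoters that were scanned
(transcripts with extractable promoters, the reported convention), BH
corrected across motifs within each cluster; clusters need ≥ 10 members by
default. Welch's unequal-variance t-test compares RP24 and expression
between motif-present and motif-absent cluster members; subgroups below two
members are marked untestable.

## Numerical conventions

- Undefined scores are NaN; infinite RP24/SP are genuine `inf` values that
  sort and plot correctly. NaN never silently propagates into a
  classification: undefined q defaults to 1 (arrhythmic) and undefined
  staccato scores never flag.
- "Zero odd coefficients" and the RP24 = 2/3 spike identity hold exactly in
  the algebra and to ~1e−9 absolute tolerance in floating point; a
  noise-free cosine's SP is therefore astronomically large rather than
  literally infinite.
- All randomness flows through `numpy.random.default_rng` seeded once per
  entry point; identical (data, n_perm, seed) reruns are byte-identical,
  and the resolved configuration is written next to every CLI run's outputs.

## Problem sizes in the bundled experiments

Spectral agreement uses 1000 random profiles; rank equivalence 200 profiles
at 200 permutations; type-I error 2000 noise profiles at 199 permutations
(chosen so p ≤ α is attainable at exactly the nominal rate); phase recovery
250 replicates per SNR in {0.01, 0.1, 1, 15}; planted-class recovery 200
transcripts per class at SNR = 10 scored with 2000 permutations; the
hypergeometric cross-check enumerates every (M ≤ 25, K, n, k) case. These
sizes are the package's reference experiment design and are what the test
suite and `scripts/acceptance.py` execute.

## Known limitations

- LD data only: decaying free-running rhythms violate the stable-oscillation
  assumption.
- The period grid is fixed by the sampling design; 24 h must be on the grid
  (`T/k = 24` for some integer k ≤ N/2) or scoring is refused.
- The staccato cutoffs are simulation-calibrated defaults, not universal
  constants; they are exposed on `ClassificationThresholds` and recorded in
  run metadata.
- Gene-level aggregation is out of scope; the scores are per transcript.
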