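# Methods

This note documents the models and algorithms implemented in
`subnanospec`, the parameters that matter, the numerical conventions, and
what the simulation-based tests do and do not establish.

## Signal model

A translocation blocks the open-pore current I₀; the blockade at sample
time t is ΔI(t) = I₀ − I(t). The working assumption is that ΔI is
dominated by the volume of the residue(s) in the pore waist, so the
per-residue blockade is modelled as a linear function of residue features
derived from amino-acid volumes (Å³, Zamyatnin 1972 whole-residue set,
bundled as `data/volumes_zamyatnin1972.tsv` and swappable). Unmodelled
variance — residue mobility, hydrophobicity, configurational noise — is
treated as additive noise and attacked by consensus averaging.

## Event extraction

The detector is a re-implementation in the OpenNanopore family:
running-median baseline (window `baseline_window`, default 2001 samples),
noise SD from the MAD of the residual (×1.4826), candidate events as
maximal runs with ΔI > `threshold_sigma`·σ (default 5), and each boundary
refined by a two-segment least-squares change point in a ±16-sample
window (equivalent to maximizing the CUSUM mean-shift statistic; exact
for a step edge at low noise). Published parameter values for this stage
do not exist, so the defaults are engineering choices validated against
the simulator: ≥95 % of embedded events are recovered with boundaries
within a couple of samples at depth ≥5×noise. Two duration thresholds are
deliberately distinct: the extraction floor (42 µs, the sampling-rate
limit for informing on single residues at 500 kS/s) and the analysis
filter (170 µs, the median-duration cut applied before consensus
building). Fractional blockades ΔI/I₀ are clipped to [0, 1] only when
binned into the 150×150 Gaussian-smoothed heatmap; stored signals are
never clipped.

## Resampling and normalization

Every nanospectrum is resampled to m = 500 points: bin means over index
ranges `[round(jL/m), round((j+1)L/m))` when L > m (equal-as-possible
bins; exact pairwise averaging when L = 2m), linear interpolation at m
equally spaced index positions when L < m. Z-normalization uses the
population SD so the output SD is exactly 1; numerically constant vectors
(relative SD below 1e−12) are rejected rather than normalized into noise.

## Theoretical nanospectra

A fitted model predicts one value per residue; expansion to length m
places residue k's anchor at fractional position (k−½)·m/n, interpolates
linearly between anchors and extends flat beyond the terminal anchors, so
each residue owns a symmetric dwell segment of expected length m/n. For
orientation the untrained unit-slope 1AAV model is used (the prediction
is the volume profile itself; every downstream correlation is
affine-invariant, so the slope is without loss of generality). Whether
predictions are z-normalized before or after expansion is immaterial for
PCC; this implementation normalizes after expansion.

## Slope-constrained DTW

Empirical and theoretical spectra (both z-normalized, equal length m) are
aligned by dynamic programming over step blocks (1,1), (2,3) and (3,2)
with squared-error pair costs. Within a (2,3) block ending at (i,j) the
pairs are (i−1,j−2), (i,j−1), (i,j) — the middle point of the longer side
pairs with the later point of the shorter side, so every index is matched
exactly once per block and the cost is additive; (3,2) is symmetric. This
is the minimal step set whose reachable local slopes are exactly
{1, 2/3, 3/2}; consequently any 6 consecutive points on one axis are
matched by 4–9 points on the other, and no axis can stall for more than
two consecutive pairs (no singularities). The (m+1)×(m+1) table costs
O(m²); the inner loop is numba-compiled (pure-Python fallback) and one
m = 500 alignment takes ~3 ms. Traceback tie-breaks deterministically,
preferring (1,1), then (2,3), then (3,2). Correctness is anchored by an
exhaustive path-enumeration oracle for m ≤ 10 and by structural audits of
every traceback at m = 500. The match score is the PCC of the two
sequences read along the path, each matched pair contributing once (a
convention; a warped-projection PCC would differ slightly).

## Orientation and consensus

S is called *forward* iff PCC(S,T) > PCC(S′,T) for the reversed spectrum
S′; ties go to backward and raise an ambiguity flag (many real spectra
differ only slightly between the two correlations). Backward spectra are
flipped before combining. The *average consensus* is the element-wise
mean of the oriented, z-normalized spectra. The *alignment consensus*
ranks spectra once by DTW distance to the average consensus (ranking is
not repeated against the evolving consensus; the procedure ranks before
the update loop) and folds the top t = 50 in one at a time: the spectrum
is warped onto the consensus, projected onto the consensus axis (per
consensus index, the mean of the spectrum values matched to it — the only
way a weighted average is well defined across a warp), and averaged with
weight 1 against u + i − 1 (u = 30). As u → ∞ the update vanishes and the
alignment consensus converges to the average consensus (verified at
u = 1e9 to 1e−6).

## Residue extraction and model fitting

One observed value per residue is read off the DTW alignment between
consensus and theoretical spectrum: the mean of the consensus values
matched to theoretical indices in residue k's segment
[(k−1)·m/n, k·m/n). Note that this segment mean is a smoothed version of
the anchor value (for the noise-free template it equals approximately
(t̂ₖ₋₁ + 6t̂ₖ + t̂ₖ₊₁)/8), which attenuates the fitted volume slope by a
fixed ≈7 % even with no noise; consistency tests therefore compare fitted
slopes against the same extraction applied to the noise-free template
rather than against the raw generating slope. Models are fitted by OLS
with an intercept (z-normalized targets make it near zero and harmless);
a degenerate intercept-only model is supported for baseline comparisons.
Cross-validation is two-fold with the two peptides as folds, and the
reported MSE pools the residuals of both folds (with equal 42/42 folds
this coincides with the mean of the per-fold MSEs).

## Decoy significance

Decoy peptides are drawn i.i.d. uniformly over the 20-letter alphabet
(composition matching would be a stricter null; uniform is the simplest
and is recorded in the output). Each decoy is scored exactly like the
target (predict → expand → z-normalize → constrained DTW → path PCC);
p = #(decoy ≥ observed)/n, the plain counting fraction, with a (k+1)/(n+1)
variant behind a flag for users who need p > 0. Decoys whose theoretical
spectrum is constant (homopolymers under position-free models) score a −1
sentinel: they are counted in the denominator, reported, and excluded
from the decoy mean. Under a null in which the consensus comes from an
unrelated random peptide, the p-value is uniform up to the 1/n lattice
(KS statistic ≲ 0.05 at n = 200 over 200 replicates).

## Simulator

The generator emulates: log-normal blockade durations (median 170 µs,
shape σ = 1, matching a regime where the duration median sits at the
analysis filter and about half the events survive it; range tens of µs to
ms), per-residue dwell-time jitter (log-normal multiplicative, mean 1,
CV 0.3 — positive and scale-free), additive Gaussian noise (SD 0.2 in
z-units), a 50/50 forward/backward orientation split, and optional
heavy-tail "slip-stick" duration outliers (off by default). The generating
signal is the continuous piecewise-linear volume profile evaluated
through the per-residue dwell warp — with zero jitter this is the same
construction as the theoretical expansion, which is what makes noiseless
end-to-end identities exact rather than approximate. Identity tests pin
the duration at 1000 µs (exactly 500 samples at 500 kS/s) so resampling
is the identity; with varying durations, bin-mean downsampling and
point-interpolation differ at anchor kinks by O(slope/m), a real but
small discretization effect. Trace synthesis adds an open-pore baseline
(250 pA, noise 6 pA) and a mean blockade depth of 0.35·I₀ with ±10 pA/z
modulation; these absolute current levels are plausible engineering
values for regime realism, not measured constants.

What the simulator does **not** model: amplifier bandwidth and filtering,
residue back-stepping (backward fluctuations during translocation; the
DTW step set cannot represent them), 1/f and capacitive noise structure,
inter-molecule depth variation beyond the modelled noise, and any
sequence-dependent dwell kinetics. Passing simulation tests therefore
demonstrates algorithmic correctness and noise behaviour under this
generative model, not performance on real acquisitions.

## Numerical conventions and degenerate inputs

Boundary semantics keep events with duration exactly equal to the filter
threshold. Resampling bin edges use `round(jL/m)`. Orientation ties break
to backward, DTW traceback ties to the diagonal block. OLS rejects
rank-deficient designs naming the collinear columns rather than silently
pseudo-inverting. Constant spectra are rejected wherever a correlation or
normalization would be undefined, except in decoy scoring where they
become an explicit sentinel. All randomness flows from a single seed with
per-spectrum substreams, so any one simulated spectrum is reproducible in
isolation and pipeline reports are byte-identical across repeated runs.

## Problem sizes

The default test and reproduction runs use simulated datasets of 950 and
4000 events for the two peptides (≈470 / ≈2000 after the 170 µs filter),
m = 500, t = 50, u = 30, and 10,000 decoys per significance estimate; the
property-test suite uses smaller sizes (tens to hundreds of spectra,
200-decoy nulls) chosen so stochastic assertions are stable across seeds.

## Known limitations

- The ABF reader/writer supports the classic version-1 header with
  float32, single-channel, gap-free data only; integer-encoded or ABF2
  files are rejected with a clear error.
- Event detection assumes events are short relative to the baseline
  window; multi-millisecond blockades bias the running median and should
  be handled with a larger window.
- The volume table ships one published variant of residue volumes;
  side-chain-volume variants would change fitted slopes but not
  correlations materially. Two adjacent volume groups overlap slightly in
  the real data (V vs E), so table validation enforces increasing group
  means rather than disjoint group ranges.
- Back-stepping detection, nanospectral clustering for peptide mixtures,
  and proteome-scale database search are out of scope.
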