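# Methods

## The combinatorial glycan mass lattice

A glycoprotein complex with several complex N-glycans varies from copy to
copy in three ways that matter for intact mass: antenna branching
(+GlcNAc₁Gal₁), antennary fucosylation (+Fuc) and terminal sialylation
(+Neu5Ac). Under the average-mass convention (appropriate above ~100 kDa,
where isotope envelopes are unresolved) the increments are 365.33, 146.14
and 291.26 Da, which are 5, 2 and 4 multiples of ~73 Da to within 0.26 Da
per unit. Any combination of additions therefore sits near a one-dimensional
lattice with unit spacing ~72.95 Da; the deviation of each residue from its
ideal multiple (Fuc +0.07, Neu5Ac −0.14, branch +0.07 Da per unit) is what
makes the collapsed lattice spacing a distribution rather than a constant.

Average masses use the IUPAC 2021 standard (abridged) atomic weights
(H 1.008, C 12.011, N 14.007, O 15.999); monoisotopic masses use the
principal-isotope masses. Every API that returns a mass requires an explicit
`kind` of `"mono"` or `"average"` — the conventions differ by ~0.5 Da per
residue, and published intact-mass work freely mixes them, so a silent
default would invite mis-annotation. The `branch` unit is defined as
HexNAc + Hex and its mass computed as that sum, so the identity
`m(branch) = m(HexNAc) + m(Hex)` holds to the last bit.

### Repeat-unit estimation and vacant rungs

`repeat_unit` collapses an enumerated ladder by single-linkage chaining
(consecutive gaps ≤ `merge_tol`, default 1.5 Da — chosen to fuse the
1.02 Da Neu5Ac/2×Fuc near-degeneracy into one rung) and averages the
consecutive spacings of the rung centroids. Combinatorial ladders have
vacant rungs: unit counts that no composition within the ranges realizes
(1, 3, and a handful near the top of the range, where the count constraints
bind). A vacant rung registers as a doubled or tripled spacing and would
bias the naive mean upward by several Da. Both `repeat_unit` and
`fine_structure_interval` therefore apply the same vacancy rule: any gap
close to an integer multiple k ≥ 2 of the median gap is split into k equal
sub-gaps before averaging. On the full enumeration (Fuc ≤ 6, Neu5Ac ≤ 16,
branch ≤ 10; 1309 compositions, 123 rungs) this yields 72.94 ± 0.59 Da.
Both estimators — theoretical (from the enumerated ladder) and empirical
(from measured peak positions) — are provided, since either is a legitimate
way to calibrate the lattice filter.

### Composition search and degeneracy

`find_compositions` is a deliberate brute force over the residue-count grid:
the grids involved (≤ a few thousand compositions) make cleverness
pointless, and exhaustiveness is the guarantee the annotation layer relies
on. Ties are broken deterministically: smallest |error|, then fewest total
residues, then lexicographic residue order. Degeneracies that native MS
cannot resolve at the intact level — one Neu5Ac vs two Fuc (1.02 Da apart),
two branch units vs five Fuc (0.04 Da), one PE phospholipid (~731 Da) vs two
branch units (730.67 Da) — are always reported as candidate sets; a priority
order (glycan-only before adduct-bearing, fewer residues first) selects a
primary label but never suppresses the alternatives.

## The synthetic-data generator

The generator emulates a disulfide-linked two-subunit transporter complex:
an apo polypeptide base of 127 027 Da carrying a fixed scaffold of four
N-glycan cores (Hex₃HexNAc₂ each) plus four core fucoses, with per-copy
variation drawn from: a discretized Gaussian over 12–21 total branch units
centred at 16 (four tetra-antennary glycans; with zero antennary fucose this
gives the 137 028 Da reference glycoform), antennary fucose counts 0–4 with
the tri/tetra forms more abundant than the bi-fucosylated one, and 9–16
total sialic acids centred at 13. Sub-stoichiometric adducts are sampled
independently: one phospho site at 20% occupancy, an optional palmitoyl
site (off by default; the wild type retains its lipid instead), and two
phospholipid (PE, 731 Da) sites at 40% occupancy each. All randomness flows
through one seeded generator and the seed plus a config hash are recorded in
every output.

The electrospray forward model places unit-area Gaussian peaks at
(M + z·1.00728)/z for integer charges in a discretized Gaussian envelope
(centre 26, spread 2 — positive mode only), with peak fwhm 0.8 m/z on a
0.1 m/z grid, optional detergent satellites as a geometric series of
+k·(monomer mass) peaks, and additive Gaussian noise scaled to the maximum
signal. What the generator does **not** emulate: isotope structure
(unresolved at this mass), Lorentzian tails and peak asymmetry, m/z-dependent
transmission, space-charge effects, chemical baseline, or correlated noise.
Passing tests on this synthetic data therefore demonstrate the correctness
of the lattice arithmetic, the charge-inference logic and the statistical
estimators — not robustness to every artifact of real spectra.

Mass-photometry events are drawn from a Gaussian mixture whose component
means include the proteomicelle (detergent) offset; the refit uses a
scikit-learn Gaussian mixture (EM, seeded, 5 restarts) and ratios come from
the fitted weights.

## Deconvolution

This is intentionally not a Bayesian joint charge–mass deconvolution; the
analytical leverage for this class of sample is the repeat-unit constraint,
so the implementation is a lattice-aware reconstruction:

1. **Centroiding.** Local maxima above a robust noise floor
   (median + `min_snr` × 1.4826·MAD), centroided by log-parabolic apex
   interpolation — exact for Gaussian peaks and free of the grid-phase bias
   of thresholded weighted means. For noisy spectra a matched Gaussian
   pre-filter (`smooth_fwhm` ≈ the known peak width) is recommended and used
   by the pipeline.
2. **Charge inference.** Fine-structure peaks are merged into one hump per
   charge state by Gaussian smoothing (σ = 6 m/z). From the most intense
   unassigned hump, each candidate charge z implies M = z(m/z − 1.00728) and
   predicts hump positions for all other charges; the z matching the most
   humps wins. The match tolerance is proportional to the local inter-hump
   spacing M/(z(z+1)) (fraction 0.08) rather than a fixed m/z window:
   envelope asymmetry shifts hump centroids by a few m/z, while a wrong
   charge displaces predictions by a full spacing, so the relative tolerance
   separates the two cleanly. Matched humps form one species; the search
   repeats on the remainder, which separates overlapping monomer/dimer
   envelopes. Every fine peak is then routed to the member charge placing
   its neutral mass closest to the species mass estimate (residuals above
   half a charge spacing are left unassigned). Humps supporting no
   consistent charge are flagged, not dropped.
3. **Zero-charge reconstruction.** Neutral masses deposit their intensity on
   a 0.5 Da grid, split linearly between flanking bins so total intensity is
   conserved exactly. With a repeat filter set (72.95 Da by default), a
   lattice is anchored at the most intense mass and detected peaks more than
   `lattice_tol` = 10 Da off-lattice are flagged — deliberately wide enough
   that phospho (+80) and lipid (+731 ≈ 2 lattice steps + 0.4) adducts
   survive as flagged or near-lattice peaks rather than being filtered away.
4. **Fourier repeat.** The segment is resampled at a quarter of the finest
   peak spacing, mean-subtracted and Fourier transformed; the winning bin is
   refined by maximizing the continuous periodogram. A periodicity is
   reported only when the peak exceeds 3× the median power **and** carries
   ≥ 5% of the non-DC power — the fraction criterion is what actually
   rejects white noise, because the maximum over thousands of
   exponentially-distributed noise bins routinely exceeds any fixed multiple
   of the median.

## Annotation and differential analyses

`infer_base_mass` grid-searches the lattice anchor minimizing
abundance-weighted squared distances of detected peaks to base + k·spacing
(0.05 Da steps over one aliasing period), with a profile-curvature error
bar; a flat objective or a single peak raises an ambiguity error carrying
the aliasing period. The search assumes the series is dominated by the
primary lattice; in practice the anchor is usually fixed from a known
composition (e.g. 131 183 Da = apo + glycan scaffold for the default
complex) and the grid search is a cross-check.

`sialic_census` matches each sialylated peak to the desialylated anchor
minimizing |ΔM − k·291.26| over integer k; on noise-free pairs the true
anchor has zero residual while the nearest wrong pairing is ≥ 1.02 Da away,
so the census is exact by construction. `adduct_share` models the intact
P-series as (1−f)·S + f·shift(S, k steps) with the dissociated series S as
reference; f has a closed-form least-squares solution clipped to [0, 1],
with a 200-resample seeded residual bootstrap for the interval. Both series
are normalized to unit sum first, making the estimate scale-invariant.
Envelope decomposition fits k Gaussians (lmfit, non-negative amplitudes,
k-quantile initialization) over the P-index axis and flags a second
component above 10% of the first — the signature of a hidden (e.g.
lipid-shifted) subpopulation.

## Oligomer assembly models

Under assembly independence an n-mer's mass distribution is the n-fold
self-convolution of the subunit distribution; on a uniform grid the
discrete convolution preserves the moment identities (mean n·μ, variance
n·σ²) to floating-point precision, which the tests check at 1e-9 relative
error. `interface_delta` defaults to 0 — assembly without interfacial
ligands — and a nonzero value shifts only the mean, so a measured n-mer mean
within the combined sd of the prediction is evidence against a retained
interfacial species. Modification occupancy under independence is
Binomial(order × sites, p); the goodness-of-fit test uses the chi-square
statistic when all expected cells are ≥ 5 and an exact multinomial tail
otherwise (vectorized over the last two cells; limited to ≤ 10⁴ events).
Type-I error is calibrated by simulation in the test suite (1000 seeded
replicates at α = 0.05, n = 200 events).

## Numerical and interface choices

* Proton mass 1.00728 Da; positive mode only.
* Zero-charge grid 0.5 Da; peak detection by local maxima with valley
  splitting and centroids restricted to bins ≥ 25% of the local apex, so a
  strong neighbour's tail cannot drag a weak peak's centroid.
* Assignment tolerance defaults to ±2 Da, matching the precision with which
  zero-charge masses are quoted in this kind of experiment.
* mzML input goes through pyteomics when its full PSI stack is importable;
  otherwise a minimal reader (stdlib XML + base64/zlib, 64/32-bit float
  arrays, MS1 scans only) handles the plain profile exports this package
  consumes. Two-column text remains the primary format.
* All file writes are atomic (temp file + rename); CSV headers carry units;
  human-facing labels are 1-based (P1…), internal branch counts 0-based.
* P-series indices are relative: P1 is the lowest branch count observed (or
  configured), not an absolute antenna count, since the minimal glycoform is
  generally not observable.

## Problem sizes

The test suite and acceptance checks run on desk-scale synthetic data:
populations of 400–3000 sampled proteoform draws (≈ 50–230 unique
proteoforms), spectra of ~3×10⁴ grid points spanning one charge envelope,
ladder enumerations of ~1300 compositions, and 1000-replicate calibration
loops. These sizes keep the full suite under half a minute while leaving
every estimator in the regime where its asymptotics are visible.

## Known limitations

* Charge-state humps must be resolvable after smoothing; at mass spreads
  approaching the inter-charge spacing (≳ M/z² per state) charge inference
  will merge species.
* Fine peaks whose true mass lies more than half a charge spacing from the
  species mass estimate are routed to the wrong charge or dropped; this is a
  physical ambiguity of overlapping envelopes, not an implementation limit.
* `infer_base_mass` is biased by strong sub-lattice structure (a fucose
  ladder inside a branching series); fix the base from composition when one
  is known.
* The degeneracy policy labels, but cannot resolve, compositions closer than
  the mass accuracy; resolving them requires orthogonal data (enzymatic
  treatment, dissociation, glycoproteomics), which is exactly the
  differential workflow the `annotate` module implements.
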