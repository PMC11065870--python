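"""Charge inference, fine-structure intervals, zero-charge reconstruction.

This is deliberately not a full Bayesian charge/mass joint deconvolution: the
analytical leverage for heavily glycosylated complexes is the ~73 Da glycoform
repeat unit, so reconstruction here is lattice-aware — charge states are
assigned by mutual neutral-mass consistency, and the zero-charge distribution
can be constrained to a repeat-unit lattice anchored at the most intense mass,
with off-lattice peaks (phospho / lipid adducts) retained and flagged rather
than discarded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np
from scipy import signal as sps

from .glycomass import PROTON_MASS, InsufficientDataError
from .synthesize import Spectrum

__all__ = [
    "PeakList",
    "ChargeSeries",
    "ChargeAssignment",
    "MassDistribution",
    "centroid",
    "infer_charges",
    "fine_structure_interval",
    "fourier_repeat",
    "zero_charge",
]


@dataclass
class PeakList:
    """Centroided peaks: (m/z, intensity, fwhm) sorted by m/z."""

    mz: np.ndarray
    intensity: np.ndarray
    fwhm: np.ndarray

    def __post_init__(self):
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        self.fwhm = np.asarray(self.fwhm, dtype=float)
        if not (self.mz.size == self.intensity.size == self.fwhm.size):
            raise ValueError("mz, intensity, fwhm must have equal length")
        if self.mz.size:
            order = np.argsort(self.mz)
            self.mz, self.intensity, self.fwhm = (
                self.mz[order],
                self.intensity[order],
                self.fwhm[order],
            )
            if np.any(self.intensity <= 0):
                raise ValueError("peak intensities must be > 0")

    def __len__(self) -> int:
        return self.mz.size

    def slice(self, lo: float, hi: float) -> "PeakList":
        mask = (self.mz >= lo) & (self.mz <= hi)
        return PeakList(self.mz[mask], self.intensity[mask], self.fwhm[mask])


@dataclass
class ChargeSeries:
    """Peaks of one charge state of one species, with neutral masses."""

    z: int
    member_mz: np.ndarray
    member_intensity: np.ndarray
    species: int = 0

    def __post_init__(self):
        self.member_mz = np.asarray(self.member_mz, dtype=float)
        self.member_intensity = np.asarray(self.member_intensity, dtype=float)

    @property
    def neutral_masses(self) -> np.ndarray:
        return self.z * (self.member_mz - PROTON_MASS)

    @property
    def mass_mean(self) -> float:
        w = self.member_intensity
        return float(np.average(self.neutral_masses, weights=w))

    @property
    def mass_sd(self) -> float:
        m = self.neutral_masses
        w = self.member_intensity
        mean = np.average(m, weights=w)
        return float(np.sqrt(np.average((m - mean) ** 2, weights=w)))


@dataclass
class ChargeAssignment:
    """Result of charge inference: assigned series plus flagged leftovers."""

    series: List[ChargeSeries] = field(default_factory=list)
    species_masses: Dict[int, float] = field(default_factory=dict)
    unassigned_mz: List[float] = field(default_factory=list)

    def by_species(self, species: int) -> List[ChargeSeries]:
        return [s for s in self.series if s.species == species]


@dataclass
class MassDistribution:
    """Zero-charge mass axis with abundances.

    The deconvolution product and the operand of the oligomer assembly model.
    The grid is strictly increasing (uniform for convolution use); abundances
    are >= 0 and sum to 1 when normalized.
    """

    masses: np.ndarray
    abundance: np.ndarray
    normalized: bool = False
    lattice_flags: np.ndarray | None = None  # per-detected-peak on-lattice flag

    def __post_init__(self):
        self.masses = np.asarray(self.masses, dtype=float)
        self.abundance = np.asarray(self.abundance, dtype=float)
        if self.masses.shape != self.abundance.shape:
            raise ValueError("masses and abundance must have equal shape")
        if np.any(np.diff(self.masses) <= 0):
            raise ValueError("mass grid must be strictly increasing")
        if np.any(self.abundance < 0):
            raise ValueError("abundances must be >= 0")

    def total(self) -> float:
        return float(self.abundance.sum())

    def normalize(self) -> "MassDistribution":
        total = self.total()
        if total <= 0:
            raise ValueError("cannot normalize an all-zero distribution")
        return MassDistribution(
            self.masses, self.abundance / total, normalized=True,
            lattice_flags=self.lattice_flags,
        )

    def mean(self) -> float:
        return float(np.average(self.masses, weights=self.abundance))

    def var(self) -> float:
        mu = self.mean()
        return float(np.average((self.masses - mu) ** 2, weights=self.abundance))

    def sd(self) -> float:
        return float(np.sqrt(self.var()))

    def argmax_mass(self) -> float:
        return float(self.masses[int(np.argmax(self.abundance))])

    def peaks(self, min_frac: float = 0.01, min_prominence: float | None = None):
        """Detected peaks as (mass, abundance) centroids.

        Local maxima above ``min_frac`` of the global maximum are found with
        at least ``min_prominence`` (defaults to the same threshold); the
        axis is then partitioned at the valleys between adjacent maxima, and
        each region yields an intensity-weighted centroid (restricted to bins
        above a quarter of the local apex, so neighbouring tails do not drag
        the centroid) and the region's summed abundance.
        """
        y = self.abundance
        if y.max() <= 0:
            return np.empty(0), np.empty(0)
        thresh = min_frac * y.max()
        prom = min_prominence if min_prominence is not None else thresh
        from scipy import signal as _sps

        maxima, _ = _sps.find_peaks(y, height=thresh, prominence=prom)
        if maxima.size == 0:
            # a lone nonzero bin at the array edge is still a peak
            maxima = np.array([int(np.argmax(y))])
        bounds = [0]
        for a, b in zip(maxima[:-1], maxima[1:]):
            bounds.append(a + int(np.argmin(y[a : b + 1])))
        bounds.append(y.size)
        centers, heights = [], []
        for i, m in enumerate(maxima):
            region = slice(bounds[i], bounds[i + 1])
            w = y[region]
            top = w >= 0.25 * y[m]
            centers.append(float(np.average(self.masses[region][top], weights=w[top])))
            heights.append(float(w.sum()))
        return np.array(centers), np.array(heights)


def centroid(
    spec: Spectrum,
    min_snr: float = 3.0,
    min_prominence: float | None = None,
    smooth_fwhm: float | None = None,
) -> PeakList:
    """Pick local-maximum peaks above the noise floor and centroid them.

    The noise floor is estimated robustly (median + ``min_snr`` x scaled MAD
    of the intensity trace); each surviving local maximum is centroided by the
    intensity-weighted mean over its half-height support, from which the fwhm
    is also estimated.  ``smooth_fwhm`` applies a matched Gaussian filter of
    that width (m/z) before peak picking — recommended at roughly the known
    peak width when the spectrum is noisy.  An all-noise/flat spectrum yields
    an empty peak list.
    """
    if len(spec) == 0:
        raise ValueError("empty spectrum")
    y = spec.intensity
    if smooth_fwhm is not None:
        from scipy.ndimage import gaussian_filter1d

        step = float(np.median(np.diff(spec.mz)))
        sigma_pts = smooth_fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0))) / step
        y = gaussian_filter1d(y, sigma_pts)
    med = float(np.median(y))
    mad = float(np.median(np.abs(y - med)))
    floor = med + min_snr * 1.4826 * mad
    floor = max(floor, 1e-9 * y.max()) if y.max() > 0 else np.inf
    prominence = min_prominence if min_prominence is not None else floor
    peaks, props = sps.find_peaks(y, height=floor, prominence=prominence)
    if peaks.size == 0:
        return PeakList(np.empty(0), np.empty(0), np.empty(0))

    centers, intensities, widths = [], [], []
    for p in peaks:
        half = y[p] / 2.0
        i0 = p
        while i0 > 0 and y[i0 - 1] >= half and y[i0 - 1] <= y[i0]:
            i0 -= 1
        i1 = p
        while i1 < y.size - 1 and y[i1 + 1] >= half and y[i1 + 1] <= y[i1]:
            i1 += 1
        # log-parabolic apex interpolation: exact for a Gaussian peak and
        # free of the grid-phase bias of a thresholded weighted mean
        center = float(spec.mz[p])
        if 0 < p < y.size - 1 and y[p - 1] > 0 and y[p + 1] > 0:
            la, lb, lc = np.log(y[p - 1]), np.log(y[p]), np.log(y[p + 1])
            denom = la - 2 * lb + lc
            if denom < 0:
                shift = np.clip(0.5 * (la - lc) / denom, -0.5, 0.5)
                step_l = spec.mz[p] - spec.mz[p - 1]
                step_r = spec.mz[p + 1] - spec.mz[p]
                center += float(shift) * float(step_r if shift > 0 else step_l)
        else:
            sl = slice(i0, i1 + 1)
            center = float(np.average(spec.mz[sl], weights=y[sl]))
        centers.append(center)
        intensities.append(float(y[p]))
        widths.append(float(spec.mz[i1] - spec.mz[i0]) or float(np.diff(spec.mz).min()))
    return PeakList(np.array(centers), np.array(intensities), np.array(widths))


def _envelope_centers(
    pl: PeakList, envelope_sigma: float, min_frac: float
) -> Tuple[np.ndarray, np.ndarray]:
    """Charge-state envelope maxima of a fine-structured peak list.

    The centroids are deposited on a coarse grid and smoothed with a Gaussian
    of width ``envelope_sigma`` (m/z), wide enough to merge glycoform fine
    structure into one hump per charge state but narrow enough to keep
    adjacent charge states apart.  Returns hump centroids and total
    intensities.
    """
    from scipy.ndimage import gaussian_filter1d

    step = max(envelope_sigma / 6.0, 0.25)
    lo = pl.mz.min() - 5 * envelope_sigma
    hi = pl.mz.max() + 5 * envelope_sigma
    grid = np.arange(lo, hi + step, step)
    profile = np.zeros_like(grid)
    idx = np.clip(np.round((pl.mz - lo) / step).astype(int), 0, grid.size - 1)
    np.add.at(profile, idx, pl.intensity)
    smooth = gaussian_filter1d(profile, envelope_sigma / step)
    maxima, _ = sps.find_peaks(smooth, prominence=min_frac * smooth.max())
    centers, totals = [], []
    half = int(round(2 * envelope_sigma / step))
    for m in maxima:
        sl = slice(max(0, m - half), min(grid.size, m + half + 1))
        w = smooth[sl]
        centers.append(float(np.average(grid[sl], weights=w)))
        totals.append(float(w.sum()))
    return np.array(centers), np.array(totals)


def infer_charges(
    pl: PeakList,
    z_range: Tuple[int, int] = (15, 35),
    envelope_sigma: float = 6.0,
    match_frac: float = 0.08,
    min_envelope_frac: float = 0.03,
) -> ChargeAssignment:
    """Assign charge states by mutual neutral-mass consistency of envelopes.

    Fine-structure peaks are first merged into charge-state envelope humps
    (Gaussian smoothing of width ``envelope_sigma``).  Starting from the most
    intense unassigned hump, every candidate charge z implies a neutral mass
    M = z (m/z - 1.00728); the candidate whose predicted hump positions
    (M + z' 1.00728)/z' match the most observed humps wins — adjacent charge
    states of one species are mutually consistent by construction.  The match
    tolerance scales with the local inter-hump spacing M/(z'(z'+1)) (fraction
    ``match_frac``), since envelope asymmetry shifts hump centroids by a few
    m/z while a wrong charge displaces them by a full spacing.  Matched humps form one species; the search repeats on the
    remainder, so overlapping envelopes (an M and a 2M series) separate into
    distinct species.  Each original fine peak is then assigned the member
    charge that places its neutral mass closest to its species' mass estimate.
    Humps supporting no consistent charge are flagged unassigned, not dropped.
    """
    if len(pl) < 2:
        return ChargeAssignment(unassigned_mz=[float(m) for m in pl.mz])
    z_lo, z_hi = int(z_range[0]), int(z_range[1])
    if z_lo < 1 or z_hi < z_lo:
        raise ValueError("invalid z_range")

    centers, totals = _envelope_centers(pl, envelope_sigma, min_envelope_frac)
    if centers.size == 0:
        return ChargeAssignment(unassigned_mz=[float(m) for m in pl.mz])
    remaining = list(range(centers.size))

    assignment = ChargeAssignment()
    species: List[Dict] = []  # {"mass": float, "members": {z: hump index}}
    while remaining:
        seed = remaining[int(np.argmax(totals[remaining]))]
        best = None
        for z in range(z_lo, z_hi + 1):
            mass = z * (centers[seed] - PROTON_MASS)
            bycluster: Dict[int, int] = {}
            for zp in range(z_lo, z_hi + 1):
                predicted = (mass + zp * PROTON_MASS) / zp
                tol = match_frac * mass / (zp * (zp + 1))
                deltas = np.abs(centers[remaining] - predicted)
                j = int(np.argmin(deltas))
                if deltas[j] > tol:
                    continue
                c = remaining[j]
                if c in bycluster:
                    prev = (mass + bycluster[c] * PROTON_MASS) / bycluster[c]
                    if abs(centers[c] - predicted) >= abs(centers[c] - prev):
                        continue
                bycluster[c] = zp
            if len(bycluster) >= 2:
                masses = np.array(
                    [zp * (centers[c] - PROTON_MASS) for c, zp in bycluster.items()]
                )
                score = (len(bycluster), -float(np.std(masses)), -z)
                if best is None or score > best[0]:
                    best = (score, bycluster)
        if best is None:
            assignment.unassigned_mz.append(float(centers[seed]))
            remaining.remove(seed)
            continue
        _, members = best
        weights = np.array([totals[c] for c in members])
        masses = np.array(
            [zp * (centers[c] - PROTON_MASS) for c, zp in members.items()]
        )
        species.append(
            {
                "mass": float(np.average(masses, weights=weights)),
                "members": {zp: c for c, zp in members.items()},
            }
        )
        for c in members:
            remaining.remove(c)

    # route each fine peak to the (species, charge) that best explains it
    buckets: Dict[Tuple[int, int], List[int]] = {}
    for i, mz in enumerate(pl.mz):
        best_key, best_rel = None, np.inf
        for sid, sp in enumerate(species):
            for z in sp["members"]:
                resid = abs(z * (mz - PROTON_MASS) - sp["mass"])
                rel = resid / (sp["mass"] / z)  # residual vs charge spacing
                if rel < best_rel:
                    best_rel, best_key = rel, (sid, z)
        if best_key is not None and best_rel <= 0.5:
            buckets.setdefault(best_key, []).append(i)
        else:
            assignment.unassigned_mz.append(float(mz))
    for (sid, z), idx in sorted(buckets.items()):
        assignment.series.append(
            ChargeSeries(
                z=z,
                member_mz=pl.mz[idx],
                member_intensity=pl.intensity[idx],
                species=sid,
            )
        )
    for sid, sp in enumerate(species):
        series = assignment.by_species(sid)
        if series:
            w = np.array([s.member_intensity.sum() for s in series])
            m = np.array([s.mass_mean for s in series])
            assignment.species_masses[sid] = float(np.average(m, weights=w))
    return assignment


def fine_structure_interval(
    pl: PeakList | Sequence[float], z: int
) -> Tuple[float, float, float]:
    """Mean and sd of adjacent fine-structure peak spacings within one charge state.

    Returns (mean dm/z, sd, implied dM = z x mean).  Combinatorial ladders can
    have vacant teeth; any gap near an integer multiple k >= 2 of the median
    gap is treated as k unit gaps of size gap/k before averaging, so a missing
    tooth does not bias the mean upward.
    """
    mz = np.asarray(pl.mz if isinstance(pl, PeakList) else pl, dtype=float)
    mz = np.unique(mz)
    if mz.size < 3:
        raise InsufficientDataError("need >= 3 fine-structure peaks")
    gaps = np.diff(mz)
    median_gap = float(np.median(gaps))
    unit_gaps: List[float] = []
    for g in gaps:
        k = max(1, int(round(g / median_gap)))
        unit_gaps.extend([g / k] * k)
    arr = np.asarray(unit_gaps)
    mean = float(arr.mean())
    sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
    return mean, sd, z * mean


def fourier_repeat(
    spec: Spectrum,
    z: int,
    min_power_ratio: float = 3.0,
    min_power_frac: float = 0.05,
) -> float | None:
    """Estimate the glycoform repeat mass from spectral periodicity.

    The segment (one charge state) is resampled onto a uniform m/z grid at a
    quarter of the finest peak spacing, mean-subtracted and Fourier
    transformed.  The dominant non-zero frequency is refined by maximizing the
    periodogram around the FFT bin; the repeat mass is period x z.  Returns
    None when no dominant periodicity exists: the winning bin must exceed
    ``min_power_ratio`` x the median power AND carry ``min_power_frac`` of the
    total non-DC power — the latter because the maximum over thousands of
    white-noise bins routinely exceeds any fixed multiple of the median.
    """
    if len(spec) < 8:
        raise InsufficientDataError("segment too short for Fourier analysis")
    pl = centroid(spec)
    if len(pl) >= 3:
        finest = float(np.min(np.diff(pl.mz)))
    else:
        finest = 8.0 * float(np.median(np.diff(spec.mz)))
    step = finest / 4.0
    grid = np.arange(spec.mz[0], spec.mz[-1], step)
    y = np.interp(grid, spec.mz, spec.intensity)
    y = y - y.mean()
    power = np.abs(np.fft.rfft(y)) ** 2
    freqs = np.fft.rfftfreq(grid.size, d=step)
    if power.size < 3:
        return None
    k = 1 + int(np.argmax(power[1:]))
    if power[k] < min_power_ratio * float(np.median(power[1:])):
        return None
    if power[k] < min_power_frac * float(power[1:].sum()):
        return None

    # refine by maximizing the continuous periodogram near the winning bin
    t = grid - grid[0]

    def neg_power(f: float) -> float:
        ph = np.exp(-2j * np.pi * f * t)
        return -np.abs(np.sum(y * ph)) ** 2

    from scipy.optimize import minimize_scalar

    df = freqs[1] - freqs[0]
    res = minimize_scalar(
        neg_power, bounds=(max(freqs[k] - df, df / 10), freqs[k] + df),
        method="bounded",
    )
    f_hat = float(res.x)
    period = 1.0 / f_hat
    return period * z


def zero_charge(
    series: Sequence[ChargeSeries],
    repeat_filter: float | None = None,
    grid_step: float = 0.5,
    lattice_tol: float = 10.0,
) -> MassDistribution:
    """Sum neutral-mass histograms of charge series onto a common grid.

    Every member peak of every series deposits its intensity at its neutral
    mass z (m/z - 1.00728), split linearly between the two flanking grid
    points (total intensity is conserved exactly).  With ``repeat_filter``
    set, detected peaks are compared to a lattice of that spacing anchored at
    the most intense mass; peaks off-lattice by more than ``lattice_tol``
    keep their mass but are flagged (phospho/lipid adducts live off-lattice).
    """
    if not series:
        raise ValueError("no charge series given")
    masses = np.concatenate([s.neutral_masses for s in series])
    weights = np.concatenate([s.member_intensity for s in series])
    lo = np.floor(masses.min() / grid_step) * grid_step - 5 * grid_step
    hi = np.ceil(masses.max() / grid_step) * grid_step + 5 * grid_step
    grid = np.arange(lo, hi + grid_step, grid_step)
    abundance = np.zeros_like(grid)
    pos = (masses - grid[0]) / grid_step
    i0 = np.floor(pos).astype(int)
    frac = pos - i0
    np.add.at(abundance, i0, weights * (1 - frac))
    np.add.at(abundance, i0 + 1, weights * frac)
    md = MassDistribution(grid, abundance)
    if repeat_filter is not None:
        centers, _ = md.peaks()
        anchor = md.argmax_mass()
        # refine anchor to the centroid of its detected peak
        if centers.size:
            anchor = float(centers[np.argmin(np.abs(centers - anchor))])
        offsets = np.abs(
            centers - (anchor + np.round((centers - anchor) / repeat_filter) * repeat_filter)
        )
        md.lattice_flags = offsets <= lattice_tol
    return md
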