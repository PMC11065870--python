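"""Lattice annotation of zero-charge distributions and differential analyses.

Peaks of a deconvolved mass distribution are explained as
``base + glycan composition + adducts`` on the combinatorial residue lattice:
the P-series indexes antenna (branch) count, the aF-series antennary fucose
count, and residuals off the glycan lattice are matched against a table of
PTM / lipid / detergent adduct masses.  Differential operations compare two
distributions: a sialylated/desialylated pair yields a per-proteoform sialic
acid census, and an intact/dissociated pair yields the bound fraction of a
lipid adduct whose mass aliases onto the glycan lattice.

Degenerate explanations (one Neu5Ac vs two Fuc, two branch units vs five Fuc,
one PE lipid vs two branch units) are always reported as candidate sets; a
deterministic priority order — glycan-only before adduct-bearing, fewer total
residues first — selects the primary label but never hides alternatives.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Sequence, Tuple

import numpy as np

from .glycomass import (
    AdductTable,
    CompositionMatch,
    GlycanComposition,
    InsufficientDataError,
    ResidueTable,
    composition_mass,
    find_compositions,
    residue_mass,
)
from .deconvolve import MassDistribution

__all__ = [
    "AmbiguousBaseError",
    "IncompatibleAdductError",
    "PeakAssignment",
    "AssignmentResult",
    "EnvelopeFit",
    "SialicCensus",
    "infer_base_mass",
    "assign_lattice",
    "sialic_census",
    "envelope_decompose",
    "adduct_share",
    "annotate_adducts",
]


class AmbiguousBaseError(ValueError):
    """Base-mass search objective is flat; reports the aliasing period."""

    def __init__(self, aliasing_period: float):
        self.aliasing_period = aliasing_period
        super().__init__(
            f"base mass is ambiguous up to shifts of {aliasing_period:.2f} Da"
        )


class IncompatibleAdductError(ValueError):
    """Adduct mass is not close to a lattice multiple and cannot be modelled."""


@dataclass
class Candidate:
    """One candidate explanation of a peak: glycans plus optional adducts."""

    composition: GlycanComposition
    adducts: Tuple[Tuple[str, int], ...]
    error: float  # signed, Da

    @property
    def n_adducts(self) -> int:
        return sum(c for _, c in self.adducts)


@dataclass
class PeakAssignment:
    mass: float
    abundance: float
    candidates: List[Candidate] = field(default_factory=list)
    label_P: int | None = None  # branch count of the primary candidate
    label_aF: int | None = None  # antennary Fuc count of the primary candidate
    degenerate: bool = False

    @property
    def assigned(self) -> bool:
        return bool(self.candidates)

    @property
    def primary(self) -> Candidate | None:
        return self.candidates[0] if self.candidates else None


@dataclass
class AssignmentResult:
    """Per-peak assignments; every input peak appears exactly once."""

    peaks: List[PeakAssignment]
    base_mass: float
    tol: float

    @property
    def assigned(self) -> List[PeakAssignment]:
        return [p for p in self.peaks if p.assigned]

    @property
    def unassigned(self) -> List[PeakAssignment]:
        return [p for p in self.peaks if not p.assigned]

    def degeneracy_groups(self) -> List[PeakAssignment]:
        return [p for p in self.peaks if p.degenerate]

    def relabelled(self) -> List[str]:
        """Human P-labels relative to the smallest assigned branch count."""
        branches = [p.label_P for p in self.assigned if p.label_P is not None]
        if not branches:
            return []
        base = min(branches)
        return [
            f"P{p.label_P - base + 1} aF{p.label_aF}" if p.assigned else "unassigned"
            for p in self.peaks
        ]


@dataclass
class EnvelopeFit:
    """k-Gaussian decomposition of a peak-series abundance envelope."""

    k: int
    means: np.ndarray
    widths: np.ndarray
    amplitudes: np.ndarray
    residual_norm: float
    converged: bool
    second_component_flagged: bool = False

    def predict(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        out = np.zeros_like(x)
        for m, s, a in zip(self.means, self.widths, self.amplitudes):
            out += a * np.exp(-0.5 * ((x - m) / s) ** 2)
        return out


@dataclass
class SialicCensus:
    """Per-peak sialic acid counts from a sialylated/desialylated pair."""

    counts: List[Tuple[float, float, int]]  # (sialylated mass, abundance, k)
    coverage: float  # abundance fraction of sialylated peaks with an anchor

    @property
    def k_min(self) -> int:
        return min(k for _, _, k in self.counts)

    @property
    def k_max(self) -> int:
        return max(k for _, _, k in self.counts)

    @property
    def k_mode(self) -> int:
        """Abundance-weighted modal sialic acid count."""
        weights: Dict[int, float] = {}
        for _, a, k in self.counts:
            weights[k] = weights.get(k, 0.0) + a
        return max(sorted(weights), key=lambda k: weights[k])


def infer_base_mass(
    md: MassDistribution,
    lattice_spacing: float,
    search_window: Tuple[float, float] | None = None,
    grid_step: float = 0.05,
    flatness_ratio: float = 0.05,
    min_frac: float = 0.01,
) -> Tuple[float, float]:
    """Anchor the lattice: grid-search the base mass minimizing peak residuals.

    For each trial base ``b`` the objective is the summed squared distance of
    every detected peak to its nearest lattice point ``b + k*spacing``.  The
    search covers one aliasing period (or the given window); the minimizing
    offset and a profile-curvature error bar are returned.  The search assumes
    the series is dominated by the primary lattice: strong sub-lattice
    structure (e.g. a fucose ladder inside a branching series) biases the
    anchor and the base should then be fixed from a known composition instead.

    Raises :class:`AmbiguousBaseError` when the objective is flat (single
    peak, or peaks that fit every offset equally well) — the base is then only
    defined modulo the lattice spacing.
    """
    centers, heights = md.peaks(min_frac=min_frac)
    if centers.size < 1:
        raise InsufficientDataError("no peaks detected in the distribution")
    anchor = float(centers[np.argmax(heights)])
    if search_window is None:
        lo, hi = anchor - lattice_spacing / 2, anchor + lattice_spacing / 2
    else:
        lo, hi = search_window
    trial = np.arange(lo, hi + grid_step, grid_step)
    resid = np.empty_like(trial)
    for i, b in enumerate(trial):
        k = np.round((centers - b) / lattice_spacing)
        d = centers - (b + k * lattice_spacing)
        resid[i] = float(np.sum(heights * d**2) / heights.sum())
    spread = resid.max() - resid.min()
    if centers.size < 2 or spread < flatness_ratio * max(resid.max(), 1e-12):
        raise AmbiguousBaseError(lattice_spacing)
    i_best = int(np.argmin(resid))
    best = float(trial[i_best])
    # curvature from a local quadratic fit around the minimum
    sl = slice(max(0, i_best - 3), min(trial.size, i_best + 4))
    coeffs = np.polyfit(trial[sl] - best, resid[sl], 2)
    curvature = max(coeffs[0], 1e-12)
    err = float(np.sqrt(max(resid[i_best], grid_step**2) / curvature))
    return best, err


def _adduct_combos(
    adduct_table: AdductTable, max_per_adduct: int, adduct_names: Sequence[str]
) -> List[Tuple[Tuple[Tuple[str, int], ...], float]]:
    combos: List[Tuple[Tuple[Tuple[str, int], ...], float]] = [((), 0.0)]
    for name in adduct_names:
        new = []
        for counts, mass in combos:
            for k in range(1, max_per_adduct + 1):
                new.append((counts + ((name, k),), mass + k * adduct_table.mass(name)))
        combos.extend(new)
    return combos


def assign_lattice(
    md: MassDistribution,
    base_mass: float,
    residue_ranges: Mapping[str, int],
    adduct_table: AdductTable | None = None,
    tol: float = 2.0,
    adduct_names: Sequence[str] | None = None,
    max_per_adduct: int = 2,
    min_frac: float = 0.01,
) -> AssignmentResult:
    """Match every detected peak to base + glycan composition (+ adducts).

    The primary candidate is chosen by priority: glycan-only explanations
    before adduct-bearing ones, then fewer total residues, then smaller
    absolute error.  Peaks with multiple candidates inside ``tol`` are marked
    degenerate; unmatched peaks are listed, never dropped.
    """
    adduct_table = adduct_table or AdductTable.default()
    if adduct_names is None:
        adduct_names = []
    centers, heights = md.peaks(min_frac=min_frac)
    combos = _adduct_combos(adduct_table, max_per_adduct, adduct_names)
    peaks: List[PeakAssignment] = []
    for mass, abundance in zip(centers, heights):
        delta = mass - base_mass
        candidates: List[Candidate] = []
        for adducts, adduct_mass in combos:
            for match in find_compositions(
                delta - adduct_mass, tol, residue_ranges, "average"
            ):
                candidates.append(
                    Candidate(match.composition, adducts, match.error)
                )
        candidates.sort(
            key=lambda c: (
                c.n_adducts > 0,
                c.n_adducts,
                c.composition.total_residues,
                abs(c.error),
                tuple(c.composition.items()),
            )
        )
        pa = PeakAssignment(mass=float(mass), abundance=float(abundance))
        if candidates:
            pa.candidates = candidates
            primary = candidates[0]
            pa.label_P = primary.composition["branch"]
            pa.label_aF = primary.composition["Fuc"]
            pa.degenerate = len(candidates) > 1
        peaks.append(pa)
    return AssignmentResult(peaks=peaks, base_mass=base_mass, tol=tol)


def sialic_census(
    sial: MassDistribution,
    desial: MassDistribution,
    tol: float = 2.0,
    min_frac: float = 0.01,
) -> SialicCensus:
    """Count sialic acids per proteoform from a sialylated/desialylated pair.

    Each sialylated peak M is matched to the desialylated anchor A minimizing
    the residual |M - A - k * m(Neu5Ac)| over integer k >= 0; peaks whose best
    residual exceeds ``tol`` are excluded and counted against coverage.
    """
    neu = residue_mass("Neu5Ac", "average")
    s_centers, s_heights = sial.peaks(min_frac=min_frac)
    d_centers, _ = desial.peaks(min_frac=min_frac)
    if s_centers.size == 0 or d_centers.size == 0:
        raise InsufficientDataError("no peaks in one of the distributions")
    counts: List[Tuple[float, float, int]] = []
    covered = 0.0
    total = float(s_heights.sum())
    for mass, abundance in zip(s_centers, s_heights):
        diffs = mass - d_centers
        ks = np.maximum(0, np.round(diffs / neu)).astype(int)
        residuals = np.abs(diffs - ks * neu)
        j = int(np.argmin(residuals))
        if residuals[j] <= tol:
            counts.append((float(mass), float(abundance), int(ks[j])))
            covered += abundance
    if not counts:
        raise InsufficientDataError("no sialylated peak matched a desialylated anchor")
    return SialicCensus(counts=counts, coverage=covered / total)


def envelope_decompose(
    abundances: Sequence[float],
    k: int,
    x: Sequence[float] | None = None,
    flag_fraction: float = 0.1,
) -> EnvelopeFit:
    """Fit k Gaussians to a peak-series abundance envelope (index axis).

    Initialization splits the abundance mass into k quantile blocks; the fit
    is nonlinear least squares with non-negative amplitudes.  The second (and
    later) component is flagged when its amplitude exceeds ``flag_fraction``
    of the largest one — the signature of a hidden subpopulation (e.g. a
    lipid-bound series shifted onto the glycan lattice).
    """
    y = np.asarray(abundances, dtype=float)
    xs = np.arange(y.size, dtype=float) if x is None else np.asarray(x, dtype=float)
    if y.size < 2 * k + 1:
        raise InsufficientDataError(f"need >= {2 * k + 1} points to fit {k} Gaussians")

    import lmfit

    cum = np.cumsum(y) / y.sum()
    model = None
    params = lmfit.Parameters()
    for i in range(k):
        q = (i + 0.5) / k
        center0 = float(np.interp(q, cum, xs))
        comp = lmfit.models.GaussianModel(prefix=f"g{i}_")
        model = comp if model is None else model + comp
        params.update(comp.make_params())
        params[f"g{i}_center"].set(value=center0)
        params[f"g{i}_sigma"].set(value=(xs[-1] - xs[0]) / (4 * k), min=1e-3)
        params[f"g{i}_amplitude"].set(value=float(y.max()), min=0.0)
    result = model.fit(y, params, x=xs)
    means = np.array([result.params[f"g{i}_center"].value for i in range(k)])
    sigmas = np.array([result.params[f"g{i}_sigma"].value for i in range(k)])
    areas = np.array([result.params[f"g{i}_amplitude"].value for i in range(k)])
    heights = areas / (sigmas * np.sqrt(2 * np.pi))
    order = np.argsort(-heights)
    means, sigmas, heights = means[order], sigmas[order], heights[order]
    residual_norm = float(np.linalg.norm(result.residual))
    flagged = bool(k > 1 and heights[1] >= flag_fraction * heights[0])
    return EnvelopeFit(
        k=k,
        means=means,
        widths=sigmas,
        amplitudes=heights,
        residual_norm=residual_norm,
        converged=bool(result.success),
        second_component_flagged=flagged,
    )


def adduct_share(
    intact: Sequence[float],
    dissociated: Sequence[float],
    adduct_mass: float,
    lattice_spacing: float,
    n_bootstrap: int = 200,
    seed: int = 0,
    lattice_frac_tol: float = 0.25,
) -> Tuple[float, Tuple[float, float]]:
    """Bound fraction of a lattice-aliasing adduct from an intact/dissociated pair.

    Both inputs are abundance series over the same P-index axis; the
    dissociated (adduct-free) series S is the reference and the intact series
    is modelled as (1-f) S + f shift(S, adduct) where the shift is the adduct
    mass rounded to its nearest whole number of lattice steps.  f is the
    non-negative least-squares solution (closed form, clipped to [0, 1]); the
    confidence interval is a seeded 200-resample residual bootstrap
    (percentile 2.5/97.5).  Scale-invariant: both series are normalized to
    unit sum first.

    Raises :class:`IncompatibleAdductError` when the adduct mass is not near
    a whole number of lattice steps (within ``lattice_frac_tol`` of a step).
    """
    steps = int(round(adduct_mass / lattice_spacing))
    off = abs(adduct_mass - steps * lattice_spacing)
    if steps < 1 or off > lattice_frac_tol * lattice_spacing:
        raise IncompatibleAdductError(
            f"adduct mass {adduct_mass} Da is {off:.1f} Da from the nearest "
            f"multiple of the {lattice_spacing} Da lattice"
        )
    I = np.asarray(intact, dtype=float)
    S = np.asarray(dissociated, dtype=float)
    if I.shape != S.shape:
        raise ValueError("series must be aligned to the same P-index axis")
    I = I / I.sum()
    S = S / S.sum()
    T = np.zeros_like(S)
    T[steps:] = S[:-steps]

    def estimate(target: np.ndarray) -> float:
        d = T - S
        denom = float(d @ d)
        if denom <= 0:
            return 0.0
        return float(np.clip((target - S) @ d / denom, 0.0, 1.0))

    f_hat = estimate(I)
    fitted = (1 - f_hat) * S + f_hat * T
    residuals = I - fitted
    rng = np.random.default_rng(seed)
    boot = np.empty(n_bootstrap)
    for b in range(n_bootstrap):
        resampled = fitted + rng.choice(residuals, size=residuals.size, replace=True)
        boot[b] = estimate(resampled)
    ci = (float(np.percentile(boot, 2.5)), float(np.percentile(boot, 97.5)))
    return f_hat, ci


def annotate_adducts(
    md: MassDistribution,
    base_mass: float,
    adduct_table: AdductTable | None = None,
    residue_ranges: Mapping[str, int] | None = None,
    tol: float = 2.0,
    max_per_adduct: int = 2,
    min_frac: float = 0.01,
) -> List[Dict[str, object]]:
    """Label off-lattice peaks by their residual mass after lattice subtraction.

    For each detected peak the best glycan-lattice explanation within the
    residue ranges is subtracted; the leftover residual is matched against
    combinations of table adducts (up to ``max_per_adduct`` each).  Rows
    report the peak mass, residual, matched adducts (empty for pure
    glycoforms) and the remaining error; unmatched residuals are listed with
    their mass rather than suppressed.
    """
    adduct_table = adduct_table or AdductTable.default()
    residue_ranges = residue_ranges if residue_ranges is not None else {
        "branch": 12, "Fuc": 10, "Neu5Ac": 0
    }
    names = [n for n in adduct_table.names() if adduct_table.adduct_class(n) != "detergent"]
    combos = _adduct_combos(adduct_table, max_per_adduct, names)
    centers, heights = md.peaks(min_frac=min_frac)
    rows: List[Dict[str, object]] = []
    for mass, abundance in zip(centers, heights):
        delta = float(mass - base_mass)
        best: Tuple[float, GlycanComposition, Tuple, float] | None = None
        for adducts, adduct_mass in combos:
            residual_target = delta - adduct_mass
            if residual_target < -tol:
                continue
            matches = find_compositions(
                residual_target, tol, residue_ranges, "average"
            )
            if matches:
                m = matches[0]
                # ambiguity policy: glycan-only before adduct-bearing, then error
                key = (sum(c for _, c in adducts), abs(m.error))
                if best is None or key < (sum(c for _, c in best[2]), abs(best[3])):
                    best = (adduct_mass, m.composition, adducts, m.error)
        if best is None:
            rows.append(
                {
                    "mass_Da": float(mass),
                    "abundance": float(abundance),
                    "residual_Da": delta,
                    "adducts": (),
                    "composition": None,
                    "error_Da": None,
                    "matched": False,
                }
            )
        else:
            adduct_mass, comp, adducts, err = best
            rows.append(
                {
                    "mass_Da": float(mass),
                    "abundance": float(abundance),
                    "residual_Da": adduct_mass + err,
                    "adducts": adducts,
                    "composition": comp,
                    "error_Da": float(err),
                    "matched": True,
                }
            )
    return rows
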