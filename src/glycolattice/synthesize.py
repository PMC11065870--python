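"""Synthetic populations, electrospray spectra and mass-photometry events.

The generator emulates the data produced by native MS of a large, heavily
glycosylated membrane-protein heterodimer: an apo complex of ~127 kDa carrying
four complex N-glycans whose branching, antennary fucosylation and sialylation
vary from copy to copy, sub-stoichiometric phospho / palmitoyl / phospholipid
adducts, a multi-charge positive-mode electrospray envelope (z around 26) with
Gaussian peak shapes and additive noise, optional detergent-monomer satellite
tails, and single-particle mass-photometry events with proteomicelle offsets.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace
from typing import Dict, List, Mapping, Sequence, Tuple

import numpy as np

from .glycomass import (
    PROTON_MASS,
    AdductTable,
    GlycanComposition,
    ResidueTable,
    composition_mass,
)

__all__ = [
    "ConfigError",
    "Proteoform",
    "SimulationConfig",
    "Spectrum",
    "MPHistogram",
    "sample_proteoforms",
    "render_spectrum",
    "apply_neuraminidase",
    "dissociate",
    "sample_mp_events",
    "fit_mp_mixture",
    "population_distribution",
]


class ConfigError(ValueError):
    """Invalid simulation or pipeline configuration."""


@dataclass(frozen=True)
class Proteoform:
    """Base mass + glycan composition + adduct stoichiometry.

    ``base_mass`` is the apo polypeptide complex including fixed modifications;
    the total mass is strictly additive over glycan residues (average-mass
    convention, as appropriate for unresolved isotope envelopes at >100 kDa)
    and adduct shifts.
    """

    base_mass: float
    glycans: GlycanComposition = field(default_factory=GlycanComposition)
    adducts: Tuple[Tuple[str, int], ...] = ()
    abundance: float = 1.0
    label: str = ""

    def __post_init__(self):
        if self.abundance < 0:
            raise ValueError("abundance must be >= 0")

    def adduct_counts(self) -> Dict[str, int]:
        return dict(self.adducts)

    def mass(
        self,
        residues: ResidueTable | None = None,
        adduct_table: AdductTable | None = None,
    ) -> float:
        adduct_table = adduct_table or AdductTable.default()
        total = self.base_mass + composition_mass(self.glycans, "average", residues)
        for name, count in self.adducts:
            total += count * adduct_table.mass(name)
        return total


def _normalize_weights(weights: Mapping[int, float], what: str) -> Dict[int, float]:
    if not weights:
        raise ConfigError(f"{what}: empty distribution")
    vals = np.array([weights[k] for k in sorted(weights)], dtype=float)
    if np.any(vals < 0) or not np.all(np.isfinite(vals)):
        raise ConfigError(f"{what}: weights must be finite and >= 0")
    total = vals.sum()
    if total <= 0:
        raise ConfigError(f"{what}: weights sum to zero")
    if abs(total - 1.0) < 1e-12:  # idempotent: keeps serialization lossless
        return {k: float(weights[k]) for k in sorted(weights)}
    return {k: float(weights[k] / total) for k in sorted(weights)}


def _gaussian_weights(support: Sequence[int], center: float, sd: float) -> Dict[int, float]:
    w = {int(k): float(np.exp(-0.5 * ((k - center) / sd) ** 2)) for k in support}
    return _normalize_weights(w, "gaussian weights")


@dataclass
class SimulationConfig:
    """Conditions of a simulated native-MS experiment.

    Defaults emulate the wild-type, fully sialylated heterodimer: apo complex
    base mass 127027 Da; a fixed scaffold of four N-glycan cores
    (Hex3HexNAc2 each) plus four core fucoses; 12-21 antenna (branch) units
    across the four glycans peaking at 16 (four tetra-antennary glycans);
    0-4 antennary fucoses with the tri/tetra forms more abundant than the
    bi-fucosylated one; 9-16 total sialic acids peaking at 13; 20% phospho
    occupancy on one site; two phospholipid (PE) sites at 40% occupancy each;
    charge envelope centred on z = 26 with spread 2.
    """

    base_mass: float = 127027.0
    # fixed glycan scaffold: 4 cores (Man3GlcNAc2 -> Hex12 HexNAc8) + 4 core Fuc
    core_glycans: GlycanComposition = field(
        default_factory=lambda: GlycanComposition(Hex=12, HexNAc=8, Fuc=4)
    )
    branch_weights: Dict[int, float] = field(
        default_factory=lambda: _gaussian_weights(range(12, 22), 16.0, 2.0)
    )
    antennary_fuc_weights: Dict[int, float] = field(
        default_factory=lambda: {0: 0.30, 1: 0.15, 2: 0.10, 3: 0.20, 4: 0.25}
    )
    neu5ac_weights: Dict[int, float] = field(
        default_factory=lambda: _gaussian_weights(range(9, 17), 13.0, 1.5)
    )
    phospho_prob: float = 0.2
    palmitoyl_prob: float = 0.0
    lipid_site_probs: Dict[str, Tuple[int, float]] = field(
        default_factory=lambda: {"PE": (2, 0.4)}
    )  # adduct name -> (site count, per-site occupancy)
    charge_center: float = 26.0
    charge_spread: float = 2.0
    peak_fwhm_mz: float = 0.8
    mz_step: float = 0.1
    noise_level: float = 0.0  # additive noise sd as a fraction of the max signal
    detergent: str = "OGNG"
    detergent_tail_ratio: float = 0.0  # geometric satellite intensity ratio
    detergent_tail_max: int = 5
    activation_strips_adducts: bool = False  # effective in-source stripping flag
    n_samples: int = 2000
    seed: int = 0

    def __post_init__(self):
        for p in (self.phospho_prob, self.palmitoyl_prob):
            if not 0.0 <= p <= 1.0:
                raise ConfigError("occupancy probabilities must be in [0, 1]")
        for name, (sites, p) in self.lipid_site_probs.items():
            if sites < 0 or not 0.0 <= p <= 1.0:
                raise ConfigError(f"invalid lipid occupancy for {name!r}")
        if not 0.0 <= self.detergent_tail_ratio < 1.0:
            raise ConfigError("detergent_tail_ratio must be in [0, 1)")
        if self.charge_spread <= 0 or self.peak_fwhm_mz <= 0 or self.mz_step <= 0:
            raise ConfigError("charge_spread, peak_fwhm_mz, mz_step must be > 0")
        if self.noise_level < 0:
            raise ConfigError("noise_level must be >= 0")
        self.branch_weights = _normalize_weights(self.branch_weights, "branch_weights")
        self.antennary_fuc_weights = _normalize_weights(
            self.antennary_fuc_weights, "antennary_fuc_weights"
        )
        self.neu5ac_weights = _normalize_weights(self.neu5ac_weights, "neu5ac_weights")

    def config_hash(self) -> str:
        payload = {
            k: (dict(v) if isinstance(v, dict) else str(v))
            for k, v in vars(self).items()
        }
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:12]

    def desialylated(self) -> "SimulationConfig":
        """Copy emulating neuraminidase treatment (all Neu5Ac removed)."""
        return replace(self, neu5ac_weights={0: 1.0})

    @property
    def lattice_base_mass(self) -> float:
        """Apo mass + fixed glycan scaffold: the anchor for lattice annotation."""
        return self.base_mass + composition_mass(self.core_glycans, "average")


@dataclass
class Spectrum:
    """m/z-intensity trace with provenance metadata."""

    mz: np.ndarray
    intensity: np.ndarray
    metadata: Dict[str, object] = field(default_factory=dict)

    def __post_init__(self):
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape or self.mz.ndim != 1:
            raise ValueError("mz and intensity must be 1-D arrays of equal length")
        if np.any(~np.isfinite(self.mz)) or np.any(~np.isfinite(self.intensity)):
            raise ValueError("spectrum contains NaN/inf")
        if np.any(np.diff(self.mz) <= 0):
            raise ValueError("m/z axis must be strictly increasing")
        if np.any(self.intensity < 0):
            raise ValueError("intensities must be >= 0")

    def __len__(self) -> int:
        return self.mz.size

    def slice(self, lo: float, hi: float) -> "Spectrum":
        mask = (self.mz >= lo) & (self.mz <= hi)
        return Spectrum(self.mz[mask], self.intensity[mask], dict(self.metadata))


@dataclass
class MPHistogram:
    """Single-particle mass events (kDa) with an optional mixture fit."""

    events: np.ndarray
    components: List[Tuple[float, float, float]] | None = None  # (mean, sigma, weight)

    def __post_init__(self):
        self.events = np.asarray(self.events, dtype=float)
        if self.events.size == 0:
            raise ValueError("MPHistogram requires at least one event")
        if np.any(self.events <= 0):
            raise ValueError("particle masses must be > 0")
        if self.components is not None:
            w = sum(c[2] for c in self.components)
            if abs(w - 1.0) > 1e-6 or any(c[2] < 0 for c in self.components):
                raise ValueError("component weights must be >= 0 and sum to 1")

    def histogram(self, bin_width_kda: float = 5.0):
        lo = np.floor(self.events.min() / bin_width_kda) * bin_width_kda
        hi = np.ceil(self.events.max() / bin_width_kda) * bin_width_kda
        edges = np.arange(lo, hi + bin_width_kda, bin_width_kda)
        counts, edges = np.histogram(self.events, bins=edges)
        return counts, edges


def _charge_states(cfg: SimulationConfig) -> Tuple[np.ndarray, np.ndarray]:
    lo = int(np.floor(cfg.charge_center - 3 * cfg.charge_spread))
    hi = int(np.ceil(cfg.charge_center + 3 * cfg.charge_spread))
    z = np.arange(max(1, lo), hi + 1)
    w = np.exp(-0.5 * ((z - cfg.charge_center) / cfg.charge_spread) ** 2)
    return z, w / w.sum()


def _draw(rng: np.random.Generator, weights: Mapping[int, float], n: int) -> np.ndarray:
    keys = np.array(sorted(weights))
    p = np.array([weights[int(k)] for k in keys])
    return rng.choice(keys, size=n, p=p)


def sample_proteoforms(cfg: SimulationConfig) -> List[Proteoform]:
    """Draw a proteoform population from the configured distributions.

    Returns aggregated unique proteoforms with abundances summing to 1,
    labelled by lattice coordinates: ``P<k>`` for the branch-count ordinal
    (P1 = lowest branch count in the configured support) and ``aF<j>`` for the
    antennary fucose count.  Reproducible for a fixed seed.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_samples
    if n <= 0:
        raise ConfigError("n_samples must be positive")
    branches = _draw(rng, cfg.branch_weights, n)
    afucs = _draw(rng, cfg.antennary_fuc_weights, n)
    neus = _draw(rng, cfg.neu5ac_weights, n)
    phospho = rng.random(n) < cfg.phospho_prob
    palmitoyl = rng.random(n) < cfg.palmitoyl_prob
    lipid_names = sorted(cfg.lipid_site_probs)
    lipid_counts = {
        name: rng.binomial(cfg.lipid_site_probs[name][0], cfg.lipid_site_probs[name][1], n)
        for name in lipid_names
    }
    min_branch = min(cfg.branch_weights)

    counter: Dict[Tuple, int] = {}
    for i in range(n):
        adducts = []
        if phospho[i]:
            adducts.append(("phospho", 1))
        if palmitoyl[i]:
            adducts.append(("palmitoyl", 1))
        for name in lipid_names:
            if lipid_counts[name][i]:
                adducts.append((name, int(lipid_counts[name][i])))
        key = (int(branches[i]), int(afucs[i]), int(neus[i]), tuple(adducts))
        counter[key] = counter.get(key, 0) + 1

    population = []
    for (nb, af, nn, adducts), count in sorted(counter.items()):
        glycans = cfg.core_glycans + GlycanComposition(
            branch=nb, Fuc=af, Neu5Ac=nn
        )
        label = f"P{nb - min_branch + 1} aF{af}"
        population.append(
            Proteoform(
                base_mass=cfg.base_mass,
                glycans=glycans,
                adducts=adducts,
                abundance=count / n,
                label=label,
            )
        )
    return population


def render_spectrum(
    population: Sequence[Proteoform],
    cfg: SimulationConfig,
    adduct_table: AdductTable | None = None,
) -> Spectrum:
    """Forward-model an electrospray spectrum of a proteoform population.

    Each proteoform contributes unit-area Gaussian peaks at
    ``(M + z * 1.00728) / z`` for every charge state in the envelope, with
    area abundance x charge weight.  Optional detergent satellites appear as a
    geometric series of +k*(monomer mass) peaks; Gaussian noise (sd =
    ``noise_level`` x max signal) is added and clipped at zero.
    """
    if not population:
        raise ValueError("population is empty")
    adduct_table = adduct_table or AdductTable.default()
    z_states, z_weights = _charge_states(cfg)
    sigma = cfg.peak_fwhm_mz / (2.0 * np.sqrt(2.0 * np.log(2.0)))

    stripped = population
    if cfg.activation_strips_adducts:
        stripped = [
            replace(
                p,
                adducts=tuple(
                    (n, c)
                    for n, c in p.adducts
                    if adduct_table.adduct_class(n) != "detergent"
                ),
            )
            for p in population
        ]

    peaks: List[Tuple[float, float]] = []  # (mz, area)
    detergent_mass = adduct_table.mass(cfg.detergent)
    tail_ratio = 0.0 if cfg.activation_strips_adducts else cfg.detergent_tail_ratio
    for p in stripped:
        mass = p.mass(adduct_table=adduct_table)
        for z, w in zip(z_states, z_weights):
            area = p.abundance * w
            peaks.append(((mass + z * PROTON_MASS) / z, area))
            if tail_ratio > 0:
                for k in range(1, cfg.detergent_tail_max + 1):
                    peaks.append(
                        (
                            (mass + k * detergent_mass + z * PROTON_MASS) / z,
                            area * tail_ratio**k,
                        )
                    )

    mz_values = np.array([m for m, _ in peaks])
    lo = mz_values.min() - 6 * cfg.peak_fwhm_mz
    hi = mz_values.max() + 6 * cfg.peak_fwhm_mz
    grid = np.arange(lo, hi + cfg.mz_step, cfg.mz_step)
    signal = np.zeros_like(grid)
    norm = 1.0 / (sigma * np.sqrt(2.0 * np.pi))
    half_window = 6 * sigma
    for center, area in peaks:
        i0 = np.searchsorted(grid, center - half_window)
        i1 = np.searchsorted(grid, center + half_window)
        window = grid[i0:i1]
        signal[i0:i1] += area * norm * np.exp(-0.5 * ((window - center) / sigma) ** 2)

    if cfg.noise_level > 0:
        noise_rng = np.random.default_rng([cfg.seed, 0xA5])
        signal = signal + noise_rng.normal(
            0.0, cfg.noise_level * signal.max(), size=signal.size
        )
        signal = np.clip(signal, 0.0, None)

    return Spectrum(
        grid,
        signal,
        metadata={
            "kind": "simulated",
            "seed": cfg.seed,
            "config_hash": cfg.config_hash(),
        },
    )


def _aggregate(population: Sequence[Proteoform]) -> List[Proteoform]:
    merged: Dict[Tuple, Proteoform] = {}
    for p in population:
        key = (p.base_mass, p.glycans, p.adducts)
        if key in merged:
            prev = merged[key]
            merged[key] = replace(prev, abundance=prev.abundance + p.abundance)
        else:
            merged[key] = p
    return sorted(merged.values(), key=lambda p: p.mass())


def apply_neuraminidase(population: Sequence[Proteoform]) -> List[Proteoform]:
    """Remove every terminal sialic acid (Neu5Ac -> 0) and re-aggregate.

    Proteoforms that become identical after desialylation are merged with
    summed abundances; all other residue and adduct counts are untouched.
    Idempotent.
    """
    desial = [
        replace(p, glycans=p.glycans.without("Neu5Ac")) for p in population
    ]
    return _aggregate(desial)


def dissociate(
    population: Sequence[Proteoform],
    light_base_mass: float,
    adduct_table: AdductTable | None = None,
    adduct_routing: Mapping[str, str] | None = None,
) -> Tuple[List[Proteoform], List[Proteoform]]:
    """Split each complex proteoform into light and heavy subunit proteoforms.

    The base-mass partition is (light_base_mass, base - light_base_mass).
    Glycans route to the glycosylated heavy subunit; adducts route per
    ``adduct_routing`` (name -> "light" | "heavy"), defaulting to the light
    subunit for lipids and PTMs (the lipid-binding and modification sites sit
    on the light catalytic subunit).  The two subunit masses always sum
    exactly to the complex mass.
    """
    adduct_table = adduct_table or AdductTable.default()
    light_pop, heavy_pop = [], []
    for p in population:
        heavy_base = p.base_mass - light_base_mass
        if light_base_mass <= 0 or heavy_base <= 0:
            raise ValueError(
                f"partition {light_base_mass} exceeds complex base mass {p.base_mass}"
            )
        light_adducts, heavy_adducts = [], []
        for name, count in p.adducts:
            side = (adduct_routing or {}).get(name, "light")
            (light_adducts if side == "light" else heavy_adducts).append((name, count))
        light_pop.append(
            Proteoform(
                base_mass=light_base_mass,
                adducts=tuple(light_adducts),
                abundance=p.abundance,
                label=p.label,
            )
        )
        heavy_pop.append(
            Proteoform(
                base_mass=heavy_base,
                glycans=p.glycans,
                adducts=tuple(heavy_adducts),
                abundance=p.abundance,
                label=p.label,
            )
        )
    return _aggregate(light_pop), _aggregate(heavy_pop)


def sample_mp_events(
    components: Sequence[Tuple[float, float, float]],
    n: int,
    seed: int = 0,
) -> MPHistogram:
    """Draw ``n`` single-particle masses (kDa) from a Gaussian mixture.

    ``components`` is a list of (mean kDa, sigma kDa, weight); weights are
    normalized internally.  Component means should include any proteomicelle
    (detergent) mass offset.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if not components:
        raise ValueError("at least one mixture component required")
    means = np.array([c[0] for c in components], dtype=float)
    sigmas = np.array([c[1] for c in components], dtype=float)
    weights = np.array([c[2] for c in components], dtype=float)
    if np.any(sigmas <= 0) or np.any(weights < 0) or weights.sum() <= 0:
        raise ValueError("sigmas must be > 0 and weights >= 0")
    weights = weights / weights.sum()
    rng = np.random.default_rng(seed)
    which = rng.choice(len(components), size=n, p=weights)
    events = rng.normal(means[which], sigmas[which])
    return MPHistogram(events=events)


def fit_mp_mixture(hist: MPHistogram, k: int, seed: int = 0) -> MPHistogram:
    """Fit a k-component Gaussian mixture to the events (EM, seeded).

    Returns a new histogram whose ``components`` are sorted by mean and whose
    weights sum to 1.
    """
    from sklearn.mixture import GaussianMixture

    x = hist.events.reshape(-1, 1)
    gm = GaussianMixture(n_components=k, n_init=5, random_state=seed).fit(x)
    order = np.argsort(gm.means_.ravel())
    components = [
        (
            float(gm.means_.ravel()[i]),
            float(np.sqrt(gm.covariances_.ravel()[i])),
            float(gm.weights_[i]),
        )
        for i in order
    ]
    total = sum(c[2] for c in components)
    components = [(m, s, w / total) for m, s, w in components]
    return MPHistogram(events=hist.events, components=components)


def population_distribution(
    population: Sequence[Proteoform],
    grid_step: float = 0.1,
    adduct_table: AdductTable | None = None,
):
    """Exact (noise-free) zero-charge mass distribution of a population.

    Convenience for tests and differential analyses that operate on neutral
    masses directly, bypassing the electrospray forward model.
    """
    from .deconvolve import MassDistribution

    masses = np.array([p.mass(adduct_table=adduct_table) for p in population])
    abund = np.array([p.abundance for p in population])
    lo = masses.min() - 5 * grid_step
    hi = masses.max() + 5 * grid_step
    grid = np.arange(lo, hi + grid_step, grid_step)
    weights = np.zeros_like(grid)
    idx = np.clip(np.round((masses - grid[0]) / grid_step).astype(int), 0, grid.size - 1)
    np.add.at(weights, idx, abund)
    return MassDistribution(grid, weights)
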