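"""Binomial oligomer-assembly models and PTM-independence tests.

An n-mer assembled from subunits drawn independently from one proteoform pool
has a mass distribution equal to the n-fold self-convolution of the subunit
distribution (mean n x subunit mean, variance n x subunit variance) plus any
interface delta — a nonzero delta would indicate an interfacial ligand or
lipid retained only in the oligomer.  Per-site modification occupancy under
assembly independence follows Binomial(order x sites, p); a goodness-of-fit
test of observed oligomer modification counts against that law asks whether
assembly is coupled to the modification.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, Tuple

import numpy as np
from scipy import stats

from .deconvolve import MassDistribution
from .synthesize import MPHistogram

__all__ = [
    "AssemblyComparison",
    "convolve_assembly",
    "compare_assembly",
    "occupancy_expected",
    "independence_test",
    "ratio_quantify",
    "compare_ratios",
]


@dataclass
class AssemblyComparison:
    delta_mean: float
    delta_sd: float
    overlap: float  # normalized inner product of the two distributions
    within_uncertainty: bool


def _require_uniform_grid(md: MassDistribution) -> float:
    steps = np.diff(md.masses)
    step = float(steps[0])
    if not np.allclose(steps, step, rtol=1e-8, atol=1e-9 * step):
        raise ValueError("mass grid must be uniform for convolution")
    return step


def convolve_assembly(
    md: MassDistribution, n: int, interface_delta: float = 0.0
) -> MassDistribution:
    """Predict the n-mer mass distribution by n-fold self-convolution.

    Requires a normalized subunit distribution on a uniform grid.  The
    default ``interface_delta`` of 0 encodes assembly without any interfacial
    ligand; pass a nonzero value to model (and test against) one.
    """
    if n < 2:
        raise ValueError("oligomer order must be >= 2")
    if not md.normalized:
        raise ValueError("subunit distribution must be normalized (call .normalize())")
    step = _require_uniform_grid(md)
    out = md.abundance.copy()
    for _ in range(n - 1):
        out = np.convolve(out, md.abundance)
    masses = n * md.masses[0] + interface_delta + step * np.arange(out.size)
    out = out / out.sum()
    return MassDistribution(masses, out, normalized=True)


def compare_assembly(
    predicted: MassDistribution, observed: MassDistribution
) -> AssemblyComparison:
    """Compare a predicted n-mer distribution with a measured one.

    Reports mean and sd differences plus a normalized inner-product overlap
    (1 for identical shapes after interpolation onto a common grid).  The
    verdict flag is set when the mean offset is within the combined sd of the
    two distributions — i.e. the measurement is consistent with assembly
    requiring no additional mass.
    """
    d_mean = observed.mean() - predicted.mean()
    d_sd = observed.sd() - predicted.sd()
    obs_on_pred = np.interp(
        predicted.masses, observed.masses, observed.abundance, left=0.0, right=0.0
    )
    p = predicted.abundance
    denom = np.linalg.norm(p) * np.linalg.norm(obs_on_pred)
    overlap = float(p @ obs_on_pred / denom) if denom > 0 else 0.0
    combined = float(np.hypot(predicted.sd(), observed.sd()))
    return AssemblyComparison(
        delta_mean=float(d_mean),
        delta_sd=float(d_sd),
        overlap=overlap,
        within_uncertainty=bool(abs(d_mean) <= combined),
    )


def occupancy_expected(p: float, sites: int, order: int) -> np.ndarray:
    """Expected modified-count fractions under assembly independence.

    Binomial(order x sites, p) mass function over k = 0 .. order*sites.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must be in [0, 1]")
    if sites < 1 or order < 1:
        raise ValueError("sites and order must be >= 1")
    n = order * sites
    return stats.binom.pmf(np.arange(n + 1), n, p)


def _exact_multinomial_pvalue(observed: np.ndarray, probs: np.ndarray) -> float:
    """Exact multinomial goodness-of-fit p-value (sum of the probabilities of
    all outcomes no more probable than the observed one).  The last two cells
    are enumerated vectorized, so the cost is O(n^(k-1)) with small constants
    — fine for the small cell counts of occupancy models."""
    from scipy.special import gammaln

    n = int(observed.sum())
    k = probs.size
    if k < 2:
        return 1.0
    logp = np.full(k, -np.inf)
    nz = probs > 0
    logp[nz] = np.log(probs[nz])

    def cell_term(count, cell):
        # count * log p, with 0 * log(0) := 0
        c = np.asarray(count, dtype=float)
        term = np.where(c > 0, c * logp[cell], 0.0)
        return term - gammaln(c + 1)

    obs_logpmf = gammaln(n + 1) + sum(
        float(cell_term(observed[i], i)) for i in range(k)
    )
    total = 0.0

    def recurse(cell: int, remaining: int, log_prefix: float) -> None:
        nonlocal total
        if cell == k - 2:
            c1 = np.arange(remaining + 1)
            c2 = remaining - c1
            lp = log_prefix + cell_term(c1, k - 2) + cell_term(c2, k - 1)
            total += float(np.exp(lp[lp <= obs_logpmf + 1e-9]).sum())
            return
        for c in range(remaining + 1):
            recurse(cell + 1, remaining - c, log_prefix + float(cell_term(c, cell)))

    recurse(0, n, gammaln(n + 1))
    return float(min(1.0, total))


def independence_test(
    observed_counts: Sequence[float],
    p: float,
    sites: int = 1,
    order: int = 2,
    method: str = "auto",
) -> Tuple[float, float]:
    """Goodness-of-fit of observed oligomer modification counts vs independence.

    ``observed_counts[k]`` is the number of oligomers carrying k modifications;
    the null is Binomial(order x sites, p).  Returns (statistic, p-value).

    ``method='auto'`` uses the chi-square statistic when every expected cell
    count is at least 5, and the exact multinomial tail otherwise (including
    whenever a zero-probability cell holds observed counts); exact computation
    is restricted to n_events <= 10^4.
    """
    observed = np.asarray(observed_counts, dtype=float)
    expected_frac = occupancy_expected(p, sites, order)
    if observed.size != expected_frac.size:
        raise ValueError(
            f"observed has {observed.size} cells; expected {expected_frac.size}"
        )
    n = observed.sum()
    if n <= 0:
        raise ValueError("no events observed")
    expected = expected_frac * n

    zero_conflict = np.any((expected_frac == 0) & (observed > 0))
    if method == "auto":
        method = (
            "exact"
            if (zero_conflict or np.any(expected < 5)) and n <= 10_000
            else "chi2"
        )
    if method == "exact":
        if n > 10_000:
            raise ValueError("exact multinomial test limited to <= 10^4 events")
        counts = np.round(observed).astype(int)
        pvalue = _exact_multinomial_pvalue(counts, expected_frac)
        with np.errstate(divide="ignore", invalid="ignore"):
            terms = (observed - expected) ** 2 / expected
        stat = float(np.sum(terms[np.isfinite(terms)]))
        return stat, pvalue
    if method == "chi2":
        if zero_conflict:
            raise ValueError(
                "observed counts in zero-expectation cells; use the exact test"
            )
        keep = expected > 0
        stat, pvalue = stats.chisquare(observed[keep], expected[keep])
        # absorb dropped zero-probability cells into the dof correction
        dof = int(keep.sum()) - 1
        pvalue = float(stats.chi2.sf(stat, dof))
        return float(stat), pvalue
    raise ValueError(f"unknown method {method!r}")


def ratio_quantify(
    data: MassDistribution | MPHistogram,
    windows: Tuple[Tuple[float, float], Tuple[float, float]] | None = None,
) -> float:
    """Oligomer/monomer abundance ratio from one measurement.

    For a mass distribution, the ratio of integrated abundance in the
    oligomer window to the monomer window (windows are (lo, hi) mass pairs,
    monomer first).  For a mass-photometry histogram with a fitted mixture,
    the ratio of responsibility-weighted component weights: the components
    within each window are summed, and when no windows are given the fitted
    components are taken as (monomer, oligomer) in mean order.  Invariant to
    overall intensity scaling; returns 0 for a single-component input.
    """
    if isinstance(data, MassDistribution):
        if windows is None:
            raise ValueError("mass-distribution input requires explicit windows")
        (m_lo, m_hi), (d_lo, d_hi) = windows
        m = data.abundance[(data.masses >= m_lo) & (data.masses <= m_hi)].sum()
        d = data.abundance[(data.masses >= d_lo) & (data.masses <= d_hi)].sum()
        if m <= 0:
            raise ValueError("monomer window holds no abundance")
        return float(d / m)
    if isinstance(data, MPHistogram):
        if data.components is None:
            raise ValueError("fit the mixture first (fit_mp_mixture)")
        comps = data.components
        if windows is None:
            if len(comps) < 2:
                return 0.0
            monomer_w = comps[0][2]
            oligomer_w = sum(c[2] for c in comps[1:])
        else:
            (m_lo, m_hi), (d_lo, d_hi) = windows
            monomer_w = sum(w for mu, _, w in comps if m_lo <= mu <= m_hi)
            oligomer_w = sum(w for mu, _, w in comps if d_lo <= mu <= d_hi)
        if monomer_w <= 0:
            raise ValueError("no component in the monomer window")
        return float(oligomer_w / monomer_w)
    raise TypeError("data must be a MassDistribution or MPHistogram")


def compare_ratios(
    condition_a: Sequence[float], condition_b: Sequence[float]
) -> Tuple[Tuple[float, float], Tuple[float, float], float, float]:
    """Replicate statistics and a two-tailed Student's t-test between conditions.

    Returns ((mean_a, sd_a), (mean_b, sd_b), t, p).  Replicate sds use ddof=1
    (0 when a condition has a single replicate or identical replicates).
    """
    a = np.asarray(condition_a, dtype=float)
    b = np.asarray(condition_b, dtype=float)
    if a.size < 1 or b.size < 1:
        raise ValueError("each condition needs at least one replicate")
    sd_a = float(a.std(ddof=1)) if a.size > 1 else 0.0
    sd_b = float(b.std(ddof=1)) if b.size > 1 else 0.0
    t, p = stats.ttest_ind(a, b)
    return (float(a.mean()), sd_a), (float(b.mean()), sd_b), float(t), float(p)
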