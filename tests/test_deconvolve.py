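"""Centroiding, charge inference, fine structure and zero-charge reconstruction."""

import dataclasses

import numpy as np
import pytest

from glycolattice.glycomass import PROTON_MASS, InsufficientDataError
from glycolattice.synthesize import (
    Proteoform,
    SimulationConfig,
    Spectrum,
    render_spectrum,
    sample_proteoforms,
)
from glycolattice.deconvolve import (
    ChargeSeries,
    MassDistribution,
    PeakList,
    centroid,
    fine_structure_interval,
    fourier_repeat,
    infer_charges,
    zero_charge,
)


def _gaussian_spectrum(centers, heights, lo, hi, step=0.02, fwhm=0.6):
    grid = np.arange(lo, hi, step)
    sigma = fwhm / 2.3548
    y = np.zeros_like(grid)
    for c, h in zip(centers, heights):
        y += h * np.exp(-0.5 * ((grid - c) / sigma) ** 2)
    return Spectrum(grid, y)


class TestCentroid:
    def test_single_gaussian_round_trip(self):
        spec = _gaussian_spectrum([5403.09], [1.0], 5390, 5415)
        pl = centroid(spec)
        assert len(pl) == 1
        assert pl.mz[0] == pytest.approx(5403.09, abs=0.01)

    def test_flat_spectrum_yields_empty_list(self):
        grid = np.arange(5000.0, 5100.0, 0.1)
        pl = centroid(Spectrum(grid, np.ones_like(grid)))
        assert len(pl) == 0

    def test_two_resolved_peaks(self):
        spec = _gaussian_spectrum([5400.0, 5401.8], [1.0, 0.7], 5395, 5407)
        pl = centroid(spec)
        assert len(pl) == 2
        assert pl.mz == pytest.approx([5400.0, 5401.8], abs=0.01)

    def test_empty_spectrum_rejected(self):
        with pytest.raises(ValueError):
            centroid(Spectrum(np.empty(0), np.empty(0)))


class TestInferCharges:
    def test_exact_charge_ladder_recovers_mass(self):
        M = 140000.0
        mz = np.array([(M + z * PROTON_MASS) / z for z in range(25, 29)])
        pl = PeakList(mz, np.ones(4), np.full(4, 0.5))
        asg = infer_charges(pl, z_range=(15, 35))
        assert len(asg.species_masses) == 1
        assert list(asg.species_masses.values())[0] == pytest.approx(M, abs=0.5)
        assert sorted(s.z for s in asg.series) == [25, 26, 27, 28]

    def test_single_peak_is_ambiguous(self):
        pl = PeakList(np.array([5403.09]), np.ones(1), np.full(1, 0.5))
        asg = infer_charges(pl)
        assert not asg.series
        assert asg.unassigned_mz == pytest.approx([5403.09])

    def test_mixed_monomer_dimer_envelopes_separate(self):
        M = 140000.0
        mz = [(M + z * PROTON_MASS) / z for z in range(24, 29)]
        mz += [(2 * M + z * PROTON_MASS) / z for z in range(34, 41)]
        pl = PeakList(np.sort(mz), np.ones(len(mz)), np.full(len(mz), 0.5))
        asg = infer_charges(pl, z_range=(20, 45))
        masses = sorted(asg.species_masses.values())
        assert len(masses) == 2
        assert masses[1] / masses[0] == pytest.approx(2.0, abs=1e-3)

    def test_invalid_z_range_rejected(self):
        pl = PeakList(np.array([5000.0, 5200.0]), np.ones(2), np.full(2, 0.5))
        with pytest.raises(ValueError):
            infer_charges(pl, z_range=(0, 30))


class TestFineStructure:
    def test_lattice_ladder_at_z26_gives_printed_interval(self):
        mz = (140000.0 + 72.95 * np.arange(10) + 26 * PROTON_MASS) / 26
        mean, sd, dM = fine_structure_interval(
            PeakList(mz, np.ones(10), np.full(10, 0.5)), z=26
        )
        assert mean == pytest.approx(2.81, abs=0.01)
        assert dM == pytest.approx(72.95, abs=0.01)

    def test_uniform_ladder_has_zero_spread(self):
        mz = 5000.0 + 2.8 * np.arange(8)
        _, sd, _ = fine_structure_interval(PeakList(mz, np.ones(8), np.ones(8)), 26)
        assert sd == pytest.approx(0.0, abs=1e-9)

    def test_missing_tooth_does_not_bias_mean(self):
        mz = 5000.0 + 2.8 * np.arange(10)
        mz = np.delete(mz, 4)  # vacancy: one doubled gap
        mean, _, _ = fine_structure_interval(PeakList(mz, np.ones(9), np.ones(9)), 26)
        assert mean == pytest.approx(2.8, abs=1e-9)

    def test_too_few_peaks_raise(self):
        with pytest.raises(InsufficientDataError):
            fine_structure_interval(PeakList(np.array([5000.0, 5002.8]), np.ones(2), np.ones(2)), 26)


class TestFourierRepeat:
    def _comb(self, spacing, n_teeth=60, noise=0.0, seed=0):
        grid = np.arange(5300.0, 5320 + spacing * n_teeth + 10, 0.02)
        y = np.zeros_like(grid)
        for k in range(n_teeth):
            y += np.exp(-0.5 * ((grid - 5320 - k * spacing) / 0.15) ** 2)
        if noise:
            rng = np.random.default_rng(seed)
            y = np.clip(y + rng.normal(0, noise * y.max(), y.size), 0, None)
        return Spectrum(grid, y)

    def test_noise_free_comb(self):
        spec = self._comb(72.95 / 26)
        assert fourier_repeat(spec, 26) == pytest.approx(72.95, abs=0.5)

    def test_white_noise_reports_no_periodicity(self):
        rng = np.random.default_rng(1)
        grid = np.arange(5300.0, 5500.0, 0.02)
        spec = Spectrum(grid, np.abs(rng.normal(1.0, 0.3, grid.size)))
        assert fourier_repeat(spec, 26) is None

    def test_noisy_comb_within_one_dalton(self):
        spec = self._comb(72.95 / 26, noise=0.2, seed=4)
        assert fourier_repeat(spec, 26) == pytest.approx(72.95, abs=1.0)

    def test_agrees_with_direct_interval_estimate(self):
        spec = self._comb(72.95 / 26)
        pl = centroid(spec)
        _, _, dM = fine_structure_interval(pl, 26)
        assert fourier_repeat(spec, 26) == pytest.approx(dM, abs=1.0)


class TestZeroCharge:
    def test_intensity_conservation(self):
        s1 = ChargeSeries(z=26, member_mz=np.array([5403.0, 5405.8]),
                          member_intensity=np.array([1.0, 0.5]))
        s2 = ChargeSeries(z=27, member_mz=np.array([5203.0]),
                          member_intensity=np.array([0.8]))
        md = zero_charge([s1, s2])
        assert md.total() == pytest.approx(2.3, rel=1e-12)

    def test_single_peak_delta_distribution(self):
        mz = 5403.084203
        md = zero_charge([ChargeSeries(z=26, member_mz=np.array([mz]),
                                       member_intensity=np.array([1.0]))])
        centers, heights = md.peaks()
        assert len(centers) == 1
        assert centers[0] == pytest.approx(26 * (mz - PROTON_MASS), abs=0.5)
        assert heights[0] == pytest.approx(1.0)

    def test_two_charge_states_of_one_species_merge(self):
        M = 140000.0
        series = [
            ChargeSeries(z=z, member_mz=np.array([(M + z * PROTON_MASS) / z]),
                         member_intensity=np.array([1.0]))
            for z in (26, 27)
        ]
        md = zero_charge(series)
        centers, heights = md.peaks()
        assert len(centers) == 1
        assert centers[0] == pytest.approx(M, abs=0.5)

    def test_repeat_filter_flags_off_lattice_peak(self):
        base = 140000.0
        masses = [base, base + 72.95, base + 2 * 72.95, base + 72.95 + 30.0]
        series = [
            ChargeSeries(z=26, member_mz=np.array([(m + 26 * PROTON_MASS) / 26]),
                         member_intensity=np.array([1.0 if i != 1 else 2.0]))
            for i, m in enumerate(masses)
        ]
        md = zero_charge(series, repeat_filter=72.95, lattice_tol=10.0)
        assert md.lattice_flags is not None
        assert md.lattice_flags.sum() == 3  # the +30 Da peak is off-lattice

    def test_empty_series_rejected(self):
        with pytest.raises(ValueError):
            zero_charge([])


def test_round_trip_recovers_generator_masses(clean_config):
    """Simulate -> centroid -> charge inference recovers the population mass."""
    pop = sample_proteoforms(clean_config)
    spec = render_spectrum(pop, clean_config)
    pl = centroid(spec)
    asg = infer_charges(pl, z_range=(18, 34))
    main = max(
        asg.species_masses,
        key=lambda s: sum(cs.member_intensity.sum() for cs in asg.by_species(s)),
    )
    true_mean = sum(p.abundance * p.mass() for p in pop)
    assert asg.species_masses[main] == pytest.approx(true_mean, abs=2.0)

    md = zero_charge(asg.by_species(main), repeat_filter=72.95)
    assert md.total() == pytest.approx(
        sum(s.member_intensity.sum() for s in asg.by_species(main)), rel=1e-9
    )
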