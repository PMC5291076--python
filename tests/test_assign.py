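"""Peak assignment, oligomer distributions, laser series, condition calls."""

from __future__ import annotations

import numpy as np
import pytest

import lilbidms as L
from lilbidms.assign import AMBIGUOUS_CLASS, AssignmentStatus
from lilbidms.complexes import ComplexSpecies
from lilbidms.simulate import DissociationParams, SimulationScenario
from lilbidms.spectra import Peak


def make_peak(apex: float, integral: float = 1.0, fwhm: float = 0.2) -> Peak:
    half = fwhm / 2
    return Peak(
        apex_kda=apex,
        height=1.0,
        fwhm_kda=fwhm,
        left_half_kda=apex - half,
        right_half_kda=apex + half,
        integral=integral,
        left_base_kda=apex - 2 * fwhm,
        right_base_kda=apex + 2 * fwhm,
    )


def distribution_from_fractions(fractions: dict, grouping: str = "nm"):
    """Build an OligomerDistribution directly from mean fractions (SD 0)."""
    return L.OligomerDistribution(
        classes={k: (v, 0.0) for k, v in fractions.items()},
        n_replicates=1,
        grouping=grouping,
    )


class TestAssignPeaks:
    def test_overlapped_tetramer_peak_is_ambiguous(self, kcsa_sample):
        species = L.enumerate_species(kcsa_sample)
        [assignment] = L.assign_peaks([make_peak(85.32)], species, 0.10)
        assert assignment.status is AssignmentStatus.AMBIGUOUS
        stoichs = {c.species.stoichiometry for c in assignment.candidates}
        assert {(4, 0, 0), (1, 2, 0)} <= stoichs

    def test_labeled_tetramer_peak_is_unique(self, msp1e3d1):
        kcsa_exp = L.construct_component(
            "KcsA", L.Role.TARGET, basis="experimental", labeled=True
        )
        msp_exp = L.construct_component(
            "MSP1E3D1", L.Role.SCAFFOLD, basis="experimental"
        )
        sample = L.SampleDefinition(target=kcsa_exp, scaffold=msp_exp, n_max=4, z_max=1)
        species = L.enumerate_species(sample)
        [assignment] = L.assign_peaks([make_peak(91.08)], species, 0.10)
        assert assignment.status is AssignmentStatus.UNIQUE
        assert assignment.best.species.stoichiometry == (4, 0, 0)

    def test_far_peak_unassigned(self, kcsa_sample):
        species = L.enumerate_species(kcsa_sample)
        [assignment] = L.assign_peaks([make_peak(300.0)], species, 0.10)
        assert assignment.status is AssignmentStatus.UNASSIGNED

    def test_candidates_ordered_by_error_then_parsimony(self):
        a = ComplexSpecies((2, 0, 0), 100.0, z_max=1)
        b = ComplexSpecies((1, 1, 0), 100.0, z_max=1)  # same mass, same copies
        c = ComplexSpecies((4, 0, 0), 100.05, z_max=1)
        [assignment] = L.assign_peaks([make_peak(100.0)], [a, b, c], 0.10)
        errors = [abs(cand.error_kda) for cand in assignment.candidates]
        assert errors == sorted(errors)
        assert assignment.candidates[-1].species.stoichiometry == (4, 0, 0)

    def test_charge_ladder_matching(self):
        species = ComplexSpecies((4, 2, 0), 149.24, z_max=4)
        [assignment] = L.assign_peaks([make_peak(74.62)], [species], 0.05)
        assert assignment.status is AssignmentStatus.UNIQUE
        assert assignment.best.z == 2


class TestOligomerDistribution:
    def test_single_assigned_peak_full_fraction(self, kcsa_sample):
        species = L.enumerate_species(kcsa_sample)
        assignments = L.assign_peaks([make_peak(149.24, integral=2.0)], species, 0.10)
        dist = L.oligomer_distribution([assignments])
        assert dist.mean_fraction((4, 2)) == pytest.approx(1.0)
        assert dist.sd((4, 2)) == 0.0
        assert dist.n_replicates == 1

    def test_two_equal_classes_split_evenly(self, kcsa, msp1e3d1):
        # single-charge species set: the monomer position is then free of
        # cross-charge coincidences (at z_max=4 the bare monomer peak would
        # coincide with the tetramer's 4- charge state and be ambiguous)
        sample = L.SampleDefinition(target=kcsa, scaffold=msp1e3d1, n_max=4, z_max=1)
        species = L.enumerate_species(sample)
        peaks = [make_peak(149.24, integral=3.0), make_peak(21.33, integral=3.0)]
        dist = L.oligomer_distribution([L.assign_peaks(peaks, species, 0.05)])
        assert dist.mean_fraction((4, 2)) == pytest.approx(0.5)
        assert dist.mean_fraction((1, 0)) == pytest.approx(0.5)

    def test_fractions_sum_to_one(self, kcsa_sample):
        species = L.enumerate_species(kcsa_sample)
        peaks = [
            make_peak(149.24, integral=5.0),
            make_peak(85.32, integral=2.0),  # ambiguous class
            make_peak(21.33, integral=1.0),
            make_peak(300.0, integral=9.0),  # unassigned, excluded
        ]
        dist = L.oligomer_distribution([L.assign_peaks(peaks, species, 0.08)])
        total = sum(mean for mean, _sd in dist.classes.values())
        assert total == pytest.approx(1.0, abs=1e-9)
        assert AMBIGUOUS_CLASS in dist.classes

    def test_invariant_under_global_intensity_rescaling(self, kcsa_sample):
        species = L.enumerate_species(kcsa_sample)
        peaks = [make_peak(149.24, integral=4.0), make_peak(21.33, integral=1.0)]
        scaled = [make_peak(149.24, integral=40.0), make_peak(21.33, integral=10.0)]
        d1 = L.oligomer_distribution([L.assign_peaks(peaks, species, 0.05)])
        d2 = L.oligomer_distribution([L.assign_peaks(scaled, species, 0.05)])
        assert d1.classes == d2.classes

    def test_replicate_with_no_assigned_area_excluded_with_warning(self, kcsa_sample):
        species = L.enumerate_species(kcsa_sample)
        good = L.assign_peaks([make_peak(149.24)], species, 0.10)
        empty = L.assign_peaks([make_peak(300.0)], species, 0.10)
        with pytest.warns(UserWarning, match="excluded"):
            dist = L.oligomer_distribution([good, empty])
        assert dist.n_replicates == 1
        assert dist.n_excluded == 1

    def test_sample_sd_across_replicates(self, kcsa_sample):
        species = L.enumerate_species(kcsa_sample)
        rep1 = L.assign_peaks(
            [make_peak(149.24, integral=3.0), make_peak(21.33, integral=1.0)],
            species, 0.05,
        )
        rep2 = L.assign_peaks(
            [make_peak(149.24, integral=1.0), make_peak(21.33, integral=1.0)],
            species, 0.05,
        )
        dist = L.oligomer_distribution([rep1, rep2])
        values = [0.75, 0.5]
        assert dist.mean_fraction((4, 2)) == pytest.approx(np.mean(values))
        assert dist.sd((4, 2)) == pytest.approx(np.std(values, ddof=1))


class TestEndToEnd:
    def test_planted_species_recovered_uniquely_without_noise(self, kcsa_sample):
        # pairwise mass gaps of the planted set far exceed 2x tolerance
        planted = {(4, 2, 0): 300.0, (0, 1, 0): 150.0, (1, 0, 0): 100.0}
        scenario = SimulationScenario(
            sample=kcsa_sample,
            abundances=planted,
            seed=17,
            sigma_inst_kda=0.05,
            charge_weights=(1.0,),
            noise_amplitude=0.0,
            grid_kda=(5.0, 180.0, 0.005),
        )
        spectrum = L.normalize(L.render_spectrum(scenario))
        species = [
            s
            for s in L.enumerate_species(kcsa_sample)
            if s.stoichiometry in planted
        ]
        assignments = L.assign_peaks(L.detect_peaks(spectrum), species, 0.10)
        recovered = {
            a.best.species.stoichiometry
            for a in assignments
            if a.status is AssignmentStatus.UNIQUE
        }
        assert recovered == set(planted)

    def test_planted_abundances_recovered_across_replicates(self, msp1e3d1):
        # hexamer-forming target with planted oligomer mix; integral
        # fractions across seeded replicates recover the planted weights
        pr = L.construct_component("PR", L.Role.TARGET)
        sample = L.SampleDefinition(
            target=pr, scaffold=msp1e3d1, n_max=6, m_max=2, z_max=1
        )
        planted = {(6, 2, 0): 500.0, (4, 2, 0): 300.0, (2, 0, 0): 200.0}
        scenario = SimulationScenario(
            sample=sample,
            abundances=planted,
            seed=29,
            sigma_inst_kda=0.1,
            charge_weights=(1.0,),
            noise_amplitude=1.0,
            grid_kda=(10.0, 260.0, 0.005),
        )
        spectra = L.simulate_replicates(scenario, 3, seeds=[101, 102, 103])
        species = L.enumerate_species(sample)
        per_rep = [
            L.assign_peaks(L.detect_peaks(L.normalize(s)), species, 0.10)
            for s in spectra
        ]
        dist = L.oligomer_distribution(per_rep)
        total = sum(planted.values())
        for (n, m, _k), abundance in planted.items():
            assert dist.mean_fraction((n, m)) == pytest.approx(
                abundance / total, abs=0.05
            )


class TestLaserSeries:
    def _distribution_at(self, sample, energy, diss, seed, abundances=None):
        scenario = SimulationScenario(
            sample=sample,
            abundances=abundances or {(4, 2, 0): 3000.0},
            seed=seed,
            sigma_inst_kda=0.05,
            charge_weights=(1.0,),
            noise_amplitude=0.0,
            laser_mj=energy,
            dissociation=diss,
            grid_kda=(5.0, 260.0, 0.005),
        )
        spectrum = L.normalize(L.render_spectrum(scenario))
        species = L.enumerate_species(sample)
        return L.oligomer_distribution(
            [L.assign_peaks(L.detect_peaks(spectrum), species, 0.05)]
        )

    def test_no_dissociation_gives_identical_distributions(self, kcsa_sample):
        dists = {
            e: self._distribution_at(kcsa_sample, e, DissociationParams.none(), 31)
            for e in (10.0, 16.0, 22.0)
        }
        report = L.laser_series_report(dists)
        assert report.trends_pass
        first = dists[10.0].classes
        assert all(d.classes == first for d in dists.values())

    def test_increasing_dissociation_trends_pass(self, msp1e3d1):
        # hexamer-forming target series in neutral-mass space: scaffold
        # loss rises with laser energy, so scaffolded classes shrink
        pr = L.construct_component("PR", L.Role.TARGET)
        sample = L.SampleDefinition(
            target=pr, scaffold=msp1e3d1, n_max=6, m_max=2, z_max=1
        )
        abundances = {(6, 2, 0): 1500.0, (4, 2, 0): 1500.0}
        diss = DissociationParams()
        dists = {
            e: self._distribution_at(sample, e, diss, 37, abundances)
            for e in (10.0, 16.0, 22.0)
        }
        # dissociation is sampled per particle, so monotonicity holds in
        # expectation; allow a small Monte-Carlo slack on the trend check
        report = L.laser_series_report(dists, trend_slack=0.01)
        assert report.trends_pass
        # scaffolded classes dominate at low energy, free classes at high
        low, high = dists[10.0], dists[22.0]
        scaffolded = lambda d: sum(
            mean
            for key, (mean, _sd) in d.classes.items()
            if isinstance(key, tuple) and key[1] >= 1
        )
        assert scaffolded(low) > scaffolded(high)

    def test_single_energy_rejected(self, kcsa_sample):
        dist = self._distribution_at(kcsa_sample, 10.0, DissociationParams.none(), 41)
        with pytest.raises(ValueError):
            L.laser_series_report({10.0: dist})

    def test_inconsistent_grouping_rejected(self):
        a = distribution_from_fractions({(1, 0): 1.0}, grouping="nm")
        b = distribution_from_fractions({(1, 0): 1.0}, grouping="nmk")
        with pytest.raises(ValueError, match="grouping"):
            L.laser_series_report({10.0: a, 20.0: b})

    def test_violations_reported_not_suppressed(self):
        rising_scaffold = {
            10.0: distribution_from_fractions({(1, 1): 0.2, (1, 0): 0.8}),
            20.0: distribution_from_fractions({(1, 1): 0.6, (1, 0): 0.4}),
        }
        report = L.laser_series_report(rising_scaffold)
        assert not report.trends_pass
        assert any("rises" in v for v in report.violations)


class TestConditionComparison:
    def test_lipid_dependent_dimer_calls(self):
        # translocase in anionic vs zwitterionic bilayers: the dimer class
        # is present only where the anionic lipid is present
        conditions = {
            "Ec/DMPG": distribution_from_fractions({(2, 2): 0.5, (1, 2): 0.3, (1, 0): 0.2}),
            "Ec/DMPC": distribution_from_fractions({(1, 2): 0.7, (1, 0): 0.29, (2, 2): 0.01}),
            "Ec/DMPG-DMPC": distribution_from_fractions({(2, 2): 0.2, (1, 2): 0.8}),
            "Bs/DMPG": distribution_from_fractions({(2, 2): 0.6, (1, 0): 0.4}),
            "Bs/DMPC": distribution_from_fractions({(2, 2): 0.55, (1, 0): 0.45}),
        }
        table = L.condition_comparison(conditions)
        calls = dict(zip(table["condition"], table["call"]))
        assert calls == {
            "Ec/DMPG": 2,
            "Ec/DMPC": 1,
            "Ec/DMPG-DMPC": 2,
            "Bs/DMPG": 2,
            "Bs/DMPC": 2,
        }

    def test_zero_dimer_fraction_calls_monomer(self):
        table = L.condition_comparison(
            {"only-monomer": distribution_from_fractions({(1, 2): 1.0, (2, 2): 0.0})}
        )
        assert table["call"].tolist() == [1]

    def test_threshold_is_configurable(self):
        dist = distribution_from_fractions({(2, 2): 0.05, (1, 2): 0.95})
        assert L.condition_comparison({"c": dist}, threshold=0.02)["call"][0] == 2
        assert L.condition_comparison({"c": dist}, threshold=0.10)["call"][0] == 1
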