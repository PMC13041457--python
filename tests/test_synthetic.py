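"""Synthetic cohort generator: structure, determinism, planted couplings."""

from dataclasses import replace

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from gaitstrat.clustering import cut_k, hac_wardlike
from gaitstrat.dtw import pairwise_matrix
from gaitstrat.preprocess import fit_normalization
from gaitstrat.synthetic_data import (
    ArchetypeSpec,
    CohortConfig,
    SEVERITY_ORDER,
    default_archetypes,
    default_side_archetypes,
    generate_cohort,
    planted_correlation_check,
)


class TestArchetypes:
    def test_six_impaired_plus_control(self):
        archs = default_archetypes()
        names = [a.name for a in archs]
        assert len(archs) == 7
        assert names[0] == "control"
        assert set(names[1:]) == {"green", "pink", "violet", "blue",
                                  "orange", "cactus"}

    def test_slowest_archetype_has_longest_cycles(self):
        by_name = {a.name: a for a in default_archetypes()}
        assert by_name["cactus"].duration_mean > by_name["control"].duration_mean
        assert by_name["orange"].duration_mean > by_name["control"].duration_mean

    def test_templates_within_physiologic_bounds(self):
        cfg = CohortConfig(
            n_subjects=6, n_controls=1, noise_sd=0.0, warp_strength=0.0,
            side_offset_jitter_sd=0.0, side_amp_jitter_sd=0.0,
            pf_jitter_sd=0.0, seed=0,
            side_archetypes=tuple(
                (a.name, a.name) for a in default_archetypes()[1:]),
        )
        cohort = generate_cohort(cfg)
        for c in cohort.cycles:
            assert np.abs(c.angles).max() <= 90.0

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            ArchetypeSpec(name="x", duration_mean=-1.0)
        with pytest.raises(ValueError):
            ArchetypeSpec(name="x", speed_slope=-0.1)

    def test_default_side_layout_counts(self):
        pairs = default_side_archetypes(28)
        sides = [s for pair in pairs for s in pair]
        counts = {n: sides.count(n) for n in set(sides)}
        assert counts == {"blue": 16, "pink": 13, "violet": 10,
                          "green": 9, "orange": 5, "cactus": 3}
        asymmetric = sum(a != b for a, b in pairs)
        assert asymmetric == 7


class TestGenerateCohort:
    def test_default_scale_280_cycles(self):
        cohort = generate_cohort(CohortConfig(seed=0))
        assert len(cohort.isci_cycles) == 28 * 2 * 5
        assert len(cohort.control_cycles) == 21 * 2 * 5
        assert len(cohort.planted) == len(cohort.cycles)

    def test_same_seed_bit_identical(self):
        a = generate_cohort(CohortConfig(n_subjects=4, n_controls=1, seed=5))
        b = generate_cohort(CohortConfig(n_subjects=4, n_controls=1, seed=5))
        for ca, cb in zip(a.cycles, b.cycles):
            np.testing.assert_array_equal(ca.angles, cb.angles)
        assert a.temporospatial == b.temporospatial
        assert a.subjects == b.subjects

    def test_different_seed_differs(self):
        a = generate_cohort(CohortConfig(n_subjects=2, n_controls=0, seed=1))
        b = generate_cohort(CohortConfig(n_subjects=2, n_controls=0, seed=2))
        assert not np.array_equal(a.cycles[0].angles, b.cycles[0].angles)

    def test_zero_noise_zero_warp_cycles_identical_within_side(self):
        cohort = generate_cohort(CohortConfig(
            n_subjects=3, n_controls=0, noise_sd=0.0, warp_strength=0.0,
            seed=2,
        ))
        by_side = {}
        for c in cohort.cycles:
            by_side.setdefault((c.subject_id, c.side), []).append(c)
        for group in by_side.values():
            for c in group[1:]:
                np.testing.assert_array_equal(c.angles, group[0].angles)
                assert c.toe_off_index == group[0].toe_off_index

    def test_cycles_satisfy_invariants_and_grades_parse(self):
        from gaitstrat.preprocess import quantize_mmt

        cohort = generate_cohort(CohortConfig(n_subjects=6, n_controls=2,
                                              seed=3))
        for c in cohort.cycles:
            assert 1 <= c.toe_off_index < c.n_samples
        for s in cohort.subjects:
            assert len(s.mmt_grades) == 18
            for g in s.mmt_grades.values():
                assert 2.0 <= quantize_mmt(g) <= 5.0

    def test_unknown_archetype_rejected(self):
        with pytest.raises(ValueError, match="unknown archetype"):
            generate_cohort(CohortConfig(
                n_subjects=1, side_archetypes=(("green", "nope"),)))


class TestPlantedCorrelation:
    def test_null_coupling_low_rho(self):
        archs = [replace(a, speed_slope=0.0, speed_intercept=0.9)
                 for a in default_archetypes()]
        rhos = []
        for seed in range(20):
            cohort = generate_cohort(
                CohortConfig(n_subjects=25, n_controls=0, seed=seed), archs)
            rhos.append(planted_correlation_check(cohort))
        assert abs(np.mean(rhos)) < 0.3

    def test_deterministic_coupling_perfect_rho(self):
        arch = replace(default_archetypes()[3], speed_sd=0.0)
        cohort = generate_cohort(
            CohortConfig(n_subjects=20, n_controls=0, seed=4,
                         side_archetypes=tuple([(arch.name, arch.name)] * 20)),
            [arch],
        )
        assert planted_correlation_check(cohort) == pytest.approx(1.0)

    def test_default_coupling_near_target(self):
        """Default cohorts recover rank rho near the calibrated 0.75."""
        rhos = [
            planted_correlation_check(generate_cohort(
                CohortConfig(n_subjects=50, n_controls=0, seed=seed)))
            for seed in range(20)
        ]
        assert 0.6 <= np.mean(rhos) <= 0.9


class TestDoseResponse:
    def test_ari_monotone_in_deviation_magnitude(self):
        """Clustering recovery rises with archetype deviation magnitude."""

        def scaled(arch, mag):
            return replace(
                arch,
                offsets={k: mag * v for k, v in arch.offsets.items()},
                amp_scale={k: 1.0 + mag * (v - 1.0)
                           for k, v in arch.amp_scale.items()},
                hip_peak_delay=mag * arch.hip_peak_delay,
                pf_attenuation=mag * arch.pf_attenuation,
                duration_mean=1.1 + mag * (arch.duration_mean - 1.1),
            )

        layout = tuple(
            (name, name)
            for name in ("green", "pink", "violet", "blue", "orange", "cactus")
            for _ in range(2)
        )
        aris = []
        for mag in (0.0, 0.4, 1.0):
            archs = [a if a.name == "control" else scaled(a, mag)
                     for a in default_archetypes()]
            cohort = generate_cohort(
                CohortConfig(n_subjects=12, n_controls=0, seed=6,
                             side_archetypes=layout), archs)
            isci = cohort.isci_cycles
            m = pairwise_matrix(isci, fit_normalization(isci))
            a = cut_k(hac_wardlike(m), 6)
            planted = dict(zip(cohort.planted.pattern_id,
                               cohort.planted.archetype))
            ids = list(a.labels)
            aris.append(adjusted_rand_score(
                [planted[i] for i in ids], [a.labels[i] for i in ids]))
        assert aris[0] < 0.3
        assert aris[0] <= aris[1] <= aris[2]
        assert aris[2] >= 0.9

    def test_severity_order_covers_archetypes(self):
        names = {a.name for a in default_archetypes()}
        assert names <= set(SEVERITY_ORDER)
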