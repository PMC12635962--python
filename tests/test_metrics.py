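"""Partitioning statistics: closed-form examples, identities, aggregation
oracles, sampling determinism and ionic-strength arithmetic."""

from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from guvphase import (
    IonSpecies,
    PartitionRecord,
    RunConfig,
    aggregate_condition,
    equivalent_concentration,
    ionic_strength,
    log_fold_change,
    normalize_attachment,
    select_heatmap_sample,
    selective_partitioning_index,
)

positive = st.floats(min_value=1e-3, max_value=1e6, allow_nan=False)


def make_record(guv="g", cond="c", rep="r", i_lo=50.0, i_ld=50.0, whole=50.0,
                qc=True) -> PartitionRecord:
    return PartitionRecord(
        guv_id=guv, condition_id=cond, replicate_id=rep,
        i_lo=i_lo, i_ld=i_ld,
        log_fc=log_fold_change(i_lo, i_ld),
        spi=selective_partitioning_index(i_lo, i_ld),
        whole_vesicle_intensity=whole, n_lo_bins=10, n_ld_bins=10, qc_pass=qc,
    )


class TestPerVesicleMetrics:
    def test_equal_phase_intensities_mean_no_preference(self):
        """Equal Lo and Ld DNA intensity gives log FC = 0 and SPI = 50%,
        the no-preference reference lines."""
        assert log_fold_change(50.0, 50.0) == 0.0
        assert selective_partitioning_index(50.0, 50.0) == 50.0

    def test_twofold_lo_enrichment(self):
        assert log_fold_change(100.0, 50.0) == pytest.approx(1.0)
        assert selective_partitioning_index(100.0, 50.0) == pytest.approx(200.0 / 3.0)

    @given(i_lo=positive, i_ld=positive)
    @settings(max_examples=300, derandomize=True)
    def test_spi_logfc_identity(self, i_lo, i_ld):
        """SPI = 100 * 2^logFC / (1 + 2^logFC) for every positive pair."""
        lfc = log_fold_change(i_lo, i_ld)
        spi = selective_partitioning_index(i_lo, i_ld)
        expected = 100.0 * 2.0**lfc / (1.0 + 2.0**lfc)
        assert spi == pytest.approx(expected, rel=1e-9)

    @given(i_lo=positive, i_ld=positive)
    @settings(max_examples=200, derandomize=True)
    def test_phase_swap_antisymmetry(self, i_lo, i_ld):
        assert log_fold_change(i_ld, i_lo) == pytest.approx(
            -log_fold_change(i_lo, i_ld), abs=1e-9
        )
        assert selective_partitioning_index(i_ld, i_lo) == pytest.approx(
            100.0 - selective_partitioning_index(i_lo, i_ld), abs=1e-9
        )

    @given(i_lo=positive, i_ld=positive,
           k=st.floats(min_value=1e-3, max_value=1e3))
    @settings(max_examples=200, derandomize=True)
    def test_scale_invariance(self, i_lo, i_ld, k):
        assert log_fold_change(k * i_lo, k * i_ld) == pytest.approx(
            log_fold_change(i_lo, i_ld), abs=1e-9
        )

    def test_nonpositive_intensity_yields_nan(self):
        assert math.isnan(log_fold_change(0.0, 50.0))
        assert math.isnan(selective_partitioning_index(-1.0, 50.0))


class TestAggregation:
    def test_two_replicates_constructed(self):
        """SPI {60, 80} and {70, 70} give replicate means 70, 70, hence
        condition mean 70 and SD 0."""
        records = [
            make_record("g1", rep="r1", i_lo=60, i_ld=40),
            make_record("g2", rep="r1", i_lo=80, i_ld=20),
            make_record("g3", rep="r2", i_lo=70, i_ld=30),
            make_record("g4", rep="r2", i_lo=70, i_ld=30),
        ]
        s = aggregate_condition(records, RunConfig(min_guvs_per_replicate=2))
        assert s.per_replicate_mean_spi == pytest.approx([70.0, 70.0])
        assert s.mean_spi == pytest.approx(70.0)
        assert s.sd_spi == pytest.approx(0.0)
        assert s.replicate_ok

    def test_replicate_below_minimum_flagged(self):
        records = [make_record(f"g{i}", rep="r1", i_lo=60, i_ld=40) for i in range(19)]
        s = aggregate_condition(records, RunConfig(min_guvs_per_replicate=20))
        assert not s.replicate_ok
        assert s.n_guvs_total == 19

    def test_single_replicate_sd_undefined(self):
        records = [make_record("g1"), make_record("g2")]
        s = aggregate_condition(records, RunConfig())
        assert s.n_replicates == 1
        assert math.isnan(s.sd_spi) and math.isnan(s.sd_log_fc)

    def test_matches_brute_force_two_stage(self):
        """Randomized records against an independent two-stage aggregation."""
        rng = np.random.default_rng(101)
        cfg = RunConfig(min_guvs_per_replicate=5)
        for _ in range(200):
            n_reps = int(rng.integers(2, 5))
            records = []
            for rep in range(n_reps):
                for g in range(int(rng.integers(2, 12))):
                    records.append(
                        make_record(
                            f"g{rep}-{g}", rep=f"r{rep}",
                            i_lo=float(rng.uniform(1, 100)),
                            i_ld=float(rng.uniform(1, 100)),
                            qc=bool(rng.random() > 0.2),
                        )
                    )
            passing = [r for r in records if r.qc_pass]
            if not passing:
                continue
            s = aggregate_condition(records, cfg)
            # brute force: dict of replicate -> values, then flat stats
            reps = sorted({r.replicate_id for r in passing})
            rep_means = [
                sum(r.spi for r in passing if r.replicate_id == k)
                / len([r for r in passing if r.replicate_id == k])
                for k in reps
            ]
            assert s.per_replicate_mean_spi == pytest.approx(rep_means)
            assert s.mean_spi == pytest.approx(sum(rep_means) / len(rep_means))
            if len(rep_means) >= 2:
                m = sum(rep_means) / len(rep_means)
                sd = math.sqrt(
                    sum((x - m) ** 2 for x in rep_means) / (len(rep_means) - 1)
                )
                assert s.sd_spi == pytest.approx(sd)
            ok = all(
                len([r for r in passing if r.replicate_id == k]) >= 5 for k in reps
            )
            assert s.replicate_ok == ok

    def test_mixed_conditions_rejected(self):
        with pytest.raises(ValueError):
            aggregate_condition(
                [make_record("a", cond="c1"), make_record("b", cond="c2")],
                RunConfig(),
            )


class TestAttachment:
    def test_reference_maps_to_unity_and_ratio(self):
        records = [
            make_record("g1", cond="ref", whole=200.0),
            make_record("g2", cond="other", whole=100.0),
        ]
        out = normalize_attachment(records, "ref")
        assert out["ref"] == 1.0
        assert out["other"] == pytest.approx(0.5)

    def test_matches_brute_force_means(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            records = []
            for cond in ("a", "b", "c"):
                for g in range(int(rng.integers(1, 8))):
                    records.append(
                        make_record(f"{cond}{g}", cond=cond,
                                    whole=float(rng.uniform(10, 500)))
                    )
            out = normalize_attachment(records, "a")
            ref = np.mean([r.whole_vesicle_intensity for r in records
                           if r.condition_id == "a"])
            for cond in ("b", "c"):
                mean = np.mean([r.whole_vesicle_intensity for r in records
                                if r.condition_id == cond])
                assert out[cond] == pytest.approx(mean / ref)

    def test_missing_reference_errors(self):
        with pytest.raises(ValueError):
            normalize_attachment([make_record(cond="x")], "absent")


class TestHeatmapSampling:
    def test_seeded_determinism_and_distinctness(self):
        records = [make_record(f"g{i}") for i in range(200)]
        a = select_heatmap_sample(records, 50, seed=3)
        b = select_heatmap_sample(records, 50, seed=3)
        assert [r.guv_id for r in a] == [r.guv_id for r in b]
        assert len({r.guv_id for r in a}) == 50

    def test_clamps_to_available(self):
        records = [make_record(f"g{i}") for i in range(30)]
        assert len(select_heatmap_sample(records, 50, seed=0)) == 30

    def test_different_seeds_differ(self):
        records = [make_record(f"g{i}") for i in range(200)]
        a = select_heatmap_sample(records, 50, seed=1)
        b = select_heatmap_sample(records, 50, seed=2)
        assert {r.guv_id for r in a} != {r.guv_id for r in b}

    def test_excludes_qc_failures(self):
        records = [make_record(f"g{i}", qc=(i % 2 == 0)) for i in range(20)]
        sample = select_heatmap_sample(records, 50, seed=0)
        assert all(r.qc_pass for r in sample)


class TestIonicStrength:
    @pytest.mark.parametrize(
        "ions, expected",
        [
            ([IonSpecies("Mg", 2, 0.5)], 1.0),
            ([IonSpecies("Na", 1, 2.0)], 1.0),
            ([], 0.0),
        ],
    )
    def test_half_sum_c_z_squared(self, ions, expected):
        assert ionic_strength(ions) == pytest.approx(expected)

    def test_single_species_equivalents_of_half_millimolar_divalent(self):
        """Monovalent 2 mM and trivalent 0.22 mM (2 d.p.) match the ionic
        strength of 0.5 mM of a divalent cation."""
        target = ionic_strength([IonSpecies("Mg", 2, 0.5)])
        assert equivalent_concentration(1, target) == pytest.approx(2.0)
        assert round(equivalent_concentration(3, target), 2) == 0.22
        assert equivalent_concentration(2, target) == pytest.approx(0.5)

    @given(z=st.integers(min_value=-4, max_value=4).filter(lambda z: z != 0),
           c=st.floats(min_value=0, max_value=100.0))
    @settings(max_examples=200, derandomize=True)
    def test_equivalent_concentration_round_trip(self, z, c):
        i = ionic_strength([IonSpecies("x", z, c)])
        assert round(equivalent_concentration(z, i), 12) == round(c, 12)

    @given(
        cs=st.lists(st.floats(min_value=0, max_value=100), min_size=0, max_size=6),
        k=st.floats(min_value=1e-3, max_value=1e3),
    )
    @settings(max_examples=100, derandomize=True)
    def test_additive_and_homogeneous(self, cs, k):
        ions = [IonSpecies(f"i{j}", (j % 3) + 1, c) for j, c in enumerate(cs)]
        total = ionic_strength(ions)
        assert total == pytest.approx(sum(ionic_strength([ion]) for ion in ions))
        scaled = [IonSpecies(ion.name, ion.z, k * ion.c_mM) for ion in ions]
        assert ionic_strength(scaled) == pytest.approx(k * total)

    def test_zero_charge_rejected(self):
        with pytest.raises(ValueError):
            IonSpecies("x", 0, 1.0)
        with pytest.raises(ValueError):
            equivalent_concentration(0, 1.0)
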