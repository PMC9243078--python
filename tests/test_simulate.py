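"""Generative model: ground truth, adhesion multipliers, counts, renders."""

import numpy as np
import pytest

import adhescreen as a
from adhescreen.simulate import well_rng


def _rng():
    return np.random.default_rng(0)


class TestGroundTruth:
    def test_null_screen_all_effects_zero(self, small_library):
        truth = a.sample_ground_truth(small_library, receptor_fraction=0.0, seed=1)
        assert all(e == 0.0 for e in truth.gene_effect.values())

    def test_saturated_screen(self, small_library):
        truth = a.sample_ground_truth(
            small_library, receptor_fraction=1.0, effect_range=(1.0, 1.0), seed=1
        )
        assert all(e == 1.0 for e in truth.gene_effect.values())

    def test_receptor_set_deterministic_for_seed(self):
        lib = a.build_library(100, 3, seed=0)
        t1 = a.sample_ground_truth(lib, receptor_fraction=0.04, seed=11)
        t2 = a.sample_ground_truth(lib, receptor_fraction=0.04, seed=11)
        assert len(t1.receptor_genes) == 4
        assert t1.receptor_genes == t2.receptor_genes
        assert t1.knockdown == t2.knockdown

    def test_explicit_receptors_and_carryover(self, small_library):
        truth = a.sample_ground_truth(
            small_library, receptor_genes=["G00003"], seed=1
        )
        assert truth.receptor_genes == ["G00003"]
        lib_b = a.library_for_genes(["G00003"], 5, seed=9)
        truth_b = a.extend_knockdown(truth, lib_b, seed=9)
        assert truth_b.gene_effect["G00003"] == truth.gene_effect["G00003"]
        for g in lib_b.genes:
            assert all(s in truth_b.knockdown for s in g.sirna_ids)

    def test_invalid_fraction_rejected(self, small_library):
        with pytest.raises(ValueError):
            a.sample_ground_truth(small_library, receptor_fraction=1.5)


class TestAdhesionMultiplier:
    def _truth(self, e, ks):
        return a.GroundTruth(
            gene_effect={"G": e},
            knockdown={f"s{i}": k for i, k in enumerate(ks)},
            offtarget_sd=0.0,
        )

    def test_no_effect_gives_unity(self):
        truth = self._truth(0.0, [0.8])
        well = a.WellSpec("gene_single", "G", ("s0",))
        assert a.adhesion_multiplier(well, truth, _rng()) == 1.0

    def test_complete_ablation(self):
        truth = self._truth(1.0, [1.0, 1.0, 1.0])
        well = a.WellSpec("gene_pool", "G", ("s0", "s1", "s2"))
        assert a.adhesion_multiplier(well, truth, _rng()) == 0.0

    def test_single_sirna_product(self):
        truth = self._truth(0.5, [0.8])
        well = a.WellSpec("gene_single", "G", ("s0",))
        assert a.adhesion_multiplier(well, truth, _rng()) == pytest.approx(0.6)

    def test_pool_rules(self):
        truth = self._truth(1.0, [0.5, 0.5, 0.5])
        well = a.WellSpec("gene_pool", "G", ("s0", "s1", "s2"))
        independent = a.adhesion_multiplier(well, truth, _rng(), pool_rule="independent")
        assert independent == pytest.approx(1 - (1 - 0.5**3))  # m = 1 - k_eff = 0.125
        assert a.adhesion_multiplier(well, truth, _rng(), pool_rule="max") == pytest.approx(0.5)

    def test_monotone_in_gene_effect(self):
        # expected ratio never increases as the adhesion effect grows
        well = a.WellSpec("gene_single", "G", ("s0",))
        ms = [
            a.adhesion_multiplier(well, self._truth(e, [0.9]), _rng())
            for e in np.linspace(0, 1, 11)
        ]
        assert all(m1 >= m2 for m1, m2 in zip(ms, ms[1:]))

    def test_control_classes(self, null_truth):
        assert a.adhesion_multiplier(a.WellSpec("untreated"), null_truth, _rng()) == 1.0
        assert a.adhesion_multiplier(
            a.WellSpec("ab_block"), null_truth, _rng()
        ) == pytest.approx(null_truth.abblock_residual)
        assert a.adhesion_multiplier(a.WellSpec("pos_ctrl_death"), null_truth, _rng()) == 1.0

    def test_empty_well_rejected(self, null_truth):
        with pytest.raises(ValueError):
            a.adhesion_multiplier(a.WellSpec("empty"), null_truth, _rng())

    def test_offtarget_noise_has_unit_mean(self, small_library):
        truth = a.sample_ground_truth(
            small_library, receptor_fraction=0.0, offtarget_sd=0.15, seed=3
        )
        rng = _rng()
        draws = [
            a.adhesion_multiplier(a.WellSpec("untreated"), truth, rng) for _ in range(20_000)
        ]
        se = np.std(draws, ddof=1) / np.sqrt(len(draws))
        assert abs(np.mean(draws) - 1.0) < 3 * se


class TestEmitCounts:
    def test_total_kill_gives_zero_nuclei(self, small_library):
        truth = a.sample_ground_truth(
            small_library, receptor_fraction=0.0, death_efficacy=1.0, seed=1
        )
        rec = a.emit_counts(
            a.WellSpec("pos_ctrl_death"), truth, a.RenderSpec(), _rng()
        )
        assert rec.n_nuclei == 0
        assert np.isnan(rec.bac_nuc_ratio)

    def test_zero_multiplier_gives_zero_bacteria(self):
        truth = a.GroundTruth({"G": 1.0}, {"s0": 1.0}, offtarget_sd=0.0)
        rec = a.emit_counts(
            a.WellSpec("gene_single", "G", ("s0",)), truth, a.RenderSpec(), _rng()
        )
        assert rec.n_bacteria == 0

    def test_poisson_moment_recovery(self):
        # 10,000 draws at m = 0.5, baseline 4, 1,000 nuclei: mean ratio
        # within 3 standard errors of 2.0
        truth = a.GroundTruth({"G": 0.5}, {"s0": 1.0}, offtarget_sd=0.0)
        spec = a.RenderSpec(nuclei_per_well=1000, bacteria_per_nucleus_baseline=4.0)
        well = a.WellSpec("gene_single", "G", ("s0",))
        rng = _rng()
        ratios = np.array(
            [a.emit_counts(well, truth, spec, rng).bac_nuc_ratio for _ in range(10_000)]
        )
        se = ratios.std(ddof=1) / np.sqrt(len(ratios))
        assert abs(ratios.mean() - 2.0) < 3 * se


class TestRender:
    def test_same_seed_bit_identical(self, null_truth, render_spec):
        well = a.WellSpec("neg_ctrl_scrambled")
        r1 = a.render_well(well, null_truth, render_spec, seed=5)
        r2 = a.render_well(well, null_truth, render_spec, seed=5)
        assert np.array_equal(r1.image, r2.image)
        assert r1.image.dtype == np.uint16

    def test_zero_nuclei_blank_dapi(self, null_truth):
        spec = a.RenderSpec(image_shape=(128, 128), nuclei_per_well=0.0)
        wr = a.render_well(a.WellSpec("untreated"), null_truth, spec.noise_free(), seed=1)
        assert wr.image[0].max() == 0
        assert len(wr.nuclei) == 0

    def test_embedded_lists_match_counts(self, noise_free_render):
        wr = noise_free_render
        assert len(wr.nuclei) == wr.counts.n_nuclei
        assert len(wr.puncta) == wr.counts.n_bacteria
        assert not wr.clipped

    def test_crowding_sets_clipped_flag(self, null_truth):
        spec = a.RenderSpec(image_shape=(96, 96), nuclei_per_well=60.0)
        wr = a.render_well(a.WellSpec("untreated"), null_truth, spec, seed=2)
        assert wr.clipped

    def test_tiff_round_trip(self, noise_free_render, tmp_path):
        path = tmp_path / "w.tif"
        a.write_well_tiff(noise_free_render.image, path)
        back = a.read_well_tiff(path)
        assert np.array_equal(back, noise_free_render.image)


class TestScreenCounts:
    def test_deterministic_and_rerenderable(self, small_library, null_truth):
        plates = a.layout_plates(small_library, controls_per_plate=16)
        d1 = a.simulate_screen_counts(plates, null_truth, a.RenderSpec(), seed=4)
        d2 = a.simulate_screen_counts(plates, null_truth, a.RenderSpec(), seed=4)
        assert d1.equals(d2)
        # any single well is reproducible in isolation from (seed, p, w)
        coord = sorted(plates[0].well_map)[5]
        rec = a.emit_counts(
            plates[0].well_map[coord], null_truth, a.RenderSpec(), well_rng(4, 0, 5)
        )
        row = d1[(d1.plate_id == plates[0].plate_id) & (d1.well == coord)].iloc[0]
        assert (rec.n_nuclei, rec.n_bacteria) == (row.n_nuclei, row.n_bacteria)

    def test_plate_effect_scales_ratio_only(self, small_library, null_truth):
        plates = a.layout_plates(small_library, controls_per_plate=16)
        base = a.simulate_screen_counts(plates, null_truth, a.RenderSpec(), seed=4)
        scaled = a.simulate_screen_counts(
            plates, null_truth, a.RenderSpec(), seed=4, plate_effect_sd=0.5
        )
        ratio = scaled.bac_nuc_ratio / base.bac_nuc_ratio
        assert np.allclose(ratio, ratio.iloc[0])
        assert (scaled.n_nuclei == base.n_nuclei).all()
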