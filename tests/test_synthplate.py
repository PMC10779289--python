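"""Synthetic plate generator: ground-truth fidelity and reproducibility."""

import numpy as np
import pytest

import mitoscreen as ms
from mitoscreen import ConditionEffect, GenerationError, SimulationParams

from conftest import two_condition_layout

NOISELESS = SimulationParams(poisson_noise=False, gaussian_noise_sd=0.0)


class TestSimulateField:
    def test_empty_noiseless_field_is_pure_background(self):
        img, truth = ms.simulate_field(0, params=NOISELESS, seed=0)
        np.testing.assert_array_equal(
            img.mros_ch, truth.background_surface(img.shape))
        assert truth.n_cells == 0

    def test_fixed_seed_reproducible(self):
        a, _ = ms.simulate_field(10, seed=123)
        b, _ = ms.simulate_field(10, seed=123)
        for ch in ("nuclei_ch", "mito_ch", "mros_ch"):
            np.testing.assert_array_equal(getattr(a, ch), getattr(b, ch))

    def test_noiseless_masked_signal_matches_truth_exactly(self):
        params = SimulationParams(poisson_noise=False, gaussian_noise_sd=0.0,
                                  background_base=0.0,
                                  background_amplitude=0.0)
        s = 1.7
        img, truth = ms.simulate_field(9, params=params, s=s, seed=4)
        mask = truth.mito_truth_labels > 0
        assert img.mros_ch[mask].sum() == pytest.approx(
            s * truth.masked_texture_sums.sum(), rel=1e-12)
        # per-cell conservation too
        for k in range(truth.n_cells):
            cell_mask = truth.mito_truth_labels == k + 1
            assert img.mros_ch[cell_mask].sum() == pytest.approx(
                s * truth.masked_texture_sums[k], rel=1e-12)

    def test_nonspecific_fraction_partitions_total_signal(self):
        params = SimulationParams(poisson_noise=False, gaussian_noise_sd=0.0,
                                  background_base=0.0,
                                  background_amplitude=0.0)
        f = 0.4
        img, truth = ms.simulate_field(8, params=params, s=1.0,
                                       nonspecific_fraction=f, seed=4)
        mask = truth.mito_truth_labels > 0
        outside = img.mros_ch[~mask].sum()
        total = img.mros_ch.sum()
        assert outside / total == pytest.approx(f, rel=1e-6)

    def test_raising_s_only_scales_masked_signal(self):
        imgs = {}
        for s in (1.0, 1.5, 2.0):
            img, truth = ms.simulate_field(10, s=s, seed=7)
            imgs[s] = (img, truth)
        m1, m15, m2 = (imgs[s][0].mros_ch[imgs[s][1].mito_truth_labels > 0]
                       .sum() for s in (1.0, 1.5, 2.0))
        assert m1 < m15 < m2
        # nuclei and mito channels are untouched by the condition scale
        for ch in ("nuclei_ch", "mito_ch"):
            np.testing.assert_array_equal(getattr(imgs[1.0][0], ch),
                                          getattr(imgs[2.0][0], ch))

    def test_masks_stay_near_their_nucleus(self, default_field):
        img, truth = default_field
        yy, xx = np.mgrid[0:img.shape[0], 0:img.shape[1]]
        reach = (SimulationParams().annulus_outer * truth.radii.max()
                 + 4 * SimulationParams().kernel_sigma_long_px)
        for k in range(truth.n_cells):
            cell = truth.mito_truth_labels == k + 1
            cy, cx = truth.centers[k]
            d = np.sqrt((yy[cell] - cy) ** 2 + (xx[cell] - cx) ** 2)
            assert d.max() <= reach

    def test_overcrowded_field_raises(self):
        with pytest.raises(GenerationError, match="fewer cells"):
            ms.simulate_field(400, seed=0)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            ms.simulate_field(-1, seed=0)
        with pytest.raises(ValueError):
            ms.simulate_field(1, params=SimulationParams(shape=(32, 32)),
                              seed=0)
        with pytest.raises(ValueError):
            ms.simulate_field(1, nonspecific_fraction=1.0, seed=0)


class TestSimulatePlate:
    def test_fold_parameter_echoed_in_truth(self):
        layout = two_condition_layout(fields_per_well=1)
        sim = ms.simulate_plate(layout,
                                {"basal": ConditionEffect(s=1.0),
                                 "oxldl": ConditionEffect(s=1.5)},
                                seed=0, n_cells_per_field=5)
        t = sim.truth_table.set_index("condition")
        assert set(t.loc["oxldl", "s"].unique() if hasattr(
            t.loc["oxldl", "s"], "unique") else [t.loc["oxldl", "s"]]) == {1.5}
        basal_s = sim.truth_table.query("condition == 'basal'")["s"]
        assert (basal_s == 1.0).all()

    def test_dose_series_follows_4pl_exactly(self):
        doses = [1.0, 3.0, 10.0, 30.0, 100.0, 300.0, 1000.0]
        ic50, hill, top, bottom = 100.0, 1.0, 1.5, 1.0
        wells, effects = [], {}
        for i, d in enumerate(doses):
            cond = f"drug_{d:g}nM"
            wells.append(ms.WellSpec(f"B{i + 2:02d}", cond, "treatment", d))
            effects[cond] = ConditionEffect(
                s=float(ms.four_pl(d, top, bottom, ic50, hill)))
        layout = ms.PlateLayout(wells=tuple(wells), fields_per_well=1)
        sim = ms.simulate_plate(layout, effects, seed=1, n_cells_per_field=3)
        t = sim.truth_table
        for d in doses:
            s_val = t.loc[t["dose_nM"] == d, "s"].iloc[0]
            assert s_val == pytest.approx(
                bottom + (top - bottom) / (1 + d / ic50), rel=1e-12)

    def test_replicate_wells_share_s_but_differ_in_noise(self):
        layout = two_condition_layout(fields_per_well=1)
        sim = ms.simulate_plate(layout, {"basal": ConditionEffect(s=1.0),
                                         "oxldl": ConditionEffect(s=1.5)},
                                seed=9, n_cells_per_field=10)
        t = sim.truth_table.set_index("well_id")
        assert t.loc["B02", "s"] == t.loc["B03", "s"]
        assert not np.array_equal(sim.fields["B02"][0].mros_ch,
                                  sim.fields["B03"][0].mros_ch)

    def test_plate_reproducible_from_master_seed(self):
        layout = two_condition_layout(fields_per_well=1)
        effects = {"basal": ConditionEffect(s=1.0),
                   "oxldl": ConditionEffect(s=1.5)}
        a = ms.simulate_plate(layout, effects, seed=21, n_cells_per_field=6)
        b = ms.simulate_plate(layout, effects, seed=21, n_cells_per_field=6)
        for w in a.fields:
            np.testing.assert_array_equal(a.fields[w][0].mros_ch,
                                          b.fields[w][0].mros_ch)

    def test_effect_spec_must_match_layout(self):
        layout = two_condition_layout(fields_per_well=1)
        with pytest.raises(ValueError, match="not present"):
            ms.simulate_plate(layout, {"basal": ConditionEffect(),
                                       "oxldl": ConditionEffect(),
                                       "ghost": ConditionEffect()}, seed=0)
        with pytest.raises(ValueError, match="without an effect"):
            ms.simulate_plate(layout, {"basal": ConditionEffect()}, seed=0)

    def test_write_plate_round_trips(self, tmp_path):
        layout = two_condition_layout(fields_per_well=1)
        sim = ms.simulate_plate(layout, {"basal": ConditionEffect(s=1.0),
                                         "oxldl": ConditionEffect(s=1.5)},
                                seed=2, n_cells_per_field=4)
        out = ms.write_plate(sim, tmp_path / "plate")
        assert (out / "truth.csv").exists()
        loaded = ms.load_plate_images(out, ms.load_layout(out / "layout.yaml"))
        np.testing.assert_array_equal(loaded["C02"][0].mros_ch,
                                      sim.fields["C02"][0].mros_ch)
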