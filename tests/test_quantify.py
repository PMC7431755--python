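"""Feature extraction and QC-filter tests."""

import numpy as np
import pandas as pd
import pytest

from hccapa import SimulationConfig
from hccapa.quantify import (
    DamageThresholds,
    apply_qc,
    calibrate_damage_thresholds,
    extract_features,
    flag_damaged,
    transfection_gate,
)
from hccapa.segmentation import MaskSet, segment_field
from hccapa.synthgen import FieldImageSet, field_rng, render_field, sample_population


def _toy_field_and_masks(value=500.0, background=100.0, shape=(64, 64)):
    """One square cell of uniform intensity on a flat background."""
    img = np.full(shape, background)
    img[20:40, 20:40] = value
    nuclei = np.zeros(shape, dtype=np.int32)
    nuclei[27:33, 27:33] = 1
    cells = np.zeros(shape, dtype=np.int32)
    cells[20:40, 20:40] = 1
    organelle = np.zeros(shape, dtype=bool)
    organelle[22:30, 22:30] = True
    field = FieldImageSet(nuclear=img, gfp=img, reporter=img, pixel_size_um=0.65)
    masks = MaskSet(
        nuclei_labels=nuclei,
        cell_labels=cells,
        organelle_mask=organelle,
        dark_mask=np.zeros(shape, dtype=bool),
        background={k: (background, 3.0) for k in ("nuclear", "gfp", "reporter")},
    )
    return field, masks


class TestExtractFeatures:
    def test_uniform_intensity_minus_background(self):
        field, masks = _toy_field_and_masks(value=500.0, background=100.0)
        rec = extract_features(field, masks)
        assert rec.loc[0, "gfp_mean_body"] == pytest.approx(400.0)
        assert rec.loc[0, "rep_mean_organelle"] == pytest.approx(400.0)
        assert rec.loc[0, "nuc_area"] == 36
        assert rec.loc[0, "organelle_area"] == 64

    def test_empty_organelle_mask_gives_missing_intensities(self):
        field, masks = _toy_field_and_masks()
        masks.organelle_mask[:] = False
        rec = extract_features(field, masks)
        assert np.isnan(rec.loc[0, "gfp_mean_organelle"])
        assert rec.loc[0, "organelle_area"] == 0

    def test_organelle_gfp_proportional_to_expression(self, clean_field):
        cfg, cells, field = clean_field
        masks = segment_field(field)
        rec = extract_features(field, masks)
        # match segmented cells to ground truth by centroid
        ratios = []
        for c in cells:
            y, x = int(round(c.centroid_px[0])), int(round(c.centroid_px[1]))
            lab = masks.cell_labels[y, x]
            if lab > 0:
                row = rec[rec["cell_id"] == lab].iloc[0]
                ratios.append(row["gfp_mean_organelle"] / (cfg.gfp_gain * c.expression))
        assert len(ratios) >= 50
        assert np.median(ratios) == pytest.approx(1.0, abs=0.02)

    def test_offtarget_puncta_do_not_touch_organelle_reporter(self, sim_config):
        cfg0 = sim_config.replace(p_damaged=0.0, offtarget_amplitude=0.0)
        cfg1 = sim_config.replace(p_damaged=0.0, offtarget_amplitude=0.3)
        rng_cells = field_rng(88, "O", 1)
        cells = sample_population(cfg0, "stable", cfg0.cp50_true, rng_cells)
        f0 = render_field(cells, cfg0, field_rng(88, "O", 2), noise=False)
        f1 = render_field(cells, cfg1, field_rng(88, "O", 2), noise=False)
        masks = segment_field(f0)
        r0 = extract_features(f0, masks)
        r1 = extract_features(f1, masks)
        # identical organelle reporter means, larger body means with puncta on
        assert np.allclose(r0["rep_mean_organelle"], r1["rep_mean_organelle"], rtol=1e-9)
        assert (r1["rep_mean_body"] >= r0["rep_mean_body"] - 1e-9).all()
        assert r1["rep_mean_body"].sum() > r0["rep_mean_body"].sum()

    def test_background_subtraction_invariant_to_offset(self, sim_config):
        from hccapa.config import CameraModel

        cells = sample_population(sim_config.replace(p_damaged=0.0), "stable", 0.0, 5)
        means = []
        for offset in (100.0, 200.0):
            cfg = sim_config.replace(
                p_damaged=0.0, camera=CameraModel(read_noise_sd=3.0, poisson_scale=0.5,
                                                  offset=offset)
            )
            field = render_field(cells, cfg, field_rng(9, "B", 1))
            masks = segment_field(field)
            rec = extract_features(field, masks)
            means.append(rec["gfp_mean_organelle"].median())
        assert means[0] == pytest.approx(means[1], rel=0.02)


class TestDamageFilter:
    def test_recovers_generator_probability(self, stable_records):
        th = calibrate_damage_thresholds(stable_records)
        out = apply_qc(stable_records, th, stable_records["bg_sd"].median(), "stable")
        assert out["qc_damaged"].mean() == pytest.approx(0.15, abs=0.02)

    def test_near_zero_false_positives_without_damage(self, sim_config):
        from conftest import collect_records

        cfg = sim_config.replace(p_damaged=0.0)
        rec = collect_records(cfg, "stable", 8, 17)
        th = calibrate_damage_thresholds(rec)
        flags = flag_damaged(rec, th)
        assert flags.mean() <= 0.01

    def test_fragmentation_boundary(self):
        rec = pd.DataFrame(
            {
                "nuc_area": [300.0, 300.0],
                "nuc_mean_intensity": [1000.0, 1000.0],
                "organelle_n_components": [5.0, 50.0],
                "organelle_area": [500.0, 500.0],
            }
        )
        th = DamageThresholds(nuc_area_min=100, nuc_intensity_max=5000, fragmentation_max=0.05)
        flags = flag_damaged(rec, th)
        assert not flags[0] and flags[1]


class TestTransfectionGate:
    def test_recovers_mixture_removal_rate(self, transient_records):
        th = calibrate_damage_thresholds(transient_records)
        out = apply_qc(
            transient_records, th, transient_records["bg_sd"].median(), "transient"
        )
        assert out["qc_gated_out"].mean() == pytest.approx(0.80, abs=0.03)

    def test_gate_inert_on_stable_population(self, stable_records):
        removed = transfection_gate(stable_records, stable_records["bg_sd"].median())
        assert removed.mean() <= 0.05

    def test_over_expresser_record_gated(self):
        rec = pd.DataFrame(
            {"dark_fraction": [0.02, 0.6, 0.6], "gfp_mean_organelle": [5000.0, 5000.0, np.nan]}
        )
        gated = transfection_gate(rec, gfp_background_sd=3.0)
        assert gated.tolist() == [True, False, True]

    def test_selected_flag_algebra(self, transient_records):
        th = calibrate_damage_thresholds(transient_records)
        out = apply_qc(
            transient_records, th, transient_records["bg_sd"].median(), "transient"
        )
        assert (
            out["selected"] == (~out["qc_damaged"] & ~out["qc_gated_out"])
        ).all()


class TestOfftargetIndex:
    def test_monotone_in_amplitude_and_limits(self, sim_config):
        base = sim_config.replace(p_damaged=0.0)
        rng_cells = field_rng(77, "I", 1)
        cells = sample_population(base, "stable", base.cp50_true, rng_cells)
        medians = []
        for amp in (0.0, 0.1, 0.2, 0.3):
            cfg = base.replace(offtarget_amplitude=amp)
            field = render_field(cells, cfg, field_rng(77, "I", 2), noise=False)
            masks = segment_field(field)
            rec = extract_features(field, masks)
            medians.append(rec["offtarget_index"].median())
        assert medians[0] == pytest.approx(0.0, abs=0.05)
        assert all(a < b for a, b in zip(medians, medians[1:]))

    def test_full_occupancy_index_approaches_one(self, sim_config):
        cfg = sim_config.replace(p_damaged=0.0, offtarget_amplitude=0.3)
        rng_cells = field_rng(78, "I", 1)
        cells = sample_population(cfg, "stable", 0.0, rng_cells)
        blocked = [
            type(c)(c.cell_id, c.centroid_px, c.expression, 1.0, c.damaged,
                    c.expr_class, c.organelle_kind)
            for c in cells
        ]
        field = render_field(blocked, cfg, field_rng(78, "I", 2), noise=False)
        masks = segment_field(field)
        rec = extract_features(field, masks)
        assert rec["offtarget_index"].median() == pytest.approx(1.0, abs=0.05)
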