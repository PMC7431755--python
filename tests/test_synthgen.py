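"""Generator tests: occupancy model, population sampling, rendering, plates."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hccapa import PlateLayout, SimulationConfig
from hccapa.synthgen import (
    build_plate,
    cells_to_frame,
    field_rng,
    occupancy_response,
    offtarget_response,
    render_field,
    sample_population,
)


class TestOccupancyResponse:
    @pytest.mark.parametrize(
        "c, cp50, h, expected",
        [
            (7.3, 7.3, 1.0, 0.5),  # midpoint defines CP50
            (7.3, 7.3, 2.7, 0.5),  # midpoint independent of slope
            (0.0, 7.3, 1.0, 0.0),  # no transporter, no blocking
            (3 * 5.0, 5.0, 1.0, 0.75),  # c = 3·cp50, h = 1 → 3/(3+1)
        ],
    )
    def test_known_values(self, c, cp50, h, expected):
        assert occupancy_response(c, cp50, h) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("cp50, h", [(0.0, 1.0), (-1.0, 1.0), (7.3, 0.0), (7.3, -2.0)])
    def test_invalid_parameters(self, cp50, h):
        with pytest.raises(ValueError):
            occupancy_response(1.0, cp50, h)

    def test_negative_concentration(self):
        with pytest.raises(ValueError):
            occupancy_response(-1.0, 7.3, 1.0)

    @given(
        cp50=st.floats(0.1, 100),
        h=st.floats(0.2, 5),
        c1=st.floats(0, 500),
        c2=st.floats(0, 500),
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_monotone_and_bounded(self, cp50, h, c1, c2):
        lo, hi = sorted((c1, c2))
        t_lo, t_hi = occupancy_response(lo, cp50, h), occupancy_response(hi, cp50, h)
        assert 0.0 <= t_lo <= t_hi <= 1.0

    def test_offtarget_response_saturates(self):
        theta = np.linspace(0, 1, 11)
        out = offtarget_response(theta, 0.4)
        assert out[0] == 0.0
        assert np.all(np.diff(out) > 0)
        assert out[-1] == pytest.approx(1 / 1.4)


class TestSamplePopulation:
    def test_damaged_fraction_matches_probability(self):
        cfg = SimulationConfig(p_damaged=0.15)
        rng = np.random.default_rng(4)
        n, dam = 0, 0
        while n < 10_000:
            cells = sample_population(cfg, "stable", 0.0, rng)
            dam += sum(c.damaged for c in cells)
            n += len(cells)
        assert dam / n == pytest.approx(0.15, abs=0.01)

    def test_all_normal_when_probabilities_degenerate(self):
        cfg = SimulationConfig(p_damaged=0.0, transient_mix=(0.0, 1.0, 0.0))
        cells = sample_population(cfg, "transient", 0.0, 9)
        assert all(c.expr_class == "normal" and not c.damaged for c in cells)

    def test_transient_mixture_and_expression_classes(self):
        cfg = SimulationConfig(transient_mix=(0.2, 0.2, 0.6))
        rng = np.random.default_rng(5)
        cells = []
        for _ in range(50):
            cells += sample_population(cfg, "transient", 0.0, rng)
        classes = pd.Series([c.expr_class for c in cells]).value_counts(normalize=True)
        assert classes["over"] == pytest.approx(0.6, abs=0.03)
        assert classes["non"] == pytest.approx(0.2, abs=0.03)
        over = [c.expression for c in cells if c.expr_class == "over"]
        non = [c.expression for c in cells if c.expr_class == "non"]
        assert min(over) >= 10 * cfg.expression_median
        assert max(non) < 0.05 * cfg.expression_median

    def test_occupancy_equals_hill_response(self):
        cfg = SimulationConfig()
        cells = sample_population(cfg, "stable", cfg.cp50_true, 3)
        assert all(c.occupancy == pytest.approx(0.5) for c in cells)

    def test_determinism(self):
        cfg = SimulationConfig()
        a = sample_population(cfg, "transient", 3.0, 42)
        b = sample_population(cfg, "transient", 3.0, 42)
        assert a == b

    def test_damage_ramp_with_concentration(self):
        cfg = SimulationConfig(p_damaged=0.1, p_damaged_slope=0.04)
        rng = np.random.default_rng(8)
        frac = []
        for conc in (0.0, 10.0, 20.0):
            dam = n = 0
            for _ in range(30):
                cells = sample_population(cfg, "stable", conc, rng)
                dam += sum(c.damaged for c in cells)
                n += len(cells)
            frac.append(dam / n)
        assert frac[0] < frac[1] < frac[2]
        assert frac[2] == pytest.approx(0.9, abs=0.03)


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kw",
        [
            {"cp50_true": 0.0},
            {"hill_true": -1.0},
            {"p_damaged": 1.4},
            {"transient_mix": (0.5, 0.4, 0.3)},
            {"field_size_px": (100, 512)},
            {"offtarget_saturation": 0.0},
        ],
    )
    def test_invalid_config_rejected(self, kw):
        with pytest.raises(ValueError):
            SimulationConfig(**kw)


class TestRenderField:
    def test_specific_signal_exact_without_noise(self, clean_field):
        cfg, cells, field = clean_field
        offset = cfg.camera.offset
        texture = field.gfp.astype(float) > offset
        rep = field.reporter.astype(float) - offset
        # no off-target, occupancy 0: reporter outside the texture is exactly zero
        assert np.all(rep[~texture] == 0)
        # on each cell's texture the amplitude is reporter_gain·expression·(1−θ);
        # probe close to the centroid so neighbouring cells cannot intrude
        yy, xx = np.mgrid[: rep.shape[0], : rep.shape[1]]
        for cell in cells[:10]:
            cy, cx = cell.centroid_px
            near = (yy - cy) ** 2 + (xx - cx) ** 2 <= 18**2
            expected = cfg.reporter_gain * cell.expression
            assert rep[near].max() == pytest.approx(expected, rel=0.01)

    def test_full_occupancy_blanks_reporter_on_organelles(self, sim_config):
        cfg = sim_config.replace(p_damaged=0.0)
        rng = field_rng(7, "Q", 1)
        cells = sample_population(cfg, "stable", 0.0, rng)
        cells = [
            type(c)(c.cell_id, c.centroid_px, c.expression, 1.0, c.damaged,
                    c.expr_class, c.organelle_kind)
            for c in cells
        ]
        field = render_field(cells, cfg, field_rng(7, "Q", 2), noise=False)
        texture = field.gfp.astype(float) > cfg.camera.offset
        assert np.all(field.reporter.astype(float)[texture] == cfg.camera.offset)

    def test_centroid_outside_field_raises(self, sim_config):
        cells = sample_population(sim_config, "stable", 0.0, 1)
        bad = type(cells[0])(1, (-5.0, 10.0), 1.0, 0.0, False, "normal", "mitochondria")
        with pytest.raises(ValueError):
            render_field([bad], sim_config, 0)

    def test_overfull_field_raises(self):
        with pytest.raises(ValueError):
            cfg = SimulationConfig(field_size_px=(128, 128), n_cells_per_field=60)
            sample_population(cfg, "stable", 0.0, 0)


class TestBuildPlate:
    def test_plate_layout_bookkeeping_and_determinism(self, tmp_path):
        concs = (0.0, 0.5, 1.0, 2.0, 4.0, 8.0, 16.0, 32.0, 64.0)
        layout = PlateLayout.dose_ladder(concs, n_replicates=3, n_fields=1)
        non_control = [w for w in layout.wells if w.concentration_um > 0]
        assert len(non_control) == 24
        assert len(layout.control_wells) == 3

        cfg = SimulationConfig(field_size_px=(256, 256), n_cells_per_field=8)
        small = PlateLayout.dose_ladder((0.0, 5.0), n_replicates=2)
        build_plate(small, cfg, "stable", 77, tmp_path / "p1")
        build_plate(small, cfg, "stable", 77, tmp_path / "p2")
        t1 = (tmp_path / "p1" / "ground_truth.csv").read_bytes()
        t2 = (tmp_path / "p2" / "ground_truth.csv").read_bytes()
        assert t1 == t2
        tifs = sorted(p.name for p in (tmp_path / "p1").glob("*.tif"))
        assert len(tifs) == 4  # 2 concentrations × 2 replicates, one field each

        truth = pd.read_csv(tmp_path / "p1" / "ground_truth.csv")
        controls = truth[truth["well"].isin(small.control_wells)]
        assert (controls["occupancy"] == 0).all()

    def test_ground_truth_schema(self, sim_config):
        cells = sample_population(sim_config, "stable", 2.0, 1)
        df = cells_to_frame(cells, "A01", 1)
        assert list(df.columns) == [
            "cell_id", "well", "field", "x_px", "y_px",
            "expression", "occupancy", "damaged", "expr_class",
        ]

    def test_field_rng_streams_independent(self):
        a = field_rng(1, "A01", 1).integers(0, 2**31, 4)
        b = field_rng(1, "A01", 2).integers(0, 2**31, 4)
        c = field_rng(1, "A02", 1).integers(0, 2**31, 4)
        d = field_rng(1, "A01", 1).integers(0, 2**31, 4)
        assert not np.array_equal(a, b) and not np.array_equal(a, c)
        assert np.array_equal(a, d)
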