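"""Germ-grain simulator and virtual sectioning: distributional oracles and
geometric contracts."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from stereosyn.tissue import (
    DistributionSpec,
    LayerSpec,
    SectionPlan,
    SynapticObject,
    TissueModel,
    compact_tissue_model,
    cut_sections,
    disk_chord,
    disk_mean_diameter_for_trace,
    default_tissue_model,
    simulate_block,
)


def _uniform_model(density_asym=5.5, density_sym=0.5, density_axon=0.0,
                   dims=(10.0, 10.0, 10.0), pad=0.0, disk=None):
    return TissueModel(
        layers=(LayerSpec("III", 1.0, density_asym, density_sym, density_axon),),
        block_dims=dims,
        disk_diameter_dist=disk or DistributionSpec("lognormal", 253.4, 0.2),
        terminal_size_dist=DistributionSpec("lognormal", 622.5, 0.35),
        axon_diameter_dist=DistributionSpec("lognormal", 800.0, 0.2),
        edge_padding_um=pad,
    )


class TestSimulateBlock:
    def test_zero_density_yields_no_objects(self):
        pop = simulate_block(_uniform_model(0.0, 0.0, 0.0), seed=1)
        assert len(pop) == 0

    def test_counts_follow_poisson_intensity(self):
        # density 5.5 on a 1000 um^3 block: counts should sit in the Poisson
        # 99% interval around 5500 for essentially all seeds
        model = _uniform_model(5.5, 0.0, 0.0, dims=(10.0, 10.0, 10.0), pad=0.0)
        lo, hi = sps.poisson.ppf([0.005, 0.995], 5500.0)
        counts = []
        for seed in range(100):
            pop = simulate_block(model, seed=seed)
            counts.append(len(pop))
        outside = sum(not (lo <= c <= hi) for c in counts)
        assert outside <= 5
        assert abs(np.mean(counts) - 5500) < 4 * math.sqrt(5500 / 100)

    def test_same_seed_is_bit_identical(self):
        model = compact_tissue_model()
        a = simulate_block(model, seed=42)
        b = simulate_block(model, seed=42)
        np.testing.assert_array_equal(a.centers, b.centers)
        np.testing.assert_array_equal(a.diameters_nm, b.diameters_nm)
        np.testing.assert_array_equal(a.normals, b.normals)
        np.testing.assert_array_equal(a.type_codes, b.type_codes)

    def test_sequence_protocol_exposes_typed_objects(self):
        pop = simulate_block(compact_tissue_model(), seed=0)
        obj = pop[0]
        assert obj.type in ("asymmetric", "symmetric", "axon")
        assert abs(np.linalg.norm(obj.normal) - 1.0) < 1e-9
        assert obj.diameter > 0

    @pytest.mark.parametrize(
        "bad",
        [
            dict(dims=(0.0, 10.0, 10.0)),
            dict(density_asym=-1.0),
        ],
    )
    def test_invalid_configuration_rejected(self, bad):
        with pytest.raises(ValueError):
            _uniform_model(**bad)

    def test_layer_fractions_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            TissueModel(
                layers=(
                    LayerSpec("I", 0.5, 1.0, 0.0, 0.0),
                    LayerSpec("II", 0.4, 1.0, 0.0, 0.0),
                ),
                block_dims=(5.0, 5.0, 5.0),
                disk_diameter_dist=DistributionSpec(),
                terminal_size_dist=DistributionSpec(),
                axon_diameter_dist=DistributionSpec(),
            )


class TestCutSections:
    def test_disk_between_sections_yields_no_profile(self):
        # edge-on disk (caliper = D = 0.2 um) centred at z = 0.5, midway
        # between the mid-planes of sections 0 (z=0.03) and 10 (z=0.63)
        obj = SynapticObject(
            center=(2.0, 2.0, 0.5), diameter=200.0, normal=(1.0, 0.0, 0.0),
            type="asymmetric", terminal_extent=500.0,
        )
        model = _uniform_model(dims=(4.0, 4.0, 1.0))
        out = cut_sections([obj], SectionPlan(indices=(0, 10)), seed=0, model=model)
        assert all(len(df) == 0 for _, df in out)

    def test_empty_population_gives_empty_tables(self):
        pop = simulate_block(_uniform_model(0.0, 0.0, 0.0), seed=0)
        out = cut_sections(pop, SectionPlan(indices=(0, 5)), seed=0)
        assert [len(df) for _, df in out] == [0, 0]

    def test_mean_chord_is_quarter_pi_diameter(self):
        # disk of fixed diameter cut by a uniformly random plane: mean chord
        # length = pi*D/4 (closed form), checked by Monte Carlo
        D = 500.0  # nm
        model = _uniform_model(
            density_asym=120.0, density_sym=0.0, dims=(20.0, 20.0, 1.0), pad=0.5,
            disk=DistributionSpec("constant", D, 0.0),
        )
        pop = simulate_block(model, seed=7)
        chords = []
        for _, df in cut_sections(pop, SectionPlan(indices=(4, 8, 12)), seed=8):
            chords.append(df.loc[df["type"] == "asymmetric", "junction_length_nm"])
        chords = pd.concat(chords)
        assert len(chords) > 3e4
        assert abs(chords.mean() - math.pi * D / 4) / (math.pi * D / 4) < 0.01

    def test_configured_junction_trace_mean(self):
        # stock calibration targets a pooled junction trace mean of 207 nm
        model = compact_tissue_model(density_asym=30.0, density_sym=0.0,
                                     density_axon=0.0, block_dims=(30.0, 10.0, 2.1))
        pooled = []
        for seed in range(4):
            pop = simulate_block(model, seed=seed)
            for _, df in cut_sections(pop, SectionPlan(indices=(5, 15, 25)), seed=seed):
                pooled.append(df["junction_length_nm"])
        pooled = pd.concat(pooled)
        assert len(pooled) > 1e4
        assert abs(pooled.mean() - 207.0) / 207.0 < 0.02

    def test_no_object_yields_two_profiles_in_one_section(self):
        pop = simulate_block(compact_tissue_model(), seed=3)
        for _, df in cut_sections(pop, SectionPlan(indices=(0, 10, 20)), seed=3):
            assert df["object_id"].is_unique
            assert df["object_id"].isin(range(len(pop))).all()

    def test_profile_intensity_matches_caliper_relation(self):
        # Delesse/DeHoff: E[profiles per area] = N_V * E[caliper height];
        # for isotropic disks E[caliper] = (pi/4) E[D]
        model = _uniform_model(density_asym=20.0, density_sym=0.0,
                               dims=(25.0, 25.0, 2.0), pad=1.0)
        n_a = []
        area = 25.0 * 25.0
        for seed in range(6):
            pop = simulate_block(model, seed=100 + seed)
            for _, df in cut_sections(pop, SectionPlan(indices=(8, 16, 24)), seed=seed):
                inside = df[(df.x_um.between(0, 25)) & (df.y_um.between(0, 25))]
                n_a.append(len(inside) / area)
        expected = 20.0 * (math.pi / 4) * model.disk_diameter_dist.mean / 1000.0
        assert abs(np.mean(n_a) - expected) / expected < 0.03

    def test_slab_mode_catches_grazing_disks(self):
        # mid-plane misses the disk but the slab overlaps it: only the
        # any-overlap sectioning model emits a profile
        z_mid = 0.03
        R_um = 0.1
        obj = SynapticObject(
            center=(2.0, 2.0, z_mid + R_um + 0.001), diameter=2 * R_um * 1000,
            normal=(1.0, 0.0, 0.0), type="asymmetric", terminal_extent=500.0,
        )
        model = _uniform_model(dims=(4.0, 4.0, 1.0))
        midplane = cut_sections([obj], SectionPlan(indices=(0,)), seed=0, model=model)
        slab = cut_sections(
            [obj], SectionPlan(indices=(0,), section_model="slab"), seed=0, model=model
        )
        assert len(midplane[0][1]) == 0
        assert len(slab[0][1]) == 1

    def test_sectioning_is_deterministic(self):
        pop = simulate_block(compact_tissue_model(), seed=5)
        a = cut_sections(pop, SectionPlan(indices=(0, 5, 10)), seed=9)
        b = cut_sections(pop, SectionPlan(indices=(0, 5, 10)), seed=9)
        for (_, da), (_, db) in zip(a, b):
            pd.testing.assert_frame_equal(da, db)


class TestGeometryHelpers:
    @given(
        d=st.floats(10.0, 2000.0),
        frac=st.floats(0.0, 2.0),
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_disk_chord_bounds(self, d, frac):
        offset = frac * d / 2
        c = disk_chord(d, offset)
        assert 0.0 <= c <= d
        assert c == disk_chord(d, -offset)
        if frac >= 1.0:
            assert c == 0.0

    def test_diameter_calibration_inverts_trace_mean(self):
        mu = disk_mean_diameter_for_trace(207.0, 0.2)
        assert abs((math.pi / 4) * mu * (1 + 0.2**2) - 207.0) < 1e-9

    def test_default_model_mean_densities(self):
        m = default_tissue_model()
        assert abs(m.mean_density("asym") - 5.5) < 1e-9
        assert abs(m.mean_density("sym") - 0.5) < 1e-9
        assert abs(m.mean_density("axon") - 0.47) < 1e-9
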