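"""SUR section selection, frame placement, and the unbiased counting frame."""

import numpy as np
import pandas as pd
import pytest

from conftest import profile_table, segment_row
from stereosyn.sampling import (
    CountingFrame,
    SamplingPlan,
    count_in_frame,
    place_frames,
    select_sections,
)
from stereosyn.tissue import SectionPlan, compact_tissue_model, cut_sections, simulate_block


class TestSelectSections:
    def test_arithmetic_progression_with_random_start(self):
        plan = SamplingPlan(ultrathin_period=5, sections_per_animal=10)
        idx = select_sections(60, plan, seed=3)
        diffs = np.diff(idx)
        assert len(idx) == 10
        assert (diffs == 5).all()
        assert 0 <= idx[0] < 5

    def test_start_is_uniform_over_period(self):
        plan = SamplingPlan(ultrathin_period=5, sections_per_animal=4)
        rng = np.random.default_rng(0)
        starts = [select_sections(30, plan, rng)[0] for _ in range(10_000)]
        counts = np.bincount(starts, minlength=5)
        # binomial(10^4, 1/5): 3 sigma band
        sigma = np.sqrt(10_000 * 0.2 * 0.8)
        assert (np.abs(counts - 2000) <= 3 * sigma).all()

    def test_series_too_short_names_requirement(self):
        plan = SamplingPlan(ultrathin_period=5, sections_per_animal=10)
        with pytest.raises(ValueError, match="at least 50"):
            select_sections(40, plan)

    def test_default_plan_selects_ten_sections(self):
        idx = select_sections(53, SamplingPlan(), seed=1)
        assert len(idx) == 10


class TestPlaceFrames:
    def test_exact_fit_tiles_with_zero_phase(self):
        plan = SamplingPlan(frame_side_um=2.0, fields_per_layer_per_section=5)
        frames = place_frames(10.0, (0.0, 2.0), plan, seed=0)
        xs = [f.origin[0] for f in frames]
        assert xs == [0.0, 2.0, 4.0, 6.0, 8.0]

    def test_frames_disjoint_and_inside_band(self):
        plan = SamplingPlan(frame_side_um=3.87, fields_per_layer_per_section=7)
        frames = place_frames(42.0, (10.0, 16.0), plan, seed=5)
        assert len(frames) == 7
        for f in frames:
            x0, y0, x1, y1 = f.bounds
            assert 0 <= x0 and x1 <= 42.0
            assert 10.0 <= y0 and y1 <= 16.0
        for a, b in zip(frames, frames[1:]):
            assert a.bounds[2] <= b.bounds[0] + 1e-12  # no overlap along the line

    def test_union_of_frame_areas_within_band_area(self):
        plan = SamplingPlan(frame_side_um=3.87, fields_per_layer_per_section=8)
        frames = place_frames(42.0, (0.0, 4.5), plan, seed=2)
        assert sum(f.area for f in frames) <= 42.0 * 4.5

    def test_narrow_band_raises(self):
        plan = SamplingPlan(frame_side_um=3.87)
        with pytest.raises(ValueError, match="cannot hold"):
            place_frames(42.0, (0.0, 2.0), plan, seed=0)

    def test_too_many_frames_suggests_fewer(self):
        plan = SamplingPlan(frame_side_um=3.87, fields_per_layer_per_section=10)
        with pytest.raises(ValueError, match="fewer frames"):
            place_frames(20.0, (0.0, 4.5), plan, seed=0)


class TestCountingFrameRule:
    FRAME = CountingFrame(origin=(0.0, 0.0), width=3.87, height=3.87)

    def test_empty_input_zero_counts(self):
        s = count_in_frame(profile_table([]).reindex(columns=[]), self.FRAME)
        assert (s.n_asym, s.n_sym, s.n_axon, s.excluded_count) == (0, 0, 0, 0)

    def test_exclusion_vs_inclusion_edge(self):
        # same trace crossing the left (exclusion) edge is rejected; shifted
        # to cross only the right (inclusion) edge it is counted
        left = segment_row(-0.1, 1.0, 0.1, 1.0)
        right = segment_row(3.8, 1.0, 4.0, 1.0)
        s = count_in_frame(profile_table([left, right]), self.FRAME)
        assert s.n_asym == 1
        assert s.excluded_count == 1
        assert s.counted.iloc[0]["x1_um"] == 3.8

    def test_bottom_edge_excludes_and_top_includes(self):
        bottom = segment_row(1.0, -0.05, 1.0, 0.05)
        top = segment_row(1.0, 3.8, 1.0, 3.95)
        s = count_in_frame(profile_table([bottom, top]), self.FRAME)
        assert s.n_asym == 1
        assert s.excluded_count == 1

    def test_corner_tie_follows_exclusion(self):
        # trace ending exactly on the bottom-right corner touches the bottom
        # exclusion edge: exclusion wins the tie
        corner = segment_row(3.87, 0.0, 4.2, 0.3)
        s = count_in_frame(profile_table([corner]), self.FRAME)
        assert s.n_asym == 0
        assert s.excluded_count == 1

    def test_interior_trace_counted(self):
        s = count_in_frame(profile_table([segment_row(1.0, 1.0, 1.2, 1.1)]), self.FRAME)
        assert s.n_asym == 1 and s.excluded_count == 0

    def test_axon_circle_against_edges(self):
        rows = [
            dict(segment_row(1.0, 1.0, 1.0, 1.0, type_="axon"), radius_um=0.4),
            dict(segment_row(-0.1, 2.0, -0.1, 2.0, type_="axon"), radius_um=0.4),
            dict(segment_row(3.9, 2.0, 3.9, 2.0, type_="axon"), radius_um=0.4),
        ]
        for r in rows:
            r["x_um"], r["y_um"] = r["x1_um"], r["y1_um"]
        s = count_in_frame(profile_table(rows), self.FRAME)
        # interior circle and right-edge circle counted; left-edge circle excluded
        assert s.n_axon == 2
        assert s.excluded_count == 1

    def test_unbiased_for_uniform_point_profiles(self):
        # zero-length traces uniform on a window: E[count] = N_A * frame area
        rng = np.random.default_rng(4)
        n, window = 40_000, 40.0
        pts = rng.uniform(0, window, size=(n, 2))
        df = pd.DataFrame(
            {
                "object_id": np.arange(n),
                "type": "asymmetric",
                "layer": "III",
                "x_um": pts[:, 0],
                "y_um": pts[:, 1],
                "x1_um": pts[:, 0],
                "y1_um": pts[:, 1],
                "x2_um": pts[:, 0],
                "y2_um": pts[:, 1],
                "junction_length_nm": 200.0,
                "terminal_membrane_length_nm": 400.0,
                "radius_um": 0.0,
                "perforated": False,
            }
        )
        frame = CountingFrame(origin=(0.0, 0.0))
        counts = []
        for _ in range(400):
            ox, oy = rng.uniform(1, window - 5, 2)
            s = count_in_frame(df, CountingFrame(origin=(ox, oy)))
            counts.append(s.n_asym)
        n_a_true = n / window**2
        expected = n_a_true * frame.area
        se = np.std(counts) / np.sqrt(len(counts))
        assert abs(np.mean(counts) - expected) <= 2.5 * se

    def test_no_double_counting_across_tiling(self):
        # a shared vertical edge is inclusion for the left tile and exclusion
        # for the right tile: every trace is counted at most once
        rng = np.random.default_rng(9)
        n = 2000
        x = rng.uniform(0, 12, n)
        y = rng.uniform(0, 4, n)
        ang = rng.uniform(0, np.pi, n)
        half = 0.15
        df = pd.DataFrame(
            {
                "object_id": np.arange(n),
                "type": "asymmetric",
                "layer": "III",
                "x_um": x,
                "y_um": y,
                "x1_um": x - half * np.cos(ang),
                "y1_um": y - half * np.sin(ang),
                "x2_um": x + half * np.cos(ang),
                "y2_um": y + half * np.sin(ang),
                "junction_length_nm": 300.0,
                "terminal_membrane_length_nm": 600.0,
                "radius_um": 0.0,
                "perforated": False,
            }
        )
        seen = []
        for i in range(3):
            s = count_in_frame(df, CountingFrame(origin=(2.0 + 2.0 * i, 1.0),
                                                 width=2.0, height=2.0))
            seen.extend(s.counted["object_id"].tolist())
        assert len(seen) == len(set(seen))


class TestFrameEstimatorProperties:
    def _section(self):
        model = compact_tissue_model(block_dims=(30.0, 20.0, 0.5))
        pop = simulate_block(model, seed=21)
        (_, df), = cut_sections(pop, SectionPlan(indices=(3,)), seed=21)
        return df

    def test_frame_estimate_matches_exhaustive_density(self):
        # N_A from many frames vs brute-force enumeration over the window;
        # the realized window count is itself Poisson-noisy, so compare at
        # the combined standard error of the two estimators
        df = self._section()
        window = (2.0, 28.0, 2.0, 18.0)
        window_area = (window[1] - window[0]) * (window[3] - window[2])
        inside = df[
            df.x_um.between(window[0], window[1]) & df.y_um.between(window[2], window[3])
        ]
        syn = inside[inside["type"] != "axon"]
        n_a_true = len(syn) / window_area
        rng = np.random.default_rng(2)
        counts = []
        frame_area = CountingFrame(origin=(0, 0)).area
        for _ in range(300):
            ox = rng.uniform(window[0], window[1] - 3.87)
            oy = rng.uniform(window[2], window[3] - 3.87)
            s = count_in_frame(df, CountingFrame(origin=(ox, oy)))
            counts.append(s.n_asym + s.n_sym)
        est = np.mean(counts) / frame_area
        se_frames = np.std(counts) / np.sqrt(len(counts)) / frame_area
        se_truth = np.sqrt(len(syn)) / window_area
        assert abs(est - n_a_true) <= 2.5 * np.hypot(se_frames, se_truth)

    def test_frame_size_invariance(self):
        # halving the frame side and quadrupling the frame count leaves the
        # N_A estimate unchanged within sampling error
        df = self._section()
        rng = np.random.default_rng(8)

        def estimate(side, n_frames):
            tot, area = 0, 0.0
            for _ in range(n_frames):
                ox = rng.uniform(2.0, 28.0 - side)
                oy = rng.uniform(2.0, 18.0 - side)
                s = count_in_frame(df, CountingFrame(origin=(ox, oy),
                                                     width=side, height=side))
                tot += s.n_asym + s.n_sym
                area += side * side
            return tot / area

        big = estimate(3.87, 150)
        small = estimate(3.87 / 2, 600)
        assert abs(big - small) / big < 0.12
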