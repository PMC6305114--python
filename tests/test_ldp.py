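import math

import numpy as np
import pandas as pd
import pytest

import lesionvario as lv
from lesionvario.ldp import build_paths, delta_table, descriptor_frame
from lesionvario.mask_io import SubjectRecord
from lesionvario.variography import VariogramFit


def _fit(direction, a, c, r2=0.99, converged=True):
    return VariogramFit(direction, a, c, r2, 16, converged)


def _desc(subject, tp, A, C, tlv=1.0):
    return lv.PatternDescriptor(
        subject_id=subject, timepoint=tp, A=A, C=C, tlv_cm3=tlv,
        a_mm={d: math.exp(A) for d in "xyz"},
        c={d: math.exp(C) for d in "xyz"},
        r2={d: 0.99 for d in "xyz"},
    )


class TestLdpCoordinates:
    def test_closed_form(self):
        A, C = lv.ldp_coordinates(
            _fit("x", math.e**2, math.e**-7),
            _fit("y", math.e**2, math.e**-7),
            _fit("z", math.e**2, math.e**-7),
        )
        assert A == pytest.approx(2.0)
        assert C == pytest.approx(-7.0)

    def test_sill_scaling_shifts_C_by_log_k(self):
        rng = np.random.default_rng(1)
        a = rng.uniform(2, 30, 3)
        c = rng.uniform(1e-4, 0.3, 3)
        k = 3.7
        A1, C1 = lv.ldp_coordinates(*[_fit(d, ai, ci) for d, ai, ci in zip("xyz", a, c)])
        A2, C2 = lv.ldp_coordinates(
            *[_fit(d, ai, k * ci) for d, ai, ci in zip("xyz", a, c)]
        )
        assert A2 == pytest.approx(A1)
        assert C2 - C1 == pytest.approx(math.log(k))

    def test_matches_direct_formula(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            a = rng.uniform(0.5, 50, 3)
            c = rng.uniform(1e-5, 0.5, 3)
            A, C = lv.ldp_coordinates(
                *[_fit(d, ai, ci) for d, ai, ci in zip("xyz", a, c)]
            )
            assert A == pytest.approx(np.mean(np.log(a)))
            assert C == pytest.approx(np.mean(np.log(c)))

    def test_non_converged_fit_rejected(self):
        good = _fit("x", 10, 0.01)
        bad = _fit("y", 10, 0.01, converged=False)
        with pytest.raises(ValueError, match="converge"):
            lv.ldp_coordinates(good, bad, _fit("z", 10, 0.01))

    def test_monotone_in_each_parameter(self):
        base = [_fit(d, 10.0, 0.01) for d in "xyz"]
        A0, C0 = lv.ldp_coordinates(*base)
        bigger = [_fit("x", 12.0, 0.01)] + base[1:]
        A1, C1 = lv.ldp_coordinates(*bigger)
        assert A1 > A0 and C1 == pytest.approx(C0)


class TestDescribePattern:
    def test_smooth_archetype_has_higher_A_than_complex(self):
        """One extended blob vs many small blobs of equal total volume."""
        smooth = lv.generate_pattern(
            lv.PatternSpec(n_blobs=1, radius_mean=8.0, radius_sd=0.0,
                           anisotropy=(1.0, 1.0), seed=5, margin_mm=20.0)
        )
        complex_ = lv.generate_pattern(
            lv.PatternSpec(n_blobs=67, radius_mean=2.0, radius_sd=0.0,
                           anisotropy=(1.0, 1.0), seed=5)
        )
        # archetypes matched in volume within ~20%
        assert lv.total_lesion_volume(smooth) == pytest.approx(
            lv.total_lesion_volume(complex_), rel=0.2
        )
        d_smooth = lv.describe_pattern(smooth)
        d_complex = lv.describe_pattern(complex_)
        assert d_smooth.A > d_complex.A

    def test_empty_mask_rejected_with_context(self):
        mask = lv.LesionMask(
            grid=np.zeros((16, 16, 16)), spacing=(1, 1, 1), subject_id="p9"
        )
        with pytest.raises(ValueError, match="p9"):
            lv.describe_pattern(mask)

    def test_deterministic(self, single_ball_mask):
        d1 = lv.describe_pattern(single_ball_mask)
        d2 = lv.describe_pattern(single_ball_mask)
        assert d1 == d2

    def test_transformer_frame_layout(self, single_ball_mask):
        frame = lv.PatternDescriptorExtractor().fit().transform([single_ball_mask])
        expected = {
            "subject_id", "timepoint", "A", "C", "tlv_cm3",
            "a_x", "a_y", "a_z", "c_x", "c_y", "c_z",
            "r2_x", "r2_y", "r2_z", "flagged",
        }
        assert set(frame.columns) == expected
        assert len(frame) == 1

    def test_transformer_params_roundtrip(self):
        ex = lv.PatternDescriptorExtractor(max_lag=20.0, lag_step=2.0)
        assert ex.get_params() == {"max_lag": 20.0, "lag_step": 2.0}
        ex.set_params(max_lag=30.0)
        assert ex.fit().config_.max_lag == 30.0


class TestEvolutionVectors:
    def test_printed_subgroup_deltas(self):
        """Published subgroup A trajectories: M2 1.80->0.94, F1 1.05->1.05."""
        m2 = lv.evolution_vector(_desc("M2", 1, 1.80, -4.0), _desc("M2", 4, 0.94, -4.0))
        assert m2[0] == pytest.approx(-0.86)
        f1 = lv.evolution_vector(_desc("F1", 1, 1.05, -4.0), _desc("F1", 4, 1.05, -4.0))
        assert f1[0] == pytest.approx(0.0)

    def test_printed_patient_vector(self):
        """Worked example: (1.06, -6.94) -> (1.40, -5.87) gives (0.34, 1.07)."""
        dA, dC, mag = lv.evolution_vector(
            _desc("p1", 1, 1.06, -6.94), _desc("p1", 4, 1.40, -5.87)
        )
        assert dA == pytest.approx(0.34)
        assert dC == pytest.approx(1.07)
        assert mag == pytest.approx(math.hypot(0.34, 1.07))

    def test_subject_mismatch_rejected(self):
        with pytest.raises(ValueError, match="different subjects"):
            lv.evolution_vector(_desc("a", 1, 1, -4), _desc("b", 2, 1, -4))

    def test_non_increasing_timepoints_rejected(self):
        with pytest.raises(ValueError, match="increase"):
            lv.evolution_vector(_desc("a", 3, 1, -4), _desc("a", 2, 1, -4))

    def test_steps_telescope_to_total(self):
        descs = [_desc("s", t, 1.0 + 0.3 * t, -4.0 - 0.1 * t) for t in (1, 2, 3, 4)]
        path = lv.EvolutionPath.from_descriptors(descs)
        total = path.total_vector()
        assert sum(s[0] for s in path.steps) == pytest.approx(total[0])
        assert sum(s[1] for s in path.steps) == pytest.approx(total[1])


class TestSubgroupVectorsAndDeltas:
    def test_singleton_subgroup_equals_subject_vector(self):
        path = lv.EvolutionPath.from_descriptors(
            [_desc("s1", 1, 2.0, -5.0), _desc("s1", 4, 1.5, -6.0)]
        )
        table = lv.subgroup_total_vector({"s1": path}, {"s1": "G"})
        row = table.iloc[0]
        assert row["dA"] == pytest.approx(-0.5)
        assert row["dC"] == pytest.approx(-1.0)

    def test_componentwise_median_arithmetic(self):
        paths = {
            f"s{i}": lv.EvolutionPath.from_descriptors(
                [_desc(f"s{i}", 1, a1, -4.0), _desc(f"s{i}", 4, a4, -4.0)]
            )
            for i, (a1, a4) in enumerate([(1, 2), (2, 3), (3, 4)])
        }
        table = lv.subgroup_total_vector(paths, {s: "G" for s in paths})
        row = table.iloc[0]
        assert row["dA"] == pytest.approx(1.0)
        assert row["dC"] == pytest.approx(0.0)

    def test_empty_subgroup_rejected(self):
        with pytest.raises(ValueError, match="no labelled"):
            lv.subgroup_total_vector({}, {})

    def test_dynamic_subgroups_outpace_static(self, cohort_descriptors):
        """Shrinking subgroups trace longer LDP vectors than static ones."""
        frame, _, labels = cohort_descriptors
        from lesionvario.pipeline import _rows_to_descriptors

        paths = build_paths(_rows_to_descriptors(frame))
        table = lv.subgroup_total_vector(paths, labels).set_index("subgroup")
        assert table.loc["F2", "magnitude"] > table.loc["F1", "magnitude"]
        assert table.loc["M2", "magnitude"] > table.loc["M1", "magnitude"]
        # the dynamic subgroups' total vectors face bottom-left
        assert table.loc["F2", "dA"] < 0 and table.loc["F2", "dC"] < 0
        assert table.loc["M2", "dA"] < 0 and table.loc["M2", "dC"] < 0

    def test_delta_table_arithmetic_and_signs(self, cohort_descriptors):
        frame, records, labels = cohort_descriptors
        from lesionvario.pipeline import _rows_to_descriptors

        paths = build_paths(_rows_to_descriptors(frame))
        table = lv.delta_table(paths, labels, records).set_index("subgroup")
        for g in table.index:
            assert table.loc[g, "dA"] == pytest.approx(
                table.loc[g, "A_last"] - table.loc[g, "A_first"]
            )
        # shrinking subgroups pair negative dA with negative dEDSS
        assert table.loc["M2", "dA"] < 0 and table.loc["M2", "dEDSS"] < 0
        assert table.loc["F2", "dA"] < 0 and table.loc["F2", "dEDSS"] < 0

    def test_delta_table_excludes_subject_missing_edss(self):
        paths = {
            "s1": lv.EvolutionPath.from_descriptors(
                [_desc("s1", 1, 1, -4), _desc("s1", 4, 2, -4)]
            ),
            "s2": lv.EvolutionPath.from_descriptors(
                [_desc("s2", 1, 1, -4), _desc("s2", 4, 2, -4)]
            ),
        }
        records = [
            SubjectRecord("s1", "F", 1, 1.0, "CIS", 0),
            SubjectRecord("s1", "F", 4, 1.5, "CIS", 1100),
            SubjectRecord("s2", "F", 1, 1.0, "CIS", 0),  # missing timepoint 4
        ]
        table = lv.delta_table(paths, {"s1": "G", "s2": "G"}, records)
        assert table.iloc[0]["n"] == 1

    def test_single_subject_constant_values_zero_deltas(self):
        paths = {
            "s1": lv.EvolutionPath.from_descriptors(
                [_desc("s1", 1, 1.2, -4), _desc("s1", 4, 1.2, -4)]
            )
        }
        records = [
            SubjectRecord("s1", "F", 1, 2.0, "CIS", 0),
            SubjectRecord("s1", "F", 4, 2.0, "CIS", 1100),
        ]
        table = lv.delta_table(paths, {"s1": "G"}, records)
        assert table.iloc[0]["dA"] == 0.0
        assert table.iloc[0]["dEDSS"] == 0.0
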