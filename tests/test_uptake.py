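"""RDU computation, reporter selection, difference profiles, region merging."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hdx_allomap.uptake import (
    SignificantPeptide,
    compute_rdu,
    difference_profile,
    exchangeable_amides,
    merge_regions,
    read_uptake_csv,
    reporter_regions,
    write_uptake_csv,
)


def table(rows):
    """rows: (peptide_id, start, end, sequence, state, t, uptake)"""
    return pd.DataFrame(
        [("prot", *r, 0.05) for r in rows],
        columns=["protein", "peptide_id", "start", "end", "sequence",
                 "state", "exposure_min", "uptake_da", "sd_da"],
    )


class TestExchangeableAmides:
    @pytest.mark.parametrize("seq,n_fast,expected", [
        ("GGGGG", 1, 4),   # N-terminal amide excluded
        ("GPGPG", 1, 2),   # prolines after position 1 carry no amide
        ("P", 1, 0),       # floored at zero
        ("PGGG", 1, 3),    # N-terminal proline is inside the exempted window
        ("GGGGG", 2, 3),   # two-residue back-exchange convention
    ])
    def test_counting_convention(self, seq, n_fast, expected):
        assert exchangeable_amides(seq, n_fast) == expected

    def test_invalid_residue_names_position(self):
        with pytest.raises(ValueError, match="position 3"):
            exchangeable_amides("GGXGG")


class TestComputeRdu:
    def test_ratio_of_deuterons_to_amides(self):
        df = table([("p1", 1, 6, "GGGGGG", "apo", 10.0, 3.35)])
        rdu = compute_rdu(df)
        assert rdu["rdu"].iloc[0] == pytest.approx(0.67)

    def test_zero_uptake(self):
        df = table([("p1", 1, 6, "GGGGGG", "apo", 10.0, 0.0)])
        assert compute_rdu(df)["rdu"].iloc[0] == 0.0

    def test_overrange_rdu_rejected(self):
        df = table([("p1", 1, 5, "GGGGG", "apo", 10.0, 5.0)])  # 4 amides
        with pytest.raises(ValueError, match="RDU"):
            compute_rdu(df, tolerance=0.1)

    def test_zero_amide_peptides_excluded_with_warning(self, caplog):
        df = table([("p1", 1, 2, "GP", "apo", 10.0, 0.0),
                    ("p2", 3, 8, "GGGGGG", "apo", 10.0, 2.0)])
        with caplog.at_level("WARNING"):
            rdu = compute_rdu(df)
        assert set(rdu["peptide_id"]) == {"p2"}
        assert "p1" in caplog.text

    def test_scale_consistency(self):
        df = table([("p1", 1, 11, "G" * 11, "apo", t, u)
                    for t, u in [(0.5, 1.0), (10.0, 4.0)]])
        doubled = df.assign(uptake_da=df["uptake_da"] * 2)
        assert np.allclose(compute_rdu(doubled)["rdu"],
                           compute_rdu(df)["rdu"] * 2)

    def test_roundtrip_csv(self, tmp_path):
        df = table([("p1", 1, 6, "GGGGGG", "apo", 10.0, 3.35)])
        path = tmp_path / "u.csv"
        write_uptake_csv(df, path)
        assert read_uptake_csv(path).equals(df)


class TestReporterRegions:
    def rdu(self, values):
        df = table([(f"p{i}", 10 * i + 1, 10 * i + 6, "GGGGGG", "apo", 10.0,
                     v * 5) for i, v in enumerate(values)])
        return compute_rdu(df)

    def test_half_maximum_threshold(self):
        result = reporter_regions(self.rdu([0.67, 0.30, 0.40]), [10.0])
        assert result.threshold == pytest.approx(0.335)
        assert result.max_rdu == pytest.approx(0.67)
        assert set(result.peptide_ids) == {"p0", "p2"}

    def test_identical_nonzero_values_all_report(self):
        result = reporter_regions(self.rdu([0.4, 0.4, 0.4]), [10.0])
        assert len(result.peptide_ids) == 3

    def test_single_peptide_is_its_own_reporter(self):
        result = reporter_regions(self.rdu([0.2]), [10.0])
        assert result.peptide_ids == ("p0",)

    def test_factor_limits(self):
        rdu = self.rdu([0.6, 0.3, 0.0])
        assert len(reporter_regions(rdu, [10.0], factor=1e-9).peptide_ids) == 2
        assert reporter_regions(rdu, [10.0],
                                factor=1 - 1e-9).peptide_ids == ("p0",)

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            reporter_regions(self.rdu([0.5]).iloc[0:0], [10.0])


class TestDifferenceProfile:
    def pair(self, apo_uptake, bound_uptake):
        apo = table([("p1", 1, 10, "G" * 10, "apo", 10.0, apo_uptake)])
        bound = table([("p1", 1, 10, "G" * 10, "lig", 10.0, bound_uptake)])
        return apo, bound

    def test_protection_is_positive_and_significant(self):
        profile = difference_profile(*self.pair(5.0, 4.0))
        assert profile.table["delta_da"].iloc[0] == pytest.approx(1.0)
        assert profile.significant_peptides[0].direction == "protection"

    def test_identical_states_not_significant(self):
        profile = difference_profile(*self.pair(4.0, 4.0))
        assert profile.significant_peptides == []

    def test_below_threshold_not_significant(self):
        profile = difference_profile(*self.pair(4.0, 4.4))
        assert profile.table["delta_da"].iloc[0] == pytest.approx(-0.4)
        assert profile.significant_peptides == []

    def test_mismatched_grids_raise_unless_intersection(self):
        apo, bound = self.pair(5.0, 4.0)
        extra = table([("p2", 21, 30, "G" * 10, "apo", 10.0, 1.0)])
        apo2 = pd.concat([apo, extra], ignore_index=True)
        with pytest.raises(ValueError, match="p2"):
            difference_profile(apo2, bound)
        profile = difference_profile(apo2, bound, strict=False)
        assert len(profile.table) == 1

    def test_min_timepoints_stringency(self):
        apo = table([("p1", 1, 10, "G" * 10, "apo", t, 5.0) for t in (1.0, 10.0)])
        bound = table([("p1", 1, 10, "G" * 10, "lig", 1.0, 4.9),
                       ("p1", 1, 10, "G" * 10, "lig", 10.0, 4.0)])
        assert difference_profile(apo, bound).significant_peptides
        assert not difference_profile(apo, bound,
                                      min_timepoints=2).significant_peptides

    def test_antisymmetry(self):
        rng = np.random.default_rng(3)
        rows_a, rows_b = [], []
        for i in range(8):
            for t in (0.5, 10.0):
                base = rng.uniform(0, 6)
                rows_a.append((f"p{i}", 5 * i + 1, 5 * i + 10, "G" * 10,
                               "apo", t, base))
                rows_b.append((f"p{i}", 5 * i + 1, 5 * i + 10, "G" * 10,
                               "lig", t, max(base + rng.normal(0, 1), 0)))
        fwd = difference_profile(table(rows_a), table(rows_b))
        rev = difference_profile(table(rows_b), table(rows_a))
        assert np.allclose(fwd.table["delta_da"], -rev.table["delta_da"])
        assert {p.id for p in fwd.significant_peptides} == \
            {p.id for p in rev.significant_peptides}
        flip = {"protection": "deprotection", "deprotection": "protection",
                "mixed": "mixed"}
        assert {p.id: flip[p.direction] for p in fwd.significant_peptides} == \
            {p.id: p.direction for p in rev.significant_peptides}


def sig(pid, start, end, direction="protection", delta=1.0):
    return SignificantPeptide(pid, start, end, direction, {10.0: delta})


class TestMergeRegions:
    def test_overlapping_same_direction_merge(self):
        regions = merge_regions([sig("a", 45, 58), sig("b", 55, 70)])
        assert [(r.start, r.end) for r in regions] == [(45, 70)]
        assert regions[0].peptide_ids == ("a", "b")

    def test_disjoint_stay_separate(self):
        regions = merge_regions([sig("a", 2, 16), sig("b", 45, 70)])
        assert [(r.start, r.end) for r in regions] == [(2, 16), (45, 70)]

    def test_adjacent_do_not_merge_by_default(self):
        regions = merge_regions([sig("a", 89, 119), sig("b", 120, 127)])
        assert len(regions) == 2
        assert len(merge_regions([sig("a", 89, 119), sig("b", 120, 127)],
                                 max_gap=1)) == 1

    def test_idempotent(self):
        peps = [sig("a", 1, 10), sig("b", 8, 20), sig("c", 30, 40)]
        once = merge_regions(peps)
        again = merge_regions([
            SignificantPeptide(";".join(r.peptide_ids), r.start, r.end,
                               r.direction, r.max_delta_da)
            for r in once
        ])
        assert [(r.start, r.end, r.direction) for r in once] == \
            [(r.start, r.end, r.direction) for r in again]

    def test_opposite_directions_become_mixed_with_warning(self):
        with pytest.warns(UserWarning, match="mixed"):
            regions = merge_regions([
                sig("a", 1, 10, "protection"),
                sig("b", 5, 15, "deprotection"),
            ])
        assert [(r.start, r.end, r.direction) for r in regions] == \
            [(1, 15, "mixed")]

    def test_max_delta_is_per_exposure_max(self):
        regions = merge_regions([
            SignificantPeptide("a", 1, 10, "protection", {0.5: 0.8, 10.0: 2.0}),
            SignificantPeptide("b", 5, 15, "protection", {0.5: 1.5, 10.0: 0.9}),
        ])
        assert regions[0].max_delta_da == {0.5: 1.5, 10.0: 2.0}

    @settings(max_examples=200, derandomize=True)
    @given(st.lists(
        st.tuples(st.integers(1, 80), st.integers(0, 15),
                  st.sampled_from(["protection", "deprotection"])),
        min_size=1, max_size=12))
    def test_residue_coverage_matches_set_union_oracle(self, spans):
        import warnings

        peps = [sig(f"p{i}", s, s + w, d)
                for i, (s, w, d) in enumerate(spans)]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # mixed-direction overlaps expected
            regions = merge_regions(peps)
        covered = set()
        for r in regions:
            block = set(range(r.start, r.end + 1))
            assert not (covered & block), "merged regions overlap"
            covered |= block
        oracle = set()
        for p in peps:
            oracle |= set(range(p.start, p.end + 1))
        assert covered == oracle
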