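"""Positional entropy, SC profiles, surface averages and insertion counts."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from specon.alignment_io import ColumnLabel, build_canonical_map
from specon.conservation import (
    DEFAULT_SURFACES,
    EquivalencyScheme,
    LoopRegions,
    PositionProfile,
    PositionSC,
    ConservationProfile,
    SurfaceDefinition,
    average_region_sc,
    conserved_insertion_count,
    family_position_average,
    positional_entropy,
    profile_alignment,
    sc_profile,
    summarize_domain,
)

from conftest import make_alignment

GROUPS = EquivalencyScheme().groups


def entropy_oracle(counts):
    """Independent closed-form exp(-sum p ln p) over positive counts."""
    total = sum(counts)
    return math.exp(-sum((c / total) * math.log(c / total) for c in counts if c))


def column_from_counts(counts):
    """One representative letter per group, repeated per count."""
    col = []
    for group, c in zip(GROUPS, counts):
        col.extend(group[0] * c)
    return col


class TestPositionalEntropy:
    def test_single_group_column_scores_1(self):
        assert positional_entropy(["A"] * 29) == pytest.approx(1.0)

    @pytest.mark.parametrize("k", range(1, 7))
    def test_uniform_k_groups_score_k(self, k):
        """Equal frequencies over k groups give an effective count of k."""
        col = column_from_counts([7] * k + [0] * (6 - k))
        assert positional_entropy(col) == pytest.approx(k, abs=1e-12)

    def test_two_to_one_mixture_matches_closed_form(self):
        col = column_from_counts([2, 1, 0, 0, 0, 0])
        expected = math.exp(-(2 / 3 * math.log(2 / 3) + 1 / 3 * math.log(1 / 3)))
        assert expected == pytest.approx(1.8899, abs=5e-5)
        assert positional_entropy(col) == pytest.approx(expected, rel=1e-15)

    def test_gap_threshold_boundary_19_of_29(self):
        """0.64 of 29 rows: 19 residues pass, 18 do not."""
        passing = ["A"] * 19 + ["-"] * 10
        failing = ["A"] * 18 + ["-"] * 11
        assert positional_entropy(passing) == pytest.approx(1.0)
        assert math.isnan(positional_entropy(failing))

    def test_ambiguity_letters_count_as_gaps(self):
        col = ["A"] * 18 + ["X"] * 11
        assert math.isnan(positional_entropy(col))

    def test_gaps_excluded_from_fractions(self):
        # 10 A + 10 K + 2 gaps: fractions over 20 residues, not 22 rows
        col = ["A"] * 10 + ["K"] * 10 + ["-"] * 2
        assert positional_entropy(col, gap_threshold=0.5) == pytest.approx(2.0)

    def test_scheme_with_one_group_rejected(self):
        with pytest.raises(ValueError):
            EquivalencyScheme(groups=("AVLIMC",))

    @given(
        counts=st.lists(st.integers(min_value=0, max_value=40), min_size=6,
                        max_size=6).filter(lambda c: sum(c) > 0)
    )
    @settings(max_examples=300, deadline=None)
    def test_matches_independent_oracle_and_range(self, counts):
        col = column_from_counts(counts)
        got = positional_entropy(col, gap_threshold=0.0)
        expected = entropy_oracle(counts)
        assert got == pytest.approx(expected, rel=1e-12)
        assert 1.0 - 1e-12 <= got <= 6.0 + 1e-12

    def test_equal_mixture_of_two_groups_is_exactly_2(self):
        col = column_from_counts([12, 12, 0, 0, 0, 0])
        assert positional_entropy(col) == pytest.approx(2.0, abs=1e-14)


class TestProfileAlignment:
    def test_identical_sequences_profile_to_1(self):
        aln = make_alignment(["AKLD"] * 3, ids=list("abc"))
        profiles = profile_alignment(aln)
        assert [p.entropy for p in profiles] == pytest.approx([1.0] * 4)

    def test_15_14_split_matches_oracle(self):
        aln = make_alignment(["A"] * 15 + ["K"] * 14, ids=[f"r{i}" for i in range(29)])
        prof = profile_alignment(aln)[0]
        assert prof.entropy == pytest.approx(entropy_oracle([15, 14]), rel=1e-12)
        assert prof.entropy == pytest.approx(1.9988, abs=5e-5)

    def test_all_gap_column_is_undefined_with_zero_nongap(self):
        aln = make_alignment(["-A", "-K"], ids=["a", "b"])
        prof = profile_alignment(aln)[0]
        assert math.isnan(prof.entropy) and prof.nongap_fraction == 0.0

    def test_row_shuffling_leaves_profiles_unchanged(self):
        rng = np.random.default_rng(7)
        seqs = ["".join(rng.choice(list("AKLDFWGP"), 10)) for _ in range(12)]
        ids = [f"r{i}" for i in range(12)]
        base = profile_alignment(make_alignment(seqs, ids=ids))
        order = rng.permutation(12)
        shuffled = profile_alignment(
            make_alignment([seqs[i] for i in order], ids=[ids[i] for i in order])
        )
        for a, b in zip(base, shuffled):
            assert a.entropy == pytest.approx(b.entropy, nan_ok=True)
            assert a.group_fractions == pytest.approx(b.group_fractions)

    def test_group_fractions_sum_to_1_where_counted(self):
        aln = make_alignment(["AKWD", "GKFD", "PKYD"], ids=list("abc"))
        for prof in profile_alignment(aln):
            assert prof.group_fractions.sum() == pytest.approx(1.0, abs=1e-12)


def make_profile(label, entropy, nongap=1.0):
    return PositionProfile(
        label=label, group_fractions=np.zeros(6), nongap_fraction=nongap,
        entropy=entropy,
    )


def canonical(n):
    return ColumnLabel("canonical", number=n)


class TestSCProfile:
    def test_ratio_of_entropies(self):
        par = [make_profile(canonical(14), 4.5)]
        ort = [make_profile(canonical(14), 1.2)]
        profile = sc_profile(par, ort, "Abp1")
        assert profile.positions[14].sc == pytest.approx(3.75)
        assert profile.positions[14].sc_rounded == pytest.approx(3.8)

    @pytest.mark.parametrize(
        "par_e,ort_e,expected", [(2.0, 2.0, 1.0), (1.0, 2.0, 0.5), (1.0, 1.0, 1.0)]
    )
    def test_simple_ratios(self, par_e, ort_e, expected):
        profile = sc_profile(
            [make_profile(canonical(1), par_e)],
            [make_profile(canonical(1), ort_e)],
            "d",
        )
        assert profile.positions[1].sc == pytest.approx(expected)

    def test_undefined_either_side_gives_undefined_sc(self):
        profile = sc_profile(
            [make_profile(canonical(1), math.nan)],
            [make_profile(canonical(1), 1.5)],
            "d",
        )
        assert math.isnan(profile.positions[1].sc)

    def test_insertion_columns_kept_separately(self):
        ort = [
            make_profile(canonical(1), 1.0),
            make_profile(ColumnLabel("insertion", number=1, suffix=1), 2.0),
        ]
        profile = sc_profile([make_profile(canonical(1), 1.0)], ort, "d")
        assert len(profile.insertion_profiles) == 1
        assert str(profile.insertion_profiles[0].label) == "1a"


def profile_with_sc(values, name="d"):
    """ConservationProfile with given {position: (par, ort)} entries."""
    return ConservationProfile(
        domain_name=name,
        positions={p: PositionSC(*pair) for p, pair in values.items()},
    )


class TestRegionAverages:
    def test_constant_sc_over_surface(self):
        prof = profile_with_sc(
            {p: (2.0, 1.0) for p in DEFAULT_SURFACES["SII"].positions}
        )
        assert average_region_sc(prof, DEFAULT_SURFACES["SII"]) == pytest.approx(2.0)

    def test_undefined_positions_excluded_from_mean(self):
        prof = profile_with_sc(
            {1: (1.0, 1.0), 2: (2.0, 1.0), 3: (3.0, 1.0), 4: (math.nan, 1.0)}
        )
        surf = SurfaceDefinition("t", frozenset({1, 2, 3, 4}))
        assert average_region_sc(prof, surf) == pytest.approx(2.0)

    def test_empty_surface_rejected(self):
        with pytest.raises(ValueError):
            SurfaceDefinition("t", frozenset())

    def test_high_sc_flag_inclusive_at_1_7(self):
        prof = profile_with_sc({p: (1.7, 1.0) for p in range(1, 61)})
        summary = summarize_domain(prof)
        assert summary.avg_sc["SII"] == pytest.approx(1.7)
        assert summary.high_sc["SII"] is True

    def test_family_average_across_domains(self):
        a = profile_with_sc({32: (2.0, 1.0)}, name="domA")
        b = profile_with_sc({32: (4.0, 1.0)}, name="domB")
        avg = family_position_average([a, b])
        assert avg[32] == pytest.approx(3.0)

    def test_single_domain_family_average_is_identity(self):
        a = profile_with_sc({1: (2.0, 1.0), 2: (3.0, 1.0)})
        avg = family_position_average([a])
        assert avg[1] == pytest.approx(2.0) and avg[2] == pytest.approx(3.0)


class TestConservedInsertionCount:
    def insertion(self, anchor, suffix=1):
        return ColumnLabel("insertion", number=anchor, suffix=suffix)

    def test_no_insertions_counts_zero(self):
        counts = conserved_insertion_count([make_profile(canonical(5), 1.0)])
        assert all(v == 0 for v in counts.values())

    def test_cutoff_is_inclusive_at_3_3(self):
        profs = [
            make_profile(self.insertion(14, 1), 1.5),
            make_profile(self.insertion(14, 2), 3.4),
            make_profile(self.insertion(14, 3), 3.3),
        ]
        counts = conserved_insertion_count(profs)
        assert counts["RT-loop"] == 2

    def test_two_fully_conserved_rt_loop_insertions(self):
        """A member with 2 perfectly conserved RT-loop insertions counts 2."""
        profs = [
            make_profile(self.insertion(12, 1), 1.0),
            make_profile(self.insertion(12, 2), 1.0),
        ]
        assert conserved_insertion_count(profs)["RT-loop"] == 2

    def test_regions_assigned_by_anchor_and_flanks(self):
        regions = LoopRegions()
        assert regions.region_of(self.insertion(30)) == "N-Src loop"
        assert regions.region_of(self.insertion(45)) == "distal loop"
        assert regions.region_of(ColumnLabel("n_flank", suffix=1)) == "N-terminus"
        assert regions.region_of(ColumnLabel("c_flank", suffix=2)) == "C-terminus"

    def test_explicit_mapping_must_cover_labels(self):
        profs = [make_profile(self.insertion(14), 1.0)]
        with pytest.raises(ValueError, match="14a"):
            conserved_insertion_count(profs, regions={"99z": "RT-loop"})

    def test_undefined_entropy_never_counts(self):
        profs = [make_profile(self.insertion(14), math.nan, nongap=0.2)]
        assert conserved_insertion_count(profs)["RT-loop"] == 0


class TestSCRecoveryOnSyntheticFamily:
    def test_planted_specificity_positions_score_highest(self, default_family):
        """Specificity positions (divergent across paralogs, conserved within
        orthologs) must out-score housekeeping and variable positions, and a
        1.7 cutoff must classify them with sensitivity/specificity >= 0.9."""
        from specon.conservation import profile_alignment, sc_profile

        fam = default_family
        pmap = build_canonical_map(fam.paralog_alignment, fam.members[0])
        par_profiles = profile_alignment(fam.paralog_alignment, pmap)
        profiles = []
        for m, aln in fam.ortholog_alignments.items():
            omap = build_canonical_map(aln, m)
            profiles.append(sc_profile(par_profiles, profile_alignment(aln, omap), m))
        avg = family_position_average(profiles)
        truth = fam.truth.set_index("position")["position_class"]
        mean_by_class = avg.groupby(truth).mean()
        assert mean_by_class["specificity"] > mean_by_class["housekeeping"]
        assert mean_by_class["specificity"] > mean_by_class["variable"]
        predicted = avg >= 1.7
        actual = truth == "specificity"
        sensitivity = (predicted & actual).sum() / actual.sum()
        specificity = ((~predicted) & (~actual)).sum() / (~actual).sum()
        assert sensitivity >= 0.9
        assert specificity >= 0.9
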