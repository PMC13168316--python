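"""Glycoform parsing, abundance tables, and quality indices."""

import numpy as np
import pandas as pd
import pytest

from glycofeed.glycoforms import (
    ARM_TOKENS,
    GlycationProfile,
    GlycoformParseError,
    GlycoformSpecies,
    GlycanArm,
    correct_hexosylation_bias,
    forward_hexosylation_bias,
    galactosylation_index,
    glycation_index,
    normalize_abundances,
    parse_glycoform,
    vocabulary,
)


class TestParsing:
    @pytest.mark.parametrize("label, g, d, fuc_both", [
        ("G1F ⋅ G0F", 1, 4, True),
        ("none ⋅ G0F", 0, 2, None),
        ("G2F ⋅ G2F", 4, 4, True),
        ("G0 ⋅ G0", 0, 4, False),
    ])
    def test_examples(self, label, g, d, fuc_both):
        sp = parse_glycoform(label)
        assert sp.g == g
        assert sp.d == d
        if fuc_both is not None:
            assert all(a.fucosylated == fuc_both
                       for a in (sp.arm_a, sp.arm_b) if a.present)

    def test_ascii_dot_alias_and_whitespace(self):
        assert parse_glycoform("G1F.G0F").label == "G0F ⋅ G1F"
        assert parse_glycoform("  G1F ⋅  G0F ").label == "G0F ⋅ G1F"

    def test_unknown_token_named_in_error(self):
        with pytest.raises(GlycoformParseError, match="G3F"):
            parse_glycoform("G3F ⋅ G0F")

    @pytest.mark.parametrize("bad", ["G0F", "G0F ⋅ G0F ⋅ G0F", ""])
    def test_wrong_arity(self, bad):
        with pytest.raises(GlycoformParseError):
            parse_glycoform(bad)

    def test_canonical_order_symmetric(self):
        assert parse_glycoform("G0F ⋅ G1F") == parse_glycoform("G1F ⋅ G0F")

    def test_parse_render_fixed_point_over_vocabulary(self):
        # every pair over the 7-token vocabulary survives a render round trip
        labels = {f"{a} ⋅ {b}" for a in ARM_TOKENS for b in ARM_TOKENS}
        assert len(labels) == 49
        for label in labels:
            sp = parse_glycoform(label)
            assert parse_glycoform(sp.label) == sp
            assert parse_glycoform(sp.label).label == sp.label

    def test_vocabulary_is_deduplicated(self):
        vocab = vocabulary()
        assert len(vocab) == len({sp.label for sp in vocab})
        # 7 tokens, unordered pairs with repetition: 7*8/2 = 28
        assert len(vocab) == 28

    def test_hexose_adduct_suffix(self):
        sp = parse_glycoform("G0F ⋅ G0F + 2Hex")
        assert sp.hexose_adducts == 2
        assert sp.label == "G0F ⋅ G0F + 2Hex"

    def test_none_arm_has_no_sites(self):
        arm = GlycanArm("none")
        assert not arm.present and arm.gal_sites == 0 and arm.gal_count == 0


class TestNormalize:
    def test_equal_split(self):
        t = normalize_abundances(pd.DataFrame(
            {"G0F ⋅ G0F": [2.0], "G1F ⋅ G1F": [2.0]}, index=["a"]))
        assert np.allclose(t.values(), [[50.0, 50.0]])

    def test_proportions_preserved(self):
        t = normalize_abundances(pd.DataFrame(
            {"G0F ⋅ G0F": [3.0], "G1F ⋅ G1F": [1.0]}, index=["a"]))
        assert np.allclose(t.values(), [[75.0, 25.0]])

    def test_all_zero_sample_errors_with_name(self):
        raw = pd.DataFrame({"G0F ⋅ G0F": [0.0], "G1F ⋅ G1F": [0.0]},
                           index=["bad_sample"])
        with pytest.raises(ValueError, match="bad_sample"):
            normalize_abundances(raw)

    def test_rows_sum_to_100(self, random_table):
        assert np.allclose(random_table.values().sum(axis=1), 100.0,
                           rtol=1e-9)


class TestGalactosylationIndex:
    def test_no_galactose_is_zero(self):
        t = normalize_abundances(pd.DataFrame({"G0F ⋅ G0F": [100.0]},
                                              index=["a"]))
        assert galactosylation_index(t).iloc[0] == 0.0

    def test_full_occupancy_is_100(self):
        t = normalize_abundances(pd.DataFrame({"G2F ⋅ G2F": [100.0]},
                                              index=["a"]))
        assert galactosylation_index(t).iloc[0] == pytest.approx(100.0)

    def test_half_mix_worked_example(self, two_species_table):
        # (50*0 + 50*2) / (50*4 + 50*4) * 100 = 25
        assert galactosylation_index(two_species_table).iloc[0] == pytest.approx(25.0)

    def test_all_unoccupied_errors(self):
        t = normalize_abundances(pd.DataFrame({"none ⋅ none": [100.0]},
                                              index=["a"]))
        with pytest.raises(ValueError):
            galactosylation_index(t)

    def test_range_and_mixture_linearity(self, random_table):
        idx = galactosylation_index(random_table)
        assert ((idx >= 0) & (idx <= 100)).all()
        # pooling two samples gives the abundance-weighted ratio of sums
        A = random_table.values()
        pooled = normalize_abundances(pd.DataFrame(
            [A[0] + A[1]], index=["pool"],
            columns=random_table.abundances.columns))
        g = np.array([sp.g for sp in random_table.species.values()])
        d = np.array([sp.d for sp in random_table.species.values()])
        expected = 100 * (A[0] + A[1]) @ g / ((A[0] + A[1]) @ d)
        assert galactosylation_index(pooled).iloc[0] == pytest.approx(expected)


class TestGlycationIndex:
    def _profile(self, *f):
        return GlycationProfile(pd.DataFrame(
            [list(f)], index=["a"],
            columns=[f"hexoses_{i}" for i in range(4)]))

    def test_no_hexoses(self):
        assert glycation_index(self._profile(100, 0, 0, 0)).iloc[0] == 0.0

    def test_saturated(self):
        assert glycation_index(self._profile(0, 0, 0, 100)).iloc[0] == pytest.approx(100.0)

    def test_worked_example(self):
        # (0*50 + 1*50) / (3*100) * 100 = 16.6667
        got = glycation_index(self._profile(50, 50, 0, 0)).iloc[0]
        assert got == pytest.approx(16.6667, abs=1e-4)

    def test_negative_fraction_rejected(self):
        with pytest.raises(ValueError):
            self._profile(110, -10, 0, 0)


class TestHexosylationBias:
    def _profile(self, f, sample_ids):
        return GlycationProfile(pd.DataFrame(
            [list(f)] * len(sample_ids), index=sample_ids,
            columns=[f"hexoses_{i}" for i in range(4)]))

    def test_zero_glycation_is_identity(self, random_table):
        prof = self._profile((100, 0, 0, 0), random_table.sample_ids)
        out = correct_hexosylation_bias(random_table, prof)
        assert np.allclose(out.values(), random_table.values(), atol=1e-9)

    def test_forward_then_correct_round_trip(self, random_table):
        prof = self._profile((70, 20, 8, 2), random_table.sample_ids)
        biased = forward_hexosylation_bias(random_table, prof)
        recovered = correct_hexosylation_bias(biased, prof)
        cols = list(random_table.abundances.columns)
        assert np.allclose(recovered.abundances[cols].to_numpy(),
                           random_table.values(), atol=1e-8)
        extra = [c for c in recovered.abundances.columns if c not in cols]
        assert np.allclose(recovered.abundances[extra].to_numpy(), 0.0,
                           atol=1e-8)

    def test_forward_shifts_apparent_galactosylation_up(self, random_table):
        prof = self._profile((50, 30, 15, 5), random_table.sample_ids)
        biased = forward_hexosylation_bias(random_table, prof)
        assert (galactosylation_index(biased)
                > galactosylation_index(random_table) - 1e-12).all()

    def test_inconsistent_profile_clips_and_renormalizes(self):
        # observed ladder has mass at high counts that no nonnegative truth
        # can produce under the declared glycation kernel
        raw = pd.DataFrame({"G0F ⋅ G0F": [95.0], "G2F ⋅ G2F": [5.0]},
                           index=["a"])
        table = normalize_abundances(raw)
        prof = self._profile((40, 60, 0, 0), ["a"])
        out = correct_hexosylation_bias(table, prof)
        vals = out.values()
        assert (vals >= 0).all()
        assert vals.sum() == pytest.approx(100.0)

    def test_sample_mismatch_errors(self, random_table):
        prof = self._profile((100, 0, 0, 0), ["other"])
        with pytest.raises(ValueError, match="sample ids"):
            correct_hexosylation_bias(random_table, prof)

    def test_adduct_resolved_input_collapses_to_plain_species(self):
        # intact-level observation with explicit +Hex species: all mass at
        # G0F.G0F with 0/1 adducts under kernel (80,20,0,0) deconvolves to
        # pure G0F.G0F
        raw = pd.DataFrame({"G0F ⋅ G0F": [80.0], "G0F ⋅ G0F + 1Hex": [20.0]},
                           index=["a"])
        table = normalize_abundances(raw)
        prof = self._profile((80, 20, 0, 0), ["a"])
        out = correct_hexosylation_bias(table, prof)
        got = dict(zip(out.abundances.columns, out.values()[0]))
        assert got["G0F ⋅ G0F"] == pytest.approx(100.0)
        assert got["G0F ⋅ G0F + 1Hex"] == pytest.approx(0.0)
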