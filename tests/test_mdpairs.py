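"""Reciprocity classification, landscape distances and local phasing."""
import numpy as np
import pandas as pd
import pytest

from rtgpoly import afshift, mdpairs
from rtgpoly.simulate import ForcedCrossover, simulate_rtg, exact_observations
from conftest import calls_and_regions


def build_pair(parent, truth_pair, min_run=9):
    mother, daughter = truth_pair
    mc, mr = calls_and_regions(mother, min_run=min_run)
    dc, dr = calls_and_regions(daughter, min_run=min_run)
    return mdpairs.MDPair("m", "d", mc, dc, mr, dr)


class TestReciprocity:
    def test_forced_co_is_reciprocal_with_full_agreement(self, small_parent, forced_co_pair):
        mother, daughter, truth, fc = forced_co_pair
        pair = build_pair(small_parent, (mother, daughter))
        out = mdpairs.classify_reciprocity(pair)
        rec = out[out["call"] == "reciprocal"]
        assert len(rec) >= 1
        assert np.allclose(rec["agreement"], 1.0)

    def test_one_sided_event_is_non_reciprocal(self, small_parent):
        # an NCO conversion tract touches a single cell
        for seed in range(40):
            mother, daughter, truth = simulate_rtg(
                small_parent, n_dsb_per_Mb=0.6, p_crossover=0.0,
                nco_tract_mean=30_000, seed=seed,
            )
            if len(truth.events) != 1:
                continue
            pair = build_pair(small_parent, (mother, daughter))
            total = len(pair.mother_regions) + len(pair.daughter_regions)
            if total == 0:
                continue
            out = mdpairs.classify_reciprocity(pair)
            assert (out["call"] == "non_reciprocal").all()
            return
        pytest.fail("no single-NCO simulation produced a callable region")

    def test_empty_region_lists_give_empty_output(self, small_parent):
        mother, daughter, _ = simulate_rtg(small_parent, n_dsb_per_Mb=0.0, seed=1)
        pair = build_pair(small_parent, (mother, daughter))
        assert len(mdpairs.classify_reciprocity(pair)) == 0

    def test_symmetric_under_mother_daughter_swap(self, small_parent, forced_co_pair):
        mother, daughter, _, _ = forced_co_pair
        pair = build_pair(small_parent, (mother, daughter))
        a = mdpairs.classify_reciprocity(pair)
        b = mdpairs.classify_reciprocity(pair.swapped())
        counts = lambda df: df["call"].value_counts().to_dict()
        assert counts(a) == counts(b)

    def test_mismatched_catalogues_rejected(self, small_parent, forced_co_pair):
        mother, daughter, _, _ = forced_co_pair
        mc, mr = calls_and_regions(mother)
        dc, dr = calls_and_regions(daughter)
        with pytest.raises(ValueError):
            mdpairs.MDPair("m", "d", mc, dc.iloc[:-1], mr, dr)


class TestLandscapeDistance:
    def test_identical_and_disjoint(self):
        mat = mdpairs.pairwise_landscape_distance(
            {"a": {1, 2, 3}, "b": {1, 2, 3}, "c": {7, 8}}
        )
        assert mat.loc["a", "b"] == 0.0
        assert mat.loc["a", "c"] == 1.0
        assert np.allclose(np.diag(mat), 0.0)
        assert np.allclose(mat, mat.T)

    def test_empty_sample_convention(self):
        mat = mdpairs.pairwise_landscape_distance({"a": set(), "b": {1}, "c": set()})
        assert mat.loc["a", "b"] == 1.0
        assert mat.loc["a", "c"] == 0.0

    def test_pairs_separate_from_each_other(self, small_parent):
        # M-D mates share (reciprocally) the same recombined intervals, so
        # within-pair distance < between-pair distance in marker space
        sets = {}
        within, between = [], []
        cases = [(60_000, (0, 1)), (140_000, (1, 2)), (220_000, (0, 2))]
        for i, (pos, homologs) in enumerate(cases):
            fc = ForcedCrossover(chrom=0, pos=pos, homologs=homologs, sisters=(0, 0))
            mother, daughter, _ = simulate_rtg(
                small_parent, n_dsb_per_Mb=0.0, seed=40 + i, forced_cos=(fc,)
            )
            mc, _ = calls_and_regions(mother)
            dc, _ = calls_and_regions(daughter)
            sets[f"m{i}"] = mdpairs.shifted_marker_set(mc)
            sets[f"d{i}"] = mdpairs.shifted_marker_set(dc)
        mat = mdpairs.pairwise_landscape_distance(sets)
        for i in range(3):
            within.append(mat.loc[f"m{i}", f"d{i}"])
            for j in range(3):
                if i != j:
                    between.append(mat.loc[f"m{i}", f"m{j}"])
                    between.append(mat.loc[f"m{i}", f"d{j}"])
        assert max(within) < min(between)


class TestPhasing:
    def test_triploid_worked_example(self):
        # initial genotype Ref/Alt/Alt, shift toward Ref in the focal cell:
        # the recombining pair carried {Ref, Alt} and the third haplotype Alt
        calls = pd.DataFrame(
            {
                "chrom": ["chrI"] * 3, "pos": [100, 200, 300],
                "k": [2, 2, 2], "p": [3, 3, 3],
                "shift_status": ["shift", "shift", "no_shift"],
                "direction": ["toward_ref", "toward_ref", "none"],
                "k_hat": [1, 1, 2],
            }
        )
        other = calls.copy()
        other["direction"] = ["toward_alt", "toward_alt", "none"]
        other["k_hat"] = [3, 3, 2]
        regions = pd.DataFrame(
            [{"chrom": "chrI", "start": 99, "end": 300, "first_idx": 0, "last_idx": 2}]
        )
        pair = mdpairs.MDPair("m", "d", calls, other, regions, regions)
        block = mdpairs.phase_md_pair(pair, regions.iloc[0], calls)
        confident = block[block["confidence"] > 0]
        assert len(confident) == 2
        assert (confident["hap_donor"] == "Ref").all()      # gained allele
        assert (confident["hap_recipient"] == "Alt").all()  # replaced allele
        assert (confident["rest"] == "Alt").all()           # third haplotype
        # dosage identity: donor + recipient + rest carry k Alt alleles
        alt_count = (
            (confident["hap_donor"] == "Alt").astype(int)
            + (confident["hap_recipient"] == "Alt").astype(int)
            + confident["n_rest_alt"]
        )
        assert (alt_count == confident["k"]).all()
        assert block.loc[block["pos"] == 300, "confidence"].iloc[0] == 0.0

    def test_tetraploid_dosage_algebra(self):
        calls = pd.DataFrame(
            {
                "chrom": ["chrI"], "pos": [100], "k": [2], "p": [4],
                "shift_status": ["shift"], "direction": ["toward_alt"], "k_hat": [3],
            }
        )
        regions = pd.DataFrame(
            [{"chrom": "chrI", "start": 99, "end": 100, "first_idx": 0, "last_idx": 0}]
        )
        pair = mdpairs.MDPair("m", "d", calls, calls, regions, regions)
        block = mdpairs.phase_md_pair(pair, regions.iloc[0], calls)
        row = block.iloc[0]
        assert row["hap_donor"] == "Alt" and row["hap_recipient"] == "Ref"
        assert row["n_rest_alt"] == 1 and row["rest"] == "Alt,Ref"

    def test_non_reciprocal_region_rejected(self):
        calls = pd.DataFrame(
            {
                "chrom": ["chrI"], "pos": [100], "k": [2], "p": [3],
                "shift_status": ["shift"], "direction": ["toward_ref"], "k_hat": [1],
            }
        )
        regions = pd.DataFrame(
            [{"chrom": "chrI", "start": 99, "end": 100, "first_idx": 0, "last_idx": 0}]
        )
        pair = mdpairs.MDPair("m", "d", calls, calls, regions, regions)
        reciprocity = pd.DataFrame(
            [{"chrom": "chrI", "start": 99, "end": 100, "cells": "both",
              "call": "non_reciprocal", "agreement": 0.0, "n_shared": 1}]
        )
        with pytest.raises(ValueError):
            mdpairs.phase_md_pair(pair, regions.iloc[0], calls, reciprocity=reciprocity)

    def test_phasing_matches_simulated_haplotypes(self, small_parent, forced_co_pair):
        mother, daughter, truth, fc = forced_co_pair
        pair = build_pair(small_parent, (mother, daughter))
        region = pair.mother_regions.iloc[0]
        block = mdpairs.phase_md_pair(pair, region, pair.mother_calls)
        confident = block[block["confidence"] > 0]
        assert len(confident) >= 9
        # truth: recombining homologs are fc.homologs; mother received the
        # recombinant of homolog 0 whose downstream content came from homolog 1
        h_recip = small_parent.haplotypes[0][fc.homologs[0]]
        h_donor = small_parent.haplotypes[0][fc.homologs[1]]
        idx = confident["marker_idx"].to_numpy()
        want_recip = np.where(h_recip[idx] == 1, "Alt", "Ref")
        want_donor = np.where(h_donor[idx] == 1, "Alt", "Ref")
        direct = (confident["hap_recipient"].to_numpy() == want_recip).mean()
        swapped = (confident["hap_recipient"].to_numpy() == want_donor).mean()
        assert max(direct, swapped) >= 0.99

    def test_cross_validation_between_two_pairs(self, small_parent):
        blocks = []
        for seed in (31, 32):
            fc = ForcedCrossover(chrom=0, pos=80_000, homologs=(0, 1), sisters=(0, 0))
            mother, daughter, truth = simulate_rtg(
                small_parent, n_dsb_per_Mb=0.0, seed=seed, forced_cos=(fc,)
            )
            pair = build_pair(small_parent, (mother, daughter))
            region = pair.mother_regions.iloc[0]
            blocks.append(mdpairs.phase_md_pair(pair, region, pair.mother_calls))
        conc, n = mdpairs.cross_validate_phasing(blocks[0], blocks[1])
        assert conc == 1.0 and n >= 9
        # symmetric in the argument order
        conc2, n2 = mdpairs.cross_validate_phasing(blocks[1], blocks[0])
        assert (conc2, n2) == (conc, n)

    def test_cross_validation_requires_overlap(self):
        a = pd.DataFrame({"marker_idx": [1, 2], "hap_recipient": ["Ref", "Alt"],
                          "confidence": [1.0, 1.0]})
        b = pd.DataFrame({"marker_idx": [5, 6], "hap_recipient": ["Ref", "Alt"],
                          "confidence": [1.0, 1.0]})
        with pytest.raises(ValueError):
            mdpairs.cross_validate_phasing(a, b)
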