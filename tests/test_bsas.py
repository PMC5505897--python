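"""BSAS quantitation: conversion, read placement, calling, group statistics."""

import numpy as np
import pytest

from dietmem import (
    AmpliconSpec,
    MethylationScenario,
    call_sites,
    convert_reference,
    make_amplicon,
    place_read,
    simulate_bisulfite_reads,
    total_methylation,
    uniform_site_methylation,
)
from dietmem import test_sites as site_group_stats
from dietmem import test_total as total_group_stats


class TestConvertReference:
    def test_definition(self):
        spec = AmpliconSpec.from_sequence("t", "ACGT")
        conv, sites = convert_reference(spec)
        assert conv == "ATGT"
        assert sites == (1,)

    def test_c_free_sequence_unchanged(self):
        spec = AmpliconSpec.from_sequence("t", "ATGGTAAT")
        conv, sites = convert_reference(spec)
        assert conv == spec.sequence and sites == ()

    def test_per_character_oracle_on_random_reference(self):
        amp = make_amplicon(397, [10, 200, 390], seed=31)
        conv, _ = convert_reference(amp)
        assert conv == "".join("T" if b == "C" else b for b in amp.sequence)

    def test_rejects_non_acgt(self):
        with pytest.raises(ValueError):
            AmpliconSpec.from_sequence("t", "ACGN")


class TestPlaceRead:
    def test_exact_converted_read_at_origin(self, small_amplicon):
        conv, _ = convert_reference(small_amplicon)
        assert place_read(conv, small_amplicon) == (0, 0)

    def test_c_t_ambiguity_at_cytosines(self, small_amplicon):
        # methylated read: C retained at a site, T elsewhere -> 0 mismatches
        conv, _ = convert_reference(small_amplicon)
        read = list(conv)
        read[4] = "C"  # CG site position
        assert place_read("".join(read), small_amplicon) == (0, 0)

    def test_interior_fragment_placed_at_offset(self, small_amplicon):
        conv, _ = convert_reference(small_amplicon)
        assert place_read(conv[7:27], small_amplicon) == (7, 0)

    def test_excess_mismatches_rejected(self, small_amplicon, rng):
        conv, _ = convert_reference(small_amplicon)
        read = list(conv)
        # corrupt 15% of non-cytosine positions with a fixed substitution
        sites = set(s.offset for s in small_amplicon.sites)
        targets = [i for i in range(len(read)) if i not in sites][:6]
        for i in targets:
            read[i] = {"A": "G", "T": "G", "G": "A", "C": "A"}[read[i]]
        assert place_read("".join(read), small_amplicon, max_mm=0.1) is None

    def test_read_longer_than_amplicon_rejected(self, small_amplicon):
        assert place_read("A" * 100, small_amplicon) is None


class TestCallSites:
    def test_counting_definition(self, small_amplicon):
        conv, _ = convert_reference(small_amplicon)
        meth = list(conv)
        meth[4] = "C"
        reads = ["".join(meth)] * 7 + [conv] * 3
        matrix = call_sites({"s1": reads}, small_amplicon, min_coverage=1)
        assert matrix.pct.loc["s1", 4] == pytest.approx(70.0)
        assert matrix.pct.loc["s1", 20] == pytest.approx(0.0)
        assert matrix.coverage.loc["s1", 4] == 10

    def test_all_converted_reads_give_zero(self, small_amplicon):
        conv, _ = convert_reference(small_amplicon)
        matrix = call_sites({"s1": [conv] * 5}, small_amplicon, min_coverage=1)
        assert (matrix.pct.loc["s1"] == 0.0).all()

    def test_binomial_oracle_at_depth_5000(self):
        amp = make_amplicon(120, [60], seed=32)
        sc = MethylationScenario(
            amplicon=amp,
            group_site_methylation={
                "AL": tuple(0.42 if s.offset == 60 else 0.0
                            for s in amp.sites)},
            depth=5000, n_samples_per_group=1, seed=33)
        reads, _ = simulate_bisulfite_reads(sc)
        matrix = call_sites(reads, amp, min_coverage=1000)
        est = matrix.pct.loc["AL_s1", 60]
        assert abs(est - 42.0) < 300 * np.sqrt(0.42 * 0.58 / 5000)

    def test_empty_read_set_warns(self, small_amplicon):
        with pytest.warns(UserWarning, match="no reads"):
            matrix = call_sites({"s1": []}, small_amplicon)
        assert matrix.coverage.to_numpy().sum() == 0

    def test_rejected_reads_counted(self, small_amplicon):
        with pytest.warns(UserWarning, match="no reads"):
            matrix = call_sites({"s1": ["GGGGGGGGGG"]}, small_amplicon,
                                min_coverage=1)
        assert matrix.n_rejected["s1"] == 1


class TestTotalMethylation:
    def _matrix_with_pcts(self, pcts_by_site, depth=2000):
        amp = make_amplicon(100, [10, 40, 70], seed=34)
        fracs = [0.0] * len(amp.sites)
        offsets = [s.offset for s in amp.sites]
        for off, pct in pcts_by_site.items():
            fracs[offsets.index(off)] = pct / 100.0
        sc = MethylationScenario(
            amplicon=amp, group_site_methylation={"AL": tuple(fracs)},
            depth=depth, n_samples_per_group=1, seed=35)
        reads, _ = simulate_bisulfite_reads(sc)
        return call_sites(reads, amp, min_coverage=100)

    def test_unweighted_mean_of_sites(self, small_amplicon):
        conv, _ = convert_reference(small_amplicon)
        # 40% at site 4, 60% at site 20, CH sites 0
        reads = []
        for i in range(10):
            r = list(conv)
            if i < 4:
                r[4] = "C"
            if i < 6:
                r[20] = "C"
            reads.append("".join(r))
        matrix = call_sites({"s1": reads}, small_amplicon, min_coverage=1)
        total = total_methylation(matrix, "CG")
        assert total["s1"] == pytest.approx(50.0)

    def test_weightings_agree_at_equal_coverage(self):
        matrix = self._matrix_with_pcts({10: 40, 40: 50, 70: 60})
        site_mean = total_methylation(matrix, "CG", "site-mean")
        read_weighted = total_methylation(matrix, "CG", "read-weighted")
        np.testing.assert_allclose(site_mean, read_weighted, atol=1e-9)

    def test_no_covered_sites_is_error(self, small_amplicon):
        conv, _ = convert_reference(small_amplicon)
        matrix = call_sites({"s1": [conv] * 5}, small_amplicon,
                            min_coverage=1000)
        with pytest.raises(ValueError, match="no covered"):
            total_methylation(matrix, "CG")


class TestGroupStats:
    def test_percent_decrease_definition(self):
        res = total_group_stats({"AL": [100.0, 100.0], "DR": [50.0, 50.0]})
        assert res.percent_decrease["DR"] == pytest.approx(50.0)

    def test_identical_groups_nothing_significant(self):
        res = total_group_stats({"AL": [50.0, 50.0], "DR": [50.0, 50.0],
                          "DR-AL": [50.0, 50.0]})
        assert res.anova_f == 0.0 and res.anova_p == 1.0
        assert (res.tukey["p_adj"] == 1.0).all()

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            total_group_stats({"AL": [1.0, 2.0]})
        with pytest.raises(ValueError):
            total_group_stats({"AL": [1.0], "DR": [2.0, 3.0]})

    def _group_matrices(self, site_fracs_by_group, depth=1500, n=4, seed=36):
        amp = make_amplicon(150, [30, 90, 140], seed=37)
        offsets = [s.offset for s in amp.sites]
        site_meth = {}
        for g, per_cg in site_fracs_by_group.items():
            fracs = [0.02] * len(amp.sites)
            for off, val in per_cg.items():
                fracs[offsets.index(off)] = val
            site_meth[g] = tuple(fracs)
        sc = MethylationScenario(amplicon=amp, group_site_methylation=site_meth,
                                 depth=depth, n_samples_per_group=n, seed=seed)
        reads, truth = simulate_bisulfite_reads(sc)
        return amp, {
            g: call_sites({s: reads[s] for s in truth["samples_by_group"][g]},
                          amp, min_coverage=1000)
            for g in site_meth
        }

    def test_programmed_site_flagged_null_sites_not(self):
        # one of 3 CG sites drops 30 points; the other two stay put
        _, mats = self._group_matrices({
            "AL": {30: 0.6, 90: 0.5, 140: 0.55},
            "DR": {30: 0.3, 90: 0.5, 140: 0.55},
        }, depth=2000, n=5)
        res = site_group_stats(mats)
        assert res.flagged_offsets("CG") == [30]

    def test_cg_and_ch_are_separate_bh_families(self):
        _, mats = self._group_matrices({
            "AL": {30: 0.6}, "DR": {30: 0.2}}, depth=1200, n=3)
        res = site_group_stats(mats)
        t = res.table
        # q within each context must equal BH over that context alone
        from dietmem import bh_adjust
        for context in ("CG", "CH"):
            sub = t[t["context"] == context]
            if len(sub):
                np.testing.assert_allclose(
                    sub["q"], bh_adjust(sub["p"].to_numpy()), rtol=1e-12)

    def test_single_group_matrix_rejected(self):
        _, mats = self._group_matrices({"AL": {30: 0.5}}, depth=1100, n=2)
        with pytest.raises(ValueError):
            site_group_stats(mats)
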