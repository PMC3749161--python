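"""SNP cascade, genotyping, depth-matching phasing, STR detection."""

import numpy as np
import pysam
import pytest

from rrlmarkers.cluster import ConsensusLocus
from rrlmarkers.variants import (PredictedSNP, PutativeSNP,
                                 call_genotypes, deduce_haplotypes,
                                 detect_strs, filter_snps, genotype_strs,
                                 group_str_loci,
                                 predict_snps, summarize_haplotypes,
                                 write_vcf, STR_THRESHOLDS)
from rrlmarkers.mapping import AlleleDepthTable

from oracles import enumerate_tandem_runs, straight_line_filter

B = "ACGT"
FOUNDERS = ("A", "B", "C", "D", "E")


def _site(locus, offset, rows):
    """rows: list of 5 dicts {base: depth}."""
    d = np.zeros((5, 4), dtype=np.int64)
    for fi, bd in enumerate(rows):
        for base, c in bd.items():
            d[fi, B.index(base)] = c
    return PredictedSNP(locus, offset, d)


class TestPredict:
    def _table(self, entries):
        table = AlleleDepthTable(FOUNDERS)
        for locus, offset, bd in entries:
            arr = table.locus_array(locus)
            for base, c in bd.items():
                arr[offset, 0, B.index(base)] = c
        return table

    def test_two_bases_above_floor_predicted(self):
        table = self._table([("L0", 5, {"A": 60, "G": 50})])
        [snp] = predict_snps(table)
        assert snp.pooled_depth == 110

    def test_monomorphic_not_predicted(self):
        table = self._table([("L0", 5, {"A": 99})])
        assert predict_snps(table) == []

    def test_below_depth_floor_not_predicted(self):
        table = self._table([("L0", 5, {"A": 60, "G": 30})])
        assert predict_snps(table) == []


class TestFilterCascade:
    def test_balanced_het_passes(self):
        site = _site("L0", 1, [{"C": 40, "T": 38}] + [{"C": 50}] * 4)
        [snp] = filter_snps([site])
        assert {snp.major, snp.minor} == {"C", "T"}

    def test_depth_cap_is_strict(self):
        over = _site("L0", 1, [{"C": 200, "T": 101}] + [{"C": 50, "T": 51}] * 4)
        assert filter_snps([over]) == []
        at_cap = _site("L0", 1, [{"C": 150, "T": 150}]
                       + [{"C": 50, "T": 51}] * 4)
        assert len(filter_snps([at_cap])) == 1

    def test_ratio_above_three_removed(self):
        site = _site("L0", 1, [{"C": 40, "T": 10}] + [{"C": 50}] * 4)
        assert filter_snps([site]) == []

    def test_duplicated_error_allele_removed_by_ratio(self):
        # a 2-read second allele sits below the presence line but still
        # trips the ratio rule in the founder carrying it
        site = _site("L0", 1, [{"T": 42, "G": 2}] + [{"T": 30}] * 4)
        assert filter_snps([site]) == []

    def test_depth_one_alleles_ignored(self):
        site = _site("L0", 1, [{"C": 40, "T": 1}, {"C": 30, "T": 30}]
                     + [{"C": 50}] * 3)
        [snp] = filter_snps([site])
        assert snp.depths[0, B.index("T")] == 0

    def test_three_present_alleles_discarded(self):
        site = _site("L0", 1, [{"A": 30, "C": 30, "G": 30}]
                     + [{"A": 50, "C": 40}] * 4)
        assert filter_snps([site]) == []

    def test_cascade_is_idempotent(self):
        rng = np.random.default_rng(0)
        sites = _random_sites(rng, 500)
        once = filter_snps(sites)
        again = filter_snps([s.to_predicted() for s in once])
        assert len(again) == len(once)
        for a, b in zip(once, again):
            assert (a.major, a.minor) == (b.major, b.minor)
            assert np.array_equal(a.depths, b.depths)

    def test_matches_straight_line_reimplementation(self):
        rng = np.random.default_rng(1)
        sites = _random_sites(rng, 10_000)
        ours = filter_snps(sites)
        oracle_in = []
        for s in sites:
            by_founder = {
                FOUNDERS[fi]: {B[bi]: int(s.depths[fi, bi])
                               for bi in range(4) if s.depths[fi, bi]}
                for fi in range(5)}
            oracle_in.append((s.locus_id, s.offset, by_founder))
        expected = straight_line_filter(oracle_in)
        assert [(s.locus_id, s.offset, s.major, s.minor) for s in ours] \
            == expected


def _random_sites(rng, n):
    """Randomised depth tables exercising every rule branch."""
    sites = []
    for i in range(n):
        d = np.zeros((5, 4), dtype=np.int64)
        n_alleles = rng.choice([1, 2, 2, 2, 3])
        alleles = rng.choice(4, size=n_alleles, replace=False)
        for fi in range(5):
            total = int(rng.integers(10, 400))
            w = rng.dirichlet(np.ones(n_alleles) * rng.uniform(0.2, 3.0))
            counts = np.floor(w * total).astype(int)
            for a, c in zip(alleles, counts):
                d[fi, a] = c
        # sprinkle depth-1 artefacts
        for fi in range(5):
            if rng.random() < 0.3:
                d[fi, rng.integers(0, 4)] = 1
        sites.append(PredictedSNP(f"L{i // 7:04d}", i % 202, d))
    return sites


class TestGenotypes:
    def test_het_hom_and_rule1_interaction(self):
        sites = [
            _site("L0", 1, [{"C": 30, "T": 25}, {"C": 30, "T": 1},
                            {"C": 40}, {"T": 40}, {"C": 22, "T": 21}]),
        ]
        putative = filter_snps(sites)
        matrix = call_genotypes(putative, FOUNDERS)
        assert matrix.n_loci == 1
        row = matrix.df.iloc[0]
        assert row["major"] == "C" and row["minor"] == "T"
        assert row["A"] == 1          # het
        assert row["B"] == 2          # depth-1 minor ignored -> hom major
        assert row["C"] == 2
        assert row["D"] == 0          # hom minor
        assert row["E"] == 1

    def test_founder_below_depth_floor_excludes_site(self):
        sites = [_site("L0", 1, [{"C": 10, "T": 9}] + [{"C": 30, "T": 30}] * 4)]
        putative = filter_snps(sites)
        assert len(putative) == 1
        matrix = call_genotypes(putative, FOUNDERS, min_founder_depth=20)
        assert matrix.n_loci == 0

    def test_matrix_consistent_with_presence(self, small_result):
        m = small_result.genotypes
        putative = {(s.locus_id, s.offset): s for s in small_result.putative}
        for _, row in m.df.iterrows():
            snp = putative[(row["locus_id"], row["offset"])]
            for fi, fid in enumerate(FOUNDERS):
                maj = snp.present[fi, snp.major_idx]
                mino = snp.present[fi, snp.minor_idx]
                expected = 1 if (maj and mino) else (2 if maj else 0)
                assert row[fid] == expected


class TestHaplotypes:
    def _snp(self, locus, offset, a1, d1, a2, d2):
        d = np.zeros((5, 4), dtype=np.int64)
        d[0, B.index(a1)] = d1
        d[0, B.index(a2)] = d2
        present = d > 0
        major, minor = (a1, a2) if d1 >= d2 else (a2, a1)
        return PutativeSNP(locus, offset, major, minor, d, present)

    def test_clean_phase_two_haplotypes(self):
        snps = [self._snp("L0", 1, "A", 30, "G", 20),
                self._snp("L0", 2, "C", 30, "T", 20)]
        hs = deduce_haplotypes(snps)
        assert hs.status == "determined"
        assert len(hs.haplotypes) == 2
        alleles = sorted(tuple(sorted(h[0].items())) for h in hs.haplotypes)
        assert alleles == [(((1, "A")), (2, "C")), ((1, "G"), (2, "T"))]

    def test_symmetric_depths_are_undetermined(self):
        snps = [self._snp("L0", 1, "A", 30, "G", 28),
                self._snp("L0", 2, "C", 29, "T", 27)]
        hs = deduce_haplotypes(snps, tolerance=4)
        assert hs.status == "undetermined"

    def test_single_offset_locus_rejected(self):
        with pytest.raises(ValueError):
            deduce_haplotypes([self._snp("L0", 1, "A", 30, "G", 20)])

    def test_well_separated_planted_haplotypes_recovered(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            n_offsets = int(rng.integers(2, 5))
            offsets = sorted(rng.choice(202, n_offsets, replace=False))
            d1 = int(rng.integers(40, 200))
            d2 = d1 + int(rng.integers(10, 80))  # separation >= tolerance
            truth = {}
            snps = []
            for off in offsets:
                a, b = rng.choice(4, 2, replace=False)
                truth[off] = (B[b], B[a])  # (deep allele, shallow allele)
                snps.append(self._snp("L0", int(off), B[a], d1, B[b], d2))
            hs = deduce_haplotypes(snps, tolerance=4.0)
            assert hs.status == "determined"
            deep = next(h for h in hs.haplotypes
                        if abs(h[1] - d2) < abs(h[1] - d1))
            for off, (deep_allele, _) in truth.items():
                assert deep[0][off] == deep_allele

    def test_depth_conservation_on_determined_loci(self, small_result):
        putative = {}
        for s in small_result.putative:
            putative.setdefault(s.locus_id, []).append(s)
        for hs in small_result.haplotype_sets:
            if hs.status != "determined":
                continue
            snps = {s.offset: s for s in putative[hs.locus_id]}
            for off in hs.offsets:
                pooled = snps[off].depths.sum()
                total = sum(h[1] for h in hs.haplotypes)
                assert abs(total - pooled) < 4 * len(hs.haplotypes)

    def test_summary_histogram_conserves_determined_loci(self, small_result):
        hist, pct = summarize_haplotypes(small_result.haplotype_sets)
        n_det = sum(1 for h in small_result.haplotype_sets
                    if h.status == "determined")
        assert hist.sum() == n_det
        if small_result.haplotype_sets:
            assert pct is not None

    def test_empty_input_summary(self):
        hist, pct = summarize_haplotypes([])
        assert hist.empty and pct is None


def _locus_with(segment_fwd, lid="L0"):
    pad = "A" if not segment_fwd.startswith("A") else "G"
    fwd = (segment_fwd + pad * 101)[:101]
    return ConsensusLocus(lid, "HAEIII_BOTH", fwd + "N" * 98 + "G" * 101, 30)


class TestDetectSTRs:
    def test_dinucleotide_threshold_boundary(self):
        hit = _locus_with("TT" + "AC" * 8 + "TT")
        miss = _locus_with("TT" + "AC" * 7 + "TT")
        found = detect_strs([hit])
        assert any(c.motif == "AC" and c.count == 8 for c in found)
        assert not any(c.motif == "AC"
                       for c in detect_strs([miss]))

    def test_tri_and_tetra_thresholds(self):
        tri = _locus_with("TT" + "AGG" * 5 + "TT")
        tetra = _locus_with("TT" + "AGAT" * 4 + "TT")
        assert any(c.motif == "AGG" and c.count == 5
                   for c in detect_strs([tri]))
        assert any(c.motif == "AGAT" and c.count == 4
                   for c in detect_strs([tetra]))

    def test_subperiodic_motifs_excluded(self):
        locus = _locus_with("TT" + "ATAT" * 5 + "GG")
        found = detect_strs([locus])
        assert all(len(c.motif) == 2 for c in found)

    def test_matches_brute_force_enumerator(self):
        rng = np.random.default_rng(3)
        for _ in range(30):
            seg = list(rng.choice(list("ACGT"), 101))
            motif = ["AC", "AGG", "AGAT"][rng.integers(0, 3)]
            count = int(rng.integers(3, 10))
            start = int(rng.integers(0, 101 - len(motif) * count))
            seg[start:start + len(motif) * count] = list(motif * count)
            seg = "".join(seg)[:101]
            locus = ConsensusLocus("L0", "HAEIII_BOTH",
                                   seg + "N" * 98 + "T" * 101, 30)
            ours = {(c.start, len(c.motif), c.count, c.region_len)
                    for c in detect_strs([locus]) if c.segment == "fwd"}
            expected = enumerate_tandem_runs(seg, STR_THRESHOLDS)
            assert ours == expected


class TestGroupAndGenotypeSTRs:
    def _allele_pair(self, count_a=8, count_b=10):
        rng = np.random.default_rng(4)
        left = "".join(rng.choice(list("ACGT"), 20))
        right = "".join(rng.choice(list("ACGT"), 70))
        loci = []
        for lid, count in (("L0", count_a), ("L1", count_b)):
            seg = (left + "AC" * count + right)[:101]
            loci.append(ConsensusLocus(lid, "HAEIII_BOTH",
                                       seg + "N" * 98 + "T" * 101, 30))
        return loci

    def test_allele_pair_merges_into_one_locus(self):
        loci = self._allele_pair()
        groups = group_str_loci(detect_strs(loci))
        assert len(groups) == 1
        assert groups[0].alleles == [8, 10]

    def test_distant_flanks_do_not_merge(self):
        rng = np.random.default_rng(5)
        loci = self._allele_pair()
        seg = list(loci[1].sequence[:101])
        flank_pos = [i for i in range(101)
                     if not (20 <= i < 40)]  # outside the run
        for pos in rng.choice(flank_pos, 10, replace=False):
            seg[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[seg[pos]]
        loci[1] = ConsensusLocus("L1", "HAEIII_BOTH",
                                 "".join(seg) + "N" * 98 + "T" * 101, 30)
        groups = group_str_loci(detect_strs(loci))
        assert len(groups) == 2

    def test_genotype_calls_follow_presence_and_depth_rules(self):
        loci = self._allele_pair()
        groups = group_str_loci(detect_strs(loci))
        pair_counts = {("L0", "A"): 15, ("L1", "A"): 14,   # het 8/10
                       ("L0", "B"): 25, ("L1", "B"): 0,    # hom 8/8
                       ("L0", "C"): 9, ("L1", "C"): 6}     # below floor
        df = genotype_strs(groups, pair_counts, ("A", "B", "C"))
        row = df.iloc[0]
        assert row["A"] == "8/10"
        assert row["B"] == "8/8"
        assert row["C"] is None

    def test_planted_strs_recovered_from_simulation(self, clean_result):
        ev = clean_result.str_eval
        assert ev.exact
        # genotypes agree with planted repeat counts per founder
        truth = clean_result.sim.truth
        df = clean_result.str_genotypes
        called = {}
        for _, row in df.iterrows():
            alleles = tuple(int(a) for a in row["alleles"].split(","))
            called[(row["motif"], alleles)] = row
        for rec in truth.strs.itertuples():
            counts = sorted({int(getattr(rec, f"{f}_h{h}"))
                             for f in FOUNDERS for h in (1, 2)})
            row = called.get((rec.motif, tuple(counts)))
            assert row is not None
            for fid in FOUNDERS:
                gt = row[fid]
                if gt is None:
                    continue
                want = sorted([getattr(rec, f"{fid}_h1"),
                               getattr(rec, f"{fid}_h2")])
                assert gt == f"{want[0]}/{want[1]}"


class TestVCF:
    def test_round_trips_through_pysam(self, tmp_path, small_result):
        path = tmp_path / "putative.vcf"
        write_vcf(small_result.putative, FOUNDERS, path)
        with pysam.VariantFile(str(path)) as vcf:
            assert list(vcf.header.samples) == list(FOUNDERS)
            records = list(vcf)
        assert len(records) == len(small_result.putative)
        by_key = {(s.locus_id, s.offset): s for s in small_result.putative}
        for rec in records:
            offset = rec.pos - 1 if rec.pos <= 101 else rec.pos - 99
            snp = by_key[(rec.chrom, offset)]
            assert rec.ref == snp.major and rec.alts == (snp.minor,)
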