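"""Paternal chromosome assignment, marker collapsing, two-point linkage."""

import numpy as np
import pytest

import radprint as rp
from radprint.chromprint import SegregationPattern
from radprint.patmap import order_exhaustive, order_greedy, _adjacent_cost

from conftest import print_to_true_chromosome

P = SegregationPattern.from_string
TAG = "ACGT" * 10
OTHER = {"A": "C", "C": "G", "G": "T", "T": "A"}


def mutate(seq, k):
    out = list(seq)
    for i in range(k):
        out[i] = OTHER[out[i]]
    return "".join(out)


def rec(seq=TAG, present=()):
    return rp.AlleleRecord(seq=seq, present=set(present))


def marker(pattern, marker_id=1, chrom=1, n=3):
    return rp.RadMarker(marker_id=marker_id, chrom_id=chrom, pattern=P(pattern),
                        allele_count=n)


class TestPaternalCandidates:
    def make_loci(self):
        prog = [f"p{i}" for i in range(20)]
        return [rp.MergedLocus("l0", [
            rec("A" * 40, {"father", *prog[:12]}),        # father-only, segregating
            rec("C" * 40, {"father", *prog}),             # father-only, all progeny
            rec("G" * 40, {"father", "mother", "p0"}),    # biparental
        ])], prog

    def test_segregating_father_allele_included(self):
        loci, prog = self.make_loci()
        cands = rp.paternal_candidates(loci, "mother", "father", prog)
        assert [c[0].seq for c in cands] == ["A" * 40]
        assert sum(cands[0][1].bits) == 12

    def test_non_segregating_and_biparental_excluded(self):
        loci, prog = self.make_loci()
        seqs = {c[0].seq for c in rp.paternal_candidates(loci, "mother", "father", prog)}
        assert "C" * 40 not in seqs and "G" * 40 not in seqs


class TestAssignByAllelism:
    def test_single_chromosome_match_assigned(self):
        paternal = [(rec(mutate(TAG, 2)), P("10" * 10))]
        out = rp.assign_by_allelism(paternal, {TAG: 5})
        assert out[0].chrom_id == 5 and out[0].basis == "allelism"
        assert out[0].partner_seq == TAG

    def test_multi_chromosome_match_unassigned(self):
        maternal = {TAG: 3, mutate(TAG, 1): 7}
        out = rp.assign_by_allelism([(rec(mutate(TAG, 2)), P("10" * 10))], maternal)
        assert out[0].chrom_id is None and out[0].basis == "unassigned"

    def test_no_match_within_three_unassigned(self):
        out = rp.assign_by_allelism([(rec(mutate(TAG, 4)), P("10" * 10))], {TAG: 5})
        assert out[0].chrom_id is None


class TestPropagatePatterns:
    def anchored(self, pattern, chrom=9):
        a = rp.PaternalAssignment(allele=rec(seq="anchor"), pattern=P(pattern),
                                  chrom_id=chrom, basis="allelism")
        return a

    def test_identical_pattern_assigned(self):
        unk = rp.PaternalAssignment(allele=rec(seq="x"), pattern=P("1100110011"))
        out = rp.propagate_patterns([self.anchored("1100110011"), unk])
        assert out[1].chrom_id == 9 and out[1].basis == "identical-pattern"

    def test_inverse_pattern_assigned(self):
        unk = rp.PaternalAssignment(allele=rec(seq="x"), pattern=P("0011001100"))
        out = rp.propagate_patterns([self.anchored("1100110011"), unk])
        assert out[1].chrom_id == 9 and out[1].basis == "inverse-pattern"

    def test_one_off_pattern_assigned(self):
        unk = rp.PaternalAssignment(allele=rec(seq="x"), pattern=P("1100110010"))
        out = rp.propagate_patterns([self.anchored("1100110011"), unk])
        assert out[1].chrom_id == 9 and out[1].basis == "one-off-pattern"

    def test_two_off_pattern_stays_unassigned(self):
        unk = rp.PaternalAssignment(allele=rec(seq="x"), pattern=P("1100110000"))
        out = rp.propagate_patterns([self.anchored("1100110011"), unk])
        assert out[1].chrom_id is None

    def test_conflicting_anchors_leave_unassigned(self):
        unk = rp.PaternalAssignment(allele=rec(seq="x"), pattern=P("1100110011"))
        out = rp.propagate_patterns([self.anchored("1100110011", 1),
                                     self.anchored("1100110011", 2), unk])
        assert out[2].chrom_id is None


class TestCollapseMarkers:
    def assignment(self, pattern, chrom=1, seq="s"):
        return rp.PaternalAssignment(allele=rec(seq=seq), pattern=P(pattern),
                                     chrom_id=chrom, basis="allelism")

    def test_five_alleles_one_marker(self):
        asg = [self.assignment("10101", seq=f"s{i}") for i in range(5)]
        markers = rp.collapse_markers(asg)
        assert len(markers) == 1 and markers[0].allele_count == 5

    def test_two_alleles_discarded(self):
        asg = [self.assignment("10101", seq=f"s{i}") for i in range(2)]
        assert rp.collapse_markers(asg) == []

    def test_phase_convention_merges_complements(self):
        asg = [self.assignment("10101", seq=f"s{i}") for i in range(3)]
        asg += [self.assignment("01010", seq=f"t{i}") for i in range(2)]
        markers = rp.collapse_markers(asg)
        assert len(markers) == 1 and markers[0].allele_count == 5

    def test_marker_name_layout(self):
        m = rp.RadMarker(marker_id=7, chrom_id=3, pattern=P("101"), allele_count=12)
        assert m.name == "7_3_12"


class TestTwoPointStats:
    def test_identical_patterns(self):
        m1, m2 = marker("1" * 10 + "0" * 10), marker("1" * 10 + "0" * 10)
        r, lod = rp.two_point_stats(m1, m2)
        assert r == 0.0
        assert lod == pytest.approx(20 * np.log10(2), abs=1e-6)
        assert lod == pytest.approx(6.0206, abs=1e-4)

    def test_complement_patterns_fold_to_zero(self):
        m1, m2 = marker("1" * 10 + "0" * 10), marker("0" * 10 + "1" * 10)
        r, lod = rp.two_point_stats(m1, m2)
        assert r == 0.0 and lod == pytest.approx(6.0206, abs=1e-4)

    def test_independence_gives_zero_lod(self):
        m1, m2 = marker("10" * 10), marker("11" * 5 + "00" * 5)
        assert m1.pattern.hamming(m2.pattern) == 10
        r, lod = rp.two_point_stats(m1, m2)
        assert r == 0.5 and lod == pytest.approx(0.0, abs=1e-12)

    def test_empty_progeny_rejected(self):
        m = rp.RadMarker(1, 1, SegregationPattern(()), 3)
        with pytest.raises(ValueError):
            rp.two_point_stats(m, m)

    @pytest.mark.parametrize("R", range(0, 11))
    def test_lod_matches_brute_force_grid(self, R):
        """The closed form equals the maximum over a dense r-grid of the
        backcross likelihood ratio, attained at r = R/N."""
        N = 20
        pattern = "1" * N
        other = "0" * R + "1" * (N - R)
        _, lod = rp.two_point_stats(marker(pattern), marker(other))
        grid = np.linspace(1e-9, 0.5, 20001)
        loglik = (N - R) * np.log10(1 - grid) + R * np.log10(grid) + N * np.log10(2)
        assert lod == pytest.approx(float(loglik.max()), abs=1e-5)
        if 0 < R < N / 2:
            assert grid[np.argmax(loglik)] == pytest.approx(R / N, abs=1e-3)


class TestOrdering:
    @pytest.mark.parametrize("seed", range(8))
    def test_greedy_matches_exhaustive(self, seed):
        """Greedy nearest-neighbour + 2-opt reaches the exhaustive optimum
        for up to 8 markers."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 9))
        pts = rng.integers(0, 2, (n, 20))
        dist = np.array([[min(int((pts[i] != pts[j]).sum()),
                              20 - int((pts[i] != pts[j]).sum()))
                          for j in range(n)] for i in range(n)])
        greedy = order_greedy(dist)
        best = order_exhaustive(dist)
        assert _adjacent_cost(greedy, dist) == _adjacent_cost(best, dist)


class TestBuildGroups:
    def test_one_recombinant_is_five_centimorgan(self):
        m1 = marker("1" * 10 + "0" * 10, 1)
        m2 = marker("1" * 10 + "0" * 9 + "1", 2)
        groups = rp.build_groups([m1, m2])
        assert len(groups) == 1
        assert groups[0].distances_cm == [5.0]

    def test_six_recombinants_not_grouped(self):
        m1 = marker("1" * 10 + "0" * 10, 1)
        m2 = marker("1" * 4 + "0" * 6 + "0" * 10, 2)
        assert m1.pattern.hamming(m2.pattern) == 6
        groups = rp.build_groups([m1, m2])
        assert len(groups) == 2

    def test_single_marker_group_has_zero_length(self):
        groups = rp.build_groups([marker("10" * 10)])
        assert groups[0].length_cm == 0.0

    def test_chain_ordering_minimizes_recombinants(self):
        base = "1" * 20
        patterns = [base, "0" + base[1:], "00" + base[2:], "000" + base[3:]]
        markers = [marker(p, i + 1) for i, p in enumerate(patterns)]
        rng = np.random.default_rng(0)
        rng.shuffle(markers)
        groups = rp.build_groups(markers)
        assert len(groups) == 1
        assert groups[0].distances_cm == [5.0, 5.0, 5.0]
        assert groups[0].length_cm == 15.0

    def test_order_invariance(self):
        rng = np.random.default_rng(4)
        base = np.zeros(20, dtype=int)
        markers = []
        pos = base.copy()
        for i in range(6):
            flip = rng.integers(0, 20)
            pos = pos.copy()
            pos[flip] ^= 1
            markers.append(rp.RadMarker(i + 1, 1, SegregationPattern(tuple(pos)), 3))
        g1 = rp.build_groups(markers)
        shuffled = list(markers)
        rng.shuffle(shuffled)
        g2 = rp.build_groups(shuffled)
        assert sorted(g.length_cm for g in g1) == sorted(g.length_cm for g in g2)
        sets1 = sorted(sorted(m.marker_id for m in g.markers) for g in g1)
        sets2 = sorted(sorted(m.marker_id for m in g.markers) for g in g2)
        assert sets1 == sets2

    def test_phase_fold_invariance(self):
        """Complementing any marker's pattern changes nothing downstream."""
        patterns = ["11111000000000000000", "11110000000000000000",
                    "11000000000000000000"]
        ms = [marker(p, i + 1) for i, p in enumerate(patterns)]
        flipped = [rp.RadMarker(m.marker_id, m.chrom_id,
                                m.pattern.complement() if i == 1 else m.pattern,
                                m.allele_count) for i, m in enumerate(ms)]
        g1, g2 = rp.build_groups(ms), rp.build_groups(flipped)
        assert [g.length_cm for g in g1] == [g.length_cm for g in g2]
        assert [[m.marker_id for m in g.markers] for g in g1] == \
            [[m.marker_id for m in g.markers] for g in g2]

    def test_cm_per_event_override(self):
        m1 = marker("1" * 10 + "0" * 10, 1)
        m2 = marker("1" * 10 + "0" * 9 + "1", 2)
        groups = rp.build_groups([m1, m2], cm_per_event=2.5)
        assert groups[0].distances_cm == [2.5]


class TestMapStats:
    def test_published_density_arithmetic(self):
        g = rp.LinkageGroup(1, 1, [marker("10" * 10), marker("10" * 10)], [1292.0])
        stats = rp.map_stats([g], genome_size_bp=int(339.4e6))
        assert stats.total_cm == 1292.0
        assert stats.kb_per_cm == 262.7

    def test_single_group_total(self):
        g = rp.LinkageGroup(1, 1, [marker("10" * 10)] * 2, [10.0])
        assert rp.map_stats([g]).total_cm == 10.0

    def test_zero_length_map_has_undefined_density(self):
        g = rp.LinkageGroup(1, 1, [marker("10" * 10)], [])
        assert rp.map_stats([g], genome_size_bp=10 ** 6).kb_per_cm is None


class TestSimulatedRecovery:
    def test_allelism_and_propagation_recover_true_chromosomes(self, midsim):
        """On error-free simulated data, every paternal allele within 3
        mismatches of a maternal allele lands on its true chromosome."""
        truth = midsim["truth"]
        to_true = print_to_true_chromosome(truth, midsim["prints"])
        true_paternal = truth.informative_paternal_alleles()
        maternal = truth.informative_maternal_alleles()
        assigned = {a.allele.seq: a for a in midsim["assignments"]}

        def hamming(a, b):
            return sum(x != y for x, y in zip(a, b))

        n_eligible = 0
        for seq, true_chrom in true_paternal.items():
            asg = assigned.get(seq)
            if asg is None:
                continue
            # anchor-eligible: all maternal alleles within 3 mismatches agree
            chroms = {c for m, (c, _h) in maternal.items() if hamming(seq, m) <= 3}
            if chroms == {true_chrom}:
                n_eligible += 1
                assert asg.chrom_id is not None, seq
            if asg.chrom_id is not None:
                assert to_true[asg.chrom_id] == true_chrom
        assert n_eligible >= 15  # enough anchor-eligible cases to be meaningful

    def test_map_length_tracks_simulated_genetic_length(self, tmp_path):
        """Total map length is within 25% of the true genetic length when
        markers densely cover the chromosomes."""
        cfg = rp.SimConfig(n_chromosomes=3, loci_per_chromosome=150, n_progeny=20,
                           paternal_het_rate=0.9, maternal_het_rate=0.9,
                           per_base_error=0.0, seed=23,
                           min_informative_per_chromosome=20)
        truth = rp.simulate_pedigree(cfg)
        # build markers directly from the truth: the paternal mapping input
        progeny = truth.progeny_ids
        true_paternal = truth.informative_paternal_alleles()
        assignments = []
        for seq, chrom in true_paternal.items():
            bits = truth.expected_pattern(seq, progeny)
            p = SegregationPattern(bits)
            if p.is_constant:
                continue
            assignments.append(rp.PaternalAssignment(
                allele=rec(seq=seq), pattern=p, chrom_id=chrom, basis="allelism"))
        markers = rp.collapse_markers(assignments)
        groups = rp.build_groups(markers)
        total = rp.map_stats(groups).total_cm
        # true genetic length: crossovers that occurred within each chromosome
        true_cm = sum(len(pos) for per_prog in truth.crossovers
                      for pos in per_prog) * (100.0 / cfg.n_progeny)
        assert total == pytest.approx(true_cm, rel=0.25)
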