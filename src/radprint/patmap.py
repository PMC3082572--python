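"""Paternal linkage map from segregating RAD markers.

Crossing over happens only in male meiosis here, so paternally derived
segregating alleles carry recombination information.  They are first
anchored to chromosomes through allelic homology with the maternally
derived, chromosome-assigned alleles (same locus, at most 3 base
differences), then propagated by segregation pattern (identical, inverse,
one genotype off).  Patterns supported by at least three alleles become RAD
markers, which are grouped and ordered by two-point linkage.

For a backcross of N progeny with R observed recombinants between two
markers (phase-folded: R = min(H, N-H) for pattern Hamming distance H), the
two-point LOD against independent assortment at the MLE r = R/N is

    LOD = log10( (1-r)^(N-R) * r^R / 0.5^N )

with the r = 0 limit N*log10(2).  Distances use the small-sample convention
of 100/N cM per crossover event (5 cM at N = 20).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .chromprint import SegregationPattern, catalog_individuals
from .crosscat import AlleleRecord, MergedLocus
from .tagcall import _BASE_CODE

logger = logging.getLogger(__name__)

DEFAULT_ALLELISM_MISMATCHES = 3
DEFAULT_MIN_ALLELES = 3
DEFAULT_LOD_GROUP = 2.0
DEFAULT_MAX_LINK_DIFFS = 5
EXHAUSTIVE_ORDER_LIMIT = 8


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class PaternalAssignment:
    """Chromosome assignment state of one paternal segregating allele."""

    allele: AlleleRecord
    pattern: SegregationPattern
    chrom_id: int | None = None
    basis: str = "unassigned"   # allelism | identical-pattern | inverse-pattern | one-off-pattern
    partner_seq: str | None = None  # maternal partner when basis == allelism


@dataclass
class RadMarker:
    """A (phase-folded) paternal segregation pattern with >= 3 alleles."""

    marker_id: int
    chrom_id: int | None
    pattern: SegregationPattern
    allele_count: int
    member_alleles: list[AlleleRecord] = field(default_factory=list)

    @property
    def name(self) -> str:
        """JoinMap-style ``i_ii_iii`` label: marker, chromosome, allele count."""
        chrom = self.chrom_id if self.chrom_id is not None else 0
        return f"{self.marker_id}_{chrom}_{self.allele_count}"


@dataclass
class LinkageGroup:
    """An ordered run of linked markers on one chromosome."""

    chrom_id: int | None
    component: int
    markers: list[RadMarker]
    distances_cm: list[float]

    @property
    def length_cm(self) -> float:
        return float(sum(self.distances_cm))


@dataclass
class MapStats:
    total_cm: float
    n_groups: int
    n_markers: int
    kb_per_cm: float | None = None


# ---------------------------------------------------------------------------
# Candidate extraction and chromosome assignment
# ---------------------------------------------------------------------------

def paternal_candidates(loci: Sequence[MergedLocus], mother_id: str, father_id: str,
                        progeny_order: Sequence[str],
                        ) -> list[tuple[AlleleRecord, SegregationPattern]]:
    """Alleles present in the father, absent from the mother, and segregating
    (pattern neither all-ones nor all-zeros) with their progeny patterns."""
    individuals = catalog_individuals(loci)
    for who, ind in (("mother", mother_id), ("father", father_id)):
        if ind not in individuals:
            raise KeyError(f"{who} {ind!r} absent from catalog")
    out = []
    for locus in loci:
        for a in locus.alleles:
            if father_id in a.present and mother_id not in a.present:
                pattern = SegregationPattern(
                    tuple(1 if p in a.present else 0 for p in progeny_order))
                if not pattern.is_constant:
                    out.append((a, pattern))
    return out


def _cross_hamming_hits(query: Sequence[str], targets: Sequence[str],
                        max_mismatches: int, block: int = 2048) -> list[list[int]]:
    """For each query sequence, indices of targets within max_mismatches."""
    if not query or not targets:
        return [[] for _ in query]
    L = len(query[0])

    def onehot(seqs):
        mat = np.frombuffer("".join(seqs).encode(), dtype=np.uint8).reshape(len(seqs), L)
        codes = _BASE_CODE[mat]
        oh = np.zeros((len(seqs), L * 4), dtype=np.float32)
        flat = np.arange(L) * 4
        for i in range(len(seqs)):
            oh[i, flat + codes[i]] = 1.0
        return oh

    q_oh, t_oh = onehot(query), onehot(targets)
    hits: list[list[int]] = [[] for _ in query]
    for start in range(0, len(query), block):
        stop = min(len(query), start + block)
        ham = L - q_oh[start:stop] @ t_oh.T
        r, c = np.nonzero(ham <= max_mismatches + 1e-6)
        for a, b in zip(r, c):
            hits[start + a].append(int(b))
    return hits


def assign_by_allelism(paternal: Sequence[tuple[AlleleRecord, SegregationPattern]],
                       maternal_assigned: Mapping[str, int],
                       mismatches: int = DEFAULT_ALLELISM_MISMATCHES,
                       ) -> list[PaternalAssignment]:
    """Anchor paternal alleles to chromosomes via allelic homology.

    A paternal allele is assigned if and only if every maternal allele within
    ``mismatches`` base differences lies on a single chromosome; zero matches
    or matches on multiple chromosomes leave it unassigned.
    """
    assignments = [PaternalAssignment(allele=a, pattern=p) for a, p in paternal]
    if not maternal_assigned:
        return assignments
    m_seqs = sorted(maternal_assigned)
    hits = _cross_hamming_hits([a.allele.seq for a in assignments], m_seqs, mismatches)
    for asg, hit in zip(assignments, hits):
        chroms = {maternal_assigned[m_seqs[i]] for i in hit}
        if len(chroms) == 1:
            asg.chrom_id = chroms.pop()
            asg.basis = "allelism"
            asg.partner_seq = m_seqs[hit[0]]
    return assignments


def propagate_patterns(assignments: Sequence[PaternalAssignment],
                       ) -> list[PaternalAssignment]:
    """Spread chromosome assignments by segregation pattern.

    Three passes in order: identical pattern, exact complement, then patterns
    one genotype away (phase-folded).  Each pass assigns an unassigned allele
    only when all matching anchored patterns agree on one chromosome;
    disagreements are logged and left unassigned.
    """
    assignments = list(assignments)

    def anchors() -> dict[SegregationPattern, set[int]]:
        out: dict[SegregationPattern, set[int]] = {}
        for a in assignments:
            if a.chrom_id is not None:
                out.setdefault(a.pattern, set()).add(a.chrom_id)
        return out

    def run_pass(basis: str, candidate_chroms) -> None:
        anc = anchors()
        for a in assignments:
            if a.chrom_id is not None:
                continue
            chroms = candidate_chroms(a.pattern, anc)
            if len(chroms) == 1:
                a.chrom_id = chroms.pop()
                a.basis = basis
            elif len(chroms) > 1:
                logger.warning("pattern %s claimed by chromosomes %s; left unassigned",
                               a.pattern, sorted(chroms))

    run_pass("identical-pattern", lambda p, anc: set(anc.get(p, ())))
    run_pass("inverse-pattern", lambda p, anc: set(anc.get(p.complement(), ())))

    def one_off(p: SegregationPattern, anc) -> set[int]:
        chroms: set[int] = set()
        pc = p.complement()
        for q, cs in anc.items():
            if min(p.hamming(q), pc.hamming(q)) == 1:
                chroms.update(cs)
        return chroms

    run_pass("one-off-pattern", one_off)
    return assignments


# ---------------------------------------------------------------------------
# Marker collapsing
# ---------------------------------------------------------------------------

def fold_pattern(pattern: SegregationPattern) -> SegregationPattern:
    """Canonical phase: the lexicographically smaller of pattern/complement."""
    comp = pattern.complement()
    return pattern if str(pattern) <= str(comp) else comp


def collapse_markers(assignments: Sequence[PaternalAssignment],
                     min_alleles: int = DEFAULT_MIN_ALLELES) -> list[RadMarker]:
    """Collapse alleles into markers by (chromosome, phase-folded pattern).

    A pattern and its complement are the same marker position observed in the
    two phases.  Groups with fewer than ``min_alleles`` alleles are discarded
    as insufficiently supported.
    """
    groups: dict[tuple, list[PaternalAssignment]] = {}
    for a in assignments:
        key = (a.chrom_id if a.chrom_id is not None else -1, fold_pattern(a.pattern))
        groups.setdefault(key, []).append(a)
    markers = []
    for (chrom, pattern), members in sorted(groups.items(), key=lambda kv: (kv[0][0], str(kv[0][1]))):
        if len(members) < min_alleles:
            continue
        markers.append(RadMarker(
            marker_id=len(markers) + 1,
            chrom_id=None if chrom == -1 else chrom,
            pattern=pattern,
            allele_count=len(members),
            member_alleles=[m.allele for m in members],
        ))
    return markers


# ---------------------------------------------------------------------------
# Two-point linkage
# ---------------------------------------------------------------------------

def recombinant_count(p1: SegregationPattern, p2: SegregationPattern) -> int:
    """Phase-folded recombinant count between two backcross patterns."""
    n = p1.n_progeny
    h = p1.hamming(p2)
    return min(h, n - h)


def two_point_stats(m1: RadMarker, m2: RadMarker) -> tuple[float, float]:
    """(recombination fraction, LOD) for a backcross marker pair."""
    n = m1.pattern.n_progeny
    if n == 0 or m2.pattern.n_progeny != n:
        raise ValueError("markers must share a non-empty progeny set")
    r_count = recombinant_count(m1.pattern, m2.pattern)
    r = r_count / n
    if r_count == 0:
        lod = n * np.log10(2.0)
    else:
        lod = ((n - r_count) * np.log10(1.0 - r) if r < 1.0 else 0.0) \
            + r_count * np.log10(r) + n * np.log10(2.0)
    return r, float(lod)


# ---------------------------------------------------------------------------
# Ordering
# ---------------------------------------------------------------------------

def _adjacent_cost(order: Sequence[int], dist: np.ndarray) -> int:
    return int(sum(dist[order[i], order[i + 1]] for i in range(len(order) - 1)))


def order_exhaustive(dist: np.ndarray) -> list[int]:
    """Best order by total adjacent recombinants over all permutations."""
    n = dist.shape[0]
    best, best_cost = list(range(n)), None
    for perm in itertools.permutations(range(n)):
        if n > 1 and perm[0] > perm[-1]:
            continue  # orientation-symmetric
        cost = _adjacent_cost(perm, dist)
        if best_cost is None or cost < best_cost:
            best, best_cost = list(perm), cost
    return best


def order_greedy(dist: np.ndarray) -> list[int]:
    """Greedy nearest-neighbour chain with 2-opt improvement."""
    n = dist.shape[0]
    if n <= 2:
        return list(range(n))
    best_order, best_cost = None, None
    for start in range(n):
        order = [start]
        left = set(range(n)) - {start}
        while left:
            nxt = min(left, key=lambda j: (dist[order[-1], j], j))
            order.append(nxt)
            left.remove(nxt)
        cost = _adjacent_cost(order, dist)
        if best_cost is None or cost < best_cost:
            best_order, best_cost = order, cost
    # 2-opt: reverse segments while it helps
    improved = True
    while improved:
        improved = False
        for i in range(len(best_order) - 1):
            for j in range(i + 1, len(best_order)):
                cand = best_order[:i] + best_order[i:j + 1][::-1] + best_order[j + 1:]
                cost = _adjacent_cost(cand, dist)
                if cost < best_cost:
                    best_order, best_cost = cand, cost
                    improved = True
    return best_order


def build_groups(markers: Sequence[RadMarker],
                 lod_group: float = DEFAULT_LOD_GROUP,
                 max_link_diffs: int = DEFAULT_MAX_LINK_DIFFS,
                 cm_per_event: float | None = None) -> list[LinkageGroup]:
    """Group and order markers into linkage groups.

    Markers are grouped within their chromosome (chromosome-less markers are
    grouped de novo) whenever LOD exceeds ``lod_group`` AND the folded
    recombinant count is at most ``max_link_diffs``; each connected component
    is ordered to minimize total adjacent recombinants (exhaustively for <= 8
    markers, greedy nearest-neighbour with 2-opt otherwise).  Adjacent
    distances are ``recombinants * cm_per_event`` with the default convention
    100/N cM per event.  Markers joining no component become singleton groups.
    """
    groups: list[LinkageGroup] = []
    by_chrom: dict[int, list[RadMarker]] = {}
    for m in markers:
        by_chrom.setdefault(m.chrom_id if m.chrom_id is not None else -1, []).append(m)
    for chrom in sorted(by_chrom):
        ms = by_chrom[chrom]
        n = len(ms)
        cm = cm_per_event if cm_per_event is not None else 100.0 / ms[0].pattern.n_progeny
        dist = np.zeros((n, n), dtype=int)
        linked = np.zeros((n, n), dtype=bool)
        for i in range(n):
            for j in range(i + 1, n):
                rc = recombinant_count(ms[i].pattern, ms[j].pattern)
                _, lod = two_point_stats(ms[i], ms[j])
                dist[i, j] = dist[j, i] = rc
                linked[i, j] = linked[j, i] = (lod > lod_group) and (rc <= max_link_diffs)
        # connected components over the linkage graph
        labels = np.full(n, -1)
        comp = 0
        for i in range(n):
            if labels[i] >= 0:
                continue
            stack = [i]
            labels[i] = comp
            while stack:
                u = stack.pop()
                for v in np.nonzero(linked[u])[0]:
                    if labels[v] < 0:
                        labels[v] = comp
                        stack.append(v)
            comp += 1
        for c in range(comp):
            idx = [i for i in range(n) if labels[i] == c]
            sub = dist[np.ix_(idx, idx)]
            order = order_exhaustive(sub) if len(idx) <= EXHAUSTIVE_ORDER_LIMIT else order_greedy(sub)
            ordered = [ms[idx[i]] for i in order]
            dists = [float(sub[order[i], order[i + 1]] * cm) for i in range(len(order) - 1)]
            groups.append(LinkageGroup(
                chrom_id=None if chrom == -1 else chrom,
                component=c + 1, markers=ordered, distances_cm=dists))
    return groups


def map_stats(groups: Sequence[LinkageGroup],
              genome_size_bp: int | None = None) -> MapStats:
    """Total map length and, given a genome size, physical density in kb/cM."""
    total = float(sum(g.length_cm for g in groups))
    n_markers = sum(len(g.markers) for g in groups)
    kb_per_cm = None
    if genome_size_bp is not None:
        kb_per_cm = round(genome_size_bp / 1000.0 / total, 1) if total > 0 else None
    return MapStats(total_cm=total, n_groups=len(groups), n_markers=n_markers,
                    kb_per_cm=kb_per_cm)


# ---------------------------------------------------------------------------
# Output
# ---------------------------------------------------------------------------

def write_marker_tsv(markers: Sequence[RadMarker], path: str | Path) -> None:
    """Marker table in a JoinMap-compatible loc layout (name = i_ii_iii)."""
    with open(path, "w") as fh:
        fh.write("name\tmarker_id\tchrom_id\tallele_count\tpattern\n")
        for m in markers:
            chrom = m.chrom_id if m.chrom_id is not None else ""
            fh.write(f"{m.name}\t{m.marker_id}\t{chrom}\t{m.allele_count}\t{m.pattern}\n")


def write_map_tsv(groups: Sequence[LinkageGroup], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("chrom_id\tcomponent\tposition\tmarker\tcumulative_cM\n")
        for g in groups:
            cum = 0.0
            for i, m in enumerate(g.markers):
                if i > 0:
                    cum += g.distances_cm[i - 1]
                chrom = g.chrom_id if g.chrom_id is not None else ""
                fh.write(f"{chrom}\t{g.component}\t{i + 1}\t{m.name}\t{cum:g}\n")
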