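"""Maternal chromosome prints from segregation patterns.

Female Lepidoptera lack crossing over, so each backcross progeny inherits
one intact maternal homolog per chromosome.  A maternal-specific allele
(present in the mother, absent from the father) is therefore present in
exactly the progeny that received the homolog carrying it: its
presence/absence bit-vector over progeny — the *segregation pattern* — is
shared by every allele on that homolog, and the two homologs of one
chromosome produce exactly complementary patterns.  Such a complementary
pattern pair is a *chromosome print*.  If progeny sexes are known, the
print whose pattern equals the female-indicator vector identifies the W/Z
pair (females are WZ, males ZZ).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .crosscat import AlleleRecord, MergedLocus

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SegregationPattern:
    """Ordered presence/absence bit-vector over progeny."""

    bits: tuple[int, ...]

    def __post_init__(self) -> None:
        if any(b not in (0, 1) for b in self.bits):
            raise ValueError("pattern bits must be 0/1")

    @property
    def n_progeny(self) -> int:
        return len(self.bits)

    def complement(self) -> "SegregationPattern":
        return SegregationPattern(tuple(1 - b for b in self.bits))

    def hamming(self, other: "SegregationPattern") -> int:
        if len(self.bits) != len(other.bits):
            raise ValueError("patterns have different lengths")
        return sum(a != b for a, b in zip(self.bits, other.bits))

    @property
    def is_constant(self) -> bool:
        return len(set(self.bits)) <= 1

    @property
    def all_ones(self) -> bool:
        return all(b == 1 for b in self.bits)

    def __str__(self) -> str:
        return "".join(map(str, self.bits))

    @classmethod
    def from_string(cls, s: str) -> "SegregationPattern":
        return cls(tuple(int(c) for c in s if c in "01"))


@dataclass
class ChromosomePrint:
    """A complementary pattern pair identifying one maternal chromosome."""

    chrom_id: int
    pattern_1: SegregationPattern
    pattern_2: SegregationPattern
    alleles_1: list = field(default_factory=list)
    alleles_2: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.pattern_2 != self.pattern_1.complement():
            raise ValueError("print patterns must be complementary")

    @property
    def support(self) -> int:
        return len(self.alleles_1) + len(self.alleles_2)


@dataclass
class SexAssignment:
    """The chromosome print matching progeny sexes: W side and Z side."""

    chrom_id: int
    w_pattern: SegregationPattern   # present in females only
    z_pattern: SegregationPattern   # present in males only


def pattern_space_size(n_progeny: int) -> int:
    """Number of possible presence/absence patterns over n progeny."""
    return 2 ** n_progeny


# ---------------------------------------------------------------------------
# Candidate extraction
# ---------------------------------------------------------------------------

def catalog_individuals(loci: Sequence[MergedLocus]) -> set[str]:
    out: set[str] = set()
    for locus in loci:
        out.update(locus.individuals())
    return out


def maternal_candidates(loci: Sequence[MergedLocus], mother_id: str, father_id: str,
                        progeny_order: Sequence[str],
                        ) -> list[tuple[AlleleRecord, SegregationPattern]]:
    """Alleles present in the mother and absent from the father, with their
    presence patterns over the (retained) progeny in the given order."""
    individuals = catalog_individuals(loci)
    for who, ind in (("mother", mother_id), ("father", father_id)):
        if ind not in individuals:
            raise KeyError(f"{who} {ind!r} absent from catalog")
    out = []
    for locus in loci:
        for a in locus.alleles:
            if mother_id in a.present and father_id not in a.present:
                bits = tuple(1 if p in a.present else 0 for p in progeny_order)
                out.append((a, SegregationPattern(bits)))
    return out


# ---------------------------------------------------------------------------
# Pattern grouping and complement pairing
# ---------------------------------------------------------------------------

def group_patterns(candidates: Iterable[tuple[AlleleRecord, SegregationPattern]],
                   ) -> tuple[dict[SegregationPattern, list[AlleleRecord]], list[AlleleRecord]]:
    """Group alleles by exact pattern equality.

    Returns ``(groups, all_ones)`` where the all-ones group (alleles present
    in every progeny: likely homozygous in the mother, not chromosome-
    assignable) is reported separately.
    """
    groups: dict[SegregationPattern, list[AlleleRecord]] = {}
    all_ones: list[AlleleRecord] = []
    for allele, pattern in candidates:
        if pattern.n_progeny and pattern.all_ones:
            all_ones.append(allele)
        else:
            groups.setdefault(pattern, []).append(allele)
    return groups, all_ones


def pair_complements(groups: Mapping[SegregationPattern, Sequence[AlleleRecord]],
                     expected_chromosomes: int | None = None,
                     ) -> tuple[list[ChromosomePrint], dict[SegregationPattern, list[AlleleRecord]]]:
    """Pair patterns with their exact bitwise complements into prints.

    Pairs are ranked by total supporting alleles (ties broken by
    lexicographic pattern).  With ``expected_chromosomes`` given, only the
    top-k pairs become prints and the remainder join the residual groups.
    Within a print, pattern_1 is the side with more alleles.
    """
    residual: dict[SegregationPattern, list[AlleleRecord]] = {}
    pairs = []
    seen: set[SegregationPattern] = set()
    for pattern, alleles in groups.items():
        if pattern in seen:
            continue
        if pattern.is_constant:
            residual[pattern] = list(alleles)
            seen.add(pattern)
            continue
        comp = pattern.complement()
        if comp in groups:
            seen.update((pattern, comp))
            a1, a2 = list(alleles), list(groups[comp])
            p1, p2 = pattern, comp
            if (len(a2), str(p1)) > (len(a1), str(p2)):
                p1, p2, a1, a2 = p2, p1, a2, a1
            pairs.append((p1, p2, a1, a2))
        else:
            seen.add(pattern)
            residual[pattern] = list(alleles)
    pairs.sort(key=lambda t: (-(len(t[2]) + len(t[3])), str(min(t[0], t[1], key=str))))
    if expected_chromosomes is not None:
        if len(pairs) < expected_chromosomes:
            logger.warning("only %d complementary pattern pairs found, expected %d",
                           len(pairs), expected_chromosomes)
        for p1, p2, a1, a2 in pairs[expected_chromosomes:]:
            residual[p1] = a1
            residual[p2] = a2
        pairs = pairs[:expected_chromosomes]
    prints = [ChromosomePrint(chrom_id=k + 1, pattern_1=p1, pattern_2=p2,
                              alleles_1=a1, alleles_2=a2)
              for k, (p1, p2, a1, a2) in enumerate(pairs)]
    return prints, residual


def classify_homozygous_maternal(candidates: Iterable[tuple[AlleleRecord, SegregationPattern]],
                                 ) -> list[AlleleRecord]:
    """Alleles present in the mother and every progeny but not the father."""
    return [a for a, p in candidates if p.n_progeny and p.all_ones]


# ---------------------------------------------------------------------------
# Sex chromosome / phenotype matching
# ---------------------------------------------------------------------------

def match_label_vector(prints: Sequence[ChromosomePrint], labels: Sequence[int],
                       ) -> tuple[int, int] | None:
    """Match a binary progeny label vector (sex, phenotype, ...) against prints.

    Returns ``(chrom_id, side)`` where side 1 or 2 is the pattern equal to the
    label indicator vector, or None if no print matches.
    """
    target = SegregationPattern(tuple(int(bool(b)) for b in labels))
    for pr in prints:
        if pr.pattern_1 == target:
            return pr.chrom_id, 1
        if pr.pattern_2 == target:
            return pr.chrom_id, 2
    return None


def identify_sex_chromosome(prints: Sequence[ChromosomePrint],
                            sexes: Mapping[str, str],
                            progeny_order: Sequence[str]) -> SexAssignment | None:
    """Find the print whose pattern equals the female-indicator vector.

    The female-matching side is the W chromosome (present in females,
    absent in males); its complement is the Z.  Returns None when no print
    matches (autosomal-only information).
    """
    missing = [p for p in progeny_order if sexes.get(p) not in ("M", "F")]
    if missing:
        raise KeyError(f"sex unknown for progeny: {', '.join(missing)}")
    female = [1 if sexes[p] == "F" else 0 for p in progeny_order]
    hit = match_label_vector(prints, female)
    if hit is None:
        return None
    chrom_id, side = hit
    pr = next(p for p in prints if p.chrom_id == chrom_id)
    w = pr.pattern_1 if side == 1 else pr.pattern_2
    return SexAssignment(chrom_id=chrom_id, w_pattern=w, z_pattern=w.complement())


# ---------------------------------------------------------------------------
# Low-coverage exclusion rule
# ---------------------------------------------------------------------------

def auto_exclude(read_counts: Mapping[str, int], fraction: float = 0.25) -> set[str]:
    """Individuals whose read count falls below ``fraction`` of the median."""
    if not read_counts:
        return set()
    med = float(np.median(list(read_counts.values())))
    return {ind for ind, n in read_counts.items() if n < fraction * med}


# ---------------------------------------------------------------------------
# Output
# ---------------------------------------------------------------------------

def write_prints_tsv(prints: Sequence[ChromosomePrint], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("chrom_id\tpattern_1\tn_alleles_1\tpattern_2\tn_alleles_2\ttotal\n")
        for pr in prints:
            fh.write(f"{pr.chrom_id}\t{pr.pattern_1}\t{len(pr.alleles_1)}\t"
                     f"{pr.pattern_2}\t{len(pr.alleles_2)}\t{pr.support}\n")


def write_residuals_tsv(residual: Mapping[SegregationPattern, Sequence[AlleleRecord]],
                        path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("pattern\tn_alleles\n")
        for pattern in sorted(residual, key=str):
            fh.write(f"{pattern}\t{len(residual[pattern])}\n")
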