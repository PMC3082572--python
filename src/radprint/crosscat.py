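"""Cross-individual catalog: locus merging, normalization, presence calls.

Candidate loci from different individuals are merged whenever they share
similar alleles (Hamming distance at most ``allele_mismatches``).  Because
sequencing depth varies strongly between multiplexed individuals, raw
fragment counts are put on a common scale before presence thresholds are
applied: each individual's fragment-count histogram shows an error peak at
very low counts, a trough, and a main single-copy peak, and the scale factor
for individual *i* against the reference *m* (the mother) is

    SF_i = (min_m / min_i + max_m / max_i) / 2

where ``min`` and ``max`` are the trough and main-peak positions.  Trough
and peak are located automatically from the smoothed histogram, with manual
overrides available.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import NormalizationError
from .tagcall import CandidateAllele, _BASE_CODE

DEFAULT_ALLELE_MISMATCHES = 3
DEFAULT_IDENTITY_MISMATCHES = 0
DEFAULT_MIN_FRAGMENTS = 3.0
DEFAULT_MIN_INDIVIDUALS = 2


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class AlleleRecord:
    """One catalog allele with per-individual fragment counts."""

    seq: str
    raw: dict[str, int] = field(default_factory=dict)
    normalized: dict[str, float] = field(default_factory=dict)
    present: set[str] = field(default_factory=set)
    read_count: int = 0


@dataclass
class MergedLocus:
    """A RAD locus merged across individuals."""

    locus_id: str
    alleles: list[AlleleRecord] = field(default_factory=list)

    def individuals(self) -> set[str]:
        out: set[str] = set()
        for a in self.alleles:
            out.update(a.raw)
            out.update(a.present)
        return out


@dataclass
class FragmentHistogram:
    """Histogram of fragment counts per candidate allele for one individual."""

    individual_id: str
    counts: dict[int, int] = field(default_factory=dict)

    def dense(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) arrays over x = 1..max observed count."""
        if not self.counts:
            return np.array([], dtype=int), np.array([], dtype=float)
        xmax = max(self.counts)
        x = np.arange(1, xmax + 1)
        y = np.array([self.counts.get(int(v), 0) for v in x], dtype=float)
        return x, y


@dataclass
class ScaleFactorEntry:
    individual_id: str
    trough: float      # min_i: x-position of the histogram trough
    peak: float        # max_i: x-position of the main peak
    sf: float


@dataclass
class ScaleFactors:
    """Per-individual scale factors relative to a reference individual."""

    reference: str
    factors: dict[str, ScaleFactorEntry] = field(default_factory=dict)

    def __getitem__(self, individual_id: str) -> float:
        return self.factors[individual_id].sf

    def __contains__(self, individual_id: str) -> bool:
        return individual_id in self.factors

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("individual_id\tmin\tmax\tSF\n")
            for e in self.factors.values():
                fh.write(f"{e.individual_id}\t{e.trough:g}\t{e.peak:g}\t{e.sf:.6g}\n")


# ---------------------------------------------------------------------------
# Locus merging
# ---------------------------------------------------------------------------

def _hamming_pairs(seqs: Sequence[str], max_mismatches: int, block: int = 2048):
    """All i<j pairs of seqs with Hamming distance <= max_mismatches."""
    n = len(seqs)
    if n < 2:
        return []
    L = len(seqs[0])
    mat = np.frombuffer("".join(seqs).encode(), dtype=np.uint8).reshape(n, L)
    codes = _BASE_CODE[mat]
    onehot = np.zeros((n, L * 4), dtype=np.float32)
    flat_idx = np.arange(L) * 4
    for i in range(n):
        onehot[i, flat_idx + codes[i]] = 1.0
    pairs = []
    for start in range(0, n, block):
        stop = min(n, start + block)
        matches = onehot[start:stop] @ onehot.T
        ham = L - matches
        r, c = np.nonzero(ham <= max_mismatches + 1e-6)
        for a, b in zip(r + start, c):
            if a < b:
                pairs.append((int(a), int(b)))
    return pairs


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, a: int) -> int:
        while self.parent[a] != a:
            self.parent[a] = self.parent[self.parent[a]]
            a = self.parent[a]
        return a

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def merge_loci(per_individual: Mapping[str, Sequence[CandidateAllele]],
               allele_mismatches: int = DEFAULT_ALLELE_MISMATCHES,
               identity_mismatches: int = DEFAULT_IDENTITY_MISMATCHES,
               ) -> list[MergedLocus]:
    """Merge per-individual candidate loci into a cross-individual catalog.

    Loci from different individuals are unioned (single linkage) whenever any
    allele pair across them is within ``allele_mismatches`` Hamming distance.
    Allele *identity* across individuals is stricter: sequences within
    ``identity_mismatches`` (default 0, i.e. exact equality after per-individual
    error correction) are registered as the same catalog allele, represented by
    the variant with the highest total read support (ties: lexicographically
    smallest sequence).
    """
    records = []  # (individual, locus_key, seq, raw, read_count)
    for ind, alleles in per_individual.items():
        for a in alleles:
            records.append((ind, (ind, a.locus_id), a.seq, a.fragment_count_raw, a.read_count))
    if not records:
        return []
    seqs = sorted({r[2] for r in records})
    seq_index = {s: i for i, s in enumerate(seqs)}
    locus_keys = sorted({r[1] for r in records})
    locus_index = {k: i for i, k in enumerate(locus_keys)}

    seq_loci: dict[int, list[int]] = {i: [] for i in range(len(seqs))}
    for ind, lk, seq, raw, rc in records:
        seq_loci[seq_index[seq]].append(locus_index[lk])

    sim_pairs = _hamming_pairs(seqs, max(allele_mismatches, identity_mismatches))

    # union loci sharing an allele, or carrying alleles within allele_mismatches
    uf_loci = _UnionFind(len(locus_keys))
    for loci in seq_loci.values():
        for other in loci[1:]:
            uf_loci.union(loci[0], other)
    # union identity classes of alleles
    uf_seq = _UnionFind(len(seqs))
    for a, b in sim_pairs:
        ham = sum(x != y for x, y in zip(seqs[a], seqs[b]))
        if ham <= allele_mismatches:
            uf_loci.union(seq_loci[a][0], seq_loci[b][0])
        if ham <= identity_mismatches:
            uf_seq.union(a, b)

    # aggregate per (merged locus, identity class)
    read_support: dict[int, dict[str, int]] = {}
    for ind, lk, seq, raw, rc in records:
        cls = uf_seq.find(seq_index[seq])
        read_support.setdefault(cls, {})
        read_support[cls][seq] = read_support[cls].get(seq, 0) + rc

    canonical: dict[int, str] = {
        cls: min(variants, key=lambda s: (-variants[s], s))
        for cls, variants in read_support.items()
    }

    merged: dict[tuple[int, int], AlleleRecord] = {}
    locus_of_root: dict[int, set[int]] = {}
    for ind, lk, seq, raw, rc in records:
        root = uf_loci.find(locus_index[lk])
        cls = uf_seq.find(seq_index[seq])
        locus_of_root.setdefault(root, set()).add(cls)
        rec = merged.get((root, cls))
        if rec is None:
            rec = AlleleRecord(seq=canonical[cls])
            merged[(root, cls)] = rec
        rec.raw[ind] = rec.raw.get(ind, 0) + raw
        rec.read_count += rc

    out = []
    for k, root in enumerate(sorted(locus_of_root,
                                    key=lambda r: min(canonical[c] for c in locus_of_root[r]))):
        alleles = sorted((merged[(root, cls)] for cls in locus_of_root[root]),
                         key=lambda a: (-a.read_count, a.seq))
        out.append(MergedLocus(locus_id=f"merged_{k:05d}", alleles=alleles))
    return out


# ---------------------------------------------------------------------------
# Fragment histograms and scale factors
# ---------------------------------------------------------------------------

def fragment_histogram(alleles: Iterable, individual_id: str = "") -> FragmentHistogram:
    """Histogram of raw fragment counts over one individual's alleles.

    Accepts :class:`~radprint.tagcall.CandidateAllele` objects or bare ints.
    """
    counts: dict[int, int] = {}
    for a in alleles:
        x = int(a if isinstance(a, (int, np.integer)) else a.fragment_count_raw)
        counts[x] = counts.get(x, 0) + 1
    return FragmentHistogram(individual_id=individual_id, counts=counts)


def _smooth(y: np.ndarray, window: int = 3) -> np.ndarray:
    """Centered moving average; edges averaged over the in-range window."""
    kernel = np.ones(window)
    return np.convolve(y, kernel, mode="same") / np.convolve(np.ones_like(y), kernel, mode="same")


def _find_trough_peak(hist: FragmentHistogram) -> tuple[int, int]:
    """Locate the histogram trough (first local minimum at x >= 2, skipping
    the error peak) and the main peak (global maximum beyond the trough,
    which also ignores the long repeat tail)."""
    x, y = hist.dense()
    if x.size < 3:
        raise NormalizationError(
            f"histogram for {hist.individual_id or '<unnamed>'} too sparse for automatic "
            "trough/peak detection; supply a manual scale-factor override")
    ys = _smooth(y)
    pos = {int(v): i for i, v in enumerate(x)}
    trough = None
    for xv in range(2, int(x[-1])):
        i = pos[xv]
        # next strictly different smoothed value to the right
        j = i + 1
        while j < ys.size and ys[j] == ys[i]:
            j += 1
        if j >= ys.size:
            break
        rising_after = ys[j] > ys[i]
        at_boundary = xv == 2
        non_increasing_before = i > 0 and ys[i] <= ys[i - 1]
        if rising_after and (at_boundary or non_increasing_before):
            trough = xv
            break
    if trough is None:
        raise NormalizationError(
            f"no trough found in fragment histogram for {hist.individual_id or '<unnamed>'}; "
            "supply a manual scale-factor override")
    after = x > trough
    peak = int(x[after][np.argmax(ys[after])])
    return trough, peak


def scale_factor_formula(min_m: float, max_m: float, min_i: float, max_i: float) -> float:
    """SF_i = (min_m/min_i + max_m/max_i) / 2."""
    return (min_m / min_i + max_m / max_i) / 2.0


def estimate_scale_factor(h_i: FragmentHistogram, h_m: FragmentHistogram) -> ScaleFactorEntry:
    """Scale factor for individual *i* against the reference histogram *m*."""
    min_i, max_i = _find_trough_peak(h_i)
    min_m, max_m = _find_trough_peak(h_m)
    sf = scale_factor_formula(min_m, max_m, min_i, max_i)
    return ScaleFactorEntry(individual_id=h_i.individual_id, trough=min_i, peak=max_i, sf=sf)


def estimate_all_scale_factors(histograms: Mapping[str, FragmentHistogram],
                               reference: str,
                               overrides: Mapping[str, float] | None = None) -> ScaleFactors:
    """Scale factors for every individual; the reference gets exactly 1."""
    if reference not in histograms:
        raise NormalizationError(f"reference individual {reference!r} has no histogram")
    overrides = dict(overrides or {})
    h_m = histograms[reference]
    out = ScaleFactors(reference=reference)
    for ind, h in histograms.items():
        if ind in overrides:
            out.factors[ind] = ScaleFactorEntry(ind, float("nan"), float("nan"), overrides[ind])
        elif ind == reference:
            min_m, max_m = _find_trough_peak(h_m)
            out.factors[ind] = ScaleFactorEntry(ind, min_m, max_m, 1.0)
        else:
            out.factors[ind] = estimate_scale_factor(h, h_m)
    return out


# ---------------------------------------------------------------------------
# Normalization and presence filtering
# ---------------------------------------------------------------------------

def normalize_and_filter(merged: Sequence[MergedLocus], sf: ScaleFactors,
                         min_fragments: float = DEFAULT_MIN_FRAGMENTS,
                         min_individuals: int = DEFAULT_MIN_INDIVIDUALS,
                         ) -> list[MergedLocus]:
    """Apply scale factors, call presence, and drop unsupported alleles.

    An allele is *present* in individual i when ``raw * SF_i >= min_fragments``;
    alleles present in fewer than ``min_individuals`` individuals are removed,
    and loci left without alleles disappear.  Thresholds are applied after
    normalization.  Allele records are annotated in place; the returned list
    contains only the surviving loci/alleles.
    """
    for locus in merged:
        for a in locus.alleles:
            missing = [ind for ind in a.raw if ind not in sf]
            if missing:
                raise NormalizationError(f"no scale factor for individual(s): {', '.join(missing)}")
    out = []
    for locus in merged:
        kept = []
        for a in locus.alleles:
            a.normalized = {ind: raw * sf[ind] for ind, raw in a.raw.items()}
            a.present = {ind for ind, v in a.normalized.items() if v >= min_fragments}
            if len(a.present) >= min_individuals:
                kept.append(a)
        if kept:
            out.append(MergedLocus(locus_id=locus.locus_id, alleles=kept))
    return out


# ---------------------------------------------------------------------------
# Catalog table
# ---------------------------------------------------------------------------

def catalog_frame(loci: Sequence[MergedLocus], individuals: Sequence[str],
                  value: str = "normalized") -> pd.DataFrame:
    """Catalog as a DataFrame: one row per (locus, allele), one column per
    individual holding raw or normalized fragment counts."""
    rows = []
    for locus in loci:
        for a in locus.alleles:
            source = a.normalized if value == "normalized" else a.raw
            row = {"locus_id": locus.locus_id, "allele_seq": a.seq}
            for ind in individuals:
                row[ind] = source.get(ind, 0)
            rows.append(row)
    return pd.DataFrame(rows, columns=["locus_id", "allele_seq", *individuals])


def write_catalog_tsv(loci: Sequence[MergedLocus], individuals: Sequence[str],
                      path: str | Path) -> None:
    catalog_frame(loci, individuals).to_csv(path, sep="\t", index=False, float_format="%.4g")
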