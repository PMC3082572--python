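"""Per-individual RAD locus and allele calling.

Identical 40-base tags are collapsed into *uniques* (with per-base median
qualities, singletons discarded), uniques are clustered into candidate RAD
loci with a quality-weighted distance, sequencing-error bases are corrected
within each locus, and the surviving haplotypes become candidate RAD
alleles.  Distinct paired-end mate sequences are then counted per allele as
a PCR-duplicate-corrected depth proxy (the *fragment count*).

The weighted distance between two uniques is the sum over mismatching
positions of the product of the two per-base correct-call probabilities,
P = 1 - 10^(-Q/10), computed from the stored median qualities.  It is
bounded above by the Hamming distance and approaches it as Q grows.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

from .io_demux import TagRead, TAG_LEN

DEFAULT_LOCUS_THRESHOLD = 7.0
DEFAULT_ALLELE_QUAL = 20
DEFAULT_ERROR_READ_RATIO = 0.1

_BASE_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _BASE_CODE[_b] = _i


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class UniqueTag:
    """A distinct tag sequence with read support and median qualities."""

    seq: str
    read_count: int
    med_qual: np.ndarray          # 40 median quality integers
    mates: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.med_qual = np.asarray(self.med_qual, dtype=np.uint8)
        if len(self.seq) != self.med_qual.size:
            raise ValueError("sequence and quality lengths differ")


@dataclass
class CandidateAllele:
    """An error-corrected tag haplotype for one individual."""

    seq: str
    read_count: int
    individual_id: str
    locus_id: str = ""
    fragment_count_raw: int = 0
    mates: list[str] = field(default_factory=list)


@dataclass
class CandidateLocus:
    """A single-linkage cluster of uniques treated as one RAD locus."""

    locus_id: str
    uniques: list[UniqueTag]
    alleles: list[CandidateAllele] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Collapse to uniques
# ---------------------------------------------------------------------------

def collapse_uniques(tags: Sequence[TagRead], min_reads: int = 2) -> list[UniqueTag]:
    """Collapse identical tags into uniques with per-base median qualities.

    Singleton sequences (read count below ``min_reads``, default 2) are
    discarded as unverifiable.  Mate sequences are carried along for later
    fragment counting.
    """
    if not tags:
        return []
    seqs = np.array([t.tag for t in tags], dtype=f"S{TAG_LEN}")
    quals = np.stack([t.tag_qual for t in tags]).astype(np.uint8)
    uniq, inverse, counts = np.unique(seqs, return_inverse=True, return_counts=True)
    order = np.argsort(inverse, kind="stable")
    bounds = np.concatenate([[0], np.cumsum(counts)])
    out = []
    for k in range(uniq.size):
        if counts[k] < min_reads:
            continue
        members = order[bounds[k]:bounds[k + 1]]
        med = np.median(quals[members], axis=0).astype(np.uint8)
        out.append(UniqueTag(
            seq=uniq[k].decode("ascii"),
            read_count=int(counts[k]),
            med_qual=med,
            mates=[tags[i].mate_seq for i in members],
        ))
    return out


# ---------------------------------------------------------------------------
# Quality-weighted distance
# ---------------------------------------------------------------------------

def _p_correct(quals: np.ndarray) -> np.ndarray:
    """Probability each base call is correct, from phred qualities."""
    return 1.0 - np.power(10.0, -np.asarray(quals, dtype=np.float64) / 10.0)


def weighted_distance(u1: UniqueTag, u2: UniqueTag) -> float:
    """Sum over mismatching positions of the joint correct-call probability."""
    if len(u1.seq) != len(u2.seq):
        raise ValueError("uniques have different lengths")
    s1 = np.frombuffer(u1.seq.encode(), dtype=np.uint8)
    s2 = np.frombuffer(u2.seq.encode(), dtype=np.uint8)
    mism = s1 != s2
    if not mism.any():
        return 0.0
    p1 = _p_correct(u1.med_qual[mism])
    p2 = _p_correct(u2.med_qual[mism])
    return float(np.sum(p1 * p2))


def _pairwise_weighted_adjacency(uniques: Sequence[UniqueTag], threshold: float,
                                 block: int = 2048):
    """Sparse i<j pairs with weighted distance <= threshold (blocked matmul)."""
    n = len(uniques)
    L = len(uniques[0].seq)
    seq_mat = np.frombuffer("".join(u.seq for u in uniques).encode(), dtype=np.uint8).reshape(n, L)
    codes = _BASE_CODE[seq_mat]
    p = _p_correct(np.stack([u.med_qual for u in uniques])).astype(np.float32)
    # weighted one-hot: Xp[i, j, b] = p[i, j] if base b at position j else 0
    xp = np.zeros((n, L, 4), dtype=np.float32)
    idx = np.arange(L)
    for i in range(n):
        xp[i, idx, codes[i]] = p[i]
    xp_flat = xp.reshape(n, L * 4)
    rows, cols = [], []
    for start in range(0, n, block):
        stop = min(n, start + block)
        # D[a,b] = sum_j p_a p_b - sum_j p_a p_b [same base]
        pp = p[start:stop] @ p.T
        same = xp_flat[start:stop] @ xp_flat.T
        d = pp - same
        r, c = np.nonzero(d <= threshold + 1e-9)
        rows.append(r + start)
        cols.append(c)
    return np.concatenate(rows), np.concatenate(cols)


def cluster_uniques(uniques: Sequence[UniqueTag],
                    locus_threshold: float = DEFAULT_LOCUS_THRESHOLD,
                    locus_prefix: str = "locus") -> list[CandidateLocus]:
    """Single-linkage clustering of uniques into candidate RAD loci.

    Uniques are connected whenever their weighted distance is at most
    ``locus_threshold`` (default 7); connected components become loci.
    """
    if locus_threshold <= 0:
        raise ValueError("locus_threshold must be positive")
    if not uniques:
        return []
    rows, cols = _pairwise_weighted_adjacency(uniques, locus_threshold)
    n = len(uniques)
    adj = coo_matrix((np.ones(rows.size, dtype=np.int8), (rows, cols)), shape=(n, n))
    n_comp, labels = connected_components(adj, directed=False)
    loci: list[CandidateLocus] = []
    for k in range(n_comp):
        members = [uniques[i] for i in np.nonzero(labels == k)[0]]
        loci.append(CandidateLocus(locus_id=f"{locus_prefix}_{k:05d}", uniques=members))
    return loci


# ---------------------------------------------------------------------------
# Allele calling
# ---------------------------------------------------------------------------

def call_alleles(locus: CandidateLocus,
                 allele_qual_threshold: int = DEFAULT_ALLELE_QUAL,
                 error_read_ratio: float = DEFAULT_ERROR_READ_RATIO) -> list[CandidateAllele]:
    """Correct likely error bases within a locus and call candidate alleles.

    For each position and base, the mean of the per-unique median qualities is
    computed across the uniques carrying that base.  A base carried by exactly
    one unique is rejected (masked) when that unique's read support is at most
    ``error_read_ratio`` times the strongest unique carrying a different base
    at the position — an isolated, weakly supported base is the signature of a
    sequencing/PCR error, while an isolated but well-supported base marks a
    genuine second haplotype.  Uniques that are identical after masking
    rejected bases and ignoring bases whose mean quality falls below
    ``allele_qual_threshold`` are merged into one allele whose sequence is the
    highest-read-count member (ties: lexicographically smallest), with read
    counts summed and mates pooled.
    """
    if not locus.uniques:
        raise ValueError("empty locus")
    uniques = locus.uniques
    n = len(uniques)
    if n == 1:
        u = uniques[0]
        alleles = [CandidateAllele(seq=u.seq, read_count=u.read_count,
                                   individual_id="", locus_id=locus.locus_id,
                                   mates=list(u.mates))]
        locus.alleles = alleles
        return alleles
    L = len(uniques[0].seq)
    seq_mat = np.frombuffer("".join(u.seq for u in uniques).encode(), dtype=np.uint8).reshape(n, L)
    codes = _BASE_CODE[seq_mat]
    quals = np.stack([u.med_qual for u in uniques]).astype(np.float64)
    counts = np.array([u.read_count for u in uniques])

    # mean quality and read support per (position, base)
    masked = np.zeros((n, L), dtype=bool)
    for j in range(L):
        col = codes[:, j]
        bases = np.unique(col)
        if bases.size == 1:
            continue
        mean_q = {b: quals[col == b, j].mean() for b in bases}
        max_count = {b: counts[col == b].max() for b in bases}
        for b in bases:
            carriers = np.nonzero(col == b)[0]
            low_qual = mean_q[b] < allele_qual_threshold
            rejected = False
            if carriers.size == 1:
                best_other = max(max_count[o] for o in bases if o != b)
                rejected = counts[carriers[0]] <= error_read_ratio * best_other
            if low_qual or rejected:
                masked[carriers, j] = True

    # merge uniques identical outside masked positions (graph components)
    adj_r, adj_c = [], []
    for a in range(n):
        for b in range(a + 1, n):
            vis = ~(masked[a] | masked[b])
            if np.array_equal(codes[a, vis], codes[b, vis]):
                adj_r.append(a)
                adj_c.append(b)
    adj = coo_matrix((np.ones(len(adj_r), dtype=np.int8), (adj_r, adj_c)), shape=(n, n))
    n_comp, labels = connected_components(adj, directed=False)

    alleles = []
    for k in range(n_comp):
        members = np.nonzero(labels == k)[0]
        rep = min(members, key=lambda i: (-uniques[i].read_count, uniques[i].seq))
        mates: list[str] = []
        for i in members:
            mates.extend(uniques[i].mates)
        alleles.append(CandidateAllele(
            seq=uniques[rep].seq,
            read_count=int(counts[members].sum()),
            individual_id="",
            locus_id=locus.locus_id,
            mates=mates,
        ))
    alleles.sort(key=lambda a: (-a.read_count, a.seq))
    locus.alleles = alleles
    return alleles


def count_fragments(allele: CandidateAllele) -> int:
    """Number of distinct paired-end mate sequences supporting the allele."""
    allele.fragment_count_raw = len(set(allele.mates))
    return allele.fragment_count_raw


# ---------------------------------------------------------------------------
# Per-individual driver
# ---------------------------------------------------------------------------

def call_individual(tags: Sequence[TagRead], individual_id: str,
                    locus_threshold: float = DEFAULT_LOCUS_THRESHOLD,
                    allele_qual_threshold: int = DEFAULT_ALLELE_QUAL,
                    error_read_ratio: float = DEFAULT_ERROR_READ_RATIO,
                    ) -> tuple[list[CandidateLocus], list[CandidateAllele]]:
    """Full per-individual pipeline: uniques -> loci -> alleles -> fragments."""
    uniques = collapse_uniques(tags)
    loci = cluster_uniques(uniques, locus_threshold, locus_prefix=individual_id)
    alleles: list[CandidateAllele] = []
    for locus in loci:
        for allele in call_alleles(locus, allele_qual_threshold, error_read_ratio):
            allele.individual_id = individual_id
            count_fragments(allele)
            alleles.append(allele)
    return loci, alleles


def write_allele_table(alleles: Iterable[CandidateAllele], path: str | Path) -> None:
    """Per-individual allele table TSV."""
    with open(path, "w") as fh:
        fh.write("individual_id\tlocus_id\tallele_seq\tread_count\tfragment_count_raw\n")
        for a in alleles:
            fh.write(f"{a.individual_id}\t{a.locus_id}\t{a.seq}\t{a.read_count}\t{a.fragment_count_raw}\n")
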