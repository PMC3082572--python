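"""Backcross RAD-seq read simulator with full truth tables.

Emulates a lepidopteran backcross experiment: a multi-chromosome genome of
restriction-site loci, a mother (WZ) heterozygous at a configurable fraction
of loci, a father (ZZ), and backcross progeny that inherit one *intact*
maternal homolog per chromosome (achiasmatic female meiosis) and a paternal
gamete shaped by Poisson crossovers.  Reads mimic the library structure:
a 5-base inline MID, the 6-base SbfI footprint (TGCAGG), 40 locus-specific
bases, and a sheared paired-end mate starting 300-700 bp downstream.
Per-individual depth multipliers reproduce the wide coverage spread seen on
one multiplexed lane; fragment counts are Poisson, reads per fragment model
PCR duplication, and per-base errors are drawn at a rate consistent with the
emitted quality scores.

Every emitted read traces back to an allele, locus, chromosome and
individual through the :class:`TruthTable`, enabling end-to-end
parameter-recovery tests without external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .io_demux import DEFAULT_FOOTPRINT, Manifest, ManifestEntry, write_manifest

TAG_LEN = 40
MATE_LEN = 51
DOWNSTREAM_LEN = 700
MIN_OFFSET, MAX_OFFSET = 300, 700

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

#: The 24 published 5-base MIDs (father, mother, then progeny barcodes).
PUBLISHED_MIDS = [
    "CGATA", "CGGCG", "CTAGG", "CTGAA", "GAAGC", "GAGAT", "GCATT", "GGAAG",
    "GTACA", "TAATG", "TAGCA", "TCAGA", "TCGAG", "TGACC", "TGGTT", "TTAAT",
    "AACCC", "ACTGC", "AAGGG", "ACGTA", "AGAGT", "ATGCT", "CAGTC", "CCAAC",
]


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class SimConfig:
    """Study conditions for one simulated backcross RAD library.

    Defaults follow the design of the mapping experiment the simulator
    emulates: 31 chromosomes, ~100 restriction loci per chromosome, 20
    retained backcross progeny, a mean of 30 sheared fragments per allele
    copy with ~1.4 reads per fragment (PCR duplication), and a log-normal
    per-individual depth spread resembling one multiplexed lane.
    ``male_crossovers`` defaults to 0.417 crossovers per chromosome per
    gamete so the expected observed map length is ~1292 cM over 31
    chromosomes at the 100/N cM-per-event convention.
    """

    n_chromosomes: int = 31
    loci_per_chromosome: float = 100.0   # Poisson mean
    n_progeny: int = 20
    maternal_het_rate: float = 0.4
    paternal_het_rate: float = 0.4
    shared_allele_mismatch_rate: float = 0.05  # per-base divergence of variant alleles
    male_crossovers: float = 0.417       # Poisson mean per chromosome per gamete
    depth_multipliers: dict[str, float] | None = None  # default: sampled log-normal
    depth_sigma: float = 0.35
    depth_clip: tuple[float, float] = (0.5, 2.0)
    fragments_per_allele: float = 30.0   # Poisson mean per allele copy
    reads_per_fragment: float = 1.4      # 1 + Poisson(reads_per_fragment - 1)
    per_base_error: float = 0.001
    seed: int = 42
    # model refinements
    maternal_shared_rate: float = 0.5    # P(one maternal het allele is the shared haplotype)
    mother_hom_private_rate: float = 0.1  # P(homozygous-private | mother not het)
    min_informative_per_chromosome: int | None = None
    sex_chromosome: bool = True          # chromosome 1 acts as Z/W; sexes follow it
    locus_min_separation: int = 10       # min Hamming distance between locus haplotypes
    genomic_mode: bool = False           # derive loci from SbfI sites in a random genome
    genome_length_per_chromosome: int = 500_000  # genomic_mode chromosome length (bp)
    mids: Sequence[str] = field(default_factory=lambda: list(PUBLISHED_MIDS))

    def __post_init__(self) -> None:
        for name in ("maternal_het_rate", "paternal_het_rate",
                     "shared_allele_mismatch_rate", "per_base_error",
                     "maternal_shared_rate", "mother_hom_private_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("loci_per_chromosome", "fragments_per_allele"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.reads_per_fragment < 1.0:
            raise ValueError("reads_per_fragment must be >= 1")
        if self.male_crossovers < 0 or self.n_chromosomes < 0 or self.n_progeny < 0:
            raise ValueError("counts and rates must be non-negative")


# ---------------------------------------------------------------------------
# Truth table
# ---------------------------------------------------------------------------

@dataclass
class TruthTable:
    """Complete ground truth for one simulated experiment."""

    config: SimConfig
    individuals: list[str]                  # mother, father, progeny...
    mids: dict[str, str]
    sexes: dict[str, str]
    depth: dict[str, float]
    allele_seqs: list[str]                  # global allele registry
    allele_chrom: np.ndarray                # (A,) chromosome per allele (1-based)
    allele_locus: np.ndarray                # (A,) global locus index per allele
    locus_chrom: np.ndarray                 # (L,) chromosome per locus (1-based)
    locus_pos: np.ndarray                   # (L,) genetic position in [0, 1)
    mother_hap: np.ndarray                  # (L, 2) allele index per maternal homolog
    father_hap: np.ndarray                  # (L, 2)
    maternal_inherit: np.ndarray            # (n_progeny, C) maternal homolog received
    paternal_gamete: np.ndarray             # (n_progeny, L) paternal homolog at locus
    crossovers: list[list[list[float]]]     # [progeny][chrom] -> positions
    downstream: np.ndarray                  # (L, DOWNSTREAM_LEN) base codes for mates

    # -- derived views -----------------------------------------------------

    @property
    def mother_id(self) -> str:
        return self.individuals[0]

    @property
    def father_id(self) -> str:
        return self.individuals[1]

    @property
    def progeny_ids(self) -> list[str]:
        return self.individuals[2:]

    def genotype(self, individual: str, locus: int) -> tuple[int, int]:
        """(maternal-copy, paternal-copy) allele indices at a locus."""
        if individual == self.mother_id:
            return tuple(self.mother_hap[locus])
        if individual == self.father_id:
            return tuple(self.father_hap[locus])
        p = self.progeny_ids.index(individual)
        c = self.locus_chrom[locus] - 1
        mat = self.mother_hap[locus, self.maternal_inherit[p, c]]
        pat = self.father_hap[locus, self.paternal_gamete[p, locus]]
        return int(mat), int(pat)

    def allele_origin(self, allele_idx: int) -> str:
        """'maternal' / 'paternal' (parent-specific) or 'shared'."""
        in_mother = allele_idx in self.mother_hap[self.allele_locus[allele_idx]]
        in_father = allele_idx in self.father_hap[self.allele_locus[allele_idx]]
        if in_mother and in_father:
            return "shared"
        return "maternal" if in_mother else "paternal"

    def informative_maternal_alleles(self) -> dict[str, tuple[int, int]]:
        """seq -> (chromosome, maternal homolog) for mother-het alleles the
        father lacks: the alleles that generate chromosome prints."""
        out: dict[str, tuple[int, int]] = {}
        for locus in range(self.locus_chrom.size):
            m0, m1 = self.mother_hap[locus]
            if m0 == m1:
                continue
            father = set(self.father_hap[locus])
            for hom, a in enumerate((m0, m1)):
                if a not in father:
                    out[self.allele_seqs[a]] = (int(self.locus_chrom[locus]), hom)
        return out

    def informative_paternal_alleles(self) -> dict[str, int]:
        """seq -> chromosome for father-het alleles the mother lacks."""
        out: dict[str, int] = {}
        for locus in range(self.locus_chrom.size):
            f0, f1 = self.father_hap[locus]
            if f0 == f1:
                continue
            mother = set(self.mother_hap[locus])
            for a in (f0, f1):
                if a not in mother:
                    out[self.allele_seqs[a]] = int(self.locus_chrom[locus])
        return out

    def expected_pattern(self, seq: str, progeny_subset: Sequence[str] | None = None,
                         ) -> tuple[int, ...]:
        """True presence bits of an allele across progeny (in truth order)."""
        a = self.allele_seqs.index(seq)
        locus = int(self.allele_locus[a])
        ids = list(progeny_subset) if progeny_subset is not None else self.progeny_ids
        return tuple(1 if a in self.genotype(p, locus) else 0 for p in ids)

    def true_carriers(self, allele_idx: int) -> set[str]:
        locus = int(self.allele_locus[allele_idx])
        return {ind for ind in self.individuals
                if allele_idx in self.genotype(ind, locus)}


# ---------------------------------------------------------------------------
# Pedigree simulation
# ---------------------------------------------------------------------------

def _random_tag(rng: np.random.Generator) -> np.ndarray:
    return rng.integers(0, 4, TAG_LEN, dtype=np.uint8)


def _codes_to_str(codes: np.ndarray) -> str:
    return _BASES[codes].tobytes().decode("ascii")


def _mutate(codes: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Derive a variant haplotype with >= 1 substitution at the given rate."""
    while True:
        mask = rng.random(codes.size) < rate
        if mask.any():
            break
    out = codes.copy()
    out[mask] = (out[mask] + rng.integers(1, 4, int(mask.sum()), dtype=np.uint8)) % 4
    return out


def simulate_pedigree(cfg: SimConfig) -> TruthTable:
    """Simulate genome, parents, and progeny inheritance (no reads yet).

    The mother transmits one intact homolog per chromosome (fair coin); the
    father's gametes carry Poisson(``male_crossovers``) crossovers at uniform
    positions along each chromosome's locus order.
    """
    rng = np.random.default_rng(cfg.seed)

    # --- individuals ------------------------------------------------------
    progeny = [f"progeny{p + 1:02d}" for p in range(cfg.n_progeny)]
    individuals = ["mother", "father", *progeny]
    mids = list(cfg.mids)
    while len(mids) < len(individuals):   # extend with fresh barcodes if needed
        cand = _codes_to_str(rng.integers(0, 4, 5, dtype=np.uint8))
        if cand not in mids:
            mids.append(cand)
    mid_of = {"mother": "CGGCG" if "CGGCG" in mids else mids[1],
              "father": "CGATA" if "CGATA" in mids else mids[0]}
    spare = [m for m in mids if m not in (mid_of["mother"], mid_of["father"])]
    for p, m in zip(progeny, spare):
        mid_of[p] = m

    if cfg.depth_multipliers is not None:
        depth = {ind: float(cfg.depth_multipliers.get(ind, 1.0)) for ind in individuals}
    else:
        lo, hi = cfg.depth_clip
        vals = np.clip(rng.lognormal(0.0, cfg.depth_sigma, len(individuals)), lo, hi)
        depth = dict(zip(individuals, map(float, vals)))

    # --- loci per chromosome ---------------------------------------------
    genomic_h0 = genomic_downstream = None
    if cfg.genomic_mode:
        n_loci_per_chrom, genomic_h0, genomic_pos, genomic_downstream = \
            _genomic_loci(cfg, rng)
        locus_pos = np.concatenate(genomic_pos) if cfg.n_chromosomes else np.zeros(0)
    else:
        n_loci_per_chrom = [max(1, int(rng.poisson(cfg.loci_per_chromosome)))
                            for _ in range(cfg.n_chromosomes)]
        locus_pos = np.concatenate([(np.arange(n) + 0.5) / n for n in n_loci_per_chrom]) \
            if cfg.n_chromosomes else np.zeros(0)
    locus_chrom = np.concatenate([np.full(n, c + 1, dtype=np.int32)
                                  for c, n in enumerate(n_loci_per_chrom)]) \
        if cfg.n_chromosomes else np.zeros(0, dtype=np.int32)
    L = locus_chrom.size

    # --- base haplotypes with enforced separation ------------------------
    if genomic_h0 is not None:
        h0 = genomic_h0 if L else np.zeros((0, TAG_LEN), np.uint8)
    else:
        h0 = np.stack([_random_tag(rng) for _ in range(L)]) if L else np.zeros((0, TAG_LEN), np.uint8)
    if L > 1 and genomic_h0 is None:
        for _ in range(20):  # resample any pair closer than the separation floor
            close = _too_close(h0, cfg.locus_min_separation)
            if not close:
                break
            for i in close:
                h0[i] = _random_tag(rng)

    # --- parental genotypes ----------------------------------------------
    allele_seq_codes: list[np.ndarray] = []
    allele_locus: list[int] = []
    seq_seen: set[bytes] = set()

    def register(codes: np.ndarray, locus: int) -> int:
        key = codes.tobytes()
        # distinct alleles must differ in sequence; regenerate on collision
        while key in seq_seen:
            codes = _mutate(codes, cfg.shared_allele_mismatch_rate, rng)
            key = codes.tobytes()
        seq_seen.add(key)
        allele_seq_codes.append(codes)
        allele_locus.append(locus)
        return len(allele_seq_codes) - 1

    mother_hap = np.zeros((L, 2), dtype=np.int32)
    father_hap = np.zeros((L, 2), dtype=np.int32)
    base_allele = np.zeros(L, dtype=np.int32)

    def new_variant(locus: int) -> int:
        return register(_mutate(h0[locus], cfg.shared_allele_mismatch_rate, rng), locus)

    def make_maternal_het(locus: int, force_both_private: bool = False) -> None:
        if not force_both_private and rng.random() < cfg.maternal_shared_rate:
            pair = [base_allele[locus], new_variant(locus)]
        else:
            pair = [new_variant(locus), new_variant(locus)]
        rng.shuffle(pair)
        mother_hap[locus] = pair

    for locus in range(L):
        base_allele[locus] = register(h0[locus].copy(), locus)
        if rng.random() < cfg.paternal_het_rate:
            father_hap[locus] = (base_allele[locus], new_variant(locus))
        else:
            father_hap[locus] = (base_allele[locus], base_allele[locus])
        if rng.random() < cfg.maternal_het_rate:
            make_maternal_het(locus)
        elif rng.random() < cfg.mother_hom_private_rate:
            hom = new_variant(locus)
            mother_hap[locus] = (hom, hom)
        else:
            mother_hap[locus] = (base_allele[locus], base_allele[locus])

    # --- top up informative maternal alleles if requested ----------------
    if cfg.min_informative_per_chromosome is not None:
        for c in range(cfg.n_chromosomes):
            idx = np.nonzero(locus_chrom == c + 1)[0]

            def informative_count() -> int:
                n = 0
                for lo in idx:
                    m0, m1 = mother_hap[lo]
                    if m0 == m1:
                        continue
                    father = set(father_hap[lo])
                    n += sum(1 for a in (m0, m1) if a not in father)
                return n

            pool = [int(lo) for lo in idx if mother_hap[lo, 0] == mother_hap[lo, 1]]
            rng.shuffle(pool)
            while informative_count() < cfg.min_informative_per_chromosome:
                if not pool:
                    raise ValueError(
                        f"chromosome {c + 1} has too few loci to reach "
                        f"{cfg.min_informative_per_chromosome} informative alleles")
                make_maternal_het(pool.pop(), force_both_private=True)

    # --- inheritance ------------------------------------------------------
    C = cfg.n_chromosomes
    maternal_inherit = rng.integers(0, 2, (cfg.n_progeny, C), dtype=np.int8) \
        if C else np.zeros((cfg.n_progeny, 0), dtype=np.int8)
    paternal_gamete = np.zeros((cfg.n_progeny, L), dtype=np.int8)
    crossovers: list[list[list[float]]] = []
    for p in range(cfg.n_progeny):
        per_chrom: list[list[float]] = []
        for c in range(C):
            k = int(rng.poisson(cfg.male_crossovers))
            pos = sorted(float(x) for x in rng.random(k))
            start = int(rng.integers(0, 2))
            mask = locus_chrom == c + 1
            switches = np.searchsorted(pos, locus_pos[mask])
            paternal_gamete[p, mask] = (start + switches) % 2
            per_chrom.append(pos)
        crossovers.append(per_chrom)

    # --- sexes ------------------------------------------------------------
    sexes = {"mother": "F", "father": "M"}
    for p, name in enumerate(progeny):
        if cfg.sex_chromosome and C >= 1:
            # homolog 1 of chromosome 1 acts as the W: carriers are female
            sexes[name] = "F" if maternal_inherit[p, 0] == 1 else "M"
        else:
            sexes[name] = "F" if rng.random() < 0.5 else "M"

    if genomic_downstream is not None and L:
        downstream = genomic_downstream
    else:
        downstream = rng.integers(0, 4, (L, DOWNSTREAM_LEN), dtype=np.uint8) \
            if L else np.zeros((0, DOWNSTREAM_LEN), dtype=np.uint8)

    return TruthTable(
        config=cfg,
        individuals=individuals,
        mids=mid_of,
        sexes=sexes,
        depth=depth,
        allele_seqs=[_codes_to_str(c) for c in allele_seq_codes],
        allele_chrom=locus_chrom[np.array(allele_locus, dtype=int)] if allele_locus
        else np.zeros(0, dtype=np.int32),
        allele_locus=np.array(allele_locus, dtype=np.int32),
        locus_chrom=locus_chrom,
        locus_pos=locus_pos,
        mother_hap=mother_hap,
        father_hap=father_hap,
        maternal_inherit=maternal_inherit,
        paternal_gamete=paternal_gamete,
        crossovers=crossovers,
        downstream=downstream,
    )


def _genomic_loci(cfg: SimConfig, rng: np.random.Generator):
    """Optional genomic mode: draw loci from SbfI occurrences (CCTGCAGG) in a
    random uniform-composition genome per chromosome (expected ~G/4^8 sites).
    The 40 bases after each site become the locus haplotype and the following
    stretch the mate-bearing downstream region."""
    site = _BASE_CODE_SEQ("CCTGCAGG")
    n_per_chrom, h0_rows, pos_lists, down_rows = [], [], [], []
    for _c in range(cfg.n_chromosomes):
        g = cfg.genome_length_per_chromosome
        for _attempt in range(50):
            genome = rng.integers(0, 4, g + len(site) + TAG_LEN + DOWNSTREAM_LEN,
                                  dtype=np.uint8)
            window = np.lib.stride_tricks.sliding_window_view(genome[:g + len(site)],
                                                              len(site))
            starts = np.nonzero((window == site).all(axis=1))[0]
            if starts.size:
                break
        else:
            raise ValueError("no restriction sites found; increase "
                             "genome_length_per_chromosome")
        n_per_chrom.append(int(starts.size))
        pos_lists.append(starts / g)
        for s in starts:
            tag_start = s + len(site)
            h0_rows.append(genome[tag_start:tag_start + TAG_LEN].copy())
            down_rows.append(genome[tag_start + TAG_LEN:
                                    tag_start + TAG_LEN + DOWNSTREAM_LEN].copy())
    h0 = np.stack(h0_rows) if h0_rows else np.zeros((0, TAG_LEN), np.uint8)
    down = np.stack(down_rows) if down_rows else np.zeros((0, DOWNSTREAM_LEN), np.uint8)
    return n_per_chrom, h0, pos_lists, down


def _too_close(h0: np.ndarray, min_sep: int, block: int = 2048) -> list[int]:
    """Indices of locus haplotypes within min_sep of an earlier one."""
    n, L = h0.shape
    onehot = np.zeros((n, L * 4), dtype=np.float32)
    flat = np.arange(L) * 4
    for i in range(n):
        onehot[i, flat + h0[i]] = 1.0
    bad: set[int] = set()
    for start in range(0, n, block):
        stop = min(n, start + block)
        ham = L - onehot[start:stop] @ onehot.T
        r, c = np.nonzero(ham <= min_sep)
        for a, b in zip(r + start, c):
            if a > b:
                bad.add(int(a))
    return sorted(bad)


# ---------------------------------------------------------------------------
# Read emission
# ---------------------------------------------------------------------------

@dataclass
class SimOutput:
    fwd_path: Path
    rev_path: Path
    manifest_path: Path
    manifest: Manifest
    read_counts: dict[str, int]


def _quality_char(per_base_error: float) -> str:
    q = 40 if per_base_error <= 0 else min(41, round(-10.0 * np.log10(per_base_error)))
    return chr(33 + q)


def _apply_errors(codes: np.ndarray, rate: float, rng: np.random.Generator) -> None:
    if rate <= 0:
        return
    mask = rng.random(codes.shape) < rate
    n = int(mask.sum())
    if n:
        codes[mask] = (codes[mask] + rng.integers(1, 4, n, dtype=np.uint8)) % 4


def emit_reads(truth: TruthTable, out_dir: str | Path,
               footprint: str = DEFAULT_FOOTPRINT) -> SimOutput:
    """Write paired FASTQ and a manifest for a simulated truth table.

    Per individual and allele copy, the fragment count is
    Poisson(``fragments_per_allele`` x depth multiplier); each fragment is
    read 1 + Poisson(``reads_per_fragment`` - 1) times (PCR duplicates share
    the fragment, hence the mate start offset, drawn uniformly from
    300-700 bp); per-base errors are applied at ``per_base_error`` on both
    reads, with quality strings consistent with the error rate.
    """
    cfg = truth.config
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 7_777]))
    fwd_path, rev_path = out_dir / "reads_1.fastq", out_dir / "reads_2.fastq"
    manifest = Manifest([
        ManifestEntry(ind,
                      "mother" if ind == truth.mother_id
                      else "father" if ind == truth.father_id else "progeny",
                      truth.sexes[ind], truth.mids[ind])
        for ind in truth.individuals])
    write_manifest(manifest, out_dir / "manifest.tsv")

    L = truth.locus_chrom.size
    A = len(truth.allele_seqs)
    allele_codes = np.zeros((A, TAG_LEN), dtype=np.uint8)
    for i, s in enumerate(truth.allele_seqs):
        allele_codes[i] = _BASE_CODE_SEQ(s)
    qchar = _quality_char(cfg.per_base_error)
    qual_fwd = qchar * (5 + len(footprint) + TAG_LEN)
    qual_rev = qchar * MATE_LEN
    fp_codes = _BASE_CODE_SEQ(footprint)
    counts: dict[str, int] = {}
    serial = 0

    with open(fwd_path, "w", buffering=1 << 22) as fh_f, \
            open(rev_path, "w", buffering=1 << 22) as fh_r:
        for ind in truth.individuals:
            if L == 0:
                counts[ind] = 0
                continue
            copies = np.empty(2 * L, dtype=np.int32)   # two allele copies per locus
            if ind == truth.mother_id:
                copies[0::2], copies[1::2] = truth.mother_hap[:, 0], truth.mother_hap[:, 1]
            elif ind == truth.father_id:
                copies[0::2], copies[1::2] = truth.father_hap[:, 0], truth.father_hap[:, 1]
            else:
                p = truth.progeny_ids.index(ind)
                mat = truth.mother_hap[np.arange(L),
                                       truth.maternal_inherit[p, truth.locus_chrom - 1]]
                pat = truth.father_hap[np.arange(L), truth.paternal_gamete[p]]
                copies[0::2], copies[1::2] = mat, pat
            lam = cfg.fragments_per_allele * truth.depth[ind]
            n_frag = rng.poisson(lam, copies.size)
            frag_allele = np.repeat(copies, n_frag)
            n_fragments = frag_allele.size
            offsets = rng.integers(MIN_OFFSET, MAX_OFFSET + 1, n_fragments)
            dups = 1 + rng.poisson(cfg.reads_per_fragment - 1.0, n_fragments)
            read_allele = np.repeat(frag_allele, dups)
            read_offset = np.repeat(offsets, dups)
            n_reads = read_allele.size
            counts[ind] = int(n_reads)
            if n_reads == 0:
                continue

            mid_codes = _BASE_CODE_SEQ(truth.mids[ind])
            fwd = np.empty((n_reads, 5 + fp_codes.size + TAG_LEN), dtype=np.uint8)
            fwd[:, :5] = mid_codes
            fwd[:, 5:5 + fp_codes.size] = fp_codes
            fwd[:, 5 + fp_codes.size:] = allele_codes[read_allele]
            _apply_errors(fwd, cfg.per_base_error, rng)

            loci = truth.allele_locus[read_allele]
            cols = (read_offset - MATE_LEN)[:, None] + np.arange(MATE_LEN)
            mate = truth.downstream[loci[:, None], cols]
            mate = (3 - mate)[:, ::-1]          # reverse complement
            _apply_errors(mate, cfg.per_base_error, rng)

            fwd_strs = _BASES[fwd].view(f"S{fwd.shape[1]}").ravel().tolist()
            rev_strs = _BASES[np.ascontiguousarray(mate)].view(f"S{MATE_LEN}").ravel().tolist()
            buf_f, buf_r = [], []
            for i in range(n_reads):
                name = f"sim{serial + i}"
                buf_f.append(f"@{name}\n{fwd_strs[i].decode()}\n+\n{qual_fwd}\n")
                buf_r.append(f"@{name}\n{rev_strs[i].decode()}\n+\n{qual_rev}\n")
            serial += n_reads
            fh_f.write("".join(buf_f))
            fh_r.write("".join(buf_r))

    return SimOutput(fwd_path=fwd_path, rev_path=rev_path,
                     manifest_path=out_dir / "manifest.tsv",
                     manifest=manifest, read_counts=counts)


def _BASE_CODE_SEQ(s: str) -> np.ndarray:
    lookup = np.full(256, 255, dtype=np.uint8)
    for i, b in enumerate(b"ACGT"):
        lookup[b] = i
    return lookup[np.frombuffer(s.encode(), dtype=np.uint8)]


# ---------------------------------------------------------------------------
# Truth table persistence
# ---------------------------------------------------------------------------

def write_truth(truth: TruthTable, out_dir: str | Path) -> None:
    """Write the truth table as plain TSV files (round-trippable)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = truth.config
    with open(out / "config.tsv", "w") as fh:
        fh.write("key\tvalue\n")
        for k, v in vars(cfg).items():
            if k == "depth_multipliers" and v is not None:
                v = ";".join(f"{i}={x}" for i, x in v.items())
            elif k in ("depth_clip",):
                v = ";".join(map(str, v))
            elif k == "mids":
                v = ";".join(v)
            fh.write(f"{k}\t{v}\n")
    with open(out / "individuals.tsv", "w") as fh:
        fh.write("individual_id\trole\tsex\tmid\tdepth_multiplier\n")
        for ind in truth.individuals:
            role = ("mother" if ind == truth.mother_id
                    else "father" if ind == truth.father_id else "progeny")
            fh.write(f"{ind}\t{role}\t{truth.sexes[ind]}\t{truth.mids[ind]}\t"
                     f"{truth.depth[ind]!r}\n")
    with open(out / "loci.tsv", "w") as fh:
        fh.write("locus\tchrom\tpos\tmother_h0\tmother_h1\tfather_h0\tfather_h1\tdownstream\n")
        for lo in range(truth.locus_chrom.size):
            fh.write(f"{lo}\t{truth.locus_chrom[lo]}\t{float(truth.locus_pos[lo])!r}\t"
                     f"{truth.mother_hap[lo, 0]}\t{truth.mother_hap[lo, 1]}\t"
                     f"{truth.father_hap[lo, 0]}\t{truth.father_hap[lo, 1]}\t"
                     f"{_codes_to_str(truth.downstream[lo])}\n")
    with open(out / "alleles.tsv", "w") as fh:
        fh.write("allele\tseq\tchrom\tlocus\torigin\n")
        for a, seq in enumerate(truth.allele_seqs):
            fh.write(f"{a}\t{seq}\t{truth.allele_chrom[a]}\t{truth.allele_locus[a]}\t"
                     f"{truth.allele_origin(a)}\n")
    with open(out / "maternal_inherit.tsv", "w") as fh:
        fh.write("\t".join(["progeny"] + [f"chrom{c + 1}" for c in range(cfg.n_chromosomes)]) + "\n")
        for p, ind in enumerate(truth.progeny_ids):
            fh.write("\t".join([ind] + [str(x) for x in truth.maternal_inherit[p]]) + "\n")
    with open(out / "paternal_gamete.tsv", "w") as fh:
        fh.write("\t".join(["progeny"] + [f"locus{lo}" for lo in range(truth.locus_chrom.size)]) + "\n")
        for p, ind in enumerate(truth.progeny_ids):
            fh.write("\t".join([ind] + [str(x) for x in truth.paternal_gamete[p]]) + "\n")
    with open(out / "crossovers.tsv", "w") as fh:
        fh.write("progeny\tchrom\tposition\n")
        for p, ind in enumerate(truth.progeny_ids):
            for c in range(cfg.n_chromosomes):
                for pos in truth.crossovers[p][c]:
                    fh.write(f"{ind}\t{c + 1}\t{pos!r}\n")


def read_truth(out_dir: str | Path) -> TruthTable:
    """Reconstruct a TruthTable written by :func:`write_truth`."""
    out = Path(out_dir)
    cfg_kv = {}
    with open(out / "config.tsv") as fh:
        next(fh)
        for line in fh:
            k, _, v = line.rstrip("\n").partition("\t")
            cfg_kv[k] = v

    def parse(k, v):
        if v == "None":
            return None
        if k == "depth_multipliers":
            return {p.split("=")[0]: float(p.split("=")[1]) for p in v.split(";")} if v else None
        if k == "depth_clip":
            return tuple(float(x) for x in v.split(";"))
        if k == "mids":
            return v.split(";")
        if k in ("sex_chromosome", "genomic_mode"):
            return v == "True"
        if k in ("n_chromosomes", "n_progeny", "seed", "locus_min_separation",
                 "min_informative_per_chromosome", "genome_length_per_chromosome"):
            return int(v)
        return float(v)

    cfg = SimConfig(**{k: parse(k, v) for k, v in cfg_kv.items()})

    individuals, mids, sexes, depth = [], {}, {}, {}
    with open(out / "individuals.tsv") as fh:
        next(fh)
        for line in fh:
            ind, role, sex, mid, d = line.rstrip("\n").split("\t")
            individuals.append(ind)
            mids[ind], sexes[ind], depth[ind] = mid, sex, float(d)

    rows = []
    with open(out / "loci.tsv") as fh:
        next(fh)
        for line in fh:
            rows.append(line.rstrip("\n").split("\t"))
    L = len(rows)
    locus_chrom = np.array([int(r[1]) for r in rows], dtype=np.int32)
    locus_pos = np.array([float(r[2]) for r in rows])
    mother_hap = np.array([[int(r[3]), int(r[4])] for r in rows], dtype=np.int32).reshape(L, 2)
    father_hap = np.array([[int(r[5]), int(r[6])] for r in rows], dtype=np.int32).reshape(L, 2)
    downstream = np.stack([_BASE_CODE_SEQ(r[7]) for r in rows]) if L \
        else np.zeros((0, DOWNSTREAM_LEN), dtype=np.uint8)

    allele_seqs, allele_chrom, allele_locus = [], [], []
    with open(out / "alleles.tsv") as fh:
        next(fh)
        for line in fh:
            a, seq, chrom, locus, _origin = line.rstrip("\n").split("\t")
            allele_seqs.append(seq)
            allele_chrom.append(int(chrom))
            allele_locus.append(int(locus))

    progeny = individuals[2:]
    maternal_inherit = np.zeros((len(progeny), cfg.n_chromosomes), dtype=np.int8)
    with open(out / "maternal_inherit.tsv") as fh:
        next(fh)
        for p, line in enumerate(fh):
            cells = line.rstrip("\n").split("\t")
            maternal_inherit[p] = [int(x) for x in cells[1:] if x]
    paternal_gamete = np.zeros((len(progeny), L), dtype=np.int8)
    with open(out / "paternal_gamete.tsv") as fh:
        next(fh)
        for p, line in enumerate(fh):
            cells = line.rstrip("\n").split("\t")
            paternal_gamete[p] = [int(x) for x in cells[1:] if x]
    crossovers = [[[] for _ in range(cfg.n_chromosomes)] for _ in progeny]
    with open(out / "crossovers.tsv") as fh:
        next(fh)
        for line in fh:
            ind, c, pos = line.rstrip("\n").split("\t")
            crossovers[progeny.index(ind)][int(c) - 1].append(float(pos))

    return TruthTable(
        config=cfg, individuals=individuals, mids=mids, sexes=sexes, depth=depth,
        allele_seqs=allele_seqs,
        allele_chrom=np.array(allele_chrom, dtype=np.int32),
        allele_locus=np.array(allele_locus, dtype=np.int32),
        locus_chrom=locus_chrom, locus_pos=locus_pos,
        mother_hap=mother_hap, father_hap=father_hap,
        maternal_inherit=maternal_inherit, paternal_gamete=paternal_gamete,
        crossovers=crossovers, downstream=downstream)


def simulate(cfg: SimConfig, out_dir: str | Path,
             write_truth_files: bool = False) -> tuple[TruthTable, SimOutput]:
    """Convenience wrapper: pedigree + reads (+ optional truth TSVs)."""
    truth = simulate_pedigree(cfg)
    sim_out = emit_reads(truth, out_dir)
    if write_truth_files:
        write_truth(truth, Path(out_dir) / "truth")
    return truth, sim_out
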