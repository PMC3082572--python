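"""Shared fixtures: published read-count table, helpers, and a mid-size
simulated experiment reused across module tests."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pytest
from hypothesis import settings

import radprint as rp

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")


#: Published per-individual Illumina read counts for the 24-plex library
#: (individual, sex, MID, reads); the two low-coverage individuals are the
#: ones dropped from analysis.
TABLE1 = [
    ("Father", "M", "CGATA", 297_795),
    ("Mother", "F", "CGGCG", 495_190),
    ("Control 1", "F", "CTAGG", 474_048),
    ("Control 2", "M", "CTGAA", 381_912),
    ("Control 3", "F", "GAAGC", 467_094),
    ("Control 4", "M", "GAGAT", 496_749),
    ("Control 5", "M", "GCATT", 16_959),
    ("Control 6", "M", "GGAAG", 510_666),
    ("Control 7", "M", "GTACA", 842_036),
    ("Control 8", "F", "TAATG", 414_966),
    ("Control 9", "F", "TAGCA", 462_595),
    ("Control 10", "F", "TCAGA", 325_581),
    ("Bioassay 1", "M", "TCGAG", 510_086),
    ("Bioassay 2", "M", "TGACC", 609_811),
    ("Bioassay 3", "M", "TGGTT", 374_328),
    ("Bioassay 4", "M", "TTAAT", 168_157),
    ("Bioassay 5", "M", "AACCC", 375_236),
    ("Bioassay 6", "F", "ACTGC", 373_667),
    ("Bioassay 7", "F", "AAGGG", 513_757),
    ("Bioassay 8", "F", "ACGTA", 463_518),
    ("Bioassay 9", "M", "AGAGT", 638_261),
    ("Bioassay 10", "M", "ATGCT", 482_003),
    ("Bioassay 11", "M", "CAGTC", 476_704),
    ("Bioassay 12", "F", "CCAAC", 45_955),
]

LOW_COVERAGE = {"Control 5", "Bioassay 12"}


@pytest.fixture(scope="session")
def table1_counts() -> dict[str, int]:
    return {name: n for name, _sex, _mid, n in TABLE1}


def make_tagread(tag: str, qual: int | list[int] = 30, mate: str = "A" * 51,
                 individual_id: str = "ind") -> rp.TagRead:
    quals = np.full(len(tag), qual, dtype=np.uint8) if isinstance(qual, int) \
        else np.asarray(qual, dtype=np.uint8)
    return rp.TagRead(individual_id, tag, quals,
                      mate, np.full(len(mate), 30, dtype=np.uint8))


def make_unique(seq: str, read_count: int = 10, qual: int | list[int] = 30,
                mates: list[str] | None = None) -> rp.UniqueTag:
    quals = [qual] * len(seq) if isinstance(qual, int) else qual
    return rp.UniqueTag(seq=seq, read_count=read_count,
                        med_qual=np.asarray(quals, dtype=np.uint8),
                        mates=mates or [])


def run_library_pipeline(truth, sim_out, workdir: Path):
    """Run the whole pipeline (library calls) on a simulated dataset."""
    manifest = rp.load_manifest(sim_out.manifest_path)
    demux_dir = Path(workdir) / "demux"
    report = rp.demux_to_dir(sim_out.fwd_path, sim_out.rev_path, manifest, demux_dir)
    excluded = rp.auto_exclude(report.assigned)
    excluded -= {manifest.mother.individual_id, manifest.father.individual_id}
    per_ind = {}
    for e in manifest.entries:
        if e.individual_id in excluded:
            continue
        tags = rp.load_tagreads(demux_dir / f"{e.individual_id}.tags.fastq",
                                demux_dir / f"{e.individual_id}.mates.fastq",
                                individual_id=e.individual_id)
        _, alleles = rp.call_individual(tags, e.individual_id)
        for a in alleles:
            a.mates = []
        per_ind[e.individual_id] = alleles
    merged = rp.merge_loci(per_ind)
    hists = {ind: rp.fragment_histogram(a, ind) for ind, a in per_ind.items()}
    sf = rp.estimate_all_scale_factors(hists, manifest.mother.individual_id)
    loci = rp.normalize_and_filter(merged, sf)
    progeny = [e.individual_id for e in manifest.retained_progeny(excluded)]
    maternal = rp.maternal_candidates(loci, manifest.mother.individual_id,
                                      manifest.father.individual_id, progeny)
    groups, all_ones = rp.group_patterns(maternal)
    prints, residual = rp.pair_complements(groups)
    maternal_assigned = {a.seq: pr.chrom_id for pr in prints
                         for a in pr.alleles_1 + pr.alleles_2}
    paternal = rp.paternal_candidates(loci, manifest.mother.individual_id,
                                      manifest.father.individual_id, progeny)
    assignments = rp.propagate_patterns(rp.assign_by_allelism(paternal, maternal_assigned))
    markers = rp.collapse_markers(assignments)
    link_groups = rp.build_groups(markers)
    return {
        "manifest": manifest, "report": report, "excluded": excluded,
        "per_individual": per_ind, "sf": sf, "loci": loci, "progeny": progeny,
        "maternal": maternal, "groups": groups, "all_ones": all_ones,
        "prints": prints, "residual": residual, "paternal": paternal,
        "assignments": assignments, "markers": markers, "link_groups": link_groups,
    }


def print_to_true_chromosome(truth, prints):
    """Map each print's patterns to the simulated chromosome whose maternal
    inheritance vector (over the retained progeny order) they match."""
    mapping = {}
    for c in range(truth.config.n_chromosomes):
        bits = tuple(int(x) for x in truth.maternal_inherit[:, c])
        mapping[bits] = c + 1
        mapping[tuple(1 - b for b in bits)] = c + 1
    return {pr.chrom_id: mapping.get(pr.pattern_1.bits) for pr in prints}


@pytest.fixture(scope="session")
def midsim(tmp_path_factory):
    """Error-free mid-size backcross: 6 chromosomes, ~25 loci each, 20 progeny."""
    cfg = rp.SimConfig(n_chromosomes=6, loci_per_chromosome=25, n_progeny=20,
                       per_base_error=0.0, seed=11,
                       min_informative_per_chromosome=10)
    workdir = tmp_path_factory.mktemp("midsim")
    truth, sim_out = rp.simulate(cfg, workdir / "reads")
    result = run_library_pipeline(truth, sim_out, workdir)
    result.update({"truth": truth, "sim_out": sim_out, "cfg": cfg})
    return result
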