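"""Demultiplexing of multiplexed paired-end RAD reads.

Forward reads carry a 5-base inline molecular identifier (MID) identifying
the individual, followed by the 6-base residual restriction footprint of the
enzyme that generated the library (TGCAGG for SbfI), followed by 40
locus-specific bases (the RAD tag).  This module assigns read pairs to
individuals by exact MID match, verifies the footprint, and emits the tag
with its qualities alongside the paired-end mate.
"""

from __future__ import annotations

import gzip
import io
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, NamedTuple, Sequence

import numpy as np
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .errors import FastqError, ManifestError

DEFAULT_FOOTPRINT = "TGCAGG"
MID_LEN = 5
TAG_LEN = 40
QUAL_CAP = 41

VALID_ROLES = {"mother", "father", "progeny"}
VALID_SEX = {"M", "F", "unknown"}


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

class ReadPair(NamedTuple):
    """One forward/reverse read pair with decoded phred qualities."""

    read_id: str
    fwd_seq: str
    fwd_qual: np.ndarray
    rev_seq: str
    rev_qual: np.ndarray


class TagRead(NamedTuple):
    """A demultiplexed 40-base RAD tag plus its paired-end mate."""

    individual_id: str
    tag: str
    tag_qual: np.ndarray
    mate_seq: str
    mate_qual: np.ndarray


@dataclass(frozen=True)
class ManifestEntry:
    individual_id: str
    role: str              # mother | father | progeny
    sex: str               # M | F | unknown
    mid: str               # 5-base inline barcode
    status: str = "retained"  # retained | excluded


@dataclass
class Manifest:
    """Validated pedigree/barcode manifest for one RAD library."""

    entries: list[ManifestEntry]

    def __post_init__(self) -> None:
        if not self.entries:
            raise ManifestError("manifest has no entries")
        mids = Counter(e.mid for e in self.entries)
        dupes = [m for m, k in mids.items() if k > 1]
        if dupes:
            raise ManifestError(f"duplicate MID(s) in manifest: {', '.join(sorted(dupes))}")
        ids = Counter(e.individual_id for e in self.entries)
        dup_ids = [i for i, k in ids.items() if k > 1]
        if dup_ids:
            raise ManifestError(f"duplicate individual id(s): {', '.join(sorted(dup_ids))}")
        for e in self.entries:
            if e.role not in VALID_ROLES:
                raise ManifestError(f"invalid role {e.role!r} for {e.individual_id}")
            if e.sex not in VALID_SEX:
                raise ManifestError(f"invalid sex {e.sex!r} for {e.individual_id}")
            if len(e.mid) != MID_LEN or set(e.mid) - set("ACGT"):
                raise ManifestError(f"MID {e.mid!r} for {e.individual_id} is not a 5-base ACGT string")
        for role in ("mother", "father"):
            n = sum(1 for e in self.entries if e.role == role)
            if n != 1:
                raise ManifestError(f"manifest must contain exactly one {role}, found {n}")

    @property
    def mother(self) -> ManifestEntry:
        return next(e for e in self.entries if e.role == "mother")

    @property
    def father(self) -> ManifestEntry:
        return next(e for e in self.entries if e.role == "father")

    @property
    def progeny(self) -> list[ManifestEntry]:
        return [e for e in self.entries if e.role == "progeny"]

    def retained_progeny(self, extra_excluded: Iterable[str] = ()) -> list[ManifestEntry]:
        """Progeny in manifest order, dropping excluded individuals."""
        drop = set(extra_excluded)
        return [e for e in self.progeny if e.status != "excluded" and e.individual_id not in drop]

    def mid_map(self) -> dict[str, str]:
        return {e.mid: e.individual_id for e in self.entries}

    def sexes(self) -> dict[str, str]:
        return {e.individual_id: e.sex for e in self.entries}


@dataclass
class DemuxReport:
    """Per-individual read accounting from one demultiplexing run."""

    assigned: dict[str, int] = field(default_factory=dict)
    discarded: int = 0
    discard_reasons: Counter = field(default_factory=Counter)

    @property
    def total(self) -> int:
        return sum(self.assigned.values()) + self.discarded

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("individual_id\treads_assigned\treads_discarded\n")
            for ind, n in self.assigned.items():
                fh.write(f"{ind}\t{n}\t0\n")
            fh.write(f"__unassigned__\t0\t{self.discarded}\n")


# ---------------------------------------------------------------------------
# Manifest I/O
# ---------------------------------------------------------------------------

def load_manifest(path: str | Path) -> Manifest:
    """Read a tab- or comma-separated manifest with a header line.

    Required columns: individual_id, role, sex, mid.  Optional: status
    (``excluded`` drops the individual from segregation patterns while it
    still consumes a barcode).
    """
    path = Path(path)
    text = path.read_text()
    lines = [ln for ln in text.splitlines() if ln.strip() and not ln.startswith("#")]
    if not lines:
        raise ManifestError(f"{path}: no entries")
    sep = "\t" if "\t" in lines[0] else ","
    header = [c.strip().lower() for c in lines[0].split(sep)]
    required = ["individual_id", "role", "sex", "mid"]
    missing = [c for c in required if c not in header]
    if missing:
        raise ManifestError(f"{path}: missing column(s) {', '.join(missing)}")
    idx = {c: header.index(c) for c in header}
    entries = []
    for ln in lines[1:]:
        cells = [c.strip() for c in ln.split(sep)]
        if len(cells) < len(required):
            raise ManifestError(f"{path}: short row {ln!r}")
        entries.append(ManifestEntry(
            individual_id=cells[idx["individual_id"]],
            role=cells[idx["role"]].lower(),
            sex=cells[idx["sex"]] if cells[idx["sex"]] in VALID_SEX else "unknown",
            mid=cells[idx["mid"]].upper(),
            status=cells[idx["status"]].lower() if "status" in idx and len(cells) > idx["status"] else "retained",
        ))
    if not entries:
        raise ManifestError(f"{path}: no entries")
    return Manifest(entries)


def write_manifest(manifest: Manifest, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("individual_id\trole\tsex\tmid\tstatus\n")
        for e in manifest.entries:
            fh.write(f"{e.individual_id}\t{e.role}\t{e.sex}\t{e.mid}\t{e.status}\n")


# ---------------------------------------------------------------------------
# FASTQ I/O
# ---------------------------------------------------------------------------

def _open_text(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return io.TextIOWrapper(gzip.open(path, "rb"))
    return open(path)


def decode_quals(qual_str: str, phred_offset: int = 33) -> np.ndarray:
    """Decode a FASTQ quality string to integers, capped at 41."""
    q = np.frombuffer(qual_str.encode("ascii"), dtype=np.uint8).astype(np.int16) - phred_offset
    if q.size and (q.min() < 0):
        raise FastqError(f"quality below zero with phred offset {phred_offset}; wrong offset?")
    return np.minimum(q, QUAL_CAP).astype(np.uint8)


def encode_quals(quals: np.ndarray | Sequence[int], phred_offset: int = 33) -> str:
    arr = np.asarray(quals, dtype=np.uint8) + phred_offset
    return arr.tobytes().decode("ascii")


def read_fastq_pairs(fwd_path: str | Path, rev_path: str | Path,
                     phred_offset: int = 33) -> Iterator[ReadPair]:
    """Stream matched read pairs from two FASTQ files (gzip transparent).

    Records must be in matching order; a length mismatch between the files or
    a malformed record raises :class:`FastqError` naming the record index.
    """
    if phred_offset not in (33, 64):
        raise FastqError(f"unsupported phred offset {phred_offset}")
    sentinel = object()
    with _open_text(fwd_path) as fh_f, _open_text(rev_path) as fh_r:
        it_f = FastqGeneralIterator(fh_f)
        it_r = FastqGeneralIterator(fh_r)
        i = 0
        while True:
            i += 1
            try:
                rec_f = next(it_f, sentinel)
            except ValueError as exc:
                raise FastqError(f"{fwd_path}: malformed record {i}: {exc}") from exc
            try:
                rec_r = next(it_r, sentinel)
            except ValueError as exc:
                raise FastqError(f"{rev_path}: malformed record {i}: {exc}") from exc
            if rec_f is sentinel and rec_r is sentinel:
                return
            if rec_f is sentinel or rec_r is sentinel:
                short = fwd_path if rec_f is sentinel else rev_path
                raise FastqError(f"paired FASTQ length mismatch: {short} ends at record {i}")
            fid, fseq, fqual = rec_f
            rid, rseq, rqual = rec_r
            yield ReadPair(
                read_id=fid.split()[0] if fid else f"read{i}",
                fwd_seq=fseq.upper(),
                fwd_qual=decode_quals(fqual, phred_offset),
                rev_seq=rseq.upper(),
                rev_qual=decode_quals(rqual, phred_offset),
            )


# ---------------------------------------------------------------------------
# Demultiplexing
# ---------------------------------------------------------------------------

def _classify(pair: ReadPair, mid_map: dict[str, str], footprint: str):
    """Return (individual_id, TagRead) or (None, reason)."""
    fwd = pair.fwd_seq
    tag_end = MID_LEN + len(footprint) + TAG_LEN
    if len(fwd) < tag_end:
        return None, "short_read"
    ind = mid_map.get(fwd[:MID_LEN])
    if ind is None:
        return None, "unknown_mid"
    if fwd[MID_LEN:MID_LEN + len(footprint)] != footprint:
        return None, "bad_footprint"
    tag = fwd[MID_LEN + len(footprint):tag_end]
    if "N" in tag:
        return None, "n_in_tag"
    return ind, TagRead(
        individual_id=ind,
        tag=tag,
        tag_qual=pair.fwd_qual[MID_LEN + len(footprint):tag_end],
        mate_seq=pair.rev_seq,
        mate_qual=pair.rev_qual,
    )


def demultiplex(pairs: Iterable[ReadPair], manifest: Manifest,
                footprint: str = DEFAULT_FOOTPRINT) -> tuple[dict[str, list[TagRead]], DemuxReport]:
    """Assign read pairs to individuals by exact inline-MID match.

    The first 5 forward bases must equal a manifest MID exactly, the next
    ``len(footprint)`` bases must equal the restriction footprint, and the
    following 40 bases become the tag.  Unmatched or N-containing reads go to
    the discarded bin; assigned + discarded always equals the input count.
    """
    mid_map = manifest.mid_map()
    out: dict[str, list[TagRead]] = {e.individual_id: [] for e in manifest.entries}
    report = DemuxReport(assigned={e.individual_id: 0 for e in manifest.entries})
    for pair in pairs:
        ind, result = _classify(pair, mid_map, footprint)
        if ind is None:
            report.discarded += 1
            report.discard_reasons[result] += 1
        else:
            out[ind].append(result)
            report.assigned[ind] += 1
    return out, report


def demux_to_dir(fwd_path: str | Path, rev_path: str | Path, manifest: Manifest,
                 out_dir: str | Path, footprint: str = DEFAULT_FOOTPRINT,
                 phred_offset: int = 33) -> DemuxReport:
    """Streaming demultiplexer writing per-individual tag and mate FASTQ files.

    Equivalent to :func:`demultiplex` but with O(1) memory in the number of
    reads; used for full-size libraries.  Writes ``<ind>.tags.fastq`` and
    ``<ind>.mates.fastq`` per individual plus ``demux_report.tsv``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    mid_map = manifest.mid_map()
    fp_len = len(footprint)
    tag_end = MID_LEN + fp_len + TAG_LEN
    report = DemuxReport(assigned={e.individual_id: 0 for e in manifest.entries})
    handles: dict[str, tuple] = {}
    for e in manifest.entries:
        th = open(out_dir / f"{e.individual_id}.tags.fastq", "w", buffering=1 << 20)
        mh = open(out_dir / f"{e.individual_id}.mates.fastq", "w", buffering=1 << 20)
        handles[e.individual_id] = (th, mh)
    shift = phred_offset - 33  # re-encode to offset 33 on output
    try:
        with _open_text(fwd_path) as fh_f, _open_text(rev_path) as fh_r:
            it_f = FastqGeneralIterator(fh_f)
            it_r = FastqGeneralIterator(fh_r)
            i = 0
            for fid, fseq, fqual in it_f:
                i += 1
                try:
                    rid, rseq, rqual = next(it_r)
                except StopIteration:
                    raise FastqError(f"paired FASTQ length mismatch: {rev_path} ends at record {i}") from None
                fseq = fseq.upper()
                if len(fseq) < tag_end:
                    report.discarded += 1
                    report.discard_reasons["short_read"] += 1
                    continue
                ind = mid_map.get(fseq[:MID_LEN])
                if ind is None:
                    report.discarded += 1
                    report.discard_reasons["unknown_mid"] += 1
                    continue
                if fseq[MID_LEN:MID_LEN + fp_len] != footprint:
                    report.discarded += 1
                    report.discard_reasons["bad_footprint"] += 1
                    continue
                tag = fseq[MID_LEN + fp_len:tag_end]
                if "N" in tag:
                    report.discarded += 1
                    report.discard_reasons["n_in_tag"] += 1
                    continue
                tq = fqual[MID_LEN + fp_len:tag_end]
                if shift:
                    tq = "".join(chr(min(ord(c) - shift, 33 + QUAL_CAP)) for c in tq)
                    rqual = "".join(chr(min(ord(c) - shift, 33 + QUAL_CAP)) for c in rqual)
                name = fid.split()[0] if fid else f"read{i}"
                th, mh = handles[ind]
                th.write(f"@{name}\n{tag}\n+\n{tq}\n")
                mh.write(f"@{name}\n{rseq.upper()}\n+\n{rqual}\n")
                report.assigned[ind] += 1
            if next(it_r, None) is not None:
                raise FastqError(f"paired FASTQ length mismatch: {fwd_path} ends at record {i}")
    finally:
        for th, mh in handles.values():
            th.close()
            mh.close()
    report.to_tsv(out_dir / "demux_report.tsv")
    return report


# ---------------------------------------------------------------------------
# TagRead round-trip I/O
# ---------------------------------------------------------------------------

def write_tagreads(tagreads: Iterable[TagRead], tag_path: str | Path,
                   mate_path: str | Path) -> None:
    """Write tags and mates to a FASTQ pair (phred 33)."""
    with open(tag_path, "w", buffering=1 << 20) as th, open(mate_path, "w", buffering=1 << 20) as mh:
        for i, tr in enumerate(tagreads):
            th.write(f"@{tr.individual_id}:{i}\n{tr.tag}\n+\n{encode_quals(tr.tag_qual)}\n")
            mh.write(f"@{tr.individual_id}:{i}\n{tr.mate_seq}\n+\n{encode_quals(tr.mate_qual)}\n")


def load_tagreads(tag_path: str | Path, mate_path: str | Path,
                  individual_id: str | None = None) -> list[TagRead]:
    """Read back per-individual tag/mate FASTQ files written by the demuxer."""
    out = []
    with _open_text(tag_path) as th, _open_text(mate_path) as mh:
        it_t = FastqGeneralIterator(th)
        it_m = FastqGeneralIterator(mh)
        for (tid, tseq, tqual), (mid_, mseq, mqual) in zip(it_t, it_m):
            ind = individual_id if individual_id is not None else tid.split(":")[0]
            out.append(TagRead(ind, tseq, decode_quals(tqual), mseq, decode_quals(mqual)))
    return out
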