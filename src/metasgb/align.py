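"""Read-to-marker alignment.

The internal aligner follows a documented surrogate contract: exact 31-mer
seeds (several fixed read offsets, both strands) extended ungapped against the
marker, accepting hits at >= 90% identity over the full read.  MAPQ is a
surrogate: 60 for a single best marker, 0 for ties between markers, otherwise
10x the score gap (capped at 60).  SAM produced by an external aligner is
accepted through :func:`alignments_from_sam` so the mapping step can be
swapped out.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from ._kmers import encode, kmer_codes
from .markerdb import MarkerDatabase


@dataclass
class ReadAlignment:
    read_id: str
    marker_id: str
    start: int  # 0-based on the marker
    aligned_length: int
    read_length: int
    mapq: int
    n_mismatches: int
    seq: str | None = None  # read sequence oriented to the marker strand
    qual: str | None = None  # phred+33, same orientation


def read_fastq(path: str | Path) -> Iterator[tuple[str, str, str]]:
    """Yield (read_id, sequence, quality) from FASTQ, gzipped or plain."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        try:
            for rid, seq, qual in FastqGeneralIterator(fh):
                yield rid.split()[0], seq, qual
        except ValueError as exc:
            raise ValueError(f"malformed FASTQ record in {path}: {exc}") from exc


class MarkerIndex:
    """Seed index over the marker sequences of a database."""

    def __init__(self, db: MarkerDatabase, seed_k: int = 31):
        self.seed_k = seed_k
        self.marker_ids: list[str] = []
        self.arrays: list[np.ndarray] = []
        codes_l, midx_l, pos_l = [], [], []
        for sgb in db.sgbs:
            for m in db.markers[sgb]:
                mi = len(self.marker_ids)
                self.marker_ids.append(m.marker_id)
                arr = encode(m.sequence)
                self.arrays.append(arr)
                c, valid = kmer_codes(arr, seed_k)
                p = np.nonzero(valid)[0]
                codes_l.append(c[p])
                midx_l.append(np.full(p.size, mi, dtype=np.int32))
                pos_l.append(p.astype(np.int32))
        if codes_l:
            codes = np.concatenate(codes_l)
            order = np.argsort(codes, kind="stable")
            self.codes = codes[order]
            self.midx = np.concatenate(midx_l)[order]
            self.pos = np.concatenate(pos_l)[order]
        else:
            self.codes = np.empty(0, np.uint64)
            self.midx = np.empty(0, np.int32)
            self.pos = np.empty(0, np.int32)


_RC = str.maketrans("ACGTN", "TGCAN")


def _batch_codes(mat: np.ndarray, offset: int, k: int) -> np.ndarray:
    a = mat[:, offset : offset + k].astype(np.uint64)
    codes = np.zeros(mat.shape[0], dtype=np.uint64)
    for j in range(k):
        codes = (codes << np.uint64(2)) | (a[:, j] & np.uint64(3))
    return codes


def align_reads(
    reads: Iterable[tuple[str, str, str]],
    db: MarkerDatabase,
    index: MarkerIndex | None = None,
    min_identity: float = 0.90,
    seed_k: int = 31,
    max_range: int = 64,
    keep_sequences: bool = False,
) -> list[ReadAlignment]:
    """Align reads against the marker database; best hit per read.

    Reads shorter than the seed length or without an accepted hit produce no
    alignment.  ``max_range`` caps how many index entries a single seed may
    enumerate (repetitive seeds).
    """
    index = index or MarkerIndex(db, seed_k=seed_k)
    out: list[ReadAlignment] = []

    by_len: dict[int, list[tuple[str, str, str]]] = {}
    for r in reads:
        by_len.setdefault(len(r[1]), []).append(r)

    for rlen, group in sorted(by_len.items()):
        if rlen < seed_k:
            continue
        allow = int((1 - min_identity) * rlen)
        # dense seed offsets: a read diverged ~4% from its marker still has an
        # exact 31-mer at one of these starts with high probability
        offsets = sorted(set(range(0, rlen - seed_k + 1, 6)) | {rlen - seed_k})
        n = len(group)
        fwd = np.zeros((n, rlen), dtype=np.uint8)
        for i, (_, seq, _) in enumerate(group):
            fwd[i] = encode(seq)
        rev = (3 - np.minimum(fwd, 3))[:, ::-1]
        rev[fwd[:, ::-1] > 3] = 255

        # (orientation, offset) -> per-read [lo, hi) ranges into the index
        ranges = []
        for mat in (fwd, rev):
            for off in offsets:
                codes = _batch_codes(mat, off, seed_k)
                lo = np.searchsorted(index.codes, codes, "left")
                hi = np.searchsorted(index.codes, codes, "right")
                ranges.append((mat, off, lo, hi))
        hit_any = np.zeros(n, dtype=bool)
        for _, _, lo, hi in ranges:
            hit_any |= hi > lo

        for i in np.nonzero(hit_any)[0]:
            seen: set[tuple[int, int, int]] = set()
            best: dict[int, tuple[int, int, int, int]] = {}  # marker -> (score, start, mism, orient)
            for oi, (mat, off, lo, hi) in enumerate(ranges):
                orient = 0 if oi < len(offsets) else 1
                for e in range(int(lo[i]), min(int(hi[i]), int(lo[i]) + max_range)):
                    mi = int(index.midx[e])
                    st = int(index.pos[e]) - off
                    key = (mi, st, orient)
                    if key in seen:
                        continue
                    seen.add(key)
                    marr = index.arrays[mi]
                    if st < 0 or st + rlen > marr.size:
                        continue
                    row = mat[i]
                    mism = int(np.count_nonzero(marr[st : st + rlen] != row))
                    if mism > allow:
                        continue
                    score = rlen - mism
                    if mi not in best or score > best[mi][0]:
                        best[mi] = (score, st, mism, orient)
            if not best:
                continue
            ranked = sorted(
                best.items(), key=lambda kv: (-kv[1][0], index.marker_ids[kv[0]])
            )
            (mi, (score, st, mism, orient)) = ranked[0]
            if len(ranked) == 1:
                mapq = 60
            elif ranked[1][1][0] == score:
                mapq = 0
            else:
                mapq = min(60, 10 * (score - ranked[1][1][0]))
            rid, seq, qual = group[i]
            aln = ReadAlignment(
                read_id=rid,
                marker_id=index.marker_ids[mi],
                start=st,
                aligned_length=rlen,
                read_length=rlen,
                mapq=mapq,
                n_mismatches=mism,
            )
            if keep_sequences:
                aln.seq = seq.translate(_RC)[::-1] if orient else seq
                aln.qual = qual[::-1] if orient else qual
            out.append(aln)
    return out


def filter_alignments(
    alns: Iterable[ReadAlignment], min_read_len: int = 70, min_mapq: int = 5
) -> list[ReadAlignment]:
    """Drop short reads (< ``min_read_len``) and low-MAPQ (< ``min_mapq``)."""
    return [
        a for a in alns if a.read_length >= min_read_len and a.mapq >= min_mapq
    ]


def alignments_from_sam(path: str | Path) -> list[ReadAlignment]:
    """Read-to-marker alignments from a SAM file (external aligner path)."""
    import pysam

    out = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for rec in sam:
            if rec.is_unmapped:
                continue
            out.append(
                ReadAlignment(
                    read_id=rec.query_name,
                    marker_id=rec.reference_name,
                    start=rec.reference_start,
                    aligned_length=rec.query_alignment_length,
                    read_length=rec.query_length or rec.infer_read_length() or 0,
                    mapq=rec.mapping_quality,
                    n_mismatches=(
                        rec.get_tag("NM") if rec.has_tag("NM") else 0
                    ),
                    seq=rec.query_sequence,
                    qual=(
                        "".join(chr(q + 33) for q in rec.query_qualities)
                        if rec.query_qualities is not None
                        else None
                    ),
                )
            )
    return out


def write_sam(
    alignments: Sequence[ReadAlignment], db: MarkerDatabase, path: str | Path
) -> None:
    """Write alignments as SAM against the marker sequences."""
    import pysam

    marker_map = db.marker_map()
    names = sorted(marker_map)
    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": n, "LN": marker_map[n].length} for n in names],
    }
    ref_id = {n: i for i, n in enumerate(names)}
    with pysam.AlignmentFile(str(path), "wh", header=header) as sam:
        for a in alignments:
            rec = pysam.AlignedSegment(sam.header)
            rec.query_name = a.read_id
            rec.reference_id = ref_id[a.marker_id]
            rec.reference_start = a.start
            rec.mapping_quality = a.mapq
            rec.cigarstring = f"{a.aligned_length}M"
            if a.seq:
                rec.query_sequence = a.seq
                if a.qual:
                    rec.query_qualities = pysam.qualitystring_to_array(a.qual)
            rec.set_tag("NM", a.n_mismatches)
            sam.write(rec)


def read_mapping_file(path: str | Path, read_length: int) -> list[ReadAlignment]:
    """Two-column read_id TAB marker_id mapping (pre-performed alignment).

    Positions are unknown in this format; alignments carry full-length reads
    at MAPQ 60 and start 0, suitable for coverage-based profiling only.
    """
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            rid, mid = line.rstrip("\n").split("\t")[:2]
            out.append(
                ReadAlignment(
                    read_id=rid,
                    marker_id=mid,
                    start=0,
                    aligned_length=read_length,
                    read_length=read_length,
                    mapq=60,
                    n_mismatches=0,
                )
            )
    return out
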