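"""SGB-resolved taxonomic profiling from read-to-marker alignments.

Marker depths are combined into a clade coverage by a robust (quantile-
truncated) average, SGBs are detected when a sufficient fraction of their
markers attract reads, coverages are normalised within the sample to
relative abundances, and the fraction of reads not attributable to any
database SGB can be estimated from coverage x genome length accounting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .align import (
    MarkerIndex,
    ReadAlignment,
    align_reads,
    filter_alignments,
    read_fastq,
)
from .markerdb import MarkerDatabase

RANKS = ("kingdom", "phylum", "class", "order", "family", "genus", "species", "SGB")


@dataclass
class MarkerCoverage:
    marker_id: str
    depth: float  # mean reads per base
    breadth: float  # covered fraction of the marker
    n_reads: int


def compute_marker_coverages(
    alignments: Iterable[ReadAlignment], db: MarkerDatabase
) -> dict[str, MarkerCoverage]:
    """Per-marker depth, breadth and read count (markers without reads omitted)."""
    marker_map = db.marker_map()
    by_marker: dict[str, list[ReadAlignment]] = {}
    for a in alignments:
        by_marker.setdefault(a.marker_id, []).append(a)
    out = {}
    for mid, alns in by_marker.items():
        L = marker_map[mid].length
        covered = np.zeros(L, dtype=bool)
        total = 0
        for a in alns:
            end = min(a.start + a.aligned_length, L)
            covered[a.start : end] = True
            total += a.aligned_length
        out[mid] = MarkerCoverage(
            marker_id=mid,
            depth=total / L,
            breadth=float(covered.mean()),
            n_reads=len(alns),
        )
    return out


def detected_marker_fraction(
    coverages: Mapping[str, MarkerCoverage], db: MarkerDatabase
) -> dict[str, float]:
    """Fraction of each SGB's markers with at least one mapped read."""
    return {
        sgb: sum(
            1
            for m in db.markers[sgb]
            if coverages.get(m.marker_id) and coverages[m.marker_id].n_reads > 0
        )
        / len(db.markers[sgb])
        for sgb in db.sgbs
    }


def robust_average(values: Sequence[float], stat_q: float = 0.2) -> float:
    """Mean after discarding the top and bottom ``floor(stat_q * n)`` entries.

    Vectors shorter than 3 take the plain mean.
    """
    v = np.sort(np.asarray(values, dtype=float))
    n = v.size
    if n == 0:
        return 0.0
    if n < 3:
        return float(v.mean())
    cut = int(math.floor(stat_q * n))
    kept = v[cut : n - cut] if cut > 0 else v
    return float(kept.mean()) if kept.size else 0.0


def clade_coverage(
    sgb: str,
    coverages: Mapping[str, MarkerCoverage],
    db: MarkerDatabase,
    detected_fraction: Mapping[str, float],
    stat_q: float = 0.2,
    perc_nonzero: float = 0.33,
) -> float:
    """Robust average coverage over the full marker vector of one SGB.

    Undetected markers contribute zero; quasi-markers are dropped when any of
    their external SGBs has at least ``perc_nonzero`` of its own markers
    present in the sample.
    """
    vec = []
    for m in db.markers[sgb]:
        if m.is_quasi and any(
            detected_fraction.get(ext, 0.0) >= perc_nonzero
            for ext, _ in m.ext_sgbs
        ):
            continue
        cov = coverages.get(m.marker_id)
        vec.append(cov.depth if cov else 0.0)
    if not vec:
        return 0.0
    return robust_average(vec, stat_q=stat_q)


@dataclass
class TaxonomicProfile:
    """Per-clade coverage and relative abundance (percent) across ranks."""

    frame: pd.DataFrame  # columns: clade_name, rank, coverage, relative_abundance
    total_reads: int = 0
    avg_read_length: float = 0.0
    unclassified_percent: float | None = None
    avg_nonzero_coverage: dict[str, float] = field(default_factory=dict)

    def sgb_abundances(self) -> dict[str, float]:
        """SGB id -> relative abundance percent (terminal t__ rows)."""
        rows = self.frame[self.frame["rank"] == "SGB"]
        return {
            r.clade_name.rsplit("|t__", 1)[1]: r.relative_abundance
            for r in rows.itertuples(index=False)
        }

    def detected_sgbs(self) -> set[str]:
        return set(self.sgb_abundances())


def detect_and_normalize(
    coverages_by_sgb: Mapping[str, float],
    detected_fraction: Mapping[str, float],
    db: MarkerDatabase,
    min_marker_fraction: float = 0.2,
) -> TaxonomicProfile:
    """Report SGBs passing the marker-detection threshold, normalised to 100.

    An SGB is reported iff at least ``min_marker_fraction`` of its markers
    attracted reads (inclusive) and its clade coverage is positive.  Higher
    ranks receive the sum of their descendant SGB abundances and coverages.
    """
    detected = {
        sgb: cov
        for sgb, cov in coverages_by_sgb.items()
        if detected_fraction.get(sgb, 0.0) >= min_marker_fraction and cov > 0
    }
    total = sum(detected.values())
    rows: dict[str, list] = {}
    for sgb, cov in detected.items():
        rel = 100.0 * cov / total
        tax = db.taxonomy.get(sgb, "")
        parts = tax.split("|") if tax else []
        clade = "|".join(parts + [f"t__{sgb}"])
        for depth in range(1, len(parts) + 1):
            name = "|".join(parts[:depth])
            rec = rows.setdefault(name, [RANKS[depth - 1], 0.0, 0.0])
            rec[1] += cov
            rec[2] += rel
        rec = rows.setdefault(clade, ["SGB", 0.0, 0.0])
        rec[1] += cov
        rec[2] += rel
    frame = pd.DataFrame(
        [
            (name, rank, cov, rel)
            for name, (rank, cov, rel) in rows.items()
        ],
        columns=["clade_name", "rank", "coverage", "relative_abundance"],
    )
    if len(frame):
        order = {r: i for i, r in enumerate(RANKS)}
        frame = frame.sort_values(
            by=["rank", "relative_abundance", "clade_name"],
            key=lambda c: c.map(order) if c.name == "rank" else c,
            ascending=[True, False, True],
        ).reset_index(drop=True)
    return TaxonomicProfile(frame=frame)


def estimate_unclassified(
    profile: TaxonomicProfile,
    db: MarkerDatabase,
    total_reads: int,
    avg_read_length: float,
) -> float:
    """Estimated percent of input reads not attributable to database SGBs.

    unclassified = (N - sum_sp avg_nonzero_cov_sp * genome_len_sp / read_len) / N
    clamped to [0, 1]; uSGB genome lengths are inflated by 7% (the average
    size deficit of MAGs relative to reference genomes), kSGB lengths come
    from reference genomes only.
    """
    if total_reads <= 0:
        raise ValueError("total_reads must be positive")
    if avg_read_length <= 0:
        raise ValueError("avg_read_length must be positive")
    classified = 0.0
    for sgb in profile.detected_sgbs():
        glen = db.avg_genome_length.get(sgb, 0.0)
        if not db.is_known.get(sgb, True):
            glen *= 1.07
        classified += profile.avg_nonzero_coverage.get(sgb, 0.0) * glen
    classified /= avg_read_length
    frac = (total_reads - classified) / total_reads
    return 100.0 * min(1.0, max(0.0, frac))


def apply_unclassified(profile: TaxonomicProfile, unclassified_percent: float) -> None:
    """Rescale clade abundances so they sum to 100 - unclassified."""
    scale = (100.0 - unclassified_percent) / 100.0
    profile.frame["relative_abundance"] *= scale
    profile.unclassified_percent = unclassified_percent


def profile_sample(
    reads: Iterable[tuple[str, str, str]] | str | Path | None = None,
    db: MarkerDatabase | None = None,
    alignments: Sequence[ReadAlignment] | None = None,
    index: MarkerIndex | None = None,
    stat_q: float = 0.2,
    perc_nonzero: float = 0.33,
    min_mapq: int = 5,
    min_read_len: int = 70,
    min_marker_fraction: float = 0.2,
    unclassified_estimation: bool = False,
    total_reads: int | None = None,
    avg_read_length: float | None = None,
) -> TaxonomicProfile:
    """End-to-end profiling of one sample (reads or precomputed alignments)."""
    if db is None:
        raise ValueError("a MarkerDatabase is required")
    if alignments is None:
        if isinstance(reads, (str, Path)):
            reads = list(read_fastq(reads))
        else:
            reads = list(reads or [])
        if total_reads is None:
            total_reads = len(reads)
        if avg_read_length is None and reads:
            avg_read_length = float(np.mean([len(r[1]) for r in reads]))
        alignments = align_reads(reads, db, index=index)
    kept = filter_alignments(alignments, min_read_len=min_read_len, min_mapq=min_mapq)
    coverages = compute_marker_coverages(kept, db)
    det_frac = detected_marker_fraction(coverages, db)
    cov_by_sgb = {
        sgb: clade_coverage(
            sgb, coverages, db, det_frac, stat_q=stat_q, perc_nonzero=perc_nonzero
        )
        for sgb in db.sgbs
    }
    profile = detect_and_normalize(
        cov_by_sgb, det_frac, db, min_marker_fraction=min_marker_fraction
    )
    profile.total_reads = int(total_reads or 0)
    profile.avg_read_length = float(avg_read_length or 0.0)
    for sgb in profile.detected_sgbs():
        depths = [
            coverages[m.marker_id].depth
            for m in db.markers[sgb]
            if m.marker_id in coverages and coverages[m.marker_id].n_reads > 0
        ]
        profile.avg_nonzero_coverage[sgb] = float(np.mean(depths)) if depths else 0.0
    if unclassified_estimation:
        if not profile.detected_sgbs():
            apply_unclassified(profile, 100.0)
        else:
            pct = estimate_unclassified(
                profile, db, profile.total_reads, profile.avg_read_length
            )
            apply_unclassified(profile, pct)
    return profile


def write_profile_tsv(
    profile: TaxonomicProfile,
    path: str | Path,
    version: str = "metasgb",
    command: str = "",
) -> None:
    """MetaPhlAn-style TSV: header lines, then clade rows."""
    with open(path, "w") as fh:
        fh.write(f"#{version}\n")
        if command:
            fh.write(f"#{command}\n")
        fh.write("#clade_name\tclade_taxid\trelative_abundance\tcoverage\n")
        if profile.unclassified_percent is not None:
            fh.write(
                f"UNCLASSIFIED\t-1\t{profile.unclassified_percent:.5f}\t-\n"
            )
        for r in profile.frame.itertuples(index=False):
            fh.write(
                f"{r.clade_name}\t-\t{r.relative_abundance:.5f}\t{r.coverage:.5f}\n"
            )


def read_profile_tsv(path: str | Path) -> TaxonomicProfile:
    rows = []
    unclassified = None
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            name, _, rel, cov = line.rstrip("\n").split("\t")
            if name == "UNCLASSIFIED":
                unclassified = float(rel)
                continue
            depth = name.count("|") + 1
            rank = RANKS[depth - 1] if "|t__" not in name else "SGB"
            rows.append((name, rank, float(cov) if cov != "-" else 0.0, float(rel)))
    frame = pd.DataFrame(
        rows, columns=["clade_name", "rank", "coverage", "relative_abundance"]
    )
    return TaxonomicProfile(frame=frame, unclassified_percent=unclassified)
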