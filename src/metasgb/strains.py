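"""Strain-level genotyping from marker pileups.

For each sample the dominant-strain consensus of every marker is called from
the read pileup (majority base; positions of low quality or low major-allele
dominance become gaps), samples and markers are co-filtered, consensuses are
concatenated into a coordinate-anchored alignment (consensus calls share the
marker reference coordinates, so columns are homologous without a de novo
MSA; insertions relative to the marker are ignored), gappy columns are
trimmed, and a neighbour-joining tree on p-distances yields normalised
phylogenetic distances and strain-sharing calls.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from io import StringIO
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj

from .align import ReadAlignment
from .markerdb import MarkerDatabase

_BASES = "ACGT"


@dataclass
class Pileup:
    """Per-position base counts and summed base qualities for one marker."""

    marker_id: str
    counts: np.ndarray  # (4, L) int32, rows A/C/G/T
    qual_sum: np.ndarray  # (L,) float, summed phred across reads
    n_reads: int = 0

    @property
    def length(self) -> int:
        return self.counts.shape[1]

    def depth(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def dominance(self) -> np.ndarray:
        """Major-allele fraction per position (1.0 where uncovered)."""
        d = self.depth()
        with np.errstate(divide="ignore", invalid="ignore"):
            dom = np.where(d > 0, self.counts.max(axis=0) / np.maximum(d, 1), 1.0)
        return dom


def build_pileups(
    alignments: Iterable[ReadAlignment], db: MarkerDatabase
) -> dict[str, Pileup]:
    """Accumulate pileups from alignments that carry read sequences."""
    marker_map = db.marker_map()
    piles: dict[str, Pileup] = {}
    for a in alignments:
        if a.seq is None:
            continue
        if a.marker_id not in piles:
            L = marker_map[a.marker_id].length
            piles[a.marker_id] = Pileup(
                a.marker_id,
                np.zeros((4, L), dtype=np.int32),
                np.zeros(L, dtype=float),
            )
        p = piles[a.marker_id]
        L = p.length
        end = min(a.start + len(a.seq), L)
        span = end - a.start
        seq_arr = np.frombuffer(a.seq[:span].encode(), dtype=np.uint8)
        pos = np.arange(a.start, end)
        for bi, b in enumerate(b"ACGT"):
            sel = seq_arr == b
            np.add.at(p.counts, (bi, pos[sel]), 1)
        if a.qual:
            q = np.frombuffer(a.qual[:span].encode(), dtype=np.uint8).astype(float) - 33
        else:
            q = np.full(span, 40.0)
        p.qual_sum[pos] += q
        p.n_reads += 1
    return piles


@dataclass
class ConsensusMarker:
    """Reconstructed dominant-strain sequence of one marker in one sample."""

    sample_id: str
    marker_id: str
    sequence: str  # over {A,C,G,T,-}; '-' = unmapped or ambiguous
    breadth: float
    mean_depth: float


def reconstruct_consensus(
    pileup: Pileup,
    sample_id: str = "",
    min_depth: int = 8,
    min_breadth: float = 0.8,
    min_base_quality: float = 30.0,
    min_dominance: float = 0.8,
) -> ConsensusMarker | None:
    """Majority-base consensus; None when the marker fails depth/breadth.

    Positions with no reads, mean base quality below ``min_base_quality`` or
    major-allele dominance below ``min_dominance`` become '-'; base ties
    resolve lexicographically.  The whole marker is rejected when covered by
    fewer than ``min_depth`` reads or with post-masking breadth below
    ``min_breadth``.
    """
    d = pileup.depth()
    with np.errstate(invalid="ignore"):
        mean_q = np.where(d > 0, pileup.qual_sum / np.maximum(d, 1), 0.0)
    dom = pileup.dominance()
    good = (d > 0) & (mean_q >= min_base_quality) & (dom >= min_dominance)
    calls = np.argmax(pileup.counts, axis=0)  # argmax ties -> lowest index = A<C<G<T
    seq = np.where(good, calls, 4)
    sequence = "".join("ACGT-"[c] for c in seq)
    breadth = float(good.mean())
    if pileup.n_reads < min_depth or breadth < min_breadth:
        return None
    return ConsensusMarker(
        sample_id=sample_id,
        marker_id=pileup.marker_id,
        sequence=sequence,
        breadth=breadth,
        mean_depth=float(d.mean()),
    )


Grid = dict[str, dict[str, ConsensusMarker]]  # sample -> marker -> consensus


def select_samples_markers(
    grid: Grid,
    sample_frac: float = 0.8,
    marker_frac: float = 0.8,
    trim: int = 50,
) -> Grid:
    """Drop thin samples, then rare markers, then trim marker ends.

    Samples holding under ``sample_frac`` of the available markers go first,
    then markers present in under ``marker_frac`` of the remaining samples;
    every retained consensus loses ``trim`` bases from each end.
    """
    if not grid:
        raise ValueError("empty genotype grid")
    available = sorted({m for per in grid.values() for m in per})
    samples = {
        s: per
        for s, per in grid.items()
        if len(per) >= sample_frac * len(available)
    }
    kept_markers = [
        m
        for m in available
        if sum(1 for per in samples.values() if m in per)
        >= marker_frac * len(samples)
    ]
    out: Grid = {}
    for s, per in samples.items():
        row = {}
        for m in kept_markers:
            if m not in per:
                continue
            cm = per[m]
            seq = cm.sequence[trim : len(cm.sequence) - trim] if trim else cm.sequence
            if not seq:
                continue
            row[m] = ConsensusMarker(
                cm.sample_id, cm.marker_id, seq, cm.breadth, cm.mean_depth
            )
        out[s] = row
    if len(out) < 4:
        raise ValueError(
            f"only {len(out)} samples survive filtering; need >= 4 for a tree"
        )
    return out


def polymorphic_rate(
    pileups: Mapping[str, Pileup], dominance_cut: float = 0.8
) -> float | None:
    """Fraction of covered positions whose major allele holds < ``dominance_cut``.

    A within-sample strain-heterogeneity signal; None when nothing is covered.
    """
    covered = 0
    poly = 0
    for p in pileups.values():
        d = p.depth()
        dom = p.dominance()
        mask = d > 0
        covered += int(mask.sum())
        poly += int((mask & (dom < dominance_cut)).sum())
    if covered == 0:
        return None
    return poly / covered


@dataclass
class StrainAlignment:
    """Concatenated, trimmed consensus matrix with a column coordinate map."""

    sample_ids: list[str]
    matrix: np.ndarray  # (n_samples, n_columns) of single-byte chars
    column_map: list[tuple[str, int]]  # column -> (marker_id, marker position)

    @property
    def length(self) -> int:
        return self.matrix.shape[1]

    def row(self, sample_id: str) -> str:
        i = self.sample_ids.index(sample_id)
        return self.matrix[i].tobytes().decode()


@dataclass
class PhyloTree:
    """Unrooted sample tree with branch lengths."""

    tree: TreeNode
    total_length: float

    @classmethod
    def from_newick(cls, newick: str) -> "PhyloTree":
        t = TreeNode.read(StringIO(newick))
        total = sum(n.length or 0.0 for n in t.traverse() if n.length)
        return cls(tree=t, total_length=total)


def build_alignment_and_tree(
    grid: Grid, max_gap_frac: float = 0.67
) -> tuple[StrainAlignment, PhyloTree]:
    """Concatenate consensuses, trim gappy columns, NJ tree on p-distances.

    Columns are homologous by construction (reference-anchored consensuses),
    columns with more than ``max_gap_frac`` gaps are removed, pairwise
    distance is mismatches over shared non-gap columns, and neighbour joining
    (negative branch lengths clamped to zero) yields the tree.
    """
    samples = sorted(grid)
    if len(samples) < 4:
        raise ValueError("need >= 4 samples for a tree")
    markers = sorted({m for per in grid.values() for m in per})
    lengths = {}
    for m in markers:
        for per in grid.values():
            if m in per:
                lengths[m] = len(per[m].sequence)
                break
    col_map: list[tuple[str, int]] = []
    blocks = []
    for m in markers:
        L = lengths[m]
        block = np.full((len(samples), L), ord("-"), dtype=np.uint8)
        for i, s in enumerate(samples):
            if m in grid[s]:
                block[i] = np.frombuffer(grid[s][m].sequence.encode(), np.uint8)
        blocks.append(block)
        col_map.extend((m, j) for j in range(L))
    mat = np.concatenate(blocks, axis=1)
    gap_frac = (mat == ord("-")).mean(axis=0)
    keep = gap_frac <= max_gap_frac
    mat = mat[:, keep]
    col_map = [c for c, k in zip(col_map, keep) if k]
    aln = StrainAlignment(sample_ids=samples, matrix=mat, column_map=col_map)

    n = len(samples)
    dm = np.zeros((n, n))
    gaps = mat == ord("-")
    for i in range(n):
        for j in range(i + 1, n):
            both = ~gaps[i] & ~gaps[j]
            nb = int(both.sum())
            if nb == 0:
                d = 0.0
            else:
                d = float(np.count_nonzero(mat[i, both] != mat[j, both])) / nb
            dm[i, j] = dm[j, i] = d
    tree = nj(DistanceMatrix(dm, ids=samples))
    for node in tree.traverse():
        if node.length is not None and node.length < 0:
            node.length = 0.0
    total = sum(node.length or 0.0 for node in tree.traverse())
    return aln, PhyloTree(tree=tree, total_length=total)


def normalized_distances(tree: PhyloTree) -> pd.DataFrame:
    """Pairwise tip-to-tip path lengths divided by the total branch length."""
    if tree.total_length <= 0:
        raise ValueError("zero total branch length: all strains identical")
    dm = tree.tree.tip_tip_distances()
    mat = dm.data / tree.total_length
    return pd.DataFrame(mat, index=list(dm.ids), columns=list(dm.ids))


def strain_sharing(
    distances: pd.DataFrame,
    pairs: Sequence[tuple[str, str]],
    cutoff: float,
) -> tuple[pd.DataFrame, float | None]:
    """Shared-strain calls for related sample pairs at a distance cutoff.

    A pair shares a strain iff its normalised distance is <= ``cutoff``
    (inclusive).  Pairs with a sample absent from the tree are skipped with a
    warning.  Returns (per-pair table, fraction of evaluable pairs shared).
    """
    rows = []
    for a, b in pairs:
        if a not in distances.index or b not in distances.index:
            warnings.warn(f"pair ({a}, {b}) not fully present in the tree; skipped")
            continue
        d = float(distances.at[a, b])
        rows.append((a, b, d, d <= cutoff))
    table = pd.DataFrame(rows, columns=["sample_a", "sample_b", "distance", "shared"])
    rate = float(table["shared"].mean()) if len(table) else None
    return table, rate


def genotype_sample(
    alignments: Iterable[ReadAlignment],
    db: MarkerDatabase,
    sgb: str,
    sample_id: str,
    min_depth: int = 8,
    min_breadth: float = 0.8,
    min_base_quality: float = 30.0,
    min_dominance: float = 0.8,
) -> tuple[dict[str, ConsensusMarker], dict[str, Pileup]]:
    """Consensus markers of one SGB for one sample, plus the raw pileups."""
    wanted = {m.marker_id for m in db.markers[sgb]}
    piles = build_pileups(
        (a for a in alignments if a.marker_id in wanted), db
    )
    consensuses = {}
    for mid, p in piles.items():
        cm = reconstruct_consensus(
            p,
            sample_id=sample_id,
            min_depth=min_depth,
            min_breadth=min_breadth,
            min_base_quality=min_base_quality,
            min_dominance=min_dominance,
        )
        if cm is not None:
            consensuses[mid] = cm
    return consensuses, piles


def write_consensus_fasta(
    grid: Grid, path: str | Path
) -> None:
    """Per-sample concatenated consensus sequences (fixed marker order)."""
    markers = sorted({m for per in grid.values() for m in per})
    with open(path, "w") as fh:
        for s in sorted(grid):
            seq = "".join(
                grid[s][m].sequence if m in grid[s] else ""
                for m in markers
            )
            fh.write(f">{s}\n{seq}\n")
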