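"""Genome catalog curation: QC, MinHash sketching, dereplication and the
clustering of genomes into species/genus/family-level genome bins (SGB/GGB/FGB).

An SGB groups genomes within 5% whole-genome distance and is the unit of
profiling; GGBs and FGBs nest SGBs at 15% and 30% distance.  A bin containing
at least one isolate reference genome is "known" (kSGB), a bin defined solely
by metagenome-assembled genomes (MAGs) is "unknown" (uSGB).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from ._kmers import bottom_hashes, encode

RANK_PREFIXES = ("k__", "p__", "c__", "o__", "f__", "g__", "s__")
RANK_NAMES = ("kingdom", "phylum", "class", "order", "family", "genus", "species")

LEVEL_CUTOFFS = {"SGB": 0.05, "GGB": 0.15, "FGB": 0.30}


@dataclass
class GenomeRecord:
    """A genome with its QC and taxonomy metadata.

    ``completeness``/``contamination`` are consumed as given (percent scales);
    isolates may carry a full 7-rank taxonomy, MAGs carry none at input.
    """

    genome_id: str
    contigs: list[str]
    source: str = "MAG"  # "isolate" or "MAG"
    completeness: float = 100.0
    contamination: float = 0.0
    taxonomy: str | None = None
    sample_id: str = ""
    environment: str = ""

    def __post_init__(self) -> None:
        if not self.contigs:
            raise ValueError(f"{self.genome_id}: contigs must be nonempty")
        if not (0 <= self.completeness <= 100):
            raise ValueError(f"{self.genome_id}: completeness outside [0,100]")
        if not (0 <= self.contamination <= 100):
            raise ValueError(f"{self.genome_id}: contamination outside [0,100]")
        if self.source not in ("isolate", "MAG"):
            raise ValueError(f"{self.genome_id}: source must be isolate or MAG")

    @property
    def length(self) -> int:
        return sum(len(c) for c in self.contigs)

    @property
    def quality_score(self) -> float:
        """Completeness − 5 × contamination (CheckM-community convention)."""
        return self.completeness - 5.0 * self.contamination

    def sequence(self) -> str:
        return "".join(self.contigs)


@dataclass
class Sketch:
    """Bottom-s MinHash sketch of a genome's canonical k-mers."""

    genome_id: str
    k: int
    s: int
    hashes: np.ndarray  # sorted, strictly increasing, |hashes| <= s


def sketch_genome(record: GenomeRecord, k: int = 21, s: int = 1000) -> Sketch:
    parts = [bottom_hashes(encode(c), k, s) for c in record.contigs]
    hashes = np.unique(np.concatenate(parts))[:s] if parts else np.empty(0, np.uint64)
    return Sketch(record.genome_id, k, s, hashes)


def minhash_distance(a: Sketch, b: Sketch) -> float:
    """Mash-style distance from merged bottom-s sketches.

    d = min(1, -(1/k) * ln(2J / (1 + J))) with J the Jaccard estimate from
    the s smallest hashes of the sketch union; J = 0 maps to the cap at 1.
    """
    if a.k != b.k or a.s != b.s:
        raise ValueError("sketches must share k and s")
    # hashes are sorted and unique: merge, dedupe, take the bottom s
    u = np.concatenate([a.hashes, b.hashes])
    u.sort(kind="mergesort")
    if u.size == 0:
        return 1.0
    keep = np.empty(u.size, dtype=bool)
    keep[0] = True
    np.not_equal(u[1:], u[:-1], out=keep[1:])
    u = u[keep][: a.s]

    def member(h: np.ndarray) -> np.ndarray:
        idx = np.searchsorted(h, u)
        ok = idx < h.size
        ok[ok] = h[idx[ok]] == u[ok]
        return ok

    shared = int(np.count_nonzero(member(a.hashes) & member(b.hashes)))
    j = shared / u.size
    if j <= 0:
        return 1.0
    return min(1.0, -(1.0 / a.k) * math.log(2.0 * j / (1.0 + j)))


def distance_matrix(
    records: Sequence[GenomeRecord], k: int = 21, s: int = 1000
) -> pd.DataFrame:
    """All-versus-all MinHash distances as a symmetric DataFrame."""
    sketches = [sketch_genome(r, k=k, s=s) for r in records]
    ids = [r.genome_id for r in records]
    n = len(ids)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            mat[i, j] = mat[j, i] = minhash_distance(sketches[i], sketches[j])
    return pd.DataFrame(mat, index=ids, columns=ids)


def qc_and_dereplicate(
    genomes: Sequence[GenomeRecord],
    derep_dist: float = 0.0001,
    distances: pd.DataFrame | None = None,
    k: int = 21,
    s: int = 1000,
) -> list[GenomeRecord]:
    """QC filter then dereplicate near-identical genomes.

    Keeps genomes with completeness >= 50 and contamination <= 5 (boundary
    values retained), then collapses groups whose pairwise sketch distance is
    <= ``derep_dist`` (99.99% identity default) to the highest-quality member
    (ties by genome_id).
    """
    if not genomes:
        raise ValueError("genomes must be nonempty")
    passed = [g for g in genomes if g.completeness >= 50 and g.contamination <= 5]
    if len(passed) <= 1:
        return passed
    if distances is None:
        distances = distance_matrix(passed, k=k, s=s)
    ids = [g.genome_id for g in passed]
    sub = distances.loc[ids, ids].to_numpy()
    # single-linkage components at derep_dist: transitive near-identity groups
    n = len(ids)
    labels = fcluster(
        linkage(squareform(sub, checks=False), method="single"),
        t=derep_dist,
        criterion="distance",
    ) if n > 1 else np.array([1])
    by_group: dict[int, list[GenomeRecord]] = {}
    for g, lab in zip(passed, labels):
        by_group.setdefault(int(lab), []).append(g)
    reps = [
        max(members, key=lambda g: (g.quality_score, g.genome_id))
        if len(members) > 1
        else members[0]
        for members in by_group.values()
    ]
    reps.sort(key=lambda g: ids.index(g.genome_id))
    return reps


@dataclass
class GenomeBin:
    """An SGB, GGB or FGB cluster of genomes."""

    level: str
    bin_id: str
    members: list[str]
    n_refs: int
    n_mags: int
    centroid_id: str
    taxonomy: str | None = None
    parent_id: str | None = None

    @property
    def known(self) -> bool:
        return self.n_refs > 0


@dataclass
class BinHierarchy:
    """Nested SGB/GGB/FGB partition of a genome catalog."""

    bins: dict[str, dict[str, GenomeBin]] = field(
        default_factory=lambda: {"SGB": {}, "GGB": {}, "FGB": {}}
    )

    def level(self, level: str) -> dict[str, GenomeBin]:
        return self.bins[level]

    def bin_of(self, genome_id: str, level: str) -> GenomeBin:
        for b in self.bins[level].values():
            if genome_id in b.members:
                return b
        raise KeyError(f"{genome_id} not binned at {level}")

    def sgb_of(self) -> dict[str, str]:
        """genome_id -> SGB id map."""
        return {
            g: b.bin_id for b in self.bins["SGB"].values() for g in b.members
        }

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for level in ("SGB", "GGB", "FGB"):
            for b in self.bins[level].values():
                for g in b.members:
                    rows.append(
                        (level, b.bin_id, g, b.known, b.taxonomy or "")
                    )
        return pd.DataFrame(
            rows, columns=["level", "bin_id", "genome_id", "known", "taxonomy"]
        )

    def to_json(self, path: str | Path) -> None:
        obj = {
            level: {
                b.bin_id: {
                    "members": b.members,
                    "n_refs": b.n_refs,
                    "n_mags": b.n_mags,
                    "known": b.known,
                    "centroid_id": b.centroid_id,
                    "taxonomy": b.taxonomy,
                    "parent_id": b.parent_id,
                }
                for b in bins.values()
            }
            for level, bins in self.bins.items()
        }
        Path(path).write_text(json.dumps(obj, indent=1))


def _medoid(members: list[str], dist: pd.DataFrame) -> str:
    if len(members) == 1:
        return members[0]
    sub = dist.loc[members, members].to_numpy()
    sums = sub.sum(axis=1)
    order = sorted(range(len(members)), key=lambda i: (sums[i], members[i]))
    return members[order[0]]


def cluster_bins(
    distances: pd.DataFrame,
    cutoffs: Mapping[str, float] | None = None,
    existing: BinHierarchy | None = None,
    sources: Mapping[str, str] | None = None,
) -> BinHierarchy:
    """Average-linkage clustering of genomes into nested SGB/GGB/FGB bins.

    When ``existing`` is given, each genome within the level cutoff of an
    existing bin's centroid is assigned to that bin first (closest centroid,
    ties by distance then bin_id); the remaining genomes are clustered de novo
    and the dendrogram is cut at each cutoff (merges at linkage <= cutoff).
    """
    cutoffs = dict(cutoffs or LEVEL_CUTOFFS)
    if list(sorted(cutoffs.values())) != [
        cutoffs["SGB"],
        cutoffs["GGB"],
        cutoffs["FGB"],
    ]:
        raise ValueError("cutoffs must increase SGB < GGB < FGB")
    mat = distances.to_numpy()
    if not np.allclose(mat, mat.T) or not np.allclose(np.diag(mat), 0):
        raise ValueError("distance matrix must be symmetric with zero diagonal")
    sources = sources or {}
    ids = list(distances.index)

    hier = BinHierarchy()
    counters = {"SGB": 0, "GGB": 0, "FGB": 0}
    if existing is not None:
        for level in ("SGB", "GGB", "FGB"):
            for b in existing.level(level).values():
                hier.level(level)[b.bin_id] = GenomeBin(
                    level, b.bin_id, list(b.members), b.n_refs, b.n_mags,
                    b.centroid_id, b.taxonomy, b.parent_id,
                )
                num = int("".join(ch for ch in b.bin_id if ch.isdigit()) or 0)
                counters[level] = max(counters[level], num)

    assigned: set[str] = set()
    if existing is not None:
        already = {
            g for b in hier.level("SGB").values() for g in b.members
        }
        assigned |= already & set(ids)
        for gid in ids:
            if gid in assigned:
                continue
            target = None
            for level in ("SGB", "GGB", "FGB"):
                cands = []
                for b in hier.level(level).values():
                    if b.centroid_id in distances.index:
                        d = float(distances.at[gid, b.centroid_id])
                        if d <= cutoffs[level]:
                            cands.append((d, b.bin_id, b))
                if cands:
                    cands.sort(key=lambda t: (t[0], t[1]))
                    target = (level, cands[0][2])
                    break
            if target is None:
                continue
            level, b = target
            lineage = {"SGB": None, "GGB": None, "FGB": None}
            if level == "SGB":
                lineage["SGB"] = b
                lineage["GGB"] = hier.level("GGB")[b.parent_id]
                lineage["FGB"] = hier.level("FGB")[lineage["GGB"].parent_id]
            elif level == "GGB":
                lineage["GGB"] = b
                lineage["FGB"] = hier.level("FGB")[b.parent_id]
            else:
                lineage["FGB"] = b
            # new bins for levels below the matched one
            for lvl, parent_lvl in (("GGB", "FGB"), ("SGB", "GGB")):
                if lineage[lvl] is None:
                    counters[lvl] += 1
                    nb = GenomeBin(
                        lvl, f"{lvl}{counters[lvl]}", [], 0, 0, gid,
                        parent_id=lineage[parent_lvl].bin_id,
                    )
                    hier.level(lvl)[nb.bin_id] = nb
                    lineage[lvl] = nb
            for lvl in ("SGB", "GGB", "FGB"):
                b = lineage[lvl]
                b.members.append(gid)
                if sources.get(gid) == "isolate":
                    b.n_refs += 1
                else:
                    b.n_mags += 1
            assigned.add(gid)

    rest = [g for g in ids if g not in assigned]
    if rest:
        sub = distances.loc[rest, rest].to_numpy()
        if len(rest) == 1:
            labels = {"SGB": np.array([1]), "GGB": np.array([1]), "FGB": np.array([1])}
        else:
            lk = linkage(squareform(sub, checks=False), method="average")
            labels = {
                lvl: fcluster(lk, t=cutoffs[lvl], criterion="distance")
                for lvl in ("SGB", "GGB", "FGB")
            }
        for lvl in ("FGB", "GGB", "SGB"):
            groups: dict[int, list[str]] = {}
            for gid, lab in zip(rest, labels[lvl]):
                groups.setdefault(int(lab), []).append(gid)
            # deterministic numbering: by smallest member id
            for members in sorted(groups.values(), key=lambda m: min(m)):
                counters[lvl] += 1
                bin_id = f"{lvl}{counters[lvl]}"
                n_refs = sum(1 for g in members if sources.get(g) == "isolate")
                b = GenomeBin(
                    lvl, bin_id, sorted(members), n_refs,
                    len(members) - n_refs, _medoid(sorted(members), distances),
                )
                hier.level(lvl)[b.bin_id] = b
        # wire parents by membership
        for lvl, parent_lvl in (("SGB", "GGB"), ("GGB", "FGB")):
            for b in hier.level(lvl).values():
                if b.parent_id is not None:
                    continue
                probe = b.members[0]
                for pb in hier.level(parent_lvl).values():
                    if probe in pb.members:
                        b.parent_id = pb.bin_id
                        break
    return hier


def _split_label(taxonomy: str) -> list[str]:
    return taxonomy.split("|")


def _majority(labels: list[str]) -> str | None:
    """Majority label, ties broken alphabetically (the representative taxon)."""
    if not labels:
        return None
    counts: dict[str, int] = {}
    for lab in labels:
        counts[lab] = counts.get(lab, 0) + 1
    best = max(counts.values())
    return sorted(lab for lab, c in counts.items() if c == best)[0]


def assign_taxonomy(
    bin_: GenomeBin,
    hierarchy: BinHierarchy,
    ref_taxonomies: Mapping[str, str],
    distances: pd.DataFrame | None = None,
) -> str:
    """Taxonomic label for an SGB from the reference genomes it (or its
    ancestors) contains.

    kSGBs take the majority 7-rank label of their member references; uSGBs
    fall back to the genus-level majority at the GGB, then the family-level
    majority at the FGB, then the phylum of the closest reference (plus up to
    100 references within closest+5% distance).  Ranks left unlabeled are
    filled with SGB/GGB/FGB-derived placeholders.
    """
    ggb = hierarchy.level("GGB")[bin_.parent_id]
    fgb = hierarchy.level("FGB")[ggb.parent_id]
    sgb_num = bin_.bin_id.replace("SGB", "")
    ggb_num = ggb.bin_id.replace("GGB", "")
    fgb_num = fgb.bin_id.replace("FGB", "")
    placeholders = [
        "k__Bacteria",
        f"p__PFGB{fgb_num}",
        f"c__CFGB{fgb_num}",
        f"o__OFGB{fgb_num}",
        f"f__FGB{fgb_num}",
        f"g__GGB{ggb_num}",
        f"s__SGB{sgb_num}",
    ]

    def member_refs(b: GenomeBin) -> list[str]:
        return [g for g in b.members if g in ref_taxonomies]

    ranks = list(placeholders)
    refs = member_refs(bin_)
    if refs:  # kSGB: full 7-rank majority label
        lab = _majority([ref_taxonomies[g] for g in refs])
        ranks[: 7] = _split_label(lab)[:7]
    else:
        ggb_refs = member_refs(ggb)
        if ggb_refs:
            lab = _majority(
                ["|".join(_split_label(ref_taxonomies[g])[:6]) for g in ggb_refs]
            )
            ranks[:6] = _split_label(lab)
        else:
            fgb_refs = member_refs(fgb)
            if fgb_refs:
                lab = _majority(
                    ["|".join(_split_label(ref_taxonomies[g])[:5]) for g in fgb_refs]
                )
                ranks[:5] = _split_label(lab)
            elif distances is not None and len(ref_taxonomies) > 0:
                ref_ids = [
                    g for g in ref_taxonomies if g in distances.index
                ]
                if ref_ids:
                    probe = bin_.centroid_id
                    ds = sorted(
                        (float(distances.at[probe, g]), g) for g in ref_ids
                    )
                    closest = ds[0][0]
                    window = [g for d, g in ds if d <= closest + 0.05][:100]
                    phyla = [
                        _split_label(ref_taxonomies[g])[1] for g in window
                    ]
                    ph = _majority(phyla)
                    if ph is not None:
                        ranks[1] = ph
    return "|".join(ranks)


def filter_usgbs(bins: Iterable[GenomeBin], min_mags: int = 5) -> list[GenomeBin]:
    """Drop uSGBs with fewer than ``min_mags`` MAGs; every kSGB is retained."""
    kept = []
    for b in bins:
        if b.level != "SGB":
            raise ValueError("filter_usgbs expects SGB-level bins")
        if b.known or b.n_mags >= min_mags:
            kept.append(b)
    return kept


# ---------------------------------------------------------------------------
# External interfaces: FASTA per genome + metadata TSV

METADATA_COLUMNS = [
    "genome_id", "source", "completeness", "contamination",
    "taxonomy", "sample_id", "environment",
]


def write_catalog(
    records: Sequence[GenomeRecord], outdir: str | Path
) -> Path:
    """Write one FASTA per genome plus the metadata TSV; returns the TSV path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for r in records:
        with open(outdir / f"{r.genome_id}.fasta", "w") as fh:
            for i, contig in enumerate(r.contigs):
                fh.write(f">{r.genome_id}_c{i}\n")
                for j in range(0, len(contig), 80):
                    fh.write(contig[j : j + 80] + "\n")
        rows.append(
            (r.genome_id, r.source, r.completeness, r.contamination,
             r.taxonomy or "", r.sample_id, r.environment)
        )
    meta = outdir / "metadata.tsv"
    pd.DataFrame(rows, columns=METADATA_COLUMNS).to_csv(meta, sep="\t", index=False)
    return meta


def read_catalog(metadata_tsv: str | Path) -> list[GenomeRecord]:
    """Load GenomeRecords from a metadata TSV plus per-genome FASTA files."""
    meta = pd.read_csv(metadata_tsv, sep="\t", keep_default_na=False)
    base = Path(metadata_tsv).parent
    records = []
    for row in meta.itertuples(index=False):
        contigs = [
            str(rec.seq)
            for rec in SeqIO.parse(base / f"{row.genome_id}.fasta", "fasta")
        ]
        records.append(
            GenomeRecord(
                genome_id=row.genome_id,
                contigs=contigs,
                source=row.source,
                completeness=float(row.completeness),
                contamination=float(row.contamination),
                taxonomy=row.taxonomy or None,
                sample_id=str(row.sample_id),
                environment=str(row.environment),
            )
        )
    return records
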