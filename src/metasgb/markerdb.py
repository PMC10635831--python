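"""SGB pangenomes, core-gene selection and the unique/quasi marker database.

For every SGB the genes of its member genomes are greedily clustered into
gene families at the amino-acid level (>90% identity over >80% of the
centroid).  A coreness value — the prevalence of a family within the
quality-ranked genomes of the SGB — selects core genes; core genes are split
into 150-nt fragments and screened against the genomes of every other SGB,
keeping genes hitting no external genome (unique markers) or fewer than 1%
of any external SGB's genomes (quasi-markers).  SGBs short of markers go
through a three-step rescue (dropping small conflicting externals, dropping
poorly-labelled externals, merging heavily conflicting SGBs) and at most 200
markers per SGB are kept, unique first then longer first.
"""

from __future__ import annotations

import json
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import edlib
import numpy as np
from Bio.Seq import Seq

from ._kmers import encode, kmer_codes
from .catalog import BinHierarchy, GenomeRecord, filter_usgbs

MARKER_MIN_LEN = 450
MARKER_MAX_LEN = 4500

#: species labels considered low-quality during marker rescue
LOW_QUALITY_LABEL = re.compile(
    r"(C|c)andidat(e|us)|_sp(_.*|$)|(.*_|^)(b|B)acterium(_.*|)"
    r"|.*(eury|)archaeo(n_|te|n$).*|.*(endo|)symbiont.*|.*genomosp_.*"
    r"|.*unidentified.*|.*_bacteria_.*|.*_taxon_.*|.*_et_al_.*|.*_and_.*"
    r"|.*(cyano|proteo|actino)bacterium_.*"
)


@dataclass
class GeneFamily:
    family_id: str
    representative_nt: str
    members: dict[str, list[str]] = field(default_factory=dict)
    coreness: float = 0.0

    @property
    def length(self) -> int:
        return len(self.representative_nt)


@dataclass
class Pangenome:
    sgb_id: str
    families: list[GeneFamily]
    coreness_threshold: float | None = None  # fraction
    core_genes: list[GeneFamily] = field(default_factory=list)
    discarded: bool = False


@dataclass
class MarkerGene:
    marker_id: str
    sgb_id: str
    sequence: str
    is_quasi: bool = False
    ext_sgbs: list[tuple[str, float]] = field(default_factory=list)
    own_hit_fraction: float = 1.0

    @property
    def length(self) -> int:
        return len(self.sequence)


def _translate(nt: str) -> str | None:
    """Frame-1 standard-code translation; None for dubious CDSs."""
    if sum(c not in "ACGTacgt" for c in nt) > 0.05 * len(nt):
        return None
    aa = str(Seq(nt[: len(nt) - len(nt) % 3]).translate())
    body = aa[:-1] if aa.endswith("*") else aa
    if "*" in body or "X" in body:
        return None
    return body


def cluster_gene_families(
    genes: Mapping[str, Sequence[tuple[str, str]]],
    identity: float = 0.90,
    coverage: float = 0.80,
) -> list[GeneFamily]:
    """Greedy centroid clustering of per-genome genes at the amino-acid level.

    Genes (longest first, ties by id) join the first existing family whose
    centroid they match at > ``identity`` over > ``coverage`` of the centroid
    length; otherwise they found a new family.  The nucleotide sequence of the
    centroid is retained as representative.
    """
    entries = []
    for genome_id, glist in genes.items():
        for gene_id, nt in glist:
            aa = _translate(nt)
            if aa is None:
                warnings.warn(f"skipping dubious CDS {gene_id}")
                continue
            entries.append((genome_id, gene_id, nt, aa))
    entries.sort(key=lambda e: (-len(e[3]), e[1]))

    families: list[GeneFamily] = []
    centroids: list[str] = []  # AA sequences, same order as families
    for genome_id, gene_id, nt, aa in entries:
        placed = None
        for fi, caa in enumerate(centroids):
            if len(aa) <= coverage * len(caa):  # cannot cover enough
                continue
            max_dist = int(len(aa) * (1 - identity))
            res = edlib.align(aa, caa, mode="HW", task="distance", k=max_dist)
            if res["editDistance"] == -1:
                continue
            if 1 - res["editDistance"] / len(aa) > identity:
                placed = fi
                break
        if placed is None:
            fam = GeneFamily(family_id=gene_id, representative_nt=nt)
            fam.members[genome_id] = [gene_id]
            families.append(fam)
            centroids.append(aa)
        else:
            families[placed].members.setdefault(genome_id, []).append(gene_id)
    return families


def compute_coreness(
    families: Iterable[GeneFamily], quality_ranked: Sequence[str]
) -> None:
    """Coreness = prevalence within the quality-ranked genome subset."""
    subset = set(quality_ranked)
    for fam in families:
        present = sum(1 for g in fam.members if g in subset)
        fam.coreness = present / len(subset) if subset else 0.0


def select_core_genes(pangenome: Pangenome, n_genomes: int) -> Pangenome:
    """Pick the coreness threshold and core set; mark tiny core sets DISCARD.

    Scans integer-percent thresholds from 100 down to the bound (60% for SGBs
    with fewer than 100 genomes, 50% otherwise) for the largest threshold
    yielding at least 800 core genes of length 450-4500 nt; if none does, the
    bound is used.  A resulting core set under 200 genes discards the SGB.
    """
    bound = 60 if n_genomes < 100 else 50

    def eligible(thr_pct: int) -> list[GeneFamily]:
        t = thr_pct / 100.0
        return [
            f
            for f in pangenome.families
            if f.coreness >= t and MARKER_MIN_LEN <= f.length <= MARKER_MAX_LEN
        ]

    chosen = bound
    for t in range(100, bound - 1, -1):
        if len(eligible(t)) >= 800:
            chosen = t
            break
    core = eligible(chosen)
    pangenome.coreness_threshold = chosen / 100.0
    pangenome.core_genes = core
    pangenome.discarded = len(core) < 200
    return pangenome


def fragment_gene(
    nt: str, fragment_len: int = 150, min_tail: int = 75
) -> list[str]:
    """Non-overlapping windows; a final window under ``fragment_len`` is kept
    only when at least ``min_tail`` nt long."""
    frags = []
    for i in range(0, len(nt), fragment_len):
        w = nt[i : i + fragment_len]
        if len(w) == fragment_len or len(w) >= min_tail:
            frags.append(w)
    return frags


_RC = str.maketrans("ACGT", "TGCA")


@dataclass
class HitTable:
    """Core-gene x SGB hit counts from the fragment screen.

    ``hits[(owner_sgb, family_id)][sgb] = number of that SGB's subset genomes
    with at least one mapped fragment``; own-SGB hits included.
    """

    hits: dict[tuple[str, str], dict[str, int]]
    subset_sizes: dict[str, int]

    def conflicts(self, owner: str, external: str) -> int:
        """Number of `owner` core genes hitting >=1 genome of `external`."""
        return sum(
            1
            for (o, _), per_sgb in self.hits.items()
            if o == owner and per_sgb.get(external, 0) > 0
        )


def compute_hit_table(
    core_sets: Mapping[str, Sequence[GeneFamily]],
    subsets: Mapping[str, Sequence[GenomeRecord]],
    fragment_len: int = 150,
    min_tail: int = 75,
    seed_k: int = 31,
    min_identity: float = 0.90,
) -> HitTable:
    """Screen every core gene's 150-nt fragments against every subset genome.

    A fragment maps to a genome when an exact ``seed_k``-mer seed extends
    ungapped to >= ``min_identity`` over the fragment; a mapped fragment is a
    hit for its gene.  Genomes are scanned once against a joint seed index.
    """
    frag_arrs: list[np.ndarray] = []
    frag_fam: list[int] = []
    fam_meta: list[tuple[str, str]] = []  # (owner sgb, family_id)
    for sgb in sorted(core_sets):
        for fam in core_sets[sgb]:
            fam_idx = len(fam_meta)
            fam_meta.append((sgb, fam.family_id))
            for frag in fragment_gene(fam.representative_nt, fragment_len, min_tail):
                for oriented in (frag, frag.translate(_RC)[::-1]):
                    frag_arrs.append(encode(oriented))
                    frag_fam.append(fam_idx)

    hits: dict[tuple[str, str], dict[str, int]] = {m: {} for m in fam_meta}
    sizes = {sgb: len(subsets[sgb]) for sgb in subsets}
    if not frag_arrs:
        return HitTable(hits, sizes)

    codes_list, fidx_list, off_list = [], [], []
    for i, arr in enumerate(frag_arrs):
        c, valid = kmer_codes(arr, seed_k)
        pos = np.nonzero(valid)[0]
        codes_list.append(c[pos])
        fidx_list.append(np.full(pos.size, i, dtype=np.int32))
        off_list.append(pos.astype(np.int32))
    seed_codes = np.concatenate(codes_list)
    seed_frag = np.concatenate(fidx_list)
    seed_off = np.concatenate(off_list)
    order = np.argsort(seed_codes, kind="stable")
    seed_codes, seed_frag, seed_off = (
        seed_codes[order], seed_frag[order], seed_off[order]
    )

    frag_lens = np.array([a.size for a in frag_arrs])
    for sgb in sorted(subsets):
        for rec in subsets[sgb]:
            garr = encode("N".join(rec.contigs))
            g_codes, valid = kmer_codes(garr, seed_k)
            gpos = np.nonzero(valid)[0]
            g_codes = g_codes[gpos]
            lo = np.searchsorted(seed_codes, g_codes, "left")
            hi = np.searchsorted(seed_codes, g_codes, "right")
            cnt = hi - lo
            m = cnt > 0
            if not m.any():
                continue
            lo, cnt, gp = lo[m], cnt[m], gpos[m]
            total = int(cnt.sum())
            base = np.repeat(lo, cnt)
            within = np.arange(total) - np.repeat(np.cumsum(cnt) - cnt, cnt)
            sel = base + within
            fr = seed_frag[sel]
            start = np.repeat(gp, cnt) - seed_off[sel]
            # one verification per (fragment, diagonal)
            key = fr.astype(np.int64) * (garr.size + fragment_len + 1) + (
                start + fragment_len
            )
            _, first = np.unique(key, return_index=True)
            hit_fams: set[int] = set()
            order2 = np.sort(first)
            for idx in order2:
                fi = int(fr[idx])
                fam_idx = frag_fam[fi]
                if fam_idx in hit_fams:
                    continue
                st = int(start[idx])
                flen = int(frag_lens[fi])
                if st < 0 or st + flen > garr.size:
                    continue
                mism = int(np.count_nonzero(garr[st : st + flen] != frag_arrs[fi]))
                if mism <= int((1 - min_identity) * flen):
                    hit_fams.add(fam_idx)
            for fam_idx in hit_fams:
                per = hits[fam_meta[fam_idx]]
                per[sgb] = per.get(sgb, 0) + 1
    return HitTable(hits, sizes)


def _candidate_markers(
    pangenome: Pangenome,
    table: HitTable,
    excluded: frozenset[str] = frozenset(),
    group: frozenset[str] | None = None,
) -> list[MarkerGene]:
    """Unique/quasi candidates of one SGB given the screen hit table.

    SGBs in ``excluded`` are ignored entirely; SGBs in ``group`` (a merged-SGB
    group containing the owner) are treated as internal.
    """
    own = pangenome.sgb_id
    internal = set(group or ()) | {own}
    thr = pangenome.coreness_threshold or 0.0
    out = []
    for fam in pangenome.core_genes:
        per = table.hits.get((own, fam.family_id), {})
        own_n = per.get(own, 0)
        own_frac = own_n / table.subset_sizes[own] if table.subset_sizes.get(own) else 0.0
        if own_frac < thr:
            continue
        ext = []
        ok = True
        for sgb, n in sorted(per.items()):
            if sgb in internal or sgb in excluded or n == 0:
                continue
            frac = n / table.subset_sizes[sgb]
            if frac < 0.01:  # strict: <100-genome subsets can never qualify
                ext.append((sgb, frac))
            else:
                ok = False
                break
        if not ok:
            continue
        out.append(
            MarkerGene(
                marker_id=fam.family_id,
                sgb_id=own,
                sequence=fam.representative_nt,
                is_quasi=bool(ext),
                ext_sgbs=ext,
                own_hit_fraction=own_frac,
            )
        )
    return out


def screen_uniqueness(
    pangenome: Pangenome,
    table: HitTable,
    excluded: frozenset[str] = frozenset(),
) -> list[MarkerGene]:
    """Unique and quasi marker candidates for one SGB (see module docstring)."""
    return _candidate_markers(pangenome, table, excluded)


def _species_name(taxonomy: str | None) -> str:
    if not taxonomy:
        return ""
    for part in taxonomy.split("|"):
        if part.startswith("s__"):
            return part[3:]
    return ""


def _is_low_quality_label(taxonomy: str | None) -> bool:
    name = _species_name(taxonomy)
    # placeholder labels (uncharacterised SGBs) count as low-quality names
    return bool(LOW_QUALITY_LABEL.search(name)) or name.startswith("SGB") or not name


def rescue_low_marker_sgbs(
    pangenome: Pangenome,
    table: HitTable,
    taxonomies: Mapping[str, str],
    genome_counts: Mapping[str, int],
    goal_step1: int = 100,
    goal_step2: int = 10,
    conflict_cut: int = 200,
    genome_frac: float = 0.10,
) -> tuple[frozenset[str], list[MarkerGene]]:
    """Steps 1-2 of the marker rescue for one low-marker SGB.

    Step 1 iteratively drops external SGBs conflicting on more than
    ``conflict_cut`` core genes and holding under 10% of the target's genome
    count (goal: 100 markers); step 2 repeats restricted to externals with
    low-quality species labels (goal: 10 markers).  Each step rolls back if
    its goal is not reached.  Returns (excluded externals, candidates).
    """
    target = pangenome.sgb_id

    def count(excl: frozenset[str]) -> int:
        return len(_candidate_markers(pangenome, table, excl))

    def run_step(
        start: frozenset[str], goal: int, allowed
    ) -> frozenset[str]:
        excl = set(start)
        while count(frozenset(excl)) < goal:
            cands = [
                (table.conflicts(target, e), e)
                for e in sorted(table.subset_sizes)
                if e != target
                and e not in excl
                and allowed(e)
                and table.conflicts(target, e) > conflict_cut
                and genome_counts.get(e, 0) < genome_frac * genome_counts.get(target, 0)
            ]
            if not cands:
                return start  # rollback
            cands.sort(key=lambda t: (-t[0], t[1]))
            excl.add(cands[0][1])
        return frozenset(excl)

    excluded = frozenset()
    if count(excluded) < goal_step1:
        excluded = run_step(excluded, goal_step1, lambda e: True)
    if count(excluded) < goal_step2:
        excluded = run_step(
            excluded,
            goal_step2,
            lambda e: _is_low_quality_label(taxonomies.get(e)),
        )
    return excluded, _candidate_markers(pangenome, table, excluded)


def merge_conflicting_sgbs(
    pangenomes: Mapping[str, Pangenome],
    table: HitTable,
    deficient: Sequence[str],
    min_markers: int = 10,
    conflict_cut: int = 200,
) -> dict[str, frozenset[str]]:
    """Step 3: greedy merging of SGBs linked by heavy core-gene conflicts.

    Builds the conflict graph (edge when either direction exceeds
    ``conflict_cut`` conflicting core genes) and repeatedly merges the
    heaviest edge touching a deficient component until every deficient
    component reaches ``min_markers`` or no edges remain.  Returns a map
    sgb -> its merged group (only for SGBs that ended up merged).
    """
    sgbs = sorted(pangenomes)
    edges = []
    for i, a in enumerate(sgbs):
        for b in sgbs[i + 1 :]:
            w = table.conflicts(a, b) + table.conflicts(b, a)
            if table.conflicts(a, b) > conflict_cut or table.conflicts(b, a) > conflict_cut:
                edges.append((w, a, b))
    edges.sort(key=lambda e: (-e[0], e[1], e[2]))

    parent = {s: s for s in sgbs}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def group_of(x: str) -> frozenset[str]:
        r = find(x)
        return frozenset(s for s in sgbs if find(s) == r)

    def group_markers(grp: frozenset[str]) -> int:
        return sum(
            len(_candidate_markers(pangenomes[s], table, group=grp)) for s in grp
        )

    def deficient_left() -> bool:
        return any(group_markers(group_of(s)) < min_markers for s in deficient)

    for w, a, b in edges:
        if not deficient_left():
            break
        ga, gb = group_of(a), group_of(b)
        if ga == gb:
            continue
        if group_markers(ga) >= min_markers and group_markers(gb) >= min_markers:
            continue
        parent[find(max(a, b))] = find(min(a, b))

    groups: dict[str, frozenset[str]] = {}
    for s in sgbs:
        grp = group_of(s)
        if len(grp) > 1:
            groups[s] = grp
    return groups


def finalize_markers(
    candidates: Sequence[MarkerGene], cap: int = 200
) -> list[MarkerGene]:
    """Keep at most ``cap`` markers: unique before quasi, longer first."""
    ranked = sorted(candidates, key=lambda m: (m.is_quasi, -m.length, m.marker_id))
    return ranked[:cap]


@dataclass
class MarkerDatabase:
    """The emitted marker database: 10-200 markers per SGB plus metadata."""

    version: str
    markers: dict[str, list[MarkerGene]]
    taxonomy: dict[str, str]
    avg_genome_length: dict[str, float]
    is_known: dict[str, bool]
    n_refs: dict[str, int] = field(default_factory=dict)
    n_mags: dict[str, int] = field(default_factory=dict)
    merged_groups: dict[str, list[str]] = field(default_factory=dict)
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for sgb, mks in self.markers.items():
            if not 10 <= len(mks) <= 200:
                raise ValueError(f"{sgb}: {len(mks)} markers outside [10, 200]")

    @property
    def sgbs(self) -> list[str]:
        return sorted(self.markers)

    def n_markers(self, sgb: str) -> int:
        return len(self.markers[sgb])

    def marker_map(self) -> dict[str, MarkerGene]:
        return {m.marker_id: m for mks in self.markers.values() for m in mks}

    def save(self, prefix: str | Path) -> tuple[Path, Path]:
        prefix = Path(prefix)
        meta = {
            "version": self.version,
            "params": self.params,
            "taxonomy": self.taxonomy,
            "avg_genome_length": self.avg_genome_length,
            "is_known": self.is_known,
            "n_refs": self.n_refs,
            "n_mags": self.n_mags,
            "merged_groups": {k: list(v) for k, v in self.merged_groups.items()},
            "markers": {
                sgb: [
                    {
                        "marker_id": m.marker_id,
                        "length": m.length,
                        "is_quasi": m.is_quasi,
                        "ext_sgbs": m.ext_sgbs,
                        "own_hit_fraction": m.own_hit_fraction,
                        "taxonomy": self.taxonomy.get(sgb, ""),
                    }
                    for m in mks
                ]
                for sgb, mks in sorted(self.markers.items())
            },
        }
        json_path = prefix.with_suffix(".json")
        fasta_path = prefix.with_suffix(".fasta")
        json_path.write_text(json.dumps(meta, indent=1, sort_keys=True))
        with open(fasta_path, "w") as fh:
            for sgb in sorted(self.markers):
                for m in self.markers[sgb]:
                    fh.write(f">{m.marker_id}\n")
                    for j in range(0, len(m.sequence), 80):
                        fh.write(m.sequence[j : j + 80] + "\n")
        return json_path, fasta_path

    @classmethod
    def load(cls, prefix: str | Path) -> "MarkerDatabase":
        prefix = Path(prefix)
        meta = json.loads(prefix.with_suffix(".json").read_text())
        seqs: dict[str, str] = {}
        with open(prefix.with_suffix(".fasta")) as fh:
            name, chunks = None, []
            for line in fh:
                line = line.strip()
                if line.startswith(">"):
                    if name is not None:
                        seqs[name] = "".join(chunks)
                    name, chunks = line[1:].split()[0], []
                else:
                    chunks.append(line)
            if name is not None:
                seqs[name] = "".join(chunks)
        markers = {
            sgb: [
                MarkerGene(
                    marker_id=m["marker_id"],
                    sgb_id=sgb,
                    sequence=seqs[m["marker_id"]],
                    is_quasi=m["is_quasi"],
                    ext_sgbs=[tuple(e) for e in m["ext_sgbs"]],
                    own_hit_fraction=m["own_hit_fraction"],
                )
                for m in mks
            ]
            for sgb, mks in meta["markers"].items()
        }
        return cls(
            version=meta["version"],
            markers=markers,
            taxonomy=meta["taxonomy"],
            avg_genome_length=meta["avg_genome_length"],
            is_known=meta["is_known"],
            n_refs=meta.get("n_refs", {}),
            n_mags=meta.get("n_mags", {}),
            merged_groups={
                k: list(v) for k, v in meta.get("merged_groups", {}).items()
            },
            params=meta.get("params", {}),
        )


def build_marker_database(
    records: Sequence[GenomeRecord],
    hierarchy: BinHierarchy,
    genes_by_genome: Mapping[str, Sequence[tuple[str, str]]],
    taxonomies: Mapping[str, str],
    version: str = "vSIM-1",
    min_mags: int = 5,
    subset_size: int = 100,
    quality_rank_size: int = 2000,
    marker_cap: int = 200,
    min_markers: int = 10,
) -> MarkerDatabase:
    """End-to-end marker database construction from a binned genome catalog."""
    by_id = {r.genome_id: r for r in records}
    sgb_bins = filter_usgbs(list(hierarchy.level("SGB").values()), min_mags=min_mags)

    def by_quality(members: Sequence[str]) -> list[str]:
        return sorted(
            members, key=lambda g: (-by_id[g].quality_score, g)
        )

    pangenomes: dict[str, Pangenome] = {}
    subsets: dict[str, list[GenomeRecord]] = {}
    genome_counts: dict[str, int] = {}
    for b in sgb_bins:
        ranked = by_quality(b.members)
        subsets[b.bin_id] = [by_id[g] for g in ranked[:subset_size]]
        genome_counts[b.bin_id] = len(b.members)
        fams = cluster_gene_families(
            {g: genes_by_genome[g] for g in b.members if g in genes_by_genome}
        )
        compute_coreness(fams, ranked[:quality_rank_size])
        pg = select_core_genes(
            Pangenome(sgb_id=b.bin_id, families=fams), n_genomes=len(b.members)
        )
        if not pg.discarded:
            pangenomes[b.bin_id] = pg

    table = compute_hit_table(
        {sgb: pg.core_genes for sgb, pg in pangenomes.items()}, subsets
    )

    candidates: dict[str, list[MarkerGene]] = {}
    deficient: list[str] = []
    for sgb, pg in sorted(pangenomes.items()):
        cands = screen_uniqueness(pg, table)
        if len(cands) < 100:
            _, cands = rescue_low_marker_sgbs(
                pg, table, taxonomies, genome_counts
            )
        candidates[sgb] = cands
        if len(cands) < min_markers:
            deficient.append(sgb)

    merged_groups: dict[str, list[str]] = {}
    if deficient:
        groups = merge_conflicting_sgbs(pangenomes, table, deficient)
        for sgb, grp in groups.items():
            merged_groups[sgb] = sorted(grp)
            candidates[sgb] = _candidate_markers(pangenomes[sgb], table, group=grp)

    markers: dict[str, list[MarkerGene]] = {}
    tax: dict[str, str] = {}
    avg_len: dict[str, float] = {}
    is_known: dict[str, bool] = {}
    n_refs: dict[str, int] = {}
    n_mags: dict[str, int] = {}
    for b in sgb_bins:
        sgb = b.bin_id
        if sgb not in candidates:
            continue
        final = finalize_markers(candidates[sgb], cap=marker_cap)
        if len(final) < min_markers:
            continue  # dropped from the database
        markers[sgb] = final
        tax[sgb] = taxonomies.get(sgb, "")
        refs = [by_id[g] for g in b.members if by_id[g].source == "isolate"]
        pool = refs if refs else [by_id[g] for g in b.members]
        avg_len[sgb] = float(np.mean([r.length for r in pool]))
        is_known[sgb] = b.known
        n_refs[sgb], n_mags[sgb] = b.n_refs, b.n_mags

    return MarkerDatabase(
        version=version,
        markers=markers,
        taxonomy=tax,
        avg_genome_length=avg_len,
        is_known=is_known,
        n_refs=n_refs,
        n_mags=n_mags,
        merged_groups=merged_groups,
        params={
            "subset_size": subset_size,
            "marker_cap": marker_cap,
            "min_markers": min_markers,
        },
    )
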