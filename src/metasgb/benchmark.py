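"""End-to-end synthetic benchmark orchestration.

Builds a seeded synthetic catalog, clusters it, constructs the marker
database and profiles simulated log-normal communities, scoring each sample
against its gold standard.  Shared by the test suite and the acceptance
script.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import catalog as cat
from .align import MarkerIndex
from .evaluate import confusion_counts, profile_metrics
from .markerdb import MarkerDatabase, build_marker_database
from .profiler import profile_sample
from .simulate import (
    CatalogTruth,
    GoldStandard,
    SimulationConfig,
    mutate_strain,
    simulate_catalog,
    simulate_community_reads,
)

#: sketch size used by the benchmark pipeline; larger than the op default
#: because desk-scale (~170 kb) genomes share few 21-mers at family-level
#: divergence and the Jaccard estimate must stay stable at the 30% cutoff
BENCH_SKETCH_S = 2000


@dataclass
class BenchmarkReference:
    """A built reference: catalog, bin hierarchy and marker database."""

    config: SimulationConfig
    records: list[cat.GenomeRecord]
    truth: CatalogTruth
    distances: pd.DataFrame
    hierarchy: cat.BinHierarchy
    db: MarkerDatabase
    sgb_of: dict[str, str]  # genome_id -> database SGB id
    index: MarkerIndex = field(repr=False, default=None)

    def genomes_in_db(self) -> list[cat.GenomeRecord]:
        return [r for r in self.records if self.sgb_of.get(r.genome_id) in self.db.markers]

    def pool(self, kind: str) -> list[cat.GenomeRecord]:
        """Community genome pool: 'all', 'usgb' or 'ksgb'."""
        out = []
        for r in self.genomes_in_db():
            sgb = self.sgb_of[r.genome_id]
            known = self.db.is_known[sgb]
            if kind == "all" or (kind == "ksgb") == known:
                out.append(r)
        return out


def build_reference(
    seed: int,
    config: SimulationConfig | None = None,
    sketch_s: int = BENCH_SKETCH_S,
) -> BenchmarkReference:
    """Simulate a catalog and run the full database-construction pipeline."""
    cfg = replace(config or SimulationConfig(), seed=seed)
    records, truth = simulate_catalog(cfg)
    dist = cat.distance_matrix(records, s=sketch_s)
    records = cat.qc_and_dereplicate(records, distances=dist)
    ids = [r.genome_id for r in records]
    dist = dist.loc[ids, ids]
    sources = {r.genome_id: r.source for r in records}
    hierarchy = cat.cluster_bins(dist, sources=sources)
    ref_taxa = {r.genome_id: r.taxonomy for r in records if r.taxonomy}
    taxonomies = {}
    for b in hierarchy.level("SGB").values():
        taxonomies[b.bin_id] = cat.assign_taxonomy(b, hierarchy, ref_taxa, dist)
        b.taxonomy = taxonomies[b.bin_id]
    db = build_marker_database(
        records, hierarchy, truth.genes_by_genome, taxonomies
    )
    ref = BenchmarkReference(
        config=cfg,
        records=records,
        truth=truth,
        distances=dist,
        hierarchy=hierarchy,
        db=db,
        sgb_of=hierarchy.sgb_of(),
        index=MarkerIndex(db),
    )
    return ref


def score_sample(
    ref: BenchmarkReference,
    reads: Sequence[tuple[str, str, str]],
    gold: GoldStandard,
) -> dict[str, float]:
    """Profile one simulated sample and score it against its gold standard."""
    profile = profile_sample(reads=reads, db=ref.db, index=ref.index)
    counts = confusion_counts(profile, gold)
    return profile_metrics(counts, profile, gold)


def run_protocol(
    ref: BenchmarkReference,
    n_samples: int,
    seed: int,
    pool: str | Sequence[cat.GenomeRecord] = "all",
    sgb_of: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Simulate and score ``n_samples`` log-normal communities.

    ``pool`` selects the community genomes ('all' / 'usgb' / 'ksgb' or an
    explicit record list, e.g. holdout strains); one genome per SGB per
    sample.
    """
    genomes = ref.pool(pool) if isinstance(pool, str) else list(pool)
    sgb_map = dict(sgb_of) if sgb_of is not None else {
        r.genome_id: ref.sgb_of[r.genome_id] for r in genomes
    }
    rows = []
    rng = np.random.default_rng(seed)
    for _ in range(n_samples):
        s = int(rng.integers(0, 2**31 - 1))
        reads, gold = simulate_community_reads(
            genomes, ref.config, seed=s, sgb_of=sgb_map
        )
        rows.append(score_sample(ref, reads, gold))
    return pd.DataFrame(rows)


def holdout_strains(
    ref: BenchmarkReference, seed: int, snp_rate: float = 0.01
) -> tuple[list[cat.GenomeRecord], dict[str, str]]:
    """One new strain per database SGB, absent from the database build.

    Each strain derives from the SGB centroid by substitution at ``snp_rate``
    (well within the 5% species boundary).
    """
    by_id = {r.genome_id: r for r in ref.records}
    strains = []
    sgb_map = {}
    rng = np.random.default_rng(seed)
    for sgb in ref.db.sgbs:
        b = ref.hierarchy.level("SGB")[sgb]
        parent = by_id[b.centroid_id]
        strain, _ = mutate_strain(parent, snp_rate, seed=int(rng.integers(0, 2**31 - 1)))
        strains.append(strain)
        sgb_map[strain.genome_id] = sgb
    return strains, sgb_map


def single_genome_sweep(
    ref: BenchmarkReference,
    depths: Sequence[float],
    seed: int,
    genome: cat.GenomeRecord | None = None,
) -> pd.DataFrame:
    """Profile one genome simulated at a range of coverages.

    Returns one row per depth with the detected SGB set size, whether the
    true SGB was found, and the false-positive count.
    """
    genome = genome or ref.genomes_in_db()[0]
    true_sgb = ref.sgb_of[genome.genome_id]
    rl = ref.config.read_length
    rows = []
    rng = np.random.default_rng(seed)
    for depth in depths:
        n_reads = max(1, int(round(depth * genome.length / rl)))
        cfg = replace(ref.config, n_reads=n_reads)
        reads, _ = simulate_community_reads(
            [genome], cfg, seed=int(rng.integers(0, 2**31 - 1)),
            sgb_of={genome.genome_id: true_sgb},
        )
        profile = profile_sample(reads=reads, db=ref.db, index=ref.index)
        detected = profile.detected_sgbs()
        rows.append(
            {
                "depth": depth,
                "n_reads": n_reads,
                "detected": len(detected),
                "true_found": true_sgb in detected,
                "false_positives": len(detected - {true_sgb}),
            }
        )
    return pd.DataFrame(rows)
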