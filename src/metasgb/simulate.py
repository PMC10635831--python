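"""Synthetic genome catalogs and metagenome simulation.

The generator emits a catalog structured as a known FGB > GGB > SGB hierarchy:
each family-level ancestor carries a pool of universal genes, each genus- and
species-level ancestor gains private genes, and genomes descend from their SGB
ancestor by per-base substitution.  Gene content plus the per-level
substitution rates place realised pairwise genome distances inside the
5% / 15% / 30% clustering bands.  Communities follow a log-normal abundance
distribution with one genome per SGB, and reads are 150-nt with uniform
substitution errors.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .catalog import GenomeRecord

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class SimulationConfig:
    seed: int = 0
    # hierarchy shape
    n_fgbs: int = 5
    ggbs_per_fgb: int = 2
    sgbs_per_ggb: int = 3
    genomes_per_sgb: int = 5
    refs_per_sgb: int = 2
    usgb_fraction: float = 0.5  # fraction of SGBs with MAGs only
    # gene content
    n_universal_genes: int = 170
    n_ggb_genes: int = 20
    n_sgb_genes: int = 60
    n_accessory_genes: int = 8
    gene_len_range: tuple[int, int] = (450, 1800)
    gene_len_log_mean: float = 6.5
    gene_len_log_sigma: float = 0.25
    accessory_len_range: tuple[int, int] = (300, 900)
    # per-level substitution rates (ancestor -> descendant)
    div_strain: float = 0.015
    div_sgb: float = 0.04
    div_ggb: float = 0.05
    # reads
    read_length: int = 150
    error_rate: float = 0.005
    n_reads: int = 200_000
    paired: bool = False
    # community composition
    lognormal_mu: float = 0.0
    lognormal_sigma: float = 1.0
    # contig fragmentation (0 = single contig per genome)
    fragments_per_genome: int = 1

    @property
    def n_sgbs(self) -> int:
        return self.n_fgbs * self.ggbs_per_fgb * self.sgbs_per_ggb

    def validate(self) -> None:
        within = 1 - (1 - self.div_strain) ** 2
        sgb_pair = 1 - ((1 - self.div_sgb) * (1 - self.div_strain)) ** 2
        ggb_pair = 1 - (
            (1 - self.div_ggb) * (1 - self.div_sgb) * (1 - self.div_strain)
        ) ** 2
        if not within < 0.05:
            raise ValueError("within-SGB divergence must stay below 5%")
        if not (0.05 < sgb_pair <= 0.15):
            raise ValueError("SGB-to-SGB divergence must fall in (5%, 15%]")
        if not (0.15 < ggb_pair <= 0.30):
            raise ValueError("GGB-to-GGB divergence must fall in (15%, 30%]")
        if not (0 <= self.error_rate < 1):
            raise ValueError("error_rate must be a probability")
        lo, hi = self.gene_len_range
        if lo < 300 or hi > 4800:
            raise ValueError("gene lengths must stay within [300, 4800]")


@dataclass
class CatalogTruth:
    """Generating structure of a simulated catalog."""

    sgb_of: dict[str, str]  # genome_id -> true SGB label
    ggb_of: dict[str, str]
    fgb_of: dict[str, str]
    genes_by_genome: dict[str, list[tuple[str, str]]]  # genome -> [(gene_id, nt)]
    species_of_sgb: dict[str, str]  # true SGB label -> 7-rank taxonomy
    is_usgb: dict[str, bool]


# stop codons as base-4 codon codes: TAA=48, TAG=50, TGA=56
_STOP_CODES = np.array([48, 50, 56])
_CODON_POOL = np.array(
    [c for c in range(64) if c not in set(_STOP_CODES.tolist())]
)


def _random_gene(rng: np.random.Generator, length: int) -> np.ndarray:
    """A random CDS: length a multiple of 3, built from non-stop codons."""
    n_codons = max(1, length // 3)
    codons = _CODON_POOL[rng.integers(0, _CODON_POOL.size, size=n_codons)]
    out = np.empty(n_codons * 3, dtype=np.uint8)
    out[0::3] = codons // 16
    out[1::3] = (codons // 4) % 4
    out[2::3] = codons % 4
    return out


def _mutate(arr: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    out = arr.copy()
    if rate <= 0:
        return out
    hits = np.nonzero(rng.random(arr.size) < rate)[0]
    if hits.size:
        out[hits] = (out[hits] + rng.integers(1, 4, size=hits.size)) % 4
    return out


def _mutate_cds(arr: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Substitutions with nonsense mutations reverted (purifying selection)."""
    out = _mutate(arr, rate, rng)
    n = out.size // 3
    cod = out[: n * 3].reshape(n, 3)
    codes = cod[:, 0] * 16 + cod[:, 1] * 4 + cod[:, 2]
    bad = np.isin(codes, _STOP_CODES)
    if bad.any():
        orig = arr[: n * 3].reshape(n, 3)
        cod[bad] = orig[bad]
        out[: n * 3] = cod.reshape(-1)
    return out


def _gene_lengths(rng: np.random.Generator, n: int, cfg: SimulationConfig) -> np.ndarray:
    raw = rng.lognormal(cfg.gene_len_log_mean, cfg.gene_len_log_sigma, size=n)
    return np.clip(raw, *cfg.gene_len_range).astype(int)


def simulate_catalog(
    config: SimulationConfig | None = None, seed: int | None = None
) -> tuple[list[GenomeRecord], CatalogTruth]:
    """Generate a genome catalog with known SGB/GGB/FGB structure.

    Deterministic under the config seed; isolates carry species labels, MAGs
    carry none.
    """
    cfg = config or SimulationConfig()
    if seed is not None:
        cfg = replace(cfg, seed=seed)
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    records: list[GenomeRecord] = []
    truth = CatalogTruth({}, {}, {}, {}, {}, {})
    n_usgb = round(cfg.usgb_fraction * cfg.n_sgbs)
    sgb_counter = 0
    sample_counter = 0

    for f in range(cfg.n_fgbs):
        fgb_label = f"T_F{f}"
        universal = [
            _random_gene(rng, L)
            for L in _gene_lengths(rng, cfg.n_universal_genes, cfg)
        ]
        for g in range(cfg.ggbs_per_fgb):
            ggb_label = f"{fgb_label}_G{g}"
            ggb_universal = [_mutate_cds(a, cfg.div_ggb, rng) for a in universal]
            ggb_private = [
                _random_gene(rng, L)
                for L in _gene_lengths(rng, cfg.n_ggb_genes, cfg)
            ]
            for s in range(cfg.sgbs_per_ggb):
                sgb_label = f"{ggb_label}_S{s}"
                # deterministic uSGB placement: odd indices first, up to quota
                if cfg.usgb_fraction >= 1:
                    is_usgb = True
                else:
                    is_usgb = sgb_counter % 2 == 1 and sgb_counter // 2 < n_usgb
                sgb_counter += 1
                ancestor = [
                    _mutate_cds(a, cfg.div_sgb, rng)
                    for a in ggb_universal + ggb_private
                ] + [
                    _random_gene(rng, L)
                    for L in _gene_lengths(rng, cfg.n_sgb_genes, cfg)
                ]
                species = (
                    f"k__Bacteria|p__Phylum{f}|c__Class{f}|o__Order{f}"
                    f"|f__Family{f}|g__Genus{f}_{g}|s__Species_{sgb_label}"
                )
                truth.species_of_sgb[sgb_label] = species
                truth.is_usgb[sgb_label] = is_usgb
                n_refs = 0 if is_usgb else min(cfg.refs_per_sgb, cfg.genomes_per_sgb)
                for i in range(cfg.genomes_per_sgb):
                    gid = f"{sgb_label}_gen{i}"
                    genes = [_mutate_cds(a, cfg.div_strain, rng) for a in ancestor]
                    acc_lens = np.clip(
                        _gene_lengths(rng, cfg.n_accessory_genes, cfg),
                        *cfg.accessory_len_range,
                    )
                    genes += [_random_gene(rng, int(L)) for L in acc_lens]
                    order = rng.permutation(len(genes))
                    gene_list = [
                        (f"{gid}|g{int(j):03d}", _BASES[genes[j]].tobytes().decode())
                        for j in order
                    ]
                    seq = "".join(nt for _, nt in gene_list)
                    contigs = [seq]
                    if cfg.fragments_per_genome > 1:
                        bounds = np.linspace(
                            0, len(seq), cfg.fragments_per_genome + 1
                        ).astype(int)
                        contigs = [
                            seq[a:b] for a, b in zip(bounds[:-1], bounds[1:])
                        ]
                    is_ref = i < n_refs
                    sample_counter += 1
                    records.append(
                        GenomeRecord(
                            genome_id=gid,
                            contigs=contigs,
                            source="isolate" if is_ref else "MAG",
                            completeness=float(
                                rng.uniform(85, 100) if is_ref else rng.uniform(60, 100)
                            ),
                            contamination=float(rng.uniform(0, 3)),
                            taxonomy=species if is_ref else None,
                            sample_id=f"SAMPLE{sample_counter}",
                            environment="synthetic",
                        )
                    )
                    truth.sgb_of[gid] = sgb_label
                    truth.ggb_of[gid] = ggb_label
                    truth.fgb_of[gid] = fgb_label
                    truth.genes_by_genome[gid] = gene_list
    return records, truth


@dataclass
class GoldStandard:
    """True per-sample composition of a simulated community."""

    genome_abundance: dict[str, float]
    sgb_abundance: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        total = sum(self.genome_abundance.values())
        if self.genome_abundance and abs(total - 1.0) > 1e-9:
            raise ValueError("genome abundances must sum to 1")


def simulate_community_reads(
    genomes: Sequence[GenomeRecord],
    config: SimulationConfig,
    seed: int,
    sgb_of: Mapping[str, str] | None = None,
) -> tuple[list[tuple[str, str, str]], GoldStandard]:
    """Log-normal community and error-bearing reads with the gold standard.

    One genome per SGB is sampled (per ``sgb_of``; each genome is its own SGB
    if omitted), abundances are log-normal draws normalised to 1, and reads
    are drawn proportional to abundance x genome length with uniform start
    positions, random strand and per-base substitution errors.
    Returns ([(read_id, sequence, quality)], gold).
    """
    if not genomes:
        raise ValueError("genomes must be nonempty")
    if config.n_reads <= 0:
        raise ValueError("n_reads must be positive")
    rng = np.random.default_rng(seed)
    sgb_of = sgb_of or {g.genome_id: g.genome_id for g in genomes}

    by_sgb: dict[str, list[GenomeRecord]] = {}
    for g in genomes:
        by_sgb.setdefault(sgb_of[g.genome_id], []).append(g)
    chosen: list[tuple[str, GenomeRecord]] = []
    for sgb in sorted(by_sgb):
        members = sorted(by_sgb[sgb], key=lambda g: g.genome_id)
        chosen.append((sgb, members[rng.integers(len(members))]))

    raw = rng.lognormal(config.lognormal_mu, config.lognormal_sigma, len(chosen))
    ab = raw / raw.sum()
    gold = GoldStandard(
        genome_abundance={g.genome_id: float(a) for (_, g), a in zip(chosen, ab)},
    )
    for (sgb, g), a in zip(chosen, ab):
        gold.sgb_abundance[sgb] = gold.sgb_abundance.get(sgb, 0.0) + float(a)

    lengths = np.array([g.length for _, g in chosen], dtype=float)
    weights = ab * lengths
    weights /= weights.sum()
    counts = rng.multinomial(config.n_reads, weights)

    reads: list[tuple[str, str, str]] = []
    rl = config.read_length
    insert = 2 * rl + 50  # paired-end fragment size
    ridx = 0
    for (sgb, g), n in zip(chosen, counts):
        if n == 0:
            continue
        arr = np.frombuffer(g.sequence().encode(), dtype=np.uint8)
        enc = np.zeros(arr.size, dtype=np.uint8)
        for b, code in zip(b"ACGT", range(4)):
            enc[arr == b] = code
        qual = "I" * rl

        def emit(mat: np.ndarray, suffix: str = "") -> list[str]:
            if config.error_rate > 0:
                errs = rng.random(mat.shape) < config.error_rate
                mat[errs] = (mat[errs] + rng.integers(1, 4, int(errs.sum()))) % 4
            return [row.tobytes().decode() for row in _BASES[mat]]

        if config.paired and enc.size >= insert:
            npairs = (n + 1) // 2
            starts = rng.integers(0, enc.size - insert + 1, size=npairs)
            r1 = enc[starts[:, None] + np.arange(rl)]
            r2 = enc[(starts + insert - rl)[:, None] + np.arange(rl)]
            r2 = (3 - r2)[:, ::-1]  # mate on the opposite strand
            for s1, s2 in zip(emit(r1), emit(r2)):
                reads.append((f"r{ridx}/1", s1, qual))
                reads.append((f"r{ridx}/2", s2, qual))
                ridx += 1
        else:
            starts = rng.integers(0, enc.size - rl + 1, size=n)
            mat = enc[starts[:, None] + np.arange(rl)]
            flip = rng.random(n) < 0.5
            mat[flip] = (3 - mat[flip])[:, ::-1]
            for s in emit(mat):
                reads.append((f"r{ridx}", s, qual))
                ridx += 1
    return reads, gold


def mutate_strain(
    genome: GenomeRecord, snp_rate: float, seed: int
) -> tuple[GenomeRecord, list[tuple[int, int, str, str]]]:
    """Derive a strain by Bernoulli substitutions; returns (strain, SNP list).

    SNPs are reported as (contig_index, position, old_base, new_base); no
    indels are introduced.
    """
    if not (0 <= snp_rate < 0.05):
        raise ValueError("snp_rate must be in [0, 0.05)")
    rng = np.random.default_rng(seed)
    contigs = []
    snps: list[tuple[int, int, str, str]] = []
    for ci, contig in enumerate(genome.contigs):
        arr = np.frombuffer(contig.encode(), dtype=np.uint8)
        enc = np.zeros(arr.size, dtype=np.uint8)
        for b, code in zip(b"ACGT", range(4)):
            enc[arr == b] = code
        out = _mutate(enc, snp_rate, rng)
        changed = np.nonzero(out != enc)[0]
        for p in changed:
            snps.append((ci, int(p), "ACGT"[enc[p]], "ACGT"[out[p]]))
        contigs.append(_BASES[out].tobytes().decode())
    strain = GenomeRecord(
        genome_id=f"{genome.genome_id}_strain{seed}",
        contigs=contigs,
        source="MAG",
        completeness=genome.completeness,
        contamination=genome.contamination,
        taxonomy=None,
        sample_id=f"{genome.sample_id}_strain",
        environment=genome.environment,
    )
    return strain, snps


def write_fastq(reads: Sequence[tuple[str, str, str]], path: str | Path) -> None:
    import gzip

    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "wt") as fh:
        for rid, seq, qual in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")
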