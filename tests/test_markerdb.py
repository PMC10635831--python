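import numpy as np
import pytest

from metasgb._kmers import encode, revcomp
from metasgb.catalog import GenomeRecord
from metasgb.markerdb import (
    LOW_QUALITY_LABEL,
    GeneFamily,
    HitTable,
    MarkerGene,
    Pangenome,
    cluster_gene_families,
    compute_coreness,
    compute_hit_table,
    finalize_markers,
    fragment_gene,
    merge_conflicting_sgbs,
    rescue_low_marker_sgbs,
    screen_uniqueness,
    select_core_genes,
)

# 61 sense codons keyed by amino acid, used to craft CDSs with exact AA identity
_AA_TO_CODON = {}
from Bio.Seq import Seq

for b1 in "ACGT":
    for b2 in "ACGT":
        for b3 in "ACGT":
            cod = b1 + b2 + b3
            aa = str(Seq(cod).translate())
            if aa != "*":
                _AA_TO_CODON.setdefault(aa, cod)


def _cds(aa_seq: str) -> str:
    return "".join(_AA_TO_CODON[a] for a in aa_seq)


def _random_aa(rng, n):
    alphabet = list("ACDEFGHIKLMNPQRSTVWY")
    return "".join(rng.choice(alphabet) for _ in range(n))


class TestClusterGeneFamilies:
    def test_identical_genes_one_family_of_two(self):
        rng = np.random.default_rng(0)
        nt = _cds(_random_aa(rng, 200))
        fams = cluster_gene_families({"g1": [("g1|a", nt)], "g2": [("g2|a", nt)]})
        assert len(fams) == 1
        assert sorted(fams[0].members) == ["g1", "g2"]

    def test_89_percent_identity_starts_new_family(self):
        rng = np.random.default_rng(1)
        aa = _random_aa(rng, 200)
        # 22 substitutions -> 89% identity, below the >90% inclusion rule
        other = list(aa)
        for i in range(22):
            pos = i * 9
            other[pos] = "W" if aa[pos] != "W" else "Y"
        fams = cluster_gene_families(
            {"g1": [("g1|a", _cds(aa))], "g2": [("g2|b", _cds("".join(other)))]}
        )
        assert len(fams) == 2

    def test_high_identity_low_coverage_starts_new_family(self):
        rng = np.random.default_rng(2)
        aa = _random_aa(rng, 200)
        short = aa[: int(0.7 * len(aa))]  # 100% identical but 70% coverage
        fams = cluster_gene_families(
            {"g1": [("g1|a", _cds(aa))], "g2": [("g2|b", _cds(short))]}
        )
        assert len(fams) == 2

    def test_dubious_cds_skipped_with_warning(self):
        rng = np.random.default_rng(3)
        good = _cds(_random_aa(rng, 150))
        with_stop = good[:30] + "TAA" + good[33:]
        with pytest.warns(UserWarning):
            fams = cluster_gene_families({"g1": [("g1|a", with_stop), ("g1|b", good)]})
        assert len(fams) == 1


class TestSelectCoreGenes:
    def _pangenome(self, spec):
        """spec: list of (coreness, length, count)."""
        fams = []
        for coreness, length, count in spec:
            for i in range(count):
                f = GeneFamily(f"f{len(fams)}", "A" * length)
                f.coreness = coreness
                fams.append(f)
        return Pangenome(sgb_id="S", families=fams)

    def test_highest_threshold_with_800_genes(self):
        # 120 genomes -> bound 50%; 790 genes at >=0.93, 60 more at 0.92
        pg = self._pangenome([(0.93, 500, 790), (0.92, 500, 60)])
        select_core_genes(pg, n_genomes=120)
        assert pg.coreness_threshold == pytest.approx(0.92)
        assert len(pg.core_genes) == 850
        assert not pg.discarded
        # maximality: one percent higher no longer yields 800 eligible genes
        above = [
            f for f in pg.families
            if f.coreness >= 0.93 and 450 <= f.length <= 4500
        ]
        assert len(above) < 800

    def test_small_core_set_discarded(self):
        pg = self._pangenome([(0.9, 500, 150)])
        select_core_genes(pg, n_genomes=50)  # bound 60%
        assert pg.coreness_threshold == pytest.approx(0.60)
        assert pg.discarded

    def test_short_gene_never_core(self):
        pg = self._pangenome([(1.0, 300, 900)])
        select_core_genes(pg, n_genomes=120)
        assert len(pg.core_genes) == 0
        assert pg.discarded

    def test_length_bounds_inclusive(self):
        pg = self._pangenome([(1.0, 450, 400), (1.0, 4500, 400), (1.0, 4501, 100)])
        select_core_genes(pg, n_genomes=120)
        assert len(pg.core_genes) == 800
        assert pg.coreness_threshold == pytest.approx(1.0)


class TestFragmentGene:
    @pytest.mark.parametrize(
        "length,expected",
        [(150, [150]), (200, [150]), (230, [150, 80]), (450, [150, 150, 150]),
         (525, [150, 150, 150, 75])],
    )
    def test_tail_windows(self, length, expected):
        frags = fragment_gene("A" * length)
        assert [len(f) for f in frags] == expected


class TestScreen:
    def _toy(self, rng, n_genes=4, gene_len=450):
        """Two 'SGBs' of one genome each, sharing no sequence."""
        genes_a = [_cds(_random_aa(rng, gene_len // 3)) for _ in range(n_genes)]
        genes_b = [_cds(_random_aa(rng, gene_len // 3)) for _ in range(n_genes)]
        ga = GenomeRecord("ga", ["".join(genes_a)])
        gb = GenomeRecord("gb", ["".join(genes_b)])
        fams_a = [GeneFamily(f"a{i}", nt, {"ga": [f"a{i}"]}, 1.0)
                  for i, nt in enumerate(genes_a)]
        return genes_a, genes_b, ga, gb, fams_a

    def test_unique_when_absent_from_external(self):
        rng = np.random.default_rng(4)
        _, _, ga, gb, fams_a = self._toy(rng)
        table = compute_hit_table({"A": fams_a}, {"A": [ga], "B": [gb]})
        pg = Pangenome("A", fams_a, coreness_threshold=0.8, core_genes=fams_a)
        markers = screen_uniqueness(pg, table)
        assert len(markers) == len(fams_a)
        assert all(not m.is_quasi and m.own_hit_fraction == 1.0 for m in markers)

    def test_shared_gene_detected_via_either_strand(self):
        rng = np.random.default_rng(5)
        genes_a, genes_b, ga, _, fams_a = self._toy(rng)
        # external genome carries gene a0 reverse-complemented
        gb = GenomeRecord("gb", [genes_b[0] + revcomp(genes_a[0]) + genes_b[1]])
        table = compute_hit_table({"A": fams_a}, {"A": [ga], "B": [gb]})
        pg = Pangenome("A", fams_a, coreness_threshold=0.8, core_genes=fams_a)
        markers = screen_uniqueness(pg, table)
        assert {m.marker_id for m in markers} == {f.family_id for f in fams_a} - {"a0"}

    def test_agrees_with_exhaustive_fragment_search(self, tiny_ref):
        """Unique markers of a built database: no fragment may match any other
        SGB's genomes exactly (verified by exhaustive substring search)."""
        db = tiny_ref.db
        sgb = db.sgbs[0]
        others = [
            r for r in tiny_ref.records
            if tiny_ref.sgb_of.get(r.genome_id) not in (None, sgb)
        ]
        blobs = [r.sequence() for r in others[:10]]
        for m in db.markers[sgb][:10]:
            if m.is_quasi:
                continue
            for frag in fragment_gene(m.sequence):
                for blob in blobs:
                    assert frag not in blob
                    assert revcomp(frag) not in blob


class TestQuasiRule:
    def _pg(self):
        fams = [GeneFamily("f0", "A" * 450, {"g": ["f0"]}, 1.0)]
        return Pangenome("T", fams, coreness_threshold=0.6, core_genes=fams)

    def _table(self, ext_hits, ext_size):
        return HitTable(
            hits={("T", "f0"): {"T": 10, "E": ext_hits}},
            subset_sizes={"T": 10, "E": ext_size},
        )

    def test_sub_percent_hit_on_large_sgb_is_quasi(self):
        markers = screen_uniqueness(self._pg(), self._table(1, 150))
        assert len(markers) == 1 and markers[0].is_quasi
        assert markers[0].ext_sgbs == [("E", 1 / 150)]

    def test_one_percent_on_hundred_genomes_rejected(self):
        assert screen_uniqueness(self._pg(), self._table(1, 100)) == []

    def test_two_percent_rejected(self):
        assert screen_uniqueness(self._pg(), self._table(3, 150)) == []

    def test_own_fraction_below_threshold_rejected(self):
        table = HitTable(
            hits={("T", "f0"): {"T": 5}}, subset_sizes={"T": 10, "E": 150}
        )
        assert screen_uniqueness(self._pg(), table) == []


class TestRescue:
    def _build(self, n_core=250, ext_genomes=2, target_genomes=30):
        fams = [
            GeneFamily(f"f{i}", "A" * 500, {"g": [f"f{i}"]}, 1.0)
            for i in range(n_core)
        ]
        pg = Pangenome("T", fams, coreness_threshold=0.6, core_genes=fams)
        hits = {}
        for i, f in enumerate(fams):
            per = {"T": target_genomes}
            if i < 250:  # 250 conflicting genes against external E
                per["E"] = ext_genomes
            hits[("T", f.family_id)] = per
        table = HitTable(
            hits=hits,
            subset_sizes={"T": target_genomes, "E": ext_genomes},
        )
        return pg, table

    def test_small_conflicting_external_removed(self):
        # E holds 2/30 < 10% of target genomes and blocks 250 > 200 genes
        pg, table = self._build()
        assert len(screen_uniqueness(pg, table)) == 0
        excluded, markers = rescue_low_marker_sgbs(
            pg, table, taxonomies={}, genome_counts={"T": 30, "E": 2}
        )
        assert excluded == frozenset({"E"})
        assert len(markers) == 250

    def test_large_external_not_removable_rolls_back(self):
        pg, table = self._build(ext_genomes=20)  # 20/30 >= 10%
        excluded, markers = rescue_low_marker_sgbs(
            pg, table, taxonomies={}, genome_counts={"T": 30, "E": 20}
        )
        assert excluded == frozenset()
        assert len(markers) == 0

    def test_low_quality_label_regex(self):
        assert LOW_QUALITY_LABEL.search("Clostridium_sp_ABC")
        assert LOW_QUALITY_LABEL.search("Candidatus_foo")
        assert LOW_QUALITY_LABEL.search("Lachnospiraceae_bacterium_28_4")
        assert not LOW_QUALITY_LABEL.search("Escherichia_coli")
        assert not LOW_QUALITY_LABEL.search("Blautia_wexlerae")

    def test_merge_step_joins_heavily_conflicting_sgbs(self):
        # two SGBs block each other on all genes: only merging rescues them
        fams_a = [GeneFamily(f"a{i}", "A" * 500, {"g": [f"a{i}"]}, 1.0) for i in range(210)]
        fams_b = [GeneFamily(f"b{i}", "A" * 500, {"h": [f"b{i}"]}, 1.0) for i in range(210)]
        pga = Pangenome("A", fams_a, 0.6, fams_a)
        pgb = Pangenome("B", fams_b, 0.6, fams_b)
        hits = {}
        for f in fams_a:
            hits[("A", f.family_id)] = {"A": 10, "B": 10}
        for f in fams_b:
            hits[("B", f.family_id)] = {"B": 10, "A": 10}
        table = HitTable(hits=hits, subset_sizes={"A": 10, "B": 10})
        groups = merge_conflicting_sgbs({"A": pga, "B": pgb}, table, ["A", "B"])
        assert groups == {"A": frozenset({"A", "B"}), "B": frozenset({"A", "B"})}


class TestFinalizeMarkers:
    def _mk(self, i, length, quasi=False):
        return MarkerGene(f"m{i:04d}", "S", "A" * length, is_quasi=quasi)

    def test_cap_longest_unique(self):
        cands = [self._mk(i, 450 + i) for i in range(250)]
        final = finalize_markers(cands)
        assert len(final) == 200
        assert min(m.length for m in final) == 450 + 50

    def test_unique_before_quasi(self):
        cands = [self._mk(i, 450 + i) for i in range(150)] + [
            self._mk(200 + i, 9000 - i, quasi=True) for i in range(100)
        ]
        final = finalize_markers(cands)
        assert len(final) == 200
        assert sum(not m.is_quasi for m in final) == 150
        quasi_lens = [m.length for m in final if m.is_quasi]
        assert len(quasi_lens) == 50 and min(quasi_lens) == 9000 - 49

    def test_below_cap_all_retained(self):
        cands = [self._mk(i, 500) for i in range(10)]
        assert len(finalize_markers(cands)) == 10


class TestDatabase:
    def test_marker_counts_within_bounds(self, tiny_ref):
        for sgb in tiny_ref.db.sgbs:
            assert 10 <= tiny_ref.db.n_markers(sgb) <= 200

    def test_save_load_round_trip_and_determinism(self, tiny_ref, tmp_path):
        p1, f1 = tiny_ref.db.save(tmp_path / "db1")
        p2, f2 = tiny_ref.db.save(tmp_path / "db2")
        assert p1.read_bytes() == p2.read_bytes()
        assert f1.read_bytes() == f2.read_bytes()
        from metasgb.markerdb import MarkerDatabase

        back = MarkerDatabase.load(tmp_path / "db1")
        assert back.sgbs == tiny_ref.db.sgbs
        sgb = back.sgbs[0]
        assert [m.marker_id for m in back.markers[sgb]] == [
            m.marker_id for m in tiny_ref.db.markers[sgb]
        ]
        assert back.markers[sgb][0].sequence == tiny_ref.db.markers[sgb][0].sequence
        assert back.avg_genome_length == tiny_ref.db.avg_genome_length

    def test_uSGBs_keep_all_members_for_genome_length(self, tiny_ref):
        db = tiny_ref.db
        assert any(not db.is_known[s] for s in db.sgbs)
        for sgb in db.sgbs:
            assert db.avg_genome_length[sgb] > 0
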