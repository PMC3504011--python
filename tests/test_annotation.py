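import pytest

from gsurveyminer.annotation import (
    CONTAMINANT_CATEGORIES,
    HomologyHit,
    best_hit,
    classify_contig,
    classify_library,
    classify_prokaryote,
    classify_rrna,
    classify_te,
    classify_virus,
    contamination_free,
    holobiont_partition,
    mito_presence,
    read_hit_table,
    write_hit_table,
)
from gsurveyminer.seq_model import Contig, Library
from gsurveyminer.synthetic_data import fabricate_holobiont_table


def hit(**kw):
    base = dict(
        query_id="c1", subject_accession="X1", evalue=1e-20, bitscore=100.0,
    )
    base.update(kw)
    return HomologyHit(**base)


class TestRRNA:
    @pytest.mark.parametrize(
        "title",
        [
            "Homo sapiens 18S ribosomal RNA gene",
            "internal transcribed spacer region ITS1",
            "clone with rDNA fragment",
            "LSU partial sequence",
            "5,8S gene region",
        ],
    )
    def test_terms_match(self, title):
        assert classify_rrna(hit(subject_title=title))

    @pytest.mark.parametrize(
        "title",
        [
            "small subunit protein S5",   # 5S must match as a token
            "ribosomal protein L3 mRNA",  # no listed term
            "",
            "ASSUME nothing",             # SSU inside a word
        ],
    )
    def test_non_terms_do_not_match(self, title):
        assert not classify_rrna(hit(subject_title=title))


class TestTransposableElements:
    def test_retrotransposon_title(self):
        assert classify_te(
            hit(subject_title="Xiphophorus Rex3 retrotransposon, complete")
        )

    def test_flanking_region_exclusion(self):
        assert not classify_te(
            hit(subject_title="Tc1 transposon flanking region clone 7")
        )

    def test_species_field_rule(self):
        assert classify_te(
            hit(
                subject_title="uncharacterized genomic clone",
                species_field="Mariner transposon Mos1",
            )
        )

    def test_neutral_title_no_match(self):
        assert not classify_te(hit(subject_title="genomic scaffold 12"))


class TestProkaryoteAndVirus:
    @pytest.mark.parametrize(
        "lineage, expected",
        [
            ("Bacteria; Proteobacteria; Gammaproteobacteria", True),
            ("Archaea; Euryarchaeota", True),
            ("Eukaryota; Metazoa; Arthropoda", False),
            ("", False),
        ],
    )
    def test_lineage_root(self, lineage, expected):
        assert classify_prokaryote(hit(lineage=lineage)) is expected

    @pytest.mark.parametrize(
        "evalue, expected",
        [(1e-61, True), (1e-60, True), (1e-50, False)],
    )
    def test_viral_threshold_inclusive(self, evalue, expected):
        assert classify_virus(
            hit(db_tag="viral_refseq", evalue=evalue)
        ) is expected

    def test_viral_rule_needs_viral_db(self):
        assert not classify_virus(hit(db_tag="nt", evalue=1e-80))


class TestClassifyContig:
    def test_virus_outranks_metazoan_hit(self):
        hits = [
            hit(db_tag="viral_refseq", evalue=1e-70),
            hit(lineage="Eukaryota; Metazoa", evalue=1e-15),
        ]
        assert classify_contig(hits).category == "virus"

    def test_weak_hit_is_unassigned(self):
        assert classify_contig([hit(evalue=1e-10)]).category == "unassigned"

    def test_prokaryote_best_hit(self):
        lab = classify_contig([hit(lineage="Bacteria; Firmicutes")])
        assert lab.category == "prokaryote"

    def test_order_invariance(self):
        hits = [
            hit(subject_accession="A", evalue=1e-30,
                subject_title="18S ribosomal RNA"),
            hit(subject_accession="B", evalue=1e-40,
                lineage="Bacteria; Proteobacteria"),
            hit(subject_accession="C", evalue=1e-20,
                subject_title="mariner transposon"),
        ]
        labels = {
            classify_contig(perm).category
            for perm in (hits, hits[::-1], [hits[1], hits[2], hits[0]])
        }
        assert labels == {"prokaryote"}

    def test_best_hit_tie_breaking(self):
        hits = [
            hit(subject_accession="B", evalue=1e-30, bitscore=100),
            hit(subject_accession="A", evalue=1e-30, bitscore=100),
            hit(subject_accession="C", evalue=1e-30, bitscore=200),
        ]
        assert best_hit(hits).subject_accession == "C"


class TestContaminationFree:
    def _library(self, n=10):
        return Library(
            id="L",
            contigs=[Contig(id=f"c{i}", sequence="ACGT" * 30) for i in range(n)],
        )

    def test_removes_exactly_contaminants(self):
        lib = self._library()
        hits = {
            "c0": [hit(query_id="c0", db_tag="viral_refseq", evalue=1e-70)],
            "c1": [hit(query_id="c1", db_tag="viral_refseq", evalue=1e-70)],
            "c2": [hit(query_id="c2", lineage="Bacteria; Firmicutes")],
            "c3": [hit(query_id="c3", subject_title="18S ribosomal RNA")],
        }
        labels = {
            cid: classify_contig(rows) for cid, rows in hits.items()
        }
        clean = contamination_free(lib, labels)
        assert len(clean) == 7  # rRNA (c3) is intra-genomic, retained
        removed = {c.id for c in lib} - {c.id for c in clean}
        assert removed == {
            cid
            for cid, lab in labels.items()
            if lab.category in CONTAMINANT_CATEGORIES
        }

    def test_no_labels_is_identity(self):
        lib = self._library()
        clean = contamination_free(lib, {})
        assert [c.id for c in clean] == [c.id for c in lib]


class TestHolobiontPartition:
    def test_planted_counts_recovered_exactly(self):
        hits, sets = fabricate_holobiont_table(
            n_plastid=10, n_symbiont=14, n_host=393, n_conflict=17, seed=0
        )
        labels = holobiont_partition(hits, sets)
        counts = {}
        for lab in labels.values():
            counts[lab.category] = counts.get(lab.category, 0) + 1
        assert counts == {
            "plastid": 10,
            "symbiont_nuclear": 14,
            "host": 393,
            "conflict": 17,
        }
        assert len(labels) == 434

    def test_single_category_rules(self):
        plastid = hit(
            query_id="p1",
            lineage="Eukaryota; Dinoflagellata",
            subject_title="plastid minicircle",
        )
        mixed = [
            hit(query_id="m1", lineage="Eukaryota; Faviinae"),
            hit(query_id="m1", lineage="Eukaryota; Dinoflagellata",
                subject_title="nuclear scaffold"),
        ]
        _, sets = fabricate_holobiont_table(0, 0, 0, 0)
        labels = holobiont_partition([plastid] + mixed, sets)
        assert labels["p1"].category == "plastid"
        assert labels["m1"].category == "conflict"


class TestMitoPresence:
    GENES = {"cox1": (0, 500), "cob": (600, 1100), "nad1": (1200, 1600)}

    def test_full_partial_absent(self):
        hits = [
            hit(query_id="c1", db_tag="mito_ref", s_start=0, s_end=500,
                q_start=0, q_end=500),
            hit(query_id="c2", db_tag="mito_ref", s_start=600, s_end=700,
                q_start=0, q_end=100),
            hit(query_id="c2", db_tag="mito_ref", s_start=650, s_end=800,
                q_start=50, q_end=200),
        ]
        presence, total = mito_presence(hits, self.GENES)
        assert presence == {"cox1": "full", "cob": "partial", "nad1": "absent"}
        # cob coverage after interval merge: 600-800 of 500 bp = 40%
        assert total == 500 + 200  # merged query spans per contig

    def test_weak_hits_ignored(self):
        hits = [
            hit(query_id="c1", db_tag="mito_ref", evalue=1e-5,
                s_start=0, s_end=500)
        ]
        presence, total = mito_presence(hits, self.GENES)
        assert set(presence.values()) == {"absent"} and total == 0

    def test_contig_lengths_override_query_spans(self):
        hits = [
            hit(query_id="c1", db_tag="mito_ref", s_start=0, s_end=400,
                q_start=0, q_end=400)
        ]
        _, total = mito_presence(
            hits, self.GENES, contig_lengths={"c1": 950}
        )
        assert total == 950


class TestHitTableIO:
    def test_round_trip(self, tmp_path):
        hits = [
            hit(subject_title="18S ribosomal RNA",
                lineage="Eukaryota; Metazoa", species_field="Danio rerio"),
            hit(query_id="c2", db_tag="viral_refseq", evalue=1e-70),
        ]
        path = tmp_path / "hits.tsv"
        write_hit_table(hits, path)
        assert read_hit_table(path) == hits

    def test_missing_columns_rejected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("query_id\tevalue\nc1\t1e-20\n")
        with pytest.raises(ValueError, match="missing columns"):
            read_hit_table(path)

    def test_classify_library_groups_by_contig(self):
        hits = [
            hit(query_id="a", db_tag="viral_refseq", evalue=1e-70),
            hit(query_id="b", lineage="Bacteria; Firmicutes"),
        ]
        labels = classify_library(hits)
        assert labels["a"].category == "virus"
        assert labels["b"].category == "prokaryote"
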