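"""Genome reading, ORF finding, similarity/HMM search and profiles."""

import re

import numpy as np
import pytest

from conftest import make_family
from pahtrait import synth
from pahtrait.annotate import (
    GeneHit,
    GenomeRecord,
    SimilarityParams,
    annotate_genome,
    find_orfs,
    group_from_lineage,
    hmm_search,
    profile_genome,
    read_genome,
    resolve_multifamily,
    similarity_search,
)
from pahtrait.refdb import FAMILY_NAMES, ReferenceDatabase, ReferenceSequence
from pahtrait.synth import generate_decoys, generate_genome, mutate, write_genbank


@pytest.fixture(scope="module")
def planted_genome(tmp_path_factory):
    rng = np.random.default_rng(8)
    prot_a = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=120))
    prot_b = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=90))
    prot_p = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=100))
    record, _ = generate_genome(
        {"nahAc": prot_a, "nahB": prot_b, "nahE": prot_p},
        background_orfs=0, seed=4, genome_id="gfix",
        lineage=["Bacteria", "Proteobacteria"],
        plasmid_families={"nahE"},
    )
    path = tmp_path_factory.mktemp("gb") / "gfix.gb"
    write_genbank(record, path)
    return record, path


class TestReadGenome:
    def test_genbank_replicon_kinds(self, planted_genome):
        _, path = planted_genome
        g = read_genome(path)
        kinds = dict(g.replicons)
        assert kinds == {"chrom1": "chromosome", "plasmid1": "plasmid"}
        assert len(g.proteins) == 3
        by_pid = {pid: rep for pid, rep, _ in g.proteins}
        assert by_pid["gfix_nahE"] == "plasmid1"

    def test_protein_fasta_replicons_unknown(self, tmp_path):
        p = tmp_path / "prot.faa"
        p.write_text("".join(f">p{i}\nMKLVADE\n" for i in range(5)))
        g = read_genome(p)
        assert len(g.proteins) == 5
        assert g.replicon_kind("unplaced") == "unknown"

    def test_translation_derived_from_coordinates(self, planted_genome, tmp_path):
        # strip /translation qualifiers; table-11 translation of the CDS
        # coordinates must reproduce the annotated proteins
        record, path = planted_genome
        stripped = tmp_path / "notrans.gb"
        text = re.sub(r'\s+/translation="[^"]*"', "", path.read_text(), flags=re.S)
        stripped.write_text(text)
        got = {pid: res for pid, _, res in read_genome(stripped).proteins}
        want = {pid: "M" + res for pid, _, res in record.proteins}
        assert got == want

    def test_unparseable_file_errors(self, tmp_path):
        bad = tmp_path / "bad.gb"
        bad.write_text("not a genbank file\n")
        with pytest.raises(ValueError):
            read_genome(bad)

    def test_duplicate_protein_ids_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            GenomeRecord("g", replicons=[("c", "chromosome")],
                         proteins=[("p1", "c", "MK"), ("p1", "c", "ML")])


class TestFindOrfs:
    def test_minimal_orf(self):
        assert find_orfs("ATGAAATAA", min_aa_length=0) == ["MK"]

    def test_reverse_strand_recovery(self, rng):
        orf = "ATGAAATAA"
        rc = orf.translate(str.maketrans("ACGT", "TGCA"))[::-1]
        embedded = "CCC" + rc + "GGG"
        assert "MK" in find_orfs(embedded, min_aa_length=0)

    def test_planted_genes_recovered_from_synthetic_genome(self):
        rng = np.random.default_rng(3)
        planted = {
            f"nah{c}": "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=120))
            for c in "BCD"
        }
        record, truth = generate_genome(planted, background_orfs=17, seed=5)
        nts = record.nucleotides["chrom1"]
        peptides = set(find_orfs(nts, min_aa_length=100))
        assert len(peptides) >= 20
        for prot in planted.values():
            assert any(pep.endswith(prot) for pep in peptides)

    def test_non_dna_rejected(self):
        with pytest.raises(ValueError):
            find_orfs("ATGAUGTAA")


@pytest.fixture(scope="module")
def ref_db():
    rng = np.random.default_rng(21)
    ref = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=100))
    return ref, ReferenceDatabase(
        sequences=[ReferenceSequence("r1", "nahE", "o", "seed", ref)]
    )


class TestSimilaritySearch:

    def test_identical_query_is_perfect_hit(self, ref_db):
        ref, db = ref_db
        hits = similarity_search([("q1", ref)], db)
        assert len(hits) == 1
        assert hits[0].identity == 1.0
        assert hits[0].length_ratio == 1.0
        assert hits[0].family == "nahE"

    def test_fragment_match_fails_length_ratio(self, ref_db):
        # a perfect 60-residue fragment of a 100-residue reference aligns
        # over 60 columns: identity 1.0 but length ratio 0.60 < 0.70
        ref, db = ref_db
        hits = similarity_search([("q1", ref[20:80])], db)
        assert hits == []

    def test_heavily_mutated_query_fails_identity(self, ref_db):
        ref, db = ref_db
        rng = np.random.default_rng(5)
        pos = rng.choice(len(ref), size=35, replace=False)
        res = list(ref)
        for i in pos:
            res[i] = next(a for a in "ACDEFGHIKLMNPQRSTVWY" if a != res[i])
        hits = similarity_search([("q1", "".join(res))], db)
        assert hits == []

    def test_empty_protein_set(self, ref_db):
        assert similarity_search([], ref_db[1]) == []

    def test_params_validated(self):
        with pytest.raises(ValueError):
            SimilarityParams(min_identity=0.0)


class TestHmmSearch:
    def test_family_homolog_hits_its_family(self, small_db, small_models):
        truth = make_family(seed=100)  # nahAc generator stream
        rng = np.random.default_rng(9)
        probe = mutate(truth.ancestor, 0.05, rng)[0]
        hits = hmm_search([("p1", probe)], small_models, genome_id="g")
        assert any(h.family == "nahAc" for h in hits)

    def test_decoys_rarely_hit(self, small_models):
        decoys = generate_decoys(100, 120, seed=13)
        hits = hmm_search([(f"d{i}", s) for i, s in enumerate(decoys)], small_models)
        assert len({h.protein_id for h in hits}) <= 5

    def test_empty_genome(self, small_models):
        assert hmm_search([], small_models) == []

    def test_model_without_ga_rejected(self):
        class Bare:
            profile = None
            ga_bits = None

        with pytest.raises(ValueError, match="gathering threshold"):
            hmm_search([("p", "MK")], {"nahE": Bare()})

    def test_hits_reverify_threshold(self, small_db, small_models):
        truth = make_family(seed=101)  # nahE stream
        rng = np.random.default_rng(10)
        probes = [("p%d" % i, mutate(truth.ancestor, 0.05, rng)[0]) for i in range(5)]
        from pahtrait.profile_hmm import score_sequence

        for h in hmm_search(probes, small_models):
            model = small_models[h.family]
            assert h.bit_score >= model.ga_bits
            assert score_sequence(model.profile, dict(probes)[h.protein_id]) == pytest.approx(
                h.bit_score
            )


class TestResolveMultifamily:
    def _hit(self, fam, score):
        return GeneHit("g", "p1", fam, "hmm", bit_score=score)

    def test_hydratase_aldolase_confusion_case(self):
        # the documented cross-pathway case: phdJ also passing as nahE
        hit = resolve_multifamily([self._hit("phdJ", 210), self._hit("nahE", 180)])
        assert hit.family == "phdJ"
        assert hit.ambiguous_families == ["nahE"]
        assert hit.superfamily_flag

    def test_single_family_clean(self):
        hit = resolve_multifamily([self._hit("nidA", 120)])
        assert hit.family == "nidA"
        assert hit.ambiguous_families == []
        assert not hit.superfamily_flag

    def test_rhd_ambiguity_not_superfamily(self):
        hit = resolve_multifamily([self._hit("nahAc", 150), self._hit("nidA", 140)])
        assert hit.family == "nahAc"
        assert hit.ambiguous_families == ["nidA"]
        assert not hit.superfamily_flag

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            resolve_multifamily([])


class TestGenomeProfile:
    def _genome(self, lineage=None):
        return GenomeRecord("g1", lineage=lineage or [],
                            replicons=[("c", "chromosome")], proteins=[])

    def test_no_hits_zero_vector(self):
        p = profile_genome(self._genome(), [], group_tag="gram_negative")
        assert (p.feature_vector == 0).all()
        assert p.present_families() == set()

    def test_max_score_semantics(self):
        hits = [GeneHit("g1", "p1", "nahE", "hmm", bit_score=120),
                GeneHit("g1", "p2", "nahE", "hmm", bit_score=150)]
        p = profile_genome(self._genome(), hits, group_tag="gram_negative")
        assert p.feature_vector[FAMILY_NAMES.index("nahE")] == 150

    def test_hit_order_invariance(self):
        hits = [GeneHit("g1", f"p{i}", "nidA", "hmm", bit_score=s)
                for i, s in enumerate([100, 300, 200])]
        a = profile_genome(self._genome(), hits, group_tag="gram_positive")
        b = profile_genome(self._genome(), hits[::-1], group_tag="gram_positive")
        assert (a.feature_vector == b.feature_vector).all()

    def test_mycobacteriaceae_overrides_phylum(self):
        lineage = ["Bacteria", "Actinobacteria", "Mycobacteriaceae", "Mycobacterium"]
        assert group_from_lineage(lineage) == "mycobacteriaceae"
        p = profile_genome(self._genome(lineage), [])
        assert p.group_tag == "mycobacteriaceae"

    def test_phylum_lookup(self):
        assert group_from_lineage(["Bacteria", "Proteobacteria"]) == "gram_negative"
        assert group_from_lineage(["Bacteria", "Firmicutes"]) == "gram_positive"

    def test_missing_lineage_requires_explicit_group(self):
        with pytest.raises(ValueError, match="group_tag"):
            profile_genome(self._genome(), [])


class TestMethodConcordance:
    def test_hmm_matches_similarity_at_low_divergence_and_wins_at_high(
        self, small_db, small_models
    ):
        """At 5% divergence both routes find the planted genes; at 35%
        the profile search must be at least as sensitive as the
        similarity route (its documented advantage on remote homologs)."""
        rng = np.random.default_rng(17)
        fams = ("nahAc", "nahE", "nidA")
        streams = {f: make_family(seed=100 + i) for i, f in enumerate(fams)}

        def genes(rate):
            return [(f, mutate(streams[f].ancestor, rate, rng)[0]) for f in fams]

        low = genes(0.05)
        sim_low = {h.protein_id for h in similarity_search(low, small_db)}
        hmm_low = {h.protein_id for h in hmm_search(low, small_models)}
        assert sim_low == hmm_low == set(fams)

        high = genes(0.35)
        sim_high = {h.protein_id for h in similarity_search(high, small_db)}
        hmm_high = {h.protein_id
                    for h in hmm_search(high, small_models)
                    }
        assert len(hmm_high) >= len(sim_high)

    def test_annotate_genome_tags_replicons(self, small_db, small_models):
        truth = make_family(seed=101)
        rng = np.random.default_rng(23)
        record, _ = generate_genome(
            {"nahE": mutate(truth.ancestor, 0.05, rng)[0]},
            background_orfs=2, seed=6, genome_id="gg",
            plasmid_families={"nahE"},
        )
        hits = annotate_genome(record, small_models)
        nahe = [h for h in hits if h.family == "nahE"]
        assert nahe and nahe[0].replicon_kind == "plasmid"
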