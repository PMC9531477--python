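import numpy as np
import pytest

from selscan.io import HomologyHit, SequenceSet
from selscan.or_annotation import (
    annotate_genome,
    assign_subfamily,
    best_hit_per_locus,
    classify_or,
    match_truth,
    nj_filter,
    nj_tree,
    predict_tm,
    reconstruct_orf,
    report_repertoire,
    scan_genome,
    OrfReport,
    ORGeneCall,
)
from selscan.simulate import (
    PlantConfig,
    back_translate,
    plant_or_genome,
    reverse_complement,
)


def small_genome(or_references, seed=11, n=2):
    cfg = PlantConfig(
        reference_proteins=or_references, seed=seed,
        n_intact=n, n_partial=0, n_pseudo=0, genome_length=12_000,
    )
    return plant_or_genome(cfg)


class TestScanner:
    def test_planted_gene_found_with_tiny_evalue(self, or_references):
        genome, truth = small_genome(or_references)
        hits = scan_genome(genome, or_references)
        gene = truth.genes[0]
        covering = [
            h for h in hits
            if h.subject_start <= gene.end and h.subject_end >= gene.start
            and h.subject_strand == gene.strand
        ]
        assert covering and min(h.evalue for h in covering) < 1e-20

    def test_random_sequence_has_no_stringent_hits(self, or_references):
        rng = np.random.default_rng(17)
        seq = "".join(rng.choice(list("ACGT"), size=100_000))
        hits = scan_genome(SequenceSet([("rand", seq)]), or_references)
        assert all(h.evalue > 1e-5 for h in hits)

    def test_strand_symmetry(self, or_references):
        genome, truth = small_genome(or_references, seed=12, n=1)
        seq = genome.records[0][1]
        flipped = SequenceSet([("synthetic_chr1", reverse_complement(seq))])
        h1 = best_hit_per_locus(scan_genome(genome, or_references))
        h2 = best_hit_per_locus(scan_genome(flipped, or_references))
        L = len(seq)
        mirrored = {(L - h.subject_end + 1, L - h.subject_start + 1) for h in h2}
        assert {(h.subject_start, h.subject_end) for h in h1} == mirrored

    def test_empty_reference_set_rejected(self, or_references):
        genome, _ = small_genome(or_references, seed=13, n=1)
        with pytest.raises(ValueError):
            scan_genome(genome, SequenceSet([]))


class TestBestHitPerLocus:
    def _hit(self, start, end, ev, bits=100.0, strand="+"):
        return HomologyHit("q", "s", 90.0, end - start + 1, 1, 10,
                           start, end, ev, bits, strand)

    def test_overlapping_keeps_smaller_evalue(self):
        kept = best_hit_per_locus([self._hit(1, 100, 1e-30), self._hit(50, 150, 1e-10)])
        assert len(kept) == 1 and kept[0].evalue == 1e-30

    def test_equal_evalue_tie_breaks_on_bitscore(self):
        kept = best_hit_per_locus(
            [self._hit(1, 100, 1e-5, bits=150), self._hit(50, 150, 1e-5, bits=200)]
        )
        assert len(kept) == 1 and kept[0].bitscore == 200

    def test_non_overlapping_both_kept(self):
        kept = best_hit_per_locus([self._hit(1, 100, 1e-5), self._hit(500, 600, 1e-5)])
        assert len(kept) == 2

    def test_opposite_strands_not_merged(self):
        kept = best_hit_per_locus(
            [self._hit(1, 100, 1e-5), self._hit(50, 150, 1e-5, strand="-")]
        )
        assert len(kept) == 2


class TestOrfReconstruction:
    def _planted(self, or_references, defect=None, seed=19):
        rng = np.random.default_rng(seed)
        ref_id, prot = or_references.records[0]
        cds = back_translate(prot, rng) + "TAA"
        if defect == "no_start":
            cds = "CTG" + cds[3:]
        elif defect == "del1":
            mid = len(cds) // 2
            mid -= mid % 3
            cds = cds[:mid] + cds[mid + 1:]
        flank = "".join(rng.choice(list("ACGT"), size=900))
        flank2 = "".join(rng.choice(list("ACGT"), size=900))
        genome = SequenceSet([("chr", flank + cds + flank2)])
        hit = HomologyHit(ref_id, "chr", 100.0, len(prot), 1, len(prot),
                          len(flank) + 30, len(flank) + len(cds) - 30, 1e-40, 500.0, "+")
        return genome, hit, prot, len(flank) + 1, len(flank) + len(cds)

    def test_intact_gene_reconstructed_cleanly(self, or_references):
        genome, hit, prot, start, end = self._planted(or_references)
        orf = reconstruct_orf(genome, hit, prot)
        assert orf.has_start and orf.has_stop
        assert orf.frameshifts == () and orf.premature_stops == ()
        assert orf.protein == prot
        assert (orf.start, orf.end) == (start, end - 3)  # stop codon excluded from span
        assert orf.cds_length == end - start + 1

    def test_single_deletion_reports_one_frameshift_near_edit(self, or_references):
        genome, hit, prot, start, end = self._planted(or_references, defect="del1")
        orf = reconstruct_orf(genome, hit, prot)
        assert len(orf.frameshifts) == 1
        edit_pos = start + (end - start + 1) // 2
        assert abs(orf.frameshifts[0] - edit_pos) <= 10

    def test_mutated_start_codon_reported(self, or_references):
        genome, hit, prot, *_ = self._planted(or_references, defect="no_start")
        orf = reconstruct_orf(genome, hit, prot)
        assert not orf.has_start
        assert orf.has_stop

    def test_window_too_short_rejected(self, or_references):
        genome = SequenceSet([("chr", "ACGT" * 10)])
        hit = HomologyHit("r", "chr", 100.0, 10, 1, 10, 5, 20, 1e-5, 50.0, "+")
        with pytest.raises(ValueError, match="90"):
            reconstruct_orf(genome, hit, or_references.records[0][1], flank=10)


class TestTmPrediction:
    def test_seven_leucine_blocks(self):
        protein = "S" * 15 + ("L" * 21 + "S" * 15) * 7
        spans = predict_tm(protein)
        assert len(spans) == 7

    def test_hydrophilic_sequence_has_no_spans(self):
        assert predict_tm("S" * 300) == []

    def test_six_block_near_miss(self):
        protein = "S" * 15 + ("L" * 21 + "S" * 15) * 6
        assert len(predict_tm(protein)) == 6

    def test_short_sequence_empty(self):
        assert predict_tm("LLLL") == []


class TestClassification:
    def _orf(self, **kw):
        base = dict(seq_id="c", start=1, end=933, strand="+", has_start=True,
                    has_stop=True, frameshifts=(), premature_stops=(),
                    protein="M" + "L" * 300, cds_length=936, reference_id="OR14_a",
                    score=100.0)
        base.update(kw)
        return OrfReport(**base)

    SEVEN = [(i * 40, i * 40 + 20) for i in range(7)]

    def test_clean_long_seven_tm_is_intact(self):
        call = classify_or(self._orf(), self.SEVEN)
        assert call.category == "intact" and call.defects == ()

    def test_missing_start_is_partial(self):
        call = classify_or(self._orf(has_start=False), self.SEVEN)
        assert call.category == "partial" and call.defects == ("no_start",)

    def test_premature_stop_plus_missing_stop_is_pseudo(self):
        call = classify_or(
            self._orf(premature_stops=(300,), has_stop=False), self.SEVEN
        )
        assert call.category == "pseudo"
        assert "premature_stop" in call.defects and "no_stop" in call.defects

    def test_defect_precedence_is_order_independent(self):
        # any combination with a frameshift or premature stop is pseudo
        for fs in ((), (10,)):
            for ps in ((), (20,)):
                for start in (True, False):
                    call = classify_or(
                        self._orf(frameshifts=fs, premature_stops=ps,
                                  has_start=start), self.SEVEN
                    )
                    if fs or ps:
                        assert call.category == "pseudo"
                    elif not start:
                        assert call.category == "partial"
                    else:
                        assert call.category == "intact"

    def test_short_gene_is_partial_with_defect(self):
        call = classify_or(self._orf(cds_length=650), self.SEVEN)
        assert call.category == "partial" and "short" in call.defects
        assert classify_or(self._orf(cds_length=651), self.SEVEN).category == "intact"

    def test_six_tm_is_partial_tm_deficient(self):
        call = classify_or(self._orf(), self.SEVEN[:6])
        assert call.category == "partial" and "tm_deficient" in call.defects


class TestNjFilter:
    def test_nj_recovers_additive_four_taxon_tree(self):
        # additive matrix for ((A,B),(C,D)) with internal edge 2
        d = np.array(
            [[0, 3, 7, 8],
             [3, 0, 8, 9],
             [7, 8, 0, 5],
             [8, 9, 5, 0]], dtype=float)
        tree = nj_tree(["A", "B", "C", "D"], d)
        names = lambda node: {t.name for t in node.tips()}  # noqa: E731
        clades = {frozenset(names(n)) for n in tree.traverse() if not n.is_tip()}
        assert frozenset({"A", "B"}) in clades or frozenset({"C", "D"}) in clades
        # patristic distances reproduce the additive matrix
        for a, da in zip("ABCD", d):
            for b, expected in zip("ABCD", da):
                if a != b:
                    assert tree.find(a).distance(tree.find(b)) == pytest.approx(expected)

    def test_candidate_identical_to_outgroup_removed(self, or_references,
                                                     gpcr_outgroups):
        out_seq = gpcr_outgroups.records[0][1]
        cands = SequenceSet([("cand_bad", out_seq),
                             ("cand_good", or_references.records[0][1])])
        kept, removed = nj_filter(cands, gpcr_outgroups, or_references)
        assert "cand_bad" in removed
        assert "cand_good" in kept

    def test_requires_outgroup(self, or_references):
        cands = SequenceSet([("c1", or_references.records[0][1])])
        with pytest.raises(ValueError):
            nj_filter(cands, SequenceSet([]), or_references)


class TestSubfamily:
    def test_exact_copy_assigned_to_family(self, or_references):
        prot = or_references.get("OR14_a")
        assert assign_subfamily(prot, or_references) == "OR14"

    def test_random_sequence_unassigned(self, or_references):
        rng = np.random.default_rng(23)
        junk = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=300))
        assert assign_subfamily(junk, or_references) is None

    def test_tie_breaks_alphabetically(self):
        refs = SequenceSet([("ORB_x", "MKLWCCPQRS"), ("ORA_y", "MKLWCCPQRS")])
        assert assign_subfamily("MKLWCCPQRS", refs) == "ORA"


class TestRepertoireReport:
    def test_printed_percentages(self):
        calls = (
            [self._call("intact")] * 93
            + [self._call("partial")] * 19
            + [self._call("pseudo")] * 132
        )
        rep = report_repertoire(calls)
        assert (rep.pct_intact, rep.pct_partial, rep.pct_pseudo) == (38.1, 7.8, 54.1)
        assert rep.total == 244

    def test_empty_list_no_division_error(self):
        rep = report_repertoire([])
        assert rep.total == 0 and rep.pct_intact == 0.0

    def test_single_intact_is_hundred_percent(self):
        rep = report_repertoire([self._call("intact")])
        assert rep.pct_intact == 100.0

    @staticmethod
    def _call(category):
        return ORGeneCall("s", 1, 900, "+", category, (), "", None, "r", 1e-10)


class TestPipelineRecovery:
    def test_small_planted_genome_recovered(self, or_references, gpcr_outgroups):
        cfg = PlantConfig(
            reference_proteins=or_references, seed=31,
            n_intact=2, n_partial=2, n_pseudo=2, genome_length=25_000,
        )
        genome, truth = plant_or_genome(cfg)
        calls = annotate_genome(genome, or_references, outgroup_gpcrs=gpcr_outgroups)
        score = match_truth(calls, truth)
        assert score["detection_rate"] == 1.0
        assert score["category_accuracy"] >= 5 / 6
        for call in calls:
            if call.category == "intact":
                assert call.defects == ()
                assert len(predict_tm(call.protein)) == 7
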