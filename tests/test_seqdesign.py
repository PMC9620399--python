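import itertools

import pytest

from rnaweave import (
    KissingLoopEnsemble,
    SequenceConstraints,
    apply_wobbles,
    build_dna_template,
    design_sequence,
    generate_kl_ensemble,
    strand_model_from_structure,
    violates_constraints,
)
from rnaweave.seqdesign import (
    CAP,
    T7_PROMOTER,
    SequenceDesignError,
    revcomp_dna,
    revcomp_rna,
    wallace_tm,
)


def hairpin_structure(stem, loop=4):
    return "(" * stem + "." * loop + ")" * stem


class TestViolatesConstraints:
    def test_homopolymer(self):
        assert violates_constraints("GAAAAC") == [("AAAA", 1)]

    def test_class_run_w(self):
        assert violates_constraints("AUAUAU") == [("WWWWWW", 0)]

    def test_clean(self):
        assert violates_constraints("GACUGACU") == []

    @pytest.mark.parametrize(
        "seq,pattern",
        [
            ("CCCC", "CCCC"),
            ("GGGGAC", "GGGG"),
            ("UUUUGC", "UUUU"),
            ("GUGUGU", "KKKKKK"),
            ("ACACAC", "MMMMMM"),
            ("AGAGAG", "RRRRRR"),
            ("CGCGCG", "SSSSSS"),
            ("CUCUCU", "YYYYYY"),
        ],
    )
    def test_all_ten_patterns(self, seq, pattern):
        assert (pattern, 0) in violates_constraints(seq)

    def test_maximal_window_reported_once(self):
        # run of five As: a single homopolymer violation at the run start
        # (no flanking bases, so no 6-run of a two-base IUPAC class forms)
        assert violates_constraints("AAAAA") == [("AAAA", 0)]

    def test_class_run_alongside_homopolymer(self):
        # a 5-A run flanked by G also completes a 6-run of R = {A, G}
        assert violates_constraints("GAAAAAC") == [
            ("RRRRRR", 0),
            ("AAAA", 1),
            ("MMMMMM", 1),
        ]

    def test_dna_alphabet(self):
        assert violates_constraints("GTTTTC", alphabet="DNA") == [("TTTT", 1)]
        assert violates_constraints("ATATAT", alphabet="DNA") == [("WWWWWW", 0)]

    def test_invalid_alphabet_rejected(self):
        with pytest.raises(ValueError):
            violates_constraints("GATC")  # T is not RNA


class TestKlEnsemble:
    def test_single_pair(self):
        ens = generate_kl_ensemble(1, seed=0)
        a, b = ens.pairs[0]
        assert b == revcomp_rna(a)
        assert len(a) == 6

    def test_prism_requirement_brute_force_hamming(self):
        ens = generate_kl_ensemble(7, seed=1, min_hamming=3)
        loops = ens.all_loops()
        assert len(loops) == 14
        for x, y in itertools.combinations(loops, 2):
            assert sum(a != b for a, b in zip(x, y)) >= 3
        for loop in loops:
            assert violates_constraints(loop) == []

    def test_deterministic(self):
        e1 = generate_kl_ensemble(5, seed=9)
        e2 = generate_kl_ensemble(5, seed=9)
        assert e1.pairs == e2.pairs

    def test_validate_catches_similar_loops(self):
        ens = KissingLoopEnsemble(
            pairs=[("GGCAAC", "GUUGCC"), ("GGCAAG", "CUUGCC")], min_hamming=3
        )
        assert any("too similar" in p for p in ens.validate())

    def test_validate_catches_non_complement(self):
        ens = KissingLoopEnsemble(pairs=[("GGCAAC", "GGCAAC")])
        assert any("reverse complements" in p for p in ens.validate())

    def test_literature_injection(self):
        lit = [("GUGGCA", revcomp_rna("GUGGCA"))]
        ens = generate_kl_ensemble(3, seed=2, literature_pairs=lit)
        assert ens.pairs[0] == lit[0]
        assert ens.provenance[0] == "literature"
        assert ens.provenance[1:] == ["generated", "generated"]

    def test_infeasible_raises(self):
        with pytest.raises(SequenceDesignError):
            generate_kl_ensemble(400, seed=0, min_hamming=4, max_attempts=3000)

    def test_tsv_round_trip(self, tmp_path):
        ens = generate_kl_ensemble(4, seed=3)
        p = tmp_path / "loops.tsv"
        ens.to_tsv(str(p))
        loaded = KissingLoopEnsemble.from_tsv(str(p))
        assert loaded.pairs == ens.pairs
        assert loaded.provenance == ens.provenance


class TestWobbles:
    def test_16bp_stem_wobbles_at_8_and_16(self):
        strand = strand_model_from_structure(hairpin_structure(16))
        seq = "GCGCGCGCGCGCGCGC" + "AAAA" + revcomp_rna("GCGCGCGCGCGCGCGC")
        out, wobbles = apply_wobbles(strand, seq)
        side5, side3 = strand.stem_blocks()[0]
        assert wobbles == [(side5[7], side3[7]), (side5[15], side3[15])]
        for i, j in wobbles:
            assert (out[i], out[j]) == ("G", "U")

    def test_short_stem_no_wobbles(self):
        strand = strand_model_from_structure(hairpin_structure(7))
        seq = "GCGCGCG" + "AAAA" + revcomp_rna("GCGCGCG")
        _, wobbles = apply_wobbles(strand, seq)
        assert wobbles == []

    def test_kissing_loops_never_wobbled(self, tetra_strand):
        seq = ["A"] * tetra_strand.length
        for i, j in tetra_strand.pairs():
            seq[i], seq[j] = "G", "C"
        _, wobbles = apply_wobbles(tetra_strand, "".join(seq))
        kl_positions = {p for a, b in tetra_strand.kl_blocks() for p in a + b}
        assert all(i not in kl_positions and j not in kl_positions for i, j in wobbles)

    def test_breaks_dna_self_complementarity(self):
        strand = strand_model_from_structure(hairpin_structure(16))
        stem = "GCGCAUGCGCAUGCGC"
        seq = stem + "AAAA" + revcomp_rna(stem)
        out, _ = apply_wobbles(strand, seq)
        s5 = out[:16].replace("U", "T")
        s3 = out[20:].replace("U", "T")
        assert revcomp_dna(s5) != s3  # the rule's stated purpose


class TestDesignSequence:
    def test_small_hairpin_complementary(self):
        strand = strand_model_from_structure(hairpin_structure(4))
        ens = generate_kl_ensemble(1, seed=0)
        res = design_sequence(strand, ens, seed=5)
        side5, side3 = strand.stem_blocks()[0]
        stem5 = "".join(res.sequence[p] for p in side5)
        partner_5to3 = "".join(res.sequence[p] for p in sorted(side3))
        # 4 bp stem is below the wobble interval: exact reverse complement
        assert partner_5to3 == revcomp_rna(stem5)
        assert all(
            (res.sequence[i], res.sequence[j])
            in {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
            for i, j in strand.pairs()
        )
        assert res.sequence[0] == "G"

    def test_tetrahedron_consumes_three_pairs(self, tetra_strand):
        ens = generate_kl_ensemble(3, seed=1)
        res = design_sequence(tetra_strand, ens, seed=2)
        assert len(res.kl_assignments) == 3
        for (side5, side3), (loop_a, loop_b) in zip(
            tetra_strand.kl_blocks(), res.kl_assignments
        ):
            assert "".join(res.sequence[p] for p in side5) == loop_a
            assert "".join(res.sequence[p] for p in sorted(side3)) == loop_b

    def test_validator_passes_posthoc(self, tetra_strand):
        ens = generate_kl_ensemble(3, seed=1)
        res = design_sequence(tetra_strand, ens, seed=7)
        assert violates_constraints(res.sequence) == []
        wc = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
        gu = {("G", "U"), ("U", "G")}
        for i, j in tetra_strand.pairs():
            assert (res.sequence[i], res.sequence[j]) in wc | gu

    def test_deterministic(self, tetra_strand):
        ens = generate_kl_ensemble(3, seed=1)
        r1 = design_sequence(tetra_strand, ens, seed=3)
        r2 = design_sequence(tetra_strand, ens, seed=3)
        assert r1.sequence == r2.sequence

    def test_ensemble_too_small(self, tetra_strand):
        ens = generate_kl_ensemble(2, seed=1)
        with pytest.raises(SequenceDesignError, match="ensemble"):
            design_sequence(tetra_strand, ens, seed=0)

    def test_external_adapter_hook(self):
        strand = strand_model_from_structure(hairpin_structure(6))
        ens = generate_kl_ensemble(1, seed=0)

        def filler(length, rng):
            return ("GACUCA" * 10)[:length]

        res = design_sequence(
            strand, ens, seed=0, designer="external-adapter", stem_filler=filler
        )
        side5, _ = strand.stem_blocks()[0]
        # first base is forced to G afterwards; the rest comes from the hook
        assert "".join(res.sequence[p] for p in side5)[1:] == "ACUCA"

    def test_adapter_requires_callable(self):
        strand = strand_model_from_structure(hairpin_structure(6))
        ens = generate_kl_ensemble(1, seed=0)
        with pytest.raises(ValueError):
            design_sequence(strand, ens, designer="external-adapter")


class TestDnaTemplate:
    def test_prefix_cap_promoter(self):
        tpl = build_dna_template("GACUGACUGCAU", tail_seed=0)
        assert tpl.template.startswith("GACTAATACGACTCACTATAG")
        assert tpl.cap == CAP == "GAC"
        assert tpl.promoter == T7_PROMOTER == "TAATACGACTCACTATAG"

    def test_tail_length_15(self):
        tpl = build_dna_template("GACUGACUGCAU", tail_seed=1)
        assert len(tpl.tail) == 15
        assert tpl.template == CAP + T7_PROMOTER + tpl.body + tpl.tail

    def test_tail_passes_dna_constraints(self):
        tpl = build_dna_template("GACUGACUGCAU", tail_seed=2)
        assert violates_constraints(tpl.tail, alphabet="DNA") == []

    def test_forward_primer(self):
        tpl = build_dna_template("GACUGACUGCAU", tail_seed=0)
        assert tpl.forward_primer == "GACTAATACGACTCACTATAG"

    def test_reverse_primer_tm_and_anchor(self):
        tpl = build_dna_template("GACUGACUGCAUGGCAUCCGAUGG", tail_seed=3, target_tm=58.0)
        assert len(tpl.reverse_primer) >= 15
        assert wallace_tm(tpl.reverse_primer) >= 58.0 or len(tpl.reverse_primer) == 40
        assert tpl.reverse_primer == revcomp_dna(tpl.template[-len(tpl.reverse_primer):])

    def test_requires_5prime_g(self):
        with pytest.raises(SequenceDesignError, match="T7 requires 5' G"):
            build_dna_template("AACU", tail_seed=0)

    def test_body_is_u_to_t(self):
        tpl = build_dna_template("GUCAUGCAUCGA", tail_seed=0)
        assert tpl.body == "GTCATGCATCGA"

    def test_deterministic_per_seed(self):
        t1 = build_dna_template("GACUGACUGCAU", tail_seed=4)
        t2 = build_dna_template("GACUGACUGCAU", tail_seed=4)
        assert t1.template == t2.template
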