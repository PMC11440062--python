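"""Cross-species mapping: E-values, alignment, window scores, filters."""

import numpy as np
import pytest
from Bio.Align import substitution_matrices

from phosmap import (
    CrossmapParams,
    FixtureConfig,
    align_pair,
    best_hit,
    blosum50_score,
    classify_central_match,
    crossmap_sites,
    evalue,
    generate_fixture,
    locate_peptides,
    transfer_site_position,
    window_similarity,
)
from phosmap.crossmap import BlastHit, select_best
from phosmap.io import ProteinRecord

AA = "ACDEFGHIKLMNPQRSTVWY"


class TestEvalue:
    def test_zero_bits_gives_mn(self):
        assert evalue(100, 1000, 0) == 100_000

    def test_direct_arithmetic(self):
        assert evalue(100, 10_000, 20) == pytest.approx(1e6 / 2**20)
        assert evalue(100, 10_000, 20) == pytest.approx(0.95367431640625)

    def test_strictly_decreasing_in_bit_score(self):
        assert evalue(100, 1000, 30) < evalue(100, 1000, 20)

    def test_nonpositive_lengths_rejected(self):
        with pytest.raises(ValueError):
            evalue(0, 1000, 10)
        with pytest.raises(ValueError):
            evalue(100, 0, 10)


class TestBestHit:
    DB = [
        ProteinRecord("S1", "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQ"),
        ProteinRecord("S2", "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVA"),
        ProteinRecord("S3", "WWWWPPPPWWWWPPPPWWWW"),
    ]

    def test_identical_sequence_wins_with_full_match(self):
        hit = best_hit(self.DB[0], self.DB)
        assert hit.subject_accession == "S1"
        assert hit.matching_percentage == 1.0

    def test_evalue_invariant_on_emitted_hits(self):
        hit = best_hit(self.DB[1], self.DB)
        expected = evalue(hit.query_length, hit.database_length, hit.bit_score)
        assert hit.evalue == pytest.approx(expected, rel=1e-9)

    def test_no_candidate_below_threshold_returns_none(self):
        query = ProteinRecord("Q", "CCCCHHHHCCCCHHHH")
        hit = best_hit(query, self.DB[:1], CrossmapParams(evalue_max=1e-30))
        assert hit is None

    def test_tie_broken_by_matching_percentage(self):
        a = BlastHit("Q", "S_low", 50.0, 1e-5, 100, 1000, 0.7, 100)
        b = BlastHit("Q", "S_high", 50.0, 1e-5, 100, 1000, 0.9, 100)
        assert select_best([a, b]).subject_accession == "S_high"

    def test_tie_then_alignment_length_then_accession(self):
        base = dict(query_accession="Q", bit_score=50.0, evalue=1e-5,
                    query_length=100, database_length=1000)
        a = BlastHit(subject_accession="A", matching_percentage=0.9, alignment_length=90, **base)
        b = BlastHit(subject_accession="B", matching_percentage=0.9, alignment_length=100, **base)
        assert select_best([a, b]).subject_accession == "B"
        c = BlastHit(subject_accession="C", matching_percentage=0.9, alignment_length=100, **base)
        assert select_best([b, c]).subject_accession == "B"


class TestAlignPair:
    def test_identical_sequences_gapless_identity_map(self):
        aln = align_pair("MKTAYIAK", "MKTAYIAK")
        assert aln.query_aligned == aln.target_aligned == "MKTAYIAK"
        assert aln.column_map == tuple((i, i) for i in range(1, 9))

    def test_single_deletion_opposite_d(self):
        aln = align_pair("ACDEFGH", "ACEFGH")
        assert aln.query_aligned == "ACDEFGH"
        assert aln.target_aligned == "AC-EFGH"

    def test_score_symmetric_under_swap(self):
        a, b = "MKTAYIAKQRQ", "MKTAYIRKQQ"
        assert align_pair(a, b).raw_score == align_pair(b, a).raw_score

    def test_gapless_recovery_of_inputs(self):
        aln = align_pair("MKTAYIAKQRQIS", "MKTAYIRKQQIS")
        assert aln.query_aligned.replace("-", "") == "MKTAYIAKQRQIS"
        assert aln.target_aligned.replace("-", "") == "MKTAYIRKQQIS"

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            align_pair("", "MK")


class TestTransferPosition:
    def test_identity_alignment(self):
        aln = align_pair("MKTAYIAK", "MKTAYIAK")
        assert transfer_site_position(aln, 5) == 5

    def test_position_after_target_gap_shifts(self):
        aln = align_pair("ACDEFGH", "ACEFGH")
        assert transfer_site_position(aln, 4) == 3  # E

    def test_gap_column_is_unmapped(self):
        aln = align_pair("ACDEFGH", "ACEFGH")
        assert transfer_site_position(aln, 3) is None  # D

    def test_out_of_range_rejected(self):
        aln = align_pair("ACDEFGH", "ACEFGH")
        with pytest.raises(ValueError):
            transfer_site_position(aln, 8)


class TestWindowSimilarity:
    def test_self_similarity_is_window_width(self):
        win = "QEVKGIGTPPNTTPI"
        assert window_similarity(win, win) == 15

    def test_only_centre_matches(self):
        assert window_similarity("AAAAAAASAAAAAAA", "CCCCCCCSCCCCCCC") == 1

    def test_single_substitution_loses_one(self):
        assert window_similarity("QEVKGIGTPPNTTPI", "QEVKGIGSPPNTTPI") == 14

    def test_pad_semantics(self):
        assert window_similarity("__AKGIGTPPNTT__", "__AKGIGTPPNTT__") == 15
        assert window_similarity("__AKGIGTPPNTT__", "AAAKGIGTPPNTTAA") == 11
        assert window_similarity(
            "__AKGIGTPPNTT__", "AAAKGIGTPPNTTAA", ignore_pads=True
        ) == 11

    def test_unknown_residue_never_matches(self):
        assert window_similarity("AAAAAAAXAAAAAAA", "AAAAAAAXAAAAAAA") == 14

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError):
            window_similarity("AAA", "AAAA")

    def test_agrees_with_per_character_oracle_on_random_pairs(self, rng):
        # independent brute-force comparison loop on 10,000 random pairs
        chars = list(AA + "_X")
        for _ in range(10_000):
            a = "".join(rng.choice(chars, 15))
            b = "".join(rng.choice(chars, 15))
            oracle = 0
            for x, y in zip(a, b):
                if x == y and x != "X":
                    oracle += 1
            assert window_similarity(a, b) == oracle


class TestBlosum50Score:
    def test_identical_all_ala_is_diagonal_sum(self):
        mat = substitution_matrices.load("BLOSUM50")
        assert blosum50_score("A" * 15, "A" * 15) == 15 * mat["A", "A"]

    def test_symmetry(self):
        a, b = "QEVKGIGTPPNTTPI", "AEVKGIGSPPNTSPI"
        assert blosum50_score(a, b) == blosum50_score(b, a)

    def test_identity_dominates_single_substitutions(self):
        win = "QEVKGIGTPPNTTPI"
        self_score = blosum50_score(win, win)
        for i in range(15):
            for res in AA:
                if res == win[i]:
                    continue
                mutant = win[:i] + res + win[i + 1:]
                assert blosum50_score(win, mutant) <= self_score

    def test_pads_stripped_before_scoring(self):
        mat = substitution_matrices.load("BLOSUM50")
        assert blosum50_score("_____AAAAA_____", "_____AAAAA_____") == 5 * mat["A", "A"]

    def test_all_pad_rejected(self):
        with pytest.raises(ValueError):
            blosum50_score("_" * 15, "A" * 15)


class TestCentralMatchClass:
    @pytest.mark.parametrize(
        "q,t,cls",
        [
            ("S", "S", "S<>S"), ("T", "T", "T<>T"), ("Y", "Y", "Y<>Y"),
            ("S", "T", "S<>T"), ("T", "S", "S<>T"),
            ("S", "Y", "S/T<>Y"), ("Y", "T", "S/T<>Y"),
            ("S", "A", "other"), ("Y", "G", "other"),
        ],
    )
    def test_five_classes_and_other(self, q, t, cls):
        assert classify_central_match(q, t) == cls


@pytest.fixture(scope="module")
def crossmap_run():
    bundle = generate_fixture(FixtureConfig(seed=21, n_proteins=10, n_sites=80))
    sites, _ = locate_peptides(bundle.peptide_table, bundle.query_proteome)
    mapped, summary = crossmap_sites(
        sites, bundle.query_proteome, bundle.target_proteome
    )
    return bundle, sites, mapped, summary


class TestCrossmapPipeline:
    def test_identity_mapping_is_perfect(self, small_bundle):
        sites, _ = locate_peptides(
            small_bundle.peptide_table, small_bundle.query_proteome
        )
        mapped, summary = crossmap_sites(
            sites, small_bundle.query_proteome, small_bundle.query_proteome
        )
        assert summary["mapped"] == len(sites)
        for m in mapped:
            assert m.passed_filters
            assert m.target_accession == m.source.protein_accession
            assert m.target_position == m.source.position
            assert m.ws_score == 15
            assert m.match_class == classify_central_match(
                m.source.residue, m.source.residue
            )

    def test_every_input_site_appears_exactly_once(self, crossmap_run):
        _, sites, mapped, summary = crossmap_run
        assert len(mapped) == len(sites)
        assert sum(summary.values()) == len(sites)

    def test_mapped_positions_agree_with_generator_truth(self, crossmap_run):
        bundle, sites, mapped, _ = crossmap_run
        truth = bundle.truth["ortholog_positions"]
        checked = 0
        for m in mapped:
            if m.target_position is None:
                continue
            tacc, tpos = truth[m.source.site_id]
            if tpos is None:
                continue
            assert m.target_accession == tacc
            assert m.target_position == tpos
            checked += 1
        assert checked > len(sites) * 0.8

    def test_threshold_monotonicity_in_ws_min(self, crossmap_run):
        bundle, sites, _, _ = crossmap_run
        previous = None
        for ws_min in range(0, 16, 3):
            mapped, _ = crossmap_sites(
                sites, bundle.query_proteome, bundle.target_proteome,
                CrossmapParams(ws_min=ws_min),
            )
            passed = {m.source.site_id for m in mapped if m.passed_filters}
            if previous is not None:
                assert passed <= previous
            previous = passed

    def test_central_match_tightening_shrinks_passed_set(self, crossmap_run):
        bundle, sites, _, _ = crossmap_run
        sets = {}
        for mode in ("any", "phospho", "exact"):
            mapped, _ = crossmap_sites(
                sites, bundle.query_proteome, bundle.target_proteome,
                CrossmapParams(central_match=mode),
            )
            sets[mode] = {m.source.site_id for m in mapped if m.passed_filters}
        assert sets["exact"] <= sets["phospho"] <= sets["any"]

    def test_central_substitution_s_to_t(self):
        # ortholog with the central S substituted to T
        q = ProteinRecord("Q0", "MAAAKAAGAASAAGAAKAAAW")
        t = ProteinRecord("T0", "MAAAKAAGAATAAGAAKAAAW")
        sites, _ = locate_peptides(
            [
                __import__("phosmap").io.ModifiedPeptide(
                    raw_string="AAGAAS#AAGAAK", stripped_sequence="AAGAASAAGAAK",
                    mod_positions=(6,), mod_residues=("S",),
                )
            ],
            [q],
        )
        mapped, _ = crossmap_sites(sites, [q], [t], CrossmapParams(central_match="phospho"))
        assert mapped[0].passed_filters and mapped[0].match_class == "S<>T"
        mapped, _ = crossmap_sites(sites, [q], [t], CrossmapParams(central_match="exact"))
        assert not mapped[0].passed_filters
        assert mapped[0].reason == "central_mismatch"

    def test_ws_below_threshold_reason_code(self):
        # windows share exactly 7 characters -> fails ws_min=8
        q = ProteinRecord("Q0", "M" + "ACDEFGH" + "S" + "IKLMNPQ" + "W")
        t = ProteinRecord("T0", "M" + "AGDHFGY" + "S" + "IRLWNPE" + "W")
        # per-character oracle count: A.D.FG. S I.L.NP. = 4 + 1 + 4 = 9... construct
        qw = "ACDEFGHSIKLMNPQ"
        tw = "AGDHFGYSIRLWNPE"
        shared = sum(1 for a, b in zip(qw, tw) if a == b)
        assert shared == 9
        sites, _ = locate_peptides(
            [
                __import__("phosmap").io.ModifiedPeptide(
                    raw_string=qw, stripped_sequence=qw,
                    mod_positions=(8,), mod_residues=("S",),
                )
            ],
            [q],
        )
        mapped, _ = crossmap_sites(sites, [q], [t], CrossmapParams(ws_min=10))
        assert mapped[0].reason == "fails_ws"
        mapped, _ = crossmap_sites(sites, [q], [t], CrossmapParams(ws_min=9))
        assert mapped[0].passed_filters

    def test_unknown_query_accession_rejected(self, crossmap_run):
        bundle, sites, _, _ = crossmap_run
        from phosmap.prealign import SiteRecord

        rogue = SiteRecord("NOPE", 8, "S", "AAAAAAASAAAAAAA")
        with pytest.raises(ValueError, match="NOPE"):
            crossmap_sites(
                [rogue], bundle.query_proteome, bundle.target_proteome
            )
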