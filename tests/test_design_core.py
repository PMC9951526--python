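"""Partitioning, enumeration, overhangs, oligo layout, and primers."""

import numpy as np
import pytest

from indelkit.design_core import (
    BSAI,
    GeometryConfig,
    VariantConfig,
    choose_codon,
    design_library,
    enumerate_variants,
    max_mutable_codons,
    melting_tm,
    partition_gene,
    platform_limits,
)
from indelkit.fixtures import random_gene
from indelkit.sequence_model import (
    AA_TO_CODONS,
    CodonUsageTable,
    make_target_gene,
    reverse_complement,
    scan_sites,
    DEFAULT_ENZYMES,
)


class TestPartition:
    def test_default_window_fits_49_codons(self):
        assert max_mutable_codons(GeometryConfig(), BSAI, VariantConfig()) == 49

    def test_436_codon_orf_partitions_into_9_sublibraries(self):
        gene = random_gene(436, 0.50, seed=3)
        subs = partition_gene(gene)
        assert len(subs) == 9

    def test_short_orf_fits_one_sublibrary(self):
        gene = random_gene(40, 0.50, seed=3)
        subs = partition_gene(gene)
        assert len(subs) == 1
        assert (subs[0].codon_start, subs[0].codon_end) == (1, 40)

    def test_100_codon_orf_gives_near_equal_windows(self):
        gene = random_gene(100, 0.50, seed=3)
        subs = partition_gene(gene)
        sizes = sorted((s.n_codons for s in subs), reverse=True)
        assert len(subs) == 3 and sizes == [34, 33, 33]

    def test_windows_tile_without_gap_or_overlap(self, medium_design):
        subs = medium_design.sublibraries
        covered = []
        for s in subs:
            covered.extend(range(s.codon_start, s.codon_end + 1))
        gene = medium_design.gene
        assert covered == list(range(gene.mut_start, gene.mut_end + 1))


class TestPlatformLimits:
    def test_default_profile_enforces_120nt_insertion_and_27nt_deletion(self):
        assert platform_limits(GeometryConfig()) == (120, 27)

    def test_oversized_insertion_request_is_rejected(self):
        vcfg = VariantConfig(insertion_payloads=("GGC" * 50,))  # 150 nt
        with pytest.raises(ValueError, match="platform limit"):
            vcfg.validate_against(GeometryConfig())

    def test_oversized_deletion_request_is_rejected(self):
        vcfg = VariantConfig(deletion_lengths=(10,))  # 30 nt
        with pytest.raises(ValueError, match="platform limit"):
            vcfg.validate_against(GeometryConfig())


class TestEnumeration:
    def test_internal_residue_yields_26_variants(self):
        # an internal Leu: 19 missense + 1 synonymous + 3 ins + 3 del
        gene = random_gene(30, 0.50, seed=4)
        pos = next(
            p for p in range(5, 25) if gene.protein[p - 1] not in "MW*"
        )
        variants = [v for v in enumerate_variants(gene) if v.codon_pos == pos]
        assert len(variants) == 26

    def test_single_codon_amino_acid_lacks_synonymous_variant(self):
        cds = "ATG" + "GCT" * 5 + "TGG" + "GCT" * 5 + "TAA"  # Trp at codon 7
        gene = make_target_gene("trp", cds)
        variants = [v for v in enumerate_variants(gene) if v.codon_pos == 7]
        assert len(variants) == 25
        assert not any(v.kind == "synonymous" for v in variants)

    def test_deletion_start_positions_follow_the_window_rule(self):
        # 10 residues, max deletion 3: starts 2..7, three lengths each
        gene = make_target_gene("ten", "ATG" + "GCT" * 9)
        dels = [v for v in enumerate_variants(gene) if v.kind == "deletion"]
        assert len(dels) == 18
        assert all(2 <= v.codon_pos <= 7 for v in dels)
        assert not any(v.codon_pos == 1 for v in dels)

    @pytest.mark.parametrize("seed", range(6))
    def test_total_count_matches_closed_form(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(12, 120))
        gene = random_gene(n, 0.5, seed=seed + 50)
        variants = enumerate_variants(gene)
        L = gene.n_residues
        syn_capable = sum(1 for aa in gene.protein[:L] if len(AA_TO_CODONS[aa]) >= 2)
        expected = 19 * L + syn_capable + 3 * L + 3 * max(L - 3 - 1, 0)
        assert len(variants) == expected

    def test_names_are_unique(self, small_design):
        names = [v.name for v in small_design.variants]
        assert len(set(names)) == len(names)

    def test_stop_variants_only_when_enabled(self):
        gene = random_gene(20, 0.5, seed=5)
        with_stop = enumerate_variants(gene, VariantConfig(include_stop=True))
        without = enumerate_variants(gene)
        stops = [v for v in with_stop if v.kind == "stop"]
        assert len(stops) == gene.n_residues
        assert len(with_stop) == len(without) + len(stops)


class TestOverhangs:
    @pytest.mark.parametrize("seed,n", [(21, 300), (22, 600)])
    def test_design_overhangs_satisfy_pairwise_constraints(self, seed, n):
        design = design_library(random_gene(n, 0.5, seed=seed))
        overhangs = []
        for s in design.sublibraries:
            overhangs += [s.up_overhang, s.down_overhang]
        assert all(len(o) == 4 for o in overhangs)
        assert len(set(overhangs)) == len(overhangs)
        for o in overhangs:
            assert o != reverse_complement(o), "palindromic overhang"
        rcs = {reverse_complement(o) for o in overhangs}
        assert not (set(overhangs) & rcs), "reverse-complement overhang pair"

    def test_overhangs_are_wildtype_fragment_ends(self, small_design):
        construct = small_design.construct
        for s in small_design.sublibraries:
            start, end = small_design.fragment_span(s)
            assert construct[start : start + 4] == s.up_overhang
            assert construct[end - 4 : end] == s.down_overhang


class TestChooseCodon:
    def test_neutral_context_returns_top_ranked_codon(self):
        usage = CodonUsageTable.default()
        assert choose_codon("A", usage, "AAAAAA", "AAAAAA") == usage.top_codon("A")

    def test_single_codon_amino_acid(self):
        usage = CodonUsageTable.default()
        assert choose_codon("M", usage, "AAAAAA", "AAAAAA") == "ATG"

    def test_site_completing_top_codon_is_skipped(self):
        usage = CodonUsageTable.default()
        # Glu ranks GAG above GAA, but GAG followed by "ACC" completes
        # GAGACC (a minus-strand BsaI site), so the second codon wins
        assert usage.top_codon("E") == "GAG"
        assert choose_codon("E", usage, "AAA", "ACCAA") == "GAA"
        # with neutral context the top codon is kept
        assert choose_codon("E", usage, "AAA", "AAAAA") == "GAG"


class TestOligos:
    def test_all_oligos_of_a_sublibrary_share_one_length(self, medium_design):
        lengths: dict[int, set[int]] = {}
        for oligo in medium_design.oligos.values():
            lengths.setdefault(oligo.sublibrary, set()).add(len(oligo.sequence))
        assert all(len(v) == 1 for v in lengths.values())

    def test_no_oligo_exceeds_platform_length(self, medium_design):
        assert all(
            len(o.sequence) <= medium_design.geom.max_oligo_len
            for o in medium_design.oligos.values()
        )

    def test_deletion_and_insertion_oligos_have_equal_length(self, small_design):
        # a 3-codon deletion and a 9-nt insertion at the same interior
        # position differ by 18 nt of payload, compensated by buffers
        d = small_design
        pos = 10
        aa = d.gene.protein[pos - 1]
        aa2 = d.gene.protein[pos + 1]
        del3 = d.oligos[f"p.{aa}{pos}_{aa2}{pos + 2}del"]
        ins9 = d.oligos[f"p.{aa}{pos}_insGSG"]
        assert len(del3.sequence) == len(ins9.sequence)
        lay_d, lay_i = dict(del3.layout), dict(ins9.layout)
        assert lay_i["payload"] - lay_d["payload"] == 18
        buf_d = lay_d["buffer5"] + lay_d["buffer3"]
        buf_i = lay_i["buffer5"] + lay_i["buffer3"]
        assert buf_d - buf_i == 18

    def test_recognition_sites_appear_exactly_twice_per_oligo(self, medium_design):
        enz = medium_design.enzyme
        rc = reverse_complement(enz.recognition)
        for oligo in medium_design.oligos.values():
            assert oligo.sequence.count(enz.recognition) + oligo.sequence.count(rc) == 2

    def test_layout_lengths_cover_the_sequence(self, small_design):
        for oligo in small_design.oligos.values():
            assert sum(n for _, n in oligo.layout) == len(oligo.sequence)


class TestPrimers:
    def test_nine_sublibrary_design_gets_nine_pairs_of_each_kind(self):
        design = design_library(random_gene(436, 0.5, seed=3))
        assert len(design.sublibraries) == 9
        subpool = [p for p in design.primers if p.kind == "subpool"]
        backbone = [p for p in design.primers if p.kind == "backbone"]
        assert len(subpool) == 9 and len(backbone) == 9

    def test_barcodes_are_unique_across_sublibraries(self, medium_design):
        codes = [s.barcode_fwd for s in medium_design.sublibraries]
        codes += [s.barcode_rev for s in medium_design.sublibraries]
        assert len(set(codes)) == len(codes)

    def test_annealing_regions_meet_tm_threshold(self, medium_design):
        for p in medium_design.primers:
            assert p.fwd_tm >= 58.0 and p.rev_tm >= 58.0

    def test_at_rich_regions_extend_annealing_length(self):
        # nearest-neighbor Tm grows with added GC, so extension terminates
        seq = "ATATATATATATATATAT"
        assert melting_tm(seq) < 58.0
        assert melting_tm(seq + "GCGCGCGCGCGC") > melting_tm(seq)

    def test_backbone_tails_carry_the_cassette(self, medium_design):
        enz = medium_design.enzyme
        for p in medium_design.primers:
            if p.kind == "backbone":
                assert p.fwd.startswith(enz.recognition)
                assert p.rev.startswith(enz.recognition)
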