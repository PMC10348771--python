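"""Receptor assembly, clonotype keys, the >2-cell expansion rule, summaries."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from clonotrack import clonotype as ck
from clonotrack.tenx import ContigRecord


def contig(barcode, chain, nt, **kw):
    defaults = dict(cdr3_aa="X" * (len(nt) // 3), productive=True, full_length=True,
                    high_confidence=True)
    defaults.update(kw)
    return ContigRecord(barcode=barcode, chain=chain, cdr3_nt=nt, **defaults)


def receptor(barcode, alphas=(), betas=()):
    return ck.CellReceptor(
        barcode=barcode,
        alpha_cdr3_nt=sorted(alphas),
        beta_cdr3_nt=list(betas),
        alpha_cdr3_aa=["A"] * len(alphas),
        beta_cdr3_aa=["B"] * len(betas),
    )


class TestCollapseVariants:
    def test_plain_tra_unchanged(self):
        (out,) = ck.collapse_variants([contig("b-1", "TRA", "TGT")])
        assert out.chain == "TRA"
        assert "non_ab_locus" not in out.extras

    def test_allele_suffix_stripped_and_locus_from_v_gene(self):
        (out,) = ck.collapse_variants(
            [contig("b-1", "Multi", "TGT", v_gene="TRAV12-2*01", j_gene="TRAJ33*01")]
        )
        assert out.chain == "TRA"
        assert out.v_gene == "TRAV12-2"
        assert out.j_gene == "TRAJ33"

    def test_trd_contig_flagged(self):
        (out,) = ck.collapse_variants([contig("b-1", "TRD", "TGT")])
        assert out.extras["non_ab_locus"] == "true"

    def test_cdr3_strings_untouched(self):
        nt = "TGTGCAAGTTTG"
        (out,) = ck.collapse_variants([contig("b-1", "TRB", nt, v_gene="TRBV2*02")])
        assert out.cdr3_nt == nt


class TestBuildReceptors:
    def test_one_alpha_one_beta_pairs(self):
        recs = ck.build_receptors([contig("b-1", "TRA", "AAA"), contig("b-1", "TRB", "CCC")])
        assert len(recs) == 1 and recs[0].is_paired
        assert recs[0].alpha_cdr3_nt == ["AAA"] and recs[0].beta_cdr3_nt == ["CCC"]

    def test_beta_only_single_chain(self):
        (r,) = ck.build_receptors([contig("b-1", "TRB", "CCC")])
        assert r.n_alpha == 0 and r.n_beta == 1 and not r.is_paired

    def test_barcode_outside_cd8_set_omitted(self):
        recs = ck.build_receptors([contig("b-1", "TRA", "AAA")], cd8_barcodes={"other-1"})
        assert recs == []

    def test_unusable_contigs_ignored(self):
        recs = ck.build_receptors([
            contig("b-1", "TRA", "AAA", productive=False),
            contig("b-1", "TRB", "CCC", high_confidence=False),
            contig("b-1", "TRD", "GGG"),
        ])
        assert recs == []

    def test_duplicate_cdr3_deduplicated(self):
        (r,) = ck.build_receptors([
            contig("b-1", "TRA", "AAA", contig_id="c1"),
            contig("b-1", "TRA", "AAA", contig_id="c2"),
        ])
        assert r.alpha_cdr3_nt == ["AAA"]

    def test_more_than_two_chains_malformed(self):
        (r,) = ck.build_receptors([
            contig("b-1", "TRA", x) for x in ("AAA", "CCC", "GGG")
        ])
        assert r.malformed


class TestCallClonotypes:
    def test_three_identical_cells_expanded(self):
        recs = [receptor(f"b{i}", ["AAA"], ["CCC"]) for i in range(3)]
        clons, keyless = ck.call_clonotypes(recs)
        assert keyless == []
        (ct,) = clons
        assert ct.size == 3 and ct.status == "expanded"

    def test_two_identical_cells_unexpanded_boundary(self):
        clons, _ = ck.call_clonotypes([receptor(f"b{i}", ["AAA"], ["CCC"]) for i in range(2)])
        assert clons[0].status == "unexpanded"

    def test_five_dual_beta_cells_are_five_keyless_units(self):
        recs = [receptor(f"b{i}", ["AAA"], ["CCC", "GGG"]) for i in range(5)]
        clons, keyless = ck.call_clonotypes(recs)
        assert clons == [] and len(keyless) == 5

    def test_single_chain_cells_keyless(self):
        recs = [receptor("b1", ["AAA"], []), receptor("b2", [], ["CCC"])]
        clons, keyless = ck.call_clonotypes(recs)
        assert clons == [] and len(keyless) == 2

    def test_partial_alpha_overlap_does_not_merge(self):
        recs = [receptor("b1", ["AAA", "TTT"], ["CCC"]), receptor("b2", ["AAA"], ["CCC"])]
        clons, _ = ck.call_clonotypes(recs)
        assert len(clons) == 2

    def test_aa_key_level_merges_synonymous_nt(self):
        r1 = ck.CellReceptor("b1", ["AAA"], ["CCC"], ["K"], ["P"])
        r2 = ck.CellReceptor("b2", ["AAG"], ["CCT"], ["K"], ["P"])  # synonymous
        nt_clons, _ = ck.call_clonotypes([r1, r2], key_level="nt")
        aa_clons, _ = ck.call_clonotypes([r1, r2], key_level="aa")
        assert len(nt_clons) == 2 and len(aa_clons) == 1

    def test_malformed_excluded(self):
        bad = receptor("b1", ["AAA"], ["CCC"])
        bad.malformed = True
        clons, keyless = ck.call_clonotypes([bad])
        assert clons == [] and keyless == []

    def test_matches_naive_all_pairs_grouping(self):
        """Hash-grouped calling equals O(n²) string-comparison grouping."""
        rng = np.random.default_rng(5)
        pool = [(tuple(sorted({"".join(rng.choice(list("ACGT"), 6)) for _ in range(rng.integers(1, 3))})),
                 "".join(rng.choice(list("ACGT"), 6))) for _ in range(12)]
        recs = []
        for i in range(80):
            alphas, beta = pool[rng.integers(0, len(pool))]
            recs.append(receptor(f"b{i}", list(alphas), [beta]))
        clons, _ = ck.call_clonotypes(recs)
        # naive grouping: all-pairs equality on (alpha set, beta)
        naive: list[list] = []
        for r in recs:
            for group in naive:
                g = group[0]
                if sorted(g.alpha_cdr3_nt) == sorted(r.alpha_cdr3_nt) and g.beta_cdr3_nt == r.beta_cdr3_nt:
                    group.append(r)
                    break
            else:
                naive.append([r])
        naive_sets = {frozenset(x.barcode for x in g) for g in naive}
        called_sets = {frozenset(c.member_barcodes) for c in clons}
        assert called_sets == naive_sets

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.lists(
        st.tuples(st.integers(0, 5), st.integers(0, 3), st.booleans()),
        min_size=1, max_size=40,
    ))
    def test_partition_property(self, spec):
        """Every receptor lands in exactly one clonotype or keyless unit."""
        recs = []
        for i, (key_id, beta_id, dual) in enumerate(spec):
            alphas = [f"A{key_id}"] + ([f"AX{key_id}"] if dual else [])
            recs.append(receptor(f"b{i}", alphas, [f"B{beta_id}"]))
        clons, keyless = ck.call_clonotypes(recs)
        total = sum(c.size for c in clons) + len(keyless)
        assert total == len(recs)
        barcodes = [bc for c in clons for bc in c.member_barcodes] + [r.barcode for r in keyless]
        assert len(barcodes) == len(set(barcodes))

    def test_status_invariant_under_input_order(self):
        rng = np.random.default_rng(3)
        recs = [receptor(f"b{i}", ["AAA"], ["CCC"]) for i in range(4)]
        recs += [receptor(f"c{i}", ["TTT"], ["GGG"]) for i in range(2)]
        shuffled = list(recs)
        rng.shuffle(shuffled)
        c1, _ = ck.call_clonotypes(recs)
        c2, _ = ck.call_clonotypes(shuffled)
        as_map = lambda cs: {c.key.serialize(): (c.size, c.status) for c in cs}
        assert as_map(c1) == as_map(c2)


class TestDualAlphaStats:
    def test_no_dual_alpha_gives_zeroes(self):
        recs = [receptor(f"b{i}", ["AAA"], ["CCC"]) for i in range(3)]
        recs += [receptor("u1", ["GGG"], ["TTT"])]
        clons, keyless = ck.call_clonotypes(recs)
        out = ck.dual_alpha_stats(clons, keyless, recs)
        assert out["pct_dual_alpha_expanded"] == 0.0
        assert out["pct_dual_alpha_unexpanded"] == 0.0
        assert out["p_value"] == 1.0

    def test_all_dual_alpha_gives_hundreds(self):
        recs = [receptor(f"b{i}", ["AAA", "TTT"], ["CCC"]) for i in range(3)]
        recs += [receptor("u1", ["GGG", "AAA"], ["TTT"])]
        clons, keyless = ck.call_clonotypes(recs)
        out = ck.dual_alpha_stats(clons, keyless, recs)
        assert out["pct_dual_alpha_expanded"] == 100.0
        assert out["pct_dual_alpha_unexpanded"] == 100.0

    def test_empty_stratum_nan(self, caplog):
        recs = [receptor(f"b{i}", ["AAA"], ["CCC"]) for i in range(3)]  # expanded only
        clons, keyless = ck.call_clonotypes(recs)
        with caplog.at_level("WARNING"):
            out = ck.dual_alpha_stats(clons, keyless, recs)
        assert np.isnan(out["pct_dual_alpha_unexpanded"])
        assert np.isnan(out["p_value"])


class TestSummarizeSample:
    @pytest.mark.parametrize(
        "n_expanded,n_total,expected",
        [(26, 336, 7.7), (24, 182, 13.2), (16, 168, 9.5), (0, 50, 0.0)],
    )
    def test_expanded_percentage_rounding(self, n_expanded, n_total, expected):
        recs = []
        for i in range(n_expanded):
            recs += [receptor(f"e{i}_{j}", [f"A{i}"], [f"B{i}"]) for j in range(3)]
        recs += [receptor(f"s{i}", [f"SA{i}"], [f"SB{i}"]) for i in range(n_total - n_expanded)]
        clons, keyless = ck.call_clonotypes(recs)
        summary = ck.summarize_sample(clons, keyless, "S")
        assert summary.n_clonotypes_total == n_total
        assert summary.n_expanded == n_expanded
        assert summary.pct_expanded == expected

    def test_counts_invariants(self):
        recs = [receptor(f"b{i}", ["AAA"], ["CCC"]) for i in range(4)]
        recs += [receptor("d1", ["AAA"], ["CCC", "GGG"])]  # dual-β keyless
        recs += [receptor("s1", [], ["TTT"])]  # single-chain keyless
        clons, keyless = ck.call_clonotypes(recs)
        s = ck.summarize_sample(clons, keyless, "S")
        assert s.n_expanded + s.n_unexpanded == s.n_clonotypes_total
        assert s.n_cd8_cells_with_receptor == len(recs)
        assert s.expanded_sizes == [4]

    def test_zero_units_nan_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            s = ck.summarize_sample([], [], "S")
        assert np.isnan(s.pct_expanded)


def test_round_half_up_semantics():
    assert ck.round_half_up(7.738095, 1) == 7.7
    assert ck.round_half_up(13.186813, 1) == 13.2
    assert ck.round_half_up(0.25, 1) == 0.3  # half goes up, unlike banker's rounding
    assert ck.round_half_up(72.22, 0) == 72.0


def test_key_serialization_roundtrip():
    key = ck.ClonotypeKey(("TTT", "AAA"), "CCC")
    assert key.alpha_set == ("AAA", "TTT")  # sorted on construction
    back = ck.parse_key(key.serialize())
    assert back == key
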