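"""Generator correctness: planted truth, determinism, marginal rates."""

import hashlib
import pathlib

import numpy as np
import pytest

from clonotrack import synthetic as syn
from clonotrack import tenx
from clonotrack.clonotype import build_receptors, collapse_variants


def cohort_digest(d):
    h = hashlib.sha256()
    for p in sorted(pathlib.Path(d).rglob("*")):
        if p.is_file():
            h.update(str(p.relative_to(d)).encode())
            h.update(p.read_bytes())
    return h.hexdigest()


def single_clone_config(size=3, seed=0, **overrides):
    clone = syn.CloneSpec(
        clone_id="C1",
        alpha_cdr3_nt=["TGTGCAGCAAGT" * 3],
        beta_cdr3_nt=["TGTGCCAGCTCA" * 3][0],
        size_by_sample={"S1": size},
    )
    participant = syn.ParticipantSpec(
        participant_id="P1", is_arm="none", samples=[("S1", "biopsy", 10)], clones=[clone]
    )
    kw = dict(participants=[participant], seed=seed, cells_per_sample=size,
              background_lineage_weights={"CD8": 1.0}, **syn.zero_noise_kwargs())
    kw.update(overrides)
    return syn.CohortConfig(**kw)


class TestZeroNoiseContigs:
    def test_single_clone_of_three_shares_one_pair(self, tmp_path):
        syn.generate_cohort(single_clone_config(size=3), tmp_path)
        contigs = tenx.read_contigs(tmp_path / "S1" / "filtered_contig_annotations.csv")
        barcodes = {c.barcode for c in contigs}
        assert len(barcodes) == 3
        pairs = {
            (tuple(sorted(c.cdr3_nt for c in contigs if c.barcode == b and c.chain == "TRA")),
             tuple(sorted(c.cdr3_nt for c in contigs if c.barcode == b and c.chain == "TRB")))
            for b in barcodes
        }
        assert len(pairs) == 1
        ((alphas, betas),) = pairs
        assert len(alphas) == 1 and len(betas) == 1

    def test_every_barcode_has_one_alpha_one_beta(self, tmp_path):
        cfg = single_clone_config(size=2, cells_per_sample=50)
        syn.generate_cohort(cfg, tmp_path)
        contigs = tenx.read_contigs(tmp_path / "S1" / "filtered_contig_annotations.csv")
        per_bc = {}
        for c in contigs:
            per_bc.setdefault(c.barcode, []).append(c.chain)
        assert all(sorted(ch) == ["TRA", "TRB"] for ch in per_bc.values())

    def test_dual_alpha_rate_one_gives_two_alphas_everywhere(self, tmp_path):
        cfg = single_clone_config(size=0, cells_per_sample=40, dual_alpha_rate=1.0)
        syn.generate_cohort(cfg, tmp_path)
        contigs = tenx.read_contigs(tmp_path / "S1" / "filtered_contig_annotations.csv")
        n_alpha = {}
        for c in contigs:
            if c.chain == "TRA":
                n_alpha[c.barcode] = n_alpha.get(c.barcode, 0) + 1
        assert set(n_alpha.values()) == {2}


class TestDeterminismAndTruth:
    def test_same_seed_byte_identical(self, tmp_path):
        cfg = syn.clonal_mix_config(5, 40, seed=3)
        d1, d2 = tmp_path / "a", tmp_path / "b"
        syn.generate_cohort(cfg, d1)
        syn.generate_cohort(syn.clonal_mix_config(5, 40, seed=3), d2)
        assert cohort_digest(d1) == cohort_digest(d2)

    def test_different_seed_differs(self, tmp_path):
        d1, d2 = tmp_path / "a", tmp_path / "b"
        syn.generate_cohort(syn.clonal_mix_config(5, 40, seed=3), d1)
        syn.generate_cohort(syn.clonal_mix_config(5, 40, seed=4), d2)
        assert cohort_digest(d1) != cohort_digest(d2)

    def test_truth_registry_expanded_count(self, tmp_path):
        truth = syn.generate_cohort(syn.clonal_mix_config(26, 336, seed=1), tmp_path)
        assert len(truth.expanded_keys("S1")) == 26
        sizes = [rec["size"] for rec in truth.samples["S1"].values()]
        assert all(rec["expanded"] == (rec["size"] > 2) for rec in truth.samples["S1"].values())
        assert all(s >= 3 for s in sizes)

    def test_truth_roundtrip_json(self, tmp_path):
        truth = syn.generate_cohort(syn.clonal_mix_config(3, 10, seed=1), tmp_path)
        back = syn.ClonalTruth.from_json(tmp_path / "truth.json")
        assert back.samples == truth.samples
        assert back.sample_meta == truth.sample_meta

    def test_referential_integrity(self, tmp_path):
        cfg = syn.example_cohort_config(seed=5, cells_per_sample=200, clones_per_participant=6,
                                        n_participants=1)
        truth = syn.generate_cohort(cfg, tmp_path)
        for sid in truth.samples:
            sidecar = set((tmp_path / sid / "barcodes.tsv").read_text().split())
            contig_bcs = {
                c.barcode
                for c in tenx.read_contigs(tmp_path / sid / "filtered_contig_annotations.csv")
            }
            truth_bcs = set(truth.barcode_map[sid])
            assert truth_bcs == sidecar
            assert contig_bcs <= sidecar


class TestMarginalRates:
    def test_paired_recovery_rate_within_3sd(self, tmp_path):
        n = 6000
        cfg = single_clone_config(size=0, cells_per_sample=n, seed=9,
                                  chain_recovery_rate=0.9, doublet_rate=0.0)
        syn.generate_cohort(cfg, tmp_path)
        contigs = collapse_variants(
            tenx.read_contigs(tmp_path / "S1" / "filtered_contig_annotations.csv")
        )
        receptors = build_receptors(contigs)
        paired = np.mean([r.is_paired for r in receptors])
        sd = np.sqrt(0.9 * 0.1 / n)
        assert abs(paired - 0.9) < 3 * sd

    def test_dual_alpha_rate_within_3sd(self, tmp_path):
        n = 6000
        cfg = single_clone_config(size=0, cells_per_sample=n, seed=13, dual_alpha_rate=0.08)
        syn.generate_cohort(cfg, tmp_path)
        contigs = collapse_variants(
            tenx.read_contigs(tmp_path / "S1" / "filtered_contig_annotations.csv")
        )
        receptors = build_receptors(contigs)
        dual = np.mean([r.is_dual_alpha for r in receptors])
        sd = np.sqrt(0.08 * 0.92 / n)
        assert abs(dual - 0.08) < 3 * sd

    def test_doublet_rate_within_3sd(self, tmp_path):
        n = 6000
        cfg = single_clone_config(size=0, cells_per_sample=n, seed=17, doublet_rate=0.05)
        syn.generate_cohort(cfg, tmp_path)
        receptors = build_receptors(collapse_variants(
            tenx.read_contigs(tmp_path / "S1" / "filtered_contig_annotations.csv")
        ))
        dual_beta = np.mean([r.n_beta == 2 for r in receptors])
        sd = np.sqrt(0.05 * 0.95 / n)
        assert abs(dual_beta - 0.05) < 3 * sd + 1.0 / n  # own-β draws shave ~1/n


class TestExpression:
    def _matrix(self, cfg, tmp_path):
        truth = syn.generate_cohort(cfg, tmp_path)
        return tenx.read_mtx(tmp_path / "S1"), truth

    def test_mito_outliers_exceed_quarter(self, tmp_path):
        cfg = single_clone_config(size=0, cells_per_sample=400, seed=2, mito_outlier_rate=0.2)
        m, truth = self._matrix(cfg, tmp_path)
        mito_idx = [i for i, g in enumerate(m.genes) if g.startswith("MT-")]
        X = m.counts.tocsc()
        frac = np.asarray(X[mito_idx, :].sum(axis=0)).ravel() / np.asarray(X.sum(axis=0)).ravel()
        flagged = [bc for bc, rec in truth.barcode_map["S1"].items() if rec["mito_outlier"]]
        assert flagged
        pos = {bc: j for j, bc in enumerate(m.barcodes)}
        assert all(frac[pos[bc]] > 0.25 for bc in flagged)

    def test_low_gene_cells_below_200_genes(self, tmp_path):
        cfg = single_clone_config(size=0, cells_per_sample=400, seed=2, low_gene_rate=0.2)
        m, truth = self._matrix(cfg, tmp_path)
        n_genes = np.asarray((m.counts.tocsc() > 0).sum(axis=0)).ravel()
        pos = {bc: j for j, bc in enumerate(m.barcodes)}
        flagged = [bc for bc, rec in truth.barcode_map["S1"].items() if rec["low_gene"]]
        normal = [bc for bc, rec in truth.barcode_map["S1"].items() if not rec["low_gene"]]
        assert flagged and normal
        assert all(n_genes[pos[bc]] < 200 for bc in flagged)
        assert all(n_genes[pos[bc]] >= 200 for bc in normal)

    def test_lineage_marker_exclusivity(self, tmp_path):
        cfg = single_clone_config(size=0, cells_per_sample=500, seed=4)
        cfg.background_lineage_weights = {"CD8": 0.5, "CD4": 0.5}
        m, truth = self._matrix(cfg, tmp_path)
        pos = {bc: j for j, bc in enumerate(m.barcodes)}
        cd8a = m.row("CD8A")
        cd4 = m.row("CD4")
        for bc, rec in truth.barcode_map["S1"].items():
            if rec["lineage"] == "CD8":
                assert cd8a[pos[bc]] > 0 and cd4[pos[bc]] == 0
            else:
                assert cd4[pos[bc]] > 0 and cd8a[pos[bc]] == 0

    def test_activated_program_raises_gzmb(self, tmp_path):
        clone = syn.CloneSpec("C1", ["TGTGCAGCAAGT"], "TGTGCCAGCTCA",
                              {"S1": 500}, phenotype_program="activated")
        participant = syn.ParticipantSpec("P1", "none", [("S1", "biopsy", 1)], [clone])
        cfg = syn.CohortConfig(participants=[participant], seed=6, cells_per_sample=1000,
                               background_lineage_weights={"CD8": 1.0},
                               **syn.zero_noise_kwargs())
        m, truth = self._matrix(cfg, tmp_path)
        pos = {bc: j for j, bc in enumerate(m.barcodes)}
        gzmb = m.row("GZMB")
        in_clone = [pos[bc] for bc, r in truth.barcode_map["S1"].items() if r["clone_id"]]
        background = [pos[bc] for bc, r in truth.barcode_map["S1"].items() if not r["clone_id"]]
        assert gzmb[in_clone].mean() > gzmb[background].mean() + 3.0


class TestConfigValidation:
    @pytest.mark.parametrize("bad", [
        dict(chain_recovery_rate=1.5),
        dict(doublet_rate=-0.1),
        dict(cells_per_sample=0),
    ])
    def test_invalid_config_names_field(self, bad):
        with pytest.raises(ValueError):
            single_clone_config(**bad)

    def test_cdr3_alphabet_enforced(self):
        with pytest.raises(ValueError, match="CDR3"):
            syn.CloneSpec("C1", ["TGTGXA"], "TGTGCC", {"S1": 1})

    def test_clone_sizes_exceeding_cells_rejected(self, tmp_path):
        cfg = single_clone_config(size=5, cells_per_sample=3)
        with pytest.raises(ValueError, match="exceed"):
            syn.generate_cohort(cfg, tmp_path)

    def test_duplicate_clone_keys_rejected(self):
        c1 = syn.CloneSpec("C1", ["TGTGCAGCAAGT"], "TGTGCCAGCTCA", {"S1": 1})
        c2 = syn.CloneSpec("C2", ["TGTGCAGCAAGT"], "TGTGCCAGCTCA", {"S1": 2})
        with pytest.raises(ValueError, match="unique"):
            syn.ParticipantSpec("P1", "none", [("S1", "biopsy", 1)], [c1, c2])

    def test_nonincreasing_days_rejected(self):
        with pytest.raises(ValueError, match="increasing"):
            syn.ParticipantSpec("P1", "none",
                                [("S1", "biopsy", 10), ("S2", "biopsy", 10)], [])


def test_translate_cdr3_standard_code():
    assert syn.translate_cdr3("TGTGCAAGT") == "CAS"
    with pytest.raises(ValueError):
        syn.translate_cdr3("TGTG")


def test_random_cdr3_well_formed():
    rng = np.random.default_rng(0)
    for _ in range(50):
        s = syn.random_cdr3(rng)
        assert 36 <= len(s) <= 54 and len(s) % 3 == 0
        assert not set(s) - set("ACGT")
        assert "*" not in syn.translate_cdr3(s)
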