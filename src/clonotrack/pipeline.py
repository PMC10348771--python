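"""End-to-end orchestration: QC → typing → clonotype calling → tracking → DEG.

``run`` executes every stage for a cohort manifest and writes the result
tables (per-sample clonal summaries, clone tracks, persistence counts,
biopsy–urine overlaps, expanded-vs-unexpanded DEGs, mTOR-panel averages)
plus a machine-readable run report that records the seed, every decided
default (key level, adjustment method, exclusion thresholds) and
per-stage cell/clone accounting, so no denominator is unauditable.
"""

from __future__ import annotations

import logging
import shutil
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import celltyping, clonotype, diffexpr, qc, tracking
from .tenx import (
    SampleManifest,
    read_contigs,
    read_manifest,
    read_mtx,
    write_run_report,
    write_tsv,
)

__all__ = ["RunConfig", "StageError", "run", "validate"]

logger = logging.getLogger(__name__)

MTOR_PANEL = ["MTOR", "RPTOR", "RICTOR", "TSC1", "TSC2", "FKBP1A"]


class StageError(RuntimeError):
    """A pipeline stage failed; the message is tagged with the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """All tunable pipeline settings with their documented defaults."""

    qc_max_mito: float = 0.25
    qc_min_genes: int = 200
    qc_blacklist: list[str] = field(default_factory=list)
    norm_scale_factor: float = 10_000.0
    clonotype_key_level: str = "nt"  # nt | aa
    clonotype_min_expanded_size: int = 3
    cd8_exclusion_threshold: float = 0.0  # raw count above which CD4/TRDC/CD68 excludes
    tracking_scope: str = "expanded"  # expanded | all
    persistence_mode: str = "expanded"  # expanded | any
    deg_logfc_threshold: float = 1.0
    deg_min_pct: float = 0.2
    deg_alpha: float = 0.05
    deg_adjust: str = "bonferroni"  # bonferroni | bh
    marker_rules_path: str | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.qc_max_mito <= 1:
            raise ValueError("qc_max_mito must be in [0, 1]")
        if self.qc_min_genes < 0:
            raise ValueError("qc_min_genes must be >= 0")
        if self.clonotype_key_level not in ("nt", "aa"):
            raise ValueError("clonotype_key_level must be nt|aa")
        if self.clonotype_min_expanded_size < 1:
            raise ValueError("clonotype_min_expanded_size must be >= 1")
        if self.tracking_scope not in ("expanded", "all"):
            raise ValueError("tracking_scope must be expanded|all")
        if self.persistence_mode not in ("expanded", "any"):
            raise ValueError("persistence_mode must be expanded|any")
        if self.deg_adjust not in ("bonferroni", "bh"):
            raise ValueError("deg_adjust must be bonferroni|bh")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        return cls(**doc)


def validate(manifest: list[SampleManifest]) -> list[str]:
    """Pre-flight checks; returns a list of human-readable issues (empty = ok)."""
    issues: list[str] = []
    if not manifest:
        issues.append("manifest lists no samples")
        return issues
    sids = [m.sample_id for m in manifest]
    for sid in sorted({s for s in sids if sids.count(s) > 1}):
        issues.append(f"duplicate sample id {sid!r}")
    by_participant: dict[tuple[str, str], list[tuple[int, str]]] = {}
    for m in manifest:
        if m.is_arm not in ("tacrolimus", "belatacept", "iscalimab", "none"):
            issues.append(f"sample {m.sample_id}: unknown is_arm {m.is_arm!r}")
        by_participant.setdefault((m.participant_id, m.compartment), []).append(
            (m.post_transplant_day, m.sample_id)
        )
        for name, d in (("vdj", m.vdj_dir), ("gex", m.gex_dir)):
            p = Path(d)
            if not p.is_dir():
                issues.append(f"sample {m.sample_id}: missing {name} directory {d}")
                continue
            expected = (
                ["filtered_contig_annotations.csv"]
                if name == "vdj"
                else ["matrix.mtx", "barcodes.tsv", "features.tsv"]
            )
            for fn in expected:
                if not (p / fn).exists():
                    issues.append(f"sample {m.sample_id}: missing file {p / fn}")
    for (pid, comp), entries in by_participant.items():
        days = [d for d, _ in entries]
        if days != sorted(days) or len(set(days)) != len(days):
            issues.append(
                f"participant {pid}: post_transplant_day not strictly increasing "
                f"within compartment {comp} (manifest order)"
            )
    return issues


def _process_sample(m: SampleManifest, config: RunConfig, rules) -> dict:
    """All per-sample stages; returns a bundle of intermediate results."""
    matrix = read_mtx(m.gex_dir)
    qc_table = qc.compute_qc(
        matrix,
        max_mito=config.qc_max_mito,
        min_genes=config.qc_min_genes,
        blacklist=set(config.qc_blacklist) or None,
    )
    filtered = qc.filter_cells(matrix, qc_table)
    normalized = qc.lognormalize(filtered, scale_factor=config.norm_scale_factor)
    annotations = celltyping.score_and_assign(normalized, rules)
    cd8 = celltyping.select_cd8(
        annotations, filtered, exclusion_threshold=config.cd8_exclusion_threshold
    )
    contigs = clonotype.collapse_variants(read_contigs(Path(m.vdj_dir) / "filtered_contig_annotations.csv"))
    receptors = clonotype.build_receptors(contigs, cd8_barcodes=cd8)
    clonotypes, keyless = clonotype.call_clonotypes(
        receptors,
        key_level=config.clonotype_key_level,
        min_expanded_size=config.clonotype_min_expanded_size,
    )
    summary = clonotype.summarize_sample(clonotypes, keyless, m.sample_id)
    dual = clonotype.dual_alpha_stats(clonotypes, keyless, receptors)
    return {
        "manifest": m,
        "matrix": filtered,
        "normalized": normalized,
        "qc_table": qc_table,
        "annotations": annotations,
        "cd8_barcodes": cd8,
        "receptors": receptors,
        "clonotypes": clonotypes,
        "keyless": keyless,
        "summary": summary,
        "dual_alpha": dual,
        "accounting": {
            "n_barcodes": matrix.n_cells,
            "n_pass_qc": int(qc_table["pass_qc"].sum()),
            "n_fail_qc": int((~qc_table["pass_qc"]).sum()),
            "n_cd8": len(cd8),
            "n_contig_rows": len(contigs),
            "n_receptors": len(receptors),
            "n_malformed_receptors": int(sum(r.malformed for r in receptors)),
            "n_clonotype_units": summary.n_clonotypes_total,
        },
    }


def _deg_expanded_vs_unexpanded(samples: list[dict], config: RunConfig):
    """Cohort-level DEG between expanded-clone member cells and unexpanded cells.

    Per-sample normalized matrices are concatenated with sample-prefixed
    barcodes (normalization is per cell, so concatenation is safe).
    """
    import scipy.sparse as sp

    from .tenx import CountMatrix

    genes = samples[0]["normalized"].genes
    blocks, barcodes, group_exp, group_unexp = [], [], [], []
    for s in samples:
        norm = s["normalized"]
        if norm.genes != genes:
            raise StageError("diffexpr", "feature lists differ between samples")
        sid = s["manifest"].sample_id
        expanded_cells = set()
        unexpanded_cells = set()
        for ct in s["clonotypes"]:
            (expanded_cells if ct.status == "expanded" else unexpanded_cells).update(
                ct.member_barcodes
            )
        unexpanded_cells.update(r.barcode for r in s["keyless"])
        wanted = [bc for bc in norm.barcodes if bc in expanded_cells | unexpanded_cells]
        if not wanted:
            continue
        sub = norm.subset_cells(wanted)
        blocks.append(sub.counts)
        for bc in sub.barcodes:
            tagged = f"{sid}:{bc}"
            barcodes.append(tagged)
            (group_exp if bc in expanded_cells else group_unexp).append(tagged)
    if not blocks or not group_exp or not group_unexp:
        logger.warning("DEG skipped: need both expanded and unexpanded CD8 cells")
        return [], None
    combined = CountMatrix(genes=list(genes), barcodes=barcodes, counts=sp.hstack(blocks))
    records = diffexpr.find_markers(
        combined,
        group_exp,
        group_unexp,
        logfc_threshold=config.deg_logfc_threshold,
        min_pct=config.deg_min_pct,
        alpha=config.deg_alpha,
        adjust=config.deg_adjust,
    )
    return records, (combined, group_exp, group_unexp)


def run(
    manifest: list[SampleManifest] | str | Path,
    config: RunConfig | None = None,
    outdir: str | Path = "clonotrack_out",
    force: bool = False,
) -> Path:
    """Execute the full pipeline and write result tables under ``outdir``.

    Validation issues block the run unless ``force``.  On a stage failure
    the partially written output directory is removed and a
    :class:`StageError` is raised.
    """
    config = config or RunConfig()
    if not isinstance(manifest, list):
        manifest = read_manifest(manifest)
    issues = validate(manifest)
    if issues and not force:
        raise StageError("validate", "; ".join(issues))
    outdir = Path(outdir)
    created = not outdir.exists()
    outdir.mkdir(parents=True, exist_ok=True)
    try:
        rules = (
            celltyping.load_rules(config.marker_rules_path)
            if config.marker_rules_path
            else celltyping.default_rules()
        )
        samples = []
        for m in manifest:
            try:
                samples.append(_process_sample(m, config, rules))
            except StageError:
                raise
            except Exception as exc:
                raise StageError(f"sample:{m.sample_id}", str(exc)) from exc

        # --- per-sample summary / dual-alpha tables
        write_tsv(
            pd.DataFrame(
                [
                    {
                        "sample_id": s["summary"].sample_id,
                        "participant_id": s["manifest"].participant_id,
                        "compartment": s["manifest"].compartment,
                        "post_transplant_day": s["manifest"].post_transplant_day,
                        "is_arm": s["manifest"].is_arm,
                        "n_cd8_cells_with_receptor": s["summary"].n_cd8_cells_with_receptor,
                        "n_clonotypes_total": s["summary"].n_clonotypes_total,
                        "n_expanded": s["summary"].n_expanded,
                        "n_unexpanded": s["summary"].n_unexpanded,
                        "pct_expanded": s["summary"].pct_expanded,
                        "expanded_sizes": ",".join(map(str, s["summary"].expanded_sizes)),
                    }
                    for s in samples
                ]
            ),
            outdir / "clonal_summary.tsv",
        )
        write_tsv(
            pd.DataFrame(
                [{"sample_id": s["summary"].sample_id, **s["dual_alpha"]} for s in samples]
            ),
            outdir / "dual_alpha.tsv",
        )

        # --- clonotype tables (key serialized)
        clono_rows = []
        for s in samples:
            sid = s["manifest"].sample_id
            for ct in s["clonotypes"]:
                clono_rows.append(
                    {"sample_id": sid, "key": ct.key.serialize(), "size": ct.size,
                     "status": ct.status}
                )
            for r in s["keyless"]:
                reason = "dual_beta" if r.n_beta == 2 else "single_chain"
                clono_rows.append(
                    {"sample_id": sid, "key": f"keyless:{reason}:{r.barcode}", "size": 1,
                     "status": "unexpanded"}
                )
        write_tsv(
            pd.DataFrame(clono_rows, columns=["sample_id", "key", "size", "status"]),
            outdir / "clonotypes.tsv",
        )

        # --- tracking / persistence / overlap
        clonotypes_by_sample = {s["manifest"].sample_id: s["clonotypes"] for s in samples}
        tracks = tracking.build_tracks(clonotypes_by_sample, manifest, scope=config.tracking_scope)
        track_rows = []
        meta = {m.sample_id: m for m in manifest}
        for t in tracks:
            for sid, size in t.size_by_sample.items():
                track_rows.append(
                    {
                        "participant_id": t.participant_id,
                        "key": t.key.serialize(),
                        "sample_id": sid,
                        "post_transplant_day": meta[sid].post_transplant_day,
                        "compartment": meta[sid].compartment,
                        "size": size,
                        "status": t.status_by_sample[sid],
                        "first_expanded_sample": t.first_expanded_sample or "",
                    }
                )
        write_tsv(
            pd.DataFrame(track_rows, columns=[
                "participant_id", "key", "sample_id", "post_transplant_day",
                "compartment", "size", "status", "first_expanded_sample",
            ]),
            outdir / "clone_tracks.tsv",
        )

        persistence_rows = []
        for m in manifest:
            if m.compartment != "biopsy":
                continue
            n_total, n_prior, pct = tracking.persistence_counts(
                tracks, m.sample_id, manifest, mode=config.persistence_mode
            )
            persistence_rows.append(
                {
                    "sample_id": m.sample_id,
                    "participant_id": m.participant_id,
                    "post_transplant_day": m.post_transplant_day,
                    "n_expanded": n_total,
                    "n_prior_seen": n_prior,
                    "pct_prior_seen": pct,
                }
            )
        write_tsv(
            pd.DataFrame(persistence_rows, columns=[
                "sample_id", "participant_id", "post_transplant_day",
                "n_expanded", "n_prior_seen", "pct_prior_seen",
            ]),
            outdir / "persistence.tsv",
        )

        expanded_keys = {
            s["manifest"].sample_id: {
                ct.key for ct in s["clonotypes"] if ct.status == "expanded"
            }
            for s in samples
        }
        overlap_rows = []
        for a in manifest:
            for b in manifest:
                if (
                    a.compartment == "biopsy"
                    and b.compartment == "urine"
                    and a.participant_id == b.participant_id
                    and a.post_transplant_day == b.post_transplant_day
                ):
                    ov = tracking.overlap(
                        a.sample_id, expanded_keys[a.sample_id],
                        b.sample_id, expanded_keys[b.sample_id],
                    )
                    overlap_rows.append(
                        {
                            "sample_biopsy": ov.sample_a,
                            "sample_urine": ov.sample_b,
                            "participant_id": a.participant_id,
                            "post_transplant_day": a.post_transplant_day,
                            "n_shared_expanded": ov.n_shared_expanded,
                            "n_biopsy_only": ov.n_a_only,
                            "n_urine_only": ov.n_b_only,
                            "shared_keys": ";;".join(k.serialize() for k in ov.shared_keys),
                        }
                    )
        write_tsv(
            pd.DataFrame(overlap_rows, columns=[
                "sample_biopsy", "sample_urine", "participant_id", "post_transplant_day",
                "n_shared_expanded", "n_biopsy_only", "n_urine_only", "shared_keys",
            ]),
            outdir / "biopsy_urine_overlap.tsv",
        )

        # --- DEG expanded vs unexpanded + mTOR panel averages by arm
        try:
            deg_records, deg_ctx = _deg_expanded_vs_unexpanded(samples, config)
        except StageError:
            raise
        except Exception as exc:
            raise StageError("diffexpr", str(exc)) from exc
        write_tsv(
            pd.DataFrame([asdict(r) for r in deg_records],
                         columns=["gene", "log_fc", "pct_1", "pct_2", "p_value",
                                  "p_adjusted", "significant"]),
            outdir / "deg_expanded_vs_unexpanded.tsv",
        )
        if deg_ctx is not None:
            combined, group_exp, _ = deg_ctx
            arm_of = {
                f"{s['manifest'].sample_id}:{bc}": s["manifest"].is_arm
                for s in samples
                for bc in s["normalized"].barcodes
            }
            exp_set = set(group_exp)
            exp_matrix = combined.subset_cells([bc for bc in combined.barcodes if bc in exp_set])
            panel = qc.panel_average(
                exp_matrix, {bc: arm_of[bc] for bc in exp_matrix.barcodes}, MTOR_PANEL
            )
            panel.reset_index().to_csv(outdir / "panel_mtor_by_arm.tsv", sep="\t", index=False)

        report = {
            "tool": "clonotrack",
            "seed": config.seed,
            "config": asdict(config),
            "n_samples": len(samples),
            "accounting": {s["manifest"].sample_id: s["accounting"] for s in samples},
            "decided_defaults": {
                "clonotype_key_level": config.clonotype_key_level,
                "clonotype_min_expanded_size": config.clonotype_min_expanded_size,
                "cd8_exclusion_genes": list(celltyping.CD8_EXCLUSION_GENES),
                "cd8_exclusion_threshold": config.cd8_exclusion_threshold,
                "deg_adjust": config.deg_adjust,
                "persistence_mode": config.persistence_mode,
            },
        }
        write_run_report(report, outdir / "run_report.json")
    except Exception:
        if created:
            shutil.rmtree(outdir, ignore_errors=True)
        raise
    return outdir
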