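"""Synthetic multi-sample, multi-compartment scRNA/scTCR cohort generator.

Emulates the per-sample outputs of a 10x 5' gene-expression + V(D)J run —
``filtered_contig_annotations.csv``, ``clonotypes.csv`` and a MatrixMarket
gene×cell count matrix with sidecars — for a longitudinal cohort of
kidney-transplant participants with serial biopsies and paired urine
samples, with fully known ("planted") clonal truth.

The generator plants:

* clonotypes with exact per-sample cell counts (so the expansion rule
  ``size > 2`` has an unambiguous ground truth),
* dual TCR-α cells (a biologically normal ~5–10% of T cells carry two
  productive α chains),
* chain dropout (a cell recovered with only one chain),
* dual-β "doublet" barcodes,
* per-cell QC violations (high mitochondrial fraction, low gene count),
* cross-sample and cross-compartment clone sharing (urine clones are the
  tissue clones that shed across the tubular basement membrane, plus
  urine-private clones).

Expression counts are negative binomial with lineage- and phenotype-program
specific means.  Lineage-defining marker genes additionally receive a small
deterministic count floor so that marker gating is exactly separable when
the noise knobs are set to zero; the exclusion markers of other lineages
(e.g. CD4/TRDC/CD68 for a CD8 T cell) have mean zero and are therefore
never expressed.  Fixing the seed makes every emitted file byte-identical
across runs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import sparse

from .clonotype import serialize_key
from .tenx import (
    ContigRecord,
    CountMatrix,
    SampleManifest,
    write_contigs,
    write_manifest,
    write_mtx,
)

__all__ = [
    "CloneSpec",
    "ParticipantSpec",
    "CohortConfig",
    "ClonalTruth",
    "generate_cohort",
    "emit_contigs",
    "emit_expression",
    "random_cdr3",
    "translate_cdr3",
    "default_gene_panel",
    "zero_noise_kwargs",
    "example_cohort_config",
    "clonal_mix_config",
    "longitudinal_persistence_config",
    "overlap_config",
]

# ---------------------------------------------------------------------------
# genetic code (standard table, bases ordered TCAG); CDR3s are drawn from
# sense codons only so translated junctions are stop-free
_BASES = "TCAG"
_AA_TABLE = "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
GENETIC_CODE = {
    b1 + b2 + b3: _AA_TABLE[16 * i + 4 * j + k]
    for i, b1 in enumerate(_BASES)
    for j, b2 in enumerate(_BASES)
    for k, b3 in enumerate(_BASES)
}
SENSE_CODONS = sorted(c for c, aa in GENETIC_CODE.items() if aa != "*")


def translate_cdr3(nt: str) -> str:
    """Translate a CDR3 nucleotide string (length must be a multiple of 3)."""
    if len(nt) % 3 != 0:
        raise ValueError(f"CDR3 length {len(nt)} is not a multiple of 3")
    return "".join(GENETIC_CODE[nt[i : i + 3]] for i in range(0, len(nt), 3))


def random_cdr3(rng: np.random.Generator, min_codons: int = 12, max_codons: int = 18) -> str:
    """Uniform stop-free CDR3 nucleotide string, 36–54 nt by default."""
    n = int(rng.integers(min_codons, max_codons + 1))
    idx = rng.integers(0, len(SENSE_CODONS), size=n)
    return "".join(SENSE_CODONS[i] for i in idx)


# ---------------------------------------------------------------------------
# gene panel

MITO_GENES = [
    "MT-ND1", "MT-ND2", "MT-ND3", "MT-ND4", "MT-ND4L", "MT-ND5", "MT-ND6",
    "MT-CO1", "MT-CO2", "MT-CO3", "MT-CYB", "MT-ATP6", "MT-ATP8",
    "MT-RNR1", "MT-RNR2", "MT-TF", "MT-TL1", "MT-TV", "MT-TP", "MT-TM",
]

MARKER_GENES = [
    "PTPRC", "CD3E", "CD3D", "CD8A", "CD8B", "CD4", "TRDC", "CD68", "CD19",
    "MS4A1", "CD14", "LYZ", "ITGAX", "NKG7", "KLRK1", "MKI67", "GZMB",
    "GZMK", "IFNG", "PRF1", "GNLY", "PDCD1", "HAVCR2", "LAG3", "TIGIT",
    "TOX", "ZNF683", "CD69", "ITGAE", "CXCR6", "S1PR1", "SELL", "MTOR",
    "RPTOR", "RICTOR", "TSC1", "TSC2", "FKBP1A", "CD27", "TNFRSF9", "CD70",
    "EPCAM", "KRT18", "UMOD",
]

# lineage → {gene: (nb_mean, deterministic_floor)}
# exclusion markers of foreign lineages are simply absent (mean 0, floor 0):
# a CD8 T cell never draws a CD4, TRDC, CD68, CD19 or CD14 count.
_T_COMMON = {"PTPRC": (2.0, 2), "CD3E": (2.5, 2), "CD3D": (1.5, 1),
             "NKG7": (1.0, 0), "KLRK1": (1.0, 0), "SELL": (0.8, 0),
             "MTOR": (1.0, 0), "RPTOR": (0.8, 0), "RICTOR": (0.8, 0),
             "TSC1": (1.0, 0), "TSC2": (1.0, 0), "FKBP1A": (1.0, 0)}
LINEAGE_MEANS: dict[str, dict[str, tuple[float, int]]] = {
    "CD8": {**_T_COMMON, "CD8A": (3.0, 3), "CD8B": (1.5, 1)},
    "CD4": {**_T_COMMON, "CD4": (3.0, 3), "CD27": (1.0, 0)},
    "gdT": {**_T_COMMON, "TRDC": (3.0, 3)},
    "B": {"PTPRC": (2.0, 2), "CD19": (2.5, 3), "MS4A1": (3.0, 2)},
    "myeloid": {"PTPRC": (2.0, 2), "CD68": (3.0, 3), "CD14": (2.5, 2),
                "LYZ": (4.0, 2), "ITGAX": (2.0, 1), "CD4": (1.0, 0)},
    "nonimmune": {"EPCAM": (3.0, 3), "KRT18": (3.0, 2), "UMOD": (1.5, 0)},
}

# phenotype programs: additive NB-mean shifts applied to member cells
PROGRAMS: dict[str, dict[str, float]] = {
    "background": {},
    "activated": {"GZMB": 6.0, "IFNG": 4.0, "PRF1": 3.0, "GNLY": 2.5, "MKI67": 1.0},
    "exhausted": {"PDCD1": 4.0, "HAVCR2": 3.0, "LAG3": 3.0, "TIGIT": 2.5, "TOX": 2.0},
    "resident_memory": {"ZNF683": 5.0, "CD69": 4.0, "ITGAE": 3.0, "CXCR6": 3.0},
    "proliferating": {"MKI67": 6.0, "GZMB": 2.0},
}

# immunosuppression-arm shifts applied to expanded-clone member cells,
# emulating the mTOR-axis contrast between treatment groups
ARM_SHIFTS: dict[str, dict[str, float]] = {
    "belatacept": {"MTOR": 2.0, "RPTOR": 2.5, "RICTOR": 2.5, "TSC1": -0.7,
                   "TSC2": -0.7, "GZMB": 1.5, "GNLY": 1.5},
    "iscalimab": {"FKBP1A": 2.5, "CD27": 2.0, "TNFRSF9": 2.0, "CD70": 1.5},
    "tacrolimus": {"FKBP1A": -0.5},
    "none": {},
}

T_LINEAGES = ("CD8", "CD4", "gdT")
DEFAULT_BACKGROUND_WEIGHTS = {
    "CD8": 0.35, "CD4": 0.20, "gdT": 0.05, "B": 0.10,
    "myeloid": 0.15, "nonimmune": 0.15,
}


def default_gene_panel(n_filler: int = 440) -> list[str]:
    """Marker genes + mitochondrial genes + numbered filler genes."""
    filler = [f"GENE{i:04d}" for i in range(1, n_filler + 1)]
    return MARKER_GENES + MITO_GENES + filler


# ---------------------------------------------------------------------------
# configuration types


@dataclass
class CloneSpec:
    """One planted T-cell clone with its receptor and per-sample cell counts."""

    clone_id: str
    alpha_cdr3_nt: list[str]
    beta_cdr3_nt: str
    size_by_sample: dict[str, int]
    phenotype_program: str = "background"
    lineage: str = "CD8"

    def __post_init__(self) -> None:
        if not 1 <= len(self.alpha_cdr3_nt) <= 2:
            raise ValueError(f"clone {self.clone_id}: need 1 or 2 alpha CDR3s")
        for s in list(self.alpha_cdr3_nt) + [self.beta_cdr3_nt]:
            if not s or len(s) % 3 != 0 or set(s) - set("ACGT"):
                raise ValueError(
                    f"clone {self.clone_id}: CDR3 {s!r} must be nonempty, "
                    "length a multiple of 3, alphabet ACGT"
                )
        if any(v < 0 for v in self.size_by_sample.values()):
            raise ValueError(f"clone {self.clone_id}: sizes must be >= 0")
        if self.phenotype_program not in PROGRAMS:
            raise ValueError(f"clone {self.clone_id}: unknown program {self.phenotype_program!r}")
        if self.lineage not in T_LINEAGES:
            raise ValueError(f"clone {self.clone_id}: lineage must be one of {T_LINEAGES}")

    @property
    def key(self) -> str:
        return serialize_key(tuple(sorted(self.alpha_cdr3_nt)), self.beta_cdr3_nt)


@dataclass
class ParticipantSpec:
    """One participant: immunosuppression arm, ordered samples, planted clones."""

    participant_id: str
    is_arm: str
    samples: list[tuple[str, str, int]]  # (sample_id, compartment, post_transplant_day)
    clones: list[CloneSpec]

    def __post_init__(self) -> None:
        if self.is_arm not in ARM_SHIFTS:
            raise ValueError(f"unknown is_arm {self.is_arm!r}")
        sids = [s[0] for s in self.samples]
        if len(set(sids)) != len(sids):
            raise ValueError(f"participant {self.participant_id}: duplicate sample_ids")
        by_comp: dict[str, list[int]] = {}
        for sid, comp, day in self.samples:
            if comp not in ("biopsy", "urine"):
                raise ValueError(f"sample {sid}: compartment must be biopsy|urine")
            by_comp.setdefault(comp, []).append(day)
        for comp, days in by_comp.items():
            if any(b <= a for a, b in zip(days, days[1:])):
                raise ValueError(
                    f"participant {self.participant_id}: post_transplant_day must be "
                    f"strictly increasing within compartment {comp}"
                )
        keys = [c.key for c in self.clones]
        if len(set(keys)) != len(keys):
            raise ValueError(f"participant {self.participant_id}: clone keys not unique")
        for c in self.clones:
            unknown = set(c.size_by_sample) - set(sids)
            if unknown:
                raise ValueError(f"clone {c.clone_id}: unknown sample ids {sorted(unknown)}")


@dataclass
class CohortConfig:
    """Full cohort recipe; probabilities are per-cell Bernoulli rates."""

    participants: list[ParticipantSpec]
    seed: int = 0
    chain_recovery_rate: float = 0.90
    dual_alpha_rate: float = 0.08
    doublet_rate: float = 0.01
    mito_outlier_rate: float = 0.03
    low_gene_rate: float = 0.03
    corrupt_contig_rate: float = 0.0
    cells_per_sample: int = 3000
    background_lineage_weights: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BACKGROUND_WEIGHTS)
    )
    n_filler_genes: int = 440
    filler_mean: float = 1.3
    mito_mean: float = 1.5
    nb_dispersion: float = 2.0

    def __post_init__(self) -> None:
        for name in ("chain_recovery_rate", "dual_alpha_rate", "doublet_rate",
                     "mito_outlier_rate", "low_gene_rate", "corrupt_contig_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.cells_per_sample < 1:
            raise ValueError("cells_per_sample must be >= 1")
        if not self.participants:
            raise ValueError("participants must be nonempty")
        bad = set(self.background_lineage_weights) - set(LINEAGE_MEANS)
        if bad:
            raise ValueError(f"unknown background lineages {sorted(bad)}")
        total = sum(self.background_lineage_weights.values())
        if total <= 0:
            raise ValueError("background_lineage_weights must sum to > 0")


def zero_noise_kwargs() -> dict:
    """Config overrides that switch off every stochastic corruption channel."""
    return dict(
        chain_recovery_rate=1.0,
        dual_alpha_rate=0.0,
        doublet_rate=0.0,
        mito_outlier_rate=0.0,
        low_gene_rate=0.0,
        corrupt_contig_rate=0.0,
    )


# ---------------------------------------------------------------------------
# truth registry


@dataclass
class ClonalTruth:
    """Planted ground truth for one generated cohort.

    ``samples`` maps sample_id → serialized clonotype key → record with the
    planted size, expansion flag (size > 2), clone id, lineage and program.
    ``barcode_map`` maps sample_id → barcode → clone assignment (clone_id
    ``None`` for background receptor-bearing cells) and lineage.
    ``sample_meta`` carries (participant, compartment, day) per sample.
    """

    samples: dict[str, dict[str, dict]] = field(default_factory=dict)
    barcode_map: dict[str, dict[str, dict]] = field(default_factory=dict)
    sample_meta: dict[str, dict] = field(default_factory=dict)

    def expanded_keys(self, sample_id: str, lineage: str | None = "CD8") -> set[str]:
        return {
            k
            for k, rec in self.samples.get(sample_id, {}).items()
            if rec["expanded"] and (lineage is None or rec["lineage"] == lineage)
        }

    def shared_keys(self, sample_a: str, sample_b: str) -> set[str]:
        return set(self.samples.get(sample_a, {})) & set(self.samples.get(sample_b, {}))

    def cross_sample_registry(self) -> dict[str, dict[str, list[str]]]:
        """participant → key → sample_ids where the key was planted."""
        reg: dict[str, dict[str, list[str]]] = {}
        for sid, keys in self.samples.items():
            pid = self.sample_meta[sid]["participant_id"]
            for k in keys:
                reg.setdefault(pid, {}).setdefault(k, []).append(sid)
        return reg

    def compartment_registry(self, participant_id: str) -> dict[str, set[str]]:
        """compartment → set of keys planted in that compartment for one participant."""
        out: dict[str, set[str]] = {"biopsy": set(), "urine": set()}
        for sid, keys in self.samples.items():
            meta = self.sample_meta[sid]
            if meta["participant_id"] == participant_id:
                out[meta["compartment"]].update(keys)
        return out

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {"samples": self.samples, "barcode_map": self.barcode_map,
                 "sample_meta": self.sample_meta},
                fh, indent=1, sort_keys=True,
            )
            fh.write("\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "ClonalTruth":
        with open(path) as fh:
            doc = json.load(fh)
        return cls(samples=doc["samples"], barcode_map=doc["barcode_map"],
                   sample_meta=doc["sample_meta"])


# ---------------------------------------------------------------------------
# per-sample emission


@dataclass
class _CellPlan:
    barcode: str
    lineage: str
    program: str
    clone: CloneSpec | None  # None = background
    arm: str


def _make_barcodes(rng: np.random.Generator, n: int) -> list[str]:
    seen: set[str] = set()
    out: list[str] = []
    while len(out) < n:
        arr = rng.integers(0, 4, size=(n - len(out), 16))
        for row in arr:
            bc = "".join("ACGT"[b] for b in row) + "-1"
            if bc not in seen:
                seen.add(bc)
                out.append(bc)
    return out


def _plan_sample(
    participant: ParticipantSpec,
    sample_id: str,
    config: CohortConfig,
    rng: np.random.Generator,
) -> list[_CellPlan]:
    plans: list[_CellPlan] = []
    for clone in participant.clones:
        n = clone.size_by_sample.get(sample_id, 0)
        for _ in range(n):
            plans.append(_CellPlan("", clone.lineage, clone.phenotype_program,
                                   clone, participant.is_arm))
    if len(plans) > config.cells_per_sample:
        raise ValueError(
            f"sample {sample_id}: planted clone cells ({len(plans)}) exceed "
            f"cells_per_sample ({config.cells_per_sample})"
        )
    lineages = sorted(config.background_lineage_weights)
    w = np.array([config.background_lineage_weights[l] for l in lineages], float)
    w /= w.sum()
    n_bg = config.cells_per_sample - len(plans)
    for l in rng.choice(lineages, size=n_bg, p=w):
        plans.append(_CellPlan("", str(l), "background", None, participant.is_arm))
    barcodes = _make_barcodes(rng, len(plans))
    for p, bc in zip(plans, barcodes):
        p.barcode = bc
    return plans


def emit_contigs(
    plans: Sequence[_CellPlan],
    config: CohortConfig,
    rng: np.random.Generator,
    used_betas: set[str] | None = None,
) -> tuple[list[ContigRecord], dict[str, dict]]:
    """Emit V(D)J contigs for every T-lineage cell of one sample.

    Returns the contig records plus a per-barcode receptor registry
    (intended chains before dropout, for truth bookkeeping).  Dropout keeps
    only one chain locus; dual-β doublets borrow a β from another cell.
    """
    if not plans:
        raise ValueError("emit_contigs: empty cell plan")
    used_betas = used_betas if used_betas is not None else set()
    for p in plans:
        if p.clone is not None:
            used_betas.add(p.clone.beta_cdr3_nt)

    receptors: dict[str, dict] = {}
    ab_cells = [p for p in plans if p.lineage in ("CD8", "CD4")]
    gd_cells = [p for p in plans if p.lineage == "gdT"]

    def fresh_beta() -> str:
        while True:
            b = random_cdr3(rng)
            if b not in used_betas:
                used_betas.add(b)
                return b

    for p in ab_cells:
        if p.clone is not None:
            alphas = list(p.clone.alpha_cdr3_nt)
            betas = [p.clone.beta_cdr3_nt]
        else:
            n_alpha = 2 if rng.random() < config.dual_alpha_rate else 1
            alphas = [random_cdr3(rng) for _ in range(n_alpha)]
            betas = [fresh_beta()]
        receptors[p.barcode] = {"alphas": alphas, "betas": list(betas)}

    all_betas = [r["betas"][0] for r in receptors.values()]
    records: list[ContigRecord] = []
    for p in ab_cells:
        rec = receptors[p.barcode]
        alphas, betas = list(rec["alphas"]), list(rec["betas"])
        if rng.random() < config.doublet_rate and all_betas:
            extra = all_betas[int(rng.integers(0, len(all_betas)))]
            if extra not in betas:
                betas.append(extra)
        if rng.random() >= config.chain_recovery_rate:
            # chain dropout: the cell is recovered with one locus only
            if rng.random() < 0.5:
                betas = []
            else:
                alphas = []
        k = 0
        for chain, cdr3s in (("TRA", alphas), ("TRB", betas)):
            for nt in cdr3s:
                k += 1
                v_locus = "TRAV" if chain == "TRA" else "TRBV"
                j_locus = "TRAJ" if chain == "TRA" else "TRBJ"
                corrupt = rng.random() < config.corrupt_contig_rate
                records.append(
                    ContigRecord(
                        barcode=p.barcode,
                        chain=chain,
                        v_gene=f"{v_locus}{rng.integers(1, 40)}-{rng.integers(1, 4)}*0{rng.integers(1, 3)}",
                        d_gene=f"TRBD{rng.integers(1, 3)}*01" if chain == "TRB" else "",
                        j_gene=f"{j_locus}{rng.integers(1, 50)}*0{rng.integers(1, 3)}",
                        cdr3_aa=translate_cdr3(nt),
                        cdr3_nt=nt,
                        productive=not corrupt,
                        full_length=True,
                        high_confidence=True,
                        umis=int(rng.integers(2, 30)),
                        contig_id=f"{p.barcode}_contig_{k}",
                    )
                )
    for p in gd_cells:
        for k, (chain, vg, jg) in enumerate(
            (("TRG", "TRGV", "TRGJ"), ("TRD", "TRDV", "TRDJ")), start=1
        ):
            nt = random_cdr3(rng)
            records.append(
                ContigRecord(
                    barcode=p.barcode, chain=chain,
                    v_gene=f"{vg}{rng.integers(1, 10)}*01",
                    j_gene=f"{jg}{rng.integers(1, 4)}*01",
                    cdr3_aa=translate_cdr3(nt), cdr3_nt=nt,
                    umis=int(rng.integers(2, 30)),
                    contig_id=f"{p.barcode}_contig_{k}",
                )
            )
        receptors[p.barcode] = {"alphas": [], "betas": []}
    return records, receptors


def emit_expression(
    plans: Sequence[_CellPlan],
    config: CohortConfig,
    rng: np.random.Generator,
) -> tuple[CountMatrix, dict[str, list[str]]]:
    """Draw the gene×cell count matrix for one sample.

    Returns the matrix and the QC-outlier assignment
    ``{"mito_outlier": [...barcodes], "low_gene": [...]}``.
    """
    genes = default_gene_panel(config.n_filler_genes)
    gene_idx = {g: i for i, g in enumerate(genes)}
    n_cells, n_genes = len(plans), len(genes)

    mu = np.zeros((n_cells, n_genes))
    floors = np.zeros((n_cells, n_genes), dtype=np.int64)
    filler_cols = np.array([gene_idx[g] for g in genes if g.startswith("GENE")])
    mito_cols = np.array([gene_idx[g] for g in MITO_GENES])
    mu[:, filler_cols] = config.filler_mean
    mu[:, mito_cols] = config.mito_mean

    for i, p in enumerate(plans):
        for g, (m, f) in LINEAGE_MEANS[p.lineage].items():
            mu[i, gene_idx[g]] += m
            floors[i, gene_idx[g]] = f
        for g, m in PROGRAMS[p.program].items():
            mu[i, gene_idx[g]] += m
        if p.clone is not None:
            for g, m in ARM_SHIFTS[p.arm].items():
                mu[i, gene_idx[g]] = max(0.0, mu[i, gene_idx[g]] + m)

    is_mito_out = rng.random(n_cells) < config.mito_outlier_rate
    is_low_gene = rng.random(n_cells) < config.low_gene_rate
    mu[np.ix_(is_low_gene, filler_cols)] *= 0.15
    mu[np.ix_(is_mito_out, mito_cols)] *= 12.0
    floors[is_low_gene, :] = 0  # low-gene cells keep no deterministic markers

    r = config.nb_dispersion
    with np.errstate(divide="ignore", invalid="ignore"):
        pvals = r / (r + mu)
    counts = np.where(mu > 0, rng.negative_binomial(r, np.clip(pvals, 1e-12, 1.0)), 0)
    counts = counts + floors

    matrix = CountMatrix(
        genes=genes,
        barcodes=[p.barcode for p in plans],
        counts=sparse.csr_matrix(counts.T),
    )
    outliers = {
        "mito_outlier": [plans[i].barcode for i in np.flatnonzero(is_mito_out)],
        "low_gene": [plans[i].barcode for i in np.flatnonzero(is_low_gene)],
    }
    return matrix, outliers


def _write_clonotypes_csv(receptors: dict[str, dict], path: Path) -> None:
    """Per-sample advisory clonotype table, grouped on intended chain sets."""
    groups: dict[str, list[str]] = {}
    for bc, rec in receptors.items():
        if not rec["betas"] and not rec["alphas"]:
            continue
        key = ";".join(
            [f"TRA:{a}" for a in sorted(rec["alphas"])]
            + [f"TRB:{b}" for b in sorted(rec["betas"])]
        )
        groups.setdefault(key, []).append(bc)
    ordered = sorted(groups.items(), key=lambda kv: (-len(kv[1]), kv[0]))
    lines = ["clonotype_id,frequency,cdr3s_aa,cdr3s_nt\n"]
    ids: dict[str, str] = {}
    for i, (key, members) in enumerate(ordered, start=1):
        cid = f"clonotype{i}"
        ids[key] = cid
        aa = ";".join(
            part.split(":")[0] + ":" + translate_cdr3(part.split(":")[1])
            for part in key.split(";")
        )
        lines.append(f"{cid},{len(members)},{aa},{key}\n")
    path.write_text("".join(lines))


def generate_cohort(config: CohortConfig, outdir: str | Path) -> ClonalTruth:
    """Write a full synthetic cohort under ``outdir`` and return its truth.

    Per sample: ``<outdir>/<sample_id>/`` with contig CSV, clonotypes CSV and
    the MTX triplet + sidecars; plus ``manifest.yaml`` and ``truth.json`` at
    the cohort root.  Regenerating with the same config is byte-identical.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    truth = ClonalTruth()
    manifest: list[SampleManifest] = []

    for pi, participant in enumerate(config.participants):
        for si, (sample_id, compartment, day) in enumerate(participant.samples):
            rng = np.random.default_rng([config.seed, pi, si])
            plans = _plan_sample(participant, sample_id, config, rng)
            contigs, receptors = emit_contigs(plans, config, rng)
            matrix, outliers = emit_expression(plans, config, rng)

            sdir = outdir / sample_id
            sdir.mkdir(exist_ok=True)
            write_contigs(contigs, sdir / "filtered_contig_annotations.csv")
            _write_clonotypes_csv(receptors, sdir / "clonotypes.csv")
            write_mtx(matrix, sdir)

            truth.sample_meta[sample_id] = {
                "participant_id": participant.participant_id,
                "compartment": compartment,
                "post_transplant_day": day,
                "is_arm": participant.is_arm,
            }
            sample_truth: dict[str, dict] = {}
            for clone in participant.clones:
                n = clone.size_by_sample.get(sample_id, 0)
                if n > 0:
                    sample_truth[clone.key] = {
                        "size": n,
                        "expanded": n > 2,
                        "clone_id": clone.clone_id,
                        "lineage": clone.lineage,
                        "program": clone.phenotype_program,
                    }
            truth.samples[sample_id] = sample_truth
            truth.barcode_map[sample_id] = {
                p.barcode: {
                    "clone_id": p.clone.clone_id if p.clone else None,
                    "lineage": p.lineage,
                    "mito_outlier": p.barcode in set(outliers["mito_outlier"]),
                    "low_gene": p.barcode in set(outliers["low_gene"]),
                }
                for p in plans
            }
            manifest.append(
                SampleManifest(
                    sample_id=sample_id,
                    participant_id=participant.participant_id,
                    compartment=compartment,
                    post_transplant_day=day,
                    is_arm=participant.is_arm,
                    vdj_dir=str(sdir),
                    gex_dir=str(sdir),
                )
            )

    write_manifest(manifest, outdir / "manifest.yaml")
    truth.to_json(outdir / "truth.json")
    return truth


# ---------------------------------------------------------------------------
# cohort recipe builders


def _clone(rng: np.random.Generator, clone_id: str, sizes: dict[str, int],
           program: str = "background", dual_alpha: bool = False,
           lineage: str = "CD8") -> CloneSpec:
    n_alpha = 2 if dual_alpha else 1
    return CloneSpec(
        clone_id=clone_id,
        alpha_cdr3_nt=[random_cdr3(rng) for _ in range(n_alpha)],
        beta_cdr3_nt=random_cdr3(rng),
        size_by_sample=sizes,
        phenotype_program=program,
        lineage=lineage,
    )


def clonal_mix_config(
    n_expanded: int,
    n_total_units: int,
    seed: int = 0,
    expanded_sizes: Sequence[int] | None = None,
    **overrides,
) -> CohortConfig:
    """One-sample cohort with an exact clonal composition.

    Plants ``n_expanded`` clones of size ≥ 3 and enough singleton background
    CD8 cells that the sample yields exactly ``n_total_units`` clonotype
    units, so the expanded fraction is ``100 · n_expanded / n_total_units``.
    Noise channels are off so the composition survives the pipeline intact.
    """
    if expanded_sizes is None:
        rng = np.random.default_rng(seed + 1)
        expanded_sizes = [int(3 + rng.integers(0, 6)) for _ in range(n_expanded)]
    if len(expanded_sizes) != n_expanded or any(s < 3 for s in expanded_sizes):
        raise ValueError("expanded_sizes must give n_expanded sizes, all >= 3")
    n_singletons = n_total_units - n_expanded
    if n_singletons < 0:
        raise ValueError("n_total_units must be >= n_expanded")
    rng = np.random.default_rng(seed)
    sid = "S1"
    clones = [
        _clone(rng, f"EXP{i:03d}", {sid: s}, program="activated")
        for i, s in enumerate(expanded_sizes)
    ]
    n_cells = sum(expanded_sizes) + n_singletons
    participant = ParticipantSpec(
        participant_id="P1", is_arm="tacrolimus",
        samples=[(sid, "biopsy", 217)], clones=clones,
    )
    kwargs = dict(
        participants=[participant],
        seed=seed,
        cells_per_sample=n_cells,
        background_lineage_weights={"CD8": 1.0},
        **zero_noise_kwargs(),
    )
    kwargs.update(overrides)
    return CohortConfig(**kwargs)


def longitudinal_persistence_config(
    n_expanded_final: int = 18,
    n_prior_seen: int = 13,
    seed: int = 0,
    days: Sequence[int] = (60, 137, 179),
    **overrides,
) -> CohortConfig:
    """Serial-biopsy cohort where the last biopsy has a known prior-seen count.

    ``n_prior_seen`` of the ``n_expanded_final`` clones expanded at the last
    time point were already expanded in an earlier biopsy.
    """
    if n_prior_seen > n_expanded_final:
        raise ValueError("n_prior_seen must be <= n_expanded_final")
    rng = np.random.default_rng(seed)
    sids = [f"BX{i+1}" for i in range(len(days))]
    clones = []
    for i in range(n_expanded_final):
        sizes = {sids[-1]: int(3 + rng.integers(0, 5))}
        if i < n_prior_seen:
            earlier = sids[int(rng.integers(0, len(sids) - 1))]
            sizes[earlier] = int(3 + rng.integers(0, 5))
        clones.append(_clone(rng, f"CL{i:03d}", sizes, program="exhausted"))
    participant = ParticipantSpec(
        participant_id="P1", is_arm="iscalimab",
        samples=[(sid, "biopsy", d) for sid, d in zip(sids, days)],
        clones=clones,
    )
    kwargs = dict(
        participants=[participant], seed=seed, cells_per_sample=300,
        background_lineage_weights={"CD8": 1.0}, **zero_noise_kwargs(),
    )
    kwargs.update(overrides)
    return CohortConfig(**kwargs)


def overlap_config(
    n_biopsy: int = 7,
    n_urine: int = 11,
    n_shared: int = 4,
    seed: int = 0,
    day: int = 137,
    **overrides,
) -> CohortConfig:
    """Paired same-day biopsy + urine with a planted expanded-clone overlap."""
    if n_shared > min(n_biopsy, n_urine):
        raise ValueError("n_shared must be <= min(n_biopsy, n_urine)")
    rng = np.random.default_rng(seed)
    clones = []
    idx = 0
    for _ in range(n_shared):
        clones.append(_clone(rng, f"SH{idx:03d}",
                             {"BX": int(3 + rng.integers(0, 4)),
                              "UR": int(3 + rng.integers(0, 4))}))
        idx += 1
    for _ in range(n_biopsy - n_shared):
        clones.append(_clone(rng, f"BXO{idx:03d}", {"BX": int(3 + rng.integers(0, 4))}))
        idx += 1
    for _ in range(n_urine - n_shared):
        clones.append(_clone(rng, f"URO{idx:03d}", {"UR": int(3 + rng.integers(0, 4))}))
        idx += 1
    participant = ParticipantSpec(
        participant_id="P1", is_arm="iscalimab",
        samples=[("BX", "biopsy", day), ("UR", "urine", day)],
        clones=clones,
    )
    kwargs = dict(
        participants=[participant], seed=seed, cells_per_sample=300,
        background_lineage_weights={"CD8": 1.0}, **zero_noise_kwargs(),
    )
    kwargs.update(overrides)
    return CohortConfig(**kwargs)


def example_cohort_config(
    seed: int = 0,
    n_participants: int = 3,
    n_timepoints: int = 3,
    cells_per_sample: int = 3000,
    clones_per_participant: int = 30,
    urine_shedding_prob: float = 0.5,
    n_urine_timepoints: int = 1,
    zero_noise: bool = False,
    **overrides,
) -> CohortConfig:
    """Default longitudinal study cohort.

    Each participant (one per immunosuppression arm, cycling through
    tacrolimus / belatacept / iscalimab) contributes ``n_timepoints`` serial
    biopsies plus urine samples paired with the first
    ``n_urine_timepoints`` biopsies.  Planted CD8 clones persist across
    time points with decaying size; urine samples carry each same-day
    tissue clone with probability ``urine_shedding_prob`` (at roughly half
    its tissue size) plus a few urine-private clones.
    """
    arms = ["tacrolimus", "belatacept", "iscalimab"]
    programs = ["activated", "exhausted", "resident_memory", "proliferating"]
    participants = []
    rng = np.random.default_rng(seed)
    dual_rate = overrides.get(
        "dual_alpha_rate", 0.0 if zero_noise else CohortConfig.__dataclass_fields__["dual_alpha_rate"].default
    )
    for pi in range(n_participants):
        pid = f"PT{pi+1:02d}"
        days = [int(60 + 80 * t + rng.integers(0, 15)) for t in range(n_timepoints)]
        samples = [(f"{pid}_BX{t+1}", "biopsy", d) for t, d in enumerate(days)]
        n_urine = min(max(n_urine_timepoints, 0), n_timepoints)
        samples += [(f"{pid}_UR{t+1}", "urine", days[t]) for t in range(n_urine)]
        clones = []
        for ci in range(clones_per_participant):
            expanded = ci < clones_per_participant // 3  # a third start expanded
            sizes: dict[str, int] = {}
            start = int(rng.integers(0, n_timepoints))
            size = int(3 + rng.integers(0, 10)) if expanded else int(1 + rng.integers(0, 2))
            for t in range(start, n_timepoints):
                s = max(0, int(round(size * (0.6 ** (t - start)))))
                if s:
                    sizes[f"{pid}_BX{t+1}"] = s
            for t in range(n_urine):
                bx = sizes.get(f"{pid}_BX{t+1}", 0)
                if bx and rng.random() < urine_shedding_prob:
                    sizes[f"{pid}_UR{t+1}"] = max(1, bx // 2)
            if not sizes:
                continue
            clones.append(
                _clone(rng, f"{pid}_CL{ci:03d}", sizes,
                       program=programs[int(rng.integers(0, len(programs)))],
                       dual_alpha=rng.random() < dual_rate)
            )
        # a couple of urine-private clones per urine sample
        for t in range(n_urine):
            for uj in range(2):
                clones.append(
                    _clone(rng, f"{pid}_URCL{t}_{uj}",
                           {f"{pid}_UR{t+1}": int(3 + rng.integers(0, 3))},
                           program="activated")
                )
        participants.append(
            ParticipantSpec(participant_id=pid, is_arm=arms[pi % len(arms)],
                            samples=samples, clones=clones)
        )
    kwargs = dict(participants=participants, seed=seed, cells_per_sample=cells_per_sample)
    if zero_noise:
        kwargs.update(zero_noise_kwargs())
    kwargs.update(overrides)
    return CohortConfig(**kwargs)
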