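"""Receptor assembly, clonotype calling and the clonal-expansion rule.

A clonotype is the set of cells sharing an identical CDR3α/β chain set:
the key is the sorted set of CDR3α sequences (one or two — dual TCR-α
cells are biologically normal) together with a single CDR3β sequence.
Clonotypes present in more than 2 cells (by unique barcode) are classified
as expanded.  Cells carrying 2 CDR3β chains (presumed doublets) or only a
single chain type are unexpanded by definition and never form keys; they
are still counted as clonotype units so that per-sample totals (the
denominator of the expanded fraction) account for every receptor-bearing
CD8 cell.

Keys default to CDR3 nucleotide identity (the stricter reading, and the
upstream caller's convention); amino-acid keying is available via
``key_level="aa"``.  V/J gene identity is deliberately not part of the key.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Literal, Sequence

import numpy as np

from .tenx import ContigRecord

__all__ = [
    "CellReceptor",
    "ClonotypeKey",
    "Clonotype",
    "ClonalSummary",
    "serialize_key",
    "parse_key",
    "collapse_variants",
    "build_receptors",
    "call_clonotypes",
    "dual_alpha_stats",
    "summarize_sample",
    "round_half_up",
]

logger = logging.getLogger(__name__)

_ALPHA_LOCI = ("TRA",)
_BETA_LOCI = ("TRB",)
USABLE_CHAINS = ("TRA", "TRB")


def round_half_up(value: float, decimals: int = 1) -> float:
    """Decimal round-half-up (26/336 → 7.738… → 7.7; 0.05-style ties go up)."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def serialize_key(alpha_set: Sequence[str], beta: str) -> str:
    """Stable text form of a clonotype key: ``TRA:a1;TRA:a2|TRB:b``."""
    return ";".join(f"TRA:{a}" for a in sorted(alpha_set)) + f"|TRB:{beta}"


def parse_key(text: str) -> "ClonotypeKey":
    alpha_part, beta_part = text.split("|")
    alphas = tuple(p.split(":", 1)[1] for p in alpha_part.split(";") if p)
    beta = beta_part.split(":", 1)[1]
    return ClonotypeKey(alpha_set=alphas, beta=beta)


@dataclass(frozen=True)
class ClonotypeKey:
    """Identity of a clonotype: sorted CDR3α set (1–2) plus one CDR3β."""

    alpha_set: tuple[str, ...]
    beta: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "alpha_set", tuple(sorted(self.alpha_set)))
        if not self.beta:
            raise ValueError("clonotype key requires a nonempty CDR3β")
        if not 1 <= len(self.alpha_set) <= 2:
            raise ValueError("clonotype key requires 1 or 2 CDR3α sequences")

    def serialize(self) -> str:
        return serialize_key(self.alpha_set, self.beta)


@dataclass
class CellReceptor:
    """Per-barcode assembled chain sets after variant collapsing."""

    barcode: str
    alpha_cdr3_nt: list[str] = field(default_factory=list)
    beta_cdr3_nt: list[str] = field(default_factory=list)
    alpha_cdr3_aa: list[str] = field(default_factory=list)
    beta_cdr3_aa: list[str] = field(default_factory=list)
    source_contig_ids: list[str] = field(default_factory=list)
    malformed: bool = False

    @property
    def n_alpha(self) -> int:
        return len(self.alpha_cdr3_nt)

    @property
    def n_beta(self) -> int:
        return len(self.beta_cdr3_nt)

    @property
    def is_paired(self) -> bool:
        return self.n_alpha >= 1 and self.n_beta >= 1

    @property
    def is_dual_alpha(self) -> bool:
        return self.n_alpha == 2

    def key(self, level: Literal["nt", "aa"] = "nt") -> ClonotypeKey | None:
        """Clonotype key, or None for keyless (dual-β / single-chain) receptors."""
        if self.malformed or self.n_beta != 1 or self.n_alpha < 1:
            return None
        if level == "nt":
            return ClonotypeKey(tuple(self.alpha_cdr3_nt), self.beta_cdr3_nt[0])
        order = np.argsort(self.alpha_cdr3_nt)  # aa lists stay parallel to nt
        return ClonotypeKey(tuple(self.alpha_cdr3_aa[i] for i in order), self.beta_cdr3_aa[0])


@dataclass
class Clonotype:
    """Equivalence class of cells with one clonotype key."""

    key: ClonotypeKey
    member_barcodes: set[str]
    min_expanded_size: int = 3  # "more than 2 cells"

    @property
    def size(self) -> int:
        return len(self.member_barcodes)

    @property
    def status(self) -> str:
        return "expanded" if self.size >= self.min_expanded_size else "unexpanded"


@dataclass
class ClonalSummary:
    """Per-sample clonal accounting (the pie-chart numbers)."""

    sample_id: str
    n_cd8_cells_with_receptor: int
    n_clonotypes_total: int
    n_expanded: int
    n_unexpanded: int
    pct_expanded: float
    expanded_sizes: list[int]


def _locus_of(contig: ContigRecord) -> str | None:
    """Infer the TCR locus from the chain label or V/J gene names."""
    if contig.chain in ("TRA", "TRB", "TRD", "TRG"):
        return contig.chain
    for gene in (contig.v_gene, contig.j_gene, contig.d_gene):
        for locus in ("TRA", "TRB", "TRD", "TRG"):
            if gene.startswith(locus):
                return locus
    return None


def _strip_allele(gene: str) -> str:
    return gene.split("*", 1)[0]


def collapse_variants(contigs: Iterable[ContigRecord]) -> list[ContigRecord]:
    """Collapse TCR gene variants onto their singular TRA / TRB locus.

    Chain labels are normalized from the contig's locus (derived from the
    V/J gene names where the chain label is uninformative) and allele
    suffixes (``*01``) are stripped from gene names.  CDR3 strings are never
    touched.  Contigs from non-αβ loci (TRD/TRG) or with unrecognizable
    chains pass through flagged in ``extras['non_ab_locus']`` and are
    excluded from receptor assembly downstream.
    """
    out = []
    for c in contigs:
        locus = _locus_of(c)
        chain = locus if locus is not None else c.chain
        extras = dict(c.extras)
        if locus not in USABLE_CHAINS:
            extras["non_ab_locus"] = "true"
        out.append(
            ContigRecord(
                barcode=c.barcode,
                chain=chain,
                v_gene=_strip_allele(c.v_gene),
                d_gene=_strip_allele(c.d_gene),
                j_gene=_strip_allele(c.j_gene),
                cdr3_aa=c.cdr3_aa,
                cdr3_nt=c.cdr3_nt,
                productive=c.productive,
                full_length=c.full_length,
                high_confidence=c.high_confidence,
                umis=c.umis,
                raw_clonotype_id=c.raw_clonotype_id,
                contig_id=c.contig_id,
                extras=extras,
            )
        )
    return out


def _usable(contig: ContigRecord) -> bool:
    return (
        contig.productive
        and contig.full_length
        and contig.high_confidence
        and contig.chain in USABLE_CHAINS
        and bool(contig.cdr3_nt)
    )


def build_receptors(
    contigs: Iterable[ContigRecord],
    cd8_barcodes: set[str] | None = None,
) -> list[CellReceptor]:
    """Group usable contigs by barcode into per-cell receptors.

    Only productive, full-length, high-confidence TRA/TRB contigs contribute.
    If ``cd8_barcodes`` is given, barcodes outside the set are omitted.
    CDR3s are deduplicated per chain; a barcode with more than 2 distinct α
    or β CDR3s is flagged malformed.  Receptors are returned in sorted
    barcode order so downstream results are independent of input order.
    """
    by_barcode: dict[str, CellReceptor] = {}
    for c in contigs:
        if not _usable(c):
            continue
        if cd8_barcodes is not None and c.barcode not in cd8_barcodes:
            continue
        r = by_barcode.setdefault(c.barcode, CellReceptor(barcode=c.barcode))
        nts, aas = (
            (r.alpha_cdr3_nt, r.alpha_cdr3_aa)
            if c.chain == "TRA"
            else (r.beta_cdr3_nt, r.beta_cdr3_aa)
        )
        if c.cdr3_nt not in nts:
            nts.append(c.cdr3_nt)
            aas.append(c.cdr3_aa)
        r.source_contig_ids.append(c.contig_id)
    receptors = [by_barcode[bc] for bc in sorted(by_barcode)]
    for r in receptors:
        order = np.argsort(r.alpha_cdr3_nt)
        r.alpha_cdr3_nt = [r.alpha_cdr3_nt[i] for i in order]
        r.alpha_cdr3_aa = [r.alpha_cdr3_aa[i] for i in order]
        if r.n_alpha > 2 or r.n_beta > 2:
            r.malformed = True
    n_malformed = sum(r.malformed for r in receptors)
    if n_malformed:
        logger.info("build_receptors: %d malformed receptors (>2 chains of one type)", n_malformed)
    return receptors


def call_clonotypes(
    receptors: Sequence[CellReceptor],
    key_level: Literal["nt", "aa"] = "nt",
    min_expanded_size: int = 3,
) -> tuple[list[Clonotype], list[CellReceptor]]:
    """Partition receptors into keyed clonotypes and keyless unexpanded units.

    Receptors with ≥1 α and exactly 1 β share a clonotype iff their keys are
    identical (dual-α cells merge only on the full α set plus β; partial α
    overlap never merges clones).  Dual-β and single-chain receptors are
    keyless units, unexpanded regardless of multiplicity.  Malformed
    receptors are excluded and counted in the log.
    """
    groups: dict[ClonotypeKey, set[str]] = {}
    keyless: list[CellReceptor] = []
    n_excluded = 0
    for r in receptors:
        if r.malformed:
            n_excluded += 1
            continue
        key = r.key(key_level)
        if key is None:
            keyless.append(r)
        else:
            groups.setdefault(key, set()).add(r.barcode)
    if n_excluded:
        logger.info("call_clonotypes: excluded %d malformed receptors", n_excluded)
    clonotypes = [
        Clonotype(key=k, member_barcodes=members, min_expanded_size=min_expanded_size)
        for k, members in sorted(groups.items(), key=lambda kv: kv[0].serialize())
    ]
    return clonotypes, keyless


def dual_alpha_stats(
    clonotypes: Sequence[Clonotype],
    keyless: Sequence[CellReceptor],
    receptors: Sequence[CellReceptor],
) -> dict:
    """Cell-level dual TCR-α percentages in expanded vs unexpanded cells.

    Returns percentages (0–100) of receptor-bearing cells carrying two
    productive α chains within members of expanded clonotypes and within
    unexpanded cells (members of unexpanded clonotypes plus keyless units),
    with a two-proportion z-test p-value.  Empty strata yield NaN with a
    warning in the log.
    """
    by_barcode = {r.barcode: r for r in receptors}
    expanded_cells: list[CellReceptor] = []
    unexpanded_cells: list[CellReceptor] = list(keyless)
    for ct in clonotypes:
        bucket = expanded_cells if ct.status == "expanded" else unexpanded_cells
        bucket.extend(by_barcode[bc] for bc in sorted(ct.member_barcodes))

    def pct_dual(cells: list[CellReceptor]) -> tuple[float, int, int]:
        n = len(cells)
        k = sum(c.is_dual_alpha for c in cells)
        return (100.0 * k / n if n else float("nan")), k, n

    pct_exp, k_exp, n_exp = pct_dual(expanded_cells)
    pct_unexp, k_unexp, n_unexp = pct_dual(unexpanded_cells)
    if n_exp == 0 or n_unexp == 0:
        logger.warning("dual_alpha_stats: empty stratum (expanded n=%d, unexpanded n=%d)",
                       n_exp, n_unexp)
        p_value = float("nan")
    elif k_exp + k_unexp == 0 or k_exp + k_unexp == n_exp + n_unexp:
        p_value = 1.0  # degenerate pooled proportion: identical strata
    else:
        from statsmodels.stats.proportion import proportions_ztest

        _, p_value = proportions_ztest([k_exp, k_unexp], [n_exp, n_unexp])
    return {
        "pct_dual_alpha_expanded": pct_exp,
        "pct_dual_alpha_unexpanded": pct_unexp,
        "n_dual_alpha_expanded": k_exp,
        "n_cells_expanded": n_exp,
        "n_dual_alpha_unexpanded": k_unexp,
        "n_cells_unexpanded": n_unexp,
        "p_value": float(p_value),
    }


def summarize_sample(
    clonotypes: Sequence[Clonotype],
    keyless: Sequence[CellReceptor],
    sample_id: str,
) -> ClonalSummary:
    """Per-sample clonal summary.

    Each keyless receptor counts as its own unexpanded clonotype unit, so
    ``n_clonotypes_total`` is the auditable denominator of the expanded
    fraction (distinct keys plus keyless cells).  The percentage is rounded
    half-up to one decimal.
    """
    n_expanded = sum(ct.status == "expanded" for ct in clonotypes)
    n_total = len(clonotypes) + len(keyless)
    n_unexpanded = n_total - n_expanded
    n_cells = sum(ct.size for ct in clonotypes) + len(keyless)
    if n_total == 0:
        logger.warning("summarize_sample(%s): zero clonotype units", sample_id)
        pct = float("nan")
    else:
        pct = round_half_up(100.0 * n_expanded / n_total, 1)
    return ClonalSummary(
        sample_id=sample_id,
        n_cd8_cells_with_receptor=n_cells,
        n_clonotypes_total=n_total,
        n_expanded=n_expanded,
        n_unexpanded=n_unexpanded,
        pct_expanded=pct,
        expanded_sizes=sorted(
            (ct.size for ct in clonotypes if ct.status == "expanded"), reverse=True
        ),
    )
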