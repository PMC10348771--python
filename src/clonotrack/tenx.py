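"""Readers and writers for 10x-style V(D)J and gene-expression file layouts.

This module is the single source of truth for file dialects:

* ``filtered_contig_annotations.csv`` / ``clonotypes.csv`` — per-cell V(D)J
  contig calls and the upstream caller's per-sample clonotype table.  The
  clonotype table is advisory only: ``raw_clonotype_id`` is scoped to one
  sample and clonal identity is always recomputed downstream.
* MatrixMarket triplet gene×cell count matrices with ``barcodes.tsv`` and
  ``features.tsv`` sidecars.  MTX indices are 1-based on disk; everything in
  memory is 0-based (one conversion point, here).
* A YAML cohort manifest mirroring the serial biopsy/urine study design
  (sample, participant, compartment, post-transplant day, immunosuppression
  arm, file locations).

Barcodes are kept verbatim, including the ``-1`` GEM-well suffix; all
cross-file joins use the verbatim string.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
import yaml

__all__ = [
    "ContigRecord",
    "CountMatrix",
    "SampleManifest",
    "read_contigs",
    "write_contigs",
    "read_clonotypes_table",
    "read_mtx",
    "write_mtx",
    "read_manifest",
    "write_manifest",
    "write_tsv",
    "write_run_report",
    "FormatError",
]

VALID_COMPARTMENTS = ("biopsy", "urine")
VALID_ARMS = ("tacrolimus", "belatacept", "iscalimab", "none")

CONTIG_COLUMNS = [
    "barcode", "is_cell", "contig_id", "high_confidence", "chain",
    "v_gene", "d_gene", "j_gene", "cdr3", "cdr3_nt",
    "productive", "full_length", "reads", "umis", "raw_clonotype_id",
]

_MANDATORY_CONTIG_COLUMNS = (
    "barcode", "chain", "cdr3", "cdr3_nt", "productive", "full_length",
)

_TRUE_STRINGS = {"true", "True", "TRUE"}
_FALSE_STRINGS = {"false", "False", "FALSE", "None", ""}


class FormatError(ValueError):
    """A file does not conform to the expected dialect."""


@dataclass
class ContigRecord:
    """One V(D)J contig call linked to one cell barcode."""

    barcode: str
    chain: str
    v_gene: str = ""
    d_gene: str = ""
    j_gene: str = ""
    cdr3_aa: str = ""
    cdr3_nt: str = ""
    productive: bool = True
    full_length: bool = True
    high_confidence: bool = True
    umis: int = 1
    raw_clonotype_id: str = ""
    contig_id: str = ""
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.barcode:
            raise ValueError("contig barcode must be nonempty")
        if bool(self.cdr3_nt) != bool(self.cdr3_aa):
            raise ValueError(
                f"cdr3_nt and cdr3_aa must be empty together (contig {self.contig_id!r})"
            )


@dataclass
class CountMatrix:
    """Sparse genes × cells count (or normalized-value) matrix.

    ``counts`` is genes on rows, cells on columns, matching the orientation
    of the on-disk MatrixMarket file.
    """

    genes: list[str]
    barcodes: list[str]
    counts: sp.spmatrix

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        if self.counts.shape != (len(self.genes), len(self.barcodes)):
            raise ValueError(
                f"matrix shape {self.counts.shape} does not match "
                f"{len(self.genes)} genes × {len(self.barcodes)} barcodes"
            )
        if len(set(self.barcodes)) != len(self.barcodes):
            raise ValueError("duplicate barcodes in count matrix")

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_cells(self) -> int:
        return len(self.barcodes)

    def gene_index(self, gene: str) -> int:
        try:
            return self.genes.index(gene)
        except ValueError:
            raise KeyError(f"gene {gene!r} not in features") from None

    def subset_cells(self, keep: Sequence[str]) -> "CountMatrix":
        """Restrict to the given barcodes, preserving current column order."""
        keep_set = set(keep)
        idx = [j for j, bc in enumerate(self.barcodes) if bc in keep_set]
        return CountMatrix(
            genes=list(self.genes),
            barcodes=[self.barcodes[j] for j in idx],
            counts=self.counts[:, idx],
        )

    def row(self, gene: str) -> np.ndarray:
        """Dense 1-D vector of values for one gene across cells."""
        return np.asarray(self.counts[self.gene_index(gene), :].todense()).ravel()


@dataclass
class SampleManifest:
    """One sample's identity and file locations within a cohort."""

    sample_id: str
    participant_id: str
    compartment: str
    post_transplant_day: int
    is_arm: str = "none"
    vdj_dir: str = ""
    gex_dir: str = ""

    def __post_init__(self) -> None:
        if self.compartment not in VALID_COMPARTMENTS:
            raise ValueError(
                f"compartment must be one of {VALID_COMPARTMENTS}, got {self.compartment!r}"
            )
        if self.post_transplant_day < 0:
            raise ValueError("post_transplant_day must be >= 0")


def _parse_bool(value) -> bool:
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    s = str(value).strip()
    if s in _TRUE_STRINGS:
        return True
    if s in _FALSE_STRINGS:
        return False
    raise FormatError(f"cannot parse boolean value {value!r}")


def read_contigs(path: str | Path) -> list[ContigRecord]:
    """Read a ``filtered_contig_annotations.csv`` into contig records.

    Unknown extra columns are preserved per record in ``extras``.  Missing
    mandatory columns raise :class:`FormatError` naming the column; an empty
    (header-only) file returns ``[]`` with a warning.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    for col in _MANDATORY_CONTIG_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"{path}: missing mandatory column {col!r}")
    if df.empty:
        warnings.warn(f"{path}: contig file has no rows")
        return []
    known = set(CONTIG_COLUMNS)
    extra_cols = [c for c in df.columns if c not in known]
    records: list[ContigRecord] = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        records.append(
            ContigRecord(
                barcode=d["barcode"],
                chain=d["chain"],
                v_gene=d.get("v_gene", ""),
                d_gene=d.get("d_gene", ""),
                j_gene=d.get("j_gene", ""),
                cdr3_aa="" if d["cdr3"] in ("None", "") else d["cdr3"],
                cdr3_nt="" if d["cdr3_nt"] in ("None", "") else d["cdr3_nt"],
                productive=_parse_bool(d["productive"]),
                full_length=_parse_bool(d["full_length"]),
                high_confidence=_parse_bool(d.get("high_confidence", "True")),
                umis=int(d.get("umis", 1) or 0),
                raw_clonotype_id=d.get("raw_clonotype_id", ""),
                contig_id=d.get("contig_id", ""),
                extras={c: d[c] for c in extra_cols},
            )
        )
    return records


def write_contigs(records: Iterable[ContigRecord], path: str | Path) -> None:
    """Write contig records as a ``filtered_contig_annotations.csv``."""
    rows = []
    for r in records:
        rows.append(
            {
                "barcode": r.barcode,
                "is_cell": "True",
                "contig_id": r.contig_id,
                "high_confidence": str(r.high_confidence),
                "chain": r.chain,
                "v_gene": r.v_gene,
                "d_gene": r.d_gene,
                "j_gene": r.j_gene,
                "cdr3": r.cdr3_aa or "None",
                "cdr3_nt": r.cdr3_nt or "None",
                "productive": str(r.productive),
                "full_length": str(r.full_length),
                "reads": r.extras.get("reads", r.umis * 50),
                "umis": r.umis,
                "raw_clonotype_id": r.raw_clonotype_id,
            }
        )
    pd.DataFrame(rows, columns=CONTIG_COLUMNS).to_csv(path, index=False)


def read_clonotypes_table(path: str | Path) -> pd.DataFrame:
    """Read the upstream caller's per-sample ``clonotypes.csv`` (advisory only)."""
    df = pd.read_csv(path, dtype={"clonotype_id": str, "cdr3s_aa": str, "cdr3s_nt": str})
    for col in ("clonotype_id", "frequency", "cdr3s_nt"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing mandatory column {col!r}")
    return df


def read_mtx(dirpath: str | Path) -> CountMatrix:
    """Read ``matrix.mtx`` + ``barcodes.tsv`` + ``features.tsv`` from a directory.

    Duplicate (i, j) entries are summed, per MatrixMarket convention.
    """
    dirpath = Path(dirpath)
    mtx_path = dirpath / "matrix.mtx"
    bc_path = dirpath / "barcodes.tsv"
    ft_path = dirpath / "features.tsv"
    for p in (mtx_path, bc_path, ft_path):
        if not p.exists():
            raise FormatError(f"missing expected file {p}")
    try:
        mat = scipy.io.mmread(mtx_path)
    except Exception as exc:  # malformed header or body
        raise FormatError(f"{mtx_path}: cannot parse MatrixMarket file: {exc}") from exc
    barcodes = bc_path.read_text().split()
    features = [line.split("\t")[0] for line in ft_path.read_text().splitlines() if line]
    mat = sp.csr_matrix(mat)  # sums duplicate COO entries
    if mat.shape != (len(features), len(barcodes)):
        raise FormatError(
            f"{mtx_path}: matrix is {mat.shape} but sidecars list "
            f"{len(features)} features × {len(barcodes)} barcodes"
        )
    return CountMatrix(genes=features, barcodes=barcodes, counts=mat)


def write_mtx(matrix: CountMatrix, dirpath: str | Path) -> None:
    """Write a count matrix in 10x triplet layout (MTX + sidecars)."""
    dirpath = Path(dirpath)
    dirpath.mkdir(parents=True, exist_ok=True)
    coo = sp.coo_matrix(matrix.counts)
    is_int = np.issubdtype(coo.dtype, np.integer)
    scipy.io.mmwrite(
        dirpath / "matrix.mtx", coo, field="integer" if is_int else "real"
    )
    (dirpath / "barcodes.tsv").write_text("".join(bc + "\n" for bc in matrix.barcodes))
    (dirpath / "features.tsv").write_text(
        "".join(f"{g}\t{g}\tGene Expression\n" for g in matrix.genes)
    )


def read_manifest(path: str | Path) -> list[SampleManifest]:
    """Read a cohort manifest YAML; relative paths resolve against its directory."""
    path = Path(path)
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not doc or "samples" not in doc:
        raise FormatError(f"{path}: manifest must contain a 'samples' list")
    out = []
    for entry in doc["samples"]:
        m = SampleManifest(
            sample_id=str(entry["sample_id"]),
            participant_id=str(entry["participant_id"]),
            compartment=str(entry["compartment"]),
            post_transplant_day=int(entry["post_transplant_day"]),
            is_arm=str(entry.get("is_arm", "none")),
            vdj_dir=str(path.parent / entry["vdj_dir"]),
            gex_dir=str(path.parent / entry["gex_dir"]),
        )
        out.append(m)
    return out


def write_manifest(samples: Sequence[SampleManifest], path: str | Path) -> None:
    path = Path(path)
    doc = {
        "samples": [
            {
                "sample_id": m.sample_id,
                "participant_id": m.participant_id,
                "compartment": m.compartment,
                "post_transplant_day": int(m.post_transplant_day),
                "is_arm": m.is_arm,
                "vdj_dir": str(Path(m.vdj_dir).name),
                "gex_dir": str(Path(m.gex_dir).name),
            }
            for m in samples
        ]
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def write_tsv(df: pd.DataFrame, path: str | Path, columns: Sequence[str] | None = None) -> None:
    """Write a result table as TSV with a stable column order."""
    if columns is not None:
        df = df.reindex(columns=list(columns))
    df.to_csv(path, sep="\t", index=False)


def write_run_report(report: Mapping, path: str | Path) -> None:
    """Write the machine-readable run report (seed, thresholds, accounting)."""
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
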