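"""Longitudinal clone tracking and biopsy–urine overlap.

Clonotype keys are matched exactly across a participant's samples, ordered
by post-transplant day.  Tracks record per-sample size and expansion
status, the first sample at which the clone was expanded ("newly expanded"
vs previously seen), and the compartments in which it was observed.
Persistence follows the convention of the serial-biopsy analyses: a clone
expanded at a given biopsy counts as prior-seen iff it was *expanded* at an
earlier sample of the same compartment set (mere size-1–2 presence counts
only in ``mode="any"``).  Keyless receptor units never form tracks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

from .clonotype import Clonotype, ClonotypeKey, round_half_up
from .tenx import SampleManifest

__all__ = ["CloneTrack", "OverlapResult", "build_tracks", "persistence_counts", "overlap"]


@dataclass
class CloneTrack:
    """One clonotype's trajectory across one participant's ordered samples."""

    participant_id: str
    key: ClonotypeKey
    size_by_sample: dict[str, int]
    status_by_sample: dict[str, str]  # expanded | unexpanded | absent
    first_expanded_sample: str | None
    compartments_seen: set[str] = field(default_factory=set)


@dataclass
class OverlapResult:
    """Exact expanded-clonotype overlap between two samples."""

    sample_a: str
    sample_b: str
    n_shared_expanded: int
    n_a_only: int
    n_b_only: int
    shared_keys: list[ClonotypeKey]


def _ordered_samples(manifest: Sequence[SampleManifest], participant_id: str) -> list[SampleManifest]:
    mine = [m for m in manifest if m.participant_id == participant_id]
    # stable order: day, then biopsy before urine, then sample id
    return sorted(mine, key=lambda m: (m.post_transplant_day, m.compartment != "biopsy", m.sample_id))


def build_tracks(
    clonotypes_by_sample: Mapping[str, Sequence[Clonotype]],
    manifest: Sequence[SampleManifest],
    scope: Literal["expanded", "all"] = "expanded",
) -> list[CloneTrack]:
    """One track per distinct key per participant.

    ``scope="expanded"`` (default, mirrors the figures) keeps only keys
    expanded in at least one sample; ``"all"`` keeps every key.  Track
    construction is independent of sample-processing order: samples are
    re-ordered by (day, compartment, id) internally.
    """
    sids = [m.sample_id for m in manifest]
    if len(set(sids)) != len(sids):
        raise ValueError("duplicate sample ids in manifest")
    unknown = set(clonotypes_by_sample) - set(sids)
    if unknown:
        raise ValueError(f"clonotype tables for samples not in manifest: {sorted(unknown)}")
    tracks: list[CloneTrack] = []
    participants = sorted({m.participant_id for m in manifest})
    for pid in participants:
        ordered = _ordered_samples(manifest, pid)
        sizes: dict[ClonotypeKey, dict[str, int]] = {}
        for m in ordered:
            for ct in clonotypes_by_sample.get(m.sample_id, []):
                sizes.setdefault(ct.key, {})[m.sample_id] = ct.size
        for key in sorted(sizes, key=lambda k: k.serialize()):
            per_sample = sizes[key]
            status = {
                m.sample_id: (
                    "absent" if per_sample.get(m.sample_id, 0) == 0
                    else ("expanded" if per_sample[m.sample_id] > 2 else "unexpanded")
                )
                for m in ordered
            }
            if scope == "expanded" and "expanded" not in status.values():
                continue
            first_exp = next(
                (m.sample_id for m in ordered if status[m.sample_id] == "expanded"), None
            )
            tracks.append(
                CloneTrack(
                    participant_id=pid,
                    key=key,
                    size_by_sample={m.sample_id: per_sample.get(m.sample_id, 0) for m in ordered},
                    status_by_sample=status,
                    first_expanded_sample=first_exp,
                    compartments_seen={
                        m.compartment for m in ordered if per_sample.get(m.sample_id, 0) > 0
                    },
                )
            )
    return tracks


def persistence_counts(
    tracks: Sequence[CloneTrack],
    sample_id: str,
    manifest: Sequence[SampleManifest],
    mode: Literal["expanded", "any"] = "expanded",
    prior_compartments: tuple[str, ...] = ("biopsy",),
) -> tuple[int, int, int]:
    """Prior-seen accounting for the clones expanded at one sample.

    Returns ``(n_expanded_total, n_seen_in_prior_samples, pct)`` where pct
    is ``100 · n_prior / n_total`` rounded half-up to the nearest integer.
    A clone is prior-seen iff it was expanded (``mode="expanded"``) or
    present at any size (``mode="any"``) in an earlier-day sample whose
    compartment is in ``prior_compartments``.
    """
    by_id = {m.sample_id: m for m in manifest}
    if sample_id not in by_id:
        raise ValueError(f"unknown sample {sample_id!r}")
    target = by_id[sample_id]
    prior_ids = [
        m.sample_id
        for m in manifest
        if m.participant_id == target.participant_id
        and m.compartment in prior_compartments
        and m.post_transplant_day < target.post_transplant_day
    ]
    n_total = 0
    n_prior = 0
    for t in tracks:
        if t.participant_id != target.participant_id:
            continue
        if t.status_by_sample.get(sample_id) != "expanded":
            continue
        n_total += 1
        if mode == "expanded":
            seen = any(t.status_by_sample.get(s) == "expanded" for s in prior_ids)
        else:
            seen = any(t.size_by_sample.get(s, 0) > 0 for s in prior_ids)
        n_prior += bool(seen)
    pct = int(round_half_up(100.0 * n_prior / n_total, 0)) if n_total else 0
    return n_total, n_prior, pct


def overlap(
    sample_a: str,
    keys_a: set[ClonotypeKey],
    sample_b: str,
    keys_b: set[ClonotypeKey],
) -> OverlapResult:
    """Exact set overlap between two expanded-key sets (Venn counts)."""
    shared = keys_a & keys_b
    return OverlapResult(
        sample_a=sample_a,
        sample_b=sample_b,
        n_shared_expanded=len(shared),
        n_a_only=len(keys_a - shared),
        n_b_only=len(keys_b - shared),
        shared_keys=sorted(shared, key=lambda k: k.serialize()),
    )
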