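"""Candidate selection: significance filter, EV-cargo cross-match, forced includes.

The scan's significant families are cross-matched against the
extracellular-vesicle cargo profile: a family becomes a candidate when at
least one of its member miRNAs sits within the top ``top_k`` cargo ranks.
Individual miRNAs can additionally be forced into the candidate list
(e.g. the most EV-enriched miRNA), flagged with ``provenance="forced"``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .enrichment import FamilyEnrichmentResult
from .errors import InputError
from .io import EVCargoProfile, TargetPredictionMap

logger = logging.getLogger("mirenrich.selection")


@dataclass(frozen=True)
class CandidateSelection:
    """One selected candidate.

    ``ev_rank`` is the best (minimum) cargo rank among the family's member
    miRNAs; ``member_mirnas_in_cargo`` lists all members found in the cargo,
    best rank first, so the first entry is the representative miRNA.
    ``provenance`` is ``"scan+cargo"`` for families passing both the
    significance and cargo filters, ``"forced"`` for manual additions (which
    carry no p-value and may lack a rank).
    """

    family_id: str
    p_value: Optional[float]
    ev_rank: Optional[int]
    member_mirnas_in_cargo: Tuple[str, ...] = ()
    provenance: str = "scan+cargo"

    @property
    def representative_mirna(self) -> str:
        if self.member_mirnas_in_cargo:
            return self.member_mirnas_in_cargo[0]
        return self.family_id


def benjamini_hochberg(p_values: Sequence[float]) -> np.ndarray:
    """BH step-up adjusted p-values: adjusted_i = min_{j>=i} p_(j) * m / j."""
    p = np.asarray(p_values, dtype=float)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    adj = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(adj[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


def significant_families(
    results: Sequence[FamilyEnrichmentResult],
    alpha: float = 0.05,
    correction: str = "none",
) -> List[FamilyEnrichmentResult]:
    """Families whose (optionally BH-adjusted) p-value is strictly below alpha.

    The inequality is strict — nominal significance means p < alpha, so a
    family at exactly alpha fails. ``correction="none"`` (default, matching
    nominal significance) or ``"bh"`` for Benjamini–Hochberg.
    """
    if not (0.0 < alpha <= 1.0):
        raise InputError(f"alpha must be in (0, 1]: {alpha}")
    if correction not in ("none", "bh"):
        raise InputError(f"unknown correction {correction!r}")
    results = list(results)
    if not results:
        return []
    p = np.array([r.p_value for r in results])
    p_eff = benjamini_hochberg(p) if correction == "bh" else p
    return [r for r, pv in zip(results, p_eff) if pv < alpha]


def crossmatch_cargo(
    families: Sequence[FamilyEnrichmentResult],
    predictions: TargetPredictionMap,
    cargo: EVCargoProfile,
    top_k: int = 50,
) -> List[CandidateSelection]:
    """Keep families with at least one member miRNA in the top ``top_k``
    cargo ranks.

    All members found anywhere in the cargo are reported (best rank first);
    ``ev_rank`` is the minimum member rank. Families without a member-map
    entry are excluded and logged. Output is sorted by ``ev_rank``.
    """
    if top_k < 1:
        raise InputError(f"top_k must be >= 1: {top_k}")
    out: List[CandidateSelection] = []
    for fam in families:
        members = predictions.family_members.get(fam.family_id)
        if not members:
            logger.warning("EXCLUDE_FAMILY_NO_MEMBER_MAP family=%s", fam.family_id)
            continue
        ranked = sorted(
            ((cargo.rank_of(m), m) for m in members if cargo.rank_of(m) is not None))
        if not ranked or ranked[0][0] > top_k:
            continue
        out.append(CandidateSelection(
            family_id=fam.family_id,
            p_value=fam.p_value,
            ev_rank=ranked[0][0],
            member_mirnas_in_cargo=tuple(m for _, m in ranked),
            provenance="scan+cargo",
        ))
    out.sort(key=lambda s: (s.ev_rank, s.family_id))
    return out


def apply_forced_includes(
    selections: Sequence[CandidateSelection],
    forced: Iterable[str],
    cargo: EVCargoProfile,
) -> List[CandidateSelection]:
    """Append manually selected miRNAs, never duplicating existing candidates.

    Each forced miRNA absent from the current selections is appended with
    ``provenance="forced"``, carrying its cargo rank when present in the
    profile and no rank otherwise. Existing scan+cargo selections are never
    modified.
    """
    out = list(selections)
    present = set()
    for s in out:
        present.add(s.family_id)
        present.update(s.member_mirnas_in_cargo)
    for mirna in forced:
        mirna = str(mirna).strip()
        if not mirna or mirna in present:
            continue
        out.append(CandidateSelection(
            family_id=mirna,
            p_value=None,
            ev_rank=cargo.rank_of(mirna),
            member_mirnas_in_cargo=(mirna,) if cargo.rank_of(mirna) is not None else (),
            provenance="forced",
        ))
        present.add(mirna)
    return out


CANDIDATE_COLUMNS = ["family_id", "representative_mirna", "p_value", "ev_rank", "provenance"]


def write_candidate_report(selections: Sequence[CandidateSelection], path) -> None:
    """Write the candidate list as a TSV (full-precision p-values)."""
    rows = [{
        "family_id": s.family_id,
        "representative_mirna": s.representative_mirna,
        "p_value": "" if s.p_value is None else repr(float(s.p_value)),
        "ev_rank": "" if s.ev_rank is None else int(s.ev_rank),
        "provenance": s.provenance,
    } for s in selections]
    pd.DataFrame(rows, columns=CANDIDATE_COLUMNS).to_csv(
        path, sep="\t", index=False, lineterminator="\n")
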