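"""Fixed-width rendering of scan results in the published table's style."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Optional, Sequence

from .enrichment import FamilyEnrichmentResult
from .errors import InputError

HEADERS = ("Family", "FC Non-Targets", "FC Targets", "p", "Rank")


def _round_half_up(value: float, places: int) -> str:
    """Decimal rounding with halves away from zero, as the published table
    rounds (0.03125 -> 0.0313)."""
    q = Decimal(1).scaleb(-places)
    return str(Decimal(repr(float(value))).quantize(q, rounding=ROUND_HALF_UP))


def render_table(
    results: Sequence[FamilyEnrichmentResult],
    ev_ranks: Optional[Mapping[str, int]] = None,
) -> str:
    """Render results as a fixed-width text table.

    Medians are shown to 2 decimals and p-values to 4 decimals (full
    precision lives only in the TSV report); ``ev_ranks`` optionally maps
    family ids to their EV cargo rank, shown as "-" when absent.
    """
    results = list(results)
    if not results:
        raise InputError("render_table: empty result list")
    ev_ranks = ev_ranks or {}
    rows = [(
        r.family_id,
        _round_half_up(r.median_fc_non_targets, 2),
        _round_half_up(r.median_fc_targets, 2),
        _round_half_up(r.p_value, 4),
        str(ev_ranks[r.family_id]) if r.family_id in ev_ranks else "-",
    ) for r in results]
    widths = [max(len(h), *(len(row[i]) for row in rows)) for i, h in enumerate(HEADERS)]
    def fmt(cells):
        return "  ".join(c.ljust(w) if i == 0 else c.rjust(w)
                         for i, (c, w) in enumerate(zip(cells, widths)))
    lines = [fmt(HEADERS), fmt(tuple("-" * w for w in widths))]
    lines += [fmt(row) for row in rows]
    return "\n".join(lines) + "\n"
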