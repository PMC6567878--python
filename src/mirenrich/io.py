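"""Readers and writers for the pipeline's tabular formats.

Three inputs feed the enrichment scan:

* a gene-level fold-change table (``gene_id<TAB>log_fc``), log fold change of
  treated vs. untreated expression;
* a two-file target-prediction map in a minimal TargetScan-like dialect:
  predictions (``family_id<TAB>gene_id``) and members (``family_id<TAB>mirna_id``);
* an extracellular-vesicle cargo profile (``mirna_id<TAB>abundance``) from
  which 1-based abundance ranks are derived.

All files are UTF-8, tab-separated, LF endings, with a header row. Every
row or family a reader drops is logged with a machine-parsable reason code
(``REJECT_*`` / ``DROP_*``); readers never return a silent partial load —
they either validate or raise a typed :class:`~mirenrich.errors.InputError`.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import InputError

logger = logging.getLogger("mirenrich.io")

#: Default gene-identifier normalization: case-fold and strip whitespace.
#: No ortholog or cross-species mapping is attempted; callers may pass a
#: richer normalizer (e.g. a symbol→ortholog lookup) to the readers.
def normalize_gene_id(gene_id: str) -> str:
    return gene_id.strip().casefold()


def _require_columns(df: pd.DataFrame, cols: Sequence[str], path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise InputError(f"{path}: missing required column(s) {missing}; found {list(df.columns)}")


def _parse_float(token) -> float:
    """Correctly-rounded string→float so repr-precision TSVs round-trip
    exactly (pandas' fast numeric parser is not IEEE round-trip safe)."""
    try:
        return float(token)
    except (TypeError, ValueError):
        return math.nan


def _read_tsv(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise InputError(f"input file not found: {path}")
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, comment=None, skip_blank_lines=True)
    except pd.errors.EmptyDataError:
        raise InputError(f"{path}: file is empty") from None
    except pd.errors.ParserError as exc:
        raise InputError(f"{path}: malformed TSV ({exc})") from None
    return df


# ---------------------------------------------------------------------------
# Fold-change table
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FoldChangeTable:
    """Gene identifier → log fold change (treated vs. untreated).

    ``values`` is a float Series indexed by normalized gene id; identifiers
    are unique and every log fold change is finite. ``n_rejected`` counts
    input rows dropped during reading (non-numeric or non-finite values).
    """

    values: pd.Series
    n_rejected: int = 0

    def __post_init__(self):
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise InputError(f"duplicate gene ids after normalization: {dups}")
        arr = self.values.to_numpy(dtype=float)
        if not np.all(np.isfinite(arr)):
            raise InputError("fold-change table contains non-finite values")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def genes(self) -> frozenset:
        return frozenset(self.values.index)

    def subset(self, genes: Iterable[str]) -> "FoldChangeTable":
        idx = self.values.index.intersection(pd.Index(genes))
        return FoldChangeTable(self.values.loc[idx])

    @classmethod
    def from_records(cls, records: Iterable[tuple],
                     normalizer: Callable[[str], str] = normalize_gene_id) -> "FoldChangeTable":
        ids, fcs = [], []
        for gene_id, log_fc in records:
            ids.append(normalizer(str(gene_id)))
            fcs.append(float(log_fc))
        return cls(pd.Series(fcs, index=pd.Index(ids, name="gene_id"), name="log_fc"))


def read_fold_change_table(
    path,
    gene_col: str = "gene_id",
    fc_col: str = "log_fc",
    duplicate_policy: str = "error",
    normalizer: Callable[[str], str] = normalize_gene_id,
) -> FoldChangeTable:
    """Read a gene-level log fold-change TSV.

    Rows with a non-numeric or non-finite ``log_fc`` are rejected and counted
    (each rejection is logged with its 1-based file line number). Duplicate
    gene ids after normalization are handled by ``duplicate_policy``:

    * ``"error"`` (default) — raise, naming the gene and the line numbers;
    * ``"first"`` — keep the first occurrence, log the drops;
    * ``"mean"`` — collapse duplicates to their mean, log the collapse.

    Raises :class:`InputError` if the file or columns are missing, or if
    every row was rejected.
    """
    if duplicate_policy not in ("error", "first", "mean"):
        raise InputError(f"unknown duplicate_policy: {duplicate_policy!r}")
    df = _read_tsv(path)
    _require_columns(df, [gene_col, fc_col], path)
    # header is line 1, first data row line 2
    df = df.reset_index(drop=True)
    df["_line"] = df.index + 2
    df["_gene"] = df[gene_col].fillna("").map(normalizer)
    df["_fc"] = df[fc_col].map(_parse_float)

    bad = ~np.isfinite(df["_fc"].to_numpy(dtype=float)) | (df["_gene"] == "")
    n_rejected = int(bad.sum())
    for _, row in df[bad].iterrows():
        logger.warning("REJECT_ROW_NONNUMERIC file=%s line=%d gene=%r value=%r",
                       path, row["_line"], row[gene_col], row[fc_col])
    df = df[~bad]
    if df.empty:
        raise InputError(f"{path}: all {n_rejected} data rows were rejected")

    dup_mask = df["_gene"].duplicated(keep=False)
    if dup_mask.any():
        groups = df[dup_mask].groupby("_gene")["_line"].apply(list)
        if duplicate_policy == "error":
            detail = "; ".join(f"{g} (lines {lines})" for g, lines in groups.items())
            raise InputError(f"{path}: duplicate gene id(s) after normalization: {detail}")
        if duplicate_policy == "first":
            for g, lines in groups.items():
                logger.warning("DROP_DUPLICATE_KEEP_FIRST file=%s gene=%s lines=%s", path, g, lines)
            df = df.drop_duplicates(subset="_gene", keep="first")
        else:  # mean
            for g, lines in groups.items():
                logger.warning("COLLAPSE_DUPLICATE_MEAN file=%s gene=%s lines=%s", path, g, lines)
            df = df.groupby("_gene", as_index=False).agg({"_fc": "mean"})

    series = pd.Series(df["_fc"].to_numpy(dtype=float),
                       index=pd.Index(df["_gene"], name="gene_id"), name="log_fc")
    return FoldChangeTable(series, n_rejected=n_rejected)


# ---------------------------------------------------------------------------
# Target-prediction map
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TargetPredictionMap:
    """miRNA family → predicted target genes, and family → member miRNAs.

    Every family carries at least one member miRNA and one target gene; the
    union of all target sets (the induced gene universe) is non-empty.
    """

    family_targets: Mapping[str, frozenset]
    family_members: Mapping[str, frozenset]

    def __post_init__(self):
        for fam, targets in self.family_targets.items():
            if not targets:
                raise InputError(f"family {fam!r} has no target genes")
            if not self.family_members.get(fam):
                raise InputError(f"family {fam!r} has no member miRNAs")
        if not self.gene_universe:
            raise InputError("target-prediction map induces an empty gene universe")

    @property
    def families(self) -> frozenset:
        return frozenset(self.family_targets)

    @property
    def gene_universe(self) -> frozenset:
        out: set = set()
        for targets in self.family_targets.values():
            out |= targets
        return frozenset(out)


def read_target_predictions(
    predictions_path,
    members_path,
    normalizer: Callable[[str], str] = normalize_gene_id,
) -> TargetPredictionMap:
    """Read the two-file prediction dialect.

    ``predictions_path``: TSV with columns (family_id, gene_id);
    ``members_path``: TSV with columns (family_id, mirna_id). Repeated rows
    are collapsed into sets. Families that end up with no members or no
    targets are dropped with a logged reason; an empty final universe is a
    hard error.
    """
    pred = _read_tsv(predictions_path)
    _require_columns(pred, ["family_id", "gene_id"], predictions_path)
    memb = _read_tsv(members_path)
    _require_columns(memb, ["family_id", "mirna_id"], members_path)

    targets: dict = {}
    for fam, gene in zip(pred["family_id"], pred["gene_id"]):
        if pd.isna(fam) or pd.isna(gene):
            continue
        targets.setdefault(str(fam).strip(), set()).add(normalizer(str(gene)))
    members: dict = {}
    for fam, mirna in zip(memb["family_id"], memb["mirna_id"]):
        if pd.isna(fam) or pd.isna(mirna):
            continue
        members.setdefault(str(fam).strip(), set()).add(str(mirna).strip())

    kept_t, kept_m = {}, {}
    for fam, tset in targets.items():
        mset = members.get(fam)
        if not mset:
            logger.warning("DROP_FAMILY_NO_MEMBERS family=%s", fam)
            continue
        if not tset:
            logger.warning("DROP_FAMILY_NO_TARGETS family=%s", fam)
            continue
        kept_t[fam] = frozenset(tset)
        kept_m[fam] = frozenset(mset)
    for fam in members:
        if fam not in targets:
            logger.warning("DROP_FAMILY_NO_TARGETS family=%s", fam)
    if not kept_t:
        raise InputError(
            f"{predictions_path}: no valid family remained; gene universe is empty")
    return TargetPredictionMap(kept_t, kept_m)


# ---------------------------------------------------------------------------
# EV cargo profile
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EVCargoProfile:
    """miRNAs ranked by extracellular-vesicle abundance.

    ``table`` has columns ``mirna_id``, ``abundance``, ``rank``; ranks are a
    1..n permutation assigned by descending abundance, ties broken
    lexicographically by miRNA id so ranking is deterministic.
    """

    table: pd.DataFrame

    def __post_init__(self):
        t = self.table
        if t["mirna_id"].duplicated().any():
            dup = t.loc[t["mirna_id"].duplicated(), "mirna_id"].tolist()
            raise InputError(f"duplicate mirna_id in cargo profile: {dup}")
        if (t["abundance"] < 0).any():
            raise InputError("negative abundance in cargo profile")
        ranks = np.sort(t["rank"].to_numpy())
        if not np.array_equal(ranks, np.arange(1, len(t) + 1)):
            raise InputError("cargo ranks are not a permutation of 1..n")

    def __len__(self) -> int:
        return len(self.table)

    def rank_of(self, mirna_id: str) -> Optional[int]:
        hit = self.table.loc[self.table["mirna_id"] == mirna_id, "rank"]
        return int(hit.iloc[0]) if len(hit) else None

    def top(self, k: int) -> frozenset:
        return frozenset(self.table.loc[self.table["rank"] <= k, "mirna_id"])

    @classmethod
    def from_abundances(cls, entries: Iterable[tuple]) -> "EVCargoProfile":
        df = pd.DataFrame(list(entries), columns=["mirna_id", "abundance"])
        df["mirna_id"] = df["mirna_id"].astype(str).str.strip()
        df["abundance"] = df["abundance"].astype(float)
        df = df.sort_values(["abundance", "mirna_id"],
                            ascending=[False, True], kind="mergesort")
        df["rank"] = np.arange(1, len(df) + 1)
        return cls(df.reset_index(drop=True))


def read_cargo_profile(path) -> EVCargoProfile:
    """Read a ``mirna_id<TAB>abundance`` TSV and assign descending-abundance
    ranks (lexicographic tie-break). Rows with negative or non-numeric
    abundance are rejected and logged; duplicate miRNA ids or an empty
    profile are hard errors."""
    df = _read_tsv(path)
    _require_columns(df, ["mirna_id", "abundance"], path)
    df = df.reset_index(drop=True)
    df["_line"] = df.index + 2
    ab = df["abundance"].map(_parse_float)
    bad = ~np.isfinite(ab.to_numpy(dtype=float)) | (ab < 0) | df["mirna_id"].isna()
    for _, row in df[bad].iterrows():
        logger.warning("REJECT_CARGO_ROW file=%s line=%d mirna=%r abundance=%r",
                       path, row["_line"], row["mirna_id"], row["abundance"])
    df = df[~bad]
    if df.empty:
        raise InputError(f"{path}: cargo profile has no valid rows")
    return EVCargoProfile.from_abundances(zip(df["mirna_id"], ab[~bad]))


# ---------------------------------------------------------------------------
# Scan report
# ---------------------------------------------------------------------------

REPORT_COLUMNS = [
    "family_id", "n_targets", "n_non_targets",
    "median_fc_targets", "median_fc_non_targets",
    "statistic", "p_value", "ev_rank", "selected",
]


def write_scan_report(results, path, selection_info: Optional[Mapping] = None) -> None:
    """Write per-family scan results as a full-precision TSV.

    ``results`` is a non-empty sequence of
    :class:`~mirenrich.enrichment.FamilyEnrichmentResult`. ``selection_info``
    optionally maps family_id → (ev_rank or None, selected: bool); families
    absent from the mapping get an empty ev_rank and selected=False. Floats
    are written with repr precision so a write→read round-trip is lossless;
    the human-readable rendering (2-decimal medians as in the published
    table) is produced separately by :func:`mirenrich.report.render_table`.
    """
    results = list(results)
    if not results:
        raise InputError("write_scan_report: empty result list")
    selection_info = selection_info or {}
    rows = []
    for r in results:
        ev_rank, selected = selection_info.get(r.family_id, (None, False))
        rows.append({
            "family_id": r.family_id,
            "n_targets": r.n_targets,
            "n_non_targets": r.n_non_targets,
            "median_fc_targets": repr(float(r.median_fc_targets)),
            "median_fc_non_targets": repr(float(r.median_fc_non_targets)),
            "statistic": repr(float(r.u_statistic)),
            "p_value": repr(float(r.p_value)),
            "ev_rank": "" if ev_rank is None else int(ev_rank),
            "selected": "true" if selected else "false",
        })
    pd.DataFrame(rows, columns=REPORT_COLUMNS).to_csv(
        path, sep="\t", index=False, lineterminator="\n")


def read_scan_report(path):
    """Read back a scan-report TSV written by :func:`write_scan_report`.

    Returns ``(results, selection_info)`` matching the writer's inputs.
    """
    from .enrichment import FamilyEnrichmentResult  # local import: avoid cycle

    df = _read_tsv(path)
    _require_columns(df, REPORT_COLUMNS, path)
    results, info = [], {}
    for _, row in df.iterrows():
        n_t, n_nt = int(row["n_targets"]), int(row["n_non_targets"])
        results.append(FamilyEnrichmentResult(
            family_id=str(row["family_id"]),
            n_targets=n_t,
            n_non_targets=n_nt,
            median_fc_targets=float(row["median_fc_targets"]),
            median_fc_non_targets=float(row["median_fc_non_targets"]),
            u_statistic=float(row["statistic"]),
            p_value=float(row["p_value"]),
            method="unknown",
        ))
        ev_rank = None if pd.isna(row["ev_rank"]) or row["ev_rank"] == "" else int(row["ev_rank"])
        info[str(row["family_id"])] = (ev_rank, str(row["selected"]).lower() == "true")
    return results, info
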