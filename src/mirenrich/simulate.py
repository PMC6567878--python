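"""Synthetic datasets with planted miRNA-family effects, plus recovery metrics.

The generator emulates the statistical structure the enrichment scan
assumes: a bipartite family→target map, gene-level log fold changes in which
the targets of a chosen set of "active" families are shifted downward by a
known amount, and an EV cargo ranking in which the active families' member
miRNAs occupy top ranks. Ground truth (the active family ids) travels with
the dataset so pipeline output can be scored.

Randomness comes from a single seeded generator consumed in a fixed stream
order — gene fold changes, then family target assignment, then cargo — so
datasets are bit-reproducible and adding later draws never reshuffles
earlier ones.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
import yaml

from .enrichment import scan_families
from .errors import ConfigError
from .io import EVCargoProfile, FoldChangeTable, TargetPredictionMap
from .selection import CandidateSelection


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic dataset.

    ``effect_delta`` is the log-fold-change shift subtracted from the targets
    of active families (a positive value plants down-regulation);
    ``baseline_mu`` and ``noise_sigma`` parameterize the normal noise on all
    gene log fold changes; ``active_member_max_rank`` bounds the cargo ranks
    at which active families' member miRNAs are planted.
    """

    n_genes: int = 2000
    n_families: int = 50
    targets_per_family: int = 40
    overlap: bool = True
    n_active: int = 5
    effect_delta: float = 0.6
    baseline_mu: float = 0.03
    noise_sigma: float = 0.2
    cargo_size: int = 150
    active_member_max_rank: int = 50
    seed: int = 0

    def __post_init__(self):
        if self.n_genes < 1 or self.n_families < 1 or self.targets_per_family < 1:
            raise ConfigError("n_genes, n_families, targets_per_family must be >= 1")
        if not (0 <= self.n_active <= self.n_families):
            raise ConfigError("n_active must be in [0, n_families]")
        if self.targets_per_family > self.n_genes:
            raise ConfigError("targets_per_family exceeds n_genes")
        if not self.overlap and self.n_families * self.targets_per_family > self.n_genes:
            raise ConfigError("disjoint target sets need n_families * targets_per_family <= n_genes")
        if self.noise_sigma <= 0:
            raise ConfigError("noise_sigma must be > 0")
        if not (0 < self.active_member_max_rank <= self.cargo_size):
            raise ConfigError("need 0 < active_member_max_rank <= cargo_size")
        if self.n_active > self.active_member_max_rank:
            raise ConfigError("more active members than top-rank slots")
        if self.cargo_size < self.n_families:
            raise ConfigError("cargo_size must be >= n_families (all members are carried)")
        n_decoys = self.cargo_size - self.n_families
        if n_decoys < self.active_member_max_rank - self.n_active:
            raise ConfigError("not enough decoy miRNAs to fill the top-rank block")

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigError(f"{path}: expected a mapping of config keys")
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ConfigError(f"{path}: unknown simulation keys {sorted(unknown)}")
        try:
            return cls(**data)
        except TypeError as exc:
            raise ConfigError(str(exc)) from None

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass(frozen=True)
class SyntheticDataset:
    """Generated inputs plus ground truth for recovery testing."""

    fc: FoldChangeTable
    predictions: TargetPredictionMap
    cargo: EVCargoProfile
    truth: frozenset  # active family ids
    config: SimulationConfig


def _member_id(family_index: int) -> str:
    return f"miR-sim{family_index + 1:03d}-5p"


def family_id_for(family_index: int) -> str:
    return f"fam{family_index + 1:03d}"


def generate_dataset(config: SimulationConfig) -> SyntheticDataset:
    """Generate one dataset under ``config``.

    Gene log fold changes are Normal(baseline_mu, noise_sigma^2); the union
    of active families' target genes is shifted by ``-effect_delta`` (shifted
    once even when an overlapping map assigns a gene to several active
    families). Each family has exactly one member miRNA. The cargo carries
    every family's member plus decoy miRNAs: active members at distinct
    random ranks within ``1..active_member_max_rank``, inactive members
    strictly below that block, decoys filling the rest; abundances are
    strictly positive draws assigned in rank order so the cargo reader
    reconstructs the planted ranks.
    """
    rng = np.random.default_rng(config.seed)

    # --- stream 1: genes -------------------------------------------------
    gene_ids = [f"gene{i + 1:05d}" for i in range(config.n_genes)]
    log_fc = rng.normal(config.baseline_mu, config.noise_sigma, config.n_genes)

    # --- stream 2: families ----------------------------------------------
    active_idx = np.sort(rng.choice(config.n_families, size=config.n_active, replace=False))
    active_set = set(int(i) for i in active_idx)
    family_targets = {}
    family_members = {}
    if config.overlap:
        target_idx = [rng.choice(config.n_genes, size=config.targets_per_family, replace=False)
                      for _ in range(config.n_families)]
    else:
        perm = rng.permutation(config.n_genes)
        target_idx = [perm[i * config.targets_per_family:(i + 1) * config.targets_per_family]
                      for i in range(config.n_families)]
    shifted: Set[int] = set()
    for i in range(config.n_families):
        fam = family_id_for(i)
        idx = target_idx[i]
        family_targets[fam] = frozenset(gene_ids[j] for j in idx)
        family_members[fam] = frozenset({_member_id(i)})
        if i in active_set:
            shifted.update(int(j) for j in idx)
    if shifted:
        shifted_arr = np.fromiter(shifted, dtype=int)
        log_fc[shifted_arr] -= config.effect_delta

    # --- stream 3: cargo --------------------------------------------------
    n_decoys = config.cargo_size - config.n_families
    decoy_ids = [f"miR-decoy{i + 1:03d}" for i in range(n_decoys)]
    ranks = np.empty(config.cargo_size, dtype=object)  # index = rank - 1
    top_slots = rng.choice(config.active_member_max_rank, size=config.n_active, replace=False)
    for slot, i in zip(top_slots, sorted(active_set)):
        ranks[slot] = _member_id(i)
    # fill the rest of the top block with decoys, everything below with
    # inactive members + remaining decoys, both in random order
    free_top = [r for r in range(config.active_member_max_rank) if ranks[r] is None]
    n_top_decoys = len(free_top)
    decoys_perm = list(rng.permutation(decoy_ids))
    for r, d in zip(free_top, decoys_perm[:n_top_decoys]):
        ranks[r] = d
    below = [_member_id(i) for i in range(config.n_families) if i not in active_set]
    below += decoys_perm[n_top_decoys:]
    below_order = rng.permutation(len(below))
    for offset, j in enumerate(below_order):
        ranks[config.active_member_max_rank + offset] = below[j]
    abundances = np.sort(rng.lognormal(mean=3.0, sigma=1.0, size=config.cargo_size))[::-1]

    fc = FoldChangeTable(pd.Series(log_fc, index=pd.Index(gene_ids, name="gene_id"),
                                   name="log_fc"))
    predictions = TargetPredictionMap(family_targets, family_members)
    cargo = EVCargoProfile.from_abundances(zip(ranks.tolist(), abundances))
    truth = frozenset(family_id_for(i) for i in active_set)
    return SyntheticDataset(fc=fc, predictions=predictions, cargo=cargo,
                            truth=truth, config=config)


def write_dataset(dataset: SyntheticDataset, out_dir) -> dict:
    """Write the dataset as the pipeline's input TSVs plus ``truth.tsv``.

    Returns a dict of the written paths keyed by role.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "fc": out / "fold_changes.tsv",
        "targets": out / "target_predictions.tsv",
        "members": out / "family_members.tsv",
        "cargo": out / "cargo.tsv",
        "truth": out / "truth.tsv",
    }
    fc_df = pd.DataFrame({"gene_id": dataset.fc.values.index,
                          "log_fc": [repr(v) for v in dataset.fc.values]})
    fc_df.to_csv(paths["fc"], sep="\t", index=False, lineterminator="\n")
    rows = [(fam, gene) for fam in sorted(dataset.predictions.family_targets)
            for gene in sorted(dataset.predictions.family_targets[fam])]
    pd.DataFrame(rows, columns=["family_id", "gene_id"]).to_csv(
        paths["targets"], sep="\t", index=False, lineterminator="\n")
    rows = [(fam, m) for fam in sorted(dataset.predictions.family_members)
            for m in sorted(dataset.predictions.family_members[fam])]
    pd.DataFrame(rows, columns=["family_id", "mirna_id"]).to_csv(
        paths["members"], sep="\t", index=False, lineterminator="\n")
    cargo_df = dataset.cargo.table.sort_values("rank")
    pd.DataFrame({"mirna_id": cargo_df["mirna_id"],
                  "abundance": [repr(v) for v in cargo_df["abundance"]]}).to_csv(
        paths["cargo"], sep="\t", index=False, lineterminator="\n")
    pd.DataFrame({"family_id": sorted(dataset.truth)}).to_csv(
        paths["truth"], sep="\t", index=False, lineterminator="\n")
    return paths


# ---------------------------------------------------------------------------
# Recovery and calibration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RecoveryMetrics:
    precision: float
    recall: float
    fdr_observed: float


def evaluate_recovery(
    selections: Sequence[CandidateSelection],
    truth: frozenset,
) -> RecoveryMetrics:
    """Score selected families against the planted truth.

    Forced includes are excluded from the counts. Conventions for empty
    denominators: precision is 1.0 when nothing was selected and the truth
    is empty (0.0 if truth is non-empty but nothing true could be claimed —
    an empty selection makes no false claims, so precision stays 1.0);
    recall is 1.0 when the truth is empty. ``fdr_observed`` is the fraction
    of selections outside the truth (0.0 when nothing was selected).
    """
    selected = {s.family_id for s in selections if s.provenance != "forced"}
    truth = frozenset(truth)
    tp = len(selected & truth)
    precision = tp / len(selected) if selected else 1.0
    recall = tp / len(truth) if truth else 1.0
    fdr = (len(selected) - tp) / len(selected) if selected else 0.0
    return RecoveryMetrics(precision=precision, recall=recall, fdr_observed=fdr)


@dataclass(frozen=True)
class CalibrationResult:
    """Per-family rejection rates across simulation replicates."""

    type1_rate: float
    power: float
    n_null_tests: int
    n_active_tests: int
    null_pvalues: np.ndarray
    active_pvalues: np.ndarray


def run_calibration(
    config: SimulationConfig,
    n_replicates: int,
    alpha: float = 0.05,
    alternative: str = "two-sided",
    min_targets: int = 5,
) -> CalibrationResult:
    """Estimate the scan's type-I error rate and power by simulation.

    Generates ``n_replicates`` independent datasets (replicate seeds spawned
    deterministically from ``config.seed``), scans each, and pools the
    family-level p-values: the type-I rate is the fraction of *inactive*
    families with p < alpha, power the same fraction among *active*
    families. With ``effect_delta=0`` every family is effectively null and
    the type-I rate is measured under the global null.
    """
    if n_replicates < 1:
        raise ConfigError("n_replicates must be >= 1")
    ss = np.random.SeedSequence(config.seed)
    child_seeds = [int(c.generate_state(1)[0] % (2 ** 31)) for c in ss.spawn(n_replicates)]
    null_p: List[float] = []
    active_p: List[float] = []
    for seed in child_seeds:
        ds = generate_dataset(dataclasses.replace(config, seed=seed))
        results = scan_families(ds.fc, ds.predictions, alternative=alternative,
                                min_targets=min_targets)
        for r in results:
            (active_p if r.family_id in ds.truth else null_p).append(r.p_value)
    null_arr = np.asarray(null_p)
    active_arr = np.asarray(active_p)
    type1 = float(np.mean(null_arr < alpha)) if null_arr.size else 0.0
    power = float(np.mean(active_arr < alpha)) if active_arr.size else 0.0
    return CalibrationResult(type1_rate=type1, power=power,
                             n_null_tests=null_arr.size, n_active_tests=active_arr.size,
                             null_pvalues=null_arr, active_pvalues=active_arr)
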