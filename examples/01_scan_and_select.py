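"""Full candidate-selection pipeline on a simulated dataset.

Builds a synthetic study — 2000 genes, 50 miRNA families, 5 of them "active"
(their predicted targets carry a 3-sigma downward log-fold-change shift and
their member miRNAs sit in the EV cargo top 50) — writes it as the pipeline's
input TSVs, runs scan -> significance filter -> cargo cross-match with a
forced include, and prints the rendered table and the recovered candidates.
"""

import tempfile
from pathlib import Path

from mirenrich import (RunConfig, SimulationConfig, evaluate_recovery,
                       generate_dataset, run_scan_pipeline, write_dataset)

workdir = Path(tempfile.mkdtemp(prefix="mirenrich_example_"))
dataset = generate_dataset(SimulationConfig(seed=11))
paths = write_dataset(dataset, workdir / "data")

out = run_scan_pipeline(RunConfig(
    fc_path=str(paths["fc"]),
    targets_path=str(paths["targets"]),
    members_path=str(paths["members"]),
    cargo_path=str(paths["cargo"]),
    out_dir=str(workdir / "run"),
    alpha=0.05, top_k=50,
    force_include=("miR-486-5p",),
))

print(f"Tested {len(out.results)} families; planted active families: "
      f"{sorted(dataset.truth)}\n")
print("Top of the scan table (medians 2 dp, p 4 dp, EV rank of candidates):")
table = Path(out.paths["table"]).read_text().splitlines()
print("\n".join(table[:8]))
print("\nCandidates (family, representative miRNA, p, EV rank, provenance):")
for c in out.candidates:
    p = "-" if c.p_value is None else f"{c.p_value:.2e}"
    rank = "-" if c.ev_rank is None else c.ev_rank
    print(f"  {c.family_id:<14} {c.representative_mirna:<16} p={p:<10} "
          f"rank={rank}  {c.provenance}")

m = evaluate_recovery(out.candidates, dataset.truth)
print(f"\nRecovery vs planted truth (forced entries excluded): "
      f"precision={m.precision:.2f} recall={m.recall:.2f}")
print("A precision and recall of 1.00 means the pipeline selected exactly "
      "the planted active families.")
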