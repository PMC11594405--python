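"""The whole census pipeline on a synthetic multi-fold study.

Emits ten folds with hinge amplitude rising from 0° to 30°, runs ingest →
align/extract → curate → metrics → group → census, and prints the fold
census ordered along the rigidity-to-heterogeneity spectrum.
"""

import json
import tempfile
from pathlib import Path

from foldflex import PipelineConfig, run_pipeline
from foldflex.synthdata import default_truths, emit_dataset

with tempfile.TemporaryDirectory() as tmp:
    tmp = Path(tmp)
    ds = emit_dataset(default_truths(seed=0), tmp / "data")
    cfg = PipelineConfig(
        structures_dir=str(tmp / "data/structures"),
        predicted_dir=str(tmp / "data/predicted"),
        domains_tsv=str(ds.domain_definitions),
        reference_fasta=str(ds.reference_fasta),
        annotations_tsv=str(ds.annotations),
        out_dir=str(tmp / "run"),
        compute_geometry=False,
        compute_sse=False,
    )
    result = run_pipeline(cfg)
    sigma = {g["topology_code"]: g["hinge_sigma_deg"]
             for g in json.loads(ds.manifest.read_text())["groups"]}

print("stage counts:", result.counts)
census = result.census["topology"].sort_values("rank_mad")
print("\nfold census, ordered by MAD (the heterogeneity spectrum):")
print(f"{'fold':>10} {'σ°':>5} {'n':>3} {'median':>7} {'MAD':>6} {'max':>6}")
for row in census.itertuples():
    print(f"{row.group_id:>10} {sigma[row.group_id]:5.1f} {row.n_instances:>3} "
          f"{row.median_rmsd:7.2f} {row.mad_rmsd:6.2f} {row.max_rmsd:6.2f}")
print("\n(rigid folds sit at the top with ~0.1 Å spread; planted hinge folds"
      "\n descend the spectrum with growing MAD and max RMSD, while every fold"
      "\n keeps one conformer at ~0 Å to the single-state reference)")
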