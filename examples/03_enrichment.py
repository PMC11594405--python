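"""Annotation enrichment between heterogeneous and consistent folds.

Emits a 10-fold dataset where the five most flexible folds carry a planted
annotation term, selects the heterogeneous/consistent protein sets, and
scores every term with the one-sided hypergeometric test.
"""

import json
import tempfile
from pathlib import Path

import pandas as pd

from foldflex import hypergeom_enrich
from foldflex.synthdata import default_truths, emit_dataset

with tempfile.TemporaryDirectory() as tmp:
    ds = emit_dataset(default_truths(seed=4), Path(tmp))
    manifest = json.loads(ds.manifest.read_text())
    threshold = manifest["het_sigma_threshold"]
    het = {g["protein_acc"] for g in manifest["groups"]
           if g["hinge_sigma_deg"] >= threshold}
    con = {g["protein_acc"] for g in manifest["groups"]} - het
    annotations = pd.read_csv(ds.annotations, sep="\t")

print(f"heterogeneous proteins (hinge σ ≥ {threshold}°): {sorted(het)}")
print(f"consistent proteins:                  {sorted(con)}")

for r in hypergeom_enrich(het, con, annotations):
    if r.direction == "het":
        print(f"  term {r.term!r}: {r.count_het}/{len(het)} het vs "
              f"{r.count_con}/{len(con)} con, p = {r.p_value:.2e} "
              f"(BH-adjusted {r.adjusted_p:.2e})")
print("(the planted term returns the exact 5-of-5 tail, 1/252 ≈ 4.0e-03;")
print(" background terms are not enriched)")
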