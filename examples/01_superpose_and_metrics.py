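"""Superpose conformers of one domain and read off its structural metrics.

Builds a 60-residue helix-bundle template, samples an ensemble of eight
conformers with a 20° hinge, and compares each to a single-state reference.
"""

import numpy as np

from foldflex import (
    geometry_metrics,
    rmsd100,
    superpose_instances,
)
from foldflex.synthdata import SyntheticGroundTruth, build_template, generate_ensemble, generate_prediction

template = build_template("helix-bundle", 60, seed=1)
truth = SyntheticGroundTruth("demo", hinge_sigma_deg=20.0, noise_sigma=0.1,
                             n_conformers=8, seed=7)
ensemble = generate_ensemble(template, truth)
reference = generate_prediction(template, ensemble, "pick_one", seed=3)

rmsds = []
for conf in ensemble:
    sup, _ = superpose_instances(conf, reference)
    rmsds.append(sup.rmsd)
    print(f"{conf.source}: rmsd {sup.rmsd:.2f} Å, rmsd100 {rmsd100(sup.rmsd, conf.n_res):.2f} Å")

print(f"\nmedian rmsd {np.median(rmsds):.2f} Å over {len(rmsds)} conformers")
print("(one conformer sits at ~0 Å: the reference is a copy of a single state)")

geom = geometry_metrics(template)
print(f"\ntemplate compactness: AV ratio {geom.av_ratio:.2f} 1/Å, "
      f"BE ratio {geom.be_ratio:.2f}")
print("(low surface-to-volume and high buried-to-exposed = compact globular fold)")
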