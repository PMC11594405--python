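# foldflex

A census of fold-dependent conformational heterogeneity in protein domains,
measured against a single predicted reference structure.

Structure-prediction models return one conformation per sequence, while
experiments routinely capture the same domain in many functional states.
`foldflex` is for structural bioinformaticians who want to quantify, fold by
fold, how much of that experimentally measured heterogeneity a single
reference structure fails to represent: it harmonizes experimental
structures, extracts CATH-style domain instances from both experiments and
full-length predicted models, superposes every experimental conformer onto
its predicted counterpart, and aggregates the deviations into a per-fold
rigidity-versus-heterogeneity spectrum with downstream biological analyses
(switch-region conformational clustering and annotation enrichment).

## The statistics at the core

For each domain instance, the CA coordinates of the residues mapped
one-on-one to the reference (by a glocal alignment: global in the domain,
free end gaps in the full-length protein; BLOSUM62, gap open 10, extend 0.2)
are superposed by the Kabsch least-squares rotation, giving

- **RMSD** — root-mean-square deviation over mapped CA atoms (Å);
- **RMSD100** — length-normalized deviation, `RMSD / (1 + ln √(N/100))`,
  comparable across domain sizes;
- per-fold robust summaries — median, **MAD** (`1.4826 · median|x − x̃|`, a
  robust standard deviation), IQR, min/max, and tier fractions (share of
  instances within 2.5 Å and 5 Å);
- compactness and environment metrics per instance — Shrake–Rupley SASA,
  van der Waals volume, the surface-to-volume ratio (AVratio),
  buried-to-exposed residue ratio (BEratio, relative-SASA cutoff 0.25),
  metal/ligand contact counts, and hydrogen-bond-based secondary-structure
  content;
- region-restricted RMSDs under the whole-domain superposition for mobile
  regions (e.g. GTPase switch I/II), clustered in the 2D RMSD plane (Ward
  linkage, silhouette-selected k);
- one-sided hypergeometric enrichment (with Benjamini–Hochberg adjustment)
  of annotation terms between proteins owning heterogeneous folds
  (median RMSD > 2.5 Å) and proteins owning folds from the lowest decile
  of median RMSD.

Because no benchmark accessions ship with the package, a first-class
synthetic-data module generates complete studies: ideal-geometry templates,
hinge-motion conformer ensembles with controlled amplitude and thermal
noise, single-state (`pick_one`) or conformational-average (`average`)
references with mock pLDDT, domain tables, FASTA, and annotation tables
with planted terms — all seeded and reproducible.

## Worked example

`examples/04_full_pipeline.py` emits ten synthetic folds whose hinge
amplitude σ rises from 0° to 30° (12 conformers each), runs the full
pipeline, and prints the fold census ordered by MAD:

```
fold census, ordered by MAD (the heterogeneity spectrum):
      fold    σ°   n  median    MAD    max
    1.10.1   0.0  12    0.25   0.01   0.27
    2.20.2   3.3  12    0.25   0.04   0.35
    3.30.3   6.7  12    0.49   0.33   0.99
    2.10.5  13.3  12    0.51   0.37   1.85
    1.40.4  10.0  12    0.72   0.42   1.27
   1.20.10  30.0  12    2.24   0.69   4.27
    1.30.7  20.0  12    1.03   0.82   3.04
    3.20.6  16.7  12    2.24   0.85   3.59
    2.40.8  23.3  12    1.40   1.11   2.79
    3.10.9  26.7  12    1.45   1.12   3.86
```

Rigid folds (σ ≈ 0) sit at the top with ~0.1 Å spread; the planted hinge
folds descend the spectrum with growing MAD and max RMSD. Every fold keeps
one conformer at ~0 Å because the single-state reference is a copy of one
experimental state — the reference is specific, not an average. The other
examples demonstrate per-instance metrics (`01`), six-pattern switch
clustering where 120 conformers split into the six planted open/closed
combinations (`02`), and planted-term enrichment recovering the exact
5-of-5 hypergeometric tail, p = 1/252 (`03`).

A thin CLI wraps the same pipeline for shell use:

```sh
foldflex simulate data --groups 10 --conformers 12 --seed 0
foldflex run-all config.yaml
```

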