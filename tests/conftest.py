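"""Shared fixtures: tiny handcrafted structures and seeded synthetic datasets."""

from __future__ import annotations

import json

import numpy as np
import pytest

from foldflex import pipeline as pl
from foldflex import synthdata as sd
from foldflex.structio import (
    AtomRecord,
    DomainDefinition,
    DomainInstance,
    ResidueRecord,
)

PDB_3RES = """\
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00 10.00           N
ATOM      2  CA  ALA A   1       1.458   0.000   0.000  1.00 10.00           C
ATOM      3  C   ALA A   1       2.009   1.420   0.000  1.00 10.00           C
ATOM      4  O   ALA A   1       1.251   2.390   0.000  1.00 10.00           O
ATOM      5  N   GLY A   2       3.332   1.536   0.000  1.00 11.00           N
ATOM      6  CA  GLY A   2       3.988   2.839   0.100  1.00 11.00           C
ATOM      7  C   GLY A   2       5.504   2.693   0.200  1.00 11.00           C
ATOM      8  O   GLY A   2       6.029   1.580   0.300  1.00 11.00           O
ATOM      9  N   SER A   3       6.189   3.829   0.200  1.00 12.00           N
ATOM     10  CA  SER A   3       7.644   3.849   0.300  1.00 12.00           C
ATOM     11  C   SER A   3       8.208   5.264   0.400  1.00 12.00           C
ATOM     12  O   SER A   3       7.467   6.247   0.400  1.00 12.00           O
TER
END
"""

@pytest.fixture()
def pdb_3res(tmp_path):
    p = tmp_path / "fix3.pdb"
    p.write_text(PDB_3RES)
    return p


@pytest.fixture()
def cif_3res(tmp_path, pdb_3res):
    """The same three residues converted to mmCIF (via gemmi)."""
    import gemmi

    st = gemmi.read_structure(str(pdb_3res))
    st.setup_entities()
    p = tmp_path / "fix3.cif"
    st.make_mmcif_document().write_file(str(p))
    return p


@pytest.fixture()
def pdb_3res_with_mg(tmp_path):
    text = PDB_3RES.replace(
        "TER\n",
        "TER\nHETATM   13 MG    MG A 101       3.000   1.500   2.000  1.00 20.00          MG\n",
    )
    p = tmp_path / "fix3mg.pdb"
    p.write_text(text)
    return p


def make_chain_instance(n: int = 10, start: int = 1, acc: str = "P1") -> DomainInstance:
    """Straight CA-trace chain with one atom per residue, 3.8 Å spacing."""
    residues = [
        ResidueRecord("A", str(start + i), "A",
                      [AtomRecord("CA", "C", [3.8 * i, 0.0, 0.0])])
        for i in range(n)
    ]
    d = DomainDefinition(f"{acc}D1", "1.10.8.10",
                         [("A", str(start), str(start + n - 1))], acc)
    return DomainInstance(d, f"{acc}s1", residues)


@pytest.fixture(scope="session")
def sigma_ramp_run(tmp_path_factory):
    """The default σ-ramp study: 10 folds, σ 0..30°, 12 conformers, seed 0.

    Runs the full pipeline once per session (geometry/SSE off: the census
    RMSD statistics do not use them) and returns (pipeline result, manifest).
    """
    tmp = tmp_path_factory.mktemp("ramp")
    truths = sd.default_truths()
    ds = sd.emit_dataset(truths, tmp / "data")
    cfg = pl.PipelineConfig(
        structures_dir=str(tmp / "data/structures"),
        predicted_dir=str(tmp / "data/predicted"),
        domains_tsv=str(ds.domain_definitions),
        reference_fasta=str(ds.reference_fasta),
        annotations_tsv=str(ds.annotations),
        out_dir=str(tmp / "run"),
        compute_geometry=False,
        compute_sse=False,
    )
    result = pl.run_pipeline(cfg)
    manifest = json.loads(ds.manifest.read_text())
    return result, manifest


def hungarian_agreement(true_labels, pred_labels) -> float:
    """Best one-to-one label-mapping agreement fraction."""
    from scipy.optimize import linear_sum_assignment

    true_labels = np.asarray(true_labels)
    pred_labels = np.asarray(pred_labels)
    k = max(true_labels.max(), pred_labels.max()) + 1
    conf = np.zeros((k, k))
    for a, b in zip(true_labels, pred_labels):
        conf[a, b] += 1
    r, c = linear_sum_assignment(-conf)
    return float(conf[r, c].sum() / len(true_labels))
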