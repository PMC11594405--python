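"""Synthetic multi-conformer datasets with controlled heterogeneity.

Builds ideal-geometry peptide backbones (N, CA, C, O plus CB) from φ/ψ
dihedrals, turns them into multi-conformer ensembles by rotating a segment
about a hinge axis (angle drawn per conformer from N(0, σ)) plus isotropic
thermal noise on every atom, and derives a "predicted" reference either as
a copy of one conformer (``pick_one`` — emulating a predictor locked to a
single experimental state) or as the per-atom coordinate average
(``average`` — a hypothetical conformational-average predictor). A mock
per-residue pLDDT (90 minus a term growing with local ensemble spread,
clipped to [50, 99]) is written into the B-factor column of predictions.

The emitted datasets carry everything the pipeline ingests — conformer PDB
files, full-length predicted models with flanking residues (so the glocal
alignment step is exercised), domain-definition tables, reference FASTA and
protein→term annotation tables — plus a JSON manifest of the hidden
generator parameters for parameter-recovery tests.

The hinge motion deliberately ignores loop closure: the rotated segment is
rigid and the chain may be geometrically strained at the hinge. Side chains
are limited to CB. These fixtures emulate the statistical structure of real
ensembles (fold-dependent spread, one-state vs average references), not
their physics.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .structio import (
    AtomRecord,
    DomainDefinition,
    DomainInstance,
    ResidueRecord,
    write_domain_pdb,
    write_fasta,
)

# ideal backbone geometry (lengths Å, angles deg)
_B_N_CA, _B_CA_C, _B_C_N, _B_C_O, _B_CA_CB = 1.458, 1.525, 1.329, 1.231, 1.530
_A_N_CA_C, _A_CA_C_N, _A_C_N_CA, _A_CA_C_O = 111.2, 116.2, 121.7, 120.5
_OMEGA = 180.0

HELIX_PHI_PSI = (-57.0, -47.0)
STRAND_PHI_PSI = (-119.0, 113.0)
LOOP_PHI_PSI = (-75.0, 150.0)

_SEQ_POOL = "ADEFIKLNQRSTVY"

TEMPLATE_KINDS = ("helix-bundle", "sheet-sandwich", "mixed", "extended")


@dataclass
class SyntheticGroundTruth:
    """Hidden parameters of one synthetic domain group."""

    group_id: str
    template_kind: str = "helix-bundle"
    n_res: int = 60
    #: rotated segment, 1-based inclusive; the default is an internal window
    #: of about a quarter of the domain starting at the midpoint, so the
    #: fixed majority anchors the superposition and hinge motion is not
    #: mistaken for an extended terminus by the curation filters
    hinge_residues: tuple[int, int] | None = None
    hinge_sigma_deg: float = 0.0
    noise_sigma: float = 0.1
    n_conformers: int = 12
    prediction_mode: str = "pick_one"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.hinge_sigma_deg < 0 or self.noise_sigma < 0 or self.n_conformers < 1:
            raise ValueError("hinge_sigma_deg, noise_sigma >= 0 and n_conformers >= 1")
        if self.template_kind not in TEMPLATE_KINDS:
            raise ValueError(f"unknown template kind {self.template_kind!r}")
        if self.hinge_residues is None:
            start = self.n_res // 2 + 1
            self.hinge_residues = (start, min(start + 11, self.n_res))


@dataclass
class SyntheticDataset:
    """File locations plus the ground truth of an emitted dataset."""

    root: Path
    structure_files: list[Path]
    predicted_files: list[Path]
    domain_definitions: Path
    reference_fasta: Path
    annotations: Path
    manifest: Path
    truth: list[SyntheticGroundTruth]


# ---------------------------------------------------------------------------
# backbone construction


def _nerf(a: np.ndarray, b: np.ndarray, c: np.ndarray,
          bond: float, angle_deg: float, dihedral_deg: float) -> np.ndarray:
    """Place atom D from A-B-C with |CD|=bond, ∠BCD=angle, τ(ABCD)=dihedral."""
    ang = np.deg2rad(angle_deg)
    tor = np.deg2rad(dihedral_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = bond * np.array(
        [-np.cos(ang), np.sin(ang) * np.cos(tor), np.sin(ang) * np.sin(tor)]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def build_backbone(
    phi_psi: list[tuple[float, float]],
    seq: str,
    start_num: int = 1,
    chain_id: str = "A",
) -> list[ResidueRecord]:
    """Residues with ideal N/CA/C/O (+CB for non-Gly) geometry from dihedrals."""
    n = len(phi_psi)
    if len(seq) != n:
        raise ValueError("sequence and dihedral list lengths differ")
    coords_n, coords_ca, coords_c = [], [], []
    coords_n.append(np.zeros(3))
    coords_ca.append(np.array([_B_N_CA, 0.0, 0.0]))
    ang = np.deg2rad(180.0 - _A_N_CA_C)
    coords_c.append(coords_ca[0] + _B_CA_C * np.array([np.cos(ang), np.sin(ang), 0.0]))
    for i in range(1, n):
        psi_prev = phi_psi[i - 1][1]
        ni = _nerf(coords_n[i - 1], coords_ca[i - 1], coords_c[i - 1],
                   _B_C_N, _A_CA_C_N, psi_prev)
        cai = _nerf(coords_ca[i - 1], coords_c[i - 1], ni, _B_N_CA, _A_C_N_CA, _OMEGA)
        ci = _nerf(coords_c[i - 1], ni, cai, _B_CA_C, _A_N_CA_C, phi_psi[i][0])
        coords_n.append(ni)
        coords_ca.append(cai)
        coords_c.append(ci)
    residues = []
    for i in range(n):
        psi = phi_psi[i][1] if i < n - 1 else 180.0
        o = _nerf(coords_n[i], coords_ca[i], coords_c[i], _B_C_O, _A_CA_C_O, psi - 180.0)
        atoms = [
            AtomRecord("N", "N", coords_n[i]),
            AtomRecord("CA", "C", coords_ca[i]),
            AtomRecord("C", "C", coords_c[i]),
            AtomRecord("O", "O", o),
        ]
        if seq[i] != "G":
            cb = _nerf(coords_c[i], coords_n[i], coords_ca[i], _B_CA_CB, 110.1, 122.6)
            atoms.append(AtomRecord("CB", "C", cb))
        residues.append(ResidueRecord(chain_id, str(start_num + i), seq[i], atoms))
    return residues


def _segment_plan(kind: str, n_res: int) -> list[tuple[float, float]]:
    if kind == "extended":
        return [STRAND_PHI_PSI] * n_res
    if kind == "helix-bundle":
        block = [HELIX_PHI_PSI] * 13 + [LOOP_PHI_PSI, (-60.0, 130.0), (80.0, 10.0),
                                        LOOP_PHI_PSI]
    elif kind == "sheet-sandwich":
        block = [STRAND_PHI_PSI] * 6 + [(-60.0, -30.0), (80.0, 10.0), LOOP_PHI_PSI]
    else:  # mixed
        block = ([HELIX_PHI_PSI] * 10 + [LOOP_PHI_PSI, (80.0, 10.0)]
                 + [STRAND_PHI_PSI] * 5 + [LOOP_PHI_PSI, (-60.0, 130.0)])
    out: list[tuple[float, float]] = []
    while len(out) < n_res:
        out.extend(block)
    return out[:n_res]


def _random_sequence(n: int, rng: np.random.Generator) -> str:
    return "".join(rng.choice(list(_SEQ_POOL), size=n))


def build_template(
    kind: str,
    n_res: int,
    seed: int = 0,
    start_num: int = 1,
    protein_acc: str = "SYN00001",
    domain_id: str | None = None,
    cath_code: str = "1.10.1.10",
) -> DomainInstance:
    """Deterministic ideal-geometry template domain of the given fold kind."""
    if n_res < 20:
        raise ValueError("n_res must be >= 20")
    rng = np.random.default_rng(seed)
    seq = _random_sequence(n_res, rng)
    residues = build_backbone(_segment_plan(kind, n_res), seq, start_num=start_num)
    definition = DomainDefinition(
        domain_id=domain_id or f"{protein_acc}D1",
        cath_code=cath_code,
        segments=[("A", str(start_num), str(start_num + n_res - 1))],
        protein_acc=protein_acc,
    )
    return DomainInstance(definition=definition, source=f"{protein_acc}_tmpl",
                          residues=residues)


def build_antiparallel_sheet(
    n_per_strand: int = 8,
    offset_perp: float = 3.75,
    offset_axial: float = 3.5,
    phi_psi: tuple[float, float] = (-140.0, 135.0),
) -> DomainInstance:
    """Two antiparallel ideal strands placed for backbone hydrogen bonding.

    A geometric fixture (the two strands are not covalently connected): a
    flat-sheet strand (φ −140°, ψ 135°) and its proper 180° rotation about
    the axis perpendicular to both the strand direction and the sheet
    normal, translated sideways into hydrogen-bonding register.
    """
    seq = "V" * n_per_strand
    strand = build_backbone([phi_psi] * n_per_strand, seq)
    ca = np.array([r.ca.coords for r in strand])
    # strand axis by least squares through the CAs
    center = ca.mean(axis=0)
    axis = np.linalg.svd(ca - center)[2][0]
    axis /= np.linalg.norm(axis)
    perp = np.cross(axis, [0.0, 0.0, 1.0])
    if np.linalg.norm(perp) < 1e-6:
        perp = np.cross(axis, [0.0, 1.0, 0.0])
    perp /= np.linalg.norm(perp)
    k = np.cross(axis, perp)
    k /= np.linalg.norm(k)

    def rot180(v: np.ndarray) -> np.ndarray:
        return 2.0 * np.outer(k, k) @ v - v  # proper rotation by π about k

    partner = []
    shift = center + offset_perp * perp + offset_axial * axis
    for r in reversed(strand):
        atoms = [
            AtomRecord(a.name, a.element, rot180(a.coords - center) + shift)
            for a in r.atoms
        ]
        partner.append(ResidueRecord("A", str(int(r.seq_label) + n_per_strand + 10),
                                     r.aa, atoms))
    residues = strand + partner
    definition = DomainDefinition(
        domain_id="SHEETD1", cath_code="2.40.1.10",
        segments=[("A", "1", str(2 * n_per_strand + 10))], protein_acc="SHEET001",
    )
    return DomainInstance(definition=definition, source="sheet_fixture",
                          residues=residues)


# ---------------------------------------------------------------------------
# conformer generation


def clone_instance(inst: DomainInstance, source: str | None = None) -> DomainInstance:
    residues = [
        ResidueRecord(
            r.chain_id, r.seq_label, r.aa,
            [AtomRecord(a.name, a.element, a.coords.copy(), a.occupancy, a.bfactor,
                        a.is_hetero) for a in r.atoms],
        )
        for r in inst.residues
    ]
    return DomainInstance(
        definition=inst.definition,
        source=source or inst.source,
        residues=residues,
        is_predicted=inst.is_predicted,
        resolution=inst.resolution,
        method=inst.method,
    )


def rotate_segment(
    inst: DomainInstance, start: int, end: int, angle_deg: float
) -> DomainInstance:
    """Rigidly rotate residues ``start..end`` (1-based within the domain)
    about the CA(start-1)→CA(start) axis through CA(start).

    ``start=1`` pivots about the first CA using the CA(1)→CA(2) direction.
    """
    out = clone_instance(inst)
    i0 = max(start - 1, 0)
    if start > 1:
        axis = inst.residues[i0].ca.coords - inst.residues[i0 - 1].ca.coords
    else:
        axis = inst.residues[1].ca.coords - inst.residues[0].ca.coords
    axis = axis / np.linalg.norm(axis)
    pivot = inst.residues[i0].ca.coords
    theta = np.deg2rad(angle_deg)
    k = axis
    kx = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
    rot = np.eye(3) + np.sin(theta) * kx + (1 - np.cos(theta)) * (kx @ kx)
    for res in out.residues[start - 1 : end]:
        for atom in res.atoms:
            atom.coords = rot @ (atom.coords - pivot) + pivot
    return out


def _add_noise(inst: DomainInstance, sigma: float, rng: np.random.Generator) -> None:
    if sigma <= 0:
        return
    for res in inst.residues:
        for atom in res.atoms:
            atom.coords = atom.coords + rng.normal(0.0, sigma, 3)


def generate_ensemble(
    template: DomainInstance, truth: SyntheticGroundTruth
) -> list[DomainInstance]:
    """Seeded conformer ensemble: hinge rotation ~ N(0, σ) plus thermal noise."""
    rng = np.random.default_rng(truth.seed)
    start, end = truth.hinge_residues
    out = []
    for i in range(truth.n_conformers):
        angle = rng.normal(0.0, truth.hinge_sigma_deg) if truth.hinge_sigma_deg > 0 else 0.0
        conf = rotate_segment(template, start, end, angle)
        _add_noise(conf, truth.noise_sigma, rng)
        conf.source = f"{truth.group_id}x{i:03d}"
        conf.resolution = float(rng.uniform(1.5, 2.5))
        conf.method = "X-RAY DIFFRACTION"
        out.append(conf)
    return out


def generate_prediction(
    template: DomainInstance,
    ensemble: list[DomainInstance],
    mode: str = "pick_one",
    seed: int = 0,
    plddt_scale: float = 8.0,
) -> DomainInstance:
    """Synthetic "predicted" reference for an ensemble.

    ``pick_one`` deep-copies a seeded-random conformer; ``average`` takes
    the per-atom coordinate mean. pLDDT is written per residue as
    clip(90 − scale × ensemble CA spread, 50, 99).
    """
    if not ensemble:
        raise ValueError("ensemble is empty")
    rng = np.random.default_rng(seed)
    if mode == "pick_one":
        pred = clone_instance(ensemble[int(rng.integers(len(ensemble)))])
    elif mode == "average":
        pred = clone_instance(ensemble[0])
        for ri, res in enumerate(pred.residues):
            for ai, atom in enumerate(res.atoms):
                atom.coords = np.mean(
                    [e.residues[ri].atoms[ai].coords for e in ensemble], axis=0
                )
    else:
        raise ValueError(f"unknown prediction mode {mode!r}")
    ca_stack = np.array([[r.ca.coords for r in e.residues] for e in ensemble])
    spread = np.sqrt(np.mean(np.sum(
        (ca_stack - ca_stack.mean(axis=0)) ** 2, axis=2), axis=0))
    plddt = np.clip(90.0 - plddt_scale * spread, 50.0, 99.0)
    for res, v in zip(pred.residues, plddt):
        for atom in res.atoms:
            atom.bfactor = float(v)
    pred.is_predicted = True
    pred.resolution = None
    pred.method = "PREDICTED"
    pred.source = f"{template.definition.protein_acc}_pred"
    return pred


def generate_switch_ensemble(
    template: DomainInstance,
    region1: tuple[int, int],
    region2: tuple[int, int],
    pattern_angles: list[tuple[float, float]] | None = None,
    n_per_pattern: int = 12,
    jitter_deg: float = 1.0,
    noise_sigma: float = 0.08,
    seed: int = 0,
) -> tuple[list[DomainInstance], list[int]]:
    """Conformers planted on discrete two-region conformational archetypes.

    ``region1``/``region2`` are 1-based inclusive residue windows within the
    domain; each archetype is a pair of hinge angles (deg) applied to the
    two regions. Defaults plant six patterns: both closed, three levels of
    region-2 opening with region 1 closed, region 1 open with region 2
    closed, and both open. Returns the conformers and their archetype index.
    """
    if pattern_angles is None:
        pattern_angles = [(0, 0), (0, 8), (0, 16), (16, 0), (16, 16), (8, 8)]
    rng = np.random.default_rng(seed)
    out, labels = [], []
    idx = 0
    for p, (a1, a2) in enumerate(pattern_angles):
        for _ in range(n_per_pattern):
            conf = rotate_segment(template, region1[0], region1[1],
                                  a1 + rng.normal(0.0, jitter_deg))
            conf = rotate_segment(conf, region2[0], region2[1],
                                  a2 + rng.normal(0.0, jitter_deg))
            _add_noise(conf, noise_sigma, rng)
            conf.source = f"{template.definition.protein_acc}s{idx:03d}"
            conf.resolution = float(rng.uniform(1.5, 2.5))
            conf.method = "X-RAY DIFFRACTION"
            out.append(conf)
            labels.append(p)
            idx += 1
    return out, labels


# ---------------------------------------------------------------------------
# dataset emission


def default_truths(
    n_groups: int = 10,
    sigma_max: float = 30.0,
    n_conformers: int = 12,
    noise_sigma: float = 0.1,
    prediction_mode: str = "pick_one",
    seed: int = 0,
    n_res: int = 60,
    kinds: tuple[str, ...] = ("helix-bundle",),
) -> list[SyntheticGroundTruth]:
    """Groups with hinge σ increasing linearly 0..σ_max.

    All groups share one template kind by default so the hinge lever
    geometry is identical across groups and the σ ramp is the only varying
    factor; pass several ``kinds`` to cycle fold types instead.
    """
    sigmas = np.linspace(0.0, sigma_max, n_groups)
    return [
        SyntheticGroundTruth(
            group_id=f"G{i:02d}",
            template_kind=kinds[i % len(kinds)],
            n_res=n_res,
            hinge_sigma_deg=float(s),
            noise_sigma=noise_sigma,
            n_conformers=n_conformers,
            prediction_mode=prediction_mode,
            seed=seed * 100003 + i,
        )
        for i, s in enumerate(sigmas)
    ]


def emit_dataset(
    truths: list[SyntheticGroundTruth],
    out_dir,
    flank: int = 8,
    planted_terms: tuple[str, ...] = ("switch_signalling",),
    het_sigma_threshold: float = 15.0,
    background_terms: tuple[str, ...] = ("housekeeping", "binding", "transport"),
) -> SyntheticDataset:
    """Write a complete pipeline-ready dataset to ``out_dir``.

    Per group: one protein accession, ``n_conformers`` experimental PDB
    files covering the domain window, one full-length predicted model with
    ``flank`` loop residues on each side and pLDDT in the B-factor column.
    Plus domains.tsv, references.fasta, annotations.tsv (planted terms on
    every group with hinge σ ≥ ``het_sigma_threshold``; background terms on
    all proteins) and manifest.json with the ground truth.
    """
    ids = [t.group_id for t in truths]
    if len(set(ids)) != len(ids):
        raise ValueError("group ids must be unique")
    root = Path(out_dir)
    (root / "structures").mkdir(parents=True, exist_ok=True)
    (root / "predicted").mkdir(parents=True, exist_ok=True)
    structure_files, predicted_files = [], []
    def_rows, fasta, ann_rows = [], {}, []
    for gi, truth in enumerate(truths):
        acc = f"SYN{gi:05d}"
        rng = np.random.default_rng(truth.seed + 7919)
        # full-length template: flank + domain + flank, numbered from 1
        n_total = truth.n_res + 2 * flank
        seq = _random_sequence(n_total, np.random.default_rng(truth.seed))
        plan = ([LOOP_PHI_PSI] * flank
                + _segment_plan(truth.template_kind, truth.n_res)
                + [LOOP_PHI_PSI] * flank)
        full_res = build_backbone(plan, seq)
        definition = DomainDefinition(
            domain_id=f"{acc}D1",
            cath_code=f"{1 + gi % 3}.{10 * (1 + gi % 4)}.{gi + 1}.10",
            segments=[("A", str(flank + 1), str(flank + truth.n_res))],
            protein_acc=acc,
        )
        template = DomainInstance(
            definition=definition, source=f"{acc}tmpl",
            residues=full_res[flank : flank + truth.n_res],
        )
        ensemble = generate_ensemble(template, truth)
        pred_domain = generate_prediction(
            template, ensemble, truth.prediction_mode, seed=truth.seed + 13
        )
        for ci, conf in enumerate(ensemble):
            conf.source = f"{acc}x{ci:03d}"  # accession prefix routes files to proteins
            path = root / "structures" / f"{conf.source}.pdb"
            write_domain_pdb(conf, path)
            structure_files.append(path)
        # full predicted model with flanks (flank pLDDT = 60: generic loops)
        flank_res = [full_res[i] for i in list(range(flank)) + list(
            range(flank + truth.n_res, n_total))]
        for r in flank_res:
            for a in r.atoms:
                a.bfactor = 60.0
        model_inst = DomainInstance(
            definition=definition, source=acc,
            residues=full_res[:flank] + pred_domain.residues + full_res[flank + truth.n_res:],
            is_predicted=True,
        )
        ppath = root / "predicted" / f"{acc}.pdb"
        write_domain_pdb(model_inst, ppath)
        predicted_files.append(ppath)
        def_rows.append(
            {
                "domain_id": definition.domain_id,
                "cath_code": definition.cath_code,
                "protein_acc": acc,
                "segments": f"A:{flank + 1}-{flank + truth.n_res}",
            }
        )
        fasta[acc] = seq
        terms = list(background_terms[: 1 + gi % len(background_terms)])
        if truth.hinge_sigma_deg >= het_sigma_threshold:
            terms.extend(planted_terms)
        for term in terms:
            ann_rows.append({"protein_acc": acc, "term": term})
    import pandas as pd

    dom_path = root / "domains.tsv"
    pd.DataFrame(def_rows).to_csv(dom_path, sep="\t", index=False)
    fasta_path = root / "references.fasta"
    write_fasta(fasta, fasta_path)
    ann_path = root / "annotations.tsv"
    pd.DataFrame(ann_rows).to_csv(ann_path, sep="\t", index=False)
    manifest_path = root / "manifest.json"
    group_entries = []
    for gi, t in enumerate(truths):
        entry = asdict(t)
        entry["protein_acc"] = f"SYN{gi:05d}"
        entry["cath_code"] = def_rows[gi]["cath_code"]
        entry["topology_code"] = ".".join(def_rows[gi]["cath_code"].split(".")[:3])
        group_entries.append(entry)
    with open(manifest_path, "w") as fh:
        json.dump(
            {"groups": group_entries, "flank": flank,
             "planted_terms": list(planted_terms),
             "het_sigma_threshold": het_sigma_threshold},
            fh, indent=2, sort_keys=True,
        )
    return SyntheticDataset(
        root=root,
        structure_files=structure_files,
        predicted_files=predicted_files,
        domain_definitions=dom_path,
        reference_fasta=fasta_path,
        annotations=ann_path,
        manifest=manifest_path,
        truth=truths,
    )
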