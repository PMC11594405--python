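"""Superposition and per-instance structural metrics.

Implements the geometric core of the census:

* Kabsch least-squares rigid superposition of matched CA sets, with RMSD and
  the length-normalized RMSD100 = rmsd / (1 + ln sqrt(n/100));
* region-restricted RMSD under an already-fixed global superposition (used
  for switch-region analyses);
* a deterministic Shrake–Rupley solvent-accessible surface area with
  golden-spiral sphere points;
* union-of-spheres van der Waals volume by voxel counting;
* buried/exposed residue classification by relative SASA (threshold 0.25)
  and the buried-to-exposed ratio (BEratio);
* metal/ligand residue contact counts (nMet, nLig);
* a hydrogen-bond (Kabsch–Sander-style) secondary-structure assignment with
  helix/sheet content and the prediction-vs-experiment SSE count difference.

RMSD is computed over CA atoms of the mapped residue intersection: robust to
side-chain noise and to residues unresolved in experiments.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .structio import DomainInstance, HetGroup

# ---------------------------------------------------------------------------
# superposition

@dataclass
class SuperpositionResult:
    """Optimal rigid-body fit of two matched coordinate sets."""

    rotation: np.ndarray  # 3x3, det +1
    translation: np.ndarray
    rmsd: float
    rmsd100: float | None
    n_atoms: int

    def apply(self, coords: np.ndarray) -> np.ndarray:
        """Map mobile-frame coordinates into the reference frame."""
        return coords @ self.rotation.T + self.translation


def kabsch_superpose(
    coords_a: np.ndarray, coords_b: np.ndarray, n_res: int | None = None
) -> SuperpositionResult:
    """Least-squares superpose ``coords_a`` (mobile) onto ``coords_b``.

    Proper rotation only (reflections corrected). ``n_res`` defaults to the
    number of points and feeds the RMSD100 normalization.
    """
    a = np.asarray(coords_a, float)
    b = np.asarray(coords_b, float)
    if a.shape != b.shape:
        raise ValueError(f"coordinate sets differ in shape: {a.shape} vs {b.shape}")
    if a.ndim != 2 or a.shape[1] != 3 or a.shape[0] < 3:
        raise ValueError("need >= 3 matched 3D points")
    ca, cb = a.mean(axis=0), b.mean(axis=0)
    a0, b0 = a - ca, b - cb
    h = a0.T @ b0
    u, s, vt = np.linalg.svd(h)
    if s[1] < 1e-10 * max(s[0], 1.0):
        raise ValueError("degenerate (collinear) point set")
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    trans = cb - rot @ ca
    diff = a0 @ rot.T - b0
    rmsd = float(np.sqrt(np.mean(np.sum(diff * diff, axis=1))))
    n = n_res if n_res is not None else a.shape[0]
    return SuperpositionResult(
        rotation=rot,
        translation=trans,
        rmsd=rmsd,
        rmsd100=rmsd100(rmsd, n),
        n_atoms=a.shape[0],
    )


def superpose_instances(
    inst: DomainInstance,
    ref: DomainInstance,
    pairs: list[tuple[int, int]] | None = None,
) -> tuple[SuperpositionResult, list[tuple[int, int]]]:
    """Superpose two instances over their CA-bearing mapped residues.

    Without an explicit residue map the instances are paired positionally.
    Returns the fit plus the residue pairs actually used.
    """
    if pairs is None:
        n = min(inst.n_res, ref.n_res)
        pairs = [(i, i) for i in range(n)]
    used = [
        (i, j)
        for i, j in pairs
        if inst.residues[i].ca is not None and ref.residues[j].ca is not None
    ]
    a = np.array([inst.residues[i].ca.coords for i, _ in used])
    b = np.array([ref.residues[j].ca.coords for _, j in used])
    return kabsch_superpose(a, b), used


def rmsd100(rmsd: float, n: int) -> float | None:
    """Length-normalized RMSD: rmsd / (1 + ln sqrt(n/100)).

    Comparable across domain sizes. For very short domains (n <= 13) the
    denominator is non-positive and the value is undefined (returns None).
    """
    if n < 1 or rmsd < 0:
        raise ValueError("need n >= 1 and rmsd >= 0")
    denom = 1.0 + math.log(math.sqrt(n / 100.0))
    if denom <= 0:
        return None
    return rmsd / denom


def region_rmsd(
    sup: SuperpositionResult,
    inst: DomainInstance,
    ref: DomainInstance,
    pairs: list[tuple[int, int]],
    region: tuple[int, int],
) -> float | None:
    """RMSD over a residue-number window, without refitting.

    ``region`` is an inclusive (start, end) interval in the *reference*
    residue numbering; the already-computed global superposition is applied
    as-is, so a region that swings away from the reference keeps its full
    displacement. Returns None when no mapped residue falls in the region.
    """
    lo, hi = region
    sel = [
        (i, j)
        for i, j in pairs
        if lo <= ref.residues[j].number <= hi
        and inst.residues[i].ca is not None
        and ref.residues[j].ca is not None
    ]
    if not sel:
        warnings.warn(f"no mapped residues in region {region}")
        return None
    a = np.array([inst.residues[i].ca.coords for i, _ in sel])
    b = np.array([ref.residues[j].ca.coords for _, j in sel])
    diff = sup.apply(a) - b
    return float(np.sqrt(np.mean(np.sum(diff * diff, axis=1))))


# ---------------------------------------------------------------------------
# SASA / volume / burial

#: van der Waals radii (Å) by element; fallback 1.7.
VDW_RADII = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80,
    "SE": 1.90, "F": 1.47, "CL": 1.75, "BR": 1.85, "I": 1.98,
    "MG": 1.73, "ZN": 1.39, "FE": 1.56, "CA": 2.31, "NA": 2.27, "K": 2.75,
    "MN": 1.61, "CU": 1.40, "NI": 1.63, "CO": 1.53,
}
DEFAULT_RADIUS = 1.7

#: Maximum attainable SASA per residue (Å^2), theoretical Gly-X-Gly values
#: (Tien et al. 2013); used as the denominator of relative SASA.
MAX_SASA = {
    "A": 129.0, "R": 274.0, "N": 195.0, "D": 193.0, "C": 167.0,
    "Q": 225.0, "E": 223.0, "G": 104.0, "H": 224.0, "I": 197.0,
    "L": 201.0, "K": 236.0, "M": 224.0, "F": 240.0, "P": 159.0,
    "S": 155.0, "T": 172.0, "W": 285.0, "Y": 263.0, "V": 174.0,
    "X": 200.0,
}


@dataclass
class GeometryMetrics:
    """Compactness and contact metrics of one domain instance."""

    sasa_total: float
    volume: float
    av_ratio: float
    n_buried: int
    n_exposed: int
    be_ratio: float | None
    n_met: int
    n_lig: int


def _sphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform points on the unit sphere (golden spiral)."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + 5.0**0.5) * i
    return np.column_stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)]
    )


def _atom_arrays(inst: DomainInstance) -> tuple[np.ndarray, np.ndarray, list[int]]:
    coords, radii, res_idx = [], [], []
    for ri, res in enumerate(inst.residues):
        for atom in res.atoms:
            if atom.element == "H":
                continue
            coords.append(atom.coords)
            radii.append(VDW_RADII.get(atom.element.upper(), DEFAULT_RADIUS))
            res_idx.append(ri)
    return np.asarray(coords, float), np.asarray(radii, float), res_idx


def shrake_rupley_sasa(
    inst: DomainInstance, probe: float = 1.4, n_points: int = 960
) -> tuple[np.ndarray, np.ndarray, float]:
    """Shrake–Rupley SASA over heavy atoms.

    Returns (per-atom SASA, per-residue SASA, total SASA) in Å². Each atom
    is sampled with ``n_points`` deterministic sphere points at radius
    vdW + probe; a point is accessible when outside every neighbour's
    expanded sphere.
    """
    coords, radii, res_idx = _atom_arrays(inst)
    if len(coords) == 0:
        raise ValueError("no heavy atoms present")
    unknown = [
        a.element
        for r in inst.residues
        for a in r.atoms
        if a.element != "H" and a.element.upper() not in VDW_RADII
    ]
    if unknown:
        warnings.warn(f"unknown elements {sorted(set(unknown))}: default radius used")
    ext = radii + probe
    unit = _sphere_points(n_points)
    tree = cKDTree(coords)
    per_atom = np.zeros(len(coords))
    rmax = ext.max()
    for i in range(len(coords)):
        pts = coords[i] + ext[i] * unit
        neighbours = [j for j in tree.query_ball_point(coords[i], ext[i] + rmax) if j != i]
        accessible = np.ones(n_points, bool)
        for j in neighbours:
            d = np.linalg.norm(pts - coords[j], axis=1)
            # points exactly on a coincident neighbour's sphere: bury on the
            # higher-index atom only, so fully overlapping atoms count once
            buried = d < ext[j] - 1e-9
            if j < i:
                buried |= np.abs(d - ext[j]) <= 1e-9
            accessible &= ~buried
        per_atom[i] = 4.0 * np.pi * ext[i] ** 2 * accessible.sum() / n_points
    per_res = np.zeros(inst.n_res)
    for sasa, ri in zip(per_atom, res_idx):
        per_res[ri] += sasa
    return per_atom, per_res, float(per_atom.sum())


def estimate_volume(inst: DomainInstance, grid: float = 0.5) -> float:
    """Volume (Å³) of the union of heavy-atom vdW spheres by voxel counting.

    Each voxel carries a fractional occupancy, the maximum over spheres of
    clip((r - d)/grid + 1/2, 0, 1) where d is the centre-to-centre distance
    — a first-order surface antialiasing that keeps the default grid
    accurate to ~2% on single spheres. Each sphere only inspects its local
    sub-grid, so cost scales with atom count, not box volume.
    """
    coords, radii, _ = _atom_arrays(inst)
    if len(coords) == 0:
        raise ValueError("no heavy atoms present")
    rmax = radii.max()
    lo = coords.min(axis=0) - rmax - 2 * grid
    shape = np.ceil((coords.max(axis=0) + rmax + 2 * grid - lo) / grid).astype(int)
    occ = np.zeros(shape)
    for c, r in zip(coords, radii):
        i0 = np.maximum(np.floor((c - r - lo) / grid).astype(int) - 1, 0)
        i1 = np.minimum(np.ceil((c + r - lo) / grid).astype(int) + 2, shape)
        sub_axes = [lo[k] + (np.arange(i0[k], i1[k]) + 0.5) * grid - c[k] for k in range(3)]
        d = np.sqrt(
            sub_axes[0][:, None, None] ** 2
            + sub_axes[1][None, :, None] ** 2
            + sub_axes[2][None, None, :] ** 2
        )
        f = np.clip((r - d) / grid + 0.5, 0.0, 1.0)
        sub = occ[i0[0]:i1[0], i0[1]:i1[1], i0[2]:i1[2]]
        np.maximum(sub, f, out=sub)
    return float(occ.sum()) * grid**3


def classify_buried_exposed(
    per_res_sasa: np.ndarray, seq: str, rel_threshold: float = 0.25
) -> tuple[int, int, float | None]:
    """Classify residues by relative SASA; returns (n_buried, n_exposed, BEratio).

    A residue is buried when SASA / max-SASA(residue type) < ``rel_threshold``.
    BEratio is None when nothing is exposed.
    """
    if len(per_res_sasa) != len(seq):
        raise ValueError("per-residue SASA and sequence lengths differ")
    rel = np.array([s / MAX_SASA.get(aa, MAX_SASA["X"]) for s, aa in zip(per_res_sasa, seq)])
    n_buried = int(np.sum(rel < rel_threshold))
    n_exposed = len(seq) - n_buried
    be = (n_buried / n_exposed) if n_exposed else None
    return n_buried, n_exposed, be


def contact_counts(
    inst: DomainInstance, het_groups: list[HetGroup], cutoff: float = 4.0
) -> tuple[int, int]:
    """Residues in contact with metal ions (nMet) and with ligands (nLig).

    A residue counts once per category when any of its heavy atoms lies
    within ``cutoff`` Å of any atom of a group of that category. Water is
    excluded.
    """
    metal_atoms, ligand_atoms = [], []
    for g in het_groups:
        if g.is_water:
            continue
        target = metal_atoms if g.is_metal else ligand_atoms
        target.extend(a.coords for a in g.atoms if a.element != "H")
    n_met = n_lig = 0
    for res in inst.residues:
        xyz = res.heavy_coords()
        if len(xyz) == 0:
            continue
        for atoms, which in ((metal_atoms, "met"), (ligand_atoms, "lig")):
            if not atoms:
                continue
            d = np.linalg.norm(xyz[:, None, :] - np.asarray(atoms)[None, :, :], axis=2)
            if np.any(d <= cutoff):
                if which == "met":
                    n_met += 1
                else:
                    n_lig += 1
    return n_met, n_lig


def geometry_metrics(
    inst: DomainInstance,
    het_groups: list[HetGroup] | None = None,
    probe: float = 1.4,
    n_points: int = 960,
    grid: float = 0.5,
) -> GeometryMetrics:
    """All compactness/contact metrics of one instance in one call."""
    _, per_res, total = shrake_rupley_sasa(inst, probe=probe, n_points=n_points)
    vol = estimate_volume(inst, grid=grid)
    n_b, n_e, be = classify_buried_exposed(per_res, inst.seq)
    n_met, n_lig = contact_counts(inst, het_groups or [])
    return GeometryMetrics(
        sasa_total=total,
        volume=vol,
        av_ratio=total / vol,
        n_buried=n_b,
        n_exposed=n_e,
        be_ratio=be,
        n_met=n_met,
        n_lig=n_lig,
    )


# ---------------------------------------------------------------------------
# secondary structure

@dataclass
class SSEProfile:
    """Per-residue secondary structure over {H, E, C} with content fractions."""

    per_residue: str
    frac_helix: float
    frac_sheet: float

    @property
    def n_sse_residues(self) -> int:
        return self.per_residue.count("H") + self.per_residue.count("E")


_HB_Q1Q2_F = 0.084 * 332.0  # kcal/mol when distances are in Å
_HB_CUTOFF = -0.5


def _hbond_energy_matrix(inst: DomainInstance) -> np.ndarray:
    """DSSP-style electrostatic N-H...O=C energies, E[i, j] for donor i, acceptor j.

    The amide H of residue i is placed along the bisector opposite direction
    of (C_{i-1} -> N_i) and (CA_i -> N_i); prolines and chain-terminal
    residues without the needed atoms donate nothing (energy 0).
    """
    n = inst.n_res
    energy = np.zeros((n, n))
    backbone = []
    for res in inst.residues:
        backbone.append(
            {
                name: (res.atom(name).coords if res.atom(name) else None)
                for name in ("N", "CA", "C", "O")
            }
        )
    h_pos: list[np.ndarray | None] = [None] * n
    for i in range(1, n):
        bi, bp = backbone[i], backbone[i - 1]
        if bi["N"] is None or bi["CA"] is None or bp["C"] is None or bp["O"] is None:
            continue
        if inst.residues[i].aa == "P":
            continue
        co = bp["C"] - bp["O"]
        co /= np.linalg.norm(co)
        h_pos[i] = bi["N"] + 1.01 * co
    for i in range(n):
        if h_pos[i] is None:
            continue
        ni = backbone[i]["N"]
        for j in range(n):
            if abs(i - j) < 2:
                continue
            bj = backbone[j]
            if bj["C"] is None or bj["O"] is None:
                continue
            r_on = np.linalg.norm(bj["O"] - ni)
            r_ch = np.linalg.norm(bj["C"] - h_pos[i])
            r_oh = np.linalg.norm(bj["O"] - h_pos[i])
            r_cn = np.linalg.norm(bj["C"] - ni)
            if min(r_on, r_ch, r_oh, r_cn) < 0.5:
                energy[i, j] = -9.9
                continue
            energy[i, j] = _HB_Q1Q2_F * (1 / r_on + 1 / r_ch - 1 / r_oh - 1 / r_cn)
    return energy


def assign_sse(inst: DomainInstance) -> SSEProfile:
    """Assign H/E/C per residue from backbone hydrogen bonds.

    A hydrogen bond exists when the electrostatic energy is below -0.5
    kcal/mol. Helix: two consecutive i→i+4 turns mark residues i+1..i+4 as
    H (yielding runs of >= 4). Sheet: DSSP parallel/antiparallel bridge
    conditions mark both partners E; isolated single-residue E runs revert
    to coil. Residues with missing backbone atoms are coil.
    """
    n = inst.n_res
    missing = [
        any(inst.residues[i].atom(a) is None for a in ("N", "CA", "C", "O"))
        for i in range(n)
    ]
    if any(missing):
        warnings.warn("residues with missing backbone atoms assigned C")
    e = _hbond_energy_matrix(inst)
    hb = e < _HB_CUTOFF  # hb[i, j]: N-H of i donates to C=O of j

    def turn4(i: int) -> bool:  # C=O of i accepts from N-H of i+4
        return i + 4 < n and hb[i + 4, i]

    ss = ["C"] * n
    for i in range(n - 5):
        if turn4(i) and turn4(i + 1):
            for k in range(i + 1, i + 5):
                ss[k] = "H"
    bridge = [False] * n
    for i in range(1, n - 1):
        for j in range(i + 3, n - 1):
            para = (hb[j, i - 1] and hb[i + 1, j]) or (hb[i, j - 1] and hb[j + 1, i])
            anti = (hb[i, j] and hb[j, i]) or (hb[j + 1, i - 1] and hb[i + 1, j - 1])
            if para or anti:
                bridge[i] = bridge[j] = True
    for i in range(n):
        if bridge[i] and ss[i] != "H":
            ss[i] = "E"
    # drop isolated single-residue strands
    for i in range(n):
        if ss[i] == "E":
            prev_e = i > 0 and ss[i - 1] == "E"
            next_e = i < n - 1 and ss[i + 1] == "E"
            if not (prev_e or next_e):
                ss[i] = "C"
    for i in range(n):
        if missing[i]:
            ss[i] = "C"
    s = "".join(ss)
    return SSEProfile(
        per_residue=s,
        frac_helix=s.count("H") / n,
        frac_sheet=s.count("E") / n,
    )


def sse_count_difference(pred: SSEProfile, expt: SSEProfile) -> int:
    """Signed difference in structured-residue count: prediction minus experiment."""
    return pred.n_sse_residues - expt.n_sse_residues
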