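"""Structure input/output and curation.

Reads experimental (PDB/mmCIF) and predicted structures into lightweight
in-memory records, slices them into domain instances according to CATH-style
segment definitions, and applies the curation filters that define the
analysis-ready dataset: a minimum number of distinct experimental structures
per protein, minimum domain length, minimum sequence identity to the
reference, maximum crystallographic resolution, absence of extended termini,
and (for predicted models) a per-residue confidence filter.

Residue identity follows the PDB author convention: author residue number
plus insertion code, 1-based, with segment ranges inclusive.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import gemmi
import numpy as np

logger = logging.getLogger(__name__)

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}

#: Elements counted as metal ions for contact classification.
METAL_ELEMENTS = frozenset({
    "LI", "NA", "K", "RB", "CS", "MG", "CA", "SR", "BA", "MN", "FE", "CO",
    "NI", "CU", "ZN", "CD", "HG", "AL", "GA", "MO", "W", "V", "CR", "PT",
})

WATER_NAMES = frozenset({"HOH", "WAT", "DOD"})


@dataclass
class AtomRecord:
    """One atom: label, element, position (Å), occupancy and B-factor.

    For predicted models the B-factor column carries the per-residue pLDDT
    confidence (0-100).
    """

    name: str
    element: str
    coords: np.ndarray
    occupancy: float = 1.0
    bfactor: float = 0.0
    is_hetero: bool = False

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if not np.all(np.isfinite(self.coords)):
            raise ValueError(f"non-finite coordinates for atom {self.name}")


@dataclass
class ResidueRecord:
    """One residue; ``seq_label`` is author number + insertion code."""

    chain_id: str
    seq_label: str
    aa: str
    atoms: list[AtomRecord] = field(default_factory=list)

    @property
    def number(self) -> int:
        """Author residue number without insertion code."""
        lab = self.seq_label
        while lab and not (lab[-1].isdigit()):
            lab = lab[:-1]
        return int(lab)

    def atom(self, name: str) -> AtomRecord | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    @property
    def ca(self) -> AtomRecord | None:
        return self.atom("CA")

    def heavy_coords(self) -> np.ndarray:
        xyz = [a.coords for a in self.atoms if a.element != "H"]
        return np.array(xyz) if xyz else np.empty((0, 3))


@dataclass
class HetGroup:
    """A HETATM group (ligand, metal ion, ...); water is kept but flagged."""

    name: str
    chain_id: str
    seq_label: str
    atoms: list[AtomRecord]

    @property
    def is_water(self) -> bool:
        return self.name in WATER_NAMES

    @property
    def is_metal(self) -> bool:
        return all(a.element.upper() in METAL_ELEMENTS for a in self.atoms)


@dataclass
class StructureModel:
    """A parsed structure: polymer chains plus het groups and metadata."""

    source_id: str
    method: str = ""
    resolution: float | None = None
    chains: dict[str, list[ResidueRecord]] = field(default_factory=dict)
    het_groups: list[HetGroup] = field(default_factory=list)

    def chain_sequence(self, chain_id: str) -> str:
        return "".join(r.aa for r in self.chains[chain_id])


@dataclass
class DomainDefinition:
    """A CATH-style domain: 4-level code plus residue segments on chains."""

    domain_id: str
    cath_code: str
    segments: list[tuple[str, str, str]]  # (chain, start_label, end_label)
    protein_acc: str

    def __post_init__(self) -> None:
        parts = self.cath_code.split(".")
        if len(parts) != 4 or not all(p.isdigit() for p in parts):
            raise ValueError(
                f"malformed CATH code {self.cath_code!r}: expected 4 dot-separated integers"
            )
        if not self.segments:
            raise ValueError(f"domain {self.domain_id}: needs at least one segment")
        _check_no_overlap(self.domain_id, self.segments)

    @property
    def topology_code(self) -> str:
        """The C.A.T (fold) prefix of the CATH code."""
        return ".".join(self.cath_code.split(".")[:3])


def _label_num(label: str) -> int:
    lab = str(label)
    while lab and not lab[-1].isdigit() and lab[-1] not in "-":
        lab = lab[:-1]
    return int(lab)


def _check_no_overlap(domain_id: str, segments: list[tuple[str, str, str]]) -> None:
    by_chain: dict[str, list[tuple[int, int]]] = {}
    for chain, start, end in segments:
        by_chain.setdefault(chain, []).append((_label_num(start), _label_num(end)))
    for chain, ranges in by_chain.items():
        ranges.sort()
        for (s0, e0), (s1, _e1) in zip(ranges, ranges[1:]):
            if s1 <= e0:
                raise ValueError(
                    f"domain {domain_id}: overlapping segments on chain {chain}"
                )


@dataclass
class DomainInstance:
    """One resolved (or extracted predicted) copy of a domain."""

    definition: DomainDefinition
    source: str
    residues: list[ResidueRecord]
    is_predicted: bool = False
    resolution: float | None = None
    method: str = ""
    pid: float | None = None  # percent identity to reference, set by seqmap
    extended_termini: bool = False

    @property
    def seq(self) -> str:
        return "".join(r.aa for r in self.residues)

    @property
    def n_res(self) -> int:
        return len(self.residues)

    @property
    def n_segments(self) -> int:
        return len(self.definition.segments)

    @property
    def instance_id(self) -> str:
        return f"{self.source}|{self.definition.domain_id}"

    def ca_coords(self) -> np.ndarray:
        """CA coordinates of residues that have a CA atom, in residue order."""
        xyz = [r.ca.coords for r in self.residues if r.ca is not None]
        return np.array(xyz) if xyz else np.empty((0, 3))

    def plddt(self) -> np.ndarray:
        """Per-residue pLDDT (B-factor of CA, else first atom)."""
        vals = []
        for r in self.residues:
            a = r.ca or (r.atoms[0] if r.atoms else None)
            vals.append(a.bfactor if a is not None else np.nan)
        return np.asarray(vals, dtype=float)


@dataclass
class CurationConfig:
    """Thresholds of the dataset curation filters.

    Defaults follow the study conditions: at least ten distinct experimental
    structures per protein, domains longer than ten residues, >= 99% sequence
    identity to the reference, resolution <= 3 Å, no extended termini, and
    predicted models with >= 90% of residues above pLDDT 80.
    """

    min_structures_per_protein: int = 10
    min_pid: float = 99.0
    min_length: int = 10  # instances with n_res <= min_length are rejected
    max_resolution: float = 3.0
    plddt_threshold: float = 80.0
    plddt_fraction: float = 0.90
    terminus_window: int = 5
    terminus_dev: float = 5.0

    def __post_init__(self) -> None:
        for name in (
            "min_structures_per_protein", "min_pid", "min_length",
            "max_resolution", "plddt_threshold", "plddt_fraction",
            "terminus_window", "terminus_dev",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


# ---------------------------------------------------------------------------
# reading


def _convert_gemmi(st: gemmi.Structure, source_id: str) -> StructureModel:
    st.setup_entities()
    resolution = st.resolution if st.resolution and st.resolution > 0 else None
    model = StructureModel(
        source_id=source_id,
        method=dict(st.info).get("_exptl.method", ""),
        resolution=resolution,
    )
    if len(st) == 0:
        raise ValueError(f"{source_id}: empty structure")
    gm = st[0]  # NMR multi-model files: first model only
    n_atoms = 0
    for chain in gm:
        for res in chain:
            het = res.het_flag == "H"
            atoms = []
            seen = {}
            for atom in res:
                # alternate locations: keep the highest-occupancy copy
                prev = seen.get(atom.name)
                if prev is not None and prev.occupancy >= atom.occ:
                    continue
                rec = AtomRecord(
                    name=atom.name,
                    element=atom.element.name.upper(),
                    coords=np.array([atom.pos.x, atom.pos.y, atom.pos.z]),
                    occupancy=atom.occ,
                    bfactor=atom.b_iso,
                    is_hetero=het,
                )
                seen[atom.name] = rec
            atoms = list(seen.values())
            n_atoms += len(atoms)
            label = f"{res.seqid.num}{res.seqid.icode}".strip()
            if het and res.name not in THREE_TO_ONE:
                model.het_groups.append(
                    HetGroup(res.name, chain.name, label, atoms)
                )
            else:
                aa = THREE_TO_ONE.get(res.name, "X")
                model.chains.setdefault(chain.name, []).append(
                    ResidueRecord(chain.name, label, aa, atoms)
                )
    if n_atoms == 0:
        raise ValueError(f"{source_id}: empty structure")
    for chain_id, residues in model.chains.items():
        labels = [r.seq_label for r in residues]
        if len(labels) != len(set(labels)):
            raise ValueError(f"{source_id}: duplicate residue labels in chain {chain_id}")
    return model


def read_structure(path, fmt: str | None = None) -> StructureModel:
    """Read a PDB or mmCIF file into a :class:`StructureModel`.

    ``fmt`` may be ``"pdb"`` or ``"mmcif"``; by default it is inferred from
    the file extension. ATOM records populate polymer chains; HETATM records
    of non-amino-acid groups are routed to ``het_groups``.
    """
    path = str(path)
    if fmt is None:
        fmt = "mmcif" if path.endswith((".cif", ".mmcif", ".cif.gz")) else "pdb"
    try:
        if fmt == "mmcif":
            st = gemmi.read_structure(path, format=gemmi.CoorFormat.Mmcif)
        elif fmt == "pdb":
            st = gemmi.read_structure(path, format=gemmi.CoorFormat.Pdb)
        else:
            raise ValueError(f"unknown format {fmt!r}")
    except (RuntimeError, ValueError) as exc:
        raise ValueError(f"cannot parse {path} as {fmt}: {exc}") from exc
    source_id = st.name or path.rsplit("/", 1)[-1].split(".")[0]
    return _convert_gemmi(st, source_id)


def read_domain_definitions(path) -> list[DomainDefinition]:
    """Read a TSV of domain definitions.

    Expected columns: ``domain_id``, ``cath_code``, ``protein_acc``,
    ``segments`` with segments encoded as ``chain:start-end`` joined by
    commas, e.g. ``A:1-120,A:180-240``.
    """
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"domain_id", "cath_code", "protein_acc", "segments"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"domain definition table missing columns: {sorted(missing)}")
    defs = []
    for row in df.itertuples(index=False):
        segments = []
        for seg in str(row.segments).split(","):
            chain, _, span = seg.strip().partition(":")
            start, sep, end = span.rpartition("-")
            if not sep or not chain:
                raise ValueError(f"domain {row.domain_id}: bad segment {seg!r}")
            segments.append((chain, start.strip(), end.strip()))
        defs.append(
            DomainDefinition(
                domain_id=row.domain_id,
                cath_code=row.cath_code,
                segments=segments,
                protein_acc=row.protein_acc,
            )
        )
    return defs


def extract_domain_instance(
    model: StructureModel, definition: DomainDefinition
) -> DomainInstance:
    """Slice a structure into a domain instance along the definition segments.

    Residues falling inside the (inclusive) segment ranges are collected in
    segment order; residues unresolved in the experiment are silently absent.
    """
    residues: list[ResidueRecord] = []
    for chain, start, end in definition.segments:
        if chain not in model.chains:
            raise KeyError(
                f"{definition.domain_id}: chain {chain!r} not in structure {model.source_id}"
            )
        lo, hi = _label_num(start), _label_num(end)
        for res in model.chains[chain]:
            if lo <= res.number <= hi:
                residues.append(res)
    if not residues:
        raise ValueError(
            f"{definition.domain_id}: no residue of {model.source_id} falls in any segment"
        )
    return DomainInstance(
        definition=definition,
        source=model.source_id,
        residues=residues,
        resolution=model.resolution,
        method=model.method,
    )


# ---------------------------------------------------------------------------
# curation

REJECTION_ORDER = ("counts", "length", "pid", "resolution", "termini")


def apply_curation(
    instances: list[DomainInstance], cfg: CurationConfig | None = None
) -> tuple[list[DomainInstance], list[tuple[DomainInstance, str]]]:
    """Split instances into (kept, rejected-with-reason).

    Rules, in fixed order (the first failing rule is the recorded reason):
    too few distinct source structures for the protein; domain too short;
    PID below threshold; resolution worse than threshold; extended termini.
    Instances without a resolution (e.g. NMR or predicted) pass the
    resolution rule; instances without a PID pass the PID rule.
    """
    cfg = cfg or CurationConfig()
    counts: dict[str, set[str]] = {}
    for inst in instances:
        counts.setdefault(inst.definition.protein_acc, set()).add(inst.source)
    kept, rejected = [], []
    for inst in instances:
        reason = None
        if len(counts[inst.definition.protein_acc]) < cfg.min_structures_per_protein:
            reason = "counts"
        elif inst.n_res <= cfg.min_length:
            reason = "length"
        elif inst.pid is not None and inst.pid < cfg.min_pid:
            reason = "pid"
        elif inst.resolution is not None and inst.resolution > cfg.max_resolution:
            reason = "resolution"
        elif inst.extended_termini:
            reason = "termini"
        if reason is None:
            kept.append(inst)
        else:
            rejected.append((inst, reason))
    return kept, rejected


def detect_extended_termini(
    inst: DomainInstance,
    ref: DomainInstance,
    cfg: CurationConfig | None = None,
    pairs: list[tuple[int, int]] | None = None,
) -> bool:
    """Flag instances whose N- or C-terminus sticks out from the domain core.

    The instance is superposed on the reference using only its core (mapped
    residues excluding ``terminus_window`` residues at each end); the flag is
    raised when every residue of a terminal window deviates by more than
    ``terminus_dev`` Å under that core superposition. A rigid-body copy of
    the reference can never be flagged.
    """
    from .structmetrics import kabsch_superpose

    cfg = cfg or CurationConfig()
    if pairs is None:
        n = min(inst.n_res, ref.n_res)
        pairs = [(i, i) for i in range(n)]
    w = cfg.terminus_window
    if len(pairs) < 2 * w + 3:
        warnings.warn("residue map too short for terminus detection; flag False")
        return False
    a = np.array([inst.residues[i].ca.coords for i, _ in pairs if inst.residues[i].ca])
    b = np.array([ref.residues[j].ca.coords for _, j in pairs if ref.residues[j].ca])
    m = min(len(a), len(b))
    a, b = a[:m], b[:m]
    core = slice(w, m - w)
    sup = kabsch_superpose(a[core], b[core])
    a_fit = a @ sup.rotation.T + sup.translation
    dev = np.linalg.norm(a_fit - b, axis=1)
    n_term = bool(np.all(dev[:w] > cfg.terminus_dev))
    c_term = bool(np.all(dev[m - w:] > cfg.terminus_dev))
    return n_term or c_term


def confidence_filter(pred: DomainInstance, cfg: CurationConfig | None = None) -> bool:
    """True iff enough of a predicted instance is high-confidence.

    Requires ``plddt_fraction`` of residues with pLDDT above
    ``plddt_threshold`` (study condition: 90% of residues above 80).
    """
    cfg = cfg or CurationConfig()
    if not pred.is_predicted:
        raise ValueError("confidence_filter applies to predicted instances")
    plddt = pred.plddt()
    if np.any(np.isnan(plddt)):
        raise ValueError(f"{pred.instance_id}: missing pLDDT values")
    frac = float(np.mean(plddt > cfg.plddt_threshold))
    return frac >= cfg.plddt_fraction


# ---------------------------------------------------------------------------
# writing


def write_domain_pdb(inst: DomainInstance, path) -> None:
    """Write a domain instance as a single-chain PDB file.

    The chain is renamed to ``A``; author residue numbering is preserved.
    Experiment type and resolution metadata are written as EXPDTA/REMARK 2
    records so they survive a round trip.
    """
    lines = []
    if inst.method:
        lines.append(f"EXPDTA    {inst.method}")
    if inst.resolution is not None:
        lines.append(f"REMARK   2 RESOLUTION. {inst.resolution:7.2f} ANGSTROMS.")
    serial = 1
    for res in inst.residues:
        resname = ONE_TO_THREE.get(res.aa, "UNK")
        icode = " "
        num_str = res.seq_label
        if num_str and not num_str[-1].isdigit():
            icode = num_str[-1]
            num_str = num_str[:-1]
        for atom in res.atoms:
            name = atom.name
            # PDB atom-name column convention: 1-char elements start in col 14
            pad = f" {name:<3s}" if len(name) < 4 and len(atom.element) == 1 else f"{name:<4s}"
            lines.append(
                f"ATOM  {serial:5d} {pad} {resname} A{int(num_str):4d}{icode}   "
                f"{atom.coords[0]:8.3f}{atom.coords[1]:8.3f}{atom.coords[2]:8.3f}"
                f"{atom.occupancy:6.2f}{atom.bfactor:6.2f}          "
                f"{atom.element:>2s}"
            )
            serial += 1
    lines.append("TER")
    lines.append("END")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def write_fasta(records: dict[str, str], path) -> None:
    with open(path, "w") as fh:
        for name, seq in records.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")


def read_fasta(path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
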