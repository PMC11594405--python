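"""End-to-end pipeline orchestration.

Stages, in order: ingest (read structures + domain definitions + reference
sequences, slice experimental domain instances), align/extract (glocal
alignment to the predicted full-length model, PID, predicted-domain
extraction, extended-terminus detection), curate, metrics (superposition
RMSD/RMSD100, geometry, secondary structure), group (sequence clusters and
topology/window sub-clusters), census (per-level summaries, tier fractions,
SSE-difference distribution, geometry trend), regions (two-region
conformational clustering for configured proteins) and enrich
(heterogeneous-vs-consistent hypergeometric enrichment).

Every stage writes TSV/JSON outputs into the run directory together with a
hash of the configuration; the pipeline is deterministic, so rerunning with
the same configuration and inputs reproduces the output files byte for byte
(idempotence). Per-stage in/out counts are logged.

Structure files are routed to proteins by source-id prefix: a structure
belongs to the protein whose accession its identifier starts with. An
explicit two-column mapping table (``source_id``, ``protein_acc``) may be
supplied instead.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import census as census_mod
from . import downstream, grouping, seqmap, structio, structmetrics

logger = logging.getLogger(__name__)

STAGES = ("ingest", "extract", "curate", "metrics", "group", "census", "regions", "enrich")


@dataclass
class PipelineConfig:
    structures_dir: str
    predicted_dir: str
    domains_tsv: str
    reference_fasta: str
    out_dir: str
    annotations_tsv: str | None = None
    structure_map_tsv: str | None = None
    curation: structio.CurationConfig = field(default_factory=structio.CurationConfig)
    alignment: seqmap.AlignmentParams = field(default_factory=seqmap.AlignmentParams)
    identity_threshold: float = 0.95
    window_agreement: float = 0.9
    tiers: tuple[float, float] = (2.5, 5.0)
    census_weight: str = "instance"
    compute_geometry: bool = True
    compute_sse: bool = True
    volume_grid: float = 0.5
    sasa_points: int = 960
    regions: list[downstream.RegionSpec] = field(default_factory=list)
    region_protein: str | None = None
    het_cutoff: float = 2.5
    con_decile: float = 0.10
    seed: int = 0

    def config_hash(self) -> str:
        """Hash of the analysis parameters (I/O paths excluded)."""
        def enc(o):
            if dataclasses.is_dataclass(o):
                return dataclasses.asdict(o)
            return str(o)

        d = dataclasses.asdict(self)
        for key in ("structures_dir", "predicted_dir", "domains_tsv",
                    "reference_fasta", "annotations_tsv", "structure_map_tsv",
                    "out_dir"):
            d.pop(key, None)
        blob = json.dumps(d, default=enc, sort_keys=True)
        return hashlib.sha1(blob.encode()).hexdigest()[:12]


def load_config(path) -> PipelineConfig:
    """Load a YAML config file into a :class:`PipelineConfig`."""
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if "curation" in raw:
        raw["curation"] = structio.CurationConfig(**raw["curation"])
    if "alignment" in raw:
        raw["alignment"] = seqmap.AlignmentParams(**raw["alignment"])
    if "regions" in raw:
        raw["regions"] = [downstream.RegionSpec(**r) for r in raw["regions"]]
    return PipelineConfig(**raw)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, detail: str):
        super().__init__(f"stage {stage!r}: {detail}")
        self.stage = stage


@dataclass
class PipelineResult:
    out_dir: Path
    metrics: pd.DataFrame
    census: dict[str, pd.DataFrame]
    tier_summary: dict
    region_table: pd.DataFrame | None
    region_clusters: downstream.ConformationCluster | None
    enrichment: pd.DataFrame | None
    counts: dict[str, int]


def _validate(cfg: PipelineConfig) -> None:
    for name in ("structures_dir", "predicted_dir", "domains_tsv", "reference_fasta"):
        p = Path(getattr(cfg, name))
        if not p.exists():
            raise PipelineError("startup", f"missing input path {name}={p}")
    if cfg.annotations_tsv and not Path(cfg.annotations_tsv).exists():
        raise PipelineError("startup", f"missing annotations table {cfg.annotations_tsv}")


def _route_structures(cfg: PipelineConfig, accs: list[str]) -> dict[str, list[Path]]:
    files = sorted(Path(cfg.structures_dir).glob("*.pdb")) + sorted(
        Path(cfg.structures_dir).glob("*.cif")
    )
    routing: dict[str, list[Path]] = {a: [] for a in accs}
    if cfg.structure_map_tsv:
        m = pd.read_csv(cfg.structure_map_tsv, sep="\t", dtype=str)
        by_source = dict(zip(m["source_id"], m["protein_acc"]))
        for f in files:
            acc = by_source.get(f.stem)
            if acc in routing:
                routing[acc].append(f)
    else:
        ordered = sorted(accs, key=len, reverse=True)  # longest prefix wins
        for f in files:
            for acc in ordered:
                if f.stem.startswith(acc):
                    routing[acc].append(f)
                    break
    return routing


def run_pipeline(cfg: PipelineConfig, stages: tuple[str, ...] = STAGES) -> PipelineResult:
    """Execute the pipeline and write all stage outputs under ``cfg.out_dir``."""
    _validate(cfg)
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = cfg.config_hash()
    (out / "config_hash.txt").write_text(chash + "\n")
    counts: dict[str, int] = {}

    # ---- ingest -----------------------------------------------------------
    definitions = structio.read_domain_definitions(cfg.domains_tsv)
    refs = structio.read_fasta(cfg.reference_fasta)
    defs_by_acc: dict[str, list[structio.DomainDefinition]] = {}
    for d in definitions:
        defs_by_acc.setdefault(d.protein_acc, []).append(d)
    routing = _route_structures(cfg, list(defs_by_acc))
    instances: list[structio.DomainInstance] = []
    het_by_source: dict[str, list] = {}
    for acc, files in sorted(routing.items()):
        for f in files:
            try:
                model = structio.read_structure(f)
            except ValueError as exc:
                raise PipelineError("ingest", str(exc)) from exc
            het_by_source[model.source_id] = model.het_groups
            for d in defs_by_acc[acc]:
                try:
                    instances.append(structio.extract_domain_instance(model, d))
                except (KeyError, ValueError) as exc:
                    logger.warning("ingest: skipping %s on %s: %s", d.domain_id, f, exc)
    counts["ingest_instances"] = len(instances)
    logger.info("ingest: %d structures -> %d domain instances",
                sum(len(v) for v in routing.values()), len(instances))

    # ---- align / extract --------------------------------------------------
    predicted_models: dict[str, structio.StructureModel] = {}
    for acc in defs_by_acc:
        for ext in (".pdb", ".cif"):
            p = Path(cfg.predicted_dir) / f"{acc}{ext}"
            if p.exists():
                predicted_models[acc] = structio.read_structure(p)
                break
        if acc not in predicted_models:
            raise PipelineError("extract", f"no predicted model for protein {acc}")
        if acc in refs and predicted_models[acc].chain_sequence(
            next(iter(predicted_models[acc].chains))
        ) != refs[acc]:
            logger.warning("extract: predicted model %s differs from reference FASTA", acc)

    pred_counterpart: dict[str, structio.DomainInstance] = {}
    sup_pairs: dict[str, list[tuple[int, int]]] = {}
    kept_for_align = []
    for inst in instances:
        acc = inst.definition.protein_acc
        model = predicted_models[acc]
        try:
            rmap, pred = seqmap.map_domain_to_model(inst, model, cfg.alignment)
        except (ValueError, IndexError) as exc:
            raise PipelineError("extract", f"{inst.instance_id}: {exc}") from exc
        pred.is_predicted = True
        pred_counterpart[inst.instance_id] = pred
        ordered = sorted(rmap.pairs, key=lambda p: p[1])
        pairs = [(q, k) for k, (q, _r) in enumerate(ordered)]
        sup_pairs[inst.instance_id] = pairs
        inst.extended_termini = structio.detect_extended_termini(
            inst, pred, cfg.curation, pairs
        )
        kept_for_align.append(inst)
    counts["extract_instances"] = len(kept_for_align)

    # ---- curate -----------------------------------------------------------
    kept, rejected = structio.apply_curation(kept_for_align, cfg.curation)
    rep = pd.DataFrame(
        [{"instance_id": i.instance_id, "kept": True, "reason": ""} for i in kept]
        + [{"instance_id": i.instance_id, "kept": False, "reason": r} for i, r in rejected]
    )
    rep["config_hash"] = chash
    rep.to_csv(out / "curation_report.tsv", sep="\t", index=False)
    counts["curated_kept"] = len(kept)
    logger.info("curate: %d in -> %d kept, %d rejected",
                len(kept_for_align), len(kept), len(rejected))
    if not kept:
        raise PipelineError("curate", "no instances survive curation")

    # ---- metrics ----------------------------------------------------------
    rows = []
    for inst in kept:
        pred = pred_counterpart[inst.instance_id]
        pairs = sup_pairs[inst.instance_id]
        sup, used = structmetrics.superpose_instances(inst, pred, pairs)
        row = {
            "instance_id": inst.instance_id,
            "protein_acc": inst.definition.protein_acc,
            "domain_id": inst.definition.domain_id,
            "cath_code": inst.definition.cath_code,
            "topology_code": inst.definition.topology_code,
            "cath_class": inst.definition.cath_code.split(".")[0],
            "n_res": inst.n_res,
            "pid": inst.pid,
            "resolution": inst.resolution,
            "rmsd": sup.rmsd,
            "rmsd100": sup.rmsd100,
        }
        if cfg.compute_geometry:
            geom = structmetrics.geometry_metrics(
                inst,
                het_by_source.get(inst.source, []),
                n_points=cfg.sasa_points,
                grid=cfg.volume_grid,
            )
            row.update(
                av_ratio=geom.av_ratio,
                be_ratio=geom.be_ratio,
                n_met=geom.n_met,
                n_lig=geom.n_lig,
            )
        if cfg.compute_sse:
            prof_e = structmetrics.assign_sse(inst)
            prof_p = structmetrics.assign_sse(pred)
            row.update(
                frac_helix=prof_e.frac_helix,
                frac_sheet=prof_e.frac_sheet,
                sse_diff=structmetrics.sse_count_difference(prof_p, prof_e),
                conf_pass=structio.confidence_filter(pred, cfg.curation),
            )
        rows.append(row)
    metrics = pd.DataFrame(rows)
    counts["metrics_instances"] = len(metrics)

    # ---- group ------------------------------------------------------------
    clusters, subclusters = grouping.build_groups(
        kept, cfg.identity_threshold, cfg.window_agreement
    )
    member_rows = []
    for cl in clusters:
        for m in cl.members:
            member_rows.append({"instance_id": m, "cluster_id": cl.cluster_id})
    mdf = pd.DataFrame(member_rows)
    sub_rows = []
    for sc in subclusters:
        for m in sc.members:
            sub_rows.append(
                {
                    "instance_id": m,
                    "subcluster_id": sc.subcluster_id,
                    "window_start": sc.window[0],
                    "window_end": sc.window[1],
                }
            )
    sdf = pd.DataFrame(sub_rows)
    metrics = metrics.merge(mdf, on="instance_id").merge(sdf, on="instance_id")
    metrics["config_hash"] = chash
    metrics.to_csv(out / "metrics.tsv", sep="\t", index=False)
    counts["clusters"] = len(clusters)
    counts["subclusters"] = len(subclusters)
    logger.info("group: %d clusters, %d sub-clusters", len(clusters), len(subclusters))

    # ---- census -----------------------------------------------------------
    census_frames: dict[str, pd.DataFrame] = {}
    census_rows: dict[str, list[census_mod.GroupCensusRow]] = {}
    for level, col in (
        ("subcluster", "subcluster_id"),
        ("topology", "topology_code"),
        ("class", "cath_class"),
    ):
        rows_l = census_mod.build_census(metrics, level, col, weight=cfg.census_weight)
        census_rows[level] = rows_l
        df = census_mod.spectrum_order(rows_l)
        df["config_hash"] = chash
        df.to_csv(out / f"census_{level}.tsv", sep="\t", index=False)
        census_frames[level] = df
    tier_summary = {
        "config_hash": chash,
        "levels": {
            level: {str(c): census_mod.tier_census(census_rows[level], c) for c in cfg.tiers}
            for level in census_rows
        },
    }
    if cfg.compute_sse and "sse_diff" in metrics:
        conf = metrics[metrics["conf_pass"]] if "conf_pass" in metrics else metrics
        dist = census_mod.sse_diff_distribution(conf["sse_diff"].dropna())
        tier_summary["sse_diff"] = {
            "cutoffs": list(dist.cutoffs),
            "frac_exceeding": list(dist.frac_exceeding),
            "n": int(conf["sse_diff"].notna().sum()),
        }
    if cfg.compute_geometry:
        trend = census_mod.geometry_trend(census_rows["topology"])
        trend.to_csv(out / "geometry_trend.tsv", sep="\t", index=False)
    with open(out / "tier_summary.json", "w") as fh:
        json.dump(tier_summary, fh, indent=2, sort_keys=True, default=float)

    # ---- regions ----------------------------------------------------------
    region_table = None
    region_clusters = None
    if len(cfg.regions) == 2 and cfg.region_protein:
        acc = cfg.region_protein
        prot_insts = [i for i in kept if i.definition.protein_acc == acc]
        if prot_insts:
            pred = pred_counterpart[prot_insts[0].instance_id]
            pair_maps = {i.instance_id: sup_pairs[i.instance_id] for i in prot_insts}
            region_table = downstream.two_region_rmsd(
                prot_insts, pred, tuple(cfg.regions), pair_maps
            )
            try:
                region_clusters = downstream.cluster_conformations(region_table)
                region_table["conformation_cluster"] = region_table["instance_id"].map(
                    region_clusters.labels
                )
            except ValueError as exc:
                logger.warning("regions: clustering skipped: %s", exc)
            region_table["config_hash"] = chash
            region_table.to_csv(out / "region_rmsd.tsv", sep="\t", index=False)
            counts["region_instances"] = len(region_table)

    # ---- enrich -----------------------------------------------------------
    enrichment = None
    if cfg.annotations_tsv:
        ann = pd.read_csv(cfg.annotations_tsv, sep="\t", dtype=str)
        het, con = downstream.select_protein_sets(
            census_rows["subcluster"], cfg.het_cutoff, cfg.con_decile
        )
        results = downstream.hypergeom_enrich(het, con, ann)
        enrichment = downstream.enrichment_frame(results)
        enrichment["config_hash"] = chash
        enrichment.to_csv(out / "enrichment.tsv", sep="\t", index=False)
        counts["het_proteins"] = len(het)
        counts["con_proteins"] = len(con)

    manifest = {"config_hash": chash, "counts": counts, "stages": list(stages)}
    with open(out / "run_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return PipelineResult(
        out_dir=out,
        metrics=metrics,
        census=census_frames,
        tier_summary=tier_summary,
        region_table=region_table,
        region_clusters=region_clusters,
        enrichment=enrichment,
        counts=counts,
    )
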