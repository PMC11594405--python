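"""Two-level grouping of domain instances.

Level 1: greedy sequence-identity clustering at 95% identity (CD-HIT-style:
sequences sorted by length, each joins the first cluster whose representative
it matches at or above the threshold, else founds a new cluster). Identity is
the number of identical matched columns divided by the shorter sequence
length.

Level 2: topology/window sub-clusters. Within a sequence cluster, members
are first partitioned by CATH topology code (C.A.T); within a topology,
members whose resolved residue windows mutually overlap by at least a
window-agreement fraction of the shorter window are linked (single linkage).
This realizes the two splitting rules: a region annotated to several
topologies yields one sub-cluster per topology, and differently resolved
windows of one topology yield separate sub-clusters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio import Align

from .structio import DomainInstance


@dataclass
class SeqCluster:
    cluster_id: str
    representative: str
    members: list[str] = field(default_factory=list)


@dataclass
class SubCluster:
    subcluster_id: str
    topology_code: str
    window: tuple[int, int]
    members: list[str] = field(default_factory=list)


def _lcs_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = 0.0
    aligner.open_gap_score = 0.0
    aligner.extend_gap_score = 0.0
    return aligner


_ALIGNER = _lcs_aligner()


def sequence_identity(a: str, b: str) -> float:
    """Identical matched columns / shorter length, in [0, 1].

    The maximal number of identical matched columns over all alignments is
    the longest common subsequence, obtained from a gap-free-cost alignment.
    """
    if not a or not b:
        return 0.0
    lcs = _ALIGNER.score(a, b)
    return float(lcs) / min(len(a), len(b))


def greedy_identity_cluster(
    instances: list[DomainInstance], threshold: float = 0.95
) -> list[SeqCluster]:
    """Greedy incremental clustering by sequence identity to representatives.

    Deterministic and order-independent: instances are processed sorted by
    (length descending, instance id).
    """
    order = sorted(instances, key=lambda x: (-x.n_res, x.instance_id))
    clusters: list[SeqCluster] = []
    reps: list[str] = []
    for inst in order:
        placed = False
        for cl, rep_seq in zip(clusters, reps):
            if sequence_identity(inst.seq, rep_seq) >= threshold:
                cl.members.append(inst.instance_id)
                placed = True
                break
        if not placed:
            clusters.append(
                SeqCluster(
                    cluster_id=f"c{len(clusters):04d}",
                    representative=inst.instance_id,
                    members=[inst.instance_id],
                )
            )
            reps.append(inst.seq)
    return clusters


def _window(inst: DomainInstance) -> tuple[int, int]:
    nums = [r.number for r in inst.residues]
    return min(nums), max(nums)


def _mutual_overlap(w1: tuple[int, int], w2: tuple[int, int]) -> float:
    inter = min(w1[1], w2[1]) - max(w1[0], w2[0]) + 1
    if inter <= 0:
        return 0.0
    shorter = min(w1[1] - w1[0] + 1, w2[1] - w2[0] + 1)
    return inter / shorter


def subcluster(
    cluster: SeqCluster,
    instances: dict[str, DomainInstance],
    window_agreement: float = 0.9,
) -> list[SubCluster]:
    """Split one sequence cluster into topology/window sub-clusters.

    Single-linkage over window overlap (>= ``window_agreement`` of the
    shorter window) within each topology; output ordered by
    (topology, window start, window end) for determinism.
    """
    by_topology: dict[str, list[str]] = {}
    for mid in cluster.members:
        topo = instances[mid].definition.topology_code
        by_topology.setdefault(topo, []).append(mid)
    out: list[SubCluster] = []
    for topo in sorted(by_topology):
        members = sorted(by_topology[topo])
        windows = {m: _window(instances[m]) for m in members}
        # single-linkage connected components under the overlap relation
        parent = {m: m for m in members}

        def find(x: str) -> str:
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for i, mi in enumerate(members):
            for mj in members[i + 1:]:
                if _mutual_overlap(windows[mi], windows[mj]) >= window_agreement:
                    parent[find(mi)] = find(mj)
        groups: dict[str, list[str]] = {}
        for m in members:
            groups.setdefault(find(m), []).append(m)
        comps = []
        for ms in groups.values():
            lo = min(windows[m][0] for m in ms)
            hi = max(windows[m][1] for m in ms)
            comps.append(((lo, hi), sorted(ms)))
        comps.sort(key=lambda c: c[0])
        for window, ms in comps:
            out.append(
                SubCluster(
                    subcluster_id=f"{cluster.cluster_id}.{topo}.{len(out)}",
                    topology_code=topo,
                    window=window,
                    members=ms,
                )
            )
    return out


def build_groups(
    instances: list[DomainInstance],
    identity_threshold: float = 0.95,
    window_agreement: float = 0.9,
) -> tuple[list[SeqCluster], list[SubCluster]]:
    """Run both grouping levels; sub-cluster ids are globally unique."""
    index = {i.instance_id: i for i in instances}
    clusters = greedy_identity_cluster(instances, identity_threshold)
    subclusters: list[SubCluster] = []
    for cl in clusters:
        subclusters.extend(subcluster(cl, index, window_agreement))
    return clusters, subclusters
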