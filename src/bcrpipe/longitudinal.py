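"""Cross-timepoint persistence, mAb-to-repertoire matching, parsimony
lineages, and the immunodominance grid.

Persistence matching works on a trimmed nucleotide core (the span between
Kabat positions 12 and 136 projected onto each query), is isotype-agnostic
for matching but records isotypes for classification, and verifies that the
UMI signatures supporting a persistent sequence are disjoint across samples
— shared UMIs would point at cross-contamination rather than biology.

Lineages are germline-rooted minimum-spanning trees under nucleotide Hamming
distance: a deterministic, oracle-checkable approximation of maximum-
parsimony networks that preserves branching structure, mutational-step edge
labels and germline rooting.  Multi-step edges keep their mutation count;
intermediate haplotypes are only ever realized by actual member sequences.
"""

from __future__ import annotations

import dataclasses
from collections import Counter

import networkx as nx
import numpy as np
import pandas as pd

MUTATED_CUTOFF = 1.0  # percent SHM; classification is strictly greater-than


def trim_core_region(row) -> str | None:
    """Nucleotide core spanning Kabat positions 12–136 for one rearrangement.

    Returns None (sequence excluded from persistence analysis) when either
    boundary was unresolved during region partitioning.
    """
    cs, ce = row.get("core_start"), row.get("core_end")
    if pd.isna(cs) or pd.isna(ce):
        return None
    return row["sequence"][int(cs) : int(ce)]


def _umi_set(row) -> frozenset:
    sigs = row.get("umi_signatures", "")
    if isinstance(sigs, str) and sigs:
        return frozenset(sigs.split(";"))
    return frozenset()


def find_persistent_sequences(
    samples: dict[str, pd.DataFrame],
    mutated_cutoff: float = MUTATED_CUTOFF,
) -> pd.DataFrame:
    """Sequences whose trimmed core is present in *every* sample.

    Returns one row per persistent core with the consensus isotype, mean SHM,
    the strict >1%-SHM mutated classification, and the UMI cross-check:
    a core supported by the same UMI signature in two samples is flagged
    ``contamination_suspect`` (excluded from headline counts by callers).
    """
    if len(samples) < 2:
        raise ValueError("persistence needs ≥2 samples")
    core_maps: dict[str, dict[str, list]] = {}
    for sid, df in samples.items():
        cores: dict[str, list] = {}
        for rec in df.to_dict("records"):
            core = trim_core_region(rec)
            if core is not None:
                cores.setdefault(core, []).append(rec)
        core_maps[sid] = cores
    sample_ids = sorted(samples)
    shared = set(core_maps[sample_ids[0]])
    for sid in sample_ids[1:]:
        shared &= set(core_maps[sid])
    rows = []
    for core in sorted(shared):
        isotypes: list[str] = []
        shms: list[float] = []
        umi_sets: list[frozenset] = []
        for sid in sample_ids:
            recs = core_maps[sid][core]
            isotypes += [r.get("isotype", "") for r in recs]
            shms += [float(r["shm_percent"]) for r in recs]
            umi_sets.append(frozenset().union(*[_umi_set(r) for r in recs]))
        disjoint = all(
            not (umi_sets[i] & umi_sets[j])
            for i in range(len(umi_sets)) for j in range(i + 1, len(umi_sets))
        )
        iso_counts = Counter(i for i in isotypes if i)
        consensus = min([i for i, n in iso_counts.items()
                         if n == max(iso_counts.values())]) if iso_counts else ""
        mean_shm = float(np.mean(shms))
        rows.append({
            "core_sequence": core,
            "n_samples": len(sample_ids),
            "sample_ids": ";".join(sample_ids),
            "isotype_consensus": consensus,
            "mean_shm": round(mean_shm, 4),
            "mutated": mean_shm > mutated_cutoff,
            "umi_disjoint": disjoint,
            "contamination_suspect": not disjoint,
        })
    df = pd.DataFrame(rows, columns=[
        "core_sequence", "n_samples", "sample_ids", "isotype_consensus",
        "mean_shm", "mutated", "umi_disjoint", "contamination_suspect",
    ])
    return df.astype({"mutated": bool, "umi_disjoint": bool,
                      "contamination_suspect": bool, "mean_shm": float})


# ---------------------------------------------------------------------------
# mAb matching

def match_mabs_to_clones(
    rearrs_all_unique: pd.DataFrame,
    mab_records: list[tuple[str, str]],
    annotator,
    threshold: float = 0.12,
    region: str = "cdrh3",
) -> pd.DataFrame:
    """Co-cluster mAb heavy chains with an all-unique-reads repertoire.

    Each mAb is annotated through the same aligner, appended to the
    repertoire as an ordinary sequence, and clustered at the constant
    ``threshold`` (nucleotide mismatch on the CDRH3 by default).  The report
    says, per mAb, whether it co-clustered with ≥1 repertoire sequence, how
    many, and in which clone.  Unannotatable mAbs are reported as such.
    """
    from .clonal import cluster_clones

    mab_rows = []
    status: dict[str, str] = {}
    for mab_id, seq in mab_records:
        ann = annotator.annotate(seq)
        if ann is None:
            status[mab_id] = "unannotatable"
            continue
        status[mab_id] = "annotated"
        mab_rows.append({
            "sequence_id": f"mab:{mab_id}", "sequence": seq, "c_call": "",
            "isotype": "", "consensus_count": 0, "duplicate_count": 0,
            "clone_id": "", **{k: v for k, v in ann.items()},
        })
    combined = pd.concat(
        [rearrs_all_unique, pd.DataFrame(mab_rows, columns=rearrs_all_unique.columns)],
        ignore_index=True,
    ) if mab_rows else rearrs_all_unique.copy()
    clustered, _ = cluster_clones(combined, threshold, region=region)
    by_id = clustered.set_index("sequence_id")
    rows = []
    for mab_id, _ in mab_records:
        if status[mab_id] == "unannotatable":
            rows.append({"mab_id": mab_id, "status": "unannotatable",
                         "matched": False, "n_matching_sequences": 0, "clone_id": ""})
            continue
        clone_id = by_id.loc[f"mab:{mab_id}", "clone_id"]
        members = clustered[clustered["clone_id"] == clone_id]
        n_rep = int((~members["sequence_id"].astype(str).str.startswith("mab:")).sum())
        rows.append({
            "mab_id": mab_id, "status": "annotated", "matched": n_rep >= 1,
            "n_matching_sequences": n_rep, "clone_id": clone_id if n_rep else "",
        })
    return pd.DataFrame(rows, columns=[
        "mab_id", "status", "matched", "n_matching_sequences", "clone_id",
    ])


# ---------------------------------------------------------------------------
# lineage reconstruction

@dataclasses.dataclass
class LineageNode:
    node_id: str
    sequence: str
    kind: str  # germline | observed
    isotypes: frozenset
    reads: int


@dataclasses.dataclass
class LineageTree:
    """Germline-rooted parsimony network of one clonal family."""

    root: str
    nodes: dict[str, LineageNode]
    edges: list[tuple[str, str, int]]  # (parent, child, nt mutation count)

    @property
    def total_length(self) -> int:
        return sum(w for _, _, w in self.edges)

    def to_newick(self) -> str:
        children: dict[str, list] = {}
        for parent, child, w in self.edges:
            children.setdefault(parent, []).append((child, w))

        def render(node: str) -> str:
            kids = sorted(children.get(node, []))
            if not kids:
                return node
            inner = ",".join(f"{render(c)}:{w}" for c, w in kids)
            return f"({inner}){node}"

        return render(self.root) + ";"

    def node_table(self) -> pd.DataFrame:
        return pd.DataFrame([
            {"node_id": n.node_id, "kind": n.kind,
             "isotypes": ";".join(sorted(n.isotypes)), "reads": n.reads,
             "sequence": n.sequence}
            for n in self.nodes.values()
        ])


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def build_lineage(members: pd.DataFrame, germline_sequence: str) -> LineageTree:
    """Minimum-spanning lineage over {germline ∪ clone members}.

    All sequences must share one length (guaranteed for clones built from
    equal-junction-length partitions on indel-free alignments).  Identical
    member sequences merge into one observed node (isotype set union, reads
    summed).  Edges are chosen by Kruskal on (distance, lexicographic
    sequence pair), so the tree is deterministic; the tree is then rooted at
    the germline node.
    """
    lengths = {len(s) for s in members["sequence"]} | {len(germline_sequence)}
    if len(lengths) != 1:
        raise ValueError("lineage members must share one aligned length")
    merged: dict[str, dict] = {}
    for rec in members.to_dict("records"):
        slot = merged.setdefault(rec["sequence"], {"isotypes": set(), "reads": 0,
                                                   "ids": []})
        if rec.get("isotype"):
            slot["isotypes"].add(rec["isotype"])
        slot["reads"] += int(rec.get("duplicate_count", 1) or 1)
        slot["ids"].append(str(rec.get("sequence_id", "")))
    nodes: dict[str, LineageNode] = {
        "germline": LineageNode("germline", germline_sequence, "germline",
                                frozenset(), 0)
    }
    seq_to_node = {}
    for seq in sorted(merged):
        if seq == germline_sequence:
            # a member identical to germline stays an observed node
            pass
        nid = sorted(merged[seq]["ids"])[0] or f"node{len(nodes)}"
        nodes[nid] = LineageNode(nid, seq, "observed",
                                 frozenset(merged[seq]["isotypes"]),
                                 merged[seq]["reads"])
        seq_to_node[seq] = nid
    graph = nx.Graph()
    ids = sorted(nodes)
    graph.add_nodes_from(ids)
    edges = []
    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            d = _hamming(nodes[a].sequence, nodes[b].sequence)
            edges.append((d, min(a, b), max(a, b)))
    for d, a, b in sorted(edges):
        graph.add_edge(a, b, weight=d)
    mst = nx.minimum_spanning_tree(graph, algorithm="kruskal")
    directed = []
    for parent, child in nx.bfs_edges(mst, "germline"):
        directed.append((parent, child, int(mst[parent][child]["weight"])))
    return LineageTree(root="germline", nodes=nodes, edges=sorted(directed))


# ---------------------------------------------------------------------------
# immunodominance grid

@dataclasses.dataclass
class ImmunodominanceGrid:
    """2-D histogram of clones over (read abundance, mean SHM)."""

    counts: np.ndarray  # shape (n_abundance_bins, n_shm_bins)
    abundance_edges: np.ndarray  # log10(reads) bin edges
    shm_edges: np.ndarray  # percent SHM bin edges
    overlays: pd.DataFrame  # named mAb clones at (reads, mean SHM)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i in range(self.counts.shape[0]):
            for j in range(self.counts.shape[1]):
                rows.append({
                    "log10_abundance_low": self.abundance_edges[i],
                    "log10_abundance_high": self.abundance_edges[i + 1],
                    "shm_low": self.shm_edges[j],
                    "shm_high": self.shm_edges[j + 1],
                    "n_clones": int(self.counts[i, j]),
                })
        return pd.DataFrame(rows)


def immunodominance_grid(
    clones,
    mab_matches: pd.DataFrame | None = None,
    n_abundance_bins: int = 12,
    n_shm_bins: int = 12,
) -> ImmunodominanceGrid:
    """Clone-density heat map: log-scaled read abundance × linear mean SHM.

    Cell counts sum to the clone count; matched mAb clones are overlaid as
    labeled points at their clone's (read abundance, mean SHM).
    """
    reads = np.array([max(c.abundance_reads, 1) for c in clones], dtype=float)
    shm = np.array([c.mean_shm for c in clones], dtype=float)
    log_reads = np.log10(reads)
    a_max = max(log_reads.max(initial=0.0), 0.1)
    s_max = max(shm.max(initial=0.0), 1.0)
    a_edges = np.linspace(0.0, a_max * (1 + 1e-9) + 1e-12, n_abundance_bins + 1)
    s_edges = np.linspace(0.0, s_max * (1 + 1e-9) + 1e-12, n_shm_bins + 1)
    counts, _, _ = np.histogram2d(log_reads, shm, bins=[a_edges, s_edges])
    overlay_rows = []
    if mab_matches is not None:
        by_clone = {c.clone_id: c for c in clones}
        for rec in mab_matches.to_dict("records"):
            clone = by_clone.get(rec.get("clone_id", ""))
            if rec.get("matched") and clone is not None:
                overlay_rows.append({
                    "mab_id": rec["mab_id"],
                    "abundance_reads": clone.abundance_reads,
                    "mean_shm": clone.mean_shm,
                    "clone_id": clone.clone_id,
                })
    overlays = pd.DataFrame(overlay_rows,
                            columns=["mab_id", "abundance_reads", "mean_shm", "clone_id"])
    return ImmunodominanceGrid(counts, a_edges, s_edges, overlays)
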