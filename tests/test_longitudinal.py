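"""Persistence, mAb matching, lineage reconstruction and the clone grid."""

import numpy as np
import pandas as pd
import pytest

from bcrpipe import clonal, longitudinal as L
from oracles import mst_total_length


def make_row(seq, core=(0, None), shm=0.0, isotype="IgM", umis="U1", sid="s0"):
    end = len(seq) if core[1] is None else core[1]
    return {"sequence_id": sid, "sequence": seq, "core_start": core[0],
            "core_end": end, "shm_percent": shm, "isotype": isotype,
            "umi_signatures": umis, "duplicate_count": 1}


def test_trim_core_identity_and_locality():
    row = make_row("AACCGGTT", core=(2, 6))
    assert L.trim_core_region(row) == "CCGG"
    other = make_row("TTCCGGAA", core=(2, 6))
    assert L.trim_core_region(other) == L.trim_core_region(row)
    unresolved = make_row("AACC", core=(0, None))
    unresolved["core_end"] = pd.NA
    assert L.trim_core_region(unresolved) is None


def test_persistence_requires_all_samples():
    a = pd.DataFrame([make_row("AAAACCCCGGGG", umis="U1")])
    b = pd.DataFrame([make_row("AAAACCCCGGGG", umis="U2")])
    c = pd.DataFrame([make_row("TTTTCCCCGGGG", umis="U3")])
    out = L.find_persistent_sequences({"s1": a, "s2": b, "s3": c})
    assert out.empty
    out = L.find_persistent_sequences({"s1": a, "s2": b})
    assert len(out) == 1 and out.iloc[0]["umi_disjoint"]


def test_persistence_against_itself_returns_unique_cores():
    df = pd.DataFrame([make_row("AAAACCCCGGGG", umis="U1"),
                       make_row("TTTTCCCCGGGG", umis="U2", sid="s1")])
    out = L.find_persistent_sequences({"a": df, "b": df})
    assert len(out) == 2


def test_persistence_monotone_in_samples():
    rows = [make_row("AAAACCCC" + s, umis=f"U{i}") for i, s in
            enumerate(["GGGG", "TTTT", "CCCC"])]
    a = pd.DataFrame(rows)
    b = pd.DataFrame(rows[:2]).assign(umi_signatures=["V0", "V1"])
    c = pd.DataFrame(rows[:1]).assign(umi_signatures=["W0"])
    two = L.find_persistent_sequences({"a": a, "b": b})
    three = L.find_persistent_sequences({"a": a, "b": b, "c": c})
    assert set(three["core_sequence"]) <= set(two["core_sequence"])


def test_mutated_classification_is_strict():
    a = pd.DataFrame([make_row("AAAACCCCGGGG", shm=0.5, umis="U1")])
    b = pd.DataFrame([make_row("AAAACCCCGGGG", shm=0.5, umis="U2")])
    out = L.find_persistent_sequences({"a": a, "b": b})
    assert not out.iloc[0]["mutated"]
    a.loc[0, "shm_percent"] = b.loc[0, "shm_percent"] = 1.5
    out = L.find_persistent_sequences({"a": a, "b": b})
    assert out.iloc[0]["mutated"]


def test_shared_umi_flags_contamination():
    a = pd.DataFrame([make_row("AAAACCCCGGGG", umis="SAME")])
    b = pd.DataFrame([make_row("AAAACCCCGGGG", umis="SAME")])
    out = L.find_persistent_sequences({"a": a, "b": b})
    assert out.iloc[0]["contamination_suspect"]


# ---------------------------------------------------------------------------
# mAb matching

def _repertoire_with_relative(annotator, ref):
    """Annotated two-sequence repertoire derived from germline V+J."""
    v = ref.v_genes[sorted(ref.v_genes)[0]]
    j = ref.j_genes[sorted(ref.j_genes)[0]]
    seq = v.sequence + j.sequence
    row = annotator.annotate(seq)
    df = pd.DataFrame([{
        "sequence_id": "rep0", "sequence": seq, "c_call": "IgG1",
        "isotype": "IgG", "consensus_count": 3, "duplicate_count": 2,
        "clone_id": "", **row,
    }])
    return df, seq, row


def test_mab_identical_and_too_far(annotator, ref):
    df, seq, row = _repertoire_with_relative(annotator, ref)
    js, je = row["junction_length"], None
    # identical mAb matches
    out = L.match_mabs_to_clones(df, [("mab_same", seq)], annotator, 0.12)
    assert out.iloc[0]["matched"] and out.iloc[0]["n_matching_sequences"] >= 1
    # mutate >12% of CDRH3 positions → unmatched at the constant threshold
    cdrh3 = row["cdrh3"]
    k = int(np.ceil(0.13 * len(cdrh3))) + 1
    start = seq.find(cdrh3)
    mutated = list(seq)
    for i in range(k):
        pos = start + i
        mutated[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[mutated[pos]]
    out = L.match_mabs_to_clones(df, [("mab_far", "".join(mutated))],
                                 annotator, 0.12)
    assert not out.iloc[0]["matched"]
    # garbage mAb reported unannotatable
    rng = np.random.default_rng(0)
    junk = "".join(rng.choice(list("ACGT"), 300))
    out = L.match_mabs_to_clones(df, [("mab_bad", junk)], annotator, 0.12)
    assert out.iloc[0]["status"] == "unannotatable"


# ---------------------------------------------------------------------------
# lineage

def members_frame(seqs, reads=None):
    return pd.DataFrame([
        {"sequence_id": f"m{i}", "sequence": s, "isotype": "IgG",
         "duplicate_count": (reads or [1] * len(seqs))[i]}
        for i, s in enumerate(seqs)
    ])


def test_stepwise_chain_reconstruction():
    germ = "AAAAAAAAAA"
    a = "CAAAAAAAAA"          # 1 mutation from germline
    b = "CAAAAAAAAT"          # 1 more on top of A
    tree = L.build_lineage(members_frame([a, b]), germ)
    assert tree.total_length == 2
    edges = {(p, c): w for p, c, w in tree.edges}
    assert edges[("germline", "m0")] == 1
    assert edges[("m0", "m1")] == 1


def test_singleton_clone_single_edge():
    germ = "ACGTACGT"
    tree = L.build_lineage(members_frame(["ACGTACGA"]), germ)
    assert tree.edges == [("germline", "m0", 1)]


def test_tree_not_longer_than_star():
    rng = np.random.default_rng(4)
    germ = "".join(rng.choice(list("ACGT"), 40))
    seqs = []
    for _ in range(6):
        s = list(germ)
        for pos in rng.choice(40, size=rng.integers(1, 6), replace=False):
            s[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[s[pos]]
        seqs.append("".join(s))
    tree = L.build_lineage(members_frame(seqs), germ)
    star = sum(sum(x != y for x, y in zip(s, germ)) for s in set(seqs))
    assert tree.total_length <= star


def test_mst_matches_bruteforce_oracle():
    rng = np.random.default_rng(8)
    for trial in range(10):
        n = int(rng.integers(2, 8))
        germ = "".join(rng.choice(list("ACGT"), 25))
        seqs = []
        for _ in range(n):
            s = list(germ)
            for pos in rng.choice(25, size=rng.integers(0, 7), replace=False):
                s[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[s[pos]]
            seqs.append("".join(s))
        tree = L.build_lineage(members_frame(seqs), germ)
        unique = sorted(set(seqs) | {germ})
        assert tree.total_length == mst_total_length(unique)


def test_unequal_lengths_rejected():
    with pytest.raises(ValueError):
        L.build_lineage(members_frame(["AAAA", "AAAAA"]), "AAAA")


def test_newick_and_node_table():
    germ = "AAAAAAAAAA"
    tree = L.build_lineage(members_frame(["CAAAAAAAAA"], reads=[7]), germ)
    assert tree.to_newick() == "(m0:1)germline;"
    table = tree.node_table()
    assert set(table["node_id"]) == {"germline", "m0"}
    assert table.loc[table["node_id"] == "m0", "reads"].iloc[0] == 7


# ---------------------------------------------------------------------------
# immunodominance grid

def _clone(cid, reads, shm, v="IGHV1-1", j="IGHJ1", jl=30, n=1):
    return clonal.Clone(cid, [f"{cid}.m"], v, j, jl, n, reads, shm, {"IgG": n})


def test_grid_counts_conserved_and_singleton_mass():
    clones = [_clone(f"c{i}", 1, 0.0) for i in range(5)]
    grid = L.immunodominance_grid(clones)
    assert grid.counts.sum() == 5
    assert grid.counts[0, 0] == 5  # all mass in the (1 read, 0% SHM) cell


def test_grid_overlay_lands_in_high_abundance_bin():
    clones = [_clone(f"c{i}", 1, 0.2) for i in range(30)]
    dominant = _clone("big", 500, 3.0, n=166)
    clones.append(dominant)
    matches = pd.DataFrame([{"mab_id": "mab1", "matched": True,
                             "clone_id": "big"}])
    grid = L.immunodominance_grid(clones, matches)
    assert grid.counts.sum() == 31
    ov = grid.overlays.iloc[0]
    assert ov["abundance_reads"] == 500 and ov["mean_shm"] == 3.0
    # the overlay's abundance falls in the top abundance bin
    assert np.log10(500) > grid.abundance_edges[-2]
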