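"""Reproducible benchmark experiments on simulated repertoires.

Each function sets up a ground-truth simulation at its stated study
condition, runs the relevant pipeline stages, and returns the measured
quantities together with the planted expectation.  They are used by the
test suite and the results-reproduction script; all randomness derives from
the ``seed`` argument.
"""

from __future__ import annotations

import dataclasses
from collections import defaultdict

import numpy as np
import pandas as pd

from . import clonal, preprocess, sim
from .annotate import Annotator
from .longitudinal import build_lineage, find_persistent_sequences, match_mabs_to_clones
from .reference import GermlineReference, default_reference


def _mutate_base(b: str) -> str:
    return {"A": "C", "C": "G", "G": "T", "T": "A"}[b]


def cells_to_rearrangements(cells, annotator: Annotator) -> pd.DataFrame:
    """Annotate cell V(D)J sequences directly (no read simulation)."""
    rows = []
    cache: dict[str, dict] = {}
    for cell in cells:
        if cell.sequence not in cache:
            cache[cell.sequence] = annotator.annotate(cell.sequence)
        ann = cache[cell.sequence]
        if ann is None:
            continue
        rows.append({
            "sequence_id": cell.cell_id, "sequence": cell.sequence,
            "c_call": cell.isotype, "isotype": cell.isotype[:3],
            "consensus_count": 1, "duplicate_count": 1, "clone_id": "",
            **ann,
        })
    return pd.DataFrame(rows)


def adjusted_rand_index(labels_a, labels_b) -> float:
    """ARI from the pair-counting contingency table."""
    a = pd.factorize(pd.Series(labels_a))[0]
    b = pd.factorize(pd.Series(labels_b))[0]
    n = len(a)
    table = defaultdict(int)
    for x, y in zip(a, b):
        table[(x, y)] += 1

    def comb2(x):
        return x * (x - 1) / 2.0

    sum_cells = sum(comb2(v) for v in table.values())
    rows, cols = defaultdict(int), defaultdict(int)
    for (x, y), v in table.items():
        rows[x] += v
        cols[y] += v
    sum_rows = sum(comb2(v) for v in rows.values())
    sum_cols = sum(comb2(v) for v in cols.values())
    expected = sum_rows * sum_cols / comb2(n)
    max_index = (sum_rows + sum_cols) / 2.0
    if max_index == expected:
        return 1.0
    return (sum_cells - expected) / (max_index - expected)


def truth_shm_percent(cell, ref: GermlineReference) -> float:
    """SHM as the pipeline defines it, from planted mutation positions."""
    cys = ref.v_genes[cell.v_name].anchors["CYS104"]
    return 100.0 * sum(1 for p in cell.mutated_positions if p < cys) / cys


def truth_core(cell, ref: GermlineReference) -> str:
    """Kabat-12..136 core straight from the simulation geometry."""
    v = ref.v_genes[cell.v_name]
    j = ref.j_genes[cell.j_name]
    start = v.anchors["KABAT12"]
    end = cell.j_start + (j.anchors["KABAT136"] - cell.j_trim)
    return cell.sequence[start:end]


# ---------------------------------------------------------------------------
# noise-free round trip

def roundtrip_experiment(seed: int, n_cells: int = 2000) -> dict:
    """Error-free reads → recovered sequences, isotypes and V/J calls."""
    ref = default_reference()
    annotator = Annotator(ref)
    config = sim.SimulationConfig(n_cells=n_cells, per_base_error=0.0, seed=seed)
    cells = sim.simulate_repertoire(config, ref)
    import tempfile
    from . import io as bio

    with tempfile.TemporaryDirectory() as tmp:
        truth = sim.generate_reads(
            cells, config, ref, f"{tmp}/r1.fastq.gz", f"{tmp}/r2.fastq.gz",
            sample_id="rt")
        pairs = bio.read_fastq_pairs(f"{tmp}/r1.fastq.gz", f"{tmp}/r2.fastq.gz")
    table, report = preprocess.preprocess_sample(
        pairs, constant_stubs=ref.constant_stubs, min_reads_per_umi=1)
    report.assert_conservation()
    truth_seqs = set(truth["sequence"])
    got_seqs = set(table["sequence"])
    iso_by_seq = dict(zip(truth["sequence"], truth["isotype"]))
    iso_ok = sum(1 for r in table.to_dict("records")
                 if r["subtype"] == iso_by_seq.get(r["sequence"]))
    call_by_seq = {t.sequence: (t.v_call, t.j_call) for t in truth.itertuples()}
    vj_ok = 0
    for seq in sorted(got_seqs):
        ann = annotator.annotate(seq)
        if ann and (ann["v_call"], ann["j_call"]) == call_by_seq.get(seq):
            vj_ok += 1
    return {
        "n_cells": n_cells,
        "n_transcripts": len(truth),
        "n_unique_sequences": len(got_seqs),
        "sequence_sets_equal": got_seqs == truth_seqs,
        "sequence_recovery_percent": 100.0 * len(got_seqs & truth_seqs)
        / len(truth_seqs),
        "isotype_accuracy_percent": 100.0 * iso_ok / len(table),
        "vj_accuracy_percent": 100.0 * vj_ok / len(got_seqs),
    }


# ---------------------------------------------------------------------------
# clone recovery

def clone_recovery_experiment(seed: int, n_clones: int = 500,
                              shm_rate: float = 0.03) -> dict:
    """Planted clones (sizes 1–50) → threshold estimation and clustering."""
    ref = default_reference()
    annotator = Annotator(ref)
    comp = dataclasses.replace(sim.memory_compartment(1.0), shm_rate=shm_rate,
                               clone_alpha=2.0, clone_max_size=50)
    config = sim.SimulationConfig(n_cells=3 * n_clones, compartments=(comp,),
                                  per_base_error=0.0, seed=seed)
    cells = sim.simulate_repertoire(config, ref)
    clone_order = list(dict.fromkeys(c.clone_id for c in cells))
    keep = set(clone_order[:n_clones])
    cells = [c for c in cells if c.clone_id in keep]
    rearrs = cells_to_rearrangements(cells, annotator)
    dist = clonal.distance_to_nearest(rearrs)
    est = clonal.find_threshold(dist)
    clustered, clones = clonal.cluster_clones(rearrs, est.threshold)
    truth_by_id = {c.cell_id: c.clone_id for c in cells}
    truth_labels = [truth_by_id[s] for s in clustered["sequence_id"]]
    ari = adjusted_rand_index(truth_labels, clustered["clone_id"].tolist())
    return {
        "n_clones_planted": n_clones,
        "n_cells": len(cells),
        "n_clones_inferred": len(clones),
        "threshold": est.threshold,
        "threshold_method": est.method,
        "adjusted_rand_index": ari,
        "rearrangements": clustered,
        "clones": clones,
    }


# ---------------------------------------------------------------------------
# persistence across timepoints

def persistence_experiment(seed: int, n_persistent: int = 50,
                           n_cells: int = 400) -> dict:
    """Three timepoints sharing planted persistent sequences."""
    ref = default_reference()
    config = sim.SimulationConfig(n_cells=n_cells, per_base_error=0.0, seed=seed)
    samples = ("nov", "may", "aug")
    plan = sim.plan_timepoints(config, ref, samples,
                               persistent_count=n_persistent)
    import tempfile
    from . import io as bio
    from .annotate import annotate_table

    annotator = Annotator(ref)
    used: set[str] = set()
    tables = {}
    with tempfile.TemporaryDirectory() as tmp:
        for i, sid in enumerate(samples):
            sim.generate_reads(
                plan[sid], config, ref, f"{tmp}/{sid}1.fq.gz",
                f"{tmp}/{sid}2.fq.gz", sample_id=sid,
                rng=np.random.default_rng([seed, i, 7]), used_umis=used)
            pairs = bio.read_fastq_pairs(f"{tmp}/{sid}1.fq.gz",
                                         f"{tmp}/{sid}2.fq.gz")
            table, _ = preprocess.preprocess_sample(
                pairs, constant_stubs=ref.constant_stubs, min_reads_per_umi=1)
            rearrs, _ = annotate_table(table, ref, {"sample_id": sid}, annotator)
            tables[sid] = rearrs
    persist = find_persistent_sequences(tables)
    clean = persist[~persist["contamination_suspect"]]
    planted = [c for c in plan[samples[0]] if c.clone_id.startswith("P")]
    planted_cores = {truth_core(c, ref) for c in planted}
    planted_mutated = {truth_core(c, ref): truth_shm_percent(c, ref) > 1.0
                       for c in planted}
    got_cores = set(clean["core_sequence"])
    classified_ok = sum(
        1 for rec in clean.to_dict("records")
        if rec["core_sequence"] in planted_mutated
        and rec["mutated"] == planted_mutated[rec["core_sequence"]]
    )
    return {
        "n_planted": len(planted_cores),
        "n_recovered": len(clean),
        "recovered_equals_planted": got_cores == planted_cores,
        "all_umi_disjoint": bool(clean["umi_disjoint"].all()),
        "n_classification_correct": classified_ok,
        "n_mutated_planted": sum(planted_mutated.values()),
        "n_mutated_recovered": int(clean["mutated"].sum()),
    }


# ---------------------------------------------------------------------------
# mAb spike-in matching

def mab_matching_experiment(seed: int, n_mabs: int = 8) -> dict:
    """8 spiked mAbs, 7 with relatives within 12% CDRH3, one beyond."""
    ref = default_reference()
    annotator = Annotator(ref)
    comp = dataclasses.replace(sim.memory_compartment(1.0), shm_rate=0.03)
    config = sim.SimulationConfig(n_cells=600, compartments=(comp,),
                                  per_base_error=0.0, seed=seed)
    cells = sim.simulate_repertoire(config, ref)
    rearrs = cells_to_rearrangements(cells, annotator)
    # pick source sequences from distinct clones with roomy CDRH3s
    by_id = {c.cell_id: c for c in cells}
    sources = []
    seen_clones = set()
    for rec in rearrs.to_dict("records"):
        clone = by_id[rec["sequence_id"]].clone_id
        if clone in seen_clones or len(rec["cdrh3"]) < 25:
            continue
        seen_clones.add(clone)
        sources.append(rec)
        if len(sources) == n_mabs:
            break
    if len(sources) < n_mabs:
        raise RuntimeError("simulation yielded too few distinct clones")
    mabs = []
    expected_matches = set()
    for i, rec in enumerate(sources):
        seq, cdrh3 = rec["sequence"], rec["cdrh3"]
        start = seq.find(cdrh3)
        L = len(cdrh3)
        if i < n_mabs - 1:  # relative: ≤12% CDRH3 mismatch
            k = max(1, int(0.08 * L))
            expected_matches.add(f"mab{i}")
        else:  # decoy: well beyond the constant threshold
            k = int(np.ceil(0.2 * L)) + 2
        mutated = list(seq)
        for pos in range(start, start + k):
            mutated[pos] = _mutate_base(mutated[pos])
        mabs.append((f"mab{i}", "".join(mutated)))
    matches = match_mabs_to_clones(rearrs, mabs, annotator, threshold=0.12)
    matched_ids = set(matches.loc[matches["matched"], "mab_id"])
    return {
        "n_mabs": n_mabs,
        "n_expected_matched": len(expected_matches),
        "n_matched": len(matched_ids),
        "matched_equals_expected": matched_ids == expected_matches,
        "matches": matches,
    }


# ---------------------------------------------------------------------------
# lineage reconstruction

def lineage_experiment(seed: int, max_members: int = 8) -> dict:
    """MST lineages vs an independent MST oracle on small planted clones."""
    from scipy.sparse.csgraph import minimum_spanning_tree as scipy_mst

    ref = default_reference()
    comp = dataclasses.replace(sim.memory_compartment(1.0), shm_rate=0.02,
                               clone_alpha=1.2, clone_max_size=max_members)
    config = sim.SimulationConfig(n_cells=120, compartments=(comp,),
                                  per_base_error=0.0, seed=seed)
    cells = sim.simulate_repertoire(config, ref)
    clones: dict[str, list] = defaultdict(list)
    for c in cells:
        clones[c.clone_id].append(c)
    agree = total = 0
    for cid, members in sorted(clones.items()):
        germ = members[0].naive_sequence
        frame = pd.DataFrame([
            {"sequence_id": m.cell_id, "sequence": m.sequence,
             "isotype": m.isotype[:3], "duplicate_count": 1}
            for m in members
        ])
        tree = build_lineage(frame, germ)
        unique = sorted({m.sequence for m in members} | {germ})
        n = len(unique)
        dist = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                d = sum(x != y for x, y in zip(unique[i], unique[j]))
                dist[i, j] = d
        oracle = int(round(scipy_mst(dist + dist.T).sum()))
        total += 1
        agree += int(tree.total_length == oracle)
    # stepwise chain fixture
    germ = "A" * 60
    a = "C" + germ[1:]
    b = "C" + germ[1:-1] + "T"
    chain = build_lineage(pd.DataFrame([
        {"sequence_id": "A", "sequence": a, "isotype": "IgG", "duplicate_count": 1},
        {"sequence_id": "B", "sequence": b, "isotype": "IgG", "duplicate_count": 1},
    ]), germ)
    edges = {(p, c): w for p, c, w in chain.edges}
    return {
        "n_clones": total,
        "n_mst_oracle_agree": agree,
        "oracle_agreement_fraction": agree / total,
        "chain_edges_ok": edges == {("germline", "A"): 1, ("A", "B"): 1},
    }


# ---------------------------------------------------------------------------
# compartment enrichment

PBMC_WEIGHTS = {"naive": 0.97, "memory": 0.03}
STIM_WEIGHTS = {"naive": 0.15, "memory": 0.85}


def _expected_isotype_fraction(weights, isotype: str) -> float:
    comps = {"naive": sim.naive_compartment(), "memory": sim.memory_compartment()}
    total = 0.0
    for name, w in weights.items():
        profile = comps[name].isotype_profile
        total += w * sum(p for sub, p in profile.items()
                         if sub.startswith(isotype))
    return total


def _expected_shm(weights, isotype: str) -> float:
    comps = {"naive": sim.naive_compartment(), "memory": sim.memory_compartment()}
    mass = {n: w * sum(p for s, p in comps[n].isotype_profile.items()
                       if s.startswith(isotype))
            for n, w in weights.items()}
    z = sum(mass.values())
    return sum(mass[n] / z * 100.0 * comps[n].shm_rate for n in mass)


def enrichment_experiment(seed: int, n_cells: int = 2500) -> dict:
    """PBMC-like vs stimulated-like sample through the full read pipeline."""
    from . import io as bio, stats
    from .annotate import annotate_table
    import tempfile

    ref = default_reference()
    annotator = Annotator(ref)
    out = {}
    for idx, (label, weights) in enumerate(
            (("pbmc", PBMC_WEIGHTS), ("stim", STIM_WEIGHTS))):
        comps = (sim.naive_compartment(weights["naive"]),
                 sim.memory_compartment(weights["memory"]))
        config = sim.SimulationConfig(n_cells=n_cells, compartments=comps,
                                      per_base_error=0.002, seed=seed)
        cells = sim.simulate_repertoire(
            config, ref, rng=np.random.default_rng([seed, 100 + idx]))
        with tempfile.TemporaryDirectory() as tmp:
            truth = sim.generate_reads(cells, config, ref, f"{tmp}/1.fq.gz",
                                       f"{tmp}/2.fq.gz", sample_id=label,
                                       rng=np.random.default_rng([seed, 200 + idx]))
            pairs = bio.read_fastq_pairs(f"{tmp}/1.fq.gz", f"{tmp}/2.fq.gz")
        table, _ = preprocess.preprocess_sample(
            pairs, constant_stubs=ref.constant_stubs, min_reads_per_umi=2)
        rearrs, _ = annotate_table(table, ref, {"sample_id": label}, annotator)
        props = stats.isotype_proportions(rearrs)
        shm_igm = float(rearrs.loc[rearrs["isotype"] == "IgM",
                                   "shm_percent"].mean())
        shm_igg = float(rearrs.loc[rearrs["isotype"] == "IgG",
                                   "shm_percent"].mean())
        # planted expectation: cells whose reads survive the ≥2 reads-per-UMI
        # rule, taken straight from the truth table
        retained = set(
            truth.loc[truth["n_reads"] >= 2, "cell_id"])
        kept = [c for c in cells if c.cell_id in retained]
        iso_kept = [c.isotype[:3] for c in kept]
        n_kept = len(kept)
        truth_igg = sum(1 for i in iso_kept if i == "IgG") / n_kept
        truth_igm = sum(1 for i in iso_kept if i == "IgM") / n_kept
        truth_shm = {
            iso: float(np.mean([truth_shm_percent(c, ref) for c in kept
                                if c.isotype.startswith(iso)]))
            for iso in ("IgM", "IgG")
        }
        out[label] = {
            "n_sequences": len(rearrs),
            "igg_fraction": props.get("IgG", 0.0),
            "igm_fraction": props.get("IgM", 0.0),
            "shm_igm_percent": shm_igm,
            "shm_igg_percent": shm_igg,
            "planted_igg_fraction": truth_igg,
            "planted_igm_fraction": truth_igm,
            "planted_shm_igm_percent": truth_shm["IgM"],
            "planted_shm_igg_percent": truth_shm["IgG"],
            "configured_igg_fraction": _expected_isotype_fraction(weights, "IgG"),
            "configured_shm_igm_percent": _expected_shm(weights, "IgM"),
            "configured_shm_igg_percent": _expected_shm(weights, "IgG"),
        }
    return out
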