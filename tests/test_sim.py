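"""Repertoire simulator: generative guarantees and statistical oracles."""

import dataclasses
import gzip

import numpy as np
import pytest

from bcrpipe import sim
from bcrpipe.errors import ConfigurationError
from bcrpipe.reference import make_reference


def test_zero_shm_reproduces_germline_recombination(ref):
    comp = dataclasses.replace(sim.naive_compartment(1.0), shm_rate=0.0)
    config = sim.SimulationConfig(n_cells=50, compartments=(comp,), seed=1)
    for cell in sim.simulate_repertoire(config, ref):
        assert cell.sequence == cell.naive_sequence
        assert cell.mutated_positions == ()


def test_degenerate_isotype_profile(ref):
    comp = dataclasses.replace(
        sim.naive_compartment(1.0),
        isotype_profile={"IgM": 1.0},
    )
    config = sim.SimulationConfig(n_cells=40, compartments=(comp,), seed=2)
    assert all(c.isotype == "IgM" for c in sim.simulate_repertoire(config, ref))


def test_shm_binomial_expectation():
    """Mean mutated-site count matches the binomial expectation n·p.

    300-nt V regions at 5% per-site rate: the direct binomial oracle gives
    mean 15, s.e. sqrt(n·p·(1−p))/sqrt(cells) on the per-cell count.
    """
    ref300 = make_reference(seed=17, v_length=300)
    comp = dataclasses.replace(sim.memory_compartment(1.0), shm_rate=0.05,
                               clone_max_size=1)
    config = sim.SimulationConfig(n_cells=1000, compartments=(comp,), seed=8)
    cells = sim.simulate_repertoire(config, ref300)
    # restrict to the germline V span so the oracle n is exactly 300
    counts = [sum(1 for p in c.mutated_positions if p < 300) for c in cells]
    n, p = 300, 0.05
    se = np.sqrt(n * p * (1 - p)) / np.sqrt(len(cells))
    assert abs(np.mean(counts) - n * p) < 3 * se


def test_clone_sizes_conserve_cell_count(ref):
    config = sim.SimulationConfig(n_cells=777, seed=3)
    cells = sim.simulate_repertoire(config, ref)
    assert len(cells) == 777
    sizes = {}
    for c in cells:
        sizes[c.clone_id] = sizes.get(c.clone_id, 0) + 1
    assert sum(sizes.values()) == 777


def test_isotype_marginals_match_profile(ref):
    config = sim.SimulationConfig(n_cells=5000, seed=4)
    cells = sim.simulate_repertoire(config, ref)
    memory = [c for c in cells if c.compartment == "memory"]
    igg1 = sum(1 for c in memory if c.isotype == "IgG1") / len(memory)
    assert abs(igg1 - 0.70) < 0.02


def test_reads_no_noise_identical_and_umi_lengths(ref, tmp_path):
    config = sim.SimulationConfig(n_cells=5, per_base_error=0.0, seed=6)
    cells = sim.simulate_repertoire(config, ref)
    truth = sim.generate_reads(cells, config, ref, tmp_path / "1.fastq",
                               tmp_path / "2.fastq", sample_id="s")
    assert set(truth["umi5"].str.len()) <= {8, 12}
    assert set(truth["umi3"].str.len()) <= {8, 12}
    with open(tmp_path / "1.fastq") as fh:
        lines = fh.read().splitlines()
    by_tx = {}
    for i in range(0, len(lines), 4):
        tx = lines[i].rsplit(".r", 1)[0]
        by_tx.setdefault(tx, set()).add(lines[i + 1])
    assert all(len(seqs) == 1 for seqs in by_tx.values())


def test_error_rate_oracle(ref, tmp_path):
    """Observed mismatch rate vs truth within 3 s.e. of the configured rate."""
    comp = dataclasses.replace(sim.naive_compartment(1.0),
                               transcripts_per_cell=1.0, reads_per_transcript=8.0)
    config = sim.SimulationConfig(n_cells=120, compartments=(comp,),
                                  per_base_error=0.01, seed=7)
    cells = sim.simulate_repertoire(config, ref)
    truth = sim.generate_reads(cells, config, ref, tmp_path / "1.fastq",
                               tmp_path / "2.fastq", sample_id="s")
    templates = {}
    for rec in truth.to_dict("records"):
        p5 = [p for p in sim.DEFAULT_PRIMERS
              if p.end == "5" and p.umi_length == len(rec["umi5"])][0]
        templates[rec["transcript_id"]] = (
            p5.sequence + rec["umi5"] + rec["sequence"])[: config.read_length]
    mismatches = total = 0
    with open(tmp_path / "1.fastq") as fh:
        lines = fh.read().splitlines()
    for i in range(0, len(lines), 4):
        tx = lines[i][1:].rsplit(".r", 1)[0]
        expect = templates[tx]
        got = lines[i + 1]
        mismatches += sum(a != b for a, b in zip(expect, got))
        total += len(expect)
    rate = mismatches / total
    se = np.sqrt(0.01 * 0.99 / total)
    assert abs(rate - 0.01) < 3 * se


def test_determinism_byte_identical(ref, tmp_path):
    config = sim.SimulationConfig(n_cells=30, seed=9)
    for run in ("a", "b"):
        cells = sim.simulate_repertoire(config, ref)
        sim.generate_reads(cells, config, ref, tmp_path / f"{run}1.fastq.gz",
                           tmp_path / f"{run}2.fastq.gz",
                           truth_path=tmp_path / f"{run}t.tsv", sample_id="s")
    for suffix in ("1.fastq.gz", "2.fastq.gz"):
        a = gzip.open(tmp_path / f"a{suffix}").read()
        b = gzip.open(tmp_path / f"b{suffix}").read()
        assert a == b
    assert (tmp_path / "at.tsv").read_bytes() == (tmp_path / "bt.tsv").read_bytes()


def test_timepoint_plan_persistence_and_umi_disjointness(ref, tmp_path):
    config = sim.SimulationConfig(n_cells=60, per_base_error=0.0, seed=10)
    plan = sim.plan_timepoints(config, ref, ("t1", "t2", "t3"),
                               persistent_count=10)
    persistent_ids = {c.cell_id for c in plan["t1"] if c.clone_id.startswith("P")}
    assert len({c.clone_id for c in plan["t1"] if c.clone_id.startswith("P")}) == 10
    seq_sets = [{c.sequence for c in plan[s]} for s in ("t1", "t2", "t3")]
    shared = seq_sets[0] & seq_sets[1] & seq_sets[2]
    assert {c.sequence for c in plan["t1"] if c.cell_id in persistent_ids} <= shared
    # fresh UMIs per sample
    used = set()
    umi_sets = []
    for s in ("t1", "t2", "t3"):
        truth = sim.generate_reads(plan[s], config, ref, tmp_path / f"{s}1.fq",
                                   tmp_path / f"{s}2.fq", sample_id=s,
                                   used_umis=used)
        umi_sets.append(set(truth["umi_signature"]))
    assert not (umi_sets[0] & umi_sets[1])
    assert not (umi_sets[0] & umi_sets[2])
    assert not (umi_sets[1] & umi_sets[2])


def test_zero_persistence_shares_nothing(ref):
    config = sim.SimulationConfig(n_cells=80, per_base_error=0.0, seed=11)
    plan = sim.plan_timepoints(config, ref, ("a", "b"), persistent_fraction=0.0)
    assert not ({c.sequence for c in plan["a"]} & {c.sequence for c in plan["b"]})


def test_configuration_errors(ref):
    with pytest.raises(ConfigurationError):
        sim.SimulationConfig(n_cells=0).validate()
    with pytest.raises(ConfigurationError):
        sim.plan_timepoints(sim.SimulationConfig(n_cells=10), ref, ("only",),
                            persistent_count=1)
    with pytest.raises(ConfigurationError):
        sim.plan_timepoints(sim.SimulationConfig(n_cells=10), ref, ("a", "b"),
                            persistent_fraction=1.5)
    with pytest.raises(ConfigurationError):
        sim.SimulationConfig(read_length=20).validate()
    bad = dataclasses.replace(sim.naive_compartment(1.0),
                              isotype_profile={"IgM": 0.5})
    with pytest.raises(ConfigurationError):
        sim.SimulationConfig(compartments=(bad,)).validate()
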