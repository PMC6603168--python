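"""Shared fixtures: references, annotators, and a small noise-free sample."""

import numpy as np
import pytest

from bcrpipe import io, preprocess, sim
from bcrpipe.annotate import Annotator
from bcrpipe.reference import default_reference, make_reference


@pytest.fixture(scope="session")
def ref():
    return default_reference()


@pytest.fixture(scope="session")
def annotator(ref):
    return Annotator(ref)


@pytest.fixture(scope="session")
def clean_sample(ref, tmp_path_factory):
    """300 noise-free cells sequenced into paired FASTQ, plus truth.

    Session-scoped so preprocess/annotate tests share one simulation.
    """
    out = tmp_path_factory.mktemp("clean_sample")
    config = sim.SimulationConfig(n_cells=300, per_base_error=0.0, seed=314)
    cells = sim.simulate_repertoire(config, ref)
    truth = sim.generate_reads(
        cells, config, ref, out / "r1.fastq.gz", out / "r2.fastq.gz",
        truth_path=out / "truth.tsv", sample_id="clean",
    )
    pairs = io.read_fastq_pairs(out / "r1.fastq.gz", out / "r2.fastq.gz")
    table, report = preprocess.preprocess_sample(
        pairs, constant_stubs=ref.constant_stubs, min_reads_per_umi=1)
    return {
        "config": config, "cells": cells, "truth": truth, "pairs": pairs,
        "processed": table, "report": report, "dir": out,
    }


@pytest.fixture(scope="session")
def tiny_ref():
    """Two genes per segment class; for aligner-oracle and toy tests."""
    return make_reference(seed=99, n_v=2, n_d=2, n_j=2, v_length=120)


def pytest_configure(config):
    np.seterr(all="warn")
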