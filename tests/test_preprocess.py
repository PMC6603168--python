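"""Read preprocessing: filters, UMI consensus, assembly, isotype, collapse."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from bcrpipe import preprocess as P
from bcrpipe.errors import MalformedInputError
from bcrpipe.sim import DEFAULT_PRIMERS, Primer, revcomp
from oracles import consensus_tally


def read(bases, quals, read_id="r", orientation="forward"):
    if isinstance(quals, int):
        quals = [quals] * len(bases)
    return P.SequencingRead(read_id, bases, np.array(quals), orientation)


# ---------------------------------------------------------------------------
# quality filter

def test_quality_filter_keeps_mean_at_boundary():
    high = read("ACGT" * 5, 37)
    low = read("ACGT" * 5, 10)
    boundary = read("ACGTACGTAC", [10] * 5 + [30] * 5)  # mean exactly 20
    kept = P.filter_by_quality([high, low, boundary], 20)
    assert kept == [high, boundary]


def test_quality_filter_rejects_empty():
    with pytest.raises(MalformedInputError):
        P.filter_by_quality([read("", [])])


# ---------------------------------------------------------------------------
# primer / UMI extraction

def test_umi12_standardized_to_prefix8():
    primer = [p for p in DEFAULT_PRIMERS if p.name == "VP12"][0]
    umi12 = "ACGTACGTACGT"
    r = read(primer.sequence + umi12 + "GGGCCCTTTAAA", 37)
    out = P.extract_primer_and_umi(r, DEFAULT_PRIMERS)
    assert out.annotations["primer_name"] == "VP12"
    assert out.annotations["umi"] == umi12
    assert out.annotations["umi8"] == umi12[:8]
    assert out.bases == "GGGCCCTTTAAA"


def test_primer_over_mismatch_dropped():
    primer = DEFAULT_PRIMERS[0]
    broken = "TTT" + primer.sequence[3:]  # 3 mismatches to the closest primer
    r = read(broken + "A" * 20, 37)
    assert P.extract_primer_and_umi(r, DEFAULT_PRIMERS) is None


def test_primer_tie_dropped():
    twins = (Primer("A1", "5", "ACGTACGTACGTACGTACGT", 8),
             Primer("A2", "5", "ACGTACGTACGTACGTACGA", 8))
    # one mismatch to each twin → tie at equal mismatch count
    r = read("ACGTACGTACGTACGTACGC" + "G" * 12, 37)
    assert P.extract_primer_and_umi(r, twins) is None


def test_true_umi_recovered_without_noise(clean_sample):
    truth = clean_sample["truth"]
    by_tx = {t.transcript_id: t for t in truth.itertuples()}
    for fwd, rev_ in clean_sample["pairs"][:200]:
        f = P.extract_primer_and_umi(fwd, DEFAULT_PRIMERS)
        r = P.extract_primer_and_umi(rev_, DEFAULT_PRIMERS)
        tx = by_tx[fwd.read_id.rsplit(".r", 1)[0]]
        assert f.annotations["umi8"] == tx.umi5[:8]
        assert r.annotations["umi8"] == tx.umi3[:8]


# ---------------------------------------------------------------------------
# consensus

def _group(reads):
    return P.UmiGroup("A" * 16, [(r, r) for r in reads])


def test_consensus_identity_and_majority_and_tie():
    identical = [read("ACGTACGT", 37, f"r{i}") for i in range(3)]
    out = P.build_consensus(_group(identical))[0]
    assert out.consensus_fwd == "ACGTACGT"
    majority = [read("AAAA", 30, "a1"), read("AAAA", 30, "a2"),
                read("CAAA", 30, "c1")]
    assert P.build_consensus(_group(majority))[0].consensus_fwd == "AAAA"
    tie = [read("AT", 30, "x"), read("CT", 30, "y")]
    assert P.build_consensus(_group(tie))[0].consensus_fwd == "NT"


@settings(max_examples=150, deadline=None)
@given(st.data())
def test_consensus_matches_bruteforce_tally(data):
    """For ≤5 short reads, consensus equals a direct per-position tally."""
    n = data.draw(st.integers(1, 5))
    length = data.draw(st.integers(1, 20))
    reads = []
    for i in range(n):
        bases = data.draw(st.text(alphabet="ACGT", min_size=length,
                                  max_size=length))
        quals = data.draw(st.lists(st.integers(1, 40), min_size=length,
                                   max_size=length))
        reads.append(read(bases, quals, f"r{i}"))
    got = P.build_consensus(_group(reads))[0].consensus_fwd
    assert got == consensus_tally(reads)


def test_consensus_splits_by_length_mode():
    report = P.StageReport()
    reads = [read("A" * 100, 37, "long1"), read("A" * 100, 37, "long2"),
             read("A" * 30, 37, "short")]
    out = P.build_consensus(P.UmiGroup("A" * 16, [(r, r) for r in reads]), report)
    assert out[0].read_count == 2
    assert report.dropped["consensus_length_fwd"] == 1


# ---------------------------------------------------------------------------
# assembly

def _assembly_group(full, fwd_len, rev_len, fwd_quals=None, rev_quals=None,
                    fwd_override=None):
    fwd = fwd_override if fwd_override is not None else full[:fwd_len]
    rev = revcomp(full[len(full) - rev_len:])
    return P.UmiGroup(
        "A" * 16, [],
        consensus_fwd=fwd, consensus_rev=rev,
        quality_fwd=np.array(fwd_quals if fwd_quals is not None
                             else [37.0] * len(fwd)),
        quality_rev=np.array(rev_quals if rev_quals is not None
                             else [37.0] * len(rev)),
    )


def test_assembly_length_arithmetic():
    rng = np.random.default_rng(0)
    full = "".join(rng.choice(list("ACGT"), 350))
    out = P.assemble_pairs(_assembly_group(full, 200, 180))
    assert out == full  # 200 + 180 − 30-nt overlap = 350


def test_assembly_no_overlap_dropped():
    g = P.UmiGroup("A" * 16, [], consensus_fwd="A" * 50, consensus_rev="A" * 50)
    g.consensus_fwd = "ACGT" * 15
    g.consensus_rev = "TTTTGGGGCCCCAAAA" * 3
    g.quality_fwd = np.full(60, 37.0)
    g.quality_rev = np.full(48, 37.0)
    assert P.assemble_pairs(g) is None


def test_assembly_mismatch_resolved_by_quality():
    rng = np.random.default_rng(1)
    full = "".join(rng.choice(list("ACGT"), 120))
    fwd = full[:80]
    pos = 60  # inside the 30-nt overlap [50, 80)
    wrong = {"A": "C", "C": "G", "G": "T", "T": "A"}[full[pos]]
    fwd = fwd[:pos] + wrong + fwd[pos + 1:]
    fwd_quals = [37.0] * 80
    fwd_quals[pos] = 5.0  # reverse side wins
    g = _assembly_group(full, 80, 70, fwd_quals=fwd_quals, fwd_override=fwd)
    out = P.assemble_pairs(g)
    assert out == full


# ---------------------------------------------------------------------------
# isotype annotation

def test_isotype_exact_and_unassigned_and_truth(ref, clean_sample):
    stub = ref.constant_stubs["IgG1"]
    assert P.annotate_isotype("ACGT" * 30 + stub, ref.constant_stubs) == ("IgG", "IgG1")
    rng = np.random.default_rng(2)
    junk = "".join(rng.choice(list("ACGT"), 160))
    assert P.annotate_isotype(junk, ref.constant_stubs) == (None, None)
    # 100% agreement with truth when error-free
    truth = clean_sample["truth"]
    iso_by_seq = dict(zip(truth["sequence"], truth["isotype"]))
    table = clean_sample["processed"]
    for rec in table.to_dict("records"):
        assert rec["subtype"] == iso_by_seq[rec["sequence"]]


def test_isotype_subtype_tie_is_ambiguous(ref):
    g1, g2 = ref.constant_stubs["IgG1"], ref.constant_stubs["IgG2"]
    diff = [i for i in range(len(g1)) if g1[i] != g2[i]]
    # build a tail equidistant (equal mismatches ≤2) from IgG1 and IgG2
    if len(diff) % 2:
        diff = diff[:-1]
    mixed = list(g1)
    for i in diff[: len(diff) // 2]:
        mixed[i] = g2[i]
    n_diff = len(diff) // 2
    if n_diff <= 2:
        iso, sub = P.annotate_isotype("ACGT" * 30 + "".join(mixed),
                                      ref.constant_stubs)
        assert (iso, sub) == ("IgG", "ambiguous")


# ---------------------------------------------------------------------------
# collapse and filter

def test_collapse_merges_and_filters():
    recs = [
        {"sequence": "AAAA", "isotype": "IgG", "subtype": "IgG1",
         "umi_signature": f"U{i}", "read_count": c}
        for i, c in enumerate([1, 2, 5])
    ]
    out = P.collapse_and_filter(recs, min_reads_per_umi=2)
    assert len(out) == 1
    row = out.iloc[0]
    assert row["umi_count"] == 3 and row["max_reads_per_umi"] == 5


def test_collapse_min_reads_boundary():
    rec = [{"sequence": "CCCC", "isotype": "IgM", "subtype": "IgM",
            "umi_signature": "U1", "read_count": 1}]
    assert len(P.collapse_and_filter(rec, min_reads_per_umi=2)) == 0
    assert len(P.collapse_and_filter(rec, min_reads_per_umi=1)) == 1


def test_collapse_is_isotype_scoped():
    recs = [
        {"sequence": "GGGG", "isotype": "IgM", "subtype": "IgM",
         "umi_signature": "U1", "read_count": 3},
        {"sequence": "GGGG", "isotype": "IgG", "subtype": "IgG1",
         "umi_signature": "U2", "read_count": 3},
    ]
    assert len(P.collapse_and_filter(recs, min_reads_per_umi=2)) == 2


# ---------------------------------------------------------------------------
# whole-sample invariants

def test_pipeline_conservation_and_roundtrip(clean_sample):
    """Noise-free reads reproduce exactly the true transcript sequences."""
    report = clean_sample["report"]
    report.assert_conservation()
    truth_seqs = set(clean_sample["truth"]["sequence"])
    got_seqs = set(clean_sample["processed"]["sequence"])
    assert got_seqs == truth_seqs
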