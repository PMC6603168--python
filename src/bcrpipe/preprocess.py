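"""Raw paired reads → unique, isotype-annotated consensus Ig sequences.

Stage order follows the UMI amplicon design: mean-quality filtering, primer
and UMI annotation (with standardization of mixed-length UMIs to an 8-nt
prefix), grouping of read pairs by the combined 16-nt UMI signature,
per-group quality-weighted consensus, paired-end assembly, constant-region
isotype/subtype annotation, and collapse of identical sequences of the same
isotype with a reads-per-UMI filter.

Every stage counts what it drops; :class:`StageReport` asserts that input
pairs are conserved (retained + dropped) across the whole run.
"""

from __future__ import annotations

import dataclasses
from collections import Counter, defaultdict

import numpy as np
import pandas as pd

from .errors import MalformedInputError
from .sim import Primer, revcomp

UMI_STD_LENGTH = 8  # mixed 8/12-nt UMIs are standardized to this prefix


@dataclasses.dataclass
class SequencingRead:
    """One read with Phred qualities and stage annotations."""

    read_id: str
    bases: str
    qualities: np.ndarray  # integer Phred scores, same length as bases
    orientation: str = "forward"
    annotations: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self):
        if len(self.bases) != len(self.qualities):
            raise MalformedInputError(
                f"{self.read_id}: {len(self.bases)} bases vs "
                f"{len(self.qualities)} quality scores"
            )


@dataclasses.dataclass
class UmiGroup:
    """Read pairs sharing one 16-nt UMI signature, with their consensus."""

    signature: str
    members: list  # list of (fwd SequencingRead, rev SequencingRead)
    consensus_fwd: str = ""
    consensus_rev: str = ""
    quality_fwd: np.ndarray | None = None
    quality_rev: np.ndarray | None = None

    @property
    def read_count(self) -> int:
        return len(self.members)


@dataclasses.dataclass
class StageReport:
    """Per-stage pair accounting for the conservation invariant."""

    pairs_in: int = 0
    dropped: dict = dataclasses.field(default_factory=lambda: defaultdict(int))
    pairs_retained: int = 0

    def drop(self, stage: str, n: int = 1) -> None:
        self.dropped[stage] += n

    def assert_conservation(self) -> None:
        total = self.pairs_retained + sum(self.dropped.values())
        if total != self.pairs_in:
            raise AssertionError(
                f"pair conservation violated: {self.pairs_in} in, "
                f"{self.pairs_retained} retained + {dict(self.dropped)} dropped"
            )


# ---------------------------------------------------------------------------
# quality filter

def filter_by_quality(reads, q_mean: float = 20.0):
    """Keep reads whose arithmetic mean Phred score is ≥ ``q_mean``.

    The boundary is inclusive: a read averaging exactly ``q_mean`` is kept.
    """
    kept = []
    for read in reads:
        if len(read.qualities) == 0:
            raise MalformedInputError(f"{read.read_id}: empty quality string")
        if float(np.mean(read.qualities)) >= q_mean:
            kept.append(read)
    return kept


# ---------------------------------------------------------------------------
# primer / UMI annotation

PRIMER_SEARCH_WINDOW = 4  # primer may start at offsets 0..4
PRIMER_MAX_MISMATCH = 2


def _mismatches(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def extract_primer_and_umi(read: SequencingRead, primer_set) -> SequencingRead | None:
    """Identify the best-matching primer and excise the adjacent UMI.

    Scans offsets 0..4 for each primer of the read's end, allows ≤2
    mismatches, records the raw UMI and its standardized 8-nt prefix
    (``umi8``), and trims primer+UMI off the read.  Returns None when no
    primer matches or two distinct primers tie at the best mismatch count.
    """
    end = "5" if read.orientation == "forward" else "3"
    candidates = []  # (mismatches, offset, primer)
    for primer in primer_set:
        if primer.end != end:
            continue
        plen = len(primer.sequence)
        for off in range(PRIMER_SEARCH_WINDOW + 1):
            if off + plen + primer.umi_length > len(read.bases):
                continue
            mm = _mismatches(read.bases[off : off + plen], primer.sequence)
            if mm <= PRIMER_MAX_MISMATCH:
                candidates.append((mm, off, primer))
    if not candidates:
        return None
    best_mm = min(mm for mm, _, _ in candidates)
    best = [c for c in candidates if c[0] == best_mm]
    if len({p.name for _, _, p in best}) > 1:
        return None  # two primers tie at equal mismatch count
    mm, off, primer = min(best, key=lambda c: c[1])
    start = off + len(primer.sequence)
    umi = read.bases[start : start + primer.umi_length]
    body = start + primer.umi_length
    return SequencingRead(
        read_id=read.read_id,
        bases=read.bases[body:],
        qualities=read.qualities[body:],
        orientation=read.orientation,
        annotations={
            **read.annotations,
            "primer_name": primer.name,
            "umi": umi,
            "umi8": umi[:UMI_STD_LENGTH],
        },
    )


def annotate_pairs(pairs, primer_set, report: StageReport):
    """Primer/UMI-annotate both mates; drop the pair if either mate fails."""
    annotated = []
    for fwd, rev in pairs:
        f = extract_primer_and_umi(fwd, primer_set)
        r = extract_primer_and_umi(rev, primer_set)
        if f is None or r is None:
            report.drop("primer")
        else:
            annotated.append((f, r))
    return annotated


# ---------------------------------------------------------------------------
# UMI grouping and consensus

LENGTH_SPLIT_TOLERANCE = 10  # nt; members farther from the length mode are split off
COLLISION_IDENTITY = 0.10  # complete-linkage cut for UMI-collision splitting
COLLISION_MIN_LENGTH = 30  # below this the per-position tie rule governs, not splitting


def group_by_umi(pairs) -> list[UmiGroup]:
    """Group annotated pairs by the 16-nt (5′ umi8 + 3′ umi8) signature."""
    groups: dict[str, list] = defaultdict(list)
    for fwd, rev in pairs:
        sig = fwd.annotations["umi8"] + rev.annotations["umi8"]
        groups[sig].append((fwd, rev))
    return [UmiGroup(sig, members) for sig, members in sorted(groups.items())]


_BASE_ORDER = "ACGNT"  # alphabetical; tie rule never depends on this order


def _column_consensus_fast(reads) -> tuple[str, np.ndarray]:
    """Vectorized consensus for equal-length members (the common case)."""
    mat = np.frombuffer("".join(r.bases for r in reads).encode(), dtype="S1")
    mat = mat.reshape(len(reads), -1)
    quals = np.stack([r.qualities for r in reads]).astype(float)
    L = mat.shape[1]
    weights = np.zeros((len(_BASE_ORDER), L))
    for k, base in enumerate(_BASE_ORDER):
        hit = mat == base.encode()
        weights[k] = np.sum(quals * hit, axis=0)
        weights[k, ~hit.any(axis=0)] = -1.0  # unobserved bases never tie
    order = np.argsort(-weights, axis=0, kind="stable")
    top, second = order[0], order[1]
    top_w = weights[top, np.arange(L)]
    tie = top_w == weights[second, np.arange(L)]
    bases = np.array(list(_BASE_ORDER))[top]
    bases[tie] = "N"
    top_w[tie] = 0.0
    return "".join(bases), top_w


def _column_consensus(reads) -> tuple[str, np.ndarray]:
    """Per-position majority base weighted by summed quality; ties → N.

    Positions covered by fewer than half the members are trimmed from the
    tail (reads share a start, so coverage only decays at the 3′ end).
    """
    if len({len(r.bases) for r in reads}) == 1:
        return _column_consensus_fast(reads)
    n = len(reads)
    max_len = max(len(r.bases) for r in reads)
    half = n / 2.0
    out_bases = []
    out_quals = []
    for pos in range(max_len):
        weights: dict[str, float] = defaultdict(float)
        covered = 0
        for r in reads:
            if pos < len(r.bases):
                covered += 1
                weights[r.bases[pos]] += float(r.qualities[pos])
        if covered < half:
            break  # >50% absent coverage: trim from the end
        ranked = sorted(weights.items(), key=lambda kv: (-kv[1], kv[0]))
        if len(ranked) > 1 and ranked[0][1] == ranked[1][1]:
            out_bases.append("N")
            out_quals.append(0.0)
        else:
            out_bases.append(ranked[0][0])
            out_quals.append(ranked[0][1])
    return "".join(out_bases), np.array(out_quals)


def _split_by_length_mode(reads, report: StageReport, side: str):
    lengths = [len(r.bases) for r in reads]
    mode = Counter(lengths).most_common(1)[0][0]
    kept = [r for r in reads if abs(len(r.bases) - mode) <= LENGTH_SPLIT_TOLERANCE]
    if len(kept) < len(reads):
        report.drop(f"consensus_length_{side}", len(reads) - len(kept))
    return kept


def _complete_linkage_split(reads):
    """Split a colliding UMI group at 10% identity distance (complete linkage)."""
    n = len(reads)
    clusters = [[i] for i in range(n)]

    def dist(i, j):
        a, b = reads[i].bases, reads[j].bases
        L = min(len(a), len(b))
        if L == 0:
            return 1.0
        return _mismatches(a[:L], b[:L]) / L

    merged = True
    while merged and len(clusters) > 1:
        merged = False
        best = None
        for x in range(len(clusters)):
            for y in range(x + 1, len(clusters)):
                d = max(dist(i, j) for i in clusters[x] for j in clusters[y])
                if d <= COLLISION_IDENTITY and (best is None or d < best[0]):
                    best = (d, x, y)
        if best is not None:
            _, x, y = best
            clusters[x] += clusters.pop(y)
            merged = True
    return [[reads[i] for i in c] for c in clusters]


def build_consensus(group: UmiGroup, report: StageReport | None = None) -> list[UmiGroup]:
    """Collapse a UMI group to forward/reverse consensus sequences.

    Returns one group in the common case; a colliding signature (members
    disagreeing at >10% of consensus positions) is split by complete linkage
    on the forward reads and each sub-group gets its own consensus.
    """
    if report is None:
        report = StageReport()
    fwd_reads = _split_by_length_mode([f for f, _ in group.members], report, "fwd")
    kept_ids = {r.read_id for r in fwd_reads}
    members = [(f, r) for f, r in group.members if f.read_id in kept_ids]
    rev_reads = [r for _, r in members]
    if not members:
        return []

    def finish(sub_members) -> UmiGroup:
        sub = UmiGroup(group.signature, sub_members)
        sub.consensus_fwd, sub.quality_fwd = _column_consensus([f for f, _ in sub_members])
        sub.consensus_rev, sub.quality_rev = _column_consensus([r for _, r in sub_members])
        return sub

    out = finish(members)
    # collision check: any member far from consensus → split and redo
    worst = 0.0
    for f, _ in members:
        L = min(len(f.bases), len(out.consensus_fwd))
        if L:
            worst = max(worst, _mismatches(f.bases[:L], out.consensus_fwd[:L]) / L)
    if (worst > COLLISION_IDENTITY and len(members) > 1
            and len(out.consensus_fwd) >= COLLISION_MIN_LENGTH):
        parts = _complete_linkage_split([f for f, _ in members])
        id_of = {id(f): k for k, part in enumerate(parts) for f in part}
        buckets: dict[int, list] = defaultdict(list)
        for f, r in members:
            buckets[id_of[id(f)]].append((f, r))
        return [finish(b) for _, b in sorted(buckets.items())]
    return [out]


# ---------------------------------------------------------------------------
# paired-end assembly

def assemble_pairs(
    group: UmiGroup,
    min_overlap: int = 10,
    max_mismatch_rate: float = 0.2,
) -> str | None:
    """Merge forward and reverse consensus by their maximal-scoring overlap.

    The reverse consensus is reverse-complemented, then the best ungapped
    suffix(fwd)/prefix(rev) overlap of length ≥ ``min_overlap`` with mismatch
    rate ≤ ``max_mismatch_rate`` is chosen by score (matches − mismatches);
    disagreements inside the overlap resolve toward the higher quality-sum
    base.  Returns None when no qualifying overlap exists.
    """
    fwd, qf = group.consensus_fwd, group.quality_fwd
    rev = revcomp(group.consensus_rev)
    qr = group.quality_rev[::-1] if group.quality_rev is not None else None
    a = np.frombuffer(fwd.encode(), dtype="S1")
    b = np.frombuffer(rev.encode(), dtype="S1")
    best = None  # (score, L)
    # fast path: exact seed of the rev prefix inside fwd
    seed = rev[: min(20, len(rev))]
    if seed and len(seed) >= min_overlap:
        pos = fwd.find(seed)
        if pos >= 0 and len(fwd) - pos >= min_overlap:
            L = len(fwd) - pos
            span = min(L, len(rev))
            mm = int(np.sum(a[pos : pos + span] != b[:span]))
            if mm / span <= max_mismatch_rate:
                best = (span - 2 * mm, L)
    if best is None:
        for L in range(min(len(fwd), len(rev)), min_overlap - 1, -1):
            span = min(L, len(rev))
            mm = int(np.sum(a[len(fwd) - L : len(fwd) - L + span] != b[:span]))
            if mm / span > max_mismatch_rate:
                continue
            score = span - 2 * mm
            if best is None or score > best[0]:
                best = (score, L)
    if best is None:
        return None
    _, L = best
    offset = len(fwd) - L  # rev position 0 aligns to fwd position `offset`
    merged = list(fwd[:offset])
    for i in range(max(L, len(rev))):
        fpos = offset + i
        fbase = fwd[fpos] if fpos < len(fwd) else None
        rbase = rev[i] if i < len(rev) else None
        if fbase is None:
            merged.append(rbase)
        elif rbase is None or fbase == rbase:
            merged.append(fbase)
        else:
            fq = float(qf[fpos]) if qf is not None else 0.0
            rq = float(qr[i]) if qr is not None else 0.0
            merged.append(fbase if fq >= rq else rbase)
    return "".join(merged)


# ---------------------------------------------------------------------------
# isotype annotation

ISOTYPE_MAX_MISMATCH = 2
ISOTYPE_SEARCH_TAIL = 10  # stub may sit up to this many nt before the 3' terminus


def annotate_isotype(sequence: str, constant_stubs: dict[str, str]):
    """Call isotype and subtype from the best constant-stub match at the 3′ end.

    Returns ``(isotype, subtype)``; subtype is "ambiguous" when two subtypes
    of one isotype tie, and ``(None, None)`` when nothing matches within 2
    mismatches or two different isotypes tie.
    """
    from .reference import isotype_of

    best_mm = None
    hits: list[str] = []
    for name in sorted(constant_stubs):
        stub = constant_stubs[name]
        if len(sequence) < len(stub):
            continue
        local = None
        for back in range(ISOTYPE_SEARCH_TAIL + 1):
            end = len(sequence) - back
            window = sequence[end - len(stub) : end]
            mm = _mismatches(window, stub)
            if mm <= ISOTYPE_MAX_MISMATCH and (local is None or mm < local):
                local = mm
        if local is None:
            continue
        if best_mm is None or local < best_mm:
            best_mm, hits = local, [name]
        elif local == best_mm:
            hits.append(name)
    if not hits:
        return None, None
    isotypes = {isotype_of(h) for h in hits}
    if len(isotypes) > 1:
        return None, None
    iso = isotypes.pop()
    return iso, hits[0] if len(hits) == 1 else "ambiguous"


# ---------------------------------------------------------------------------
# collapse and filter

def collapse_and_filter(sequences, min_reads_per_umi: int = 2) -> pd.DataFrame:
    """Merge identical nucleotide sequences of identical isotype.

    ``sequences`` is an iterable of dicts with keys sequence, isotype,
    subtype, umi_signature, read_count (one entry per assembled UMI group).
    Collapse sums distinct UMI signatures into ``umi_count`` and tracks
    ``max_reads_per_umi``; a collapsed sequence is retained when
    ``max_reads_per_umi ≥ min_reads_per_umi``.  ``min_reads_per_umi=1``
    yields the all-unique-reads view used for constant-threshold comparisons.
    """
    merged: dict[tuple, dict] = {}
    for rec in sequences:
        key = (rec["sequence"], rec["isotype"], rec["subtype"])
        slot = merged.setdefault(
            key,
            {"sequence": rec["sequence"], "isotype": rec["isotype"],
             "subtype": rec["subtype"], "umi_signatures": set(),
             "max_reads_per_umi": 0, "total_reads": 0},
        )
        slot["umi_signatures"].add(rec["umi_signature"])
        slot["max_reads_per_umi"] = max(slot["max_reads_per_umi"], rec["read_count"])
        slot["total_reads"] += rec["read_count"]
    rows = []
    for slot in merged.values():
        if slot["max_reads_per_umi"] >= min_reads_per_umi:
            rows.append({
                "sequence": slot["sequence"],
                "isotype": slot["isotype"],
                "subtype": slot["subtype"],
                "umi_count": len(slot["umi_signatures"]),
                "max_reads_per_umi": slot["max_reads_per_umi"],
                "total_reads": slot["total_reads"],
                "umi_signatures": ";".join(sorted(slot["umi_signatures"])),
            })
    rows.sort(key=lambda r: (-r["umi_count"], r["sequence"], r["isotype"]))
    df = pd.DataFrame(rows, columns=[
        "sequence", "isotype", "subtype", "umi_count", "max_reads_per_umi",
        "total_reads", "umi_signatures",
    ])
    df.insert(0, "sequence_id", [f"seq-{i + 1:06d}" for i in range(len(df))])
    return df


# ---------------------------------------------------------------------------
# whole-sample orchestration

def preprocess_sample(
    pairs,
    primer_set=None,
    constant_stubs=None,
    q_mean: float = 20.0,
    min_reads_per_umi: int = 2,
    min_overlap: int = 10,
    max_mismatch_rate: float = 0.2,
) -> tuple[pd.DataFrame, StageReport]:
    """Run the full read-to-ProcessedSequence stage on paired reads.

    ``pairs`` is a list of (forward, reverse) :class:`SequencingRead`.
    Returns the collapsed sequence table and the stage report (conservation
    asserted).
    """
    from .sim import DEFAULT_PRIMERS

    if primer_set is None:
        primer_set = DEFAULT_PRIMERS
    if constant_stubs is None:
        from .reference import default_reference

        constant_stubs = default_reference().constant_stubs
    report = StageReport(pairs_in=len(pairs))
    qual_ok = []
    for fwd, rev in pairs:
        if len(filter_by_quality([fwd, rev], q_mean)) == 2:
            qual_ok.append((fwd, rev))
        else:
            report.drop("quality")
    annotated = annotate_pairs(qual_ok, primer_set, report)
    groups = group_by_umi(annotated)
    assembled = []
    for group in groups:
        for sub in build_consensus(group, report):
            seq = assemble_pairs(sub, min_overlap, max_mismatch_rate)
            if seq is None:
                report.drop("assembly", sub.read_count)
                continue
            iso, sub_iso = annotate_isotype(seq, constant_stubs)
            if iso is None:
                report.drop("isotype", sub.read_count)
                continue
            report.pairs_retained += sub.read_count
            assembled.append({
                "sequence": seq, "isotype": iso, "subtype": sub_iso,
                "umi_signature": sub.signature, "read_count": sub.read_count,
            })
    report.assert_conservation()
    table = collapse_and_filter(assembled, min_reads_per_umi)
    return table, report
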