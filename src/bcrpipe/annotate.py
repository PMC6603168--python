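"""Germline V/D/J assignment, region partitioning and SHM quantification.

The aligner is deliberately simple and fully specified: best V gene by
semi-global alignment (match +1, mismatch −1, linear gap −4, terminal gaps
free), best J gene likewise on the query segment downstream of the V, and a
best-effort D call by longest exact substring (≥5 nt) of the intervening
segment.  Ties break lexicographically by gene name so every call is
deterministic.  Somatic hypermutation is the percent of mismatched aligned
columns over the V segment, junction excluded, indel columns excluded —
measured strictly against the provided germline reference.

Pairwise alignment is delegated to ``biotite.sequence.align``; a k-mer
prescreen limits which V genes are aligned (all genes are aligned when the
prescreen is inconclusive, so calls do not depend on it).
"""

from __future__ import annotations

from collections import defaultdict

import numpy as np
import pandas as pd
import biotite.sequence as bseq
import biotite.sequence.align as balign

from .reference import GermlineReference, isotype_of

MIN_QUERY_LENGTH = 100
MIN_V_IDENTITY = 0.6
MIN_D_MATCH = 5
GAP_PENALTY = -4
PRESCREEN_K = 12

#: AIRR-style output columns (coordinates are 0-based, half-open)
AIRR_COLUMNS = [
    "sequence_id", "sequence", "v_call", "d_call", "j_call", "v_identity",
    "junction", "junction_length", "cdrh3", "shm_percent", "c_call", "isotype",
    "consensus_count", "duplicate_count", "clone_id",
    "fwr1_start", "fwr1_end", "cdr1_start", "cdr1_end", "fwr2_start",
    "fwr2_end", "cdr2_start", "cdr2_end", "fwr3_start", "fwr3_end",
    "fwr4_start", "fwr4_end", "core_start", "core_end",
    "sample_id", "donor", "timepoint", "condition", "replicate",
]


def _nt_matrix() -> balign.SubstitutionMatrix:
    """+1 on the A/C/G/T diagonal, −1 everywhere else (N never matches)."""
    alph = bseq.NucleotideSequence.alphabet_amb
    n = len(alph)
    scores = np.full((n, n), -1, dtype=np.int32)
    for base in "ACGT":
        i = alph.encode(base)
        scores[i, i] = 1
    return balign.SubstitutionMatrix(alph, alph, scores)


def _semiglobal(ref_seq, query_seq, matrix):
    """Best semi-global alignment (terminal gaps free); returns biotite alignment."""
    alignments = balign.align_optimal(
        ref_seq, query_seq, matrix,
        gap_penalty=GAP_PENALTY, terminal_penalty=False, max_number=1,
    )
    return alignments[0]


def _trace_map(alignment) -> dict[int, int]:
    """Germline position → query position over aligned (non-gap) columns."""
    trace = alignment.trace
    both = (trace[:, 0] >= 0) & (trace[:, 1] >= 0)
    return {int(g): int(q) for g, q in trace[both]}


def _identity(alignment, ref_str: str, query_str: str) -> tuple[int, int]:
    """(matching columns, aligned columns) over non-gap columns."""
    trace = alignment.trace
    both = (trace[:, 0] >= 0) & (trace[:, 1] >= 0)
    pairs = trace[both]
    matches = sum(1 for g, q in pairs if ref_str[g] == query_str[q])
    return matches, len(pairs)


def _longest_common_substring(a: str, b: str) -> int:
    if not a or not b:
        return 0
    prev = [0] * (len(b) + 1)
    best = 0
    for i in range(1, len(a) + 1):
        cur = [0] * (len(b) + 1)
        for j in range(1, len(b) + 1):
            if a[i - 1] == b[j - 1]:
                cur[j] = prev[j - 1] + 1
                best = max(best, cur[j])
        prev = cur
    return best


class Annotator:
    """Stateful annotator holding the reference, matrix and k-mer prescreen."""

    def __init__(self, ref: GermlineReference, min_v_identity: float = MIN_V_IDENTITY):
        self.ref = ref
        self.min_v_identity = min_v_identity
        self.matrix = _nt_matrix()
        self._v_seqs = {
            name: bseq.NucleotideSequence(rec.sequence, ambiguous=False)
            for name, rec in ref.v_genes.items()
        }
        self._j_seqs = {
            name: bseq.NucleotideSequence(rec.sequence, ambiguous=False)
            for name, rec in ref.j_genes.items()
        }
        self._kmer_index: dict[str, set[str]] = defaultdict(set)
        for name, rec in ref.v_genes.items():
            seq = rec.sequence
            for i in range(len(seq) - PRESCREEN_K + 1):
                self._kmer_index[seq[i : i + PRESCREEN_K]].add(name)

    # -- candidate selection ------------------------------------------------
    def _v_candidates(self, query: str) -> list[str]:
        hits: dict[str, int] = defaultdict(int)
        for i in range(0, len(query) - PRESCREEN_K + 1, 4):
            for name in self._kmer_index.get(query[i : i + PRESCREEN_K], ()):
                hits[name] += 1
        if not hits:
            return sorted(self.ref.v_genes)
        top = max(hits.values())
        chosen = sorted(n for n, h in hits.items() if h >= max(1, top // 2))
        return chosen if len(chosen) >= 1 else sorted(self.ref.v_genes)

    # -- operations ----------------------------------------------------------
    def assign_vdj(self, sequence: str) -> dict | None:
        """Gene calls plus alignments for one query; None if unannotatable."""
        query = sequence.upper()
        if len(query) < MIN_QUERY_LENGTH:
            return None
        has_amb = bool(set(query) - set("ACGT"))
        qseq = bseq.NucleotideSequence(query, ambiguous=True if has_amb else False)
        best_v = None  # (score, name, alignment)
        for name in self._v_candidates(query):
            al = _semiglobal(self._v_seqs[name], qseq, self.matrix)
            if best_v is None or al.score > best_v[0]:
                best_v = (al.score, name, al)
        score, v_name, v_al = best_v
        matches, cols = _identity(v_al, self.ref.v_genes[v_name].sequence, query)
        if cols == 0 or matches / cols < self.min_v_identity:
            return None
        v_map = _trace_map(v_al)
        v_qend = max(v_map.values())
        # J on the downstream segment
        tail_start = v_qend + 1
        tail = query[tail_start:]
        if len(tail) < 10:
            return None
        has_amb_t = bool(set(tail) - set("ACGT"))
        tseq = bseq.NucleotideSequence(tail, ambiguous=True if has_amb_t else False)
        best_j = None
        for name in sorted(self.ref.j_genes):
            al = _semiglobal(self._j_seqs[name], tseq, self.matrix)
            if best_j is None or al.score > best_j[0]:
                best_j = (al.score, name, al)
        j_score, j_name, j_al = best_j
        j_map = {g: q + tail_start for g, q in _trace_map(j_al).items()}
        if not j_map or j_score <= 0:
            return None
        # D by longest exact substring of the intervening segment
        j_qstart = min(j_map.values())
        between = query[v_qend + 1 : j_qstart]
        d_name, d_len = "", 0
        for name in sorted(self.ref.d_genes):
            lcs = _longest_common_substring(self.ref.d_genes[name].sequence, between)
            if lcs > d_len:
                d_name, d_len = name, lcs
        if d_len < MIN_D_MATCH:
            d_name = ""
        return {
            "v_call": v_name, "j_call": j_name, "d_call": d_name,
            "v_score": int(score), "j_score": int(j_score),
            "v_identity": matches / cols,
            "v_map": v_map, "j_map": j_map,
        }

    def partition_regions(self, query: str, calls: dict) -> dict:
        """Project germline region bounds and anchors onto query coordinates.

        Returns a dict of 0-based half-open query intervals for FWR1–FWR4 and
        CDR1–2, plus junction/core anchors; an entry is None when alignment
        gaps destroy its boundary.
        """
        v_rec = self.ref.v_genes[calls["v_call"]]
        j_rec = self.ref.j_genes[calls["j_call"]]
        v_map, j_map = calls["v_map"], calls["j_map"]
        out: dict[str, object] = {}
        for rec, gmap in ((v_rec, v_map), (j_rec, j_map)):
            for region, (start, end) in rec.region_bounds.items():
                qpos = [gmap[g] for g in range(start, end) if g in gmap]
                out[region] = (min(qpos), max(qpos) + 1) if qpos else None
        # anchors: project through the alignment; when terminal mismatches
        # left an anchor outside the aligned span, extrapolate from the
        # nearest aligned column (valid because the offset is ungapped there)
        def project(gmap: dict[int, int], pos: int | None, limit: int = 12):
            if pos is None:
                return None
            if pos in gmap:
                return gmap[pos]
            nearest = min(gmap, key=lambda g: (abs(g - pos), g), default=None)
            if nearest is None or abs(nearest - pos) > limit:
                return None
            q = gmap[nearest] + (pos - nearest)
            return q if 0 <= q < len(query) else None

        cys = v_rec.anchors.get("CYS104")
        trp = j_rec.anchors.get("TRP118")
        jn_start = project(v_map, cys)
        jn_end_inner = project(j_map, trp + 2 if trp is not None else None)
        out["junction_start"] = jn_start
        out["junction_end"] = jn_end_inner + 1 if jn_end_inner is not None else None
        # Kabat 12..136 core span
        k12 = v_rec.anchors.get("KABAT12")
        k136 = j_rec.anchors.get("KABAT136")  # exclusive germline end on J
        out["core_start"] = project(v_map, k12)
        core_inner = project(j_map, k136 - 1 if k136 is not None else None)
        out["core_end"] = core_inner + 1 if core_inner is not None else None
        return out

    def compute_shm(self, query: str, calls: dict) -> float | None:
        """Percent mismatched aligned columns over the V segment, junction
        (Cys codon onward) excluded; indel columns never counted."""
        v_rec = self.ref.v_genes[calls["v_call"]]
        cys = v_rec.anchors.get("CYS104", len(v_rec.sequence))
        germ = v_rec.sequence
        mism = cols = 0
        for g, q in calls["v_map"].items():
            if g >= cys:
                continue
            cols += 1
            if germ[g] != query[q]:
                mism += 1
        if cols == 0:
            return None
        return 100.0 * mism / cols

    def annotate(self, sequence: str) -> dict | None:
        """Full per-sequence annotation; None when the sequence cannot be
        aligned (no V at ≥60% identity, or no junction)."""
        calls = self.assign_vdj(sequence)
        if calls is None:
            return None
        regions = self.partition_regions(sequence, calls)
        if regions["junction_start"] is None or regions["junction_end"] is None:
            return None
        shm = self.compute_shm(sequence, calls)
        if shm is None:
            return None
        js, je = regions["junction_start"], regions["junction_end"]
        junction = sequence[js:je]
        row = {
            "v_call": calls["v_call"], "d_call": calls["d_call"],
            "j_call": calls["j_call"], "v_identity": round(calls["v_identity"], 4),
            "junction": junction, "junction_length": len(junction),
            "cdrh3": junction[3:-3], "shm_percent": shm,
        }
        for region in ("FWR1", "CDR1", "FWR2", "CDR2", "FWR3", "FWR4"):
            span = regions.get(region)
            row[f"{region.lower()}_start"] = span[0] if span else pd.NA
            row[f"{region.lower()}_end"] = span[1] if span else pd.NA
        row["core_start"] = regions["core_start"] if regions["core_start"] is not None else pd.NA
        row["core_end"] = regions["core_end"] if regions["core_end"] is not None else pd.NA
        return row


def annotate_table(
    processed: pd.DataFrame,
    ref: GermlineReference,
    metadata: dict | None = None,
    annotator: Annotator | None = None,
) -> tuple[pd.DataFrame, int]:
    """Annotate a ProcessedSequence table into an AIRR-style rearrangement table.

    Returns ``(rearrangements, n_unannotatable)``.  Identical sequences are
    aligned once and the result reused.
    """
    if annotator is None:
        annotator = Annotator(ref)
    metadata = metadata or {}
    cache: dict[str, dict | None] = {}
    rows = []
    failed = 0
    for rec in processed.to_dict("records"):
        seq = rec["sequence"]
        if seq not in cache:
            cache[seq] = annotator.annotate(seq)
        ann = cache[seq]
        if ann is None:
            failed += 1
            continue
        row = {
            "sequence_id": rec.get("sequence_id", ""),
            "sequence": seq,
            "c_call": rec.get("subtype", ""),
            "isotype": rec.get("isotype", isotype_of(rec.get("subtype", ""))),
            "consensus_count": rec.get("total_reads", rec.get("max_reads_per_umi", 1)),
            "duplicate_count": rec.get("umi_count", 1),
            "clone_id": "",
            **ann,
        }
        for key in ("sample_id", "donor", "timepoint", "condition", "replicate"):
            row[key] = rec.get(key, metadata.get(key, ""))
        if "umi_signatures" in rec:
            row["umi_signatures"] = rec["umi_signatures"]
        rows.append(row)
    cols = AIRR_COLUMNS + (["umi_signatures"] if rows and "umi_signatures" in rows[0] else [])
    df = pd.DataFrame(rows, columns=cols)
    return df, failed
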