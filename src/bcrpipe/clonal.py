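"""Clonal family inference from junction distances.

Sequences are partitioned by (V gene, J gene, junction length) — gene-level,
alleles collapsed — and clones are single-linkage connected components under
a normalized junction Hamming distance threshold.  The threshold is either
estimated per sample from the bimodal distance-to-nearest distribution
(kernel-density valley between clone-mates and background) or held constant
across samples; the constant value is derived as the rounded median of
per-sample optimized thresholds.
"""

from __future__ import annotations

import dataclasses
import hashlib
import math

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

FALLBACK_THRESHOLD = 0.12


def _gene_level(call: str) -> str:
    """IGHV1-2*01 → IGHV1-2 (allele ambiguity collapsed before partitioning)."""
    return call.split("*")[0]


def partition_key(row) -> tuple[str, str, int]:
    return (_gene_level(row["v_call"]), _gene_level(row["j_call"]),
            int(row["junction_length"]))


def _partition_groups(rearrs: pd.DataFrame) -> dict[tuple, list]:
    """Row indices grouped by (V gene, J gene, junction length)."""
    groups: dict[tuple, list] = {}
    for idx, v, j, jl in zip(
        rearrs.index, rearrs["v_call"], rearrs["j_call"], rearrs["junction_length"]
    ):
        groups.setdefault((_gene_level(v), _gene_level(j), int(jl)), []).append(idx)
    return groups


def _seq_matrix(seqs: list[str]) -> np.ndarray:
    return np.frombuffer("".join(seqs).encode(), dtype="S1").reshape(len(seqs), -1)


def _pairwise_hamming(seqs: list[str]) -> np.ndarray:
    """Normalized pairwise Hamming distances for equal-length sequences."""
    mat = _seq_matrix(seqs)
    n, L = mat.shape
    out = np.zeros((n, n))
    for i in range(n):
        out[i] = np.sum(mat != mat[i], axis=1) / L
    return out


def distance_to_nearest(rearrs: pd.DataFrame, region: str = "junction") -> pd.Series:
    """Per-sequence minimum normalized Hamming distance within its partition.

    Sequences alone in their (V, J, junction-length) partition get NaN and do
    not contribute to threshold estimation.
    """
    dist = pd.Series(np.nan, index=rearrs.index)
    for _, idx in sorted(_partition_groups(rearrs).items()):
        if len(idx) < 2:
            continue
        seqs = rearrs.loc[idx, region].tolist()
        d = _pairwise_hamming(seqs)
        np.fill_diagonal(d, np.inf)
        dist.loc[idx] = d.min(axis=1)
    return dist


@dataclasses.dataclass
class ThresholdEstimate:
    sample_id: str
    distances: np.ndarray
    threshold: float
    method: str  # "valley" | "fallback"


def find_threshold(
    distances,
    sample_id: str = "",
    min_distances: int = 50,
    grid_size: int = 512,
) -> ThresholdEstimate:
    """Clonal threshold from the distance-to-nearest distribution.

    A Gaussian KDE (Silverman bandwidth) is evaluated on [0, 1]; the
    threshold is the density minimum between the two highest local maxima.
    With a unimodal density — or fewer than ``min_distances`` finite
    distances — the method falls back to the constant 0.12.
    """
    d = np.asarray(distances, dtype=float)
    d = d[np.isfinite(d)]
    if len(d) < min_distances or np.ptp(d) < 1e-12:
        return ThresholdEstimate(sample_id, d, FALLBACK_THRESHOLD, "fallback")
    # weighted KDE over unique values: the density (and hence the threshold)
    # depends only on the empirical distribution, not on duplication
    values, counts = np.unique(d, return_counts=True)
    kde = gaussian_kde(values, weights=counts, bw_method="silverman")
    grid = np.linspace(0.0, 1.0, grid_size)
    dens = kde(grid)
    interior = np.arange(1, grid_size - 1)
    is_max = (dens[interior] >= dens[interior - 1]) & (dens[interior] > dens[interior + 1])
    maxima = interior[is_max]
    # include boundary maxima
    if dens[0] > dens[1]:
        maxima = np.concatenate([[0], maxima])
    if dens[-1] > dens[-2]:
        maxima = np.concatenate([maxima, [grid_size - 1]])
    if len(maxima) < 2:
        return ThresholdEstimate(sample_id, d, FALLBACK_THRESHOLD, "fallback")
    top2 = maxima[np.argsort(dens[maxima])[-2:]]
    lo, hi = int(top2.min()), int(top2.max())
    valley = lo + int(np.argmin(dens[lo : hi + 1]))
    threshold = float(grid[valley])
    threshold = min(max(threshold, 1e-6), 1 - 1e-6)  # strictly inside (0, 1)
    return ThresholdEstimate(sample_id, d, threshold, "valley")


def derive_constant_threshold(per_sample_thresholds) -> int:
    """Median of per-sample thresholds (percent), rounded half-up to integer.

    For an even count the median is the mean of the two middle values.
    """
    values = sorted(float(v) for v in per_sample_thresholds)
    if not values:
        raise ValueError("derive_constant_threshold: empty threshold list")
    n = len(values)
    mid = n // 2
    median = values[mid] if n % 2 else (values[mid - 1] + values[mid]) / 2.0
    return int(math.floor(median + 0.5))


# ---------------------------------------------------------------------------
# clustering

class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[max(ra, rb)] = min(ra, rb)


@dataclasses.dataclass
class Clone:
    """One clonal family with its abundance and mutation summary."""

    clone_id: str
    members: list[str]  # sequence_ids
    v_gene: str
    j_gene: str
    junction_length: int
    abundance_sequences: int
    abundance_reads: int
    mean_shm: float
    isotype_counts: dict[str, int]


def cluster_clones(
    rearrs: pd.DataFrame,
    threshold: float,
    region: str = "junction",
) -> tuple[pd.DataFrame, list[Clone]]:
    """Single-linkage clonal clustering within (V, J, junction-length) partitions.

    An edge joins two sequences when their normalized Hamming distance on
    ``region`` ("junction", or "cdrh3" for the constant-threshold mode) is ≤
    ``threshold``; connected components are clones.  Returns the table with
    ``clone_id`` filled plus :class:`Clone` summaries.  Clone ids hash the
    sorted member sequence_ids, so they are stable across runs.
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must be inside (0, 1)")
    rearrs = rearrs.copy()
    rearrs["clone_id"] = ""
    clones: list[Clone] = []
    for key, idx in sorted(_partition_groups(rearrs).items()):
        seqs = rearrs.loc[idx, region].tolist()
        uf = _UnionFind(len(idx))
        if len(idx) > 1:
            d = _pairwise_hamming(seqs)
            for i in range(len(idx)):
                for j in range(i + 1, len(idx)):
                    if d[i, j] <= threshold:
                        uf.union(i, j)
        comps: dict[int, list[int]] = {}
        for i in range(len(idx)):
            comps.setdefault(uf.find(i), []).append(i)
        for root in sorted(comps):
            member_idx = [idx[i] for i in comps[root]]
            member_ids = sorted(rearrs.loc[member_idx, "sequence_id"].astype(str))
            digest = hashlib.sha1("|".join(member_ids).encode()).hexdigest()[:12]
            clone_id = f"clone-{digest}"
            rearrs.loc[member_idx, "clone_id"] = clone_id
            sub = rearrs.loc[member_idx]
            clones.append(Clone(
                clone_id=clone_id,
                members=member_ids,
                v_gene=key[0], j_gene=key[1], junction_length=key[2],
                abundance_sequences=len(member_ids),
                abundance_reads=int(sub["duplicate_count"].sum())
                if "duplicate_count" in sub else len(member_ids),
                mean_shm=float(sub["shm_percent"].mean()),
                isotype_counts=sub["isotype"].value_counts().to_dict()
                if "isotype" in sub else {},
            ))
    clones.sort(key=lambda c: c.clone_id)
    return rearrs, clones


def clones_to_frame(clones: list[Clone]) -> pd.DataFrame:
    rows = [{
        "clone_id": c.clone_id, "v_gene": c.v_gene, "j_gene": c.j_gene,
        "junction_length": c.junction_length,
        "abundance_sequences": c.abundance_sequences,
        "abundance_reads": c.abundance_reads,
        "mean_shm": round(c.mean_shm, 4),
        "isotype_counts": ";".join(f"{k}:{v}" for k, v in sorted(c.isotype_counts.items())),
    } for c in clones]
    return pd.DataFrame(rows, columns=[
        "clone_id", "v_gene", "j_gene", "junction_length",
        "abundance_sequences", "abundance_reads", "mean_shm", "isotype_counts",
    ])
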