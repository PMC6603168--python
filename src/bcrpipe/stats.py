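"""Repertoire summaries and condition comparisons.

Covers per-sample counts of heavy-chain sequences and clonal families with
per-isotype mean SHM at the sequence and clone level, isotype/subtype
proportions, V-gene usage, the subsampling-based Repertoire Dissimilarity
Index on V-gene usage, and a Holm–Šidák-adjusted two-sample t comparison of
SHM distributions.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .reference import isotype_of


def summarize_repertoire(
    rearrs: pd.DataFrame,
    clones,
    sample_id: str = "",
    threshold: float | None = None,
) -> pd.DataFrame:
    """Table-shaped summary: sequence/clone counts and mean SHM per isotype.

    Sequence-level mean SHM is the unweighted mean over unique sequences;
    clone-level SHM is the mean over clones of each clone's mean member SHM.
    """
    rows = [
        {"metric": "hc_sequences", "value": float(len(rearrs))},
        {"metric": "hc_clonal_families", "value": float(len(clones))},
    ]
    if threshold is not None:
        rows.append({"metric": "threshold_percent", "value": 100.0 * threshold})
    for iso in ("IgM", "IgG", "IgA"):
        sub = rearrs[rearrs["isotype"] == iso]
        rows.append({"metric": f"{iso}_sequences", "value": float(len(sub))})
        if len(sub):
            rows.append({"metric": f"shm_{iso}_sequences",
                         "value": float(sub["shm_percent"].mean())})
        iso_clones = [c for c in clones
                      if max(c.isotype_counts, key=lambda k: (c.isotype_counts[k], k),
                             default="") == iso]
        rows.append({"metric": f"{iso}_clonal_families", "value": float(len(iso_clones))})
        if iso_clones:
            rows.append({"metric": f"shm_{iso}_clonal_families",
                         "value": float(np.mean([c.mean_shm for c in iso_clones]))})
    df = pd.DataFrame(rows)
    df.insert(0, "sample_id", sample_id)
    return df


def aggregate_condition_means(per_sample_means, weights=None) -> float:
    """Mean of per-sample percent values, rounded to one decimal.

    Unweighted by default (the convention behind published condition-level
    aggregates); pass per-sample sequence counts as ``weights`` for a
    count-weighted mean instead.
    """
    values = [float(v) for v in per_sample_means]
    if not values:
        raise ValueError("aggregate_condition_means: empty input")
    if weights is not None:
        if len(weights) != len(values):
            raise ValueError("weights must pair with values")
        return round(float(np.average(values, weights=weights)) + 1e-12, 1)
    return round(float(np.mean(values)) + 1e-12, 1)


def isotype_proportions(rearrs: pd.DataFrame, level: str = "isotype") -> dict[str, float]:
    """Fractions of assigned sequences per isotype or subtype; sums to 1."""
    if level not in ("isotype", "subtype"):
        raise ValueError("level must be 'isotype' or 'subtype'")
    col = "isotype" if level == "isotype" else "c_call"
    labels = rearrs[col][rearrs[col].astype(str) != ""].dropna()
    if labels.empty:
        raise ValueError("no assigned sequences")
    counts = labels.value_counts()
    return {k: float(v) / len(labels) for k, v in sorted(counts.items())}


def vgene_usage(rearrs: pd.DataFrame, by_isotype: bool = False) -> pd.DataFrame:
    """Per-V-gene sequence fractions, optionally stratified by isotype."""
    genes = rearrs["v_call"].map(lambda c: c.split("*")[0])
    if by_isotype:
        rows = []
        for iso, idx in genes.groupby(rearrs["isotype"]).groups.items():
            sub = genes.loc[idx].value_counts()
            for gene in sorted(sub.index):
                rows.append({"isotype": iso, "v_gene": gene,
                             "frequency": float(sub[gene]) / len(idx)})
        return pd.DataFrame(rows, columns=["isotype", "v_gene", "frequency"])
    counts = genes.value_counts()
    return pd.DataFrame(
        [{"v_gene": g, "frequency": float(counts[g]) / len(genes)}
         for g in sorted(counts.index)],
        columns=["v_gene", "frequency"],
    )


def _usage_counts(rearrs_or_counts) -> dict[str, int]:
    if isinstance(rearrs_or_counts, pd.DataFrame):
        genes = rearrs_or_counts["v_call"].map(lambda c: c.split("*")[0])
        return genes.value_counts().to_dict()
    return dict(rearrs_or_counts)


def rdi(
    sample_a,
    sample_b,
    depth: int = 100,
    iterations: int = 100,
    seed: int = 0,
) -> float:
    """Repertoire Dissimilarity Index between two V-gene usage profiles.

    Each iteration subsamples both repertoires to ``depth`` sequences without
    replacement, forms per-gene count vectors, applies a log2(1+x) transform
    and takes the Euclidean distance; the score is the mean over iterations.
    Symmetric: each repertoire's subsampling stream depends only on its own
    contents, not on argument order.
    """
    counts_a, counts_b = _usage_counts(sample_a), _usage_counts(sample_b)
    for counts in (counts_a, counts_b):
        if sum(counts.values()) < depth:
            raise ValueError("depth exceeds a sample's size")
    genes = sorted(set(counts_a) | set(counts_b))

    def expand(counts):
        return np.repeat(
            np.arange(len(genes)),
            [counts.get(g, 0) for g in genes],
        )

    pool_a, pool_b = expand(counts_a), expand(counts_b)
    # order-independent stream assignment: the lexicographically smaller
    # serialized profile gets substream 0
    key_a = tuple(sorted(counts_a.items()))
    key_b = tuple(sorted(counts_b.items()))
    swap = key_b < key_a
    rng0 = np.random.default_rng([seed, 0])
    rng1 = np.random.default_rng([seed, 1])
    rng_a, rng_b = (rng1, rng0) if swap else (rng0, rng1)
    total = 0.0
    for _ in range(iterations):
        va = np.bincount(rng_a.choice(pool_a, size=depth, replace=False),
                         minlength=len(genes))
        vb = np.bincount(rng_b.choice(pool_b, size=depth, replace=False),
                         minlength=len(genes))
        total += float(np.linalg.norm(np.log2(1 + va) - np.log2(1 + vb)))
    return total / iterations


def compare_shm(
    groups_a: list[np.ndarray],
    groups_b: list[np.ndarray],
) -> pd.DataFrame:
    """Two-sample t tests of paired SHM distributions, Holm–Šidák adjusted.

    ``groups_a[i]`` vs ``groups_b[i]`` are compared with Welch's t; the
    family of p-values is adjusted with the Holm–Šidák step-down rule.
    """
    if len(groups_a) != len(groups_b):
        raise ValueError("group lists must pair up")
    raw = []
    for a, b in zip(groups_a, groups_b):
        t, p = sps.ttest_ind(np.asarray(a, float), np.asarray(b, float),
                             equal_var=False)
        raw.append((float(t), float(p)))
    m = len(raw)
    order = np.argsort([p for _, p in raw])
    adjusted = [0.0] * m
    running = 0.0
    for rank, i in enumerate(order):
        adj = 1.0 - (1.0 - raw[i][1]) ** (m - rank)
        running = max(running, adj)
        adjusted[i] = min(1.0, running)
    return pd.DataFrame({
        "comparison": range(m),
        "t_statistic": [t for t, _ in raw],
        "p_value": [p for _, p in raw],
        "p_adjusted": adjusted,
    })
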