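"""Synthetic repertoire generator with ground truth.

Emulates the two library types the pipeline is designed to contrast:

* a **naïve-dominated compartment** (PBMC-like): >90% IgM, low somatic
  hypermutation (0.5–1% of sites), mostly singleton clones, few mRNA
  transcripts per cell;
* a **stimulated/memory compartment**: IgG-dominated (IgG1 the major
  subtype), 4–7% hypermutation, a skewed clone-size distribution and
  several-fold more transcripts (and reads) per cell, reflecting the
  proliferation and transcriptional up-regulation of activated B cells.

Each simulated cell is a V(D)J recombination event (uniform 0–5 nt junctional
trimming, uniform 0–10 nt non-templated N-insertion at each join) with
substitution-only hypermutation applied uniformly over the V(D)J region —
star-shaped clones descended from one naïve ancestor.  Each transcript of a
cell receives a unique 5′ and 3′ UMI (8 or 12 nt) and is sequenced into a
configurable number of paired-end reads with i.i.d. per-base substitution
errors.  Every read traces back to exactly one truth record.
"""

from __future__ import annotations

import dataclasses
import gzip
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .reference import DNA, GermlineReference, ISOTYPE_SUBTYPES

_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclasses.dataclass(frozen=True)
class Primer:
    """Amplicon primer: anchor sequence plus the UMI length that follows it."""

    name: str
    end: str  # "5" or "3"
    sequence: str
    umi_length: int


#: default amplicon primer set: 5′ (leader-side) and 3′ (constant-side)
#: primers exist in 8-nt and 12-nt UMI variants, mirroring mixed-length
#: UMI designs used to offset low sequence diversity at amplicon ends.
DEFAULT_PRIMERS = (
    Primer("VP8", "5", "ACACGACGCTCTTCCGATCT", 8),
    Primer("VP12", "5", "TACGGTAGCAGAGACTTGGT", 12),
    Primer("CP8", "3", "AGACGTGTGCTCTTCCGATC", 8),
    Primer("CP12", "3", "GTGACTGGAGTTCAGACGTG", 12),
)


@dataclasses.dataclass(frozen=True)
class CompartmentSpec:
    """Generative parameters of one B-cell compartment."""

    name: str
    weight: float
    isotype_profile: dict[str, float]
    shm_rate: float
    clone_alpha: float  # power-law exponent of the clone-size distribution
    clone_max_size: int
    transcripts_per_cell: float
    reads_per_transcript: float

    def validate(self) -> None:
        if not 0 <= self.weight <= 1:
            raise ConfigurationError(f"{self.name}: weight outside [0,1]")
        if not 0 <= self.shm_rate < 1:
            raise ConfigurationError(f"{self.name}: shm_rate outside [0,1)")
        total = sum(self.isotype_profile.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigurationError(f"{self.name}: isotype profile sums to {total}")
        for iso, p in self.isotype_profile.items():
            if iso not in ISOTYPE_SUBTYPES:
                raise ConfigurationError(f"{self.name}: unknown isotype {iso}")
            if not 0 <= p <= 1:
                raise ConfigurationError(f"{self.name}: profile value outside [0,1]")
        if self.clone_max_size < 1 or self.clone_alpha <= 0:
            raise ConfigurationError(f"{self.name}: bad clone-size distribution")
        if self.transcripts_per_cell < 1 or self.reads_per_transcript < 1:
            raise ConfigurationError(f"{self.name}: per-cell means must be ≥1")


def naive_compartment(weight: float = 1.0) -> CompartmentSpec:
    """PBMC-like compartment: IgM-dominated, near-germline, singleton clones."""
    return CompartmentSpec(
        name="naive",
        weight=weight,
        isotype_profile={
            "IgM": 0.92,
            "IgG1": 0.02,
            "IgG2": 0.01,
            "IgG3": 0.005,
            "IgG4": 0.005,
            "IgA1": 0.03,
            "IgA2": 0.01,
        },
        shm_rate=0.0075,
        clone_alpha=3.5,
        clone_max_size=5,
        transcripts_per_cell=1.5,
        reads_per_transcript=3.0,
    )


def memory_compartment(weight: float = 1.0) -> CompartmentSpec:
    """Stimulated-PBMC-like compartment: IgG1-dominated, hypermutated,
    skewed clone sizes, ≥3× the naïve transcript output per cell."""
    return CompartmentSpec(
        name="memory",
        weight=weight,
        isotype_profile={
            "IgM": 0.10,
            "IgG1": 0.70,
            "IgG2": 0.08,
            "IgG3": 0.04,
            "IgG4": 0.02,
            "IgA1": 0.04,
            "IgA2": 0.02,
        },
        shm_rate=0.055,
        clone_alpha=2.0,
        clone_max_size=50,
        transcripts_per_cell=3.0,
        reads_per_transcript=9.0,
    )


@dataclasses.dataclass(frozen=True)
class SimulationConfig:
    """Knobs of one simulated sample."""

    n_cells: int = 2000
    compartments: tuple[CompartmentSpec, ...] = dataclasses.field(
        default_factory=lambda: (naive_compartment(0.5), memory_compartment(0.5))
    )
    per_base_error: float = 0.002
    umi_lengths: tuple[int, ...] = (8, 12)
    read_length: int = 250
    seed: int = 0

    def validate(self) -> None:
        if self.n_cells < 1:
            raise ConfigurationError("n_cells must be positive")
        if not 0 <= self.per_base_error < 1:
            raise ConfigurationError("per_base_error outside [0,1)")
        if not set(self.umi_lengths) <= {8, 12}:
            raise ConfigurationError("umi_lengths must be a subset of {8, 12}")
        if abs(sum(c.weight for c in self.compartments) - 1.0) > 1e-9:
            raise ConfigurationError("compartment weights must sum to 1")
        for comp in self.compartments:
            comp.validate()
        max_prefix = max(len(p.sequence) + p.umi_length for p in DEFAULT_PRIMERS)
        if self.read_length <= max_prefix:
            raise ConfigurationError("read_length shorter than primer+UMI prefix")


@dataclasses.dataclass
class Cell:
    """Ground-truth record of one simulated B cell."""

    cell_id: str
    clone_id: str
    compartment: str
    v_name: str
    d_name: str
    j_name: str
    isotype: str  # subtype-level label (IgM, IgG1, ...)
    sequence: str  # mutated V(D)J nucleotides
    naive_sequence: str
    mutated_positions: tuple[int, ...]
    junction_start: int  # conserved Cys codon start, on `sequence`
    junction_end: int  # one past the conserved Trp codon, on `sequence`
    j_start: int  # start of the J segment on `sequence`
    j_trim: int

    @property
    def junction(self) -> str:
        return self.sequence[self.junction_start : self.junction_end]

    def full_sequence(self, ref: GermlineReference) -> str:
        """V(D)J plus the constant-region stub of the cell's isotype."""
        return self.sequence + ref.constant_stubs[self.isotype]


def _power_law_sizes(rng, alpha: float, max_size: int) -> np.ndarray:
    sizes = np.arange(1, max_size + 1)
    p = sizes.astype(float) ** -alpha
    return sizes, p / p.sum()


def _recombine(rng, ref: GermlineReference) -> tuple[str, str, str, str, int, int, int, int]:
    """One naïve V(D)J junction: returns (v, d, j, sequence, junction bounds, j geometry)."""
    v = ref.v_genes[rng.choice(sorted(ref.v_genes))]
    d = ref.d_genes[rng.choice(sorted(ref.d_genes))] if ref.d_genes else None
    j = ref.j_genes[rng.choice(sorted(ref.j_genes))]
    v_trim = int(rng.integers(0, 6))
    j_trim = int(rng.integers(0, 6))
    n1 = "".join(rng.choice(DNA, size=int(rng.integers(0, 11))))
    n2 = "".join(rng.choice(DNA, size=int(rng.integers(0, 11))))
    if d is not None:
        d5 = int(rng.integers(0, 6))
        d3 = int(rng.integers(0, min(6, max(1, len(d.sequence) - d5 - 5))))
        d_part = d.sequence[d5 : len(d.sequence) - d3]
    else:
        d_part = ""
    v_part = v.sequence[: len(v.sequence) - v_trim]
    j_part = j.sequence[j_trim:]
    seq = v_part + n1 + d_part + n2 + j_part
    junction_start = v.anchors["CYS104"]
    j_start = len(seq) - len(j_part)
    junction_end = j_start + (j.anchors["TRP118"] - j_trim) + 3
    return (v.name, d.name if d else "", j.name, seq,
            junction_start, junction_end, j_start, j_trim)


def _mutate(rng, seq: str, rate: float) -> tuple[str, tuple[int, ...]]:
    if rate <= 0:
        return seq, ()
    hits = np.nonzero(rng.random(len(seq)) < rate)[0]
    bases = list(seq)
    for pos in hits:
        choices = [b for b in "ACGT" if b != bases[pos]]
        bases[pos] = choices[int(rng.integers(0, 3))]
    return "".join(bases), tuple(int(p) for p in hits)


def simulate_repertoire(
    config: SimulationConfig,
    ref: GermlineReference,
    rng: np.random.Generator | None = None,
    clone_prefix: str = "C",
) -> list[Cell]:
    """Draw a repertoire of cells with known clonal structure.

    Clone sizes follow a truncated discrete power law per compartment; all
    members of a clone share one naïve recombination and mutate from it
    independently (star topology).  Deterministic given ``config.seed``.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    # largest-remainder apportionment of cells to compartments
    weights = np.array([c.weight for c in config.compartments])
    raw = weights * config.n_cells
    counts = np.floor(raw).astype(int)
    for i in np.argsort(-(raw - counts))[: config.n_cells - counts.sum()]:
        counts[i] += 1
    cells: list[Cell] = []
    clone_no = 0
    for comp, n_comp in zip(config.compartments, counts):
        sizes, probs = _power_law_sizes(rng, comp.clone_alpha, comp.clone_max_size)
        iso_names = sorted(comp.isotype_profile)
        iso_p = np.array([comp.isotype_profile[i] for i in iso_names])
        assigned = 0
        while assigned < n_comp:
            size = int(rng.choice(sizes, p=probs))
            size = min(size, n_comp - assigned)  # conserve Σ sizes == n_cells
            clone_no += 1
            clone_id = f"{clone_prefix}{clone_no:05d}"
            v, d, j, naive, js, je, j_start, j_trim = _recombine(rng, ref)
            for _ in range(size):
                iso = iso_names[int(rng.choice(len(iso_names), p=iso_p))]
                mutated, positions = _mutate(rng, naive, comp.shm_rate)
                cells.append(
                    Cell(
                        cell_id=f"{clone_id}.{len(cells):06d}",
                        clone_id=clone_id,
                        compartment=comp.name,
                        v_name=v,
                        d_name=d,
                        j_name=j,
                        isotype=iso,
                        sequence=mutated,
                        naive_sequence=naive,
                        mutated_positions=positions,
                        junction_start=js,
                        junction_end=je,
                        j_start=j_start,
                        j_trim=j_trim,
                    )
                )
            assigned += size
    return cells


# ---------------------------------------------------------------------------
# read generation

TRUTH_COLUMNS = [
    "transcript_id", "cell_id", "clone_id", "compartment", "v_call", "d_call",
    "j_call", "isotype", "sequence", "junction_start", "junction_end",
    "mutated_positions", "umi5", "umi3", "umi_signature", "n_reads", "sample_id",
]


def _draw_umi(rng, length: int) -> str:
    return "".join(rng.choice(DNA, size=length))


def _apply_errors(rng, seq: str, rate: float) -> tuple[str, str]:
    """Substitution errors plus a two-valued quality string (Q37/Q20)."""
    qual = np.full(len(seq), 37)
    if rate > 0:
        hits = np.nonzero(rng.random(len(seq)) < rate)[0]
        if hits.size:
            bases = list(seq)
            for pos in hits:
                choices = [b for b in "ACGT" if b != bases[pos]]
                bases[pos] = choices[int(rng.integers(0, 3))]
            seq = "".join(bases)
            qual[hits] = 20
    return seq, "".join(chr(q + 33) for q in qual)


def generate_reads(
    cells: list[Cell],
    config: SimulationConfig,
    ref: GermlineReference,
    fwd_path,
    rev_path,
    truth_path=None,
    sample_id: str = "sample",
    rng: np.random.Generator | None = None,
    used_umis: set[str] | None = None,
) -> pd.DataFrame:
    """Emit UMI-tagged paired-end FASTQ plus the transcript truth table.

    The forward read is 5′-primer + UMI + the start of the transcript; the
    reverse read is 3′-primer + UMI + the reverse complement of the
    transcript end (constant stub first).  ``used_umis`` lets a caller
    guarantee UMI disjointness across samples.
    """
    if not cells:
        raise ConfigurationError("generate_reads requires a nonempty cell list")
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    if used_umis is None:
        used_umis = set()
    p5 = {p.umi_length: p for p in DEFAULT_PRIMERS if p.end == "5"}
    p3 = {p.umi_length: p for p in DEFAULT_PRIMERS if p.end == "3"}
    tpc = {c.name: c.transcripts_per_cell for c in config.compartments}
    rpt = {c.name: c.reads_per_transcript for c in config.compartments}
    records = []
    fwd_open = gzip.open if str(fwd_path).endswith(".gz") else open
    rev_open = gzip.open if str(rev_path).endswith(".gz") else open
    with fwd_open(fwd_path, "wt") as ffh, rev_open(rev_path, "wt") as rfh:
        for cell in cells:
            template = cell.full_sequence(ref)
            n_tx = max(1, int(rng.poisson(tpc.get(cell.compartment, 1.5))))
            for t in range(n_tx):
                l5 = int(rng.choice(config.umi_lengths))
                l3 = int(rng.choice(config.umi_lengths))
                while True:
                    umi5, umi3 = _draw_umi(rng, l5), _draw_umi(rng, l3)
                    sig = umi5[:8] + umi3[:8]
                    if sig not in used_umis:
                        used_umis.add(sig)
                        break
                n_reads = max(1, int(rng.poisson(rpt.get(cell.compartment, 3.0))))
                tx_id = f"{sample_id}.{cell.cell_id}.t{t}"
                fwd_t = p5[l5].sequence + umi5 + template
                rev_t = p3[l3].sequence + umi3 + revcomp(template)
                for k in range(n_reads):
                    fb, fq = _apply_errors(rng, fwd_t[: config.read_length],
                                           config.per_base_error)
                    rb, rq = _apply_errors(rng, rev_t[: config.read_length],
                                           config.per_base_error)
                    rid = f"{tx_id}.r{k}"
                    ffh.write(f"@{rid}/1\n{fb}\n+\n{fq}\n")
                    rfh.write(f"@{rid}/2\n{rb}\n+\n{rq}\n")
                records.append(
                    (tx_id, cell.cell_id, cell.clone_id, cell.compartment,
                     cell.v_name, cell.d_name, cell.j_name, cell.isotype,
                     template, cell.junction_start, cell.junction_end,
                     ",".join(map(str, cell.mutated_positions)),
                     umi5, umi3, sig, n_reads, sample_id)
                )
    truth = pd.DataFrame(records, columns=TRUTH_COLUMNS)
    if truth_path is not None:
        truth.to_csv(truth_path, sep="\t", index=False)
    return truth


def plan_timepoints(
    config: SimulationConfig,
    ref: GermlineReference,
    samples: tuple[str, ...],
    persistent_count: int = 0,
    persistent_fraction: float | None = None,
    rng: np.random.Generator | None = None,
) -> dict[str, list[Cell]]:
    """Per-sample cell lists sharing a designated set of persistent clones.

    Persistent cells are drawn once (from the configured compartment mixture,
    so their hypermutation spans the naïve and memory ranges) and contribute
    the *identical mutated sequence* to every sample; everything else is
    drawn independently per sample.  UMIs are assigned later, per sample,
    from disjoint pools.
    """
    if len(samples) < 2:
        raise ConfigurationError("plan_timepoints needs ≥2 named samples")
    if persistent_fraction is not None:
        if not 0 <= persistent_fraction <= 1:
            raise ConfigurationError("persistence fraction outside [0,1]")
        persistent_count = int(round(persistent_fraction * config.n_cells))
    if persistent_count > config.n_cells:
        raise ConfigurationError("persistent_count exceeds n_cells")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    persistent: list[Cell] = []
    if persistent_count:
        # persistent cells are singleton clones so each contributes one
        # distinct core sequence to every sample
        singles = tuple(
            dataclasses.replace(c, clone_max_size=1) for c in config.compartments
        )
        pconf = dataclasses.replace(config, n_cells=persistent_count,
                                    compartments=singles)
        persistent = simulate_repertoire(pconf, ref, rng=rng, clone_prefix="P")
    plan: dict[str, list[Cell]] = {}
    n_private = config.n_cells - persistent_count
    for sample in samples:
        cells = list(persistent)
        if n_private:
            sconf = dataclasses.replace(config, n_cells=n_private)
            cells += simulate_repertoire(sconf, ref, rng=rng,
                                         clone_prefix=f"{sample}.C")
        plan[sample] = cells
    return plan
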