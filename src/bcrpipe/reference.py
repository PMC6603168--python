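"""Germline gene reference: V/D/J segments, region bounds and anchor positions.

The reference is the coordinate authority for the whole pipeline: framework /
CDR partitioning, junction extraction, the Kabat-numbered core used by the
persistence analysis, and the germline baseline for somatic hypermutation all
come from the per-gene annotations stored here.

A synthetic reference can be generated deterministically (``make_reference``)
for simulation and testing, or loaded from a FASTA file plus a tab-separated
sidecar carrying region bounds and anchor positions (0-based, half-open).
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np

DNA = np.array(list("ACGT"))

#: region names carried on V genes, 5'→3'
V_REGIONS = ("FWR1", "CDR1", "FWR2", "CDR2", "FWR3")
#: anchor rows stored in the sidecar alongside regions
V_ANCHORS = ("CYS104", "KABAT12")
J_REGIONS = ("FWR4",)
J_ANCHORS = ("TRP118", "KABAT136")

ISOTYPE_SUBTYPES = ("IgM", "IgG1", "IgG2", "IgG3", "IgG4", "IgA1", "IgA2")


def isotype_of(subtype: str) -> str:
    """Collapse a subtype label (IgG1, IgA2, ...) to its isotype (IgG, IgA)."""
    if subtype.startswith("IgG"):
        return "IgG"
    if subtype.startswith("IgA"):
        return "IgA"
    return subtype


@dataclasses.dataclass(frozen=True)
class GeneRecord:
    """One germline gene segment.

    ``region_bounds`` maps region names to 0-based half-open intervals on
    ``sequence``; ``anchors`` maps anchor names (CYS104, TRP118, KABAT12,
    KABAT136) to 0-based positions (KABAT136 stores an *exclusive* end).
    """

    name: str
    sequence: str
    region_bounds: dict[str, tuple[int, int]] = dataclasses.field(default_factory=dict)
    anchors: dict[str, int] = dataclasses.field(default_factory=dict)

    def __post_init__(self):
        seq = self.sequence
        if not seq or set(seq) - set("ACGT"):
            raise ValueError(f"{self.name}: sequence must be non-empty uppercase ACGT")
        prev_end = 0
        for region, (start, end) in self.region_bounds.items():
            if not (0 <= start < end <= len(seq)):
                raise ValueError(f"{self.name}: region {region} bounds out of range")
            if start < prev_end:
                raise ValueError(f"{self.name}: region {region} overlaps predecessor")
            prev_end = end

    @property
    def gene(self) -> str:
        """Gene name without the allele suffix (IGHV1-1*01 → IGHV1-1)."""
        return self.name.split("*")[0]


@dataclasses.dataclass(frozen=True)
class GermlineReference:
    """V/D/J gene segments plus constant-region stubs for isotype calling."""

    v_genes: dict[str, GeneRecord]
    d_genes: dict[str, GeneRecord]
    j_genes: dict[str, GeneRecord]
    constant_stubs: dict[str, str]

    def __post_init__(self):
        for label, genes in (("V", self.v_genes), ("J", self.j_genes)):
            if not genes:
                raise ValueError(f"reference has no {label} genes")
        for iso, stub in self.constant_stubs.items():
            if len(stub) < 20:
                raise ValueError(f"constant stub {iso} shorter than 20 nt")

    def v(self, name: str) -> GeneRecord:
        return self.v_genes[name]

    def j(self, name: str) -> GeneRecord:
        return self.j_genes[name]


def _random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(DNA, size=length))


def make_reference(
    seed: int = 20190304,
    n_v: int = 8,
    n_d: int = 4,
    n_j: int = 4,
    v_length: int = 291,
    j_length: int = 48,
    stub_length: int = 40,
) -> GermlineReference:
    """Generate a deterministic synthetic germline reference.

    V genes carry FWR1/CDR1/FWR2/CDR2/FWR3 bounds, the conserved cysteine
    codon (CYS104) at ``v_length - 9`` followed by a 6-nt trimmable tail, and
    the KABAT12 anchor at nucleotide 33 (codon 12).  J genes carry the
    conserved tryptophan codon (TRP118) at position 12, FWR4 downstream of
    it, and KABAT136 as an exclusive end 3 nt before the gene end.  Constant
    stubs for the IgG and IgA subtypes share an isotype backbone but differ
    pairwise at ≥6 positions so subtype calls are unambiguous at the ≤2
    mismatch tolerance.
    """
    if v_length % 3 != 0 or v_length < 120:
        raise ValueError("v_length must be a multiple of 3 and ≥120")
    rng = np.random.default_rng(seed)
    cys = v_length - 9  # conserved Cys codon start; 6-nt tail after it
    # region bounds at fixed fractions of the pre-Cys V, codon aligned
    fractions = (0.0, 0.27, 0.36, 0.53, 0.62, 1.0)
    cuts = [3 * round(f * cys / 3) for f in fractions]
    v_genes = {}
    for i in range(n_v):
        name = f"IGHV{i % 4 + 1}-{i + 1}*01"
        seq = list(_random_dna(rng, v_length))
        seq[cys : cys + 3] = "TGT"  # conserved cysteine
        bounds = {r: (cuts[k], cuts[k + 1]) for k, r in enumerate(V_REGIONS)}
        v_genes[name] = GeneRecord(
            name, "".join(seq), bounds, {"CYS104": cys, "KABAT12": 33}
        )
    d_genes = {}
    for i in range(n_d):
        name = f"IGHD{i + 1}-{i + 1}*01"
        d_genes[name] = GeneRecord(name, _random_dna(rng, int(rng.integers(16, 25))))
    j_genes = {}
    trp = 12
    for i in range(n_j):
        name = f"IGHJ{i + 1}*01"
        seq = list(_random_dna(rng, j_length))
        seq[trp : trp + 3] = "TGG"  # conserved tryptophan
        bounds = {"FWR4": (trp, j_length)}
        j_genes[name] = GeneRecord(
            name, "".join(seq), bounds, {"TRP118": trp, "KABAT136": j_length - 3}
        )
    # constant stubs: per-isotype backbone, subtypes differ at 6 spread positions
    stubs: dict[str, str] = {"IgM": _random_dna(rng, stub_length)}
    for iso, subtypes in (("IgG", 4), ("IgA", 2)):
        backbone = list(_random_dna(rng, stub_length))
        for k in range(subtypes):
            stub = backbone.copy()
            for p in range(6):
                pos = (p * subtypes + k) * stub_length // (6 * subtypes)
                stub[pos] = DNA[(list(DNA).index(stub[pos]) + 1 + k) % 4]
            stubs[f"{iso}{k + 1}"] = "".join(stub)
    return GermlineReference(v_genes, d_genes, j_genes, stubs)


# ---------------------------------------------------------------------------
# FASTA + sidecar round trip

def write_reference(ref: GermlineReference, fasta_path, sidecar_path) -> None:
    """Write the reference as FASTA plus a tab-separated annotation sidecar.

    Sidecar columns: gene, feature, start, end.  Region rows use half-open
    [start, end); anchor rows store the position in ``start`` with end = -1.
    Constant stubs appear in the FASTA with a ``CONST|`` name prefix.
    """
    with open(fasta_path, "w") as fh:
        for genes in (ref.v_genes, ref.d_genes, ref.j_genes):
            for rec in genes.values():
                fh.write(f">{rec.name}\n{rec.sequence}\n")
        for iso, stub in ref.constant_stubs.items():
            fh.write(f">CONST|{iso}\n{stub}\n")
    with open(sidecar_path, "w") as fh:
        fh.write("gene\tfeature\tstart\tend\n")
        for genes in (ref.v_genes, ref.j_genes):
            for rec in genes.values():
                for region, (s, e) in rec.region_bounds.items():
                    fh.write(f"{rec.name}\t{region}\t{s}\t{e}\n")
                for anchor, pos in rec.anchors.items():
                    fh.write(f"{rec.name}\t{anchor}\t{pos}\t-1\n")


def read_reference(fasta_path, sidecar_path) -> GermlineReference:
    """Load a reference written by :func:`write_reference`."""
    from Bio import SeqIO

    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        seqs[rec.id] = str(rec.seq).upper()
    bounds: dict[str, dict[str, tuple[int, int]]] = {}
    anchors: dict[str, dict[str, int]] = {}
    with open(sidecar_path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != ["gene", "feature", "start", "end"]:
            raise ValueError(f"unrecognized sidecar header: {header}")
        for line in fh:
            gene, feature, start, end = line.rstrip("\n").split("\t")
            if int(end) < 0:
                anchors.setdefault(gene, {})[feature] = int(start)
            else:
                bounds.setdefault(gene, {})[feature] = (int(start), int(end))
    v, d, j, stubs = {}, {}, {}, {}
    for name, seq in seqs.items():
        if name.startswith("CONST|"):
            stubs[name.split("|", 1)[1]] = seq
        elif "IGHV" in name:
            v[name] = GeneRecord(name, seq, bounds.get(name, {}), anchors.get(name, {}))
        elif "IGHD" in name:
            d[name] = GeneRecord(name, seq)
        elif "IGHJ" in name:
            j[name] = GeneRecord(name, seq, bounds.get(name, {}), anchors.get(name, {}))
        else:
            raise ValueError(f"cannot classify reference record {name!r}")
    return GermlineReference(v, d, j, stubs)


_DEFAULT: GermlineReference | None = None


def default_reference() -> GermlineReference:
    """The bundled synthetic reference used by simulations and the demo."""
    global _DEFAULT
    if _DEFAULT is None:
        _DEFAULT = make_reference()
    return _DEFAULT
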