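"""End-to-end orchestration: simulate → preprocess → annotate → cluster →
summarize → longitudinal, driven by a single structured run configuration.

The configuration is a YAML document (see :class:`RunConfig`) so every run
is reproducible from one serialized record.  All randomness derives from the
configured seed; rerunning a config byte-reproduces the rearrangement
tables.
"""

from __future__ import annotations

import dataclasses
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import clonal, io, longitudinal, preprocess, sim, stats
from .annotate import Annotator, annotate_table
from .errors import ConfigurationError, StageError
from .reference import default_reference, read_reference

DEFAULT_PARAMS = {
    "q_mean": 20.0,
    "min_reads_per_umi": 2,
    "constant_threshold_percent": 12.0,
    "mutated_cutoff_percent": 1.0,
    "min_overlap": 10,
    "max_mismatch_rate": 0.2,
}

METADATA_KEYS = ("donor", "timepoint", "condition", "replicate")


@dataclasses.dataclass
class RunConfig:
    """Validated run configuration."""

    seed: int
    output_dir: Path
    params: dict
    simulate: dict | None
    samples: list[dict]
    mabs_path: Path | None
    reference_paths: tuple[Path, Path] | None

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw, base_dir=Path(path).parent)

    @classmethod
    def from_dict(cls, raw: dict, base_dir: Path = Path(".")) -> "RunConfig":
        params = {**DEFAULT_PARAMS, **(raw.get("params") or {})}
        if not 0 <= params["q_mean"] <= 60:
            raise ConfigurationError("q_mean outside [0, 60]")
        if params["min_reads_per_umi"] < 1:
            raise ConfigurationError("min_reads_per_umi must be ≥1")
        simulate = raw.get("simulate")
        samples = list(raw.get("samples") or [])
        if simulate:
            samples = list(simulate.get("samples") or [])
            if not samples:
                raise ConfigurationError("simulate section lists no samples")
        if not samples:
            raise ConfigurationError("no samples configured")
        mabs = raw.get("mabs")
        mabs_path = (base_dir / mabs) if mabs else None
        if mabs_path and not mabs_path.exists():
            raise ConfigurationError(f"mAb FASTA not found: {mabs_path}")
        ref_paths = None
        if raw.get("reference"):
            fasta = base_dir / raw["reference"]["fasta"]
            sidecar = base_dir / raw["reference"]["sidecar"]
            for p in (fasta, sidecar):
                if not p.exists():
                    raise ConfigurationError(f"reference file not found: {p}")
            ref_paths = (fasta, sidecar)
        if not simulate:
            for spec in samples:
                for key in ("fastq_fwd", "fastq_rev"):
                    fq = base_dir / spec.get(key, "")
                    if not spec.get(key) or not fq.exists():
                        raise ConfigurationError(
                            f"sample {spec.get('id', '?')}: missing FASTQ {key}"
                        )
                    spec[key] = fq
        return cls(
            seed=int(raw.get("seed", 0)),
            output_dir=base_dir / raw.get("output_dir", "bcrpipe_out"),
            params=params,
            simulate=simulate,
            samples=samples,
            mabs_path=mabs_path,
            reference_paths=ref_paths,
        )


def _sim_config(simulate: dict, spec: dict, seed: int) -> sim.SimulationConfig:
    weights = (spec.get("compartment_weights")
               or simulate.get("compartment_weights")
               or {"naive": 0.5, "memory": 0.5})
    comps = tuple(
        c for c in (
            sim.naive_compartment(weights.get("naive", 0.0)),
            sim.memory_compartment(weights.get("memory", 0.0)),
        ) if c.weight > 0
    )
    return sim.SimulationConfig(
        n_cells=int(simulate.get("n_cells", 2000)),
        compartments=comps,
        per_base_error=float(simulate.get("per_base_error", 0.002)),
        seed=seed,
    )


def process_sample(
    pairs,
    ref,
    params: dict,
    metadata: dict,
    annotator: Annotator | None = None,
):
    """Preprocess + annotate one sample; returns dict of stage products."""
    table, report = preprocess.preprocess_sample(
        pairs,
        constant_stubs=ref.constant_stubs,
        q_mean=params["q_mean"],
        min_reads_per_umi=1,  # collapse once; the ≥2 view filters below
        min_overlap=params["min_overlap"],
        max_mismatch_rate=params["max_mismatch_rate"],
    )
    for key in METADATA_KEYS + ("sample_id",):
        table[key] = metadata.get(key, "")
    filtered = table[table["max_reads_per_umi"] >= params["min_reads_per_umi"]]
    if annotator is None:
        annotator = Annotator(ref)
    rearrs, n_failed = annotate_table(filtered, ref, metadata, annotator)
    rearrs_unique, n_failed_uniq = annotate_table(table, ref, metadata, annotator)
    dist = clonal.distance_to_nearest(rearrs)
    est = clonal.find_threshold(dist, sample_id=metadata.get("sample_id", ""))
    clustered, clones = clonal.cluster_clones(rearrs, est.threshold)
    return {
        "processed": table,
        "report": report,
        "rearrangements": clustered,
        "rearrangements_all_unique": rearrs_unique,
        "clones": clones,
        "threshold": est,
        "n_unannotatable": n_failed,
        "n_unannotatable_all_unique": n_failed_uniq,
    }


def run_pipeline(config: RunConfig) -> dict:
    """Execute every configured stage; returns the run report dict."""
    t0 = time.time()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    ref = (read_reference(*config.reference_paths)
           if config.reference_paths else default_reference())
    annotator = Annotator(ref)
    report: dict = {"seed": config.seed, "params": dict(config.params),
                    "samples": {}, "stages": {}}
    prov = {"seed": config.seed}
    results: dict[str, dict] = {}

    # --- stage: simulate (optional) ---------------------------------------
    sample_pairs: dict[str, list] = {}
    try:
        if config.simulate:
            persistent = int(config.simulate.get("persistent_count", 0))
            used_umis: set[str] = set()
            specs = config.samples
            if persistent and len(specs) >= 2:
                base = _sim_config(config.simulate, specs[0], config.seed)
                plan = sim.plan_timepoints(
                    base, ref, tuple(s["id"] for s in specs),
                    persistent_count=persistent,
                    rng=np.random.default_rng([config.seed, 104729]),
                )
            else:
                plan = None
            for i, spec in enumerate(specs):
                sid = spec["id"]
                sdir = out / sid
                sdir.mkdir(exist_ok=True)
                conf = _sim_config(config.simulate, spec, config.seed)
                rng = np.random.default_rng([config.seed, i])
                cells = plan[sid] if plan else sim.simulate_repertoire(
                    conf, ref, rng=rng)
                truth = sim.generate_reads(
                    cells, conf, ref,
                    sdir / "reads_R1.fastq.gz", sdir / "reads_R2.fastq.gz",
                    truth_path=sdir / "truth.tsv", sample_id=sid,
                    rng=np.random.default_rng([config.seed, i, 1]),
                    used_umis=used_umis,
                )
                report["samples"].setdefault(sid, {})["n_cells"] = len(cells)
                report["samples"][sid]["n_transcripts"] = len(truth)
                spec["fastq_fwd"] = sdir / "reads_R1.fastq.gz"
                spec["fastq_rev"] = sdir / "reads_R2.fastq.gz"
    except Exception as exc:  # noqa: BLE001 - stage tagging
        raise StageError("simulate", str(exc)) from exc

    # --- stages: preprocess / annotate / cluster ---------------------------
    thresholds = []
    for spec in config.samples:
        sid = spec["id"]
        sdir = out / sid
        sdir.mkdir(exist_ok=True)
        metadata = {"sample_id": sid, **{k: spec.get(k, "") for k in METADATA_KEYS}}
        try:
            pairs = io.read_fastq_pairs(spec["fastq_fwd"], spec["fastq_rev"])
        except Exception as exc:  # noqa: BLE001
            raise StageError("read_input", f"{sid}: {exc}") from exc
        try:
            res = process_sample(pairs, ref, config.params, metadata, annotator)
        except Exception as exc:  # noqa: BLE001
            raise StageError("preprocess", f"{sid}: {exc}") from exc
        results[sid] = res
        io.write_airr(res["processed"], sdir / "processed.tsv", prov)
        io.write_airr(res["rearrangements"], sdir / "rearrangements.tsv", prov)
        io.write_airr(res["rearrangements_all_unique"],
                      sdir / "rearrangements_all_unique.tsv", prov)
        io.write_airr(clonal.clones_to_frame(res["clones"]),
                      sdir / "clones.tsv", prov)
        summary = stats.summarize_repertoire(
            res["rearrangements"], res["clones"], sid, res["threshold"].threshold)
        io.write_airr(summary, sdir / "summary.tsv", prov)
        io.write_airr(stats.vgene_usage(res["rearrangements"]),
                      sdir / "vgene_usage.tsv", prov)
        thresholds.append({
            "sample_id": sid,
            "n_distances": int(np.isfinite(res["threshold"].distances).sum()),
            "threshold": res["threshold"].threshold,
            "method": res["threshold"].method,
        })
        rep = res["report"]
        report["samples"].setdefault(sid, {}).update({
            "pairs_in": rep.pairs_in,
            "pairs_retained": rep.pairs_retained,
            "dropped": dict(rep.dropped),
            "sequences": len(res["processed"]),
            "rearrangements": len(res["rearrangements"]),
            "clones": len(res["clones"]),
            "unannotatable": res["n_unannotatable"],
            "threshold": res["threshold"].threshold,
        })
    io.write_airr(pd.DataFrame(thresholds), out / "thresholds.tsv", prov)
    report["stages"]["constant_threshold_percent"] = clonal.derive_constant_threshold(
        [100 * t["threshold"] for t in thresholds])

    # --- stage: longitudinal ------------------------------------------------
    try:
        if len(results) >= 2:
            persist = longitudinal.find_persistent_sequences(
                {sid: res["rearrangements_all_unique"]
                 for sid, res in results.items()},
                mutated_cutoff=config.params["mutated_cutoff_percent"],
            )
            io.write_airr(persist, out / "persistence.tsv", prov)
            clean = persist[~persist["contamination_suspect"]]
            report["stages"]["persistent_sequences"] = int(len(clean))
            report["stages"]["persistent_mutated"] = int(clean["mutated"].sum())
        if config.mabs_path:
            mabs = io.read_fasta(config.mabs_path)
            first = next(iter(results.values()))
            matches = longitudinal.match_mabs_to_clones(
                first["rearrangements_all_unique"], mabs, annotator,
                threshold=config.params["constant_threshold_percent"] / 100.0,
            )
            io.write_airr(matches, out / "mab_matches.tsv", prov)
            report["stages"]["mabs_matched"] = int(matches["matched"].sum())
        # lineage of the most sequence-rich clone of the first sample
        first = next(iter(results.values()))
        if first["clones"]:
            top = max(first["clones"],
                      key=lambda c: (c.abundance_sequences, c.clone_id))
            members = first["rearrangements"][
                first["rearrangements"]["clone_id"] == top.clone_id]
            members = _vdj_view(members)
            if members is not None and len(set(members["sequence"].str.len())) == 1:
                germ = _clone_germline(members, ref, annotator)
                if germ is not None:
                    tree = longitudinal.build_lineage(members, germ)
                    (out / "lineage.nwk").write_text(tree.to_newick() + "\n")
                    io.write_airr(tree.node_table(), out / "lineage_nodes.tsv", prov)
                    report["stages"]["lineage_total_length"] = tree.total_length
        grid = longitudinal.immunodominance_grid(first["clones"])
        io.write_airr(grid.to_frame(), out / "immunodominance.tsv", prov)
    except StageError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise StageError("longitudinal", str(exc)) from exc

    report["runtime_seconds"] = round(time.time() - t0, 2)
    with open(out / "run_report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report


def _vdj_view(members: pd.DataFrame) -> pd.DataFrame | None:
    """Clone members with sequences truncated at FWR4 end (constant stub off)."""
    if members["fwr4_end"].isna().any():
        return None
    trimmed = [s[: int(e)] for s, e in zip(members["sequence"], members["fwr4_end"])]
    return members.assign(sequence=trimmed)


def _clone_germline(members: pd.DataFrame, ref, annotator) -> str | None:
    """Reconstruct the naïve (germline) sequence of a clone.

    Takes the clone's V and J calls and rebuilds germline V and J over the
    aligned span, keeping the observed junction-interior nucleotides of the
    clone's consensus where no germline template exists (N regions / D).
    """
    row = members.iloc[0]
    seq = row["sequence"]
    calls = annotator.assign_vdj(seq)
    if calls is None:
        return None
    germ = list(seq)
    v_rec = ref.v_genes[calls["v_call"]]
    for g, q in calls["v_map"].items():
        germ[q] = v_rec.sequence[g]
    j_rec = ref.j_genes[calls["j_call"]]
    for g, q in calls["j_map"].items():
        germ[q] = j_rec.sequence[g]
    return "".join(germ)
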