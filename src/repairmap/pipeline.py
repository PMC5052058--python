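"""Manifest-driven end-to-end runs: simulate -> normalize -> analyse -> report.

A run manifest is a YAML/dict document with a global seed, an output
directory and an ordered list of steps.  Each step consumes named objects
produced by earlier steps (or files on disk) and registers its outputs under
its own name.  Every output is stamped with the parameters, the seed and the
package version; a failed step aborts the run with the step name and cause,
leaving partial outputs next to a FAILED marker.

The global seed fans out to per-stage seeds by stable hashing of stage
names, so inserting a stage does not perturb the randomness of the others.
"""

from __future__ import annotations

import json
import logging
import zlib
from pathlib import Path

import numpy as np

from . import __version__, io_formats
from .core import GeneAnnotation, SignalSet, SiteSet, TrackMeta
from .domains import call_domain, profile_correlation, profile_difference
from .enrichment import DetectionParams, detect_enrichment
from .normalization import normalize_set
from .profiles import ProfileSchema, gene_profile, localize_sites, point_profile, select_genes
from .signal_analysis import aggregate, repair_rate
from .synthetic import (
    RepairModel,
    SyntheticSpec,
    generate_genome,
    simulate_acetylation_signal,
    simulate_binding_signal,
    simulate_damage_signal,
)

log = logging.getLogger(__name__)

__all__ = ["PipelineError", "run"]


class PipelineError(RuntimeError):
    pass


def stage_seed(global_seed: int, stage_name: str) -> int:
    return (int(global_seed) ^ zlib.crc32(stage_name.encode())) & 0x7FFFFFFF


def run(manifest: dict | str | Path, base_dir: str | Path | None = None) -> dict:
    """Execute a run manifest; returns the run report (also written to disk)."""
    if not isinstance(manifest, dict):
        mpath = Path(manifest)
        base_dir = base_dir if base_dir is not None else mpath.parent
        manifest = io_formats.read_manifest(mpath)
    base = Path(base_dir) if base_dir is not None else Path.cwd()
    outdir = base / manifest.get("output_dir", "run_output")
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(manifest.get("seed", 0))
    registry: dict[str, object] = {}
    report: dict = {"seed": seed, "version": __version__, "steps": []}
    for i, step in enumerate(manifest.get("steps", [])):
        kind = step.get("step")
        name = step.get("name", f"step{i}_{kind}")
        try:
            entry = _STEP_HANDLERS[kind](step, name, registry, base, outdir, seed)
        except KeyError as exc:
            _fail(outdir, report, name, f"unknown step kind {kind!r}")
            raise PipelineError(f"step {name!r} failed: unknown step kind {kind!r}") from exc
        except Exception as exc:
            _fail(outdir, report, name, str(exc))
            raise PipelineError(f"step {name!r} failed: {exc}") from exc
        entry.update({"step": kind, "name": name})
        report["steps"].append(entry)
        log.info("step %s (%s) done: %s", name, kind, entry)
    with open(outdir / "run_report.json", "w") as fh:
        json.dump(report, fh, indent=2)
    return report


def _fail(outdir: Path, report: dict, name: str, cause: str) -> None:
    (outdir / "FAILED").write_text(f"step {name}: {cause}\n")
    with open(outdir / "run_report.json", "w") as fh:
        json.dump({**report, "failed_step": name, "cause": cause}, fh, indent=2)


def _get(registry: dict, key: str, want: type):
    if key not in registry:
        raise PipelineError(f"no object named {key!r} (available: {sorted(registry)})")
    obj = registry[key]
    if not isinstance(obj, want):
        raise PipelineError(f"object {key!r} is {type(obj).__name__}, expected {want.__name__}")
    return obj


def _step_simulate(step, name, registry, base, outdir, seed):
    spec = SyntheticSpec(**{"seed": stage_seed(seed, name), **step.get("spec", {})})
    layout, genes, sites = generate_genome(spec)
    registry[f"{name}.genes"] = genes
    registry[f"{name}.sites"] = sites
    registry[f"{name}.layout"] = layout
    n_groups = 0
    for scn in step.get("repair", {}).get("scenarios", []):
        model = RepairModel(scenario=scn, **step.get("repair", {}).get("model", {}))
        for tp in (0, 120):
            sset = simulate_damage_signal(spec, genes, sites, model, tp, seed=spec.seed)
            registry[f"{name}.cpd.{scn}.t{tp}"] = sset
            n_groups += 1
    bconf = step.get("binding", {})
    for state in bconf.get("uv_states", []):
        sset = simulate_binding_signal(
            spec, sites, genes, state,
            redistribution_fraction=bconf.get("redistribution_fraction", 0.0),
            seed=spec.seed, factor=bconf.get("factor", "Abf1"),
        )
        registry[f"{name}.binding.{state}"] = sset
        n_groups += 1
    aconf = step.get("acetylation", {})
    for state in aconf.get("uv_states", []):
        sset = simulate_acetylation_signal(
            spec, sites, state,
            induction_amplitude=aconf.get("induction_amplitude", 0.5),
            induction_offset_bp=aconf.get("induction_offset_bp", 500.0),
            seed=spec.seed,
        )
        registry[f"{name}.acetylation.{state}"] = sset
        n_groups += 1
    io_formats.write_gff3(genes, outdir / f"{name}_genes.gff3")
    io_formats.write_bed_sites(sites, outdir / f"{name}_sites.bed")
    return {"n_genes": len(genes), "n_sites": len(sites), "n_groups": n_groups,
            "stage_seed": spec.seed}


def _step_load_group(step, name, registry, base, outdir, seed):
    tracks = []
    for p in step["paths"]:
        path = base / p
        if not path.exists():
            raise PipelineError(f"input file not found: {path}")
        tracks.append(io_formats.read_bedgraph(path, meta=TrackMeta(
            strain=step.get("strain", ""), factor=step.get("factor", ""),
            uv_timepoint_min=step.get("timepoint"),
        )))
    registry[name] = SignalSet(
        tracks, strain=step.get("strain", ""), factor=step.get("factor", ""),
        uv_timepoint_min=step.get("timepoint"),
    )
    return {"n_replicates": len(tracks), "n_probes": len(tracks[0])}


def _step_load_annotation(step, name, registry, base, outdir, seed):
    path = base / step["path"]
    if not path.exists():
        raise PipelineError(f"annotation file not found: {path}")
    genes = io_formats.read_gff3(path) if path.suffix in (".gff3", ".gff") \
        else io_formats.read_bed_genes(path)
    if "expression" in step:
        genes = io_formats.attach_expression(
            genes, io_formats.read_expression_table(base / step["expression"])
        )
    registry[name] = genes
    return {"n_genes": len(genes)}


def _step_normalize(step, name, registry, base, outdir, seed):
    sset = _get(registry, step["input"], SignalSet)
    registry[name] = normalize_set(sset, step.get("mode", "full"))
    return {"mode": step.get("mode", "full"), "n_probes": len(sset.grid)}


def _step_repair_rate(step, name, registry, base, outdir, seed):
    t0 = _get(registry, step["t0"], SignalSet)
    t1 = _get(registry, step["t_repair"], SignalSet)
    rate = repair_rate(t0, t1)
    registry[name] = rate
    io_formats.write_bedgraph(rate.track, outdir / f"{name}.bedgraph")
    io_formats.write_bedgraph(
        rate.track.with_values(rate.dispersion), outdir / f"{name}_dispersion.bedgraph"
    )
    return {"n_probes": len(rate.track), "mean_rate": float(np.mean(rate.track.value))}


def _step_detect(step, name, registry, base, outdir, seed):
    sset = _get(registry, step["input"], SignalSet)
    params = DetectionParams(**step.get("params", {}))
    sites = detect_enrichment(aggregate(sset), params)
    registry[name] = sites
    io_formats.write_bed_sites(sites, outdir / f"{name}.bed")
    return {"n_sites": len(sites)}


def _step_profile(step, name, registry, base, outdir, seed):
    data = registry.get(step["track"])
    if data is None:
        raise PipelineError(f"no object named {step['track']!r}")
    if hasattr(data, "track"):  # RepairRateTrack / AggregateTrack
        data = data.track
    schema = ProfileSchema(**step.get("schema", {}))
    mode = step.get("mode", "gene")
    if mode == "gene":
        genes = _get(registry, step["features"], GeneAnnotation)
        if step.get("select", True):
            genes = select_genes(genes)
        prof = gene_profile(data, genes, schema)
    else:
        sites = _get(registry, step["features"], SiteSet)
        prof = point_profile(data, sites, schema)
    registry[name] = prof
    prof.to_frame().to_csv(outdir / f"{name}.tsv", sep="\t", index=False)
    return {"mode": mode, "n_bins": len(prof), "empty_bins": int(np.sum(~prof.nonempty))}


def _step_localize(step, name, registry, base, outdir, seed):
    sites = _get(registry, step["sites"], SiteSet)
    genes = _get(registry, step["genes"], GeneAnnotation)
    loc = localize_sites(sites, genes, ProfileSchema(**step.get("schema", {})))
    registry[name] = loc
    out = {"class_counts": loc.class_counts,
           "class_score_fractions": loc.class_score_fractions,
           "n_unattached": loc.n_unattached}
    with open(outdir / f"{name}.json", "w") as fh:
        json.dump(out, fh, indent=2)
    return out


def _step_difference(step, name, registry, base, outdir, seed):
    from .profiles import CompositeProfile
    p1 = _get(registry, step["p1"], CompositeProfile)
    p2 = _get(registry, step["p2"], CompositeProfile)
    diff = profile_difference(p1, p2)
    registry[name] = diff
    diff.to_frame().to_csv(outdir / f"{name}.tsv", sep="\t", index=False)
    return {"max_diff": float(np.nanmax(diff.mean))}


def _step_domain(step, name, registry, base, outdir, seed):
    from .profiles import CompositeProfile
    diff = _get(registry, step["input"], CompositeProfile)
    call = call_domain(diff, step.get("threshold_fraction", 0.5))
    registry[name] = call
    out = {"found": call.found, "start_bin": call.start_bin, "end_bin": call.end_bin,
           "peak_bin": call.peak_bin, "peak_value": call.peak_value, "area": call.area}
    with open(outdir / f"{name}.json", "w") as fh:
        json.dump(out, fh, indent=2)
    return out


def _step_correlation(step, name, registry, base, outdir, seed):
    from .profiles import CompositeProfile
    p1 = _get(registry, step["p1"], CompositeProfile)
    p2 = _get(registry, step["p2"], CompositeProfile)
    r, n = profile_correlation(p1, p2)
    out = {"r": r, "n_bins": n}
    registry[name] = out
    with open(outdir / f"{name}.json", "w") as fh:
        json.dump(out, fh, indent=2)
    return out


_STEP_HANDLERS = {
    "simulate": _step_simulate,
    "load_group": _step_load_group,
    "load_annotation": _step_load_annotation,
    "normalize": _step_normalize,
    "repair_rate": _step_repair_rate,
    "detect": _step_detect,
    "profile": _step_profile,
    "localize": _step_localize,
    "difference": _step_difference,
    "domain": _step_domain,
    "correlation": _step_correlation,
}
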