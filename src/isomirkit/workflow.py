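"""End-to-end workflows: configuration validation, the annotation-analysis
run (SAM -> ncRNA filter -> isomiR calling -> count tables and summaries),
and the simulation benchmark, with a run manifest and a stage-level log."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
from dataclasses import dataclass, field

from . import classifier as clf
from . import simulate as sim
from .reference import ReferenceBundle, load_reference
from .samio import read_sam
from .variants import VariantThresholds


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    """Parameters of a classify run (two experimental conditions)."""

    condition1: list[str] = field(default_factory=list)  # SAM paths
    condition2: list[str] = field(default_factory=list)
    genome_path: str = ""
    mirna_gff_path: str = ""
    ncrna_path: str | None = None
    vcf_path: str | None = None
    taxon_mode: str = "animal"
    max_mismatches: int = 3
    max_hits: int = 5
    max_shift: int = 5
    thresholds: VariantThresholds = field(default_factory=VariantThresholds)
    output_dir: str = "isomir_out"
    seed: int = 0


def validate_config(config: RunConfig) -> list[str]:
    """Return a list of violations (empty means valid)."""
    errors = []
    if not 0 <= config.max_mismatches <= 3:
        errors.append(
            f"max_mismatches={config.max_mismatches}: at most 3 mismatches are "
            "supported (the cap that still allows 3'-tail detection)"
        )
    if not 1 <= config.max_hits <= 5:
        errors.append(f"max_hits={config.max_hits}: genomic hits must range from one to five")
    if config.max_shift < 0:
        errors.append("max_shift must be >= 0")
    if config.taxon_mode not in ("animal", "plant"):
        errors.append(f"taxon_mode={config.taxon_mode!r}: must be animal or plant")
    for path in config.condition1 + config.condition2:
        if not os.path.exists(path):
            errors.append(f"input file not found: {path}")
        elif not path.endswith((".sam", ".SAM")):
            errors.append(f"input format not recognized (expected SAM): {path}")
    return errors


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_classify(config: RunConfig, bundle: ReferenceBundle | None = None) -> dict:
    """Run the annotation analysis and write the output tree.

    Outputs under ``config.output_dir``: ``ncRNA/class_counts.tsv``,
    ``not_ambiguous/isomir_counts.tsv``, ``ambiguous/isomir_counts.tsv``,
    ``summaries/{type,arm}_proportions.json``, ``manifest.json`` and
    ``run.log``.  Returns a result dict with the in-memory tables.
    """
    errors = validate_config(config)
    if errors:
        raise ConfigError("; ".join(errors))
    os.makedirs(config.output_dir, exist_ok=True)
    log_lines: list[str] = []

    def log(stage: str, msg: str) -> None:
        log_lines.append(f"[{stage}] {msg}")

    if bundle is None:
        log("reference", f"loading {config.genome_path} + {config.mirna_gff_path}")
        bundle = load_reference(
            config.genome_path, config.mirna_gff_path,
            config.ncrna_path, config.vcf_path, config.taxon_mode,
        )
    log("reference", f"{len(bundle.precursors)} precursors, {len(bundle.matures)} matures")

    sample_paths: dict[str, str] = {}
    condition_map: dict[str, str] = {}
    for cond, paths in (("condition1", config.condition1), ("condition2", config.condition2)):
        for path in paths:
            name = os.path.splitext(os.path.basename(path))[0]
            if name in sample_paths:
                name = f"{name}.{len(sample_paths)}"
            sample_paths[name] = path
            condition_map[name] = cond

    calls_by_sample: dict[str, list[clf.IsomiRCall]] = {}
    ncrna_counts: dict[str, dict[str, int]] = {}
    conservation: dict[str, dict[str, int]] = {}
    for sample, path in sample_paths.items():
        reads, n_bad = read_sam(path, bundle)
        log("input", f"{sample}: {len(reads)} alignments ({n_bad} malformed records dropped)")
        retained, class_counts = clf.filter_ncrna(reads, bundle)
        ncrna_counts[sample] = class_counts
        log("ncrna_filter", f"{sample}: {len(reads) - len(retained)} rRNA reads removed")
        calls = clf.classify_reads(
            retained, bundle,
            max_shift=config.max_shift,
            max_mismatches=config.max_mismatches,
            thresholds=config.thresholds,
        )
        calls_by_sample[sample] = calls
        tally = {"assigned": 0, "ambiguous": 0, "unassigned": 0, "discarded": 0}
        for c in calls:
            tally[c.status] += 1
        conservation[sample] = tally
        log("classify", f"{sample}: {tally}")

    unamb, amb = clf.accumulate_counts(calls_by_sample, condition_map)
    os.makedirs(os.path.join(config.output_dir, "not_ambiguous"), exist_ok=True)
    os.makedirs(os.path.join(config.output_dir, "ambiguous"), exist_ok=True)
    os.makedirs(os.path.join(config.output_dir, "ncRNA"), exist_ok=True)
    os.makedirs(os.path.join(config.output_dir, "summaries"), exist_ok=True)
    _write_counts(
        os.path.join(config.output_dir, "not_ambiguous", "isomir_counts.tsv"),
        unamb, condition_map,
    )
    _write_counts(
        os.path.join(config.output_dir, "ambiguous", "isomir_counts.tsv"),
        amb, condition_map,
    )
    with open(os.path.join(config.output_dir, "ncRNA", "class_counts.tsv"), "w") as fh:
        classes = sorted({c for d in ncrna_counts.values() for c in d})
        fh.write("class\t" + "\t".join(sorted(ncrna_counts)) + "\n")
        for cls in classes:
            fh.write(cls + "\t" + "\t".join(str(ncrna_counts[s].get(cls, 0)) for s in sorted(ncrna_counts)) + "\n")

    summaries: dict[str, dict] = {}
    if not unamb.empty and int(unamb.to_numpy().sum()) > 0:
        types = clf.summarize_types(unamb, condition_map)
        arms = clf.arm_proportions(unamb, bundle, condition_map)
        summaries["type_proportions"] = {c: types[c].round(6).to_dict() for c in types.columns}
        summaries["arm_proportions"] = {c: arms[c].round(6).to_dict() for c in arms.columns}
    else:
        summaries["type_proportions"] = {}
        summaries["arm_proportions"] = {}
        log("summaries", "no assigned reads; summaries are empty")
    for name in ("type_proportions", "arm_proportions"):
        with open(os.path.join(config.output_dir, "summaries", f"{name}.json"), "w") as fh:
            json.dump(summaries[name], fh, indent=2, sort_keys=True)

    manifest = {
        "parameters": {
            "max_mismatches": config.max_mismatches,
            "max_hits": config.max_hits,
            "max_shift": config.max_shift,
            "taxon_mode": config.taxon_mode,
            "thresholds": dataclasses.asdict(config.thresholds),
            "seed": config.seed,
        },
        "inputs": {s: {"path": p, "sha256": _sha256(p)} for s, p in sample_paths.items()},
        "conditions": condition_map,
        "read_conservation": conservation,
    }
    with open(os.path.join(config.output_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    log("done", "outputs written")
    with open(os.path.join(config.output_dir, "run.log"), "w") as fh:
        fh.write("\n".join(log_lines) + "\n")
    return {
        "unambiguous": unamb,
        "ambiguous": amb,
        "ncrna_counts": ncrna_counts,
        "summaries": summaries,
        "conservation": conservation,
        "manifest": manifest,
    }


def _write_counts(path: str, counts, condition_map: dict[str, str]) -> None:
    with open(path, "w") as fh:
        header = ["isomiR_ID"] + [f"{condition_map[s]}:{s}" for s in counts.columns]
        fh.write("\t".join(header) + "\n")
        for ident, row in counts.iterrows():
            fh.write(ident + "\t" + "\t".join(str(int(v)) for v in row) + "\n")


def run_benchmark(config: sim.SimConfig, thresholds: VariantThresholds | None = None) -> dict:
    """Simulate, classify and score end to end; returns the metrics dict."""
    thresholds = thresholds or VariantThresholds()
    bundle = sim.simulate_reference(config)
    reads, truth = sim.simulate_reads(bundle, config)
    reads, truth = sim.inject_variants_and_tails(reads, truth, config, bundle)
    if not reads:
        return {
            "n_reads": 0, "tp": 0, "fp": 0, "fn": 0,
            "sensitivity": None, "specificity": None, "type_accuracy": None,
            "per_type": {}, "warning": "zero reads simulated",
        }
    calls = clf.classify_reads(reads, bundle, max_shift=config.max_shift, thresholds=thresholds)
    metrics = sim.score_performance(truth, calls)
    return {
        "n_reads": len(reads),
        "tp": metrics.tp,
        "fp": metrics.fp,
        "fn": metrics.fn,
        "sensitivity": metrics.sensitivity,
        "specificity": metrics.specificity,
        "type_accuracy": metrics.type_accuracy,
        "per_type": metrics.per_type,
        "mean_mature_coverage": sim.mean_mature_coverage(reads, truth, bundle),
        "mean_hairpin_coverage": sim.mean_hairpin_coverage(reads, truth, bundle),
    }
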