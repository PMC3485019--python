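"""End-to-end orchestration: design → genomic filter → expression rank →
match → select → report, as one reproducible run.

Each stage writes its tables to the output directory and the run finishes
with a JSON manifest recording the effective configuration (hashed), input
checksums, per-stage row counts and the coverage report.  Outputs are
byte-identical across re-runs with the same inputs and configuration;
timestamps appear only in the log file.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import dataclass, field, asdict

import pandas as pd

from . import acgh as acgh_mod
from . import age as age_mod
from . import align, design, select
from .core import (
    TranscriptomeAssembly,
    read_fasta,
    read_isogroup_mapping,
    read_table,
    write_fasta,
    write_isogroup_mapping,
    write_table,
)
from .simulate import SimBundle, SimConfig, simulate_all

logger = logging.getLogger(__name__)

PROBE_SCHEMA = {
    "probe_id": str,
    "source_id": str,
    "start": int,
    "strand": str,
    "sequence": str,
    "gc": float,
    "origin": str,
}
ACGH_SCHEMA = {"probe_id": str, "t_log2": float, "r_log2": float}
AGE_SCHEMA = {"probe_id": str, "reg_log2": float, "res_log2": float}


@dataclass
class RunConfig:
    """Paths and parameters for one pipeline run."""

    assembly_fasta: str | None = None  # isotigs
    singleton_fasta: str | None = None
    mapping_tsv: str | None = None  # isotig_id -> isogroup_id
    probes_tsv: str | None = None
    acgh_tsv: str | None = None
    age_tsv: str | None = None
    matches_tsv: str | None = None  # externally produced hits (optional)
    outdir: str = "probeatlas_run"
    force: bool = False
    seed: int = 0
    thresholds: acgh_mod.AcghThresholds = field(default_factory=acgh_mod.AcghThresholds)
    scoring: align.ScoringScheme = field(default_factory=align.ScoringScheme)
    selection: select.SelectionConfig = field(default_factory=select.SelectionConfig)
    sim: SimConfig | None = None  # set for self-contained demo runs

    def to_jsonable(self) -> dict:
        d = asdict(self)
        return d


def _sha256_file(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _config_hash(cfg: RunConfig) -> str:
    d = cfg.to_jsonable()
    d.pop("outdir", None)  # where a run lands does not change what it computes
    d.pop("force", None)
    blob = json.dumps(d, sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()


def load_assembly(cfg: RunConfig) -> TranscriptomeAssembly:
    isotigs = {r.id: r for r in read_fasta(cfg.assembly_fasta, kind="isotig")}
    mapping = read_isogroup_mapping(cfg.mapping_tsv)
    isogroups: dict[str, list[str]] = {}
    for it, ig in mapping.items():
        isogroups.setdefault(ig, []).append(it)
    singletons = {}
    if cfg.singleton_fasta:
        singletons = {
            r.id: r for r in read_fasta(cfg.singleton_fasta, kind="singleton")
        }
    return TranscriptomeAssembly(
        isogroups=isogroups, isotigs=isotigs, singletons=singletons
    )


def validate_inputs(
    assembly: TranscriptomeAssembly,
    probes: pd.DataFrame,
    acgh_tbl: pd.DataFrame | None = None,
    age_tbl: pd.DataFrame | None = None,
    matches: pd.DataFrame | None = None,
) -> dict:
    """Cross-check id consistency across input tables (report-only).

    Hard inconsistencies (the pipeline refuses to run on them): matches
    referencing unknown probes or targets.  Warnings: probes with intensity
    rows but no sequence entry (intensity-only mode), intensity rows for
    unknown probes.
    """
    report: dict[str, list[str]] = {"hard": [], "warnings": []}
    known_probes = set(probes["probe_id"])
    targets = set(assembly.isotigs) | set(assembly.singletons)
    for name, tbl in (("acgh", acgh_tbl), ("age", age_tbl)):
        if tbl is None:
            continue
        orphans = sorted(set(tbl["probe_id"]) - known_probes)
        if orphans:
            report["warnings"].append(
                f"{name}: {len(orphans)} intensity rows without a probe "
                f"entry (e.g. {orphans[:3]}); intensity-only mode"
            )
        missing = sorted(known_probes - set(tbl["probe_id"]))
        if missing:
            report["hard"].append(
                f"{name}: {len(missing)} probes lack intensity rows "
                f"(e.g. {missing[:3]})"
            )
    if matches is not None:
        bad_p = sorted(set(matches["probe_id"]) - known_probes)
        if bad_p:
            report["hard"].append(
                f"matches reference unknown probes (e.g. {bad_p[:3]})"
            )
        bad_t = sorted(set(matches["target_id"]) - targets)
        if bad_t:
            report["hard"].append(
                f"matches reference unknown targets (e.g. {bad_t[:3]})"
            )
    return report


@dataclass
class PipelineResult:
    assembly: TranscriptomeAssembly
    probes: list
    hyb: pd.DataFrame
    rates: pd.DataFrame
    age: pd.DataFrame
    matches: dict[str, list[align.ProbeMatch]]
    selection: select.SelectionResult
    report: dict
    manifest: dict
    bundle: SimBundle | None = None  # set for simulated (demo) runs


def run_pipeline(cfg: RunConfig) -> PipelineResult:
    """Execute all stages and write outputs + manifest under cfg.outdir."""
    outdir = cfg.outdir
    if os.path.isdir(outdir) and os.listdir(outdir) and not cfg.force:
        raise FileExistsError(f"output directory {outdir!r} not empty (use force)")
    os.makedirs(outdir, exist_ok=True)
    log_path = os.path.join(outdir, "run.log")
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    root = logging.getLogger("probeatlas")
    root.addHandler(handler)
    root.setLevel(logging.INFO)

    manifest: dict = {
        "config_hash": _config_hash(cfg),
        "config": cfg.to_jsonable(),
        "inputs": {},
        "stages": {},
    }

    try:
        bundle = None
        if cfg.sim is not None:
            bundle = simulate_all(cfg.sim)
            write_bundle(bundle, outdir)
            assembly = bundle.sim.assembly
            probes = bundle.probes
            probe_df = design.probes_to_frame(probes)
            acgh_tbl = bundle.acgh
            age_tbl = bundle.age
            matches_df = None
        else:
            for name in ("assembly_fasta", "mapping_tsv", "probes_tsv",
                         "acgh_tsv", "age_tsv"):
                path = getattr(cfg, name)
                if path is None:
                    raise FileNotFoundError(f"required input {name} not set")
                if not os.path.exists(path):
                    raise FileNotFoundError(f"{name}: no such file {path!r}")
                manifest["inputs"][name] = _sha256_file(path)
            assembly = load_assembly(cfg)
            probe_df = read_table(cfg.probes_tsv, PROBE_SCHEMA)
            probes = design.probes_from_frame(probe_df)
            acgh_tbl = read_table(cfg.acgh_tsv, ACGH_SCHEMA)
            age_tbl = read_table(cfg.age_tsv, AGE_SCHEMA)
            matches_df = (
                read_table(cfg.matches_tsv) if cfg.matches_tsv else None
            )

        report = validate_inputs(assembly, probe_df, acgh_tbl, age_tbl, matches_df)
        if report["hard"]:
            raise ValueError("input validation failed: " + "; ".join(report["hard"]))
        for w in report["warnings"]:
            logger.warning("validate: %s", w)

        # stage: aCGH categorization
        hyb = acgh_mod.categorize_table(acgh_tbl, cfg.thresholds)
        origin = dict(zip(probe_df["probe_id"], probe_df["origin"]))
        hyb_known = hyb[hyb["probe_id"].isin(origin)]
        rates = acgh_mod.selection_rates(hyb_known, origin)
        write_table(hyb, os.path.join(outdir, "acgh_stats.tsv"))
        write_table(rates, os.path.join(outdir, "acgh_rates.tsv"))
        manifest["stages"]["acgh"] = {"n_probes": len(hyb)}

        # stage: aGE classification + ranking
        age_df = age_mod.add_ma(age_tbl)
        age_df["origin"] = age_df["probe_id"].map(origin)
        age_df = age_mod.classify_population(age_df)
        age_df = age_mod.rank_probes(age_df, key=cfg.selection.rank_key)
        write_table(age_df.drop(columns=["origin"]),
                    os.path.join(outdir, "age_records.tsv"))
        manifest["stages"]["age"] = {"n_probes": len(age_df)}

        # stage: matching
        if matches_df is not None:
            match_list = align.matches_from_frame(matches_df)
            matches = {p.probe_id: [] for p in probes}
            for m in match_list:
                matches.setdefault(m.probe_id, []).append(m)
        else:
            matches = align.match_all(
                probes, assembly, cfg.scoring,
                threshold=cfg.selection.good_match_threshold,
            )
        flat = [m for ms in matches.values() for m in ms]
        write_table(align.matches_to_frame(flat),
                    os.path.join(outdir, "matches.tsv"))
        manifest["stages"]["match"] = {
            "n_probes": len(matches),
            "n_good_matches": len(flat),
        }

        # stage: selection
        categories = dict(zip(hyb["probe_id"], hyb["category"]))
        ranks = dict(zip(age_df["probe_id"], age_df["rank"]))
        selection = select.select_probes(
            assembly, probes, categories, ranks, matches, cfg.selection
        )
        select.write_result(selection, outdir)
        cov = select.coverage_report(selection, assembly)
        manifest["stages"]["select"] = {
            "n_selected": len(selection.selected),
            "n_filtered": len(selection.filter_log),
        }
        manifest["coverage_report"] = cov
        with open(os.path.join(outdir, "manifest.json"), "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True, default=str)

        return PipelineResult(
            assembly=assembly,
            probes=probes,
            hyb=hyb,
            rates=rates,
            age=age_df,
            matches=matches,
            selection=selection,
            report=cov,
            manifest=manifest,
            bundle=bundle,
        )
    except Exception:
        logger.exception("pipeline aborted")
        raise
    finally:
        root.removeHandler(handler)
        handler.close()


def write_bundle(bundle: SimBundle, outdir: str) -> None:
    """Write a synthetic bundle as the standard input file set."""
    os.makedirs(outdir, exist_ok=True)
    sim = bundle.sim
    write_fasta([sim.target_genome], os.path.join(outdir, "target_genome.fasta"))
    write_fasta(
        [sim.reference_genome], os.path.join(outdir, "reference_genome.fasta")
    )
    write_fasta(sim.assembly.isotigs.values(), os.path.join(outdir, "isotigs.fasta"))
    write_fasta(
        sim.assembly.singletons.values(), os.path.join(outdir, "singletons.fasta")
    )
    write_isogroup_mapping(sim.assembly, os.path.join(outdir, "isogroups.tsv"))
    write_fasta(bundle.reads, os.path.join(outdir, "reads.fasta"))
    write_table(bundle.read_truth, os.path.join(outdir, "read_truth.tsv"))
    write_table(
        design.probes_to_frame(bundle.probes), os.path.join(outdir, "probes.tsv")
    )
    write_table(bundle.truth, os.path.join(outdir, "probe_truth.tsv"))
    write_table(bundle.acgh, os.path.join(outdir, "acgh_intensities.tsv"))
    write_table(bundle.age, os.path.join(outdir, "age_intensities.tsv"))
    bundle.discard_log.write(os.path.join(outdir, "design_discards.tsv"))
    with open(os.path.join(outdir, "sim_config.json"), "w") as fh:
        json.dump(bundle.cfg.to_dict(), fh, indent=2, sort_keys=True)


def run_demo(seed: int = 42, outdir: str = "probeatlas_demo", **sim_kwargs):
    """Self-contained run: simulate inputs, then execute the full pipeline."""
    cfg = RunConfig(sim=SimConfig(seed=seed, **sim_kwargs), outdir=outdir, force=True)
    return run_pipeline(cfg)


def config_from_file(path: str, **overrides) -> RunConfig:
    """Build a RunConfig from a YAML/JSON file; keyword overrides win.

    Recognized sections: top-level RunConfig fields plus nested ``sim``,
    ``thresholds``, ``scoring`` and ``selection`` parameter mappings.
    """
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    nested = {
        "sim": SimConfig,
        "thresholds": acgh_mod.AcghThresholds,
        "scoring": align.ScoringScheme,
        "selection": select.SelectionConfig,
    }
    kwargs: dict = {}
    for key, value in raw.items():
        if key in nested:
            kwargs[key] = nested[key](**value)
        else:
            kwargs[key] = value
    kwargs.update(overrides)
    return RunConfig(**kwargs)
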