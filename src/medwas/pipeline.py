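"""End-to-end pipeline: simulate → scan → prioritize → report.

Each stage consumes and produces only files, so a run can be resumed from
any stage; a run manifest records the config hash, seed, panel sizes and
sha256 checksums of every artifact, making determinism checkable (two runs
with the same config and seed produce identical checksums for every data
artifact — the manifest's own timestamp is the only wall-clock field).
"""

from __future__ import annotations

import datetime
import hashlib
import json
import logging
from pathlib import Path

import yaml

from . import __version__
from .cohort import write_consort
from .prioritize import (
    PrioritizationConfig,
    apply_hard_filters,
    apply_soft_constraints,
    classify_yield,
    load_annotations,
    triage_report,
    write_triage,
)
from .pregnancy import default_dictionary, load_dictionary
from .scan import MedWAS, ScanConfig
from .simulate import (
    ConfoundingEffect,
    SimulationConfig,
    generate_population,
    load_population,
    write_population,
)
from .vocab import load_drug_map, load_phecode_map

logger = logging.getLogger(__name__)


class PipelineConfigError(ValueError):
    """Config invalid; raised before any stage runs."""


_TOP_KEYS = {
    "seed",
    "simulation",
    "scan",
    "prioritization",
    "annotations",
    "data_dir",
    "phecode_map",
    "drug_map",
    "gestation_dictionary",
    "min_code_count",
}


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    validate_config(cfg)
    return cfg


def validate_config(cfg: dict) -> None:
    """Schema-check the pipeline config; raise before any stage runs."""
    if not isinstance(cfg, dict):
        raise PipelineConfigError("config must be a mapping")
    unknown = set(cfg) - _TOP_KEYS
    if unknown:
        raise PipelineConfigError(f"unknown config keys: {sorted(unknown)}")
    if "simulation" not in cfg:
        # external-data mode: inputs must be named explicitly
        for key in ("data_dir", "phecode_map", "drug_map"):
            if key not in cfg:
                raise PipelineConfigError(
                    f"config without a 'simulation' section must provide {key!r}"
                )
    sim = cfg.get("simulation", {})
    if not isinstance(sim, dict):
        raise PipelineConfigError("'simulation' must be a mapping")
    try:
        simulation_config(cfg)
    except (TypeError, ValueError) as exc:
        raise PipelineConfigError(f"invalid simulation config: {exc}") from exc
    try:
        scan_config(cfg)
    except (TypeError, ValueError) as exc:
        raise PipelineConfigError(f"invalid scan config: {exc}") from exc


def simulation_config(cfg: dict, seed: int | None = None) -> SimulationConfig | None:
    if "simulation" not in cfg:
        return None
    kwargs = dict(cfg["simulation"])
    if "confounding_effects" in kwargs:
        kwargs["confounding_effects"] = [
            ConfoundingEffect(**c) if isinstance(c, dict) else ConfoundingEffect(*c)
            for c in kwargs["confounding_effects"]
        ]
    if "true_effects" in kwargs:
        kwargs["true_effects"] = [tuple(e) for e in kwargs["true_effects"]]
    if "nutraceutical_drug_ids" in kwargs:
        kwargs["nutraceutical_drug_ids"] = set(kwargs["nutraceutical_drug_ids"])
    if "trimester_exposure_weights" in kwargs:
        kwargs["trimester_exposure_weights"] = tuple(kwargs["trimester_exposure_weights"])
    sc = SimulationConfig(**kwargs)
    if seed is not None:
        sc.seed = seed
    elif "seed" not in cfg.get("simulation", {}) and "seed" in cfg:
        sc.seed = int(cfg["seed"])
    sc.validate()
    return sc


def scan_config(cfg: dict) -> ScanConfig:
    return ScanConfig(**cfg.get("scan", {}))


def prioritization_config(cfg: dict) -> PrioritizationConfig:
    return PrioritizationConfig(**cfg.get("prioritization", {}))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(
    config: str | Path | dict, outdir: str | Path, seed: int | None = None
) -> Path:
    """Execute all stages; returns the artifact directory.

    Artifacts: ``data/`` (simulated tables + synthetic vocabulary, when the
    config has a simulation section), ``results.tsv``, ``consort.tsv``,
    ``triage.tsv``, ``summary.txt`` and ``manifest.json``.
    """
    if isinstance(config, (str, Path)):
        cfg = load_config(config)
    else:
        cfg = dict(config)
        validate_config(cfg)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    eff_seed = int(seed if seed is not None else cfg.get("seed", 0))

    # --- stage 1: simulate (or point at external data) ---------------------
    sim_cfg = simulation_config(cfg, seed=eff_seed)
    if sim_cfg is not None:
        tables, truth = generate_population(sim_cfg)
        data_dir = write_population(tables, truth, outdir / "data", config=sim_cfg)
        phecode_map_path = data_dir / "phecode_map.csv"
        drug_map_path = data_dir / "drug_map.tsv"
    else:
        data_dir = Path(cfg["data_dir"])
        tables = load_population(data_dir)
        phecode_map_path = Path(cfg["phecode_map"])
        drug_map_path = Path(cfg["drug_map"])

    phecode_map = load_phecode_map(phecode_map_path)
    drug_map = load_drug_map(drug_map_path)
    dictionary = (
        load_dictionary(cfg["gestation_dictionary"])
        if "gestation_dictionary" in cfg
        else default_dictionary()
    )

    # --- stage 2: scan ------------------------------------------------------
    model = MedWAS.from_tables(
        tables,
        phecode_map,
        drug_map,
        dictionary=dictionary,
        config=scan_config(cfg),
        min_code_count=int(cfg.get("min_code_count", 1)),
    )
    results = model.fit()
    results.to_tsv(outdir / "results.tsv")
    write_consort(model.consort, outdir / "consort.tsv")

    # --- stage 3: prioritize ------------------------------------------------
    pcfg = prioritization_config(cfg)
    annotations = (
        load_annotations(cfg["annotations"]) if cfg.get("annotations") else {}
    )
    prioritized = classify_yield(
        apply_hard_filters(apply_soft_constraints(results.table, pcfg), annotations),
        annotations,
        pcfg,
    )
    write_triage(prioritized, outdir / "triage.tsv")

    # --- stage 4: report ----------------------------------------------------
    rep = triage_report(prioritized)
    with open(outdir / "summary.txt", "w") as fh:
        fh.write(results.summary())
        fh.write("\n\nTriage\n------\n")
        for y in ("high", "low", "parsed"):
            fh.write(f"{y:>7}: {rep['yield_counts'][y]}\n")

    artifacts = sorted(
        p for p in outdir.rglob("*") if p.is_file() and p.name != "manifest.json"
    )
    manifest = {
        "medwas_version": __version__,
        "seed": eff_seed,
        "config_hash": hashlib.sha256(
            json.dumps(cfg, sort_keys=True, default=str).encode()
        ).hexdigest(),
        "panel_sizes": {
            "drugs": len(model.drug_panel),
            "phecodes": len(model.phecode_panel),
            "dyads": results.metadata["n_dyads"],
        },
        "checksums": {str(p.relative_to(outdir)): _sha256(p) for p in artifacts},
        "timestamp": datetime.datetime.now().isoformat(timespec="seconds"),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return outdir
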