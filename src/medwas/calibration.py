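"""Replicate-level calibration studies: FWER under the null, power and
effect recovery for planted signals.

These run the *full* pipeline per replicate — simulate a population, apply
the inclusion rule, infer episodes, assign phenotype statuses, scan — so
the quantities they report reflect the behaviour of the whole tool, not of
the fitting routine in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .cohort import apply_inclusion_rule, exposure_matrix
from .pregnancy import default_dictionary
from .scan import MedWAS, ScanConfig
from .simulate import SimulationConfig, generate_population
from .vocab import PhecodeMap, phenotype_status_matrix


def _synthetic_phecode_map(config: SimulationConfig) -> PhecodeMap:
    from .vocab import PhecodeMap

    pmap = PhecodeMap()
    for i in range(config.n_phecodes):
        p = f"{i + 1:03d}.0"
        for which in (0, 1):
            pmap.entries.setdefault((f"SYN{i:03d}.{which}", "ICD10"), set()).add(p)
        pmap.exclusion_ranges[p] = [(float(p), float(p))]
    return pmap


def scan_population(
    sim_config: SimulationConfig,
    scan_config: ScanConfig | None = None,
    min_code_count: int = 1,
):
    """Simulate one population and run the end-to-end scan on it.

    Returns the fitted :class:`~medwas.scan.MedWASResults`; drugs are scanned
    at ingredient-token level (each synthetic drug has its own ATC-4 class,
    so token- and class-level scans coincide).
    """
    tables, _ = generate_population(sim_config)
    dictionary = default_dictionary()
    dyads, _ = apply_inclusion_rule(tables, dictionary)
    pmap = _synthetic_phecode_map(sim_config)
    panel = sim_config.phecode_ids()
    expo = exposure_matrix(dyads, sim_config.drug_tokens(), level="token")
    case, excl = phenotype_status_matrix(
        tables["condition_occurrence"], expo.index, panel, pmap, min_code_count=min_code_count
    )
    model = MedWAS(expo, case, excl, config=scan_config)
    return model.fit()


@dataclass
class FwerStudy:
    """Null-scan calibration summary over replicates."""

    n_replicates: int
    n_drug_families: int
    family_fwer: float  # fraction of (replicate × drug) families with >=1 hit
    replicate_any_rate_per_drug: float  # fraction of replicates with >=1 hit (per-drug family)
    replicate_any_rate_global: float  # same under a global Bonferroni family


def fwer_study(
    base_config: SimulationConfig,
    n_replicates: int = 200,
    seed: int = 0,
    scan_config: ScanConfig | None = None,
) -> FwerStudy:
    """All-null replicates: how often does Bonferroni flag anything?

    Per-drug Bonferroni controls the family-wise error *per drug family*;
    ``family_fwer`` is the corresponding empirical rate.  The replicate-level
    any-signal rates are reported for both family definitions.
    """
    scan_config = scan_config or ScanConfig()
    global_config = replace(scan_config, family="global")
    seeds = np.random.SeedSequence(seed).generate_state(n_replicates) % (2**31)
    fam_hits = 0
    fam_total = 0
    rep_any_per_drug = 0
    rep_any_global = 0
    for s in seeds:
        cfg = replace(base_config, true_effects=[], confounding_effects=[], seed=int(s))
        res = scan_population(cfg, scan_config)
        hits = res.significant
        per_drug_hit_drugs = hits["drug"].nunique()
        fam_hits += per_drug_hit_drugs
        fam_total += base_config.n_drugs
        rep_any_per_drug += int(len(hits) > 0)
        thr_global = scan_config.alpha / (base_config.n_drugs * base_config.n_phecodes)
        rep_any_global += int((res.table["p_value"] <= thr_global).fillna(False).any())
    return FwerStudy(
        n_replicates=n_replicates,
        n_drug_families=fam_total,
        family_fwer=fam_hits / fam_total,
        replicate_any_rate_per_drug=rep_any_per_drug / n_replicates,
        replicate_any_rate_global=rep_any_global / n_replicates,
    )


@dataclass
class PowerStudy:
    """Planted-effect detection and recovery summary."""

    n_replicates: int
    detection_rate: float  # planted pair Bonferroni-significant
    mean_log_or: float
    planted_log_or: float


def power_study(
    base_config: SimulationConfig,
    drug: int | str,
    phecode: int | str,
    odds_ratio: float,
    n_replicates: int = 200,
    seed: int = 0,
    scan_config: ScanConfig | None = None,
) -> PowerStudy:
    """Replicates with one planted (drug, phecode, OR) effect: detection rate
    at the planted pair and the mean estimated log-OR."""
    scan_config = scan_config or ScanConfig()
    seeds = np.random.SeedSequence(seed).generate_state(n_replicates) % (2**31)
    detected = 0
    log_ors: list[float] = []
    for s in seeds:
        cfg = replace(
            base_config, true_effects=[(drug, phecode, odds_ratio)], seed=int(s)
        )
        drug_tok = cfg.drug_tokens()[cfg._drug_index(drug)]
        phe_id = cfg.phecode_ids()[cfg._phecode_index(phecode)]
        res = scan_population(cfg, scan_config)
        row = res.result_for(drug_tok, phe_id)
        detected += int(bool(row["bonferroni_significant"]))
        if np.isfinite(row["beta"]):
            log_ors.append(float(row["beta"]))
    return PowerStudy(
        n_replicates=n_replicates,
        detection_rate=detected / n_replicates,
        mean_log_or=float(np.mean(log_ors)) if log_ors else float("nan"),
        planted_log_or=float(np.log(odds_ratio)),
    )


def null_effect_calibration(
    base_config: SimulationConfig,
    drug: int | str = 0,
    phecode: int | str = 0,
    n_replicates: int = 200,
    seed: int = 0,
) -> float:
    """Mean generated cross-product log-OR at a planted OR=1 pair (should
    centre on 0): checks the generator plants no spurious enrichment."""
    seeds = np.random.SeedSequence(seed).generate_state(n_replicates) % (2**31)
    log_ors = []
    for s in seeds:
        cfg = replace(base_config, true_effects=[(drug, phecode, 1.0)], seed=int(s))
        tables, truth = generate_population(cfg)
        d_tok = cfg.drug_tokens()[cfg._drug_index(drug)]
        p_id = cfg.phecode_ids()[cfg._phecode_index(phecode)]
        exposed_babies = set(truth.exposures.loc[truth.exposures["drug"] == d_tok, "baby_id"])
        cond = tables["condition_occurrence"]
        case_babies = set(
            cond.loc[cond["condition_code"] == f"SYN{cfg._phecode_index(phecode):03d}.0", "person_id"]
        )
        all_babies = truth.episodes["baby_id"]
        e = all_babies.isin(exposed_babies).to_numpy()
        c = all_babies.isin(case_babies).to_numpy()
        a = np.sum(e & c) + 0.5
        b = np.sum(e & ~c) + 0.5
        cc = np.sum(~e & c) + 0.5
        d = np.sum(~e & ~c) + 0.5
        log_ors.append(np.log((a * d) / (b * cc)))
    return float(np.mean(log_ors))
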