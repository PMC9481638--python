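"""Synthetic population generator: validity, determinism, planted effects."""

import numpy as np
import pandas as pd
import pytest

from medwas.calibration import null_effect_calibration
from medwas.simulate import (
    ConfigurationError,
    ConfoundingEffect,
    SimulationConfig,
    SyntheticTruth,
    generate_population,
    write_population,
)


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs,field",
        [
            (dict(n_dyads=-1), "n_dyads"),
            (dict(baseline_prevalence=1.5), "baseline_prevalence"),
            (dict(exposure_prevalence=-0.1), "exposure_prevalence"),
            (dict(trimester_exposure_weights=(0.5, 0.5, 0.5)), "trimester_exposure_weights"),
            (dict(missing_delivery_code_rate=2.0), "missing_delivery_code_rate"),
            (dict(true_effects=[(0, 0, -2.0)]), "odds_ratio"),
            (dict(true_effects=[(99, 0, 2.0)]), "drug index"),
        ],
    )
    def test_invalid_config_names_offending_field(self, kwargs, field):
        with pytest.raises(ConfigurationError, match=field):
            SimulationConfig(**kwargs).validate()

    def test_confounding_effect_validation(self):
        with pytest.raises(ConfigurationError):
            SimulationConfig(
                confounding_effects=[
                    ConfoundingEffect("900.0", 0, "001.0", or_exposure=-1)
                ]
            ).validate()


def test_zero_dyads_yields_empty_tables_and_truth():
    tables, truth = generate_population(SimulationConfig(n_dyads=0, seed=1))
    assert all(len(t) == 0 for t in tables.values())
    assert len(truth.episodes) == 0 and len(truth.exposures) == 0


def test_same_seed_byte_identical_output(tmp_path):
    cfg = SimulationConfig(n_dyads=150, n_drugs=4, n_phecodes=6, seed=99)
    for d in ("a", "b"):
        tables, truth = generate_population(cfg)
        write_population(tables, truth, tmp_path / d, config=cfg)
    for f in sorted((tmp_path / "a").iterdir()):
        assert f.read_bytes() == (tmp_path / "b" / f.name).read_bytes(), f.name


def test_different_seed_different_output():
    t1, _ = generate_population(SimulationConfig(n_dyads=100, seed=1))
    t2, _ = generate_population(SimulationConfig(n_dyads=100, seed=2))
    assert not t1["drug_exposure"].equals(t2["drug_exposure"])


class TestGeneratedStructure:
    def test_exposure_dates_inside_assigned_trimester(self, small_population):
        tables, truth = small_population
        epi = truth.episodes.set_index("baby_id")
        merged = truth.exposures.merge(epi, left_on="baby_id", right_index=True)
        start = pd.to_datetime(merged["pregnancy_start"])
        day = (pd.to_datetime(merged["drug_exposure_date"]) - start).dt.days
        ga = merged["gestational_age_days"].astype(int)
        assert (day >= 0).all() and (day < ga).all()
        lo = np.select([merged["trimester"] == 1, merged["trimester"] == 2], [0, 98], 196)
        hi = np.select([merged["trimester"] == 1, merged["trimester"] == 2], [98, 196], ga)
        assert (day >= lo).all() and (day < hi).all()

    def test_every_baby_has_postpartum_note(self, small_population):
        tables, truth = small_population
        notes = tables["note_event"].merge(
            truth.episodes[["baby_id", "delivery_date"]],
            left_on="person_id",
            right_on="baby_id",
        )
        first = notes.groupby("person_id")["note_date"].min()
        assert set(first.index) == set(truth.episodes["baby_id"])

    def test_delivery_and_week_codes_emitted_per_mother(self, small_population):
        tables, truth = small_population
        cond = tables["condition_occurrence"]
        deliv_mothers = set(cond.loc[cond["condition_code"] == "O80", "person_id"])
        week_mothers = set(
            cond.loc[cond["condition_code"].str.startswith("Z3A."), "person_id"]
        )
        assert deliv_mothers == week_mothers == set(truth.episodes["mother_id"])

    def test_missing_delivery_rate_ablation(self):
        cfg = SimulationConfig(n_dyads=500, missing_delivery_code_rate=0.2, seed=5)
        tables, truth = generate_population(cfg)
        cond = tables["condition_occurrence"]
        n_missing = 500 - cond.loc[cond["condition_code"] == "O80", "person_id"].nunique()
        assert 60 <= n_missing <= 140  # Binomial(500, 0.2) within ~4.5 sd

    def test_unexposed_prevalence_matches_baseline(self):
        """Marginal phenotype rate among unexposed dyads ~ baseline (±3 binomial SE)."""
        cfg = SimulationConfig(
            n_dyads=4000, n_drugs=3, n_phecodes=4, baseline_prevalence=0.06,
            exposure_prevalence=0.1, true_effects=[(0, 0, 5.0)], seed=31,
        )
        tables, truth = generate_population(cfg)
        exposed0 = set(truth.exposures.loc[truth.exposures["drug"] == "drug_000", "baby_id"])
        unexposed = truth.episodes.loc[~truth.episodes["baby_id"].isin(exposed0), "baby_id"]
        cond = tables["condition_occurrence"]
        cases = set(cond.loc[cond["condition_code"] == "SYN000.0", "person_id"])
        rate = unexposed.isin(cases).mean()
        se = np.sqrt(0.06 * 0.94 / len(unexposed))
        assert abs(rate - 0.06) <= 3 * se

    def test_truth_roundtrips_through_json(self, small_population):
        _, truth = small_population
        back = SyntheticTruth.from_json(truth.to_json())
        assert len(back.episodes) == len(truth.episodes)
        assert back.effects == truth.effects


class TestPlantedEffects:
    def test_null_effect_centres_on_log_or_zero(self):
        """Planted OR=1.0: mean generated cross-product log-OR within ±0.05
        over 200 replicates (no spurious enrichment)."""
        base = SimulationConfig(
            n_dyads=2000, n_drugs=2, n_phecodes=2, baseline_prevalence=0.05,
            exposure_prevalence=0.10,
        )
        mean_log_or = null_effect_calibration(base, n_replicates=200, seed=17)
        assert abs(mean_log_or) <= 0.05

    def test_planted_or4_cross_product_distribution(self):
        """MC oracle at the stated design: the generated 2×2 cross-product OR
        centres on the planted OR=4 (mean log-OR within ±0.08 of log 4) and
        lands in [3.0, 5.3] for most seeds (oracle-derived rate ~0.80)."""
        log_ors, in_band = [], 0
        for seed in range(50):
            cfg = SimulationConfig(
                n_dyads=2000, baseline_prevalence=0.05, exposure_prevalence=0.10,
                n_drugs=2, n_phecodes=2, true_effects=[(0, 0, 4.0)], seed=seed,
            )
            tables, truth = generate_population(cfg)
            ex = set(truth.exposures.loc[truth.exposures["drug"] == "drug_000", "baby_id"])
            cond = tables["condition_occurrence"]
            cases = set(cond.loc[cond["condition_code"] == "SYN000.0", "person_id"])
            babies = truth.episodes["baby_id"]
            e = babies.isin(ex).to_numpy()
            c = babies.isin(cases).to_numpy()
            a, b = (e & c).sum(), (e & ~c).sum()
            cc, d = (~e & c).sum(), (~e & ~c).sum()
            orr = (a * d) / (b * cc)
            log_ors.append(np.log(orr))
            in_band += int(3.0 <= orr <= 5.3)
        assert abs(np.mean(log_ors) - np.log(4)) <= 0.08
        assert in_band / 50 >= 0.68

    def test_confounding_by_indication_induces_spurious_association(self):
        """A null drug linked to an indication that raises the outcome shows
        an inflated crude OR."""
        conf = ConfoundingEffect(
            indication_phecode="900.0", drug=1, neonatal_phecode="002.0",
            or_exposure=6.0, or_outcome=6.0, indication_prevalence=0.2,
        )
        log_ors = []
        for seed in range(20):
            cfg = SimulationConfig(
                n_dyads=3000, n_drugs=3, n_phecodes=3, baseline_prevalence=0.05,
                exposure_prevalence=0.10, confounding_effects=[conf], seed=seed,
            )
            tables, truth = generate_population(cfg)
            ex = set(truth.exposures.loc[truth.exposures["drug"] == "drug_001", "baby_id"])
            cond = tables["condition_occurrence"]
            cases = set(cond.loc[cond["condition_code"] == "SYN001.0", "person_id"])
            babies = truth.episodes["baby_id"]
            e = babies.isin(ex).to_numpy()
            c = babies.isin(cases).to_numpy()
            a, b = (e & c).sum() + 0.5, (e & ~c).sum() + 0.5
            cc, d = (~e & c).sum() + 0.5, (~e & ~c).sum() + 0.5
            log_ors.append(np.log((a * d) / (b * cc)))
        assert np.mean(log_ors) > 0.15  # crude OR biased away from the null
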