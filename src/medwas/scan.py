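"""The drug × phenotype association scan (the MedWAS engine).

For every (drug entity, phecode) pair the engine fits an unadjusted
univariate logistic regression of neonatal case status on maternal
gestational exposure,

    logit P(case) = beta0 + beta1 * exposed,

and reports ``OR = exp(beta1)``, a two-sided Wald p-value (likelihood-ratio
optional), a per-drug Bonferroni significance flag at ``alpha / m`` where m
is the phenotype-panel size, and the *coincidence rate* — the fraction of
cases whose mothers were exposed.  With a single binary predictor the model
is saturated, so the maximum-likelihood ``exp(beta1)`` coincides with the
2×2 cross-product odds ratio; the engine exploits this by fitting Newton's
method on the aggregated two-covariate-pattern likelihood, which is exact
and fast enough for replicate-level calibration studies.  Tables with a zero
cell (separation) fall back to Fisher's exact p-value with a
Haldane–Anscombe (+0.5) corrected OR.

The public surface follows the model/results idiom: build a :class:`MedWAS`
model from cohort data (or directly from EHR tables via
:meth:`MedWAS.from_tables`), call :meth:`MedWAS.fit`, and read estimates off
the returned :class:`MedWASResults`.
"""

from __future__ import annotations

import hashlib
import io
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

logger = logging.getLogger(__name__)

RESULT_COLUMNS = [
    "drug",
    "phecode",
    "n_case",
    "n_control",
    "n_exposed_case",
    "n_exposed_control",
    "beta",
    "se",
    "odds_ratio",
    "p_value",
    "bonferroni_significant",
    "coincidence_rate",
    "method",
]


@dataclass
class ScanConfig:
    """Scan-wide settings.

    Parameters
    ----------
    alpha
        Baseline significance level (default 0.05).
    m
        Bonferroni family size.  Defaults to the phenotype-panel size
        (per-drug correction across all neonatal diseases); set
        ``family="global"`` to use drugs × phenotypes instead.
    min_cases
        Pairs with fewer cases are emitted as ``skipped_min_cases`` without
        a fit (default 20, guarding near-unary artifacts).
    covariates
        Optional adjustment covariates (dyad-aligned columns).  Ships empty;
        when supplied the fit is delegated to statsmodels GLM.
    separation_policy
        What to do on a zero cell; only ``"fisher"`` (Fisher exact p +
        Haldane–Anscombe OR) is implemented.
    p_method
        ``"wald"`` (default) or ``"lrt"``.
    """

    alpha: float = 0.05
    m: int | None = None
    min_cases: int = 20
    covariates: list[str] = field(default_factory=list)
    separation_policy: str = "fisher"
    family: str = "per_drug"  # or "global"
    p_method: str = "wald"

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.m is not None and self.m < 1:
            raise ValueError("m must be >= 1")
        if self.separation_policy != "fisher":
            raise ValueError(f"unsupported separation_policy {self.separation_policy!r}")
        if self.family not in ("per_drug", "global"):
            raise ValueError("family must be 'per_drug' or 'global'")
        if self.p_method not in ("wald", "lrt"):
            raise ValueError("p_method must be 'wald' or 'lrt'")


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Bonferroni-corrected per-test threshold ``alpha / m``."""
    if m < 1:
        raise ValueError("m must be >= 1")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    return alpha / m


def contingency(cohort, statuses: dict[str, str]) -> np.ndarray:
    """2×2 table ``[[exposed&case, exposed&control], [unexposed&case,
    unexposed&control]]`` for one exposure cohort.

    ``statuses`` maps baby_id → "case" | "control" | "excluded"; excluded
    babies are dropped from both margins, and dyads absent from ``statuses``
    are ignored.
    """
    a = b = c = d = 0
    for bid in cohort.exposed:
        s = statuses.get(bid)
        if s == "case":
            a += 1
        elif s == "control":
            b += 1
    for bid in cohort.control:
        s = statuses.get(bid)
        if s == "case":
            c += 1
        elif s == "control":
            d += 1
    return np.array([[a, b], [c, d]], dtype=int)


# --------------------------------------------------------------------------
# per-pair fit
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class PairFit:
    beta: float
    se: float
    p_value: float
    odds_ratio: float
    method: str  # "logit" | "fisher_fallback" | "degenerate_outcome"
    reason: str | None = None


def _newton_logit_cells(
    a: np.ndarray, b: np.ndarray, c: np.ndarray, d: np.ndarray, tol: float = 1e-12
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised Newton-Raphson MLE of the univariate logit on 2×2 cells.

    Cells: a = exposed cases, b = exposed controls, c = unexposed cases,
    d = unexposed controls (all > 0).  Returns (beta1, se(beta1)).
    """
    a, b, c, d = (np.asarray(x, dtype=float) for x in (a, b, c, d))
    n1, y1 = a + b, a
    n0, y0 = c + d, c
    eta1 = np.log((y1 + 0.5) / (n1 - y1 + 0.5))
    eta0 = np.log((y0 + 0.5) / (n0 - y0 + 0.5))
    for _ in range(50):
        p1, p0 = expit(eta1), expit(eta0)
        g1 = y1 - n1 * p1
        g0 = y0 - n0 * p0
        w1 = np.maximum(n1 * p1 * (1 - p1), 1e-300)
        w0 = np.maximum(n0 * p0 * (1 - p0), 1e-300)
        step1, step0 = g1 / w1, g0 / w0
        eta1 = eta1 + step1
        eta0 = eta0 + step0
        if max(np.abs(step1).max(initial=0), np.abs(step0).max(initial=0)) < tol:
            break
    beta = eta1 - eta0
    p1, p0 = expit(eta1), expit(eta0)
    w1 = n1 * p1 * (1 - p1)
    w0 = n0 * p0 * (1 - p0)
    se = np.sqrt(1 / w1 + 1 / w0)
    return beta, se


def _loglik_cells(a, b, c, d, eta1, eta0) -> np.ndarray:
    n1, y1, n0, y0 = a + b, a, c + d, c
    return (
        y1 * eta1
        - n1 * np.log1p(np.exp(eta1))
        + y0 * eta0
        - n0 * np.log1p(np.exp(eta0))
    )


def _fisher_fallback(a: int, b: int, c: int, d: int) -> PairFit:
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    ah, bh, ch, dh = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    orr = (ah * dh) / (bh * ch)
    se = float(np.sqrt(1 / ah + 1 / bh + 1 / ch + 1 / dh))
    return PairFit(
        beta=float(np.log(orr)),
        se=se,
        p_value=float(p),
        odds_ratio=float(orr),
        method="fisher_fallback",
    )


def fit_pair(
    exposure: Sequence[int] | np.ndarray,
    outcome: Sequence[int] | np.ndarray,
    config: ScanConfig | None = None,
) -> PairFit:
    """Fit one drug-disease test from dyad-level binary vectors.

    Maximum-likelihood univariate logit with two-sided Wald p (or LRT);
    any zero cell triggers the separation policy (Fisher exact p +
    Haldane–Anscombe OR).  An all-constant outcome is undefined and returned
    with ``method="degenerate_outcome"``.
    """
    config = config or ScanConfig()
    x = np.asarray(exposure, dtype=bool)
    y = np.asarray(outcome, dtype=bool)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 1:
        raise ValueError("exposure and outcome must be equal-length 1-D vectors")
    if config.covariates:
        raise NotImplementedError(
            "covariate adjustment is available through MedWAS.fit, not fit_pair"
        )

    a = int(np.sum(x & y))
    b = int(np.sum(x & ~y))
    c = int(np.sum(~x & y))
    d = int(np.sum(~x & ~y))
    return fit_cells(a, b, c, d, config)


def fit_cells(a: int, b: int, c: int, d: int, config: ScanConfig | None = None) -> PairFit:
    """:func:`fit_pair` on pre-tabulated 2×2 cells."""
    config = config or ScanConfig()
    if a + b + c + d == 0 or (a + c == 0) or (b + d == 0):
        return PairFit(
            beta=float("nan"),
            se=float("nan"),
            p_value=float("nan"),
            odds_ratio=float("nan"),
            method="degenerate_outcome",
            reason="degenerate_outcome",
        )
    if min(a, b, c, d) == 0:
        return _fisher_fallback(a, b, c, d)
    beta, se = _newton_logit_cells(
        np.array([a]), np.array([b]), np.array([c]), np.array([d])
    )
    beta_f, se_f = float(beta[0]), float(se[0])
    if config.p_method == "lrt":
        p = float(_lrt_p(np.array([a]), np.array([b]), np.array([c]), np.array([d]))[0])
    else:
        z = beta_f / se_f
        p = float(2 * stats.norm.sf(abs(z)))
    return PairFit(
        beta=beta_f, se=se_f, p_value=p, odds_ratio=float(np.exp(beta_f)), method="logit"
    )


def _lrt_p(a, b, c, d) -> np.ndarray:
    a, b, c, d = (np.asarray(x, dtype=float) for x in (a, b, c, d))
    n = a + b + c + d
    pbar = np.clip((a + c) / n, 1e-300, 1 - 1e-300)
    eta_null = np.log(pbar / (1 - pbar))
    ll_null = _loglik_cells(a, b, c, d, eta_null, eta_null)
    eta1 = np.log(a / b)
    eta0 = np.log(c / d)
    ll_sat = _loglik_cells(a, b, c, d, eta1, eta0)
    lr = np.maximum(2 * (ll_sat - ll_null), 0.0)
    return stats.chi2.sf(lr, df=1)


# --------------------------------------------------------------------------
# the scan model
# --------------------------------------------------------------------------

class MedWAS:
    """Drug × phenotype association scan model.

    Parameters
    ----------
    exposure
        Boolean dyad × drug-entity DataFrame (index: dyad/baby ids).
    case, excluded
        Boolean dyad × phecode DataFrames on the same index: case status and
        control-exclusion status from the phecode map.  ``excluded`` may be
        None (no exclusions).
    config
        :class:`ScanConfig`.
    metadata
        Extra run metadata to embed in the results header.
    """

    def __init__(
        self,
        exposure: pd.DataFrame,
        case: pd.DataFrame,
        excluded: pd.DataFrame | None = None,
        config: ScanConfig | None = None,
        metadata: dict | None = None,
        covariates: pd.DataFrame | None = None,
    ) -> None:
        if not exposure.index.equals(case.index):
            case = case.reindex(exposure.index, fill_value=False)
        if excluded is None:
            excluded = pd.DataFrame(False, index=case.index, columns=case.columns)
        elif not excluded.index.equals(exposure.index):
            excluded = excluded.reindex(exposure.index, fill_value=False)
        self.exposure = exposure.astype(bool)
        self.case = case.astype(bool)
        self.excluded = excluded.astype(bool)
        self.config = config or ScanConfig()
        self.metadata = dict(metadata or {})
        self.drug_panel = list(exposure.columns)
        self.phecode_panel = list(case.columns)
        if not self.drug_panel or not self.phecode_panel:
            raise ValueError("drug and phecode panels must be non-empty")
        self.covariates = None
        if self.config.covariates:
            if covariates is None:
                raise ValueError("config names covariates but no covariate data given")
            missing = set(self.config.covariates) - set(covariates.columns)
            if missing:
                raise ValueError(f"covariate columns missing from data: {sorted(missing)}")
            self.covariates = (
                covariates[list(self.config.covariates)]
                .reindex(exposure.index)
                .astype(float)
            )
            if self.covariates.isna().any().any():
                raise ValueError("covariate data missing for some dyads")

    @classmethod
    def from_tables(
        cls,
        tables: dict[str, pd.DataFrame],
        phecode_map,
        drug_map,
        dictionary=None,
        config: ScanConfig | None = None,
        min_code_count: int = 1,
        apply_exclusions: bool = True,
        phecode_panel: list[str] | None = None,
        drug_panel: list[str] | None = None,
    ) -> "MedWAS":
        """Build the model from raw EHR tables.

        Runs the inclusion rule, infers pregnancy episodes, aggregates
        exposures to ATC-4 and assigns phenotype statuses.  The consort log
        and retained dyads are attached as ``model.consort`` / ``model.dyads``.
        """
        from .cohort import apply_inclusion_rule, exposure_matrix
        from .pregnancy import default_dictionary
        from .vocab import UNMAPPED_ATC4, phenotype_status_matrix

        dictionary = dictionary or default_dictionary()
        dyads, consort = apply_inclusion_rule(tables, dictionary, drug_map=drug_map)
        if drug_panel is None:
            drug_panel = sorted(set(drug_map.classes)) if drug_map else sorted(
                {e.atc4 for d in dyads for e in d.exposures}
            )
            drug_panel = [c for c in drug_panel if c != UNMAPPED_ATC4]
        if phecode_panel is None:
            phecode_panel = phecode_map.phecodes
        expo = exposure_matrix(dyads, drug_panel)
        case, excl = phenotype_status_matrix(
            tables["condition_occurrence"],
            expo.index,
            phecode_panel,
            phecode_map,
            min_code_count=min_code_count,
            apply_exclusions=apply_exclusions,
        )
        model = cls(expo, case, excl, config=config)
        model.dyads = dyads
        model.consort = consort
        model.metadata["n_dyads_retained"] = len(dyads)
        return model

    # ------------------------------------------------------------------
    def _cells(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """Per-pair 2×2 cells (D × P arrays), excluded babies dropped."""
        E = self.exposure.to_numpy(dtype=float)  # n × D
        C = self.case.to_numpy(dtype=bool)
        X = self.excluded.to_numpy(dtype=bool)
        include = ~X  # n × P; cases are never marked excluded upstream
        case_inc = (C & include).astype(float)
        inc = include.astype(float)
        a = E.T @ case_inc  # exposed cases
        n1 = E.T @ inc  # exposed included
        tot_case = case_inc.sum(axis=0)  # per-phecode included cases
        tot_inc = inc.sum(axis=0)
        b = n1 - a
        c = tot_case[None, :] - a
        d = (tot_inc[None, :] - n1) - c
        return (
            np.rint(a).astype(int),
            np.rint(b).astype(int),
            np.rint(c).astype(int),
            np.rint(d).astype(int),
        )

    def _fit_adjusted(self, i: int, j: int) -> tuple[float, float, float] | None:
        """Row-level covariate-adjusted logit for one pair via statsmodels."""
        import statsmodels.api as sm

        include = ~self.excluded.iloc[:, j].to_numpy()
        y = self.case.iloc[:, j].to_numpy()[include].astype(float)
        if y.min() == y.max():
            return None
        x = self.exposure.iloc[:, i].to_numpy()[include].astype(float)
        X = np.column_stack([np.ones(len(y)), x, self.covariates.to_numpy()[include]])
        try:
            res = sm.GLM(y, X, family=sm.families.Binomial()).fit()
        except Exception:  # perfect separation etc.
            return None
        return float(res.params[1]), float(res.bse[1]), float(res.pvalues[1])

    def fit(self) -> "MedWASResults":
        """Run the scan and return a :class:`MedWASResults`."""
        cfg = self.config
        D, P = len(self.drug_panel), len(self.phecode_panel)
        a, b, c, d = self._cells()
        n_case = a + c
        n_control = b + d

        beta = np.full((D, P), np.nan)
        se = np.full((D, P), np.nan)
        p = np.full((D, P), np.nan)
        orr = np.full((D, P), np.nan)
        method = np.full((D, P), "logit", dtype=object)

        skipped = n_case < cfg.min_cases
        degenerate = (n_case == 0) | (n_control == 0)
        zero_cell = (np.minimum(np.minimum(a, b), np.minimum(c, d)) == 0) & ~degenerate
        clean = ~skipped & ~degenerate & ~zero_cell

        method[skipped] = "skipped_min_cases"
        method[degenerate & ~skipped] = "degenerate_outcome"

        if self.covariates is not None:
            # adjusted fits delegate to statsmodels GLM, pair by pair
            for i, j in np.argwhere(clean | zero_cell):
                fitij = self._fit_adjusted(i, j)
                if fitij is None:
                    method[i, j] = "degenerate_outcome"
                    continue
                beta[i, j], se[i, j], p[i, j] = fitij
                orr[i, j] = np.exp(beta[i, j])
                method[i, j] = "logit_adjusted"
            clean = np.zeros_like(clean)
            zero_cell = np.zeros_like(zero_cell)

        if clean.any():
            bb, ss = _newton_logit_cells(a[clean], b[clean], c[clean], d[clean])
            beta[clean], se[clean] = bb, ss
            orr[clean] = np.exp(bb)
            if cfg.p_method == "lrt":
                p[clean] = _lrt_p(a[clean], b[clean], c[clean], d[clean])
            else:
                p[clean] = 2 * stats.norm.sf(np.abs(bb / ss))

        fz = np.argwhere(zero_cell & ~skipped)
        for i, j in fz:
            pf = _fisher_fallback(a[i, j], b[i, j], c[i, j], d[i, j])
            beta[i, j], se[i, j] = pf.beta, pf.se
            p[i, j], orr[i, j] = pf.p_value, pf.odds_ratio
            method[i, j] = "fisher_fallback"

        if cfg.m is not None:
            m = cfg.m
        elif cfg.family == "global":
            m = D * P
        else:
            m = P
        thr = bonferroni_threshold(cfg.alpha, m)
        significant = np.where(np.isnan(p), False, p <= thr)

        with np.errstate(invalid="ignore", divide="ignore"):
            coincidence = np.where(n_case > 0, a / np.maximum(n_case, 1), np.nan)

        di, pi = np.meshgrid(np.arange(D), np.arange(P), indexing="ij")
        table = pd.DataFrame(
            {
                "drug": np.array(self.drug_panel, dtype=object)[di.ravel()],
                "phecode": np.array(self.phecode_panel, dtype=object)[pi.ravel()],
                "n_case": n_case.ravel(),
                "n_control": n_control.ravel(),
                "n_exposed_case": a.ravel(),
                "n_exposed_control": b.ravel(),
                "beta": beta.ravel(),
                "se": se.ravel(),
                "odds_ratio": orr.ravel(),
                "p_value": p.ravel(),
                "bonferroni_significant": significant.ravel(),
                "coincidence_rate": coincidence.ravel(),
                "method": method.ravel(),
            }
        )
        table = table.sort_values(
            ["drug", "p_value"], na_position="last", kind="mergesort"
        ).reset_index(drop=True)

        meta = {
            "alpha": cfg.alpha,
            "m": m,
            "family": cfg.family,
            "bonferroni_threshold": thr,
            "min_cases": cfg.min_cases,
            "p_method": cfg.p_method,
            "n_drugs": D,
            "n_phecodes": P,
            "n_dyads": int(len(self.exposure)),
            "config_hash": _config_hash(cfg),
            **self.metadata,
        }
        return MedWASResults(table=table, model=self, metadata=meta)


def _config_hash(cfg: ScanConfig) -> str:
    payload = json.dumps(asdict(cfg), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


class MedWASResults:
    """Fitted scan: one row per (drug, phecode) pair, plus run metadata."""

    def __init__(self, table: pd.DataFrame, model: MedWAS | None, metadata: dict) -> None:
        self.table = table
        self.model = model
        self.metadata = metadata

    @property
    def significant(self) -> pd.DataFrame:
        """Bonferroni-significant rows."""
        return self.table[self.table["bonferroni_significant"]]

    def result_for(self, drug: str, phecode: str) -> pd.Series:
        sel = self.table[(self.table["drug"] == drug) & (self.table["phecode"] == phecode)]
        if sel.empty:
            raise KeyError((drug, phecode))
        return sel.iloc[0]

    def summary(self, top: int = 10) -> str:
        """Human-readable scan summary."""
        t = self.table
        tested = t[t["method"].isin(["logit", "fisher_fallback"])]
        buf = io.StringIO()
        buf.write("MedWAS scan results\n")
        buf.write("=" * 60 + "\n")
        buf.write(
            f"pairs tested: {len(tested)} of {len(t)} "
            f"({(t['method'] == 'skipped_min_cases').sum()} below min_cases, "
            f"{(t['method'] == 'degenerate_outcome').sum()} degenerate)\n"
        )
        buf.write(
            f"alpha={self.metadata['alpha']}, Bonferroni family={self.metadata['family']} "
            f"(m={self.metadata['m']}, threshold={self.metadata['bonferroni_threshold']:.3g})\n"
        )
        buf.write(f"Bonferroni-significant pairs: {len(self.significant)}\n\n")
        cols = ["drug", "phecode", "odds_ratio", "p_value", "coincidence_rate", "method"]
        head = tested.nsmallest(top, "p_value")[cols]
        buf.write(head.to_string(index=False, float_format=lambda v: f"{v:.4g}"))
        return buf.getvalue()

    def to_tsv(self, path: str | Path) -> None:
        """Write the result table as TSV with '#'-prefixed metadata header."""
        path = Path(path)
        with open(path, "w") as fh:
            for k in sorted(self.metadata):
                fh.write(f"# {k}: {self.metadata[k]}\n")
            self.table.to_csv(fh, sep="\t", index=False, float_format="%.10g")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "MedWASResults":
        path = Path(path)
        meta: dict = {}
        with open(path) as fh:
            pos = fh.tell()
            line = fh.readline()
            while line.startswith("#"):
                k, _, v = line[1:].partition(":")
                meta[k.strip()] = v.strip()
                pos = fh.tell()
                line = fh.readline()
            fh.seek(pos)
            table = pd.read_csv(fh, sep="\t")
        return cls(table=table, model=None, metadata=meta)


def run_scan(
    dyads,
    drug_panel: list[str],
    phecode_panel: list[str],
    case: pd.DataFrame,
    excluded: pd.DataFrame | None = None,
    config: ScanConfig | None = None,
) -> MedWASResults:
    """Functional wrapper: scan retained dyads against the two panels."""
    from .cohort import exposure_matrix

    if not drug_panel or not phecode_panel:
        raise ValueError("panels must be non-empty")
    expo = exposure_matrix(dyads, drug_panel)
    model = MedWAS(expo, case.reindex(columns=phecode_panel), excluded, config=config)
    return model.fit()
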