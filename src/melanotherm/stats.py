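"""Statistical battery: correlations, normality-gated paired block contrasts,
OLS models with interactions, and Cook's-distance influence diagnostics.

Paired block contrasts follow the field's R-style convention: a Shapiro-Wilk
test on the paired differences at alpha = 0.05 decides between the paired
t-test and the Wilcoxon signed-rank test.  The Wilcoxon statistic V is the
sum of the ranks of the positive differences (zero differences dropped,
midranks for tied magnitudes); the two-sided p-value is exact (full null
distribution) for n <= 25 without ties and a normal approximation with
continuity and tie correction otherwise.

OLS fitting goes through statsmodels with Wilkinson formulas (two-level
factors get treatment contrasts), and every fit carries leverages and Cook's
distances; observations with D > 1 are flagged as influential.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd
import scipy.stats as sps
import statsmodels.formula.api as smf
from statsmodels.stats.outliers_influence import OLSInfluence

__all__ = [
    "PairedTestResult",
    "ModelResult",
    "pearson",
    "spearman",
    "shapiro_wilk",
    "wilcoxon_signed_rank",
    "paired_t",
    "paired_contrast",
    "ols_fit",
    "cooks_distance",
    "StudyDataset",
    "AnalysisReport",
    "run_analysis",
]

INFLUENCE_THRESHOLD = 1.0  # Cook's distance cutoff for flagging an individual


@dataclass(frozen=True)
class PairedTestResult:
    """Outcome of a paired contrast (t or Wilcoxon signed-rank)."""

    test_kind: Literal["t", "wilcoxon"]
    statistic: float
    p_two_sided: float
    n: int
    normality_p: float | None = None


@dataclass
class ModelResult:
    """An OLS fit with per-term inference and influence diagnostics."""

    formula: str
    params: pd.Series
    tvalues: pd.Series
    pvalues: pd.Series
    adjusted_r2: float
    r2: float
    residuals: pd.Series
    leverages: np.ndarray
    cooks_distances: np.ndarray
    flagged_influential: list
    nobs: int

    def summary_row(self, term: str) -> dict:
        return {
            "term": term,
            "coef": float(self.params[term]),
            "t": float(self.tvalues[term]),
            "p": float(self.pvalues[term]),
        }


def _as_clean_array(x, name: str) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if not np.isfinite(x).all():
        raise ValueError(f"{name} contains non-finite values")
    return x


def pearson(x, y) -> tuple[float, float, float]:
    """Pearson product-moment correlation: returns (r, r_squared, p_two_sided).

    Both r and r**2 are reported explicitly — squared correlations and
    adjusted model R**2 are different quantities and are kept separate
    throughout this package.
    """
    x, y = _as_clean_array(x, "x"), _as_clean_array(y, "y")
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need >= 3 paired finite values")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("constant input has undefined correlation")
    res = sps.pearsonr(x, y)
    r = float(res.statistic)
    return r, r * r, float(res.pvalue)


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation (midranks for ties): returns (rho, p)."""
    x, y = _as_clean_array(x, "x"), _as_clean_array(y, "y")
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need >= 3 paired finite values")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("constant input has undefined correlation")
    res = sps.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)


def shapiro_wilk(d) -> tuple[float, float]:
    """Shapiro-Wilk normality test; the alpha=0.05 gate for paired contrasts."""
    d = _as_clean_array(d, "d")
    if not 3 <= len(d) <= 5000:
        raise ValueError("Shapiro-Wilk requires 3 <= n <= 5000")
    if np.ptp(d) == 0:
        raise ValueError("constant sample has undefined normality statistic")
    res = sps.shapiro(d)
    return float(res.statistic), float(res.pvalue)


def _signed_rank_null_cdf(n: int) -> np.ndarray:
    """Counts of the null distribution of V = sum of positive ranks over
    all 2**n sign assignments of ranks 1..n (tie-free case)."""
    m = n * (n + 1) // 2
    counts = np.zeros(m + 1, dtype=float)
    counts[0] = 1.0
    for r in range(1, n + 1):
        counts[r:] += counts[:-r].copy()
    return counts


def wilcoxon_signed_rank(x, y, exact_max_n: int = 25) -> PairedTestResult:
    """Wilcoxon signed-rank test for paired samples.

    V = sum of the ranks of the positive differences of d = x - y, with zero
    differences dropped and midranks for tied magnitudes.  The two-sided
    p-value is exact (by the full null distribution of V) when the retained
    n <= ``exact_max_n`` and no magnitudes are tied; otherwise a normal
    approximation with continuity correction and the usual tie correction of
    the null variance is used.
    """
    x, y = _as_clean_array(x, "x"), _as_clean_array(y, "y")
    d = x - y
    d = d[d != 0]
    n = len(d)
    if n < 2:
        raise ValueError("fewer than 2 nonzero paired differences")
    ranks = sps.rankdata(np.abs(d))
    V = float(ranks[d > 0].sum())
    _, tie_counts = np.unique(np.abs(d), return_counts=True)
    has_ties = (tie_counts > 1).any()

    if n <= exact_max_n and not has_ties:
        counts = _signed_rank_null_cdf(n)
        total = 2.0 ** n
        v_int = int(round(V))
        p_le = counts[: v_int + 1].sum() / total
        p_ge = counts[v_int:].sum() / total
        p = min(1.0, 2.0 * min(p_le, p_ge))
    else:
        mu = n * (n + 1) / 4.0
        sigma2 = n * (n + 1) * (2 * n + 1) / 24.0
        sigma2 -= (tie_counts ** 3 - tie_counts).sum() / 48.0
        sigma = math.sqrt(sigma2)
        # continuity correction toward the mean
        z = (V - mu - 0.5 * np.sign(V - mu)) / sigma
        p = min(1.0, 2.0 * sps.norm.sf(abs(z)))
    return PairedTestResult(test_kind="wilcoxon", statistic=V, p_two_sided=float(p), n=n)


def paired_t(x, y) -> PairedTestResult:
    """Paired t-test: t = mean(d) / (sd(d)/sqrt(n)), df = n - 1, two-sided."""
    x, y = _as_clean_array(x, "x"), _as_clean_array(y, "y")
    if len(x) != len(y) or len(x) < 2:
        raise ValueError("need >= 2 pairs")
    d = x - y
    sd = d.std(ddof=1)
    if sd == 0:
        if d.mean() == 0:
            return PairedTestResult(test_kind="t", statistic=0.0, p_two_sided=1.0, n=len(d))
        raise ValueError("zero-variance differences: t undefined")
    t = d.mean() / (sd / math.sqrt(len(d)))
    p = 2.0 * sps.t.sf(abs(t), df=len(d) - 1)
    return PairedTestResult(test_kind="t", statistic=float(t), p_two_sided=float(p), n=len(d))


def paired_contrast(x, y, alpha: float = 0.05) -> PairedTestResult:
    """Normality-gated paired contrast.

    Shapiro-Wilk on the differences: p >= alpha -> paired t-test, else
    Wilcoxon signed-rank.  The gate p-value is recorded in the result.
    """
    x, y = _as_clean_array(x, "x"), _as_clean_array(y, "y")
    d = x - y
    if np.ptp(d) == 0:
        raise ValueError("identical pairs: contrast undefined")
    _, norm_p = shapiro_wilk(d)
    if norm_p >= alpha:
        res = paired_t(x, y)
    else:
        res = wilcoxon_signed_rank(x, y)
    return PairedTestResult(
        test_kind=res.test_kind, statistic=res.statistic,
        p_two_sided=res.p_two_sided, n=res.n, normality_p=norm_p,
    )


def ols_fit(formula: str, data: pd.DataFrame) -> ModelResult:
    """Least-squares fit of a Wilkinson formula with influence diagnostics.

    Supports main effects, interactions (``a * b``) and two-level categorical
    factors (treatment contrasts).  Adjusted R**2 may be negative.  Raises on
    rank-deficient designs or n <= number of terms.
    """
    data = data.dropna(subset=_formula_columns(formula, data))
    fit = smf.ols(formula, data=data).fit()
    exog = fit.model.exog
    if np.linalg.matrix_rank(exog) < exog.shape[1]:
        raise ValueError("design matrix is rank deficient")
    if fit.nobs <= exog.shape[1]:
        raise ValueError("need more observations than model terms")
    influence = OLSInfluence(fit)
    lev = influence.hat_matrix_diag
    if _is_perfect_fit(fit.resid, fit.fittedvalues):
        cooks = np.zeros(int(fit.nobs))
    else:
        cooks = influence.cooks_distance[0]
    idx = list(data.index)
    flagged = [idx[i] for i in np.flatnonzero(cooks > INFLUENCE_THRESHOLD)]
    return ModelResult(
        formula=formula,
        params=fit.params,
        tvalues=fit.tvalues,
        pvalues=fit.pvalues,
        adjusted_r2=float(fit.rsquared_adj),
        r2=float(fit.rsquared),
        residuals=fit.resid,
        leverages=lev,
        cooks_distances=cooks,
        flagged_influential=flagged,
        nobs=int(fit.nobs),
    )


def _formula_columns(formula: str, data: pd.DataFrame) -> list[str]:
    return [c for c in data.columns if c in formula.replace("~", "+").replace("*", "+")]


def _is_perfect_fit(resid, fitted) -> bool:
    scale = 1.0 + float(np.abs(np.asarray(fitted)).max(initial=0.0))
    return bool(np.abs(np.asarray(resid)).max(initial=0.0) <= 1e-10 * scale)


def cooks_distance(model: ModelResult) -> np.ndarray:
    """Cook's distance per observation: D_i = e_i^2 h_ii / (p s^2 (1-h_ii)^2).

    Equivalent to the leave-one-out definition: the scaled squared shift of
    all fitted values when observation i is deleted.  A numerically perfect
    fit has no influence to measure (all D = 0 rather than 0/0).  Raises if
    any leverage equals 1 (an exactly-fit point makes the deletion form
    undefined).
    """
    e = np.asarray(model.residuals, dtype=float)
    h = np.asarray(model.leverages, dtype=float)
    p = len(model.params)
    if np.any(h >= 1.0 - 1e-12):
        raise ValueError("leverage of 1 encountered; Cook's distance undefined")
    if _is_perfect_fit(e, np.zeros_like(e)):
        return np.zeros_like(e)
    s2 = (e ** 2).sum() / (model.nobs - p)
    return e ** 2 * h / (p * s2 * (1.0 - h) ** 2)


# ---------------------------------------------------------------------------
# Whole-study orchestration


@dataclass
class StudyDataset:
    """Tidy inputs for the full analysis.

    thermal : per-timepoint table (through ``prepare_thermal_table``), with
        columns individual_id, seq_index, block, body_temp, substrate_temp,
        logger_cold/warm/hide, atmospheric, humidity.
    metrics : per-image pattern table with columns individual_id, seq_index,
        block, melanistic_proportion, mean_lum_mel, mean_lum_nonmel
        (QC-rejected images already removed).
    individuals : one row per animal: individual_id, sex, mass_g, svl_mm.
    """

    thermal: pd.DataFrame
    metrics: pd.DataFrame
    individuals: pd.DataFrame


@dataclass
class AnalysisReport:
    """Every table the block-based thermal analysis produces."""

    correlations: pd.DataFrame
    contrasts: pd.DataFrame
    rate_models: pd.DataFrame
    proportion_model: ModelResult
    luminance_models: dict[str, ModelResult]
    cooks_flags: dict[str, list]
    counts: dict[str, int]
    rates: pd.DataFrame
    block_means: pd.DataFrame
    models: dict[str, ModelResult] = field(default_factory=dict)

    def to_markdown(self) -> str:
        lines = ["# Thermal analysis report", "", "## Counts"]
        lines += [f"- {k}: {v}" for k, v in self.counts.items()]
        lines += ["", "## Correlations", self.correlations.to_markdown(index=False)]
        lines += ["", "## Block contrasts", self.contrasts.to_markdown(index=False)]
        lines += ["", "## Rate models", self.rate_models.to_markdown(index=False)]
        lines += ["", "## Influential individuals (Cook's D > 1)"]
        lines += [f"- {k}: {v}" for k, v in self.cooks_flags.items() if v] or ["- none"]
        return "\n".join(lines)

    def write_csv(self, out_dir) -> None:
        from pathlib import Path
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.correlations.to_csv(out / "correlations.csv", index=False)
        self.contrasts.to_csv(out / "contrasts.csv", index=False)
        self.rate_models.to_csv(out / "rate_models.csv", index=False)
        self.rates.to_csv(out / "rates.csv", index=False)
        self.block_means.to_csv(out / "block_means.csv", index=False)
        (out / "report.md").write_text(self.to_markdown())


_BLOCK_PAIRS = {"cooling": (1, 3), "heating": (3, 5), "start_end": (1, 5)}


def run_analysis(dataset: StudyDataset) -> AnalysisReport:
    """Run the full block-based thermoregulation analysis.

    Produces: body-vs-substrate / datalogger / atmospheric / humidity
    correlations; paired block contrasts (1-3, 3-5, 1-5) for body temperature
    and for melanistic / non-melanistic luminance; models of log heating and
    cooling rates against mass, SVL and sex; the log-proportion ~ SVL x sex
    model; and, per segment class and block pair, the luminance-change ~
    log-proportion x temperature-change interaction model with
    Cook's-distance flags.
    """
    from .quantification import block_summaries, thermal_rates

    thermal, metrics, individuals = dataset.thermal, dataset.metrics, dataset.individuals
    for frame, cols in [
        (thermal, ["individual_id", "block", "body_temp"]),
        (metrics, ["individual_id", "block", "melanistic_proportion",
                   "mean_lum_mel", "mean_lum_nonmel"]),
        (individuals, ["individual_id", "sex", "mass_g", "svl_mm"]),
    ]:
        missing = set(cols) - set(frame.columns)
        if missing:
            raise ValueError(f"dataset missing required columns: {sorted(missing)}")
    present_blocks = set(thermal["block"].unique())
    if not {1, 2, 3, 4, 5} <= present_blocks:
        raise ValueError(f"dataset missing block(s) {sorted({1,2,3,4,5} - present_blocks)}")

    # --- correlations (per-timepoint)
    logger_cols = [c for c in ("logger_cold", "logger_warm", "logger_hide")
                   if c in thermal.columns]
    t = thermal.copy()
    if logger_cols:
        # a timepoint with any invalidated logger reading has no valid average
        t["logger_mean"] = t[logger_cols].mean(axis=1).where(
            t[logger_cols].notna().all(axis=1))
    corr_specs = [
        ("body_temp", "substrate_temp", "body vs IR substrate"),
        ("body_temp", "logger_mean", "body vs terrarium loggers (mean)"),
        ("body_temp", "atmospheric", "body vs atmospheric logger"),
        ("logger_mean", "substrate_temp", "terrarium loggers vs IR substrate"),
        ("body_temp", "humidity", "body vs relative humidity"),
    ]
    corr_rows = []
    for xcol, ycol, label in corr_specs:
        if xcol not in t.columns or ycol not in t.columns:
            continue
        sub = t[[xcol, ycol]].dropna()
        try:
            r, r2, p = pearson(sub[xcol], sub[ycol])
        except ValueError:  # degenerate (constant) channel
            r = r2 = p = float("nan")
        corr_rows.append({"comparison": label, "r": r, "r_squared": r2,
                          "p": p, "n": len(sub)})
    correlations = pd.DataFrame(corr_rows)

    # --- per-block means and contrasts
    blocks = block_summaries(thermal, metrics)
    contrast_rows = []
    for var in ("mean_body_temp", "mean_lum_mel", "mean_lum_nonmel"):
        wide = blocks.pivot(index="individual_id", columns="block", values=var)
        for phase, (b_from, b_to) in _BLOCK_PAIRS.items():
            pairs = wide[[b_from, b_to]].dropna()
            try:
                res = paired_contrast(pairs[b_from], pairs[b_to])
                row = {"test": res.test_kind, "statistic": res.statistic,
                       "p": res.p_two_sided, "n": res.n,
                       "normality_p": res.normality_p}
            except ValueError:  # identical pairs: no change to test
                row = {"test": "degenerate", "statistic": float("nan"),
                       "p": float("nan"), "n": len(pairs), "normality_p": float("nan")}
            contrast_rows.append({"variable": var, "phase": phase,
                                  "blocks": f"{b_from}-{b_to}", **row})
    contrasts = pd.DataFrame(contrast_rows)

    # --- per-individual rates and pattern summaries
    rates = pd.DataFrame([vars(r) for r in thermal_rates(blocks)])
    pattern = (
        metrics.groupby("individual_id", as_index=False)
        .agg(mean_proportion=("melanistic_proportion", "mean"))
    )
    pattern["log_prop"] = np.log(pattern["mean_proportion"].where(
        pattern["mean_proportion"] > 0))
    per_ind = (
        individuals.merge(rates, on="individual_id").merge(pattern, on="individual_id")
    )

    # --- rate models: log rate vs mass, SVL, sex (separately, as reported)
    models: dict[str, ModelResult] = {}
    rate_rows = []
    for rate_col in ("log_heating", "log_cooling"):
        sub = per_ind.dropna(subset=[rate_col])
        for pred in ("mass_g", "svl_mm", "sex"):
            key = f"{rate_col}~{pred}"
            m = ols_fit(f"{rate_col} ~ {pred}", sub)
            models[key] = m
            term = [x for x in m.params.index if x != "Intercept"][0]
            rate_rows.append({
                "response": rate_col, "predictor": pred,
                "coef": float(m.params[term]), "t": float(m.tvalues[term]),
                "p": float(m.pvalues[term]), "adjusted_r2": m.adjusted_r2,
            })
        key = f"{rate_col}~log_prop"
        m = ols_fit(f"{rate_col} ~ log_prop", sub.dropna(subset=["log_prop"]))
        models[key] = m
        rate_rows.append({
            "response": rate_col, "predictor": "log_prop",
            "coef": float(m.params["log_prop"]), "t": float(m.tvalues["log_prop"]),
            "p": float(m.pvalues["log_prop"]), "adjusted_r2": m.adjusted_r2,
        })
    rate_models = pd.DataFrame(rate_rows)

    # --- melanistic proportion vs size and sex
    proportion_model = ols_fit("log_prop ~ svl_mm * sex",
                               per_ind.dropna(subset=["log_prop"]))
    models["log_prop~svl_mm*sex"] = proportion_model

    # --- luminance change vs log proportion x body-temperature change
    lum_models: dict[str, ModelResult] = {}
    cooks_flags: dict[str, list] = {}
    temp_wide = blocks.pivot(index="individual_id", columns="block",
                             values="mean_body_temp")
    for seg_class, var in (("mel", "mean_lum_mel"), ("nonmel", "mean_lum_nonmel")):
        lum_wide = blocks.pivot(index="individual_id", columns="block", values=var)
        for phase, (b_from, b_to) in _BLOCK_PAIRS.items():
            df = pd.DataFrame({
                "lum_change": lum_wide[b_to] - lum_wide[b_from],
                "temp_change": temp_wide[b_to] - temp_wide[b_from],
            }).join(per_ind.set_index("individual_id")["log_prop"]).dropna()
            key = f"lum_{seg_class}_{phase}"
            try:
                m = ols_fit("lum_change ~ log_prop * temp_change", df)
            except ValueError:  # degenerate design (e.g. constant temp change)
                cooks_flags[key] = []
                continue
            lum_models[key] = m
            models[key] = m
            cooks_flags[key] = m.flagged_influential

    counts = {
        "n_individuals": int(individuals["individual_id"].nunique()),
        "n_visible_points": int(len(metrics)),
        "n_ir_points": int(thermal["body_temp"].notna().sum()),
        "n_logger_points": int(t["logger_mean"].notna().sum()) if "logger_mean" in t else 0,
        "n_logger_invalid": int(thermal.attrs.get("n_logger_invalid", 0)),
    }

    return AnalysisReport(
        correlations=correlations,
        contrasts=contrasts,
        rate_models=rate_models,
        proportion_model=proportion_model,
        luminance_models=lum_models,
        cooks_flags=cooks_flags,
        counts=counts,
        rates=rates,
        block_means=blocks,
        models=models,
    )
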