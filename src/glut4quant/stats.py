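"""Linear mixed-effects models over the per-fibre measurement table.

Fibres are the rows; repeated measurement within a participant is handled
by a subject-level random intercept, matching the repeated-biopsy design
(three timepoints per subject, many fibres per biopsy).  Fixed effects are
drawn from training-status group, infusion arm, timepoint, fibre type and
layer.  Count responses are modelled on the log1p scale within the
Gaussian mixed model.  Post-hoc pairwise contrasts between factor levels
are marginal-mean contrasts with Bonferroni adjustment; degrees of freedom
are residual (Satterthwaite approximations are not available for this
fitter), which is recorded in the output.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from patsy import dmatrix
from scipy import stats as sps

from .core import LAYER_NAMES

__all__ = [
    "ModelSpec",
    "ContrastResult",
    "MixedModelFit",
    "fit_mixed_model",
    "posthoc_pairwise",
    "wald_factor_test",
    "summarize_study",
]

#: responses that live in wide per-layer columns and melt to long format
PER_LAYER_RESPONSES = ("small_count", "large_count", "total_count", "layer_intensity")

_CATEGORICAL = {
    "timepoint_h": "C(timepoint_h)",
    "group": "C(group)",
    "infusion": "C(infusion)",
    "fibre_type": "C(fibre_type)",
    "layer": "C(layer)",
}


@dataclass(frozen=True)
class ModelSpec:
    """Declarative description of one mixed model.

    ``response`` is one of ``pcc``, ``total_intensity``, ``layer_intensity``,
    ``small_count``, ``large_count``, ``total_count``.  Per-layer responses
    are analysed in long format with ``layer`` available as a fixed factor,
    or restricted to a single layer via ``layer``.
    """

    response: str
    fixed: tuple[str, ...] = ("group", "infusion", "timepoint_h")
    interactions: tuple[str, ...] = ()
    layer: str | None = None
    count_transform: str = "log1p"

    def __post_init__(self) -> None:
        known = ("pcc", "total_intensity") + PER_LAYER_RESPONSES
        if self.response not in known:
            raise ValueError(f"unknown response {self.response!r}; expected one of {known}")
        if self.layer is not None and self.response not in PER_LAYER_RESPONSES:
            raise ValueError("layer restriction only applies to per-layer responses")


@dataclass(frozen=True)
class ContrastResult:
    """One pairwise post-hoc contrast between two factor levels."""

    term: str
    comparison: str  # e.g. "0v2"
    estimate: float
    std_error: float
    statistic: float
    df: float
    p_value: float
    p_adjusted: float

    @property
    def significant(self) -> bool:
        return self.p_adjusted < 0.05


@dataclass
class MixedModelFit:
    """Fitted mixed model plus the long-format data and bookkeeping."""

    result: object  # statsmodels MixedLMResults
    data: pd.DataFrame
    formula: str
    spec: ModelSpec
    converged: bool
    singular: bool
    df_resid: float
    extras: dict = field(default_factory=dict)

    @property
    def fixed_effects(self) -> pd.Series:
        return self.result.fe_params

    @property
    def subject_variance(self) -> float:
        return float(self.result.cov_re.iloc[0, 0])

    @property
    def residual_variance(self) -> float:
        return float(self.result.scale)

    def summary_frame(self) -> pd.DataFrame:
        res = self.result
        fe = res.fe_params
        se = res.bse_fe
        z = fe / se
        p = 2 * sps.t.sf(np.abs(z), self.df_resid)
        return pd.DataFrame(
            {"estimate": fe, "std_error": se, "statistic": z, "p_value": p}
        )


def _long_table(table: pd.DataFrame, spec: ModelSpec) -> pd.DataFrame:
    if spec.response in ("pcc", "total_intensity"):
        df = table.copy()
        df["value"] = df[spec.response].astype(float)
        return df.dropna(subset=["value"])
    prefix_map = {
        "small_count": lambda lyr: table[f"small_{lyr}"],
        "large_count": lambda lyr: table[f"large_{lyr}"],
        "total_count": lambda lyr: table[f"small_{lyr}"] + table[f"large_{lyr}"],
        "layer_intensity": lambda lyr: table[f"intensity_{lyr}"],
    }
    getter = prefix_map[spec.response]
    layers = [spec.layer] if spec.layer else list(LAYER_NAMES)
    parts = []
    for lyr in layers:
        part = table.copy()
        part["layer"] = lyr
        part["value"] = getter(lyr).astype(float)
        parts.append(part)
    df = pd.concat(parts, ignore_index=True).dropna(subset=["value"])
    if spec.response.endswith("_count") and spec.count_transform == "log1p":
        df["value"] = np.log1p(df["value"])
    return df


def _build_formula(spec: ModelSpec, df: pd.DataFrame) -> str:
    terms = []
    for f in spec.fixed:
        if f == "layer" and spec.layer is not None:
            continue
        if f not in df.columns:
            raise ValueError(f"fixed factor {f!r} not in the table")
        if df[f].nunique() < 2:
            raise ValueError(f"fixed factor {f!r} has a single observed level")
        terms.append(_CATEGORICAL.get(f, f))
    for inter in spec.interactions:
        parts = [p.strip() for p in inter.split(":")]
        terms.append(":".join(_CATEGORICAL.get(p, p) for p in parts))
    rhs = " + ".join(terms) if terms else "1"
    return f"value ~ {rhs}"


def fit_mixed_model(table: pd.DataFrame, spec: ModelSpec) -> MixedModelFit:
    """REML fit of a Gaussian mixed model with a subject random intercept.

    Singular fits and non-convergence are flagged on the returned object,
    never silently dropped.

    Raises
    ------
    ValueError
        Fewer than two subjects (random intercept unidentifiable), or a
        fixed factor with a single observed level.
    """
    if "subject_id" not in table.columns:
        raise ValueError("table must have a subject_id column")
    if table["subject_id"].nunique() < 2:
        raise ValueError("at least 2 subjects are required for a subject random intercept")
    df = _long_table(table, spec)
    formula = _build_formula(spec, df)
    model = smf.mixedlm(formula, df, groups=df["subject_id"])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        result = model.fit(reml=True)
    converged = bool(getattr(result, "converged", True))
    subject_var = float(result.cov_re.iloc[0, 0])
    singular = subject_var <= 1e-10 * max(float(result.scale), 1e-300)
    k = np.linalg.matrix_rank(model.exog)
    df_resid = len(df) - k - 1  # one fitted variance component
    return MixedModelFit(
        result=result,
        data=df,
        formula=formula,
        spec=spec,
        converged=converged,
        singular=singular,
        df_resid=float(df_resid),
    )


def _marginal_design_row(fit: MixedModelFit, factor: str, level) -> np.ndarray:
    """Mean fixed-effects design row with `factor` forced to `level`.

    Averaging the modified design over all observed rows yields
    marginal-mean contrasts that remain valid when the factor participates
    in interactions.
    """
    design_info = fit.result.model.data.design_info
    df2 = fit.data.copy()
    df2[factor] = level
    X = np.asarray(dmatrix(design_info, df2, return_type="matrix"))
    return X.mean(axis=0)


def posthoc_pairwise(
    fit: MixedModelFit,
    factor: str,
    *,
    adjust: str = "bonferroni",
) -> list[ContrastResult]:
    """All pairwise level contrasts of a fixed factor, multiplicity adjusted.

    Contrasts are differences of marginal-mean design rows; p-values use a
    t reference with residual degrees of freedom and are Bonferroni
    adjusted across the factor's pairs by default.

    Raises
    ------
    ValueError
        If the factor is absent from the fitted model or has fewer than
        two levels.
    """
    if factor not in fit.data.columns or all(
        factor not in t for t in fit.formula.split("~")[1].split("+")
    ):
        raise ValueError(f"factor {factor!r} is not part of the fitted model")
    levels = sorted(fit.data[factor].unique())
    if len(levels) < 2:
        raise ValueError(f"factor {factor!r} has fewer than 2 levels in the fit")
    rows = {lvl: _marginal_design_row(fit, factor, lvl) for lvl in levels}
    params = np.asarray(fit.result.fe_params)
    cov = np.asarray(fit.result.cov_params())[: len(params), : len(params)]
    pairs = list(itertools.combinations(levels, 2))
    m = len(pairs)
    out = []
    for a, b in pairs:
        c = rows[b] - rows[a]
        est = float(c @ params)
        se = float(np.sqrt(c @ cov @ c))
        tstat = est / se if se > 0 else np.nan
        p = float(2 * sps.t.sf(abs(tstat), fit.df_resid)) if np.isfinite(tstat) else np.nan
        p_adj = min(1.0, p * m) if adjust == "bonferroni" else p
        out.append(
            ContrastResult(
                term=factor,
                comparison=f"{a:g}v{b:g}" if isinstance(a, (int, float)) else f"{a}v{b}",
                estimate=est,
                std_error=se,
                statistic=tstat,
                df=fit.df_resid,
                p_value=p,
                p_adjusted=p_adj,
            )
        )
    return out


def wald_factor_test(fit: MixedModelFit, factor: str) -> tuple[float, float, float]:
    """Joint Wald F-test that all of a factor's fixed-effect terms are zero.

    Returns ``(F, df_num, p_value)`` with residual denominator df.
    """
    design_info = fit.result.model.data.design_info
    patsy_name = _CATEGORICAL.get(factor, factor)
    cols: list[int] = []
    for term, slc in design_info.term_name_slices.items():
        if patsy_name in term.split(":"):
            cols.extend(range(slc.start, slc.stop))
    if not cols:
        raise ValueError(f"factor {factor!r} has no fixed-effect terms in the model")
    params = np.asarray(fit.result.fe_params)
    cov = np.asarray(fit.result.cov_params())[: len(params), : len(params)]
    R = np.zeros((len(cols), len(params)))
    for i, j in enumerate(cols):
        R[i, j] = 1.0
    rb = R @ params
    W = float(rb @ np.linalg.solve(R @ cov @ R.T, rb))
    q = len(cols)
    F = W / q
    p = float(sps.f.sf(F, q, fit.df_resid))
    return F, q, p


def _cell_stats(df: pd.DataFrame, value: str, by: list[str]) -> pd.DataFrame:
    g = df.groupby(by, observed=True)[value]
    out = g.agg(mean="mean", sd="std", n="count").reset_index()
    out["se"] = out["sd"] / np.sqrt(out["n"].clip(lower=1))
    return out


def summarize_study(table: pd.DataFrame, *, alpha: float = 0.05) -> dict[str, pd.DataFrame]:
    """Results-style tidy summary tables from a measurement table.

    Produces cell means +/- SE for PCC by time, total intensity by fibre
    type, per-layer small/large spot counts by condition, and small-spot
    fractions per layer and group computed as small/(small+large); an
    empty layer yields a missing fraction, never 0/0.
    """
    if table.empty:
        raise ValueError("measurement table is empty")
    out: dict[str, pd.DataFrame] = {}
    out["pcc_by_time"] = _cell_stats(table, "pcc", ["group", "infusion", "timepoint_h"])
    if table["fibre_type"].notna().any():
        out["intensity_by_fibre_type"] = _cell_stats(
            table.dropna(subset=["fibre_type"]), "total_intensity", ["group", "fibre_type"]
        )
    count_rows = []
    frac_rows = []
    for (group, tp), sub in table.groupby(["group", "timepoint_h"], observed=True):
        for lyr in LAYER_NAMES:
            small = sub[f"small_{lyr}"].sum()
            large = sub[f"large_{lyr}"].sum()
            count_rows.append(
                {
                    "group": group,
                    "timepoint_h": tp,
                    "layer": lyr,
                    "small_mean": sub[f"small_{lyr}"].mean(),
                    "large_mean": sub[f"large_{lyr}"].mean(),
                    "small_se": sub[f"small_{lyr}"].sem(),
                    "large_se": sub[f"large_{lyr}"].sem(),
                }
            )
            total = small + large
            frac_rows.append(
                {
                    "group": group,
                    "timepoint_h": tp,
                    "layer": lyr,
                    "small_fraction": small / total if total > 0 else np.nan,
                }
            )
    out["spot_counts"] = pd.DataFrame(count_rows)
    out["small_fractions"] = pd.DataFrame(frac_rows)

    overall = []
    for group, sub in table.groupby("group", observed=True):
        small = sum(sub[f"small_{lyr}"].sum() for lyr in LAYER_NAMES)
        large = sum(sub[f"large_{lyr}"].sum() for lyr in LAYER_NAMES)
        pm_small = sub["small_PM"].sum()
        pm_large = sub["large_PM"].sum()
        overall.append(
            {
                "group": group,
                "small_fraction_all": small / (small + large) if small + large else np.nan,
                "small_fraction_pm": pm_small / (pm_small + pm_large)
                if pm_small + pm_large
                else np.nan,
            }
        )
    out["small_fraction_overall"] = pd.DataFrame(overall)
    return out
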