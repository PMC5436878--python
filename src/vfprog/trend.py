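"""Hierarchical linear mixed models for global-index trends.

MD and PSD, expressed in common log10 units (SAP dB / 10, FDT dB / 20),
are modeled jointly over both test types:

    y_ijt = b0 + b1 * FDT + b2 * t + b3 * t * FDT
            + u0_i + u1_i * t + v_ij + e_ijt

with fixed effects for test type (SAP the reference), follow-up time in
years, and their interaction (the rate difference); a correlated random
intercept/slope (u0, u1) per subject i; a random intercept v per eye j
nested in subject; and i.i.d. residuals.  Fitting is by REML through
statsmodels MixedLM; Wald tests use the normal approximation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy import stats

from .scales import db_to_log10, log10_to_db

__all__ = ["LMMFit", "prepare_long_indices", "fit_lmm", "slope_in_db"]

#: canonical fixed-effect names in model term order
FIXED_EFFECTS = ("intercept", "fdt_offset", "time_slope", "time_fdt_interaction")


@dataclass(eq=False)
class LMMFit:
    """REML fit of the two-type trend model."""

    response: str  # "MD" | "PSD"
    fixed_effects: pd.DataFrame  # estimate, se, p_value, ci_low, ci_high
    variance_components: dict[str, float]
    converged: bool
    singular: bool
    n_obs: int
    result: object  # statsmodels MixedLMResults

    def estimate(self, name: str) -> float:
        return float(self.fixed_effects.loc[name, "estimate"])

    def wald_p(self, name: str) -> float:
        return float(self.fixed_effects.loc[name, "p_value"])


def prepare_long_indices(df: pd.DataFrame) -> pd.DataFrame:
    """Convert a long index table with dB columns to common log10 units.

    Expects columns subject_id, eye_id, test_type, time_years, md_db,
    psd_db; adds md_log10 and psd_log10.
    """
    out = df.copy()
    for col in ("md", "psd"):
        out[f"{col}_log10"] = [
            db_to_log10(v, tt) for v, tt in zip(out[f"{col}_db"], out["test_type"])
        ]
    return out


def fit_lmm(records: pd.DataFrame, response: str = "PSD",
            reml: bool = True) -> LMMFit:
    """Fit the hierarchical trend model for MD or PSD.

    ``records`` is long-format with columns subject_id, eye_id, test_type
    ('SAP'/'FDT'), time_years, and md_log10 / psd_log10.  Random
    intercept+slope at the subject level (unstructured 2x2 covariance) and
    a random intercept per eye nested within subject.
    """
    response = response.upper()
    if response not in ("MD", "PSD"):
        raise ValueError("response must be 'MD' or 'PSD'")
    ycol = f"{response.lower()}_log10"
    df = records.copy()
    if df["test_type"].nunique() < 2:
        raise ValueError("both test types required for the joint model")
    df["fdt"] = (df["test_type"] == "FDT").astype(float)
    # within-subject eye label: nested random intercepts need only
    # distinguish eyes inside a subject, keeping the VC design narrow
    df["eye_in_subject"] = (
        df.groupby("subject_id")["eye_id"]
        .transform(lambda s: pd.factorize(s)[0])
        .astype(str)
    )
    formula = f"{ycol} ~ fdt + time_years + time_years:fdt"
    model = smf.mixedlm(
        formula,
        data=df,
        groups=df["subject_id"],
        re_formula="~time_years",
        vc_formula={"eye": "0 + C(eye_in_subject)"},
    )
    fit = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for method in ("lbfgs", "powell", "cg"):
            try:
                fit = model.fit(reml=reml, method=method, maxiter=500)
            except (np.linalg.LinAlgError, ValueError):
                continue
            if fit.converged:
                break
    if fit is None:
        raise RuntimeError("linear mixed model failed to converge")
    names = {
        "Intercept": "intercept",
        "fdt": "fdt_offset",
        "time_years": "time_slope",
        "time_years:fdt": "time_fdt_interaction",
    }
    fe = fit.fe_params
    se = fit.bse_fe
    z = stats.norm.ppf(0.975)
    rows = {}
    for raw, name in names.items():
        est, s = float(fe[raw]), float(se[raw])
        p = 2 * stats.norm.sf(abs(est / s)) if s > 0 else np.nan
        rows[name] = {"estimate": est, "se": s, "p_value": p,
                      "ci_low": est - z * s, "ci_high": est + z * s}
    cov_re = fit.cov_re
    vc = {
        "subject_intercept_var": float(cov_re.iloc[0, 0]),
        "subject_slope_var": float(cov_re.iloc[1, 1]),
        "subject_int_slope_cov": float(cov_re.iloc[0, 1]),
        "eye_intercept_var": float(fit.vcomp[0]) if len(fit.vcomp) else 0.0,
        "residual_var": float(fit.scale),
    }
    singular = (
        vc["subject_intercept_var"] <= 1e-10
        or vc["subject_slope_var"] <= 1e-12
        or vc["eye_intercept_var"] < 0
    )
    return LMMFit(
        response=response,
        fixed_effects=pd.DataFrame(rows).T[["estimate", "se", "p_value",
                                            "ci_low", "ci_high"]],
        variance_components=vc,
        converged=bool(fit.converged),
        singular=singular,
        n_obs=len(df),
        result=fit,
    )


def slope_in_db(fit: LMMFit, test_type: str) -> float:
    """Annual rate of change on the instrument's own dB scale.

    SAP: time slope x 10; FDT: (time slope + interaction) x 20.
    """
    slope = fit.estimate("time_slope")
    if test_type == "FDT":
        slope += fit.estimate("time_fdt_interaction")
    return log10_to_db(slope, test_type)
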