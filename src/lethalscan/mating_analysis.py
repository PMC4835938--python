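"""Sire x maternal-grandsire mating-type analysis of stillbirth.

Dams are not genotyped in routine cattle recording, so the dam's carrier
probability is proxied by her sire (the calf's maternal grandsire, MGS).
Matings are cross-classified by sire and MGS carrier status into types
I-IV; under Hardy-Weinberg proportions the expected fraction of conceptuses
homozygous for a recessive lethal allele of frequency p is 0, 0,
p/(4(1+p)) and (1+p)/(4(2+p)) for types I-IV, approaching 12.5 % for type
IV as p -> 0.  A linear mixed model on the 0/1 stillbirth outcome with
parity and insemination month-year as fixed effects and an
A-structured random MGS effect estimates the mating-type contrasts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .mixed_models import (FitResult, ModelSpec, RelationshipMatrix,
                           reml_fit)

MATING_TYPES = ("I", "II", "III", "IV")


def classify_mating(sire_carrier: bool, mgs_carrier: bool) -> str:
    """(noncarrier, noncarrier) -> I, (noncarrier, carrier) -> II,
    (carrier, noncarrier) -> III, (carrier, carrier) -> IV."""
    return MATING_TYPES[2 * bool(sire_carrier) + bool(mgs_carrier)]


def expected_homozygote_fraction(mating_type: str, p: float) -> float:
    """Hardy-Weinberg expected fraction of conceptuses homozygous for a
    recessive allele of frequency p, given the mating type.  Type IV tends to
    1/8 (12.5 %) as p -> 0: the carrier sire and the carrier MGS each
    transmit the allele to the relevant gamete with probability 1/2, and the
    dam must additionally have inherited it from the MGS."""
    if not 0.0 <= p < 1.0:
        raise ValueError("p must be in [0, 1)")
    mt = str(mating_type).upper()
    if mt in ("I", "II"):
        return 0.0
    if mt == "III":
        return p / (4.0 * (1.0 + p))
    if mt == "IV":
        return (1.0 + p) / (4.0 * (2.0 + p))
    raise ValueError(f"unknown mating type {mating_type!r}")


def build_mating_records(calving: pd.DataFrame,
                         carrier_status: pd.Series | dict) -> pd.DataFrame:
    """Attach mating types to calving records.

    ``carrier_status`` maps animal id -> bool for every classified sire/MGS;
    records whose MGS is unrecorded or whose sire/MGS status is unknown are
    dropped (they cannot be classified).  The outcome is re-coded so that
    y = 1 means stillborn (the calving table codes survived = 1), and a
    heifer/cow stratum is derived from parity.
    """
    status = pd.Series(carrier_status).astype(bool)
    rec = calving.copy()
    rec = rec[rec["mgs"].astype(str) != ""]
    known = rec["sire"].isin(status.index) & rec["mgs"].isin(status.index)
    rec = rec.loc[known].copy()
    sire_c = status.loc[rec["sire"]].to_numpy()
    mgs_c = status.loc[rec["mgs"]].to_numpy()
    rec["mating_type"] = [classify_mating(s, m) for s, m in zip(sire_c, mgs_c)]
    rec["y"] = 1 - rec["survived"].astype(int)
    rec["stratum"] = np.where(rec["parity"].astype(int) <= 1, "heifer", "cow")
    return rec.reset_index(drop=True)


@dataclass
class MatingModelResult:
    fit: FitResult
    contrasts: dict  # e.g. {"IV-I": (estimate, se)}
    reference: str = "I"
    model: str = "linear"

    def contrast(self, mating_type: str) -> tuple[float, float]:
        return self.contrasts[f"{mating_type}-{self.reference}"]


def fit_mating_model(records: pd.DataFrame,
                     mgs_relationships: RelationshipMatrix | None = None,
                     include_covariates: bool = True,
                     model: str = "linear") -> MatingModelResult:
    """Fit the stillbirth mixed model and return mating-type contrasts.

    The default is a linear mixed model on the 0/1 outcome (the binary trait
    analysed on the observed scale), with parity and insemination month-year
    as fixed effects when ``include_covariates`` and the MGS as a random
    effect with covariance from ``mgs_relationships`` (identity if None).
    Mating type I is the reference; types with zero records are reported as
    absent.  ``model='logistic'`` fits a fixed-effects logistic regression
    instead, as a sensitivity analysis on the odds scale.
    """
    if len(records) == 0:
        raise ValueError("no classifiable mating records (every record needs a "
                         "known MGS and carrier status for sire and MGS)")
    rec = records.copy()
    rec["mating_type"] = pd.Categorical(rec["mating_type"],
                                        categories=list(MATING_TYPES))
    present = [t for t in MATING_TYPES if (rec["mating_type"] == t).any()]
    rec["mating_type"] = rec["mating_type"].cat.set_categories(present)

    fixed = ["mating_type"] + (["parity", "ins_ym"] if include_covariates else [])
    if model == "logistic":
        import statsmodels.api as sm

        spec = ModelSpec(response="y", fixed=fixed)
        rec2 = rec.copy()
        rec2["parity"] = rec2["parity"].astype(str)
        y, X, _, _, names = spec.build(rec2)
        glm = sm.GLM(y, X, family=sm.families.Binomial()).fit()
        fit = FitResult(fixed_names=names, beta=np.asarray(glm.params),
                        se=np.asarray(glm.bse), cov_beta=np.asarray(glm.cov_params()),
                        varcomp={}, loglik=float(glm.llf), converged=glm.converged,
                        n=len(y), p=X.shape[1])
    else:
        spec = ModelSpec(response="y", fixed=fixed,
                         random=[("mgs", "mgs", mgs_relationships)])
        rec2 = rec.copy()
        rec2["parity"] = rec2["parity"].astype(str)
        y, X, terms, _, names = spec.build(rec2)
        fit = reml_fit(y, X, terms, fixed_names=names)

    contrasts = {}
    for t in MATING_TYPES[1:]:
        name = f"mating_type_{t}"
        if name in fit.fixed_names:
            est, se = fit.coef(name)
            contrasts[f"{t}-I"] = (est, se)
    return MatingModelResult(fit=fit, contrasts=contrasts, model=model)


def raw_type_contrast(records: pd.DataFrame, mating_type: str,
                      reference: str = "I") -> tuple[float, float]:
    """Unadjusted stillbirth-rate difference between two mating types with a
    heteroscedasticity-honest standard error (per-type binomial variance).

    The linear mixed model assumes one residual variance for every record,
    which understates the uncertainty of the rare, high-risk type-IV class;
    this raw contrast is the appropriate yardstick when comparing against a
    theoretical excess.
    """
    a = records.loc[records["mating_type"] == mating_type, "y"].astype(float)
    b = records.loc[records["mating_type"] == reference, "y"].astype(float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both mating types need records")
    diff = a.mean() - b.mean()
    se = float(np.sqrt(a.var(ddof=1) / len(a) + b.var(ddof=1) / len(b)))
    return float(diff), se


def stillbirth_rate_table(records: pd.DataFrame,
                          stratum_col: str = "stratum") -> pd.DataFrame:
    """Counts and calf survival percentages per stratum x mating type.

    Columns are a (mating type, {N | survival}) MultiIndex plus row totals;
    a 'Total' row aggregates over strata.  Every record is counted exactly
    once.
    """
    rec = records.copy()
    rec["survived"] = 1 - rec["y"].astype(int) if "y" in rec else rec["survived"]
    types = [t for t in MATING_TYPES if (rec["mating_type"] == t).any()]
    strata = list(pd.unique(rec[stratum_col]))

    def cell(df):
        n = len(df)
        surv = 100.0 * df["survived"].mean() if n else float("nan")
        return n, surv

    rows = []
    for stratum in strata + ["Total"]:
        sub = rec if stratum == "Total" else rec[rec[stratum_col] == stratum]
        row = {}
        for t in types:
            n, s = cell(sub[sub["mating_type"] == t])
            row[(t, "N")] = n
            row[(t, "survival")] = s
        n, s = cell(sub)
        row[("Total", "N")] = n
        row[("Total", "survival")] = s
        rows.append(pd.Series(row, name=stratum))
    out = pd.DataFrame(rows)
    out.columns = pd.MultiIndex.from_tuples(out.columns)
    return out
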