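"""Survival stratification: median splits, Kaplan-Meier, log-rank, Cox.

Patients are stratified either by a morphometric feature (median split,
ties to the "high" group) or by classifier score groups, and the groups are
compared with the product-limit estimator, the log-rank test (hypergeometric
variance for ties) and a Cox proportional-hazards fit (Efron ties) adjusted
for age, stage and grade.  The heavy lifting delegates to lifelines; toy
cases are pinned against hand-tabulated oracles in the test suite.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank


@dataclass
class SurvivalRecord:
    """One time-to-event observation for one endpoint."""

    sample_id: str
    time: float  # months
    event: bool  # True = event observed
    endpoint: str = "OS"
    age: float | None = None
    stage: str | None = None
    grade: str | None = None

    def __post_init__(self) -> None:
        if self.time <= 0:
            raise ValueError("time must be positive")
        if self.endpoint not in {"OS", "PFS"}:
            raise ValueError("endpoint must be OS or PFS")


@dataclass
class KMResult:
    curve: pd.DataFrame = field(repr=False)  # columns: time, survival, at_risk
    median: float  # NaN if the curve never reaches 0.5

    def survival_at(self, t: float) -> float:
        c = self.curve
        below = c[c["time"] <= t]
        return 1.0 if below.empty else float(below["survival"].iloc[-1])


def records_to_frame(records: list[SurvivalRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "time": [r.time for r in records],
            "event": [r.event for r in records],
            "endpoint": [r.endpoint for r in records],
            "age": [r.age for r in records],
            "stage": [r.stage for r in records],
            "grade": [r.grade for r in records],
        },
        index=pd.Index([r.sample_id for r in records], name="sample_id"),
    )


def frame_to_records(frame: pd.DataFrame, endpoint: str = "OS") -> list[SurvivalRecord]:
    """Build records from a clinical table with <endpoint>_months/_event columns."""
    tcol, ecol = f"{endpoint.lower()}_months", f"{endpoint.lower()}_event"
    return [
        SurvivalRecord(
            sample_id=str(i),
            time=float(r[tcol]),
            event=bool(r[ecol]),
            endpoint=endpoint,
            age=float(r["age"]) if "age" in frame.columns else None,
            stage=str(r["stage"]) if "stage" in frame.columns else None,
            grade=str(r["grade"]) if "grade" in frame.columns else None,
        )
        for i, r in frame.iterrows()
    ]


def median_split(features: pd.DataFrame, feature_name: str) -> pd.Series:
    """Split samples at the feature median: >= median -> "high", < -> "low".

    Requires >= 2 non-missing values; all-identical values leave a single
    group, which is an error.  Samples with missing values get no label (NaN).
    """
    if feature_name not in features.columns:
        raise KeyError(feature_name)
    v = features[feature_name]
    valid = v.dropna()
    if len(valid) < 2:
        raise ValueError("need at least two non-missing values")
    med = float(valid.median())
    if valid.min() == valid.max():
        raise ValueError(f"feature {feature_name} is constant: no split exists")
    out = pd.Series(np.nan, index=features.index, dtype=object, name=feature_name)
    out[valid.index] = np.where(valid >= med, "high", "low")
    return out


def km_estimate(records: list[SurvivalRecord]) -> KMResult:
    """Product-limit survival curve and median survival time.

    The median is the earliest time at which the estimate drops to <= 0.5,
    NaN if never reached.
    """
    if not records:
        raise ValueError("records must be non-empty")
    frame = records_to_frame(records)
    kmf = KaplanMeierFitter()
    kmf.fit(frame["time"], frame["event"])
    curve = pd.DataFrame(
        {
            "time": kmf.survival_function_.index.to_numpy(dtype=float),
            "survival": kmf.survival_function_["KM_estimate"].to_numpy(),
            "at_risk": kmf.event_table["at_risk"].reindex(
                kmf.survival_function_.index
            ).to_numpy(),
        }
    )
    med = float(kmf.median_survival_time_)
    return KMResult(curve=curve, median=(float("nan") if np.isinf(med) else med))


def logrank_test(
    group_a: list[SurvivalRecord], group_b: list[SurvivalRecord]
) -> tuple[float, float]:
    """Log-rank chi-square statistic and p-value for two groups."""
    if not group_a or not group_b:
        raise ValueError("both groups must be non-empty")
    fa, fb = records_to_frame(group_a), records_to_frame(group_b)
    if not (fa["event"].any() or fb["event"].any()):
        raise ValueError("no events in either group")
    res = _ll_logrank(fa["time"], fb["time"], fa["event"], fb["event"])
    return float(res.test_statistic), float(res.p_value)


def cox_ph(
    records: list[SurvivalRecord],
    groups: pd.Series,
    covariates: tuple[str, ...] = ("age", "stage", "grade"),
) -> pd.DataFrame:
    """Cox proportional-hazards fit of group membership adjusted for covariates.

    ``groups`` maps sample id to a two-level label; the indicator is 1 for the
    lexicographically lower level (documented in the output index).  Efron tie
    handling.  Constant covariates are dropped with a warning; non-convergence
    propagates as an error.  Returns a frame indexed by term with columns
    hazard_ratio, ci_lower, ci_upper, p.
    """
    frame = records_to_frame(records)
    g = groups.reindex(frame.index).dropna()
    levels = sorted(set(g))
    if len(levels) != 2:
        raise ValueError("groups must have exactly two levels among the records")
    frame = frame.loc[g.index]
    if not frame["event"].any():
        raise ValueError("no events present")
    df = pd.DataFrame(
        {
            "time": frame["time"].astype(float),
            "event": frame["event"].astype(int),
            f"group_{levels[0]}": (g == levels[0]).astype(int),
        }
    )
    for cov in covariates:
        if cov not in frame.columns or frame[cov].isna().all():
            continue
        col = frame[cov]
        if col.dtype == object:
            dummies = pd.get_dummies(col, prefix=cov, drop_first=True, dtype=int)
            df = pd.concat([df, dummies], axis=1)
        else:
            df[cov] = col.astype(float)
    dropped = [c for c in df.columns[2:] if df[c].nunique() <= 1]
    if dropped:
        warnings.warn(f"dropping constant covariates: {dropped}", stacklevel=2)
        df = df.drop(columns=dropped)
    cph = CoxPHFitter()
    cph.fit(df, duration_col="time", event_col="event")
    summary = cph.summary
    return pd.DataFrame(
        {
            "hazard_ratio": summary["exp(coef)"],
            "ci_lower": summary["exp(coef) lower 95%"],
            "ci_upper": summary["exp(coef) upper 95%"],
            "p": summary["p"],
        }
    )
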