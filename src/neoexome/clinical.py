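"""Trial endpoints, design operating characteristics, survival and exposure.

The trial is a single-stage exact binomial phase II design: n = 40 patients,
null response rate p0 = 0.30, alternative p1 = 0.50, success declared when at
least r = 17 patients achieve pathological complete response (pCR). Its
operating characteristics are the exact binomial tails
``alpha = P[X >= r | n, p0]`` and ``power = P[X >= r | n, p1]``.

Endpoints: breast pCR (ypT0/is ypN0-3), breast-and-node pCR, near-complete
response (nCR, scattered residual tumour cells only), breast conservation
rate, disease-free survival (DFS, Kaplan-Meier with right censoring; primary
progression during treatment is not an event), relative dose intensity (RDI =
delivered / planned dose) and an adverse-event summary in which a patient
counts once per term at the worst grade.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from scipy.stats import binom

from .records import SUBTYPES, PatientOutcome


@dataclass
class DesignSpec:
    """Single-stage binomial phase II design."""

    n: int = 40
    r: int = 17  # success threshold: >= r responders
    p0: float = 0.30
    p1: float = 0.50

    def __post_init__(self) -> None:
        if not 0.0 < self.p0 < self.p1 < 1.0:
            raise ValueError("need 0 < p0 < p1 < 1")
        if not 0 <= self.r <= self.n:
            raise ValueError("need 0 <= r <= n")


def design_operating_characteristics(spec: DesignSpec) -> tuple[float, float]:
    """(type I error, power) of the design under the exact binomial law."""
    alpha = float(binom.sf(spec.r - 1, spec.n, spec.p0))
    power = float(binom.sf(spec.r - 1, spec.n, spec.p1))
    return alpha, power


def _rate(num: int, den: int) -> dict[str, float | int]:
    return {
        "n": num,
        "denominator": den,
        "fraction": num / den if den else float("nan"),
        "percent": 100.0 * num / den if den else float("nan"),
    }


def response_rates(outcomes: list[PatientOutcome]) -> dict[str, object]:
    """Response-rate table: overall and per-subtype pCR endpoints with numerators.

    Fractions are carried raw; ``percent`` is the same value on the 0-100
    scale, left unrounded (display rounding is the caller's concern).
    """
    for o in outcomes:
        if o.subtype not in SUBTYPES:
            raise ValueError(f"unknown subtype {o.subtype!r} for {o.patient_id}")
    n = len(outcomes)
    out: dict[str, object] = {
        "breast_pcr": _rate(sum(o.breast_pcr for o in outcomes), n),
        "breast_ln_pcr": _rate(sum(o.breast_ln_pcr for o in outcomes), n),
        "ypt0_ypn0": _rate(sum(o.ypt0_ypn0 for o in outcomes), n),
        "ncr": _rate(sum(o.ncr for o in outcomes), n),
        "pcr_or_ncr": _rate(sum(o.breast_pcr or o.ncr for o in outcomes), n),
        "breast_conserving": _rate(sum(o.surgery == "breast_conserving" for o in outcomes), n),
    }
    by_subtype: dict[str, object] = {}
    for st in SUBTYPES:
        group = [o for o in outcomes if o.subtype == st]
        if not group:
            continue
        by_subtype[st] = {
            "breast_pcr": _rate(sum(o.breast_pcr for o in group), len(group)),
            "breast_ln_pcr": _rate(sum(o.breast_ln_pcr for o in group), len(group)),
        }
    out["by_subtype"] = by_subtype
    return out


def km_dfs(outcomes: list[PatientOutcome], by_subtype: bool = False):
    """Kaplan-Meier DFS estimate (product-limit with right censoring).

    Returns ``(curve, median)`` where curve is a DataFrame with columns
    ``time, survival`` and median is the smallest time with S(t) <= 0.5, or
    None while the curve stays above 0.5 ("median not reached"). With
    ``by_subtype`` a dict of per-subtype ``(curve, median)`` is returned.
    Primary progression during treatment is excluded from events by
    construction of :class:`PatientOutcome`.
    """
    if by_subtype:
        return {
            st: km_dfs([o for o in outcomes if o.subtype == st])
            for st in SUBTYPES
            if any(o.subtype == st for o in outcomes)
        }
    times = np.array([o.dfs_months for o in outcomes], dtype=float)
    if (times < 0).any():
        raise ValueError("negative DFS time")
    events = np.array([bool(o.dfs_event) and not o.progressed_on_treatment for o in outcomes])
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    curve = kmf.survival_function_.reset_index()
    curve.columns = ["time", "survival"]
    median = float(kmf.median_survival_time_)
    return curve, (None if np.isinf(median) else median)


def dose_intensity(outcomes: list[PatientOutcome], rdi_threshold: float = 0.85) -> dict[str, object]:
    """Per-patient relative dose intensity and the cohort fraction at >= 85%."""
    rows = []
    for o in outcomes:
        if o.planned_dose <= 0:
            raise ValueError(f"nonpositive planned dose for {o.patient_id}")
        rows.append({"patient_id": o.patient_id, "rdi": o.delivered_dose / o.planned_dose})
    table = pd.DataFrame(rows)
    n_ge = int((table["rdi"] >= rdi_threshold).sum())
    return {
        "per_patient": table,
        "mean_rdi": float(table["rdi"].mean()),
        "at_or_above_threshold": _rate(n_ge, len(outcomes)),
        "threshold": rdi_threshold,
    }


def ae_table(
    outcomes: list[PatientOutcome], min_any_grade_fraction: float = 0.10
) -> pd.DataFrame:
    """Adverse-event summary: per term, patients with any grade and grade >= 3.

    A patient with several events under one term counts once (worst grade).
    Rows are kept when the any-grade rate reaches ``min_any_grade_fraction``
    or any patient had a grade >= 3 event for the term.
    """
    n = len(outcomes)
    worst: dict[str, dict[str, int]] = {}
    for o in outcomes:
        per_patient: dict[str, int] = {}
        for term, grade in o.adverse_events:
            if not 1 <= grade <= 5:
                raise ValueError(f"grade {grade} outside 1..5 ({o.patient_id}, {term})")
            per_patient[term] = max(per_patient.get(term, 0), grade)
        for term, grade in per_patient.items():
            cell = worst.setdefault(term, {"any": 0, "ge3": 0})
            cell["any"] += 1
            if grade >= 3:
                cell["ge3"] += 1
    rows = []
    for term in sorted(worst):
        cell = worst[term]
        if cell["any"] / n >= min_any_grade_fraction or cell["ge3"] > 0:
            rows.append(
                {
                    "term": term,
                    "any_grade_n": cell["any"],
                    "any_grade_pct": 100.0 * cell["any"] / n,
                    "grade_ge3_n": cell["ge3"],
                    "grade_ge3_pct": 100.0 * cell["ge3"] / n,
                }
            )
    return pd.DataFrame(
        rows, columns=["term", "any_grade_n", "any_grade_pct", "grade_ge3_n", "grade_ge3_pct"]
    )


# ---------------------------------------------------------------------------
# outcomes CSV schema

_OUTCOME_COLUMNS = [
    "patient_id",
    "subtype",
    "breast_pcr",
    "breast_ln_pcr",
    "ypt0_ypn0",
    "ncr",
    "surgery",
    "dfs_months",
    "dfs_event",
    "planned_dose",
    "delivered_dose",
    "progressed_on_treatment",
    "adverse_events",  # semicolon list of term:grade
]


def write_outcomes(outcomes: list[PatientOutcome], path) -> None:
    rows = []
    for o in outcomes:
        row = {c: getattr(o, c) for c in _OUTCOME_COLUMNS[:-1]}
        row["adverse_events"] = ";".join(f"{t}:{g}" for t, g in o.adverse_events)
        rows.append(row)
    pd.DataFrame(rows, columns=_OUTCOME_COLUMNS).to_csv(path, index=False)


def read_outcomes(path) -> list[PatientOutcome]:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    out = []
    for row in df.to_dict("records"):
        aes = []
        if row["adverse_events"]:
            for part in row["adverse_events"].split(";"):
                term, grade = part.rsplit(":", 1)
                aes.append((term, int(grade)))
        out.append(
            PatientOutcome(
                patient_id=row["patient_id"],
                subtype=row["subtype"],
                breast_pcr=row["breast_pcr"] == "True",
                breast_ln_pcr=row["breast_ln_pcr"] == "True",
                ypt0_ypn0=row["ypt0_ypn0"] == "True",
                ncr=row["ncr"] == "True",
                surgery=row["surgery"],
                dfs_months=float(row["dfs_months"]),
                dfs_event=row["dfs_event"] == "True",
                planned_dose=float(row["planned_dose"]),
                delivered_dose=float(row["delivered_dose"]),
                progressed_on_treatment=row["progressed_on_treatment"] == "True",
                adverse_events=aes,
            )
        )
    return out
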