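"""Per-patient derived perioperative metrics from raw clinical data.

Repeated measurements are summarised as areas under the curve (AUC) by
the trapezoidal rule, optionally normalized by monitoring duration so
that the metric reads as a time-averaged value.  Threshold metrics
(oliguria, arterial-pressure deficit, >50 % creatinine rise) integrate
the excursion beyond the threshold with exact linear-interpolation
crossing points, so they account for both magnitude and duration.

The full derived-variable table (:func:`compute_all`) reconstructs the
indicator set entering factor analysis: three uNGAL excretion metrics
over 12 h, creatinine variation metrics and AKIN stage over 48 h,
three oliguria deficit AUCs and the arterial-pressure deficit below
the age-group first quintile over 24 h, lactate AUC, the
vasoactive-inotropic score, 24-h fluid balance, the composite
pre-operative history score, and the static surgical variables.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "TimeSeries",
    "trapezoid_auc",
    "threshold_deficit_auc",
    "map_quintile_threshold",
    "delta_scr_metrics",
    "vis_score",
    "composite_preop_score",
    "akin_stage",
    "fluid_balance",
    "compute_all",
    "PREOP_FLAGS",
    "UMOL_PER_MGDL",
]

#: serum creatinine unit conversion (values carried in umol/L)
UMOL_PER_MGDL = 88.4

#: binary history items entering the composite pre-operative score
PREOP_FLAGS = (
    "preop_resuscitation",
    "preop_mechanical_ventilation",
    "preop_inotropic_support",
    "preop_infection",
    "preop_enterocolitis",
    "preop_pulmonary_hypertension",
    "preop_nephrotoxic_exposure",
    "preop_genetic_syndrome",
)


@dataclass(frozen=True)
class TimeSeries:
    """One monitored channel for one patient."""

    patient_id: object
    variable: str
    times: np.ndarray       # hours after surgery, strictly increasing
    values: np.ndarray
    window: tuple[float, float]

    def __post_init__(self):
        t = np.asarray(self.times, float)
        v = np.asarray(self.values, float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)
        if t.ndim != 1 or t.shape != v.shape:
            raise ValueError("times and values must be 1-D and equal length")
        if np.any(np.diff(t) <= 0):
            raise ValueError("sample times must be strictly increasing")
        lo, hi = self.window
        if not hi > lo:
            raise ValueError("monitoring window end must exceed its start")


def _clip_to_window(series: TimeSeries):
    """Samples restricted to the window, interpolating at the edges."""
    lo, hi = series.window
    t, v = series.times, series.values
    inside = (t >= lo) & (t <= hi)
    tt = t[inside]
    vv = v[inside]
    if (t < lo).any() and (t >= lo).any() and (tt.size == 0 or tt[0] > lo):
        vv = np.insert(vv, 0, np.interp(lo, t, v))
        tt = np.insert(tt, 0, lo)
    if (t > hi).any() and (t <= hi).any() and (tt.size == 0 or tt[-1] < hi):
        vv = np.append(vv, np.interp(hi, t, v))
        tt = np.append(tt, hi)
    if tt.size < 2:
        raise ValueError(
            f"need at least 2 samples inside the window for {series.variable!r} "
            f"(patient {series.patient_id})"
        )
    return tt, vv


def trapezoid_auc(series: TimeSeries, normalize_by_duration: bool = False) -> float:
    """Trapezoidal AUC over the monitoring window.

    With ``normalize_by_duration`` the integral is divided by the
    covered duration, returning the time-averaged value.
    """
    t, v = _clip_to_window(series)
    auc = float(np.trapezoid(v, t))
    if normalize_by_duration:
        auc /= float(t[-1] - t[0])
    return auc


def _excursion_auc(t, v, threshold, direction):
    """Integral of the excursion beyond the threshold with exact
    crossing points inserted."""
    dev = (threshold - v) if direction == "below" else (v - threshold)
    # insert zero crossings of dev
    tt = [t[0]]
    dd = [dev[0]]
    for i in range(1, len(t)):
        d0, d1 = dev[i - 1], dev[i]
        if (d0 > 0 > d1) or (d0 < 0 < d1):
            frac = d0 / (d0 - d1)
            tt.append(t[i - 1] + frac * (t[i] - t[i - 1]))
            dd.append(0.0)
        tt.append(t[i])
        dd.append(d1)
    dd = np.clip(np.asarray(dd), 0.0, None)
    return float(np.trapezoid(dd, np.asarray(tt)))


def threshold_deficit_auc(series: TimeSeries, threshold: float,
                          direction: str = "below") -> float:
    """AUC of the deficit below (or surplus above) a threshold, in
    value x hours."""
    if direction not in ("below", "above"):
        raise ValueError("direction must be 'below' or 'above'")
    t, v = _clip_to_window(series)
    return _excursion_auc(t, v, threshold, direction)


def map_quintile_threshold(pressure_series, age_days) -> dict:
    """First-quintile pressure threshold per age stratum.

    Pools every windowed sample of the cohort within each stratum
    (<=2 days, 3-28 days, >28 days at surgery) and returns the 20th
    percentile (linear interpolation).  Empty strata get ``None``.

    Parameters
    ----------
    pressure_series
        Iterable of :class:`TimeSeries` (one per patient).
    age_days
        Mapping patient_id -> age in days.
    """
    pools = {"<=2d": [], "3-28d": [], ">28d": []}
    for s in pressure_series:
        t, v = _clip_to_window(s)
        pools[_stratum(age_days[s.patient_id])].append(v)
    out = {}
    for name, chunks in pools.items():
        if chunks:
            out[name] = float(np.percentile(np.concatenate(chunks), 20))
        else:
            out[name] = None
    return out


def _stratum(age: float) -> str:
    if age <= 2:
        return "<=2d"
    if age <= 28:
        return "3-28d"
    return ">28d"


def delta_scr_metrics(series: TimeSeries, baseline: float) -> tuple[float, float]:
    """Creatinine variation metrics relative to the pre-operative baseline.

    Returns ``(relative-variation AUC, >50%-increase AUC)``: the
    duration-normalized AUC of ``sCr/baseline - 1``, and the integral
    of the excess above ``1.5 x baseline`` on the relative scale
    (fraction x hours).
    """
    if baseline <= 0:
        raise ValueError("baseline creatinine must be positive")
    t, v = _clip_to_window(series)
    rel = v / baseline - 1.0
    rel_auc = float(np.trapezoid(rel, t) / (t[-1] - t[0]))
    excess = _excursion_auc(t, rel, 0.5, "above")
    return rel_auc, excess


def vis_score(dopamine=0.0, dobutamine=0.0, epinephrine=0.0,
              norepinephrine=0.0, milrinone=0.0, vasopressin=0.0) -> float:
    """Vasoactive-inotropic score from infusion rates in ug/kg/min
    (vasopressin in U/kg/min):

    ``dopamine + dobutamine + 100 epinephrine + 100 norepinephrine
    + 10 milrinone + 10000 vasopressin``.
    """
    rates = dict(dopamine=dopamine, dobutamine=dobutamine,
                 epinephrine=epinephrine, norepinephrine=norepinephrine,
                 milrinone=milrinone, vasopressin=vasopressin)
    for k, v in rates.items():
        if np.any(np.asarray(v) < 0):
            raise ValueError(f"negative infusion rate for {k}")
    return (rates["dopamine"] + rates["dobutamine"]
            + 100.0 * rates["epinephrine"] + 100.0 * rates["norepinephrine"]
            + 10.0 * rates["milrinone"] + 10000.0 * rates["vasopressin"])


def composite_preop_score(flags) -> int:
    """Count of positive pre-operative history items (0-8)."""
    if isinstance(flags, dict) or isinstance(flags, pd.Series):
        return int(sum(bool(flags.get(k, False)) for k in PREOP_FLAGS))
    return int(sum(bool(x) for x in flags))


def akin_stage(scr_series: TimeSeries, baseline: float,
               dialysis: bool = False) -> int:
    """AKIN severity stage from the 48-h creatinine course.

    Stage 1: rise to >=150 % of baseline or an absolute rise of
    >=0.3 mg/dl; stage 2: >200 %; stage 3: >300 % or any renal
    replacement therapy.  Oliguria criteria are not applied here (urine
    output is analysed as its own family of metrics).
    """
    if baseline is None or not baseline > 0:
        raise ValueError("a positive baseline creatinine is required")
    if dialysis:
        return 3
    t, v = _clip_to_window(scr_series)
    peak = float(np.max(v))
    ratio = peak / baseline
    rise_mgdl = (peak - baseline) / UMOL_PER_MGDL
    if ratio > 3.0:
        return 3
    if ratio > 2.0:
        return 2
    if ratio >= 1.5 or rise_mgdl >= 0.3:
        return 1
    return 0


def fluid_balance(in_ml: float, out_ml: float, weight_kg: float) -> float:
    """Net 24-h fluid balance in ml/kg (negative = net loss)."""
    if not weight_kg > 0:
        raise ValueError("weight must be positive")
    return (in_ml - out_ml) / weight_kg


# ---------------------------------------------------------------------------
# cohort-level driver
# ---------------------------------------------------------------------------

_WINDOWS = {
    "ungal": (0.0, 12.0),
    "urine_output": (0.0, 24.0),
    "sap": (0.0, 24.0),
    "map": (0.0, 24.0),
    "scr": (0.0, 48.0),
    "lactate": (0.0, 48.0),
}


def _series_by_patient(ts: pd.DataFrame, variable: str) -> dict:
    out = {}
    win = _WINDOWS[variable]
    sub = ts[ts["variable"] == variable]
    for pid, grp in sub.groupby("patient_id"):
        grp = grp.sort_values("time_h")
        out[pid] = TimeSeries(pid, variable, grp["time_h"].to_numpy(),
                              grp["value"].to_numpy(), win)
    return out


def compute_all(timeseries: pd.DataFrame, statics: pd.DataFrame) -> pd.DataFrame:
    """Derived-variable table (one row per patient) from long-format
    time series and the static record.

    Expects the channels ``scr, urine_output, sap, map, lactate,
    ungal`` (creatinine-normalized concentration) and the static
    columns produced by the cohort simulator or an equivalently shaped
    export of real data.
    """
    ts = timeseries
    chans = {v: _series_by_patient(ts, v) for v in _WINDOWS}
    pids = list(statics.index)

    sap_thr = map_quintile_threshold(chans["sap"].values(), statics["age_days"])
    map_thr = map_quintile_threshold(chans["map"].values(), statics["age_days"])

    rows = []
    for pid in pids:
        st = statics.loc[pid]
        stratum = _stratum(st["age_days"])
        uo = chans["urine_output"][pid]
        scr = chans["scr"][pid]
        ungal = chans["ungal"][pid]
        rel_auc, excess50 = delta_scr_metrics(scr, st["baseline_scr"])
        ungal_norm = trapezoid_auc(ungal, normalize_by_duration=True)
        ungal_abs = ungal_norm * st["urine_creatinine"] * 100.0  # conc per ml
        mean_uo = trapezoid_auc(uo, normalize_by_duration=True)  # ml/kg/h
        row = {
            "patient_id": pid,
            "ungal_norm_auc": ungal_norm,
            "ungal_abs_auc": ungal_abs,
            "ungal_excretion_auc": ungal_abs * mean_uo * st["weight_kg"] / 1000.0,
            "dscr_rel_auc": rel_auc,
            "dscr50_auc": excess50,
            "akin_stage": akin_stage(scr, st["baseline_scr"], bool(st["dialysis"])),
            "oliguria_05_auc": threshold_deficit_auc(uo, 0.5),
            "oliguria_1_auc": threshold_deficit_auc(uo, 1.0),
            "oliguria_2_auc": threshold_deficit_auc(uo, 2.0),
            "sap_auc": (threshold_deficit_auc(chans["sap"][pid], sap_thr[stratum])
                        if sap_thr[stratum] is not None else np.nan),
            "map_auc": (threshold_deficit_auc(chans["map"][pid], map_thr[stratum])
                        if map_thr[stratum] is not None else np.nan),
            "lactate_auc": trapezoid_auc(chans["lactate"][pid],
                                         normalize_by_duration=True),
            "vis": vis_score(
                dopamine=st["dopamine"], dobutamine=st["dobutamine"],
                epinephrine=st["epinephrine"],
                norepinephrine=st["norepinephrine"],
                milrinone=st["milrinone"], vasopressin=st["vasopressin"],
            ),
            "fluid_balance": fluid_balance(st["fluid_in_ml"], st["fluid_out_ml"],
                                           st["weight_kg"]),
            "preop_score": composite_preop_score(st),
            "age": st["age_days"],
            "weight": st["weight_kg"],
            "cpb_duration": st["cpb_duration"],
            "crossclamp_duration": st["crossclamp_duration"],
            "ultrafiltration": st["ultrafiltration"],
            "transfusions": st["transfusions"],
            "ventilation_days": st["ventilation_days"],
            "icu_days": st["icu_days"],
            "mortality": float(st["mortality"]),
        }
        rows.append(row)
    return pd.DataFrame(rows).set_index("patient_id")
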