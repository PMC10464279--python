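"""Sleep-initiation phenotypes and covariates.

Nine measures are analyzed: bedtime, sleep-onset latency (SOL) and
sleep-onset time (SOT), each assessed by self-report (SR), actigraphy
(ACT) and polysomnography (PSG).  Bedtimes and SOTs are clock times on a
*continuous* scale in decimal hours where post-midnight times exceed 24
(e.g. 04:30 is represented as 28.5); this removes the midnight
wraparound from every downstream mean, difference and regression.  SOL
is in minutes.  SOT is defined as bedtime + SOL/60 on the continuous
scale.

The self-reported habitual bedtime is a school-week weighted average of
the weekday and weekend items, (5*weekday + 2*weekend)/7.
"""

from __future__ import annotations

import logging
import re

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

__all__ = [
    "MEASURES",
    "COVARIATES",
    "CLOCK_MIN",
    "CLOCK_MAX",
    "parse_clock",
    "format_clock",
    "weighted_bedtime",
    "sot",
    "load_phenotypes",
]

#: Canonical measure column names, grouped by construct then method.
MEASURES = (
    "bedtime_sr", "bedtime_act", "bedtime_psg",
    "sol_sr", "sol_act", "sol_psg",
    "sot_sr", "sot_act", "sot_psg",
)

#: Covariate columns adjusted for in every per-site model: age (years),
#: male (0/1), minority (0/1), BMI percentile (0-100) and sequencing
#: batch (categorical label, one-hot encoded at fit time).
COVARIATES = ("age", "male", "minority", "bmi_pct", "batch")

#: Continuous clock domain, decimal hours.  Noon today to noon tomorrow:
#: no adolescent bedtime falls in the excluded morning-to-noon window.
CLOCK_MIN = 12.0
CLOCK_MAX = 36.0

#: SOL plausibility bounds, minutes.
SOL_MIN = 0.0
SOL_MAX = 600.0

_CLOCK_RE = re.compile(r"^\s*(\d{1,2}):(\d{2})(?::\d{2})?\s*$")


def parse_clock(text: str) -> float:
    """Parse an ``hh:mm`` string to continuous decimal hours.

    Hours may exceed 23 (post-midnight display convention, e.g.
    ``"28:30"``).  Times written on the ordinary 24-h clock with an hour
    below 12 are taken to be post-midnight and mapped forward by 24, so
    ``"04:30"`` and ``"28:30"`` both parse to 28.5.

    Raises
    ------
    ValueError
        If the text is not ``hh:mm`` with minutes < 60, or the result
        falls outside the continuous domain [12, 36).
    """
    m = _CLOCK_RE.match(str(text))
    if not m:
        raise ValueError(f"malformed clock time: {text!r}")
    hh, mm = int(m.group(1)), int(m.group(2))
    if mm >= 60:
        raise ValueError(f"minutes must be < 60 in clock time {text!r}")
    value = hh + mm / 60.0
    if value < CLOCK_MIN:
        value += 24.0
    if not (CLOCK_MIN <= value < CLOCK_MAX):
        raise ValueError(
            f"clock time {text!r} -> {value:g} h outside [{CLOCK_MIN}, {CLOCK_MAX})"
        )
    return value


def format_clock(value: float) -> str:
    """Format continuous decimal hours as ``hh:mm``, rounded to the minute.

    The inverse of :func:`parse_clock` up to the post-midnight +24
    mapping: hours ≥ 24 are kept as printed (``25.0 -> "25:00"``).
    """
    if not (CLOCK_MIN <= value < CLOCK_MAX):
        raise ValueError(f"clock value {value!r} outside [{CLOCK_MIN}, {CLOCK_MAX})")
    total_min = int(round(value * 60.0))
    return f"{total_min // 60:02d}:{total_min % 60:02d}"


def weighted_bedtime(weekday, weekend):
    """School-week weighted average bedtime, (5*weekday + 2*weekend)/7.

    Both inputs must already be on the continuous clock scale; the
    result stays on it.  Accepts scalars or arrays.
    """
    return (5.0 * np.asarray(weekday) + 2.0 * np.asarray(weekend)) / 7.0


def sot(bedtime, sol_minutes):
    """Sleep-onset time: bedtime (continuous hours) + SOL (minutes)/60.

    Raises ``ValueError`` on negative SOL or a result leaving the clock
    domain.
    """
    bedtime = np.asarray(bedtime, dtype=float)
    sol_minutes = np.asarray(sol_minutes, dtype=float)
    if np.any(sol_minutes < 0):
        raise ValueError("SOL must be non-negative")
    out = bedtime + sol_minutes / 60.0
    if np.any(out >= CLOCK_MAX) or np.any(out < CLOCK_MIN):
        raise ValueError("sleep-onset time outside the continuous clock domain")
    return out if out.ndim else float(out)


# Raw-field columns from which the nine measures can be derived.
_RAW_COLUMNS = (
    "bedtime_weekday_sr", "bedtime_weekend_sr", "sol_sr",
    "bedtime_act", "sol_act",
    "bedtime_psg", "sol_psg",
)


def _to_hours(series: pd.Series) -> pd.Series:
    """Coerce a bedtime column to continuous hours (strings parsed)."""
    if series.dtype == object:
        return series.map(parse_clock).astype(float)
    return series.astype(float)


def load_phenotypes(path) -> pd.DataFrame:
    """Load a phenotype/covariate CSV into the canonical wide table.

    Two layouts are accepted, detected from the header:

    * **raw fields** — weekday/weekend SR bedtimes plus per-method
      bedtime and SOL columns; weighted SR bedtime and the three SOTs
      are derived here.
    * **precomputed** — all nine measure columns present; the identity
      sot = bedtime + sol/60 is re-checked to within one minute and a
      violation raises.

    Bedtime columns may be ``hh:mm`` strings (parsed, post-midnight
    mapped by +24) or decimal hours.  The index is ``subject_id``;
    covariate columns are kept as-is and a boolean
    ``covariates_complete`` column flags rows with no missing covariate.

    Raises ``ValueError`` on an empty file or missing mandatory columns.
    """
    df = pd.read_csv(path)
    if df.empty:
        raise ValueError(f"phenotype file {path} contains no rows")
    if "subject_id" not in df.columns:
        raise ValueError("phenotype file must have a 'subject_id' column")
    df = df.set_index(df["subject_id"].astype(str)).drop(columns=["subject_id"])
    if df.index.duplicated().any():
        raise ValueError("duplicate subject_id values in phenotype file")

    have_raw = all(c in df.columns for c in _RAW_COLUMNS)
    have_pre = all(c in df.columns for c in MEASURES)
    if not (have_raw or have_pre):
        missing = [c for c in MEASURES if c not in df.columns]
        raise ValueError(
            "phenotype file must carry either raw fields "
            f"{_RAW_COLUMNS} or all nine measures (missing {missing})"
        )

    out = pd.DataFrame(index=df.index)
    if have_pre:
        for c in MEASURES:
            out[c] = (_to_hours(df[c]) if ("bedtime" in c or "sot" in c)
                      else df[c].astype(float))
        for method in ("sr", "act", "psg"):
            resid = (out[f"sot_{method}"]
                     - out[f"bedtime_{method}"]
                     - out[f"sol_{method}"] / 60.0)
            bad = resid.abs() > (1.0 / 60.0 + 1e-9)
            if bad.any():
                raise ValueError(
                    f"sot_{method} != bedtime_{method} + sol_{method}/60 "
                    f"beyond 1 minute for subjects {list(out.index[bad])[:5]}"
                )
    else:
        wd = _to_hours(df["bedtime_weekday_sr"])
        we = _to_hours(df["bedtime_weekend_sr"])
        out["bedtime_sr"] = weighted_bedtime(wd, we)
        out["bedtime_act"] = _to_hours(df["bedtime_act"])
        out["bedtime_psg"] = _to_hours(df["bedtime_psg"])
        for method in ("sr", "act", "psg"):
            out[f"sol_{method}"] = df[f"sol_{method}"].astype(float)
            out[f"sot_{method}"] = sot(out[f"bedtime_{method}"],
                                       out[f"sol_{method}"])

    for method in ("sr", "act", "psg"):
        s = out[f"sol_{method}"]
        n_bad = int(((s < SOL_MIN) | (s >= SOL_MAX)).sum())
        if n_bad:
            log.warning("sol_%s outside the plausible [%g, %g) minute range "
                        "for %d subject(s)", method, SOL_MIN, SOL_MAX, n_bad)

    for c in COVARIATES:
        if c in df.columns:
            out[c] = df[c]
    present = [c for c in COVARIATES if c in out.columns]
    out["covariates_complete"] = (
        out[present].notna().all(axis=1) if present else False
    )
    return out
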