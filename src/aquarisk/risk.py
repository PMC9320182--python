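"""Deterministic ingestion-pathway exposure and risk (USEPA framework).

Chronic daily intake of a metal through drinking water:

    CDI = C * IR * EF * ED / (BW * AT)        [mg/kg-day]

with C the concentration (mg/L), IR ingestion rate (L/day), EF exposure
frequency (days/year), ED exposure duration (years), BW body weight (kg) and
AT averaging time (days).  With the default cohort parameters EF*ED equals AT
for both adults and children, so CDI collapses algebraically to C*IR/BW.

Non-carcinogenic hazard is the quotient HQ = CDI / RfD per metal and the
hazard index HI = sum(HQ) across metals; HI > 1 flags potential non-cancer
effects.  Carcinogenic risk is CR = CDI * SF per carcinogen (As, Pb, Ni here)
and TCR = sum(CR); 1e-4 is the regulatory action threshold.

All computation is full precision; table formatting to three significant
figures is presentation-only.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .campaign import WaterSample
from .reference import (
    CARCINOGENS,
    METALS,
    ExposureParams,
    classify,
    get_exposure,
    get_toxicity,
)

__all__ = ["RiskResult", "cdi", "hq", "hi", "cr", "tcr", "assess", "risk_table"]


@dataclass(frozen=True)
class RiskResult:
    """Per-subject, per-cohort risk metrics."""

    subject: str
    cohort: str
    cdi: dict[str, float]  # metal -> mg/kg-day
    hq: dict[str, float]  # metal -> unitless
    hi: float
    exceeds_one: bool  # HI > 1
    cr: dict[str, float]  # carcinogen -> lifetime risk
    tcr: float
    tcr_label: str
    cr_shares: dict[str, float]  # carcinogen -> % of TCR


def cdi(c_i: float, p: ExposureParams) -> float:
    """Chronic daily intake, mg/kg-day, for concentration ``c_i`` in mg/L."""
    if c_i < 0:
        raise ValueError(f"concentration must be >= 0, got {c_i}")
    if p.bw <= 0 or p.at <= 0:
        raise ValueError("BW and AT must be > 0")
    return c_i * p.ir * p.ef * p.ed / (p.bw * p.at)


def hq(cdi_val: float, rfd: float) -> float:
    """Hazard quotient CDI / RfD."""
    if rfd <= 0:
        raise ValueError(f"RfD must be > 0, got {rfd}")
    return cdi_val / rfd


def hi(hq_values: Iterable[float]) -> float:
    """Hazard index: sum of hazard quotients."""
    return float(sum(hq_values))


def cr(cdi_val: float, sf: float | None) -> float:
    """Carcinogenic risk CDI * SF.  Raises for metals without a slope factor."""
    if sf is None:
        raise ValueError("no slope factor: metal is not in the carcinogen set")
    return cdi_val * sf


def tcr(cr_values: Mapping[str, float]) -> tuple[float, str, dict[str, float]]:
    """Total carcinogenic risk, its category label and per-carcinogen shares (%)."""
    total = float(sum(cr_values.values()))
    label = classify("TCR", total)
    if total > 0:
        shares = {m: v / total * 100.0 for m, v in cr_values.items()}
    else:
        shares = {m: 0.0 for m in cr_values}
    return total, label, shares


def assess(
    conc: Mapping[str, float],
    cohort: str | ExposureParams,
    *,
    subject: str = "sample",
) -> RiskResult:
    """Full deterministic risk chain for one concentration vector."""
    p = cohort if isinstance(cohort, ExposureParams) else get_exposure(cohort)
    cdis: dict[str, float] = {}
    hqs: dict[str, float] = {}
    crs: dict[str, float] = {}
    for m in conc:
        tox = get_toxicity(m)
        d = cdi(conc[m], p)
        cdis[m] = d
        hqs[m] = hq(d, tox.rfd_oral)
        if tox.is_carcinogen:
            crs[m] = cr(d, tox.sf_oral)
    hi_val = hi(hqs.values())
    tcr_val, label, shares = tcr(crs)
    return RiskResult(
        subject=subject,
        cohort=p.cohort,
        cdi=cdis,
        hq=hqs,
        hi=hi_val,
        exceeds_one=hi_val > 1.0,
        cr=crs,
        tcr=tcr_val,
        tcr_label=label,
        cr_shares=shares,
    )


def _group_mean_conc(samples: Sequence[WaterSample]) -> dict[str, dict[str, float]]:
    groups: dict[str, list[WaterSample]] = {}
    for s in samples:
        groups.setdefault(s.source_type, []).append(s)
    return {
        src: {m: float(np.mean([s.conc[m] for s in members])) for m in METALS}
        for src, members in groups.items()
    }


def risk_table(
    samples: Sequence[WaterSample] | Mapping[str, Mapping[str, float]],
    cohorts: Sequence[str] = ("adult", "child"),
    *,
    mode: str = "group",
) -> pd.DataFrame:
    """Risk results as a flat table, one row per subject x cohort.

    ``mode='group'`` first averages concentrations within each source type and
    applies the risk chain to the mean vector (the convention used when risk
    is reported from published mean concentration tables); ``mode='sample'``
    assesses every sample individually.  ``samples`` may alternatively be a
    ready-made mapping of group id -> concentration vector.
    """
    if isinstance(samples, Mapping):
        subjects = {k: dict(v) for k, v in samples.items()}
    elif mode == "group":
        if len(samples) == 0:
            raise ValueError("empty sample collection")
        subjects = _group_mean_conc(samples)
    elif mode == "sample":
        subjects = {s.sample_id: s.conc for s in samples}
    else:
        raise ValueError(f"unknown mode {mode!r}")
    if not subjects:
        raise ValueError("empty group")

    rows = []
    for cohort in cohorts:
        for subj, conc in subjects.items():
            r = assess(conc, cohort, subject=subj)
            row: dict[str, object] = {"subject": subj, "cohort": cohort}
            for m in METALS:
                row[f"cdi_{m}"] = r.cdi.get(m, np.nan)
            for m in METALS:
                row[f"hq_{m}"] = r.hq.get(m, np.nan)
            row["hi"] = r.hi
            for m in CARCINOGENS:
                row[f"cr_{m}"] = r.cr.get(m, np.nan)
            row["tcr"] = r.tcr
            row["tcr_label"] = r.tcr_label
            for m in CARCINOGENS:
                row[f"share_{m}"] = r.cr_shares.get(m, np.nan)
            rows.append(row)
    return pd.DataFrame(rows)
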