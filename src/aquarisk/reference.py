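"""Regulatory standards, toxicity values, exposure parameters and classification scales.

Everything downstream — pollution indices, ingestion-risk metrics, Monte Carlo
propagation — consumes the constants housed here:

* drinking-water permissible limits (mg/L) for the eight study metals under the
  Philippine National Standards for Drinking Water (PNSDW, the default) and WHO
  guidelines;
* oral reference doses (RfD, mg/kg-day) for all eight metals and cancer slope
  factors (SF, per mg/kg-day) for the three carcinogens As, Pb and Ni;
* cohort ingestion-exposure parameters (adult and child);
* categorical classification scales for the heavy-metal pollution index (MPI),
  the Nemerow pollution index (NPI), total carcinogenic risk (TCR) and the
  coefficient of variation (CV).

The constants are compiled in but can be exported to / re-imported from a YAML
config so other jurisdictions' standards can be swapped in.  Units are fixed
(mg/L, mg/kg-day, L/day, days, years, kg); no unit conversion is attempted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import yaml

__all__ = [
    "METALS",
    "CARCINOGENS",
    "SOURCE_TYPES",
    "MetalStandard",
    "ToxicityEntry",
    "ExposureParams",
    "ClassificationScale",
    "LookupError_",
    "get_standard",
    "get_toxicity",
    "get_exposure",
    "get_scale",
    "classify",
    "study_summary",
    "study_mean_concentrations",
    "export_config",
    "import_config",
]

#: The eight heavy metals and metalloids of the study, in reporting order.
METALS: tuple[str, ...] = ("As", "Ba", "Cu", "Fe", "Pb", "Mn", "Ni", "Zn")

#: Metals with an oral cancer slope factor (IARC-listed carcinogens here).
CARCINOGENS: tuple[str, ...] = ("As", "Pb", "Ni")

#: Domestic water source types: water refilling station, groundwater, tap water.
SOURCE_TYPES: tuple[str, ...] = ("WRS", "GW", "TW")

AUTHORITIES: tuple[str, ...] = ("PNSDW", "WHO")

#: Default regulatory authority for index computation.
DEFAULT_AUTHORITY = "PNSDW"


class LookupError_(KeyError):
    """Unknown metal, authority, cohort or scale name."""


@dataclass(frozen=True)
class MetalStandard:
    """Permissible limit of one metal under one regulatory authority."""

    metal: str
    s_i: float  # permissible limit, mg/L
    authority: str

    def __post_init__(self) -> None:
        if self.s_i <= 0:
            raise ValueError(f"permissible limit must be > 0, got {self.s_i}")


@dataclass(frozen=True)
class ToxicityEntry:
    """Oral reference dose and (for carcinogens) oral slope factor of one metal."""

    metal: str
    rfd_oral: float  # mg/kg-day
    sf_oral: float | None = None  # (mg/kg-day)^-1; None for non-carcinogens

    def __post_init__(self) -> None:
        if self.rfd_oral <= 0:
            raise ValueError(f"RfD must be > 0, got {self.rfd_oral}")

    @property
    def is_carcinogen(self) -> bool:
        return self.sf_oral is not None


@dataclass(frozen=True)
class ExposureParams:
    """Cohort ingestion parameters for the chronic-daily-intake equation.

    CDI = C * IR * EF * ED / (BW * AT)
    """

    cohort: str
    ir: float  # ingestion rate, L/day
    ef: float  # exposure frequency, days/year
    ed: float  # exposure duration, years
    bw: float  # body weight, kg
    at: float  # averaging time, days

    def __post_init__(self) -> None:
        for name in ("ir", "ef", "ed", "bw", "at"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


# --- compiled-in constants -------------------------------------------------

# Permissible limits, mg/L.
_STANDARDS: dict[str, dict[str, float]] = {
    "WHO": {
        "As": 0.01, "Ba": 0.70, "Cu": 2.00, "Fe": 0.30,
        "Pb": 0.01, "Mn": 0.40, "Ni": 0.07, "Zn": 3.00,
    },
    "PNSDW": {
        "As": 0.01, "Ba": 0.70, "Cu": 1.00, "Fe": 1.00,
        "Pb": 0.01, "Mn": 0.40, "Ni": 0.07, "Zn": 5.00,
    },
}

# Oral RfD (mg/kg-day) and oral SF ((mg/kg-day)^-1, carcinogens only).
_TOXICITY: dict[str, tuple[float, float | None]] = {
    "As": (3e-4, 1.5),
    "Ba": (2e-1, None),
    "Cu": (0.04, None),
    "Fe": (7e-1, None),
    "Mn": (1.4e-1, None),
    "Ni": (0.02, 0.84),
    "Zn": (0.3, None),
    "Pb": (0.0014, 8.5e-3),
}

_EXPOSURE: dict[str, dict[str, float]] = {
    "adult": {"ir": 2.2, "ef": 365.0, "ed": 70.0, "bw": 70.0, "at": 25550.0},
    "child": {"ir": 1.0, "ef": 365.0, "ed": 10.0, "bw": 25.0, "at": 3650.0},
}


@dataclass(frozen=True)
class ClassificationScale:
    """Ordered-threshold categorical scale.

    ``breakpoints`` are strictly increasing.  ``closures[i]`` says which side
    breakpoint *i* belongs to: ``"lower"`` puts an exact hit in the interval
    below it, ``"upper"`` in the interval above (the more-polluted label wins
    wherever the printed inequality signs conflict or leave a gap).
    """

    name: str
    breakpoints: tuple[float, ...]
    labels: tuple[str, ...]
    closures: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.breakpoints) + 1:
            raise ValueError("need exactly one more label than breakpoints")
        if any(b >= c for b, c in zip(self.breakpoints, self.breakpoints[1:])):
            raise ValueError("breakpoints must be strictly increasing")
        closures = self.closures or ("upper",) * len(self.breakpoints)
        if len(closures) != len(self.breakpoints):
            raise ValueError("one closure per breakpoint")
        object.__setattr__(self, "closures", closures)

    def classify(self, value: float) -> str:
        if value != value:  # NaN
            raise ValueError(f"cannot classify NaN on scale {self.name!r}")
        if value < 0:
            raise ValueError(f"{self.name} value must be >= 0, got {value}")
        for i, (bp, side) in enumerate(zip(self.breakpoints, self.closures)):
            if value < bp or (value == bp and side == "lower"):
                return self.labels[i]
        return self.labels[-1]


_SCALES: dict[str, ClassificationScale] = {
    # <90 Low, 90–180 Medium, >180 High  (90 and 180 read as Medium)
    "MPI": ClassificationScale(
        "MPI", (90.0, 180.0), ("Low", "Medium", "High"), ("upper", "lower")
    ),
    # <1 Unpolluted, [1,2.5) Slight, [2.5,7) Moderate, >=7 Heavy
    "NPI": ClassificationScale(
        "NPI",
        (1.0, 2.5, 7.0),
        ("Unpolluted", "Slightly polluted", "Moderately polluted", "Heavily polluted"),
    ),
    # decade thresholds; exact hits take the riskier label
    "TCR": ClassificationScale(
        "TCR",
        (1e-6, 1e-5, 1e-4, 1e-3),
        ("Very low", "Low", "Medium", "High", "Very high"),
    ),
    # CV% variability classes: <=15 low, (15,35) intermediate, >=35 high
    "CV": ClassificationScale(
        "CV", (15.0, 35.0), ("low", "intermediate", "high"), ("lower", "upper")
    ),
}


# --- study summary table ---------------------------------------------------

# Published per-source campaign summary: (mean, SD) of the physicochemical
# fields and metal concentrations (mg/L) in water-refilling-station (n=25),
# groundwater (n=26) and tap-water samples.  These are the defaults of the
# synthetic campaign generator and the deterministic inputs for group-mean
# risk chains.
STUDY_GROUP_N: dict[str, int] = {"WRS": 25, "GW": 26, "TW": 21}

_STUDY_SUMMARY: dict[str, dict[str, tuple[float, float]]] = {
    "WRS": {
        "temperature": (26.6, 3.69), "ph": (6.74, 0.89),
        "ec": (51.6, 84.6), "tds": (19.2, 38.8),
        "As": (0.515, 1.86), "Ba": (0.027, 0.02), "Cu": (0.038, 0.08),
        "Fe": (0.178, 0.31), "Pb": (0.371, 0.59), "Mn": (0.009, 0.004),
        "Ni": (0.082, 0.02), "Zn": (0.029, 0.01),
    },
    "GW": {
        "temperature": (29.3, 1.99), "ph": (7.03, 0.48),
        "ec": (680.0, 735.0), "tds": (328.0, 367.0),
        "As": (0.106, 0.19), "Ba": (0.025, 0.02), "Cu": (0.025, 0.06),
        "Fe": (0.901, 2.93), "Pb": (1.23, 3.03), "Mn": (0.009, 0.01),
        "Ni": (0.077, 0.04), "Zn": (0.035, 0.03),
    },
    "TW": {
        "temperature": (29.4, 1.61), "ph": (6.91, 1.03),
        "ec": (378.0, 286.0), "tds": (180.0, 143.0),
        "As": (1.05, 3.84), "Ba": (0.023, 0.02), "Cu": (0.027, 0.09),
        "Fe": (0.138, 0.31), "Pb": (0.432, 0.80), "Mn": (0.010, 0.01),
        "Ni": (0.208, 0.58), "Zn": (0.030, 0.02),
    },
}


def study_summary(source_type: str) -> Mapping[str, tuple[float, float]]:
    """(mean, SD) of every field for one source type of the study campaign."""
    if source_type not in _STUDY_SUMMARY:
        raise LookupError_(f"unknown source type {source_type!r}; expected one of {SOURCE_TYPES}")
    return dict(_STUDY_SUMMARY[source_type])


def study_mean_concentrations(source_type: str) -> dict[str, float]:
    """Published mean metal concentrations (mg/L) for one source type."""
    summ = study_summary(source_type)
    return {m: summ[m][0] for m in METALS}


# --- lookups ----------------------------------------------------------------


def get_standard(metal: str, authority: str = DEFAULT_AUTHORITY) -> MetalStandard:
    """Permissible limit of ``metal`` under ``authority`` (stored, never computed)."""
    if authority not in _STANDARDS:
        raise LookupError_(f"unknown authority {authority!r}; expected one of {AUTHORITIES}")
    try:
        s_i = _STANDARDS[authority][metal]
    except KeyError:
        raise LookupError_(f"unknown metal {metal!r}; expected one of {METALS}") from None
    return MetalStandard(metal=metal, s_i=s_i, authority=authority)


def get_toxicity(metal: str) -> ToxicityEntry:
    """Oral RfD (and SF when carcinogenic) of ``metal``."""
    try:
        rfd, sf = _TOXICITY[metal]
    except KeyError:
        raise LookupError_(f"unknown metal {metal!r}; expected one of {METALS}") from None
    return ToxicityEntry(metal=metal, rfd_oral=rfd, sf_oral=sf)


def get_exposure(cohort: str) -> ExposureParams:
    """Default ingestion-exposure parameters for ``cohort`` ('adult' or 'child')."""
    try:
        p = _EXPOSURE[cohort]
    except KeyError:
        raise LookupError_(f"unknown cohort {cohort!r}; expected 'adult' or 'child'") from None
    return ExposureParams(cohort=cohort, **p)


def get_scale(name: str) -> ClassificationScale:
    try:
        return _SCALES[name]
    except KeyError:
        raise LookupError_(f"unknown scale {name!r}; expected one of {sorted(_SCALES)}") from None


def classify(scale_name: str, value: float) -> str:
    """Map a finite non-negative index value to exactly one category label."""
    return get_scale(scale_name).classify(value)


# --- config round-trip ------------------------------------------------------


def _as_config() -> dict:
    return {
        "standards": {a: dict(v) for a, v in _STANDARDS.items()},
        "toxicity": {
            m: {"rfd_oral": rfd, "sf_oral": sf} for m, (rfd, sf) in _TOXICITY.items()
        },
        "exposure": {c: dict(v) for c, v in _EXPOSURE.items()},
        "scales": {
            n: {
                "breakpoints": list(s.breakpoints),
                "labels": list(s.labels),
                "closures": list(s.closures),
            }
            for n, s in _SCALES.items()
        },
    }


def export_config(path) -> None:
    """Write the compiled-in constants to an editable YAML config file."""
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(_as_config(), fh, sort_keys=True)


def import_config(path) -> dict:
    """Read a constants config written by :func:`export_config`.

    Returns the parsed dictionary (sections ``standards``, ``toxicity``,
    ``exposure``, ``scales``).  Values round-trip bit-exactly: YAML stores the
    shortest decimal repr of each float, which parses back to the same double.
    """
    with open(path, "r", encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    missing = {"standards", "toxicity", "exposure", "scales"} - set(cfg)
    if missing:
        raise ValueError(f"config missing sections: {sorted(missing)}")
    return cfg
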