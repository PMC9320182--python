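"""Synthetic sampling-campaign generator.

Emulates a domestic-water monitoring campaign over three source types
(water refilling stations, groundwater wells, household taps) on an
island-scale planar domain.  Metal concentrations are drawn from per-metal,
per-source lognormal distributions moment-matched to target means and SDs
(defaults: the published study summary in :mod:`aquarisk.reference`);
environmental concentrations are non-negative and strongly right-skewed, and
the study's coefficients of variation (>300% for As in tap water) are
incompatible with a normal model.  Below-detection-limit results are recorded
as zero concentration.

An optional spatial mode superimposes a smooth latent field — a low-order
polynomial trend plus a fixed number of random cosine modes with a configured
correlation length — on the log-concentration of one chosen metal, so that
interpolation methods can be tested against known ground truth
(:func:`make_latent_field` exposes the true field).
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .reference import METALS, SOURCE_TYPES, STUDY_GROUP_N, study_summary

__all__ = [
    "WaterSample",
    "CampaignConfig",
    "CampaignSchemaError",
    "lognormal_params",
    "make_latent_field",
    "generate_campaign",
    "samples_to_frame",
    "frame_to_samples",
    "write_campaign",
    "read_campaign",
    "CAMPAIGN_COLUMNS",
]

CAMPAIGN_COLUMNS = [
    "sample_id", "source_type", "x", "y",
    "temperature_C", "pH", "EC_uScm", "TDS_ppm",
    "As_mgL", "Ba_mgL", "Cu_mgL", "Fe_mgL",
    "Pb_mgL", "Mn_mgL", "Ni_mgL", "Zn_mgL",
]

_METAL_COL = {m: f"{m}_mgL" for m in METALS}


class CampaignSchemaError(ValueError):
    """Campaign table violates the CSV schema (message carries the row number)."""


@dataclass(frozen=True)
class WaterSample:
    """One sampling point: source type, planar coordinates (km unless the
    campaign metadata declares lon/lat degrees), field physicochemistry and
    the eight metal concentrations in mg/L (0 = below detection limit)."""

    sample_id: str
    source_type: str
    x: float
    y: float
    temperature: float  # degC
    ph: float
    ec: float  # uS/cm
    tds: float  # ppm
    conc: dict[str, float]  # metal -> mg/L

    def __post_init__(self) -> None:
        if self.source_type not in SOURCE_TYPES:
            raise ValueError(f"unknown source_type {self.source_type!r}")
        missing = set(METALS) - set(self.conc)
        if missing:
            raise ValueError(f"sample {self.sample_id}: missing metals {sorted(missing)}")
        neg = {m: v for m, v in self.conc.items() if v < 0}
        if neg:
            raise ValueError(f"sample {self.sample_id}: negative concentrations {neg}")


def _default_targets() -> dict[str, dict[str, tuple[float, float]]]:
    return {src: {m: study_summary(src)[m] for m in METALS} for src in SOURCE_TYPES}


def _default_physchem() -> dict[str, dict[str, tuple[float, float]]]:
    keys = ("temperature", "ph", "ec", "tds")
    return {src: {k: study_summary(src)[k] for k in keys} for src in SOURCE_TYPES}


@dataclass
class CampaignConfig:
    """Campaign design: sample counts, concentration targets and spatial field.

    ``conc_targets[source][metal]`` is the target ``(mean, sd)`` in mg/L of the
    moment-matched lognormal; defaults are the published per-source summary.
    ``counts`` defaults to the study design (25 WRS / 26 GW / 21 TW).
    """

    counts: dict[str, int] = field(
        default_factory=lambda: dict(STUDY_GROUP_N)
    )
    conc_targets: dict[str, dict[str, tuple[float, float]]] = field(
        default_factory=_default_targets
    )
    physchem_targets: dict[str, dict[str, tuple[float, float]]] = field(
        default_factory=_default_physchem
    )
    p_lod: dict[str, float] = field(default_factory=lambda: {m: 0.0 for m in METALS})
    lod_substitution: float = 0.0  # value stored for below-LOD draws
    extent: tuple[float, float, float, float] = (0.0, 40.0, 0.0, 30.0)  # xmin,xmax,ymin,ymax km
    spatial_metal: str | None = None  # metal whose log-concentration follows the field
    trend_amplitude: float = 1.0  # field SD in log-concentration units
    correlation_length: float = 8.0  # km; cosine-mode wavelength scale
    n_modes: int = 6
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n < 0 for n in self.counts.values()):
            raise ValueError("sample counts must be >= 0")
        for src, targets in self.conc_targets.items():
            for m, (mean, sd) in targets.items():
                if mean < 0 or sd < 0:
                    raise ValueError(f"{src}/{m}: mean and SD must be >= 0")
        if not all(0.0 <= p <= 1.0 for p in self.p_lod.values()):
            raise ValueError("p_lod must be in [0, 1]")
        if self.correlation_length <= 0:
            raise ValueError("correlation_length must be > 0")


def lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """Moment-match a lognormal to a target mean and SD.

    sigma^2 = ln(1 + sd^2/mean^2),  mu = ln(mean) - sigma^2/2.
    The resulting distribution has analytic mean ``mean`` and SD ``sd``;
    sd = 0 degenerates to a point mass at ``mean``.
    """
    if mean <= 0:
        raise ValueError("moment matching needs mean > 0")
    sigma2 = math.log1p((sd / mean) ** 2)
    mu = math.log(mean) - sigma2 / 2.0
    return mu, math.sqrt(sigma2)


def make_latent_field(config: CampaignConfig) -> Callable[[np.ndarray, np.ndarray], np.ndarray]:
    """Smooth ground-truth field on the campaign domain.

    Superposition of a low-order polynomial trend and ``n_modes`` random
    cosine modes whose wavelengths sit at the configured correlation length.
    Deterministic given the config seed; normalised to zero mean and SD
    ``trend_amplitude`` over the domain (estimated on a dense grid).
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x5F1E1D]))
    xmin, xmax, ymin, ymax = config.extent
    span = max(xmax - xmin, ymax - ymin)

    # linear + quadratic trend coefficients on unit-normalised coordinates
    coef = rng.normal(size=5)
    # cosine modes: wavevector magnitude ~ 2*pi / correlation length
    k = 2.0 * math.pi / config.correlation_length
    angles = rng.uniform(0.0, 2.0 * math.pi, size=config.n_modes)
    scales = rng.uniform(0.7, 1.3, size=config.n_modes)
    phases = rng.uniform(0.0, 2.0 * math.pi, size=config.n_modes)
    amps = rng.normal(size=config.n_modes)

    def raw(x: np.ndarray, y: np.ndarray) -> np.ndarray:
        u = (np.asarray(x, dtype=float) - xmin) / span
        v = (np.asarray(y, dtype=float) - ymin) / span
        out = coef[0] * u + coef[1] * v + coef[2] * u * v + coef[3] * u**2 + coef[4] * v**2
        for j in range(config.n_modes):
            kx = k * scales[j] * math.cos(angles[j])
            ky = k * scales[j] * math.sin(angles[j])
            out = out + amps[j] * np.cos(kx * np.asarray(x, float) + ky * np.asarray(y, float) + phases[j])
        return out

    gx, gy = np.meshgrid(np.linspace(xmin, xmax, 60), np.linspace(ymin, ymax, 60))
    vals = raw(gx.ravel(), gy.ravel())
    mu, sd = float(vals.mean()), float(vals.std())
    if sd == 0.0:
        sd = 1.0

    def fieldf(x: np.ndarray, y: np.ndarray) -> np.ndarray:
        return (raw(x, y) - mu) / sd * config.trend_amplitude

    return fieldf


def generate_campaign(config: CampaignConfig) -> list[WaterSample]:
    """Draw a full campaign: exact per-source counts, lognormal concentrations,
    truncated-normal physicochemistry, uniform coordinates (field-modulated
    log-concentration for ``spatial_metal`` when spatial mode is on)."""
    rng = np.random.default_rng(config.seed)
    fieldf = make_latent_field(config) if config.spatial_metal else None
    xmin, xmax, ymin, ymax = config.extent

    samples: list[WaterSample] = []
    idx = 0
    for src in SOURCE_TYPES:
        n = config.counts.get(src, 0)
        for _ in range(n):
            idx += 1
            x = float(rng.uniform(xmin, xmax))
            y = float(rng.uniform(ymin, ymax))
            phys = {}
            for key, (m, s) in config.physchem_targets[src].items():
                lo, hi = (0.0, 14.0) if key == "ph" else (0.0, math.inf)
                v = float(rng.normal(m, s))
                phys[key] = min(max(v, lo), hi)
            conc: dict[str, float] = {}
            for metal in METALS:
                mean, sd = config.conc_targets[src][metal]
                if rng.uniform() < config.p_lod.get(metal, 0.0):
                    conc[metal] = config.lod_substitution
                    continue
                if mean == 0.0:
                    conc[metal] = 0.0
                    continue
                mu, sigma = lognormal_params(mean, sd)
                if fieldf is not None and metal == config.spatial_metal:
                    mu = mu + float(fieldf(np.array([x]), np.array([y]))[0])
                conc[metal] = float(np.exp(mu + sigma * rng.standard_normal())) if sigma > 0 else float(np.exp(mu))
            samples.append(
                WaterSample(
                    sample_id=f"{src}-{idx:03d}",
                    source_type=src,
                    x=x,
                    y=y,
                    temperature=phys["temperature"],
                    ph=phys["ph"],
                    ec=phys["ec"],
                    tds=phys["tds"],
                    conc=conc,
                )
            )
    return samples


# --- tabular I/O ------------------------------------------------------------


def samples_to_frame(samples: Sequence[WaterSample]) -> pd.DataFrame:
    rows = []
    for s in samples:
        row = {
            "sample_id": s.sample_id, "source_type": s.source_type,
            "x": s.x, "y": s.y, "temperature_C": s.temperature,
            "pH": s.ph, "EC_uScm": s.ec, "TDS_ppm": s.tds,
        }
        for m in METALS:
            row[_METAL_COL[m]] = s.conc[m]
        rows.append(row)
    return pd.DataFrame(rows, columns=CAMPAIGN_COLUMNS)


def frame_to_samples(df: pd.DataFrame) -> list[WaterSample]:
    missing = [c for c in CAMPAIGN_COLUMNS if c not in df.columns]
    if missing:
        raise CampaignSchemaError(f"missing required columns: {missing}")
    samples = []
    for i, row in enumerate(df.itertuples(index=False)):
        rec = dict(zip(df.columns, row))
        if rec["source_type"] not in SOURCE_TYPES:
            raise CampaignSchemaError(
                f"row {i}: unknown source_type {rec['source_type']!r}"
            )
        conc = {}
        for m in METALS:
            v = float(rec[_METAL_COL[m]])
            if not math.isfinite(v) or v < 0:
                raise CampaignSchemaError(f"row {i}: invalid {m} concentration {v}")
            conc[m] = v
        samples.append(
            WaterSample(
                sample_id=str(rec["sample_id"]),
                source_type=str(rec["source_type"]),
                x=float(rec["x"]), y=float(rec["y"]),
                temperature=float(rec["temperature_C"]), ph=float(rec["pH"]),
                ec=float(rec["EC_uScm"]), tds=float(rec["TDS_ppm"]),
                conc=conc,
            )
        )
    return samples


def write_campaign(
    samples: Sequence[WaterSample],
    path,
    *,
    coordinate_convention: str = "planar_km",
    seed: int | None = None,
) -> None:
    """Write the campaign CSV plus a JSON metadata sidecar (``<path>.meta.json``)."""
    path = Path(path)
    # %.17g round-trips any double exactly
    samples_to_frame(samples).to_csv(path, index=False, float_format="%.17g")
    meta = {"coordinate_convention": coordinate_convention, "seed": seed,
            "n_samples": len(samples)}
    path.with_suffix(path.suffix + ".meta.json").write_text(
        json.dumps(meta, indent=1), encoding="utf-8"
    )


def read_campaign(path) -> list[WaterSample]:
    """Read a campaign CSV, validating the schema row by row."""
    df = pd.read_csv(path, float_precision="round_trip")
    return frame_to_samples(df)
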