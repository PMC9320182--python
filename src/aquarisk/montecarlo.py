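"""Monte Carlo propagation of input uncertainty through the cancer-risk chain.

Each uncertain input of CR = C * IR * EF * ED / (BW * AT) * SF is described by
a :class:`DistributionSpec`; a seeded run draws all inputs independently
(draw order fixed alphabetically by variable name so seeds are portable),
evaluates CR per draw and summarises the output distribution (mean, empirical
p5/p50/p95 with linear interpolation).

Sensitivity is the contribution-to-variance convention of spreadsheet risk
add-ins: for each varying input compute the Spearman rank correlation rho_i
with the output, then

    contribution_i = sign(rho_i) * rho_i^2 / sum_j rho_j^2 * 100  [%]

so numerator variables (concentration, IR, EF, ED, SF) report positive
contributions and denominator variables (BW, AT) negative ones.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sps

from .reference import ExposureParams, get_exposure, get_toxicity

__all__ = [
    "DistributionSpec",
    "MCSummary",
    "fit_input_distributions",
    "run_mc",
    "sensitivity",
    "histogram_export",
]

_FAMILIES = ("lognormal", "normal", "triangular", "uniform", "point")

#: CR-equation variables that enter the numerator / denominator.
NUMERATOR_VARS = ("concentration", "ir", "ef", "ed", "sf")
DENOMINATOR_VARS = ("bw", "at")


@dataclass(frozen=True)
class DistributionSpec:
    """Distribution of one input variable.

    parameters by family:
      lognormal   mu, sigma   (log-scale; use :func:`from_moments` for mean/SD)
      normal      mean, sd
      triangular  low, mode, high
      uniform     low, high
      point       value
    Optional truncation clamps draws into [lower, upper].
    """

    variable: str
    family: str
    parameters: dict[str, float]
    truncation: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        if self.truncation is not None:
            lo, hi = self.truncation
            if not lo < hi:
                raise ValueError("truncation lower bound must be < upper")

    @classmethod
    def from_moments(cls, variable: str, mean: float, sd: float) -> "DistributionSpec":
        """Lognormal moment-matched to (mean, sd); point mass when sd == 0."""
        if mean <= 0:
            raise ValueError("lognormal moment matching needs mean > 0")
        if sd == 0:
            return cls(variable, "point", {"value": mean})
        sigma2 = np.log1p((sd / mean) ** 2)
        mu = np.log(mean) - sigma2 / 2.0
        return cls(variable, "lognormal", {"mu": float(mu), "sigma": float(np.sqrt(sigma2))})

    @property
    def is_point(self) -> bool:
        return self.family == "point"

    def draw(self, rng: np.random.Generator, n: int) -> np.ndarray:
        p = self.parameters
        if self.family == "point":
            out = np.full(n, p["value"], dtype=float)
        elif self.family == "lognormal":
            out = rng.lognormal(p["mu"], p["sigma"], size=n)
        elif self.family == "normal":
            out = rng.normal(p["mean"], p["sd"], size=n)
        elif self.family == "triangular":
            out = rng.triangular(p["low"], p["mode"], p["high"], size=n)
        else:  # uniform
            out = rng.uniform(p["low"], p["high"], size=n)
        if self.truncation is not None:
            out = np.clip(out, *self.truncation)
        return out

    def analytic_mean(self) -> float:
        """Mean of the untruncated distribution (closed form)."""
        p = self.parameters
        if self.family == "point":
            return p["value"]
        if self.family == "lognormal":
            return float(np.exp(p["mu"] + p["sigma"] ** 2 / 2.0))
        if self.family == "normal":
            return p["mean"]
        if self.family == "triangular":
            return (p["low"] + p["mode"] + p["high"]) / 3.0
        return (p["low"] + p["high"]) / 2.0


@dataclass(frozen=True)
class MCSummary:
    """Result of one Monte Carlo run for one (metal, cohort) target."""

    target: tuple[str, str]  # (metal, cohort)
    n_iter: int
    seed: int
    mean: float
    p5: float
    p50: float
    p95: float
    sensitivity: dict[str, float]  # variable -> signed contribution, %
    specs: tuple[DistributionSpec, ...] = field(default=(), repr=False)

    def to_dict(self) -> dict:
        return {
            "target": {"metal": self.target[0], "cohort": self.target[1]},
            "n_iter": self.n_iter,
            "seed": self.seed,
            "mean": self.mean,
            "p5": self.p5,
            "p50": self.p50,
            "p95": self.p95,
            "sensitivity": dict(self.sensitivity),
            "specs": [
                {
                    "variable": s.variable,
                    "family": s.family,
                    "parameters": dict(s.parameters),
                    "truncation": list(s.truncation) if s.truncation else None,
                }
                for s in self.specs
            ],
        }


def fit_input_distributions(
    concentrations: Sequence[float],
    cohort: str | ExposureParams,
    *,
    metal: str = "concentration",
    uncertain_exposure: bool = False,
) -> list[DistributionSpec]:
    """Distribution specs for one metal's CR simulation.

    The concentration gets a lognormal moment-matched to the positive sample
    moments (all-zero vectors degenerate to a point at 0 with a warning);
    exposure variables default to point masses at the cohort values, or — with
    ``uncertain_exposure`` — normal BW (CV 10%) and uniform IR (+/-25%), a
    profile meant for sensitivity studies.
    """
    c = np.asarray(list(concentrations), dtype=float)
    if c.size < 3:
        raise ValueError("need at least 3 concentration values to fit")
    if (c < 0).any():
        raise ValueError("negative concentration in input")
    if (c > 0).any():
        mean = float(c.mean())
        sd = float(c.std(ddof=1))
        conc_spec = DistributionSpec.from_moments("concentration", mean, sd)
    else:
        warnings.warn(f"{metal}: all-zero concentrations; degenerate point at 0")
        conc_spec = DistributionSpec("concentration", "point", {"value": 0.0})

    p = cohort if isinstance(cohort, ExposureParams) else get_exposure(cohort)
    if uncertain_exposure:
        bw = DistributionSpec("bw", "normal", {"mean": p.bw, "sd": 0.1 * p.bw},
                              truncation=(1e-6, 10.0 * p.bw))
        ir = DistributionSpec("ir", "uniform", {"low": 0.75 * p.ir, "high": 1.25 * p.ir})
    else:
        bw = DistributionSpec("bw", "point", {"value": p.bw})
        ir = DistributionSpec("ir", "point", {"value": p.ir})
    return [
        conc_spec,
        ir,
        DistributionSpec("ef", "point", {"value": p.ef}),
        DistributionSpec("ed", "point", {"value": p.ed}),
        bw,
        DistributionSpec("at", "point", {"value": p.at}),
    ]


def _evaluate_cr(draws: Mapping[str, np.ndarray]) -> np.ndarray:
    return (
        draws["concentration"] * draws["ir"] * draws["ef"] * draws["ed"]
        / (draws["bw"] * draws["at"]) * draws["sf"]
    )


def run_mc(
    specs: Sequence[DistributionSpec],
    metal: str,
    cohort: str,
    n_iter: int = 10_000,
    seed: int = 0,
) -> MCSummary:
    """Propagate the input distributions through CR for one carcinogen.

    A slope-factor spec may be included in ``specs``; otherwise the stored SF
    of ``metal`` is used as a point mass (an error if the metal has none).
    Fixed seed implies identical output; variables are drawn in alphabetical
    order from one generator.
    """
    if n_iter < 100:
        raise ValueError("n_iter must be >= 100")
    by_var = {s.variable: s for s in specs}
    if "sf" not in by_var:
        tox = get_toxicity(metal)
        if not tox.is_carcinogen:
            raise ValueError(f"{metal} has no slope factor (not a carcinogen)")
        by_var["sf"] = DistributionSpec("sf", "point", {"value": tox.sf_oral})
    missing = {"concentration", "ir", "ef", "ed", "bw", "at", "sf"} - set(by_var)
    if missing:
        raise ValueError(f"missing distribution specs: {sorted(missing)}")

    rng = np.random.default_rng(seed)
    draws = {v: by_var[v].draw(rng, n_iter) for v in sorted(by_var)}
    out = _evaluate_cr(draws)
    p5, p50, p95 = np.percentile(out, [5, 50, 95])  # linear interpolation
    sens = sensitivity(draws, out)
    return MCSummary(
        target=(metal, cohort),
        n_iter=n_iter,
        seed=seed,
        mean=float(out.mean()),
        p5=float(p5),
        p50=float(p50),
        p95=float(p95),
        sensitivity=sens,
        specs=tuple(by_var[v] for v in sorted(by_var)),
    )


def sensitivity(
    input_draws: Mapping[str, np.ndarray], output: np.ndarray
) -> dict[str, float]:
    """Signed contribution-to-variance (%) of each varying input.

    Spearman rank correlation rho_i between input and output; contribution
    = sign(rho_i) * rho_i^2 normalised over varying inputs to 100% in absolute
    value.  Constant inputs report 0; a zero-variance output reports all 0
    with a warning.
    """
    output = np.asarray(output, dtype=float)
    n = output.size
    if n < 100:
        raise ValueError("need >= 100 draws for sensitivity")
    for v, d in input_draws.items():
        if len(d) != n:
            raise ValueError(f"input {v!r} length {len(d)} != output length {n}")
    contrib = {v: 0.0 for v in input_draws}
    if np.ptp(output) == 0.0:
        warnings.warn("zero-variance output: contributions undefined, reported as 0")
        return contrib
    rhos: dict[str, float] = {}
    for v, d in input_draws.items():
        d = np.asarray(d, dtype=float)
        if np.ptp(d) == 0.0:
            continue
        rho = sps.spearmanr(d, output).statistic
        if np.isfinite(rho):
            rhos[v] = float(rho)
    total = sum(r * r for r in rhos.values())
    if total == 0.0:
        return contrib
    for v, r in rhos.items():
        contrib[v] = float(np.sign(r) * r * r / total * 100.0)
    return contrib


def histogram_export(values: np.ndarray, bins: int = 50) -> "np.recarray":
    """Histogram as (bin_left, bin_right, count) rows for CSV plotting export."""
    counts, edges = np.histogram(np.asarray(values, float), bins=bins)
    rec = np.recarray(counts.size, dtype=[("bin_left", float), ("bin_right", float), ("count", int)])
    rec.bin_left = edges[:-1]
    rec.bin_right = edges[1:]
    rec.count = counts
    return rec
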