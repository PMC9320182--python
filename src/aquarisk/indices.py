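"""Heavy-metal pollution indices: MPI, SFPI and NPI.

MPI is the weighted arithmetic mean of per-metal quality ratings
Q_i = (C_i / S_i) * 100 with weights W_i = 1 / S_i (inverse permissible
limit), so the scarcest-tolerated metals dominate:

    MPI = sum(Q_i * W_i) / sum(W_i)

SFPI (single-factor pollution index) is the plain exceedance ratio
C_i / S_i; values above 1 mean the metal exceeds its standard.  NPI
(Nemerow pollution index) is the root mean square of the maximum and the
mean SFPI, emphasising the worst single pollutant:

    NPI = sqrt((SFPI_max^2 + SFPI_mean^2) / 2)

All three are unit-free and invariant to a common rescaling of
concentrations and standards.  Metals reported as 0 (below detection) are
kept in the summations with Q_i = 0; dropping them would change sum(W_i).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .campaign import WaterSample
from .reference import DEFAULT_AUTHORITY, METALS, classify, get_standard

__all__ = [
    "IndexResult",
    "quality_rating",
    "sfpi",
    "npi",
    "mpi",
    "sample_indices",
    "index_table",
    "group_indices",
]


@dataclass(frozen=True)
class IndexResult:
    """Per-sample pollution indices with category labels."""

    sample_id: str
    mpi: float
    mpi_label: str
    sfpi: dict[str, float]
    npi: float
    npi_label: str


def quality_rating(c_i: float, s_i: float) -> float:
    """Quality rating Q_i = (C_i / S_i) * 100 of one metal.

    ``c_i``: measured concentration, mg/L; ``s_i``: permissible limit, mg/L.
    """
    if s_i <= 0:
        raise ValueError(f"permissible limit must be > 0, got {s_i}")
    if c_i < 0:
        raise ValueError(f"concentration must be >= 0, got {c_i}")
    return c_i / s_i * 100.0


def sfpi(c_i: float, s_i: float) -> float:
    """Single-factor pollution index C_i / S_i (Q_i / 100)."""
    return quality_rating(c_i, s_i) / 100.0


def npi(sfpi_values: Iterable[float]) -> float:
    """Nemerow index from a collection of per-metal SFPI values."""
    vals = np.asarray(list(sfpi_values), dtype=float)
    if vals.size == 0:
        raise ValueError("npi needs at least one SFPI value")
    return math.sqrt((vals.max() ** 2 + vals.mean() ** 2) / 2.0)


def _standards_for(metals: Sequence[str], authority: str) -> dict[str, float]:
    return {m: get_standard(m, authority).s_i for m in metals}


def mpi(
    conc: Mapping[str, float] | WaterSample,
    authority: str = DEFAULT_AUTHORITY,
    *,
    standards: Mapping[str, float] | None = None,
) -> float:
    """Weighted-arithmetic-mean pollution index of one sample.

    ``conc`` is a metal -> mg/L mapping (or a :class:`WaterSample`); limits
    come from one authority (mixing authorities in one MPI is not allowed —
    pass explicit ``standards`` to override the stored table).
    """
    if isinstance(conc, WaterSample):
        conc = conc.conc
    metals = list(conc)
    std = dict(standards) if standards is not None else _standards_for(metals, authority)
    missing = [m for m in metals if m not in std]
    if missing:
        raise ValueError(f"no standard for metals {missing}")
    num = 0.0
    den = 0.0
    for m in metals:
        w = 1.0 / std[m]
        num += quality_rating(conc[m], std[m]) * w
        den += w
    return num / den


def sample_indices(
    sample: WaterSample, authority: str = DEFAULT_AUTHORITY
) -> IndexResult:
    """MPI, per-metal SFPI and NPI of one sample, with category labels."""
    std = _standards_for(METALS, authority)
    sf = {m: sfpi(sample.conc[m], std[m]) for m in METALS}
    mpi_val = mpi(sample.conc, authority)
    npi_val = npi(sf.values())
    return IndexResult(
        sample_id=sample.sample_id,
        mpi=mpi_val,
        mpi_label=classify("MPI", mpi_val),
        sfpi=sf,
        npi=npi_val,
        npi_label=classify("NPI", npi_val),
    )


def index_table(
    samples: Sequence[WaterSample], authority: str = DEFAULT_AUTHORITY
) -> pd.DataFrame:
    """One row per sample: mpi, mpi_label, npi, npi_label, sfpi_<metal>..."""
    rows = []
    for s in samples:
        r = sample_indices(s, authority)
        row = {
            "sample_id": r.sample_id,
            "source_type": s.source_type,
            "mpi": r.mpi,
            "mpi_label": r.mpi_label,
            "npi": r.npi,
            "npi_label": r.npi_label,
        }
        for m in METALS:
            row[f"sfpi_{m}"] = r.sfpi[m]
        rows.append(row)
    return pd.DataFrame(rows)


def group_indices(
    samples: Sequence[WaterSample], authority: str = DEFAULT_AUTHORITY
) -> pd.DataFrame:
    """Group-level (per source type) indices, computed both ways.

    ``*_of_means``: index of the group-mean concentration vector.
    ``mean_of_*``:  mean of the per-sample indices.
    The two differ whenever concentrations vary within the group (the index
    of means is not the mean of indices for NPI, which is nonlinear).
    """
    per_sample = index_table(samples, authority)
    std = _standards_for(METALS, authority)
    rows = []
    for src, grp in per_sample.groupby("source_type", sort=False):
        members = [s for s in samples if s.source_type == src]
        mean_conc = {m: float(np.mean([s.conc[m] for s in members])) for m in METALS}
        mpi_of_means = mpi(mean_conc, authority)
        npi_of_means = npi(sfpi(mean_conc[m], std[m]) for m in METALS)
        rows.append(
            {
                "source_type": src,
                "n": len(members),
                "mpi_of_means": mpi_of_means,
                "mpi_of_means_label": classify("MPI", mpi_of_means),
                "mean_of_mpi": float(grp["mpi"].mean()),
                "npi_of_means": npi_of_means,
                "npi_of_means_label": classify("NPI", npi_of_means),
                "mean_of_npi": float(grp["npi"].mean()),
            }
        )
    return pd.DataFrame(rows)
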