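"""Deterministic pollution indices and ingestion-risk chain.

Runs the full index + risk chain on the package's compiled-in study summary
(mean tap-water concentrations) and prints each published-style quantity.
"""

from aquarisk import assess, classify, mpi, npi, sfpi
from aquarisk.reference import METALS, get_standard, study_mean_concentrations

tw = study_mean_concentrations("TW")
std = {m: get_standard(m, "PNSDW").s_i for m in METALS}

mpi_val = mpi(tw)
npi_val = npi(sfpi(tw[m], std[m]) for m in METALS)
print(f"MPI  = {mpi_val:8.1f}  ({classify('MPI', mpi_val)} pollution)")
print(f"NPI  = {npi_val:8.2f}  ({classify('NPI', npi_val)})")

for cohort in ("adult", "child"):
    r = assess(tw, cohort, subject="TW")
    print(f"\n--- tap water, {cohort} ---")
    print(f"CDI(As) = {r.cdi['As']:.4f} mg/kg-day")
    print(f"HQ(As)  = {r.hq['As']:.1f}   HI = {r.hi:.1f}  (HI > 1 -> non-cancer concern)")
    print(f"CR(As)  = {r.cr['As']:.3e}  TCR = {r.tcr:.3e}  [{r.tcr_label}]")
    shares = ", ".join(f"{m} {s:.1f}%" for m, s in r.cr_shares.items())
    print(f"share of TCR: {shares}")

# An MPI in the thousands (>180 'High') and a TCR far above the 1e-4 action
# threshold both say the same thing: arsenic dominates the hazard in this
# source type, for adults and children alike.
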