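"""Monte Carlo cancer-risk propagation with sensitivity analysis.

Fits a lognormal to synthetic tap-water arsenic concentrations, propagates
10,000 draws through CR = C*IR*EF*ED/(BW*AT)*SF with an uncertain-exposure
profile, and prints the risk distribution and each input's signed
contribution to variance.
"""

from aquarisk import CampaignConfig, generate_campaign, run_mc
from aquarisk.montecarlo import fit_input_distributions

samples = generate_campaign(CampaignConfig(seed=3))
conc = [s.conc["As"] for s in samples if s.source_type == "TW"]

specs = fit_input_distributions(conc, "adult", metal="As", uncertain_exposure=True)
summary = run_mc(specs, "As", "adult", n_iter=10_000, seed=3)

print(f"TCR(As, adult): mean {summary.mean:.2e}")
print(f"  5th / 50th / 95th percentile: {summary.p5:.2e} / {summary.p50:.2e} / {summary.p95:.2e}")
print("sensitivity (signed contribution to variance):")
for var, pct in sorted(summary.sensitivity.items(), key=lambda kv: -abs(kv[1])):
    if pct != 0.0:
        print(f"  {var:14s} {pct:+6.1f} %")

# Concentration dominates with a positive sign (more metal, more risk); body
# weight contributes negatively (heavier bodies dilute the dose).
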