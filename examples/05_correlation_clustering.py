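"""Correlation structure and hierarchical clustering of metals.

Computes the Pearson correlation matrix of the water-quality variables for
tap water and clusters the eight metals from their z-scored sample profiles
(Ward linkage), printing the two-cluster partition.
"""

from aquarisk import CampaignConfig, cluster_metals, generate_campaign
from aquarisk.campaign import samples_to_frame
from aquarisk.reference import METALS
from aquarisk.stats import correlation_long, correlation_matrix

df = samples_to_frame(generate_campaign(CampaignConfig(seed=11)))
tw = df[df.source_type == "TW"]

variables = ["EC_uScm", "TDS_ppm"] + [f"{m}_mgL" for m in METALS]
r, p = correlation_matrix(tw, variables)
long = correlation_long(r, p)
strong = long[long["p"] < 0.01].sort_values("r", ascending=False)
print("significant correlations (p < 0.01):")
print(strong.to_string(index=False))

tree = cluster_metals(tw, [f"{m}_mgL" for m in METALS])
print("\ntwo-cluster cut of the metal dendrogram:")
for label, cid in tree.cut(2).items():
    print(f"  {label.removesuffix('_mgL'):3s} -> cluster {cid}")

# Metals that co-vary across samples (a shared origin, e.g. mine drainage)
# land in the same cluster; EC-TDS is the expected physicochemical pair.
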