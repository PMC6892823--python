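"""Compare prey profiles across samples: Bray–Curtis similarity, UPGMA
dendrogram (Newick), and cross-marker detection concordance.

Samples sharing prey cluster together at low merge height; the concordance
table counts, per (sample, taxon), detections corroborated by both markers.
"""
from preyid import (
    SampleProfile,
    average_linkage_cluster,
    detection_matrix,
    marker_concordance,
    similarity_matrix,
)

profiles_12s = [
    SampleProfile("SF7", "12S", {"Bairdiella chrysoura": 6000, "Anchoa mitchilli": 4000}),
    SampleProfile("SF8", "12S", {"Bairdiella chrysoura": 5000, "Anchoa mitchilli": 5000}),
    SampleProfile("SF9", "12S", {"Elops saurus": 10000}),
]
profiles_16s = [
    SampleProfile("SF7", "16S", {"Bairdiella chrysoura": 7000, "Eucinostomus harengulus": 3000}),
    SampleProfile("SF8", "16S", {"Anchoa mitchilli": 10000}),
    SampleProfile("SF9", "16S", {"Elops saurus": 10000}),
]

sim = similarity_matrix(profiles_12s)
print("Bray-Curtis similarity (12S):")
print(sim.round(3).to_string())
dendro = average_linkage_cluster(sim)
print("UPGMA merge heights:", [round(h, 3) for h in dendro.merge_heights])
print("newick:", dendro.to_newick())

conc = marker_concordance(detection_matrix(profiles_12s), detection_matrix(profiles_16s))
print("cross-marker detection classification counts:", conc.counts)
print(
    f"12S instances {conc.instances_12s} (corroborated {conc.corroborated_12s}), "
    f"16S instances {conc.instances_16s} (corroborated {conc.corroborated_16s})"
)
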