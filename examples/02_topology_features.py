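"""Regulator topology features on a small hand-built network.

NTG is a miRNA's out-degree; NSR counts its targets regulated by no other
miRNA (in-degree 1, the vulnerable "single-line" points); NSR/NTG is the
exclusively-controlled fraction.  The second part recomputes the published
worked-example ratios for the nine prostate-cancer biomarker miRNAs from
their reported NTG/NSR pairs.
"""

from mirmark import BipartiteNetwork, compute_nsr, compute_ntg, compute_ratio

net = BipartiteNetwork.from_edges(
    [("miR-a", "g1"), ("miR-a", "g2"), ("miR-a", "g3"), ("miR-b", "g3"), ("miR-b", "g4")]
)
for m in ("miR-a", "miR-b"):
    ntg = compute_ntg(net, m)
    nsr = compute_nsr(net, m)
    print(f"{m}: NTG={ntg} NSR={nsr} NSR/NTG={compute_ratio(ntg, nsr)}")
# miR-a targets g1,g2,g3 but only g1,g2 exclusively (g3 is co-regulated):
# NTG=3, NSR=2.  miR-b: NTG=2, NSR=1 (g4 only).

print()
print("published worked example (occurrence network):")
for mirna, ntg, nsr in [
    ("hsa-miR-1-3p", 69, 15), ("hsa-miR-198", 50, 14), ("hsa-miR-22-3p", 83, 19),
]:
    print(f"  {mirna}: NTG={ntg} NSR={nsr} -> NSR/NTG={compute_ratio(ntg, nsr)}")
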