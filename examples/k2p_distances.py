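"""K2P sequence divergences: the molecular evidence for a species split.

Simulates a two-species alignment under the K2P model, then summarizes
intra- and interspecific pairwise distances with pairwise deletion of gaps.
A clean split shows minimum interspecific divergence well above the maximum
intraspecific one.
"""

from mra import distance_summary, k2p_distance
from mra.synthetic import simulate_k2p_alignment

d = k2p_distance("AACGTACGTC", "GACGTACGTC")
print(f"single A<->G transition among 10 sites: d = {d:.5f} "
      "(the K2P closed form -0.5 ln 0.8)")

aln = simulate_k2p_alignment(n_per_species=5, length=1000,
                             d_within=0.02, d_between=0.2, seed=42)
summary = distance_summary(aln)
print("\nintraspecific K2P divergences (min / mean / max):")
print(summary.intraspecific.round(4).to_string())
print("\ninterspecific K2P divergences:")
print(summary.interspecific.round(4).to_string())

gap = (summary.interspecific["min"].iloc[0]
       - summary.intraspecific["max"].max())
print(f"\nbarcode gap = {gap:.3f}: interspecific divergence exceeds all "
      "within-species variation, supporting two species")
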