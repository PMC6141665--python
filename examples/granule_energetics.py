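"""Estimate the glucose content of glycogen granules from their diameter.

Glycogen grows in ~1.9 nm concentric tiers of branching chains (~13 glucose
residues per chain, branching degree 2), so the residue count rises
exponentially with diameter: GR(d) = 13 * (2**(d / 3.8) - 1).
"""

from glycopap import GrParams, glucose_residues

params = GrParams()  # 13 residues/chain, branching 2, tier 1.9 nm
print(f"defaults: {params}")
for d in (0.0, 3.8, 20.0, 26.3, 27.2, 42.0):
    print(f"diameter {d:5.1f} nm -> {glucose_residues(d, params):10.1f} glucose residues")

# A granule spanning exactly one tier (d = 2L = 3.8 nm) holds one chain's worth
# of residues (13); typical cortical granules (~27 nm) hold a couple of thousand.
# Because GR is convex in d, the mean GR of a granule population exceeds GR of
# the mean diameter - populations with the same mean size but wider spread
# store more glucose.
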