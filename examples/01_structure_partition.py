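"""Generate a synthetic plastome and infer its quadripartite structure.

Builds a full-size circular plastome (LSC 87.6 kb, IRs 30.5 kb, SSC
13.4 kb, 80 genes), detects the inverted repeats, and canonicalizes the
genome.  The detected region lengths should match the generating
parameters exactly, and canonicalization should be a no-op on an
already-canonical genome.
"""

from plastidqc import canonicalize, detect_inverted_repeat
from plastidqc.simulate import PlastomeSpec, generate_plastome

plastome = generate_plastome(PlastomeSpec(seed=1))
print(f"generated genome: {len(plastome.genome):,} bp, {len(plastome.genes)} genes")

partition = detect_inverted_repeat(plastome.genome)
print(f"detected IR length: {partition.ir_length:,} bp "
      f"(mismatches between arms: {partition.ir_mismatches})")
for name, length in partition.region_lengths.items():
    print(f"  {name}: {length:,} bp")

canonical = canonicalize(plastome.genome, partition)
print("canonical form identical to generated genome:",
      canonical.residues == plastome.genome.residues)
# The four region lengths are the quadripartite fingerprint used in all
# downstream assembly comparisons; exact recovery of the planted 30,500 bp
# arm shows the detector finds maximal exact reverse-complement repeats.
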