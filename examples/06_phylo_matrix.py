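"""Prepare a partitioned phylogenetic supermatrix.

Extracts coding/intron/spacer regions from an annotated genome, codes
alignment gaps as binary characters (simple indel coding), and exports a
concatenated supermatrix with a nucleotide and a binary partition.
"""

from plastidqc.phylo import concatenate_partitions, extract_regions, simple_indel_coding
from plastidqc.simulate import PlastomeSpec, generate_plastome

plastome = generate_plastome(
    PlastomeSpec(lsc_len=30_000, ssc_len=6_000, ir_len=9_000, n_genes=40, seed=1)
)
regions = extract_regions(plastome.genome, plastome.genes)
n_cod, n_int, n_spa = regions.counts
print(f"extracted {n_cod} coding regions, {n_int} introns, {n_spa} intergenic spacers")

# a toy 3-taxon alignment of one region with one shared deletion
alignment = {
    "taxonA": "ATGAAACCC---GGGTAA",
    "taxonB": "ATGAAACCCTTTGGGTAA",
    "taxonC": "ATGAAACCC---GGGTAA",
}
indels = simple_indel_coding(alignment)
print(f"indel characters: {indels.characters}")
for taxon, states in sorted(indels.states.items()):
    print(f"  {taxon}: {states}")

supermatrix = concatenate_partitions({"toy_region": alignment}, indels)
print(f"supermatrix: {len(supermatrix.matrix)} taxa x {supermatrix.length} characters")
for name, start, end, datatype in supermatrix.partitions:
    print(f"  partition {name}: columns {start + 1}-{end} ({datatype})")
supermatrix.write_phylip("/tmp/supermatrix.phy")
supermatrix.write_raxml_partitions("/tmp/partitions.txt")
print("wrote /tmp/supermatrix.phy and /tmp/partitions.txt")
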