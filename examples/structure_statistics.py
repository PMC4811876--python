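"""Gene-structure statistics of the curated grapevine GRAS family.

Loads the bundled 52-locus table and prints the exon/intron and chromosome
distribution: how many genes are intronless (a hallmark of this family), and
which chromosomes carry the LISCL tandem clusters.
"""

from grasfam import grapevine_gras_table, summarize

table = grapevine_gras_table()
s = summarize(table)

print(f"loci: {s.n_loci}")
print(f"intronless: {s.n_intronless} ({s.pct_intronless}%)")
print(f"exon-count histogram: {s.exon_count_histogram}")
print(f"genes on chr6 / chr13: {s.per_chromosome_counts[6]} / {s.per_chromosome_counts[13]}")
print(f"single-gene chromosomes: {s.singleton_chromosomes}")
span, spliced = s.length_table["Vitvi02g00974"]
print(f"VviSCL3b (truncated pseudogene candidate): {spliced} nt spliced")
# Most of the family is single-exon; the high chr6/chr13 counts come from
# the tandem LISCL arrays, and the 294-nt SCL3b is the family's shortest gene.
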