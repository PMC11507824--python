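"""Extract an exon-length series from a GFF3 annotation.

Builds a tiny in-memory GFF3, parses its exon features and orders them along
the chromosome.  The printed lengths are end - start + 1 (1-based inclusive
coordinates), and the series index is the exon ordinal, not the coordinate.
"""

from qexon import build_series, parse_exons

GFF3 = """##gff-version 3
chr1\tdemo\tgene\t101\t470\t.\t+\t.\tID=g1
chr1\tdemo\texon\t101\t200\t.\t+\t.\tParent=g1
chr1\tdemo\texon\t301\t450\t.\t+\t.\tParent=g1
chr1\tdemo\texon\t460\t470\t.\t+\t.\tParent=g1
"""

records = parse_exons(GFF3.splitlines(keepends=True))
series = build_series(records, "chr1")

print(f"chromosome: {series.chromosome}")
print(f"exon count: {series.n}")
print(f"lengths (bp): {[int(l) for l in series.lengths]}")
# -> [100, 150, 11]: each exon's span in base pairs, in genomic order.
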