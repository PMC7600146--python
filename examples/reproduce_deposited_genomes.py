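"""Run the full analysis on real deposited phage/host GenBank records.

The pipeline itself never touches the network.  Download the annotated
records you want to analyse first, e.g. with NCBI's datasets/efetch tools:

    efetch -db nucleotide -id <PHAGE_ACC>  -format gbwithparts > phage.gbk
    efetch -db nucleotide -id <HOST_ACC>   -format gbwithparts > host.gbk

then:

    python examples/reproduce_deposited_genomes.py phage.gbk host.gbk

This prints each genome's summary (length, GC%, CDS and tRNA counts), the
phage's tRNA gene(s) with decoded codon, and the rank of each tRNA-decoded
codon in the phage/host usage-ratio table — the mechanical test of whether
the phage encodes tRNAs for codons it favours over its host.
"""

import sys

from phagetools import (
    concordance,
    count_codons,
    extract_cds,
    extract_trna,
    read_genome,
    relative_frequencies,
    summarize_genome,
    usage_ratios,
)
from phagetools.concordance import report_to_text
from phagetools.genome import summaries_to_frame, trnas_to_frame

if len(sys.argv) < 3:
    sys.exit("usage: reproduce_deposited_genomes.py PHAGE.gbk [PHAGE2.gbk ...] HOST.gbk")

*phage_paths, host_path = sys.argv[1:]
host = read_genome(host_path)
phages = [read_genome(p) for p in phage_paths]

print(summaries_to_frame([summarize_genome(g) for g in [*phages, host]]).to_string(index=False))

host_usage = relative_frequencies(
    count_codons(extract_cds(host)), genome_id=host.genome_id
)
for phage in phages:
    trnas = extract_trna(phage)
    print()
    print(trnas_to_frame(trnas).to_string(index=False))
    ratios = usage_ratios(
        relative_frequencies(count_codons(extract_cds(phage)), genome_id=phage.genome_id),
        host_usage,
    )
    for t in trnas:
        print(
            f"{phage.genome_id}: codon {t.decoded_codon} (decoded by anticodon "
            f"{t.anticodon}) has ratio {ratios.r[t.decoded_codon]:.3f}, "
            f"rank {ratios.rank.get(t.decoded_codon)} of {ratios.n_defined}"
        )
    print()
    print(report_to_text(concordance(trnas, ratios)))
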