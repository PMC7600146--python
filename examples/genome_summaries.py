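"""Genome summary statistics from an annotated record.

Generates a small phage-like genome, writes it as GenBank, reads it back
and prints the summary table: length, GC%, CDS count, how many CDS have a
functional (non-hypothetical) product annotation, and the tRNA count.
"""

import tempfile
from pathlib import Path

from phagetools import (
    CodonBiasSpec,
    extract_trna,
    generate_genome,
    read_genome,
    summarize_genome,
    write_genbank,
)
from phagetools.genome import summaries_to_frame, trnas_to_frame

spec = CodonBiasSpec(n_cds=62, cds_length_codons=(100, 300), seed=3)
genome = generate_genome(spec, trna_anticodons=["TGG"], genome_id="demo_phage")

with tempfile.TemporaryDirectory() as d:
    path = Path(d) / "demo_phage.gbk"
    write_genbank(genome, path)
    genome = read_genome(path, genome_id="demo_phage")

summary = summarize_genome(genome)
print(summaries_to_frame([summary]).to_string(index=False))
print()
print(trnas_to_frame(extract_trna(genome)).to_string(index=False))
print()
print(
    "functional_percent is 100 * n_functional / n_cds: the share of CDS\n"
    "whose product annotation is something other than a hypothetical/\n"
    "unknown protein.  The tRNA's decoded codon is the reverse complement\n"
    "of its anticodon."
)
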