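"""Match phage tRNA anticodons against phage-favoured codons.

The phage carries a single tRNA with anticodon TGG, which decodes codon CCA
(proline).  CCA is enriched in the phage's codon usage, so the tRNA should
be reported as matched; AGA is even more enriched but has no cognate tRNA,
so it should surface as the top uncovered codon.
"""

from phagetools import (
    CodonBiasSpec,
    concordance,
    count_codons,
    extract_cds,
    extract_trna,
    generate_pair,
    relative_frequencies,
    usage_ratios,
)
from phagetools.concordance import report_to_text

host_spec = CodonBiasSpec(n_cds=100, cds_length_codons=(100, 300), seed=2)
host, phage, _ = generate_pair(
    host_spec, {"CCA": 1.8, "AGA": 2.5}, phage_trnas=["TGG"], seed=2
)

ratios = usage_ratios(
    relative_frequencies(count_codons(extract_cds(phage)), genome_id=phage.genome_id),
    relative_frequencies(count_codons(extract_cds(host)), genome_id=host.genome_id),
)
report = concordance(extract_trna(phage), ratios)
print(report_to_text(report))
print(
    "A matched line means the phage encodes a tRNA for a codon it uses at\n"
    "least 1.1x more than its host; uncovered codons are phage-favoured\n"
    "codons with no cognate phage tRNA, strongest mismatch first."
)
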