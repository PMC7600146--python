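"""Phage/host codon-usage ratios on a synthetic pair with known truth.

Generates a host genome and a phage genome whose CDS codons are drawn from
the host's distribution with CCA enriched 1.8x and AGA 2.5x, computes the
relative codon frequencies f_i and the usage ratios r_i = f_i(phage)/
f_i(host), and prints the top/bottom-5 ranked report.  The enriched codons
should land at the top with ratios near their analytic expectations.
"""

from phagetools import (
    CodonBiasSpec,
    count_codons,
    extract_cds,
    generate_pair,
    ratio_report,
    relative_frequencies,
    usage_ratios,
)

host_spec = CodonBiasSpec(n_cds=100, cds_length_codons=(100, 300), seed=1)
host, phage, truth = generate_pair(host_spec, {"CCA": 1.8, "AGA": 2.5}, seed=1)

host_usage = relative_frequencies(
    count_codons(extract_cds(host)), genome_id=host.genome_id
)
phage_usage = relative_frequencies(
    count_codons(extract_cds(phage)), genome_id=phage.genome_id
)
ratios = usage_ratios(phage_usage, host_usage)

print(f"expected r(CCA) = {truth['CCA']:.3f}, observed = {ratios.r['CCA']:.3f}")
print(f"expected r(AGA) = {truth['AGA']:.3f}, observed = {ratios.r['AGA']:.3f}")
print()
report = ratio_report(ratios, k=5)
print(report.to_string(index=False, float_format=lambda v: f"{v:.4f}"))
print()
print(
    "Each row is one codon: its phage and host relative frequencies, their\n"
    "ratio, the threshold class (>=1.1 phage_higher, 0.9-1.1 similar,\n"
    "<0.9 host_higher) and its rank by decreasing ratio."
)
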