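"""Concordance between phage-encoded tRNAs and codon-usage ratios.

The adaptive-tRNA hypothesis holds that a phage carries tRNA genes for the
codons it uses more heavily than its host.  This module tests that reading
mechanically: a tRNA is *matched* when the codon it decodes (the exact
reverse complement of its anticodon — wobble pairing is deliberately not
modeled) is classified phage_higher (r_i >= 1.1) in the usage-ratio table.
Phage-favoured codons with no cognate tRNA are reported as uncovered, in
decreasing ratio order, so cases like a top-ranked codon lacking its tRNA
surface immediately without interpretation.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

from .codons import CLASS_PHAGE_HIGHER, UsageRatioTable
from .genome import TrnaGene


@dataclass(frozen=True)
class MatchedTrna:
    trna: TrnaGene
    codon: str
    ratio: float
    rank: int


@dataclass(frozen=True)
class CodonGap:
    """A phage_higher codon with no cognate phage tRNA."""

    codon: str
    ratio: float
    rank: int


@dataclass(frozen=True)
class ConcordanceReport:
    phage_id: str
    host_id: str
    matched: tuple
    unmatched_trnas: tuple
    uncovered_codons: tuple


def concordance(trnas, ratios: UsageRatioTable) -> ConcordanceReport:
    """Partition phage tRNAs by whether their decoded codon is phage-favoured.

    Every input tRNA lands in exactly one of ``matched`` /
    ``unmatched_trnas``; ``uncovered_codons`` lists every phage_higher codon
    whose cognate tRNA is absent, ordered by decreasing ratio.  Output is
    invariant to input tRNA order.
    """
    ordered = sorted(trnas, key=lambda t: (t.anticodon, t.trna_id))
    matched = []
    unmatched = []
    for t in ordered:
        codon = t.decoded_codon
        if ratios.clazz.get(codon) == CLASS_PHAGE_HIGHER:
            matched.append(
                MatchedTrna(
                    trna=t, codon=codon, ratio=ratios.r[codon], rank=ratios.rank[codon]
                )
            )
        else:
            unmatched.append(t)
    decoded = {t.decoded_codon for t in ordered}
    uncovered = [
        CodonGap(codon=c, ratio=ratios.r[c], rank=ratios.rank[c])
        for c in sorted(ratios.rank, key=ratios.rank.get)
        if ratios.clazz[c] == CLASS_PHAGE_HIGHER and c not in decoded
    ]
    return ConcordanceReport(
        phage_id=ratios.phage_id,
        host_id=ratios.host_id,
        matched=tuple(matched),
        unmatched_trnas=tuple(unmatched),
        uncovered_codons=tuple(uncovered),
    )


def report_to_dict(report: ConcordanceReport) -> dict:
    def _num(x):
        return None if isinstance(x, float) and math.isnan(x) else x

    return {
        "phage_id": report.phage_id,
        "host_id": report.host_id,
        "matched": [
            {
                "trna_id": m.trna.trna_id,
                "anticodon": m.trna.anticodon,
                "codon": m.codon,
                "amino_acid": m.trna.amino_acid,
                "ratio": _num(m.ratio),
                "rank": m.rank,
            }
            for m in report.matched
        ],
        "unmatched_trnas": [
            {
                "trna_id": t.trna_id,
                "anticodon": t.anticodon,
                "codon": t.decoded_codon,
                "amino_acid": t.amino_acid,
            }
            for t in report.unmatched_trnas
        ],
        "uncovered_codons": [
            {"codon": g.codon, "ratio": _num(g.ratio), "rank": g.rank}
            for g in report.uncovered_codons
        ],
    }


def write_report_json(report: ConcordanceReport, path) -> None:
    with open(path, "w") as fh:
        json.dump(report_to_dict(report), fh, indent=2, sort_keys=True)
        fh.write("\n")


def report_to_text(report: ConcordanceReport) -> str:
    """Human-readable summary of the concordance report."""
    lines = [f"tRNA/codon-usage concordance: {report.phage_id} vs {report.host_id}", ""]
    if report.matched:
        lines.append("tRNAs decoding phage-favoured codons (r >= 1.1):")
        for m in report.matched:
            lines.append(
                f"  {m.trna.trna_id}: anticodon {m.trna.anticodon} -> codon "
                f"{m.codon} ({m.trna.amino_acid}), ratio {m.ratio:.3f}, rank {m.rank}"
            )
    else:
        lines.append("No tRNA decodes a phage-favoured codon.")
    if report.unmatched_trnas:
        lines.append("tRNAs whose codon is not phage-favoured:")
        for t in report.unmatched_trnas:
            lines.append(
                f"  {t.trna_id}: anticodon {t.anticodon} -> codon "
                f"{t.decoded_codon} ({t.amino_acid})"
            )
    if report.uncovered_codons:
        lines.append("Phage-favoured codons with no cognate phage tRNA:")
        for g in report.uncovered_codons:
            lines.append(f"  {g.codon}: ratio {g.ratio:.3f}, rank {g.rank}")
    return "\n".join(lines) + "\n"
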