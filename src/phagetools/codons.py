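"""Relative codon frequencies and phage/host usage ratios.

For a set of complete coding sequences the relative frequency of codon *i*
is

    f_i = (count of codon i) / (total codons counted)

over all 64 codons, stop codons included.  Start codons are removed by
default (the first in-frame triplet of every CDS is skipped) so the
initiator does not inflate ATG/GTG/TTG.

The phage-to-host usage ratio is

    r_i = f_i(phage) / f_i(host)

classified against fixed thresholds: r_i >= 1.1 means the phage uses codon
*i* more than the host ("phage_higher"), 0.9 <= r_i < 1.1 is "similar", and
r_i < 0.9 is "host_higher".  Codons with zero host frequency get an
undefined ratio and are excluded from ranking.  Ranks sort by decreasing
r_i, ties broken alphabetically by codon, so reports are deterministic.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import pandas as pd

from .errors import ValidationError
from .genome import CodingSequence, codon_amino_acid

logger = logging.getLogger(__name__)

#: The 64 codons in alphabetical order.
CODONS = tuple("".join(p) for p in itertools.product("ACGT", repeat=3))

#: Classification thresholds on r_i.  These define the statistic itself and
#: are deliberately not configurable anywhere in the package.
RATIO_HIGH = 1.1
RATIO_LOW = 0.9

CLASS_PHAGE_HIGHER = "phage_higher"
CLASS_SIMILAR = "similar"
CLASS_HOST_HIGHER = "host_higher"
CLASS_UNDEFINED = "undefined"


@dataclass(frozen=True)
class CodonCounts:
    """Raw codon tallies over a CDS set (all 64 codons always present)."""

    counts: dict
    total: int
    n_skipped_codons: int
    n_cds_used: int
    drop_start_applied: bool

    def __post_init__(self):
        if set(self.counts) != set(CODONS):
            raise ValidationError("counts must cover exactly the 64 codons")
        if self.total != sum(self.counts.values()):
            raise ValidationError("total does not equal the sum of counts")


@dataclass(frozen=True)
class CodonUsageTable:
    """Relative codon frequencies f_i for one genome's CDS set."""

    genome_id: str
    f: dict
    total_codons: int


@dataclass(frozen=True)
class UsageRatioTable:
    """Per-codon phage/host ratios r_i with class labels and ranks."""

    phage_id: str
    host_id: str
    r: dict          # codon -> float (NaN where host f_i == 0)
    clazz: dict      # codon -> class label
    rank: dict       # codon -> 1-based rank among defined ratios
    f_phage: dict = field(default_factory=dict)
    f_host: dict = field(default_factory=dict)

    @property
    def n_defined(self) -> int:
        return len(self.rank)


def count_codons(cds_list, drop_start: bool = True) -> CodonCounts:
    """Tally in-frame codons over the complete CDS in ``cds_list``.

    Each complete CDS contributes its non-overlapping in-frame triplets,
    omitting the first when ``drop_start``.  Triplets containing non-ACGT
    characters are excluded from the counts and tallied separately.
    Incomplete CDS are ignored (and logged); plain strings are accepted and
    treated as complete CDS.
    """
    counts = dict.fromkeys(CODONS, 0)
    skipped = 0
    used = 0
    ignored = 0
    for cds in cds_list:
        if isinstance(cds, CodingSequence):
            if not cds.is_complete:
                ignored += 1
                continue
            nt = cds.nt
        else:
            nt = str(cds).upper()
        used += 1
        start = 3 if drop_start else 0
        for i in range(start, len(nt) - len(nt) % 3, 3):
            codon = nt[i : i + 3]
            if codon in counts:
                counts[codon] += 1
            else:
                skipped += 1
    if ignored:
        logger.info("count_codons: ignored %d incomplete CDS", ignored)
    return CodonCounts(
        counts=counts,
        total=sum(counts.values()),
        n_skipped_codons=skipped,
        n_cds_used=used,
        drop_start_applied=drop_start,
    )


def relative_frequencies(
    counts: CodonCounts, genome_id: str = "", pseudocount: float = 0.0
) -> CodonUsageTable:
    """f_i = count_i / total.  All f_i are NaN when the total is zero.

    ``pseudocount`` adds the given value to every codon count before
    normalizing (off by default); apply it to both genomes of a pair if the
    host has zero-count codons that should still yield finite ratios.
    """
    adj = {c: counts.counts[c] + pseudocount for c in CODONS}
    total = sum(adj.values())
    if total == 0:
        f = dict.fromkeys(CODONS, math.nan)
    else:
        f = {c: adj[c] / total for c in CODONS}
    return CodonUsageTable(genome_id=genome_id, f=f, total_codons=counts.total)


def usage_ratios(phage: CodonUsageTable, host: CodonUsageTable) -> UsageRatioTable:
    """Compute r_i = f_i(phage)/f_i(host), classify and rank every codon."""
    for table, who in ((phage, "phage"), (host, "host")):
        if table.total_codons == 0 or any(math.isnan(v) for v in table.f.values()):
            raise ValidationError(f"{who} usage table is undefined (zero total codons)")
    r: dict = {}
    clazz: dict = {}
    for c in CODONS:
        fh = host.f[c]
        if fh == 0:
            r[c] = math.nan
            clazz[c] = CLASS_UNDEFINED
            continue
        ri = phage.f[c] / fh
        r[c] = ri
        if ri >= RATIO_HIGH:
            clazz[c] = CLASS_PHAGE_HIGHER
        elif ri >= RATIO_LOW:
            clazz[c] = CLASS_SIMILAR
        else:
            clazz[c] = CLASS_HOST_HIGHER
    defined = sorted(
        (c for c in CODONS if not math.isnan(r[c])), key=lambda c: (-r[c], c)
    )
    rank = {c: i for i, c in enumerate(defined, start=1)}
    return UsageRatioTable(
        phage_id=phage.genome_id,
        host_id=host.genome_id,
        r=r,
        clazz=clazz,
        rank=rank,
        f_phage=dict(phage.f),
        f_host=dict(host.f),
    )


def ratio_report(table: UsageRatioTable, k: int = 10) -> pd.DataFrame:
    """Top-k and bottom-k codons by usage ratio, deterministic under ties.

    Returns a frame with one row per reported codon (columns: end, rank,
    codon, amino_acid, f_phage, f_host, ratio, class), top block first.
    """
    n = table.n_defined
    if k < 1 or 2 * k > n:
        raise ValidationError(
            f"k must satisfy 1 <= k <= {n // 2} for {n} defined ratios; got {k}"
        )
    by_rank = sorted(table.rank, key=table.rank.get)
    rows = []
    for end, codons in (("top", by_rank[:k]), ("bottom", by_rank[-k:])):
        for c in codons:
            rows.append(
                {
                    "end": end,
                    "rank": table.rank[c],
                    "codon": c,
                    "amino_acid": codon_amino_acid(c),
                    "f_phage": table.f_phage.get(c, math.nan),
                    "f_host": table.f_host.get(c, math.nan),
                    "ratio": table.r[c],
                    "class": table.clazz[c],
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Tabular / JSON output


def usage_to_frame(table: CodonUsageTable, counts: CodonCounts | None = None) -> pd.DataFrame:
    rows = []
    for c in CODONS:
        rows.append(
            {
                "codon": c,
                "amino_acid": codon_amino_acid(c),
                "count": counts.counts[c] if counts else pd.NA,
                "f": table.f[c],
            }
        )
    return pd.DataFrame(rows)


def ratios_to_frame(
    table: UsageRatioTable, phage_counts: CodonCounts | None = None
) -> pd.DataFrame:
    """Full 64-row ratio table (codon, amino_acid, count, f_phage, f_host,
    ratio, class, rank); ratios are printed to 3 decimals by the TSV writer
    while all in-memory comparisons stay at full precision."""
    rows = []
    for c in CODONS:
        rows.append(
            {
                "codon": c,
                "amino_acid": codon_amino_acid(c),
                "count": phage_counts.counts[c] if phage_counts else pd.NA,
                "f_phage": table.f_phage.get(c, math.nan),
                "f_host": table.f_host.get(c, math.nan),
                "ratio": table.r[c],
                "class": table.clazz[c],
                "rank": table.rank.get(c, pd.NA),
            }
        )
    return pd.DataFrame(rows)


def write_ratio_tsv(frame: pd.DataFrame, path) -> None:
    out = frame.copy()
    for col in ("ratio",):
        if col in out:
            out[col] = out[col].map(lambda v: "" if pd.isna(v) else f"{v:.3f}")
    for col in ("f", "f_phage", "f_host"):
        if col in out:
            out[col] = out[col].map(lambda v: "" if pd.isna(v) else f"{v:.6f}")
    out.to_csv(path, sep="\t", index=False)


def ratio_table_to_dict(table: UsageRatioTable) -> dict:
    """JSON-ready representation (NaN ratios serialized as null)."""
    return {
        "phage_id": table.phage_id,
        "host_id": table.host_id,
        "thresholds": {"high": RATIO_HIGH, "low": RATIO_LOW},
        "codons": {
            c: {
                "ratio": None if math.isnan(table.r[c]) else table.r[c],
                "class": table.clazz[c],
                "rank": table.rank.get(c),
                "f_phage": table.f_phage.get(c),
                "f_host": table.f_host.get(c),
            }
            for c in CODONS
        },
    }


def plot_ratio_report(report: pd.DataFrame, path) -> None:
    """Bar chart of the top/bottom-k usage ratios (log scale)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(9, 4))
    colors = ["#1f77b4" if e == "top" else "#ff7f0e" for e in report["end"]]
    labels = [f"{r.codon} ({r.amino_acid})" for r in report.itertuples()]
    ax.bar(range(len(report)), report["ratio"], color=colors)
    ax.axhline(1.0, color="grey", lw=0.8)
    ax.set_xticks(range(len(report)), labels, rotation=90, fontsize=7)
    ax.set_yscale("log")
    ax.set_ylabel("phage/host usage ratio $r_i$")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
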