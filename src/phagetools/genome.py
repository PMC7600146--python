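"""Annotated-genome input/output and feature extraction.

Genomes are held as a single case-normalized nucleotide string plus a flat
list of positional features (1-based inclusive coordinates, GenBank/GFF3
convention).  Multi-record inputs — draft assemblies in particular — are
pooled under one genome id by concatenating the records and offsetting the
feature coordinates, so genome-wide statistics such as GC% are computed over
the whole assembly.

Coding sequences are extracted strand-aware (minus-strand features are
reverse-complemented before any codon-level operation) and flagged complete
or excluded per a configurable completeness policy.  tRNA features are
consumed as annotations: the anticodon qualifier is read, never predicted.
"""

from __future__ import annotations

import logging
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Data import CodonTable
from Bio.Seq import Seq
from Bio.SeqFeature import AfterPosition, BeforePosition, SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord
from Bio.SeqUtils import seq3

from .errors import ConsistencyError, InputError, ValidationError

logger = logging.getLogger(__name__)

FEATURE_KINDS = ("CDS", "tRNA", "other")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(nt: str) -> str:
    """Reverse complement over the {A,C,G,T,N} alphabet."""
    return nt.translate(_COMPLEMENT)[::-1]


def _normalize_sequence(raw: str) -> str:
    """Uppercase and collapse IUPAC ambiguity codes to N."""
    seq = raw.upper()
    if not seq:
        raise ValidationError("sequence must have length >= 1")
    if not re.fullmatch(r"[A-Z]+", seq):
        raise ValidationError("sequence contains non-letter characters")
    return re.sub(r"[^ACGT]", "N", seq)


@dataclass(frozen=True)
class Feature:
    """A positional genome feature (1-based inclusive, explicit strand)."""

    kind: str
    start: int
    end: int
    strand: str
    qualifiers: dict = field(default_factory=dict)
    feature_id: str = ""

    def __post_init__(self):
        if self.kind not in FEATURE_KINDS:
            raise ValidationError(f"unknown feature kind {self.kind!r}")
        if self.start > self.end:
            raise ValidationError(
                f"feature {self.feature_id or self.kind}: start {self.start} > end {self.end}"
            )
        if self.strand not in ("+", "-"):
            raise ValidationError(
                f"feature {self.feature_id or self.kind}: illegal strand {self.strand!r}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class AnnotatedGenome:
    """A nucleotide sequence plus its CDS/tRNA/other features."""

    genome_id: str
    sequence: str
    features: list = field(default_factory=list)

    def __post_init__(self):
        self.sequence = _normalize_sequence(self.sequence)
        n = len(self.sequence)
        for f in self.features:
            if f.start < 1 or f.end > n:
                raise ValidationError(
                    f"feature {f.feature_id or f.kind} at {f.start}..{f.end} "
                    f"outside sequence bounds 1..{n}"
                )

    def features_of_kind(self, kind: str) -> list:
        return [f for f in self.features if f.kind == kind]

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class CodingSequence:
    """One extracted CDS, already in reading frame (5'->3' of the gene)."""

    cds_id: str
    nt: str
    is_complete: bool
    exclusion_reason: str | None = None


@dataclass(frozen=True)
class GenomeSummary:
    genome_id: str
    length_bp: int
    gc_percent: float
    n_cds: int
    n_functional: int
    functional_percent: float
    n_trna: int


@dataclass(frozen=True)
class TrnaGene:
    """A tRNA annotation: anticodon (5'->3'), the codon it decodes, amino acid."""

    trna_id: str
    anticodon: str
    decoded_codon: str
    amino_acid: str
    length_bp: int


@dataclass(frozen=True)
class CompletenessPolicy:
    """Which checks make a CDS count as incomplete.

    Frame (length divisible by 3) and annotated partial-location markers are
    the reproducible core and are on by default; requiring a standard start
    codon and rejecting internal stops are optional strictness flags.
    """

    check_frame: bool = True
    check_partial: bool = True
    require_start: bool = False
    check_internal_stop: bool = False
    start_codons: tuple = ("ATG", "GTG", "TTG")


# Standard (table 1) genetic code, codon -> 1-letter amino acid, stops as '*'.
_TABLE = CodonTable.unambiguous_dna_by_id[1]
STOP_CODONS = frozenset(_TABLE.stop_codons)
GENETIC_CODE = {**_TABLE.forward_table, **{c: "*" for c in _TABLE.stop_codons}}


def codon_amino_acid(codon: str, three_letter: bool = True) -> str:
    """Amino acid for a codon under the standard code ('Ter' for stops)."""
    aa = GENETIC_CODE.get(codon.upper())
    if aa is None:
        return "Xaa" if three_letter else "X"
    return seq3(aa) if three_letter else aa


# ---------------------------------------------------------------------------
# Readers / writer


def _partial_from_location(location) -> bool:
    return isinstance(location.start, BeforePosition) or isinstance(
        location.end, AfterPosition
    )


def _features_from_record(record: SeqRecord, offset: int) -> list:
    feats = []
    counters: dict = {}
    for sf in record.features:
        if sf.type == "source":
            continue
        kind = sf.type if sf.type in ("CDS", "tRNA") else "other"
        counters[kind] = counters.get(kind, 0) + 1
        quals = {k: "; ".join(str(x) for x in v) for k, v in sf.qualifiers.items()}
        if _partial_from_location(sf.location):
            quals.setdefault("partial", "true")
        fid = quals.get("locus_tag") or quals.get(
            "gene", f"{record.id}_{kind}_{counters[kind]}"
        )
        strand = "-" if sf.location.strand == -1 else "+"
        feats.append(
            Feature(
                kind=kind,
                start=int(sf.location.start) + 1 + offset,
                end=int(sf.location.end) + offset,
                strand=strand,
                qualifiers=quals,
                feature_id=fid,
            )
        )
    return feats


def _read_genbank(path: Path, genome_id: str | None) -> AnnotatedGenome:
    try:
        records = list(SeqIO.parse(str(path), "genbank"))
    except Exception as exc:  # Biopython raises assorted parse errors
        raise InputError(f"could not parse GenBank file {path}: {exc}") from exc
    if not records:
        raise InputError(f"no records found in GenBank file {path}")
    sequence, features, offset = [], [], 0
    for rec in records:
        seq = str(rec.seq)
        features.extend(_features_from_record(rec, offset))
        sequence.append(seq)
        offset += len(seq)
    return AnnotatedGenome(
        genome_id=genome_id or records[0].id, sequence="".join(sequence), features=features
    )


def _read_fasta_gff3(path: Path, gff: Path, genome_id: str | None) -> AnnotatedGenome:
    import gffutils

    try:
        records = list(SeqIO.parse(str(path), "fasta"))
    except Exception as exc:
        raise InputError(f"could not parse FASTA file {path}: {exc}") from exc
    if not records:
        raise InputError(f"no records found in FASTA file {path}")
    offsets, sequence, offset = {}, [], 0
    for rec in records:
        offsets[rec.id] = offset
        sequence.append(str(rec.seq))
        offset += len(rec.seq)
    try:
        db = gffutils.create_db(
            str(gff), dbfn=":memory:", force=True, keep_order=True,
            merge_strategy="create_unique",
        )
    except Exception as exc:
        raise InputError(f"could not parse GFF3 file {gff}: {exc}") from exc
    features = []
    for gf in db.all_features():
        if gf.seqid not in offsets:
            raise ConsistencyError(
                f"GFF3 seqid {gf.seqid!r} not present in FASTA {path}"
            )
        kind = gf.featuretype if gf.featuretype in ("CDS", "tRNA") else "other"
        quals = {k: ",".join(v) for k, v in gf.attributes.items()}
        fid = quals.get("ID") or quals.get("locus_tag") or f"{gf.seqid}_{gf.start}_{kind}"
        off = offsets[gf.seqid]
        features.append(
            Feature(
                kind=kind,
                start=gf.start + off,
                end=gf.end + off,
                strand="-" if gf.strand == "-" else "+",
                qualifiers=quals,
                feature_id=fid,
            )
        )
    return AnnotatedGenome(
        genome_id=genome_id or records[0].id, sequence="".join(sequence), features=features
    )


def read_genome(
    path, format: str = "genbank", gff=None, genome_id: str | None = None
) -> AnnotatedGenome:
    """Read an annotated genome from GenBank or FASTA+GFF3.

    Parameters
    ----------
    path
        GenBank flat file, or nucleotide FASTA when ``format="fasta+gff3"``.
    format
        ``"genbank"`` or ``"fasta+gff3"``.
    gff
        GFF3 annotation path, required for ``fasta+gff3``.
    genome_id
        Override the id taken from the first record.

    Multi-record files (draft assemblies) are pooled: sequences concatenated,
    feature coordinates offset accordingly.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"input file {path} does not exist")
    if format == "genbank":
        return _read_genbank(path, genome_id)
    if format == "fasta+gff3":
        if gff is None:
            raise InputError("format 'fasta+gff3' requires a GFF3 path")
        gff = Path(gff)
        if not gff.exists():
            raise InputError(f"annotation file {gff} does not exist")
        return _read_fasta_gff3(path, gff, genome_id)
    raise InputError(f"unknown format {format!r}; use 'genbank' or 'fasta+gff3'")


def write_genbank(genome: AnnotatedGenome, path) -> None:
    """Write a genome as a single-record GenBank flat file.

    The LOCUS date is pinned so identical genomes serialize byte-identically.
    """
    record = SeqRecord(
        Seq(genome.sequence),
        id=genome.genome_id,
        name=genome.genome_id[:16].replace(" ", "_"),
        description=f"{genome.genome_id} annotated genome",
        annotations={"molecule_type": "DNA", "date": "01-JAN-1980"},
    )
    for f in genome.features:
        quals = {k: [v] for k, v in f.qualifiers.items()}
        record.features.append(
            SeqFeature(
                SimpleLocation(f.start - 1, f.end, strand=-1 if f.strand == "-" else 1),
                type=f.kind,
                qualifiers=quals,
            )
        )
    with open(path, "w") as fh:
        SeqIO.write([record], fh, "genbank")


# ---------------------------------------------------------------------------
# Extraction and summaries


def _completeness(nt: str, feature: Feature, policy: CompletenessPolicy):
    if policy.check_partial and "partial" in {k.lower() for k in feature.qualifiers}:
        return "partial annotation"
    if policy.check_frame and len(nt) % 3 != 0:
        return "length not multiple of 3"
    if policy.require_start and nt[:3] not in policy.start_codons:
        return f"no standard start codon ({nt[:3]})"
    if policy.check_internal_stop and len(nt) % 3 == 0:
        for i in range(0, len(nt) - 3, 3):
            if nt[i : i + 3] in STOP_CODONS:
                return f"internal stop codon at nt {i + 1}"
    return None


def extract_cds(
    genome: AnnotatedGenome, policy: CompletenessPolicy = CompletenessPolicy()
) -> list:
    """Extract one in-frame :class:`CodingSequence` per CDS feature.

    Minus-strand features are reverse-complemented.  Failures are never
    fatal: each CDS is either flagged complete or carries an
    ``exclusion_reason``.  Order follows feature start position.
    """
    out = []
    cds_feats = sorted(genome.features_of_kind("CDS"), key=lambda f: (f.start, f.end))
    for i, f in enumerate(cds_feats, start=1):
        nt = genome.sequence[f.start - 1 : f.end]
        if f.strand == "-":
            nt = reverse_complement(nt)
        reason = _completeness(nt, f, policy)
        out.append(
            CodingSequence(
                cds_id=f.feature_id or f"{genome.genome_id}_CDS_{i}",
                nt=nt,
                is_complete=reason is None,
                exclusion_reason=reason,
            )
        )
    n_excl = sum(not c.is_complete for c in out)
    if n_excl:
        logger.info(
            "%s: excluded %d of %d CDS as incomplete", genome.genome_id, n_excl, len(out)
        )
    return out


_NONFUNCTIONAL = re.compile(r"hypothetical|unknown|uncharacteri[sz]ed", re.IGNORECASE)


def default_functional_predicate(qualifiers: dict) -> bool:
    """A CDS counts as functional unless its product is absent or generic.

    Reproduces the functional/hypothetical split of a typical phage feature
    table without re-running any homology search: products matching
    "hypothetical", "unknown" or "uncharacterized" (case-insensitive), or
    missing entirely, are non-functional.
    """
    product = qualifiers.get("product", "")
    return bool(product) and not _NONFUNCTIONAL.search(product)


def gc_percent(sequence: str, ndigits: int | None = 1) -> float:
    """GC% over unambiguous bases: 100*(G+C)/(A+C+G+T), N excluded."""
    seq = sequence.upper()
    gc = seq.count("G") + seq.count("C")
    at = seq.count("A") + seq.count("T")
    if gc + at == 0:
        raise ValidationError("sequence has no unambiguous bases")
    pct = 100.0 * gc / (gc + at)
    return round(pct, ndigits) if ndigits is not None else pct


def summarize_genome(
    genome: AnnotatedGenome,
    functional_predicate: Callable[[dict], bool] = default_functional_predicate,
) -> GenomeSummary:
    """Genome-level summary: length, GC%, CDS/functional/tRNA counts."""
    cds = genome.features_of_kind("CDS")
    n_func = sum(functional_predicate(f.qualifiers) for f in cds)
    func_pct = round(100.0 * n_func / len(cds), 1) if cds else 0.0
    return GenomeSummary(
        genome_id=genome.genome_id,
        length_bp=genome.length,
        gc_percent=gc_percent(genome.sequence),
        n_cds=len(cds),
        n_functional=n_func,
        functional_percent=func_pct,
        n_trna=len(genome.features_of_kind("tRNA")),
    )


_ANTICODON_SEQ = re.compile(r"seq\s*:\s*([acgtuACGTU]{3})")


def _parse_anticodon(value: str) -> str | None:
    """Accept a plain 3-mer or a GenBank-style '(pos:..,aa:Pro,seq:tgg)'."""
    value = value.strip()
    m = _ANTICODON_SEQ.search(value)
    if m:
        return m.group(1).upper().replace("U", "T")
    if re.fullmatch(r"[acgtuACGTU]{3}", value):
        return value.upper().replace("U", "T")
    return None


def extract_trna(genome: AnnotatedGenome) -> list:
    """Extract :class:`TrnaGene` records from tRNA features.

    The decoded codon is the reverse complement of the anticodon (both read
    5'->3'); the amino acid follows from the standard genetic code.  Features
    without a parsable anticodon qualifier are skipped with a warning.
    """
    out = []
    for i, f in enumerate(genome.features_of_kind("tRNA"), start=1):
        raw = f.qualifiers.get("anticodon") or f.qualifiers.get("note", "")
        anticodon = _parse_anticodon(raw) if raw else None
        if anticodon is None:
            msg = (
                f"{genome.genome_id}: tRNA feature "
                f"{f.feature_id or i} has no parsable anticodon; skipped"
            )
            logger.warning(msg)
            warnings.warn(msg)
            continue
        codon = reverse_complement(anticodon)
        out.append(
            TrnaGene(
                trna_id=f.feature_id or f"{genome.genome_id}_tRNA_{i}",
                anticodon=anticodon,
                decoded_codon=codon,
                amino_acid=codon_amino_acid(codon),
                length_bp=f.length,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Tabular output

SUMMARY_COLUMNS = [
    "genome_id", "length_bp", "gc_percent", "n_cds",
    "n_functional", "functional_percent", "n_trna",
]
TRNA_COLUMNS = ["trna_id", "anticodon", "decoded_codon", "amino_acid", "length_bp"]


def summaries_to_frame(summaries: Sequence[GenomeSummary]) -> pd.DataFrame:
    return pd.DataFrame([vars(s) for s in summaries], columns=SUMMARY_COLUMNS)


def trnas_to_frame(trnas: Iterable[TrnaGene]) -> pd.DataFrame:
    return pd.DataFrame([vars(t) for t in trnas], columns=TRNA_COLUMNS)


def write_tsv(frame: pd.DataFrame, path) -> None:
    frame.to_csv(path, sep="\t", index=False)
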