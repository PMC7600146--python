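"""Synthetic annotated genomes and one-step growth curves with known truth.

The generator emulates the statistical structure the analysis pipeline
assumes rather than any particular biology: CDS bodies are i.i.d. draws
from a 64-codon distribution (stop-free inside the body, one terminal stop
appended), so phage/host frequency ratios are controllable in closed form;
tRNA features carry a chosen anticodon qualifier over a 77-nt span; growth
curves are deterministic step functions optionally observed through Poisson
plaque counts.

Defaults mirror a small temperate-free lytic siphovirus system on a GC-rich
host: ~46 kb phage genomes of 60-odd CDS at 100-300 codons, host base
composition at 65% GC, one 77-nt tRNA, and growth parameters of latent
period 50 min, burst size 34, baseline 1e4 PFU/mL sampled every 10 min in
three replicates.

All randomness flows from a single integer seed; each operation draws from
independent child streams spawned from it, so outputs are reproducible and
adding one consumer does not perturb the others.
"""

from __future__ import annotations

import itertools
import json
import re
from dataclasses import dataclass, field, replace

import numpy as np

from .codons import CODONS
from .errors import ValidationError
from .genome import STOP_CODONS, AnnotatedGenome, Feature, reverse_complement
from .growth import GrowthCurve

#: Terminal stop appended to every synthetic CDS (fixed for determinism).
TERMINAL_STOP = "TAA"

_FUNCTIONAL_PRODUCTS = (
    "terminase large subunit",
    "capsid protein",
    "tail protein",
    "DNA polymerase I",
    "DNA helicase",
    "peptidase M15",
)


def gc_biased_distribution(gc: float = 0.65) -> dict:
    """64-codon distribution from independent per-base draws at the given GC.

    Each base is G or C with probability ``gc`` (split evenly) and A or T
    otherwise; a codon's probability is the product over its three bases.
    This reproduces the first-order compositional bias of a genome with that
    GC content.
    """
    if not 0 < gc < 1:
        raise ValidationError("gc must lie strictly between 0 and 1")
    p = {"G": gc / 2, "C": gc / 2, "A": (1 - gc) / 2, "T": (1 - gc) / 2}
    return {c: p[c[0]] * p[c[1]] * p[c[2]] for c in CODONS}


@dataclass(frozen=True)
class CodonBiasSpec:
    """Parameters of a synthetic CDS set with controllable codon bias.

    ``base_distribution`` is a probability vector over the 64 codons
    (default: GC-biased at 65%); ``enrichment`` multiplies chosen codons
    before renormalization.  Stop codons are excluded from CDS bodies (the
    body distribution is renormalized without them) and a single terminal
    stop is appended when ``include_stop``.
    """

    base_distribution: dict | None = None
    enrichment: dict = field(default_factory=dict)
    n_cds: int = 60
    cds_length_codons: tuple = (100, 300)
    start_codon: str = "ATG"
    include_stop: bool = True
    seed: int = 0
    n_partial_cds: int = 0
    functional_fraction: float = 0.22

    def __post_init__(self):
        dist = self.base_distribution
        if dist is not None:
            if set(dist) - set(CODONS):
                raise ValidationError("base_distribution has non-codon keys")
            if abs(sum(dist.values()) - 1.0) > 1e-9:
                raise ValidationError("base_distribution must sum to 1 within 1e-9")
            if any(v < 0 for v in dist.values()):
                raise ValidationError("base_distribution has negative entries")
        if any(v <= 0 for v in self.enrichment.values()):
            raise ValidationError("enrichment factors must be positive")
        if set(self.enrichment) - set(CODONS):
            raise ValidationError("enrichment has non-codon keys")
        if self.n_cds < 1:
            raise ValidationError("n_cds must be >= 1")
        lo, hi = self.cds_length_codons
        if lo < 1 or hi < lo:
            raise ValidationError("cds_length_codons must be a nonempty range")
        if not 0 <= self.n_partial_cds <= self.n_cds:
            raise ValidationError("n_partial_cds must lie in [0, n_cds]")

    def body_distribution(self) -> dict:
        """Enriched, stop-free, renormalized sampling distribution."""
        base = self.base_distribution or gc_biased_distribution()
        w = {
            c: base.get(c, 0.0) * self.enrichment.get(c, 1.0)
            for c in CODONS
            if c not in STOP_CODONS
        }
        z = sum(w.values())
        if z <= 0:
            raise ValidationError("body distribution has zero total mass")
        return {c: v / z for c, v in w.items()}


@dataclass(frozen=True)
class GrowthParams:
    """Ground-truth parameters of a simulated one-step growth experiment."""

    latent_min: float = 50.0
    burst_size: float = 34.0
    baseline_titer: float = 1e4
    sampling_interval_min: float = 10.0
    horizon_min: float = 120.0
    n_replicates: int = 3
    noise: str = "none"  # "none" or "poisson"
    plate_volume_ml: float = 0.01
    seed: int = 0

    def __post_init__(self):
        if not self.latent_min < self.horizon_min:
            raise ValidationError("latent_min must be below horizon_min")
        if self.burst_size <= 0:
            raise ValidationError("burst_size must be positive")
        if self.sampling_interval_min <= 0:
            raise ValidationError("sampling_interval_min must be positive")
        if self.baseline_titer <= 0:
            raise ValidationError("baseline_titer must be positive")
        if self.n_replicates < 1:
            raise ValidationError("n_replicates must be >= 1")
        if self.noise not in ("none", "poisson"):
            raise ValidationError("noise must be 'none' or 'poisson'")
        if self.plate_volume_ml <= 0:
            raise ValidationError("plate_volume_ml must be positive")


_SPACER_NT = 20


def _draw_cds_bodies(spec: CodonBiasSpec, r_len, r_codon) -> list:
    body = spec.body_distribution()
    codons = np.array(sorted(body))
    probs = np.array([body[c] for c in codons])
    probs = probs / probs.sum()
    lo, hi = spec.cds_length_codons
    lengths = r_len.integers(lo, hi + 1, size=spec.n_cds)
    return ["".join(r_codon.choice(codons, size=n, p=probs)) for n in lengths]


def generate_genome(
    spec: CodonBiasSpec,
    trna_anticodons=(),
    genome_id: str = "synthetic",
    rng: np.random.Generator | None = None,
) -> AnnotatedGenome:
    """Generate an annotated genome whose CDS codons follow ``spec``.

    CDS are placed non-overlapping with random spacer nucleotides between
    them, on alternating strands (minus-strand bodies are inserted as the
    reverse complement so extraction recovers the sampled codons).  One
    77-nt tRNA feature is added per requested anticodon.  Byte-identical
    output for a given seed.
    """
    for ac in trna_anticodons:
        if not re.fullmatch(r"[ACGT]{3}", str(ac).upper()):
            raise ValidationError(f"anticodon {ac!r} is not a 3-mer over ACGT")
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    r_len, r_codon, r_spacer, r_trna = rng.spawn(4)

    bodies = _draw_cds_bodies(spec, r_len, r_codon)
    n_func = round(spec.functional_fraction * spec.n_cds)
    products = itertools.cycle(_FUNCTIONAL_PRODUCTS)
    seq_parts: list = []
    features: list = []
    pos = 0  # 0-based running offset

    def _spacer():
        nonlocal pos
        s = "".join(r_spacer.choice(list("ACGT"), size=_SPACER_NT))
        seq_parts.append(s)
        pos += _SPACER_NT

    _spacer()
    for i, body in enumerate(bodies):
        nt = spec.start_codon + body + (TERMINAL_STOP if spec.include_stop else "")
        quals: dict = {}
        if i < spec.n_partial_cds:
            nt = nt[:-1]  # also breaks the reading frame
            quals["partial"] = "true"
            quals["product"] = "hypothetical protein"
        elif i < spec.n_partial_cds + n_func:
            quals["product"] = next(products)
        else:
            quals["product"] = "hypothetical protein"
        strand = "+" if i % 2 == 0 else "-"
        placed = nt if strand == "+" else reverse_complement(nt)
        start = pos + 1
        seq_parts.append(placed)
        pos += len(placed)
        features.append(
            Feature(
                kind="CDS", start=start, end=pos, strand=strand,
                qualifiers=quals, feature_id=f"{genome_id}_CDS_{i + 1:04d}",
            )
        )
        _spacer()
    for j, ac in enumerate(trna_anticodons):
        ac = str(ac).upper()
        body = "".join(r_trna.choice(list("ACGT"), size=77))
        start = pos + 1
        seq_parts.append(body)
        pos += 77
        codon = reverse_complement(ac)
        features.append(
            Feature(
                kind="tRNA", start=start, end=pos, strand="+",
                qualifiers={"anticodon": ac.lower(), "product": f"tRNA ({codon})"},
                feature_id=f"{genome_id}_tRNA_{j + 1}",
            )
        )
        _spacer()
    return AnnotatedGenome(genome_id=genome_id, sequence="".join(seq_parts), features=features)


def expected_ratios(host_spec: CodonBiasSpec, phage_enrichment: dict) -> dict:
    """Closed-form expected usage ratios for a generated pair.

    With host body distribution p and phage body distribution
    p_i * e_i / Z (Z the renormalization constant), the expected ratio for
    every sense codon with p_i > 0 is simply e_i / Z.  Terminal stop codons
    are excluded: their frequency is set by the CDS count, not the bias
    spec, and is equal in expectation for both genomes.
    """
    p_host = host_spec.body_distribution()
    z = sum(p_host[c] * phage_enrichment.get(c, 1.0) for c in p_host)
    return {
        c: phage_enrichment.get(c, 1.0) / z for c in p_host if p_host[c] > 0
    }


def generate_pair(
    host_spec: CodonBiasSpec,
    phage_enrichment: dict | None = None,
    phage_trnas=(),
    seed: int = 0,
    phage_spec: CodonBiasSpec | None = None,
):
    """Generate a (host, phage, truth) triple with known expected ratios.

    The phage samples from the host's base distribution multiplied by
    ``phage_enrichment`` (renormalized); ``truth`` maps every sense codon
    with nonzero host probability to its analytically expected r_i.
    ``phage_spec`` may override the phage's CDS count/length geometry; its
    distribution fields are always derived from the host's.
    """
    phage_enrichment = dict(phage_enrichment or {})
    if any(v <= 0 for v in phage_enrichment.values()):
        raise ValidationError("enrichment factors must be positive")
    geometry = phage_spec or host_spec
    combined = {
        c: host_spec.enrichment.get(c, 1.0) * phage_enrichment.get(c, 1.0)
        for c in set(host_spec.enrichment) | set(phage_enrichment)
    }
    phage_full_spec = replace(
        geometry,
        base_distribution=host_spec.base_distribution,
        enrichment=combined,
    )
    ss = np.random.SeedSequence(seed)
    host_rng, phage_rng = (np.random.default_rng(s) for s in ss.spawn(2))
    host = generate_genome(host_spec, genome_id="synthetic_host", rng=host_rng)
    phage = generate_genome(
        phage_full_spec, trna_anticodons=phage_trnas,
        genome_id="synthetic_phage", rng=phage_rng,
    )
    truth = expected_ratios(host_spec, phage_enrichment)
    return host, phage, truth


def simulate_growth_curve(params: GrowthParams) -> GrowthCurve:
    """Simulate a one-step growth curve as a step function, optionally
    observed through Poisson plaque counts.

    The noise-free titer is ``baseline`` up to the latent period, the
    plateau ``baseline * (1 + burst)`` from one sampling interval later,
    and linear in between.  Poisson mode replaces each titer with a plaque
    count drawn at ``plate_volume_ml`` and rescaled to PFU/mL.
    """
    t = np.arange(0.0, params.horizon_min + 1e-9, params.sampling_interval_min)
    base, burst = params.baseline_titer, params.burst_size
    lat, step = params.latent_min, params.sampling_interval_min
    frac = np.clip((t - lat) / step, 0.0, 1.0)
    clean = base * (1.0 + burst * frac)
    titers = np.tile(clean, (params.n_replicates, 1))
    if params.noise == "poisson":
        rng = np.random.default_rng(params.seed)
        counts = rng.poisson(titers * params.plate_volume_ml)
        titers = counts / params.plate_volume_ml
    return GrowthCurve(times=t, titers=titers, moi=None)


def write_manifest(path, **truth) -> None:
    """Record the ground-truth parameters of emitted fixtures as JSON."""
    with open(path, "w") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
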