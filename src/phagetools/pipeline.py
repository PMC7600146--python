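"""Reproducible orchestration of the analysis stages.

A :class:`RunConfig` (flat YAML document or constructed in Python) names the
phage and host inputs and the analysis options; :func:`run_codon_pipeline`
produces genome summaries, codon-usage and ratio tables, the top/bottom-k
report and the tRNA concordance report for each phage (or the pooled phage
CDS set), plus a machine-readable manifest.  Identical config + inputs +
seed give byte-identical outputs.

The 0.9/1.1 ratio thresholds define the statistic and are not configurable.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .codons import (
    count_codons,
    ratio_report,
    ratios_to_frame,
    relative_frequencies,
    usage_ratios,
    write_ratio_tsv,
)
from .concordance import concordance, report_to_text, write_report_json
from .errors import InputError, ValidationError
from .genome import (
    CompletenessPolicy,
    extract_cds,
    extract_trna,
    read_genome,
    summaries_to_frame,
    summarize_genome,
    trnas_to_frame,
    write_tsv,
)
from .growth import estimate_burst, read_growth_csv, write_estimate_json

logger = logging.getLogger(__name__)

CONFIG_VERSION = 1

POOLED = "pooled"
PER_PHAGE = "per_phage"


@dataclass(frozen=True)
class GenomeInput:
    label: str
    path: str
    format: str = "genbank"
    gff: str | None = None


@dataclass
class RunConfig:
    """Flat, versioned run configuration."""

    phages: list
    host: GenomeInput
    outdir: str
    pooling: str = PER_PHAGE
    drop_start: bool = True
    check_frame: bool = True
    check_partial: bool = True
    require_start: bool = False
    check_internal_stop: bool = False
    report_k: int = 10
    rise_factor: float = 2.0
    plateau_tol: float = 0.25
    growth_csvs: dict = field(default_factory=dict)  # phage label -> csv path
    seed: int = 0
    config_version: int = CONFIG_VERSION

    def __post_init__(self):
        if self.pooling not in (POOLED, PER_PHAGE):
            raise ValidationError(f"pooling must be '{POOLED}' or '{PER_PHAGE}'")
        if not self.phages:
            raise ValidationError("at least one phage input is required")
        for gi in [*self.phages, self.host]:
            if not Path(gi.path).exists():
                raise ValidationError(f"input path {gi.path} does not exist")
            if gi.format == "fasta+gff3" and (gi.gff is None or not Path(gi.gff).exists()):
                raise ValidationError(f"input {gi.label}: missing GFF3 annotation")
        for label, csv in self.growth_csvs.items():
            if not Path(csv).exists():
                raise ValidationError(f"growth CSV for {label}: {csv} does not exist")

    @property
    def policy(self) -> CompletenessPolicy:
        return CompletenessPolicy(
            check_frame=self.check_frame,
            check_partial=self.check_partial,
            require_start=self.require_start,
            check_internal_stop=self.check_internal_stop,
        )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["phages"] = [asdict(p) for p in self.phages]
        d["host"] = asdict(self.host)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        version = d.pop("config_version", CONFIG_VERSION)
        if version != CONFIG_VERSION:
            raise ValidationError(f"unsupported config_version {version}")
        d["phages"] = [GenomeInput(**p) for p in d.get("phages", [])]
        d["host"] = GenomeInput(**d["host"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        if not isinstance(data, dict):
            raise InputError(f"config {path} is not a mapping")
        return cls.from_dict(data)


def _load(gi: GenomeInput):
    return read_genome(gi.path, format=gi.format, gff=gi.gff, genome_id=gi.label)


def _setup_run_logging(outdir: Path):
    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("phagetools")
    root.setLevel(logging.INFO)
    root.addHandler(handler)
    return handler


def run_codon_pipeline(config: RunConfig) -> dict:
    """Run summaries, codon usage, ratios and concordance for every phage.

    Returns a manifest dict (also written to ``outdir/manifest.json``)
    listing every output file, the effective config and package versions.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = _setup_run_logging(outdir)
    outputs = []
    try:
        host = _load(config.host)
        phages = [_load(p) for p in config.phages]

        summaries = [summarize_genome(g) for g in [*phages, host]]
        write_tsv(summaries_to_frame(summaries), outdir / "summary.tsv")
        outputs.append("summary.tsv")

        all_trnas = {g.genome_id: extract_trna(g) for g in phages}
        trna_frame = trnas_to_frame([t for ts in all_trnas.values() for t in ts])
        write_tsv(trna_frame, outdir / "trna.tsv")
        outputs.append("trna.tsv")

        host_cds = extract_cds(host, config.policy)
        n_host_excluded = sum(not c.is_complete for c in host_cds)
        logger.info(
            "host %s: %d CDS, %d excluded as incomplete",
            host.genome_id, len(host_cds), n_host_excluded,
        )
        host_counts = count_codons(host_cds, drop_start=config.drop_start)
        host_usage = relative_frequencies(host_counts, genome_id=host.genome_id)

        if config.pooling == POOLED:
            pooled_cds = [c for g in phages for c in extract_cds(g, config.policy)]
            units = [("pooled", pooled_cds, [t for ts in all_trnas.values() for t in ts])]
        else:
            units = [
                (g.genome_id, extract_cds(g, config.policy), all_trnas[g.genome_id])
                for g in phages
            ]

        for label, cds, trnas in units:
            counts = count_codons(cds, drop_start=config.drop_start)
            logger.info(
                "%s: %d CDS counted, %d codons, %d skipped (non-ACGT)",
                label, counts.n_cds_used, counts.total, counts.n_skipped_codons,
            )
            usage = relative_frequencies(counts, genome_id=label)
            ratios = usage_ratios(usage, host_usage)
            write_ratio_tsv(ratios_to_frame(ratios, counts), outdir / f"{label}.ratios.tsv")
            outputs.append(f"{label}.ratios.tsv")
            k = min(config.report_k, ratios.n_defined // 2)
            report = ratio_report(ratios, k)
            write_ratio_tsv(report, outdir / f"{label}.report.tsv")
            outputs.append(f"{label}.report.tsv")
            conc = concordance(trnas, ratios)
            write_report_json(conc, outdir / f"{label}.concordance.json")
            outputs.append(f"{label}.concordance.json")
            (outdir / f"{label}.concordance.txt").write_text(report_to_text(conc))
            outputs.append(f"{label}.concordance.txt")

        manifest = {
            "phagetools_version": __version__,
            "config": config.to_dict(),
            "seed": config.seed,
            "outputs": sorted(outputs),
            "host_cds_excluded": n_host_excluded,
        }
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
            fh.write("\n")
        return manifest
    finally:
        logging.getLogger("phagetools").removeHandler(handler)
        handler.close()


def run_growth(config: RunConfig, csv=None, label: str = "growth") -> dict:
    """Estimate latent period and burst size from growth CSV input(s).

    ``csv`` may name a single file; otherwise ``config.growth_csvs`` maps
    phage labels to files.  Writes one ``<label>.growth.json`` per input.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    jobs = {label: csv} if csv is not None else dict(config.growth_csvs)
    if not jobs:
        raise InputError("no growth CSV provided")
    results = {}
    for name, path in sorted(jobs.items()):
        curve = read_growth_csv(path)
        est = estimate_burst(
            curve, rise_factor=config.rise_factor, plateau_tol=config.plateau_tol
        )
        write_estimate_json(est, outdir / f"{name}.growth.json")
        logger.info(
            "%s: latent %.1f min, burst %.2f +/- %.2f (n=%d)",
            name, est.latent_min, est.burst_size, est.burst_sem, est.n_replicates,
        )
        results[name] = est
    return results
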