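"""Config-driven orchestration of the full analysis.

``run_condition`` executes callers -> consensus -> annotation -> coincidence
-> motif scan/enrichment -> gene-set enrichment for one condition and writes
every report table under ``outdir/<condition>/`` together with a manifest of
parameters and input checksums.  Re-running with unchanged inputs reuses the
cached outputs.  ``compare_conditions`` produces descriptive two-condition
tables (fold changes and deltas; no between-condition significance test).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import io as oio
from .annotation import annotate_peaks, category_fractions, chromosome_density, tss_profile
from .coincidence import coincidence_table, peak_track_coincidence
from .consensus import cluster_peaks, select_consensus, venn_counts, write_consensus, write_venn
from .motifs import (
    motif_enrichment,
    motif_enrichment_table,
    scan,
    scannable_positions,
    write_hits,
)
from .peakcalling import (
    CallerParams,
    call_peaks_poisson,
    call_peaks_strand_transition,
    call_peaks_threshold,
    write_peaks,
    write_summits,
)
from .stats import enrichment_table, gene_set_enrichment

logger = logging.getLogger(__name__)

REPORT_TABLES = (
    "venn.tsv",
    "consensus.bed",
    "peak_annotation.tsv",
    "category_fractions.tsv",
    "tss_histogram.tsv",
    "chromosome_density.tsv",
    "coincidence.tsv",
    "motif_hits.tsv",
    "motif_enrichment.tsv",
    "gene_set_enrichment.tsv",
)


@dataclass
class ConditionInputs:
    treatment: str
    control: str


@dataclass
class RunConfig:
    chrom_sizes: str
    genome: str
    genes: str
    conditions: dict[str, ConditionInputs]
    tracks: dict[str, str] = field(default_factory=dict)
    motifs: str | None = None
    terms: str | None = None
    outdir: str = "occupeak_out"
    caller: CallerParams = field(default_factory=CallerParams)
    min_support: int = 2
    tss_window: int = 20_000
    tss_bin: int = 500
    alpha_genes: float = 0.01
    alpha_motifs: float = 0.05
    scan_pvalue_cutoff: float = 1e-4
    seed: int = 0

    def __post_init__(self) -> None:
        if not 1 <= self.min_support <= 3:
            raise ValueError("min_support must be in 1..3")
        for w in (self.tss_window, self.tss_bin):
            if w <= 0:
                raise ValueError("annotation windows must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        conditions = {
            name: ConditionInputs(**cond) for name, cond in raw.pop("conditions").items()
        }
        caller = CallerParams(**raw.pop("caller", {}))
        return cls(conditions=conditions, caller=caller, **raw)

    def input_paths(self, condition: str) -> dict[str, str]:
        cond = self.conditions[condition]
        paths = {
            "chrom_sizes": self.chrom_sizes,
            "genome": self.genome,
            "genes": self.genes,
            "treatment": cond.treatment,
            "control": cond.control,
        }
        for name, p in self.tracks.items():
            paths[f"track_{name}"] = p
        if self.motifs:
            paths["motifs"] = self.motifs
        if self.terms:
            paths["terms"] = self.terms
        return paths


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _params_dict(config: RunConfig) -> dict:
    d = dataclasses.asdict(config)
    d.pop("conditions")
    d.pop("outdir")
    return d


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


@dataclass
class ReportBundle:
    condition: str
    directory: Path
    manifest: dict

    def table(self, name: str) -> pd.DataFrame:
        return pd.read_csv(self.directory / name, sep="\t")


def run_condition(config: RunConfig, condition: str) -> ReportBundle:
    """Execute the full analysis for one condition; idempotent under a
    manifest of input checksums and parameters."""
    if condition not in config.conditions:
        raise ValueError(f"unknown condition {condition!r}")
    inputs = config.input_paths(condition)
    for label, p in inputs.items():
        if not Path(p).exists():
            raise FileNotFoundError(f"missing input {label!r}: {p}")

    outdir = Path(config.outdir) / condition
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "condition": condition,
        "parameters": _params_dict(config),
        "inputs": {k: _sha256(v) for k, v in sorted(inputs.items())},
    }
    manifest_path = outdir / "manifest.json"
    if manifest_path.exists():
        old = json.loads(manifest_path.read_text())
        expected = [f for f in old.get("outputs", {})]
        if (
            old.get("inputs") == manifest["inputs"]
            and old.get("parameters") == manifest["parameters"]
            and all((outdir / f).exists() for f in expected)
        ):
            logger.info("condition %s: inputs unchanged, reusing cache", condition)
            return ReportBundle(condition, outdir, old)

    sizes = oio.read_chrom_sizes(inputs["chrom_sizes"])
    genes = oio.read_genes(inputs["genes"])
    treatment = oio.read_tags(inputs["treatment"], "treatment")
    control = oio.read_tags(inputs["control"], "control")
    genome_len = sum(sizes.values())

    # -- peak calling -----------------------------------------------------
    try:
        peaksets = {
            "poisson": call_peaks_poisson(treatment, control, sizes, config.caller),
            "strand_transition": call_peaks_strand_transition(
                treatment, control, sizes, config.caller
            ),
            "threshold": call_peaks_threshold(treatment, control, sizes, config.caller),
        }
    except Exception as exc:  # noqa: BLE001 - stage attribution
        raise StageError("peak_calling", str(exc)) from exc
    for name, ps in peaksets.items():
        write_peaks(outdir / f"peaks_{name}.bed", ps)
        write_summits(outdir / f"summits_{name}.bed", ps)

    # -- consensus --------------------------------------------------------
    clusters = cluster_peaks(list(peaksets.values()))
    consensus = select_consensus(clusters, config.min_support)
    write_consensus(outdir / "consensus.bed", consensus)
    write_consensus(outdir / "merged.bed", select_consensus(clusters, 1))
    write_consensus(outdir / "stringent.bed", select_consensus(clusters, 3))
    write_venn(outdir / "venn.tsv", venn_counts(clusters, list(peaksets)))
    peaks = [c.interval for c in consensus]

    # -- annotation -------------------------------------------------------
    if peaks:
        cats = annotate_peaks(peaks, genes)
        pd.DataFrame(
            [
                (p.chrom, p.start, p.end, c.label, c.assigned_gene or "")
                for p, c in zip(peaks, cats)
            ],
            columns=["chrom", "start", "end", "category", "gene"],
        ).to_csv(outdir / "peak_annotation.tsv", sep="\t", index=False)
        fractions = category_fractions(peaks, genes)
        fractions.to_frame().to_csv(
            outdir / "category_fractions.tsv", sep="\t", index=False
        )
        profile = tss_profile(peaks, genes, config.tss_window, config.tss_bin)
        profile.to_frame().to_csv(outdir / "tss_histogram.tsv", sep="\t", index=False)
    else:
        logger.warning("condition %s: no consensus peaks", condition)
        for name in ("peak_annotation.tsv", "category_fractions.tsv", "tss_histogram.tsv"):
            (outdir / name).write_text("")
        profile = None
    chromosome_density(peaks, sizes).to_frame().to_csv(
        outdir / "chromosome_density.tsv", sep="\t", index=False
    )

    # -- coincidence ------------------------------------------------------
    results = []
    for name in sorted(config.tracks):
        track = oio.read_track(inputs[f"track_{name}"], name)
        if peaks:
            results.append(peak_track_coincidence(peaks, track, genome_len))
    coincidence_table(results, condition).to_csv(
        outdir / "coincidence.tsv", sep="\t", index=False
    )

    # -- motif scan + enrichment -----------------------------------------
    if config.motifs and peaks:
        genome = oio.read_fasta(inputs["genome"])
        pwms = oio.read_meme(inputs["motifs"])
        all_hits = []
        enr = []
        for pwm in pwms:
            genome_hits = scan(pwm, genome, pvalue_cutoff=config.scan_pvalue_cutoff)
            peak_hits = [
                h
                for h in genome_hits
                if any(
                    h.interval.chrom == p.chrom
                    and h.interval.start >= p.start
                    and h.interval.end <= p.end
                    for p in peaks
                )
            ]
            all_hits.extend(genome_hits)
            N = scannable_positions([len(s) for s in genome.values()], pwm.width)
            n = scannable_positions([len(p) for p in peaks], pwm.width)
            enr.append(
                motif_enrichment(pwm.name, len(peak_hits), n, len(genome_hits), N)
            )
        write_hits(outdir / "motif_hits.tsv", all_hits)
        enrichment_table(
            motif_enrichment_table(enr, config.alpha_motifs)
        ).to_csv(outdir / "motif_enrichment.tsv", sep="\t", index=False)
    else:
        (outdir / "motif_hits.tsv").write_text("")
        (outdir / "motif_enrichment.tsv").write_text("")

    # -- gene-set enrichment ---------------------------------------------
    if config.terms and peaks:
        annotation_map: dict[str, set[str]] = {}
        with open(inputs["terms"]) as fh:
            for line in fh:
                if line.strip():
                    term, gene = line.rstrip("\n").split("\t")
                    annotation_map.setdefault(term, set()).add(gene)
        universe = {g.name for g in genes}
        selected = {
            c.assigned_gene
            for c in annotate_peaks(peaks, genes)
            if c.assigned_gene is not None
        }
        if selected:
            res = gene_set_enrichment(
                selected, universe, annotation_map, config.alpha_genes
            )
            enrichment_table(res).to_csv(
                outdir / "gene_set_enrichment.tsv", sep="\t", index=False
            )
        else:
            (outdir / "gene_set_enrichment.tsv").write_text("")
    else:
        (outdir / "gene_set_enrichment.tsv").write_text("")

    outputs = sorted(
        p.name for p in outdir.iterdir() if p.name != "manifest.json"
    )
    manifest["outputs"] = {name: _sha256(outdir / name) for name in outputs}
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return ReportBundle(condition, outdir, manifest)


def compare_conditions(bundle_a: ReportBundle, bundle_b: ReportBundle) -> dict[str, pd.DataFrame]:
    """Descriptive A-vs-B comparison tables.

    Requires both bundles to derive from the same reference inputs (genome,
    sizes, genes); raises on checksum mismatch.
    """
    for key in ("genome", "chrom_sizes", "genes"):
        if bundle_a.manifest["inputs"].get(key) != bundle_b.manifest["inputs"].get(key):
            raise ValueError(f"reference input {key!r} differs between bundles")
    out: dict[str, pd.DataFrame] = {}

    ca = bundle_a.table("coincidence.tsv")
    cb = bundle_b.table("coincidence.tsv")
    if len(ca) and len(cb):
        a = ca[ca.direction == "peaks_on_track"][["track", "fraction"]]
        b = cb[cb.direction == "peaks_on_track"][["track", "fraction"]]
        m = a.merge(b, on="track", suffixes=("_a", "_b"))
        m["fold_a_over_b"] = m.apply(
            lambda r: r.fraction_a / r.fraction_b if r.fraction_b > 0 else float("nan"),
            axis=1,
        )
        m["difference"] = m.fraction_a - m.fraction_b
        out["coincidence_compare"] = m

    fa = bundle_a.table("category_fractions.tsv")
    fb = bundle_b.table("category_fractions.tsv")
    if len(fa) and len(fb):
        m = fa.merge(fb, on="category", suffixes=("_a", "_b"))
        m["delta"] = m.fraction_a - m.fraction_b
        out["category_compare"] = m[
            ["category", "fraction_a", "fraction_b", "delta"]
        ]

    ta = bundle_a.table("tss_histogram.tsv")
    tb = bundle_b.table("tss_histogram.tsv")
    if len(ta) and len(tb):
        m = ta.merge(tb, on=["bin_start", "bin_end"], suffixes=("_a", "_b"))
        out["tss_compare"] = m

    ma = bundle_a.table("motif_enrichment.tsv")
    mb = bundle_b.table("motif_enrichment.tsv")
    if len(ma) and len(mb):
        m = ma.merge(mb, on="term", suffixes=("_a", "_b"))
        m["pattern"] = m.apply(
            lambda r: {
                (True, True): "both",
                (True, False): "a_only",
                (False, True): "b_only",
                (False, False): "neither",
            }[(bool(r.significant_a), bool(r.significant_b))],
            axis=1,
        )
        out["motif_compare"] = m[
            ["term", "q_a", "q_b", "significant_a", "significant_b", "pattern"]
        ]
    return out


def write_comparison(tables: dict[str, pd.DataFrame], outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name, df in tables.items():
        df.to_csv(outdir / f"{name}.tsv", sep="\t", index=False)
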