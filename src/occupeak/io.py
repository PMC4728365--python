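"""Readers and writers for the pipeline's file formats.

BED3/BED6 (0-based half-open), two-column chromosome sizes, 6-column gene
tables, multi-record FASTA (via Biopython) and MEME minimal motif files
(parsed with ``Bio.motifs``, re-exported through the package's PWM type).
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO, motifs as bio_motifs
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .intervals import GenomicInterval, GeneModel, TagAlignment, Track

logger = logging.getLogger(__name__)


def read_intervals(path: str | Path, format: str = "bed6") -> list[GenomicInterval]:
    """Read a BED3/BED6 file into intervals, in file order.

    Strand is "." when absent (bed3, or a bed6 line with fewer fields).
    Unparsable coordinates or empty intervals raise with the line number;
    other malformed lines (fewer than 3 fields) are counted and logged.
    """
    if format not in ("bed3", "bed6"):
        raise ValueError(f"unknown BED format {format!r}")
    out: list[GenomicInterval] = []
    n_malformed = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                n_malformed += 1
                continue
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: unparsable coordinate") from exc
            if end <= start:
                raise ValueError(f"{path}:{lineno}: end <= start ({start}, {end})")
            strand = "."
            if format == "bed6" and len(fields) >= 6 and fields[5] in ("+", "-"):
                strand = fields[5]
            out.append(GenomicInterval(fields[0], start, end, strand))
    if n_malformed:
        logger.warning("%s: skipped %d malformed line(s)", path, n_malformed)
    return out


def write_intervals(
    path: str | Path,
    ivs: Iterable[GenomicInterval],
    names: Sequence[str] | None = None,
    scores: Sequence[float] | None = None,
) -> None:
    """Write intervals as BED6 (name/score default to "." and 0)."""
    ivs = list(ivs)
    with open(path, "w") as fh:
        for i, iv in enumerate(ivs):
            name = names[i] if names is not None else "."
            score = scores[i] if scores is not None else 0
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{score:g}\t{iv.strand}\n")


def read_tags(path: str | Path, sample: str) -> list[TagAlignment]:
    """Read a BED6 tag file into TagAlignments with the given sample label."""
    return [TagAlignment(iv, sample) for iv in read_intervals(path, "bed6")]


def write_tags(path: str | Path, tags: Iterable[TagAlignment]) -> None:
    write_intervals(path, [t.interval for t in tags])


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    """Two-column "name<TAB>length" file -> ordered dict of sizes."""
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 columns")
            sizes[parts[0]] = int(parts[1])
    return sizes


def write_chrom_sizes(path: str | Path, sizes: dict[str, int]) -> None:
    with open(path, "w") as fh:
        for name, length in sizes.items():
            fh.write(f"{name}\t{length}\n")


def read_genes(path: str | Path) -> list[GeneModel]:
    """6-column gene table: chrom, start, end, strand, name[, id]."""
    genes: list[GeneModel] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 5:
                raise ValueError(f"{path}:{lineno}: expected >= 5 columns")
            chrom, start, end, strand, name = parts[:5]
            genes.append(
                GeneModel(GenomicInterval(chrom, int(start), int(end), strand), name)
            )
    return genes


def write_genes(path: str | Path, genes: Iterable[GeneModel]) -> None:
    with open(path, "w") as fh:
        for g in genes:
            iv = g.interval
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.strand}\t{g.name}\n")


def read_track(path: str | Path, name: str) -> Track:
    return Track(name, read_intervals(path, "bed3"))


def read_fasta(path: str | Path) -> dict[str, str]:
    """Multi-record FASTA -> {name: uppercase sequence}."""
    return {
        rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")
    }


def write_fasta(path: str | Path, sequences: dict[str, str], width: int = 70) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


def read_meme(path: str | Path):
    """Parse a MEME minimal motif file into a list of PWM objects."""
    from .motifs import PWM

    with open(path) as fh:
        records = bio_motifs.parse(fh, "minimal")
    pwms = []
    for rec in records:
        counts = np.array(
            [[rec.counts[base][i] for base in "ACGT"] for i in range(rec.length)],
            dtype=float,
        )
        rowsum = counts.sum(axis=1, keepdims=True)
        background = np.array([rec.background[b] for b in "ACGT"], dtype=float)
        pwms.append(PWM(rec.name, counts / rowsum, background=background))
    return pwms


def write_meme(path: str | Path, pwms, background=None) -> None:
    """Write PWMs in MEME minimal format."""
    if background is None:
        background = pwms[0].background if pwms else np.full(4, 0.25)
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
        fh.write("Background letter frequencies\n")
        fh.write(
            "A {0:.5f} C {1:.5f} G {2:.5f} T {3:.5f}\n\n".format(*background)
        )
        for pwm in pwms:
            fh.write(f"MOTIF {pwm.name}\n")
            fh.write(
                f"letter-probability matrix: alength= 4 w= {pwm.width} "
                "nsites= 1000000 E= 0\n"
            )
            for row in pwm.matrix:
                fh.write(" ".join(f"{p:.6f}" for p in row) + "\n")
            fh.write("\n")
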