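"""Format adapters: CTSS BED, promoter BED, FASTA, GTF, JASPAR PWMs, TSV.

All coordinates are 0-based half-open on disk and in memory. CTSS BED rows
are (chrom, start, start+1, name, count, strand) with `start` the TSS base.
Adapters validate strictly and report line numbers on malformed input;
write->read round-trips are identity on valid data.
"""

from __future__ import annotations

import textwrap
from pathlib import Path

import numpy as np
import pandas as pd

from .ctss import TagCluster
from .motifs import PWM

__all__ = [
    "read_ctss_bed",
    "write_ctss_bed",
    "write_cluster_bed",
    "read_fasta",
    "write_fasta",
    "read_gtf_genes",
    "write_gtf",
    "read_jaspar",
    "write_tsv",
    "read_tsv",
]

_STRANDS = {"+", "-"}


def read_ctss_bed(path: str | Path) -> pd.DataFrame:
    """Read a CTSS BED track (chrom, start, end=start+1, name, count, strand)."""
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            parts = line.split("\t")
            if len(parts) != 6:
                raise ValueError(f"{path}:{ln}: expected 6 BED fields, got {len(parts)}")
            chrom, start, end, name, count, strand = parts
            try:
                start_i, end_i, count_f = int(start), int(end), float(count)
            except ValueError as exc:
                raise ValueError(f"{path}:{ln}: non-numeric coordinate or count") from exc
            if end_i != start_i + 1:
                raise ValueError(f"{path}:{ln}: CTSS intervals must be single-base")
            if strand not in _STRANDS:
                raise ValueError(f"{path}:{ln}: invalid strand {strand!r}")
            if count_f <= 0:
                raise ValueError(f"{path}:{ln}: count must be positive")
            rows.append((chrom, start_i, strand, count_f))
    return pd.DataFrame(rows, columns=["chrom", "pos", "strand", "count"])


def write_ctss_bed(track: pd.DataFrame, path: str | Path, name_prefix: str = "ctss") -> None:
    ordered = track.sort_values(["chrom", "pos", "strand"])[
        ["chrom", "pos", "strand", "count"]
    ]
    with open(path, "w") as fh:
        for i, (chrom, pos, strand, count) in enumerate(
            ordered.itertuples(index=False, name=None), 1
        ):
            count = int(count) if float(count).is_integer() else count
            fh.write(f"{chrom}\t{pos}\t{pos + 1}\t{name_prefix}{i}\t{count}\t{strand}\n")


def write_cluster_bed(clusters: list[TagCluster], path: str | Path) -> None:
    """Promoter BED6: name = promoter id, score = pooled tags."""
    with open(path, "w") as fh:
        for cl in clusters:
            fh.write(
                f"{cl.chrom}\t{cl.start}\t{cl.end}\t{cl.cluster_id}\t{cl.total_tags:g}\t{cl.strand}\n"
            )


def write_fasta(genome: dict[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for chrom in genome:
            fh.write(f">{chrom}\n")
            fh.write(textwrap.fill(genome[chrom], width) + "\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_gtf(genes: pd.DataFrame, path: str | Path, source: str = "fitcage") -> None:
    """Write gene models (gene_id, chrom, start, end, strand) as GTF genes.

    GTF is 1-based inclusive on disk; in-memory coordinates are 0-based
    half-open, so start+1..end is written.
    """
    with open(path, "w") as fh:
        for row in genes.itertuples(index=False):
            attrs = f'gene_id "{row.gene_id}";'
            fh.write(
                f"{row.chrom}\t{source}\tgene\t{row.start + 1}\t{row.end}\t.\t{row.strand}\t.\t{attrs}\n"
            )


def read_gtf_genes(path: str | Path) -> pd.DataFrame:
    """Parse gene records from a GTF via gffutils; returns 0-based half-open
    coordinates plus the strand-resolved 5' end (tss)."""
    import gffutils

    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique", disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    rows = []
    for feat in db.features_of_type("gene"):
        start, end = feat.start - 1, feat.end
        rows.append(
            {
                "gene_id": feat.attributes["gene_id"][0],
                "chrom": feat.seqid,
                "start": start,
                "end": end,
                "strand": feat.strand,
                "tss": start if feat.strand == "+" else end - 1,
            }
        )
    return pd.DataFrame(rows)


def read_jaspar(path: str | Path) -> list[PWM]:
    """Read JASPAR-format PWMs (any release) via Bio.motifs."""
    from Bio import motifs as bio_motifs

    pwms = []
    with open(path) as fh:
        for m in bio_motifs.parse(fh, "jaspar"):
            counts = np.column_stack([m.counts[b] for b in "ACGT"])
            name = m.matrix_id or m.name
            if m.name and m.matrix_id:
                name = f"{m.matrix_id}_{m.name}"
            pwms.append(PWM.from_counts(name, counts))
    return pwms


def write_tsv(df: pd.DataFrame, path: str | Path, provenance: dict | None = None) -> None:
    """Write a TSV with optional '# key=value' provenance header lines."""
    with open(path, "w") as fh:
        if provenance:
            for key, val in provenance.items():
                fh.write(f"# {key}={val}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")
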