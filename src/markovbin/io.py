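"""Readers and writers for the formats the tool exchanges.

FASTA/FASTQ parsing is delegated to Biopython; gzip is sniffed from the
``.gz`` suffix. Quality values are ignored throughout.
"""

from __future__ import annotations

import gzip
import json
from pathlib import Path
from typing import Iterator

import pandas as pd
from Bio import SeqIO

from .reference import Genome
from .taxonomy import RANKS, TaxLineage, read_lineage_table


def _open_text(path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def sniff_format(path) -> str:
    """'fasta' or 'fastq' from the (possibly .gz-wrapped) file extension."""
    name = Path(path).name
    if name.endswith(".gz"):
        name = name[:-3]
    ext = Path(name).suffix.lower()
    if ext in (".fq", ".fastq"):
        return "fastq"
    if ext in (".fa", ".fasta", ".fna", ".ffn"):
        return "fasta"
    raise ValueError(f"cannot infer sequence format from {path}")


def read_sequences(path, fmt: str | None = None) -> Iterator[tuple[str, str]]:
    """Yield (record_id, sequence) from a FASTA/FASTQ file, plain or gzip."""
    fmt = fmt or sniff_format(path)
    with _open_text(path) as fh:
        for rec in SeqIO.parse(fh, fmt):
            yield rec.id, str(rec.seq)


def load_genomes_from_manifest(
    manifest_path, lineages: dict[str, TaxLineage]
) -> list[Genome]:
    """Two-column TSV manifest (path, genome_id); paths relative to the
    manifest. All records in a file pool under its genome_id."""
    base = Path(manifest_path).parent
    df = pd.read_csv(manifest_path, sep="\t", header=None, names=["path", "genome_id"],
                     dtype=str, comment="#")
    genomes = []
    for row in df.itertuples(index=False):
        p = Path(row.path)
        if not p.is_absolute():
            p = base / p
        records = tuple(seq for _, seq in read_sequences(p))
        genomes.append(Genome(row.genome_id, records, lineages.get(row.genome_id)))
    return genomes


def load_genomes_from_fasta(
    fasta_path, lineages: dict[str, TaxLineage]
) -> list[Genome]:
    """One multi-record FASTA where each record is one genome."""
    return [
        Genome(rid, seq, lineages.get(rid)) for rid, seq in read_sequences(fasta_path)
    ]


def write_assignments_tsv(result, path) -> None:
    """Per-read TSV: read_id, genome_id, score, seven lineage columns."""
    result.assignments_frame().to_csv(path, sep="\t", index=False)


def write_profiles_tsv(result, path) -> None:
    """Per-rank composition TSV: rank, taxon, n_reads, proportion."""
    rows = []
    for rank, series in result.profiles.items():
        counts = pd.Series(
            [a.lineage.name_at(rank) for a in result.assignments
             if a.classified and a.lineage.name_at(rank) != "NA"]
        ).value_counts() if len(series) else pd.Series(dtype=int)
        for taxon, prop in series.items():
            rows.append((rank, taxon, int(counts.get(taxon, 0)), prop))
    pd.DataFrame(rows, columns=["rank", "taxon", "n_reads", "proportion"]).to_csv(
        path, sep="\t", index=False
    )


def write_run_log(log: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(log, fh, indent=2, default=str)
        fh.write("\n")


def read_assignments_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"read_id": str, "genome_id": str},
                     keep_default_na=False)
    expected = ["read_id", "genome_id", "score", *RANKS]
    missing = [c for c in expected if c not in df.columns]
    if missing:
        raise ValueError(f"assignment table {path} lacks columns: {missing}")
    return df


def read_truth_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in ("read_id", "genome_id", *RANKS) if c not in df.columns]
    if missing:
        raise ValueError(f"truth table {path} lacks columns: {missing}")
    return df


__all__ = [
    "read_sequences", "sniff_format", "load_genomes_from_manifest",
    "load_genomes_from_fasta", "write_assignments_tsv", "write_profiles_tsv",
    "write_run_log", "read_assignments_tsv", "read_truth_tsv",
    "read_lineage_table",
]
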