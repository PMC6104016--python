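"""Taxonomic lineages and the lineage-table TSV format.

Lineages arrive pre-resolved as a seven-rank table (superkingdom through
species); the sentinel ``"NA"`` marks an unknown rank and never matches
another ``"NA"`` in equality tests.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import pandas as pd

RANKS = ("superkingdom", "phylum", "class", "order", "family", "genus", "species")

#: Ranks at which clade exclusion is meaningful, coarsest last.
EXCLUDABLE_LEVELS = ("species", "genus", "family", "order", "class")

#: Ranks used for per-rank evaluation, coarse to fine.
EVAL_RANKS = ("phylum", "class", "order", "family", "genus", "species")

NA = "NA"


@dataclass(frozen=True)
class TaxLineage:
    """A seven-rank taxonomic lineage. Unknown ranks hold the ``"NA"`` sentinel."""

    superkingdom: str = NA
    phylum: str = NA
    class_: str = NA
    order: str = NA
    family: str = NA
    genus: str = NA
    species: str = NA

    def name_at(self, rank: str) -> str:
        if rank == "class":
            return self.class_
        if rank not in RANKS:
            raise ValueError(f"unknown rank: {rank!r}")
        return getattr(self, rank)

    def matches_at(self, other: "TaxLineage", rank: str) -> bool:
        """Rank-name equality; ``NA`` never matches anything, including ``NA``."""
        a, b = self.name_at(rank), other.name_at(rank)
        return a != NA and b != NA and a == b

    def to_tuple(self) -> tuple[str, ...]:
        return tuple(getattr(self, f.name) for f in fields(self))

    @classmethod
    def from_names(cls, names) -> "TaxLineage":
        names = list(names)
        if len(names) != len(RANKS):
            raise ValueError(f"expected {len(RANKS)} rank names, got {len(names)}")
        return cls(*[str(n) if pd.notna(n) else NA for n in names])


def read_lineage_table(path) -> dict[str, TaxLineage]:
    """Read a lineage TSV with header ``genome_id`` + the seven rank columns."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in ("genome_id", *RANKS) if c not in df.columns]
    if missing:
        raise ValueError(f"lineage table {path} lacks columns: {missing}")
    out: dict[str, TaxLineage] = {}
    for gid, *names in df[["genome_id", *RANKS]].itertuples(index=False, name=None):
        if gid in out:
            raise ValueError(f"duplicate genome_id in lineage table: {gid!r}")
        out[gid] = TaxLineage(*names)
    return out


def lineages_from_frame(df: pd.DataFrame, id_column: str = "read_id") -> dict[str, TaxLineage]:
    """Per-row lineages keyed by ``id_column`` from any frame carrying the
    seven rank columns (e.g. a simulator truth table)."""
    out: dict[str, TaxLineage] = {}
    for key, *names in df[[id_column, *RANKS]].itertuples(index=False, name=None):
        out[key] = TaxLineage(*[str(n) for n in names])
    return out


def write_lineage_table(lineages: dict[str, TaxLineage], path) -> None:
    rows = [(gid, *lin.to_tuple()) for gid, lin in lineages.items()]
    pd.DataFrame(rows, columns=["genome_id", *RANKS]).to_csv(path, sep="\t", index=False)
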