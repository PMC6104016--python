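"""Reference database of per-genome k-th-order Markov transition models.

Each genome is summarised as a vector of negative-log transition
probabilities over all 4**(k+1) k-mer -> k-mer steps:

    P_i(O_n | O_m) = (F_i(O_n | O_m) + c) / (F_i(O_m) + 4 c)

where ``F_i(O_n | O_m)`` counts occurrences of the (k+1)-mer formed by prefix
state O_m followed by the last base of O_n, ``F_i(O_m)`` counts prefix
occurrences *that have a successor* (so every row normalises exactly), and
``c`` is an additive pseudocount that keeps every transition probability
strictly positive. Prefix states never observed get the uniform row P = 1/4.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from ._kmers import transition_counts
from .taxonomy import EXCLUDABLE_LEVELS, NA, TaxLineage

#: Stand-in for -ln(0) when building with pseudocount 0: -ln of the smallest
#: positive double. Keeps score matrices finite; an impossible transition
#: still dominates any realistic score.
ZERO_PROB_NEGLOG = 745.0

_MAGIC = "#markovbin-db"
FORMAT_VERSION = "1"


class DegenerateGenomeError(ValueError):
    """Raised when a genome contains no valid (k+1)-mer window."""


@dataclass(frozen=True)
class Genome:
    """A reference genome: one id, one or more nucleotide records, a lineage."""

    genome_id: str
    sequence: str | tuple[str, ...]
    lineage: TaxLineage | None = None

    @property
    def records(self) -> tuple[str, ...]:
        if isinstance(self.sequence, str):
            return (self.sequence,)
        return tuple(self.sequence)


@dataclass(frozen=True)
class TransitionModel:
    """Negative-log transition probabilities of one genome's order-k chain."""

    genome_id: str
    k: int
    neglogp: np.ndarray  # length 4**(k+1)

    def as_matrix(self) -> np.ndarray:
        """View as (4**k prefix states) x (4 successor bases)."""
        return self.neglogp.reshape(4 ** self.k, 4)


def build_transition_model(
    genome: Genome | str,
    k: int,
    pseudocount: float = 1.0,
    genome_id: str = "",
) -> TransitionModel:
    """Estimate the order-k transition model of a genome.

    Multi-record genomes are pooled; windows never span record boundaries.
    Raises :class:`DegenerateGenomeError` if no record contains a valid
    (k+1)-mer over {A,C,G,T}.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    if pseudocount < 0:
        raise ValueError(f"pseudocount must be >= 0, got {pseudocount}")
    if isinstance(genome, Genome):
        records, gid = genome.records, genome.genome_id
    else:
        records, gid = (genome,), genome_id
    counts = np.zeros(4 ** (k + 1), dtype=np.float64)
    for rec in records:
        counts += transition_counts(rec, k)
    if counts.sum() == 0:
        raise DegenerateGenomeError(
            f"genome {gid!r} has no valid (k+1)-mer for k={k}"
        )
    cmat = counts.reshape(4 ** k, 4)
    row_tot = cmat.sum(axis=1, keepdims=True)
    if pseudocount > 0:
        p = (cmat + pseudocount) / (row_tot + 4 * pseudocount)
    else:
        p = np.full_like(cmat, 0.25)
        seen = row_tot[:, 0] > 0
        p[seen] = cmat[seen] / row_tot[seen]
    neglogp = np.where(p > 0, -np.log(np.where(p > 0, p, 1.0)), ZERO_PROB_NEGLOG)
    neglogp = np.maximum(neglogp, 0.0)  # kill -0.0 from P = 1
    return TransitionModel(gid, k, neglogp.reshape(-1))


@dataclass
class ReferenceDatabase:
    """Stacked transition models plus taxonomy; row order is canonical."""

    k: int
    models: list[TransitionModel]
    lineages: dict[str, TaxLineage]
    format_version: str = FORMAT_VERSION
    _matrix: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        if not self.models:
            raise ValueError("empty reference database is forbidden")
        ids = [m.genome_id for m in self.models]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate genome_id in database")
        for m in self.models:
            if m.k != self.k:
                raise ValueError(f"model {m.genome_id!r} has k={m.k}, database k={self.k}")
            if m.genome_id not in self.lineages:
                raise ValueError(f"genome {m.genome_id!r} lacks a lineage")

    def __len__(self) -> int:
        return len(self.models)

    @property
    def genome_ids(self) -> list[str]:
        return [m.genome_id for m in self.models]

    def matrix(self) -> np.ndarray:
        """(n_genomes x 4**(k+1)) negative-log-probability matrix."""
        if self._matrix is None:
            self._matrix = np.vstack([m.neglogp for m in self.models])
        return self._matrix

    def lineage_of(self, genome_id: str) -> TaxLineage:
        return self.lineages[genome_id]

    # -- serialization: versioned single-file text format -------------------
    # Header line: magic, format_version, k, genome count.
    # Per genome: one tab-separated lineage line ("@" + id + 7 ranks), then
    # one line of IEEE-754 hex floats (exact round-trip, endianness-free).

    def save(self, path) -> None:
        path = Path(path)
        opener = gzip.open if path.suffix == ".gz" else open
        with opener(path, "wt") as fh:
            fh.write(
                f"{_MAGIC}\tformat_version={self.format_version}\tk={self.k}"
                f"\tn_genomes={len(self.models)}\n"
            )
            for m in self.models:
                lin = self.lineages[m.genome_id]
                fh.write("@" + "\t".join((m.genome_id, *lin.to_tuple())) + "\n")
                fh.write(" ".join(float.hex(float(v)) for v in m.neglogp) + "\n")

    @classmethod
    def load(cls, path) -> "ReferenceDatabase":
        path = Path(path)
        opener = gzip.open if path.suffix == ".gz" else open
        with opener(path, "rt") as fh:
            header = fh.readline().rstrip("\n").split("\t")
            if not header or header[0] != _MAGIC:
                raise ValueError(f"{path} is not a markovbin database")
            meta = dict(kv.split("=", 1) for kv in header[1:])
            k, n = int(meta["k"]), int(meta["n_genomes"])
            models, lineages = [], {}
            for _ in range(n):
                linefields = fh.readline().rstrip("\n").split("\t")
                gid = linefields[0].lstrip("@")
                lineages[gid] = TaxLineage(*linefields[1:8])
                vec = np.array(
                    [float.fromhex(t) for t in fh.readline().split()], dtype=np.float64
                )
                models.append(TransitionModel(gid, k, vec))
        return cls(k=k, models=models, lineages=lineages,
                   format_version=meta.get("format_version", "?"))

    def dump_tsv(self, fh) -> None:
        """Plain-TSV debug dump: genome_id, (k+1)-mer, neglogp."""
        width = self.k + 1
        kmers = ["".join("ACGT"[(i >> (2 * (width - 1 - j))) & 3] for j in range(width))
                 for i in range(4 ** width)]
        fh.write("genome_id\ttransition\tneglogp\n")
        for m in self.models:
            for kmer, v in zip(kmers, m.neglogp):
                fh.write(f"{m.genome_id}\t{kmer}\t{v!r}\n")


def build_database(
    genomes: Iterable[Genome],
    lineages: dict[str, TaxLineage],
    k: int = 5,
    pseudocount: float = 1.0,
) -> ReferenceDatabase:
    """Build a database with one model per genome, in stable input order."""
    genomes = list(genomes)
    if not genomes:
        raise ValueError("empty genome collection: empty database forbidden")
    seen: set[str] = set()
    models = []
    for g in genomes:
        if g.genome_id in seen:
            raise ValueError(f"duplicate genome_id: {g.genome_id!r}")
        seen.add(g.genome_id)
        if g.genome_id not in lineages:
            raise ValueError(f"genome {g.genome_id!r} missing from lineage table")
        models.append(build_transition_model(g, k=k, pseudocount=pseudocount))
    return ReferenceDatabase(
        k=k, models=models, lineages={g.genome_id: lineages[g.genome_id] for g in genomes}
    )


def exclude_clade(
    db: ReferenceDatabase,
    query_taxa: Sequence[TaxLineage],
    level: str,
) -> ReferenceDatabase:
    """Drop every genome sharing a query taxon name at ``level``.

    ``level="none"`` returns an identical database. ``NA`` at ``level`` never
    causes exclusion, on either side.
    """
    if level == "none":
        return ReferenceDatabase(
            k=db.k, models=list(db.models), lineages=dict(db.lineages),
            format_version=db.format_version,
        )
    if level not in EXCLUDABLE_LEVELS:
        raise ValueError(f"level must be one of {EXCLUDABLE_LEVELS + ('none',)}, got {level!r}")
    if not query_taxa:
        raise ValueError("query_taxa must be non-empty")
    names = {t.name_at(level) for t in query_taxa} - {NA}
    kept = [m for m in db.models if db.lineages[m.genome_id].name_at(level) not in names]
    if not kept:
        raise ValueError(f"excluding {level!r} would empty the database")
    return ReferenceDatabase(
        k=db.k, models=kept,
        lineages={m.genome_id: db.lineages[m.genome_id] for m in kept},
        format_version=db.format_version,
    )
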