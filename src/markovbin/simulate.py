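"""Synthetic data: Markov-chain genomes, toy taxonomies, communities, reads.

The generator produces the study conditions the classifier is tested under:
genomes drawn from distinct order-k Markov chains, communities with
predefined genome proportions (uniform or geometrically skewed, mock-style),
and single-end reads with uniform start positions and i.i.d. substitution
errors. It deliberately omits platform error profiles, coverage/GC bias,
indels and paired ends: it is a minimal uniform-position sampler, not a
sequencing emulator.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from ._kmers import reverse_complement
from .reference import Genome
from .taxonomy import RANKS, TaxLineage

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class CommunitySpec:
    """A community to sequence: genome proportions and read parameters."""

    members: tuple[tuple[str, float], ...]  # (genome_id, proportion)
    read_length: int = 100
    n_reads: int = 1000
    substitution_rate: float = 0.0
    seed: int = 0
    forward_only: bool = False

    def __post_init__(self):
        props = np.array([p for _, p in self.members], dtype=float)
        if len(props) == 0 or np.any(props <= 0):
            raise ValueError("proportions must be positive")
        if abs(props.sum() - 1.0) > 1e-9:
            raise ValueError(f"proportions must sum to 1, got {props.sum()}")
        if self.n_reads < 1:
            raise ValueError("n_reads must be >= 1")
        if not 0.0 <= self.substitution_rate <= 1.0:
            raise ValueError("substitution_rate must be in [0, 1]")

    def proportions(self) -> np.ndarray:
        return np.array([p for _, p in self.members], dtype=float)

    def genome_ids(self) -> list[str]:
        return [g for g, _ in self.members]


@dataclass(frozen=True)
class GenomeSpec:
    """Recipe for one synthetic genome: an order-k chain to sample from."""

    genome_id: str
    order: int
    transition_matrix: np.ndarray  # (4**order, 4), rows sum to 1
    lineage: TaxLineage


def _validate_stochastic(matrix: np.ndarray, order: int) -> np.ndarray:
    matrix = np.asarray(matrix, dtype=float)
    if matrix.shape != (4 ** order, 4):
        raise ValueError(f"transition matrix must be {(4 ** order, 4)}, got {matrix.shape}")
    if np.any(matrix < 0) or not np.allclose(matrix.sum(axis=1), 1.0, atol=1e-9):
        raise ValueError("rows of the transition matrix must be non-negative and sum to 1")
    return matrix


def random_transition_matrix(
    order: int, concentration: float, rng: np.random.Generator
) -> np.ndarray:
    """Draw a stochastic matrix with Dirichlet(concentration) rows.

    Small concentration gives skewed, highly distinguishable chains; large
    concentration approaches the uniform chain.
    """
    return rng.dirichlet([concentration] * 4, size=4 ** order)


def generate_markov_genome(
    order: int,
    transition_spec,
    length: int,
    seed: int,
    genome_id: str = "genome",
    lineage: TaxLineage | None = None,
) -> Genome:
    """Sample a genome of ``length`` bases from an order-k Markov chain.

    ``transition_spec`` is either a (4**order, 4) stochastic matrix or a
    Dirichlet concentration parameter from which one is drawn. Deterministic
    given ``seed``.
    """
    if order < 1:
        raise ValueError("order must be >= 1")
    if length < order + 1:
        raise ValueError(f"length must be >= order+1 = {order + 1}")
    rng = np.random.default_rng(seed)
    if np.isscalar(transition_spec):
        matrix = random_transition_matrix(order, float(transition_spec), rng)
    else:
        matrix = _validate_stochastic(transition_spec, order)
    cdf = np.cumsum(matrix, axis=1)
    cdf[:, -1] = 1.0
    codes = np.empty(length, dtype=np.int64)
    codes[:order] = rng.integers(0, 4, size=order)
    state = 0
    for i in range(order):
        state = state * 4 + codes[i]
    n_states = 4 ** order
    draws = rng.random(length - order)
    for i in range(order, length):
        nxt = int(np.searchsorted(cdf[state], draws[i - order], side="right"))
        codes[i] = nxt
        state = (state * 4 + nxt) % n_states  # drop the oldest base
    seq = _BASES[codes].tobytes().decode("ascii")
    return Genome(genome_id=genome_id, sequence=seq, lineage=lineage)


def make_toy_taxonomy(
    n_phyla: int,
    genera_per_phylum: int,
    species_per_genus: int,
    seed: int,
    order: int = 1,
    concentration: float = 0.5,
    divergence: float = 0.1,
) -> tuple[dict[str, TaxLineage], list[GenomeSpec]]:
    """Build a full seven-rank toy taxonomy with correlated chain models.

    Each genus gets a base transition matrix; congeneric species perturb it
    by mixing in an independent random matrix with weight ``divergence``
    (0 = congeners share an identical chain), so taxonomic proximity
    correlates with model similarity. Distinct genera and phyla draw
    independent matrices.
    """
    if min(n_phyla, genera_per_phylum, species_per_genus) < 1:
        raise ValueError("all counts must be >= 1")
    if not 0.0 <= divergence <= 1.0:
        raise ValueError("divergence must be in [0, 1]")
    rng = np.random.default_rng(seed)
    lineages: dict[str, TaxLineage] = {}
    specs: list[GenomeSpec] = []
    for p in range(1, n_phyla + 1):
        phylum = f"p{p}"
        for g in range(1, genera_per_phylum + 1):
            genus = f"{phylum}.g{g}"
            base = random_transition_matrix(order, concentration, rng)
            for s in range(1, species_per_genus + 1):
                species = f"{genus}.s{s}"
                gid = species
                if divergence > 0:
                    noise = random_transition_matrix(order, concentration, rng)
                    matrix = (1.0 - divergence) * base + divergence * noise
                else:
                    matrix = base.copy()
                lin = TaxLineage(
                    superkingdom="Bacteria",
                    phylum=phylum,
                    class_=f"{phylum}.c1",
                    order=f"{phylum}.o1",
                    family=f"{genus}.f",
                    genus=genus,
                    species=species,
                )
                lineages[gid] = lin
                specs.append(GenomeSpec(gid, order, matrix, lin))
    return lineages, specs


def realize_genomes(
    specs: Sequence[GenomeSpec], length: int, seed: int
) -> list[Genome]:
    """Sample one genome per spec; per-genome seeds derive from ``seed``."""
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(specs))
    out = []
    for spec, child in zip(specs, children):
        sub_seed = int(child.generate_state(1)[0] % (2 ** 31))
        out.append(
            generate_markov_genome(
                spec.order, spec.transition_matrix, length, sub_seed,
                genome_id=spec.genome_id, lineage=spec.lineage,
            )
        )
    return out


def make_mock_community(
    genome_ids: Sequence[str],
    skew: float,
    read_length: int = 100,
    n_reads: int = 1000,
    substitution_rate: float = 0.0,
    seed: int = 0,
) -> CommunitySpec:
    """Geometric-series proportions with ratio exp(-skew); skew 0 is uniform."""
    if skew < 0:
        raise ValueError("skew must be >= 0")
    raw = np.exp(-skew * np.arange(len(genome_ids)))
    props = raw / raw.sum()
    return CommunitySpec(
        members=tuple(zip(genome_ids, props)),
        read_length=read_length,
        n_reads=n_reads,
        substitution_rate=substitution_rate,
        seed=seed,
    )


def simulate_reads(
    genomes: Sequence[Genome], spec: CommunitySpec
) -> tuple[list[tuple[str, str]], pd.DataFrame]:
    """Sample single-end reads from a community.

    Per read: source genome drawn by proportion, start uniform, strand
    uniform (unless ``forward_only``), then i.i.d. substitutions at
    ``substitution_rate`` choosing among the three other bases. Returns
    (reads as (read_id, sequence) pairs, truth table).
    """
    by_id = {g.genome_id: g for g in genomes}
    missing = [gid for gid in spec.genome_ids() if gid not in by_id]
    if missing:
        raise ValueError(f"community references unknown genomes: {missing}")
    seqs = {}
    for gid in spec.genome_ids():
        seq = "".join(by_id[gid].records)
        if spec.read_length > len(seq):
            raise ValueError(
                f"read_length {spec.read_length} exceeds genome {gid!r} length {len(seq)}"
            )
        seqs[gid] = seq

    rng = np.random.default_rng(spec.seed)
    gids = spec.genome_ids()
    sources = rng.choice(len(gids), size=spec.n_reads, p=spec.proportions())
    reads: list[tuple[str, str]] = []
    truth_rows = []
    code_of = {65: 0, 67: 1, 71: 2, 84: 3}
    for i in range(spec.n_reads):
        gid = gids[sources[i]]
        seq = seqs[gid]
        start = int(rng.integers(0, len(seq) - spec.read_length + 1))
        fragment = seq[start:start + spec.read_length]
        strand = "+"
        if not spec.forward_only and rng.integers(0, 2) == 1:
            strand = "-"
            fragment = reverse_complement(fragment)
        if spec.substitution_rate > 0:
            arr = np.frombuffer(fragment.encode("ascii"), dtype=np.uint8).copy()
            hits = rng.random(spec.read_length) < spec.substitution_rate
            if hits.any():
                idx = np.nonzero(hits)[0]
                for j in idx:
                    orig = code_of.get(int(arr[j]))
                    if orig is None:
                        continue  # leave ambiguous bases untouched
                    shift = int(rng.integers(1, 4))
                    arr[j] = _BASES[(orig + shift) % 4]
                fragment = arr.tobytes().decode("ascii")
        rid = f"read_{i:06d}"
        reads.append((rid, fragment))
        lin = by_id[gid].lineage or TaxLineage()
        truth_rows.append((rid, gid, *lin.to_tuple(), strand, start))
    truth = pd.DataFrame(
        truth_rows, columns=["read_id", "genome_id", *RANKS, "strand", "start"]
    )
    return reads, truth


def write_fastq(reads: Sequence[tuple[str, str]], path) -> None:
    """Write reads as FASTQ with constant quality 'I' (ignored downstream)."""
    with open(path, "w") as fh:
        for rid, seq in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{'I' * len(seq)}\n")


def write_fasta(records: Sequence[tuple[str, str]], path) -> None:
    with open(path, "w") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i:i + 80] + "\n")
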