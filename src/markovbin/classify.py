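"""Read scoring, assignment, and the iterative abundance-weighting loop.

A read of length l contributes l-k valid k-mer -> k-mer steps. Its raw score
against genome i is the negative log-likelihood under the genome's order-k
chain,

    S_raw[r, i] = -sum_j ln p_i(O_{j+1} | O_j),

computed for a whole batch as one dense matrix product between the reads'
transition-count vectors and the database's negative-log-probability matrix.
Abundance weighting multiplies column i by (1 + omega_i) with
omega_i = -alpha * q_i, where q_i is the current estimate of genome i's read
proportion: genomes estimated to be abundant get a smaller multiplier, so
ties and near-ties resolve toward the more abundant organism. The loop
re-estimates q after each full pass and stops when the Bray-Curtis distance
between successive q vectors drops below a cutoff.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import braycurtis as _sp_braycurtis

from ._kmers import reverse_complement, transition_counts
from .reference import ReferenceDatabase
from .taxonomy import NA, RANKS, TaxLineage

UNCLASSIFIED = "UNCLASSIFIED"

_NA_LINEAGE = TaxLineage()


@dataclass(frozen=True)
class TransitionCountVector:
    """Per-read tally of (k+1)-mer transition steps."""

    read_id: str
    k: int
    counts: np.ndarray  # length 4**(k+1)
    n_valid: int


@dataclass(frozen=True)
class WeightVector:
    """Per-genome weights omega, aligned with the database's canonical order."""

    omega: np.ndarray
    iteration: int = 0

    def multipliers(self) -> np.ndarray:
        return 1.0 + self.omega


@dataclass
class ScoreMatrix:
    """reads x genomes score matrix plus the metadata needed to assign."""

    read_ids: list[str]
    genome_ids: list[str]
    values: np.ndarray  # (n_reads, n_genomes)
    n_valid: np.ndarray  # per read


@dataclass(frozen=True)
class Assignment:
    read_id: str
    genome_id: str  # UNCLASSIFIED sentinel for reads with no valid window
    score: float
    lineage: TaxLineage

    @property
    def classified(self) -> bool:
        return self.genome_id != UNCLASSIFIED


@dataclass
class ClassifyConfig:
    """Loop parameters.

    ``alpha`` bounds the abundance prior: a genome's score is shrunk by at
    most ``alpha * q_i`` (10% at the default for a fully dominant genome), so
    the prior resolves near-ties without overriding clear likelihood margins.
    Much larger values make the re-estimation loop rich-get-richer unstable:
    the multiplicative weight scales with the whole negative log-likelihood,
    and a spread beyond typical inter-genome score margins collapses skewed
    communities onto the dominant genome.
    """

    alpha: float = 0.1
    bc_cutoff: float = 1e-3
    max_iter: int = 20
    batch_size: int = 1000
    both_strands: bool = True

    def __post_init__(self):
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError(f"alpha must be in [0, 1], got {self.alpha}")
        if self.bc_cutoff < 0 or self.max_iter < 1 or self.batch_size < 1:
            raise ValueError("invalid classify configuration")


@dataclass
class ClassificationResult:
    assignments: list[Assignment]
    profiles: dict[str, pd.Series]  # rank -> taxon proportions
    log: dict = field(default_factory=dict)

    def assignments_frame(self) -> pd.DataFrame:
        rows = [
            (a.read_id, a.genome_id, a.score, *a.lineage.to_tuple())
            for a in self.assignments
        ]
        return pd.DataFrame(rows, columns=["read_id", "genome_id", "score", *RANKS])


def encode_read(read, k: int) -> TransitionCountVector:
    """Convert a read to its transition-count vector.

    ``read`` may be a ``(read_id, sequence)`` pair, a Biopython SeqRecord, or
    a bare string. Reads shorter than k+1, or with no N-free window, yield
    ``n_valid = 0`` (they flow to UNCLASSIFIED; this is not an error).
    """
    if isinstance(read, str):
        rid, seq = "", read
    elif hasattr(read, "seq"):
        rid, seq = read.id, str(read.seq)
    else:
        rid, seq = read
    counts = transition_counts(seq, k)
    return TransitionCountVector(rid, k, counts, int(counts.sum()))


def raw_scores(
    batch: Sequence[TransitionCountVector], db: ReferenceDatabase
) -> ScoreMatrix:
    """Unweighted scores for a batch as a counts x models matrix product."""
    if not batch:
        raise ValueError("empty batch")
    for v in batch:
        if v.k != db.k:
            raise ValueError(f"read {v.read_id!r} encoded at k={v.k}, database k={db.k}")
    M = db.matrix()
    # one matrix-vector product per read: the reduction order is then fixed
    # per read, so results are bit-identical for any batch size
    values = np.empty((len(batch), M.shape[0]))
    for i, v in enumerate(batch):
        values[i] = M @ v.counts
    return ScoreMatrix(
        read_ids=[v.read_id for v in batch],
        genome_ids=db.genome_ids,
        values=values,
        n_valid=np.array([v.n_valid for v in batch]),
    )


def apply_weights(S_raw: ScoreMatrix, w: WeightVector) -> ScoreMatrix:
    """Column-wise weighting: S[r, i] = S_raw[r, i] * (1 + omega_i)."""
    mult = w.multipliers()
    if len(mult) != len(S_raw.genome_ids):
        raise ValueError("weight vector length does not match genome count")
    if np.any(mult <= 0):
        raise ValueError("all multipliers (1 + omega_i) must be strictly positive")
    return ScoreMatrix(
        read_ids=S_raw.read_ids,
        genome_ids=S_raw.genome_ids,
        values=S_raw.values * mult,
        n_valid=S_raw.n_valid,
    )


def assign(S: ScoreMatrix, db: ReferenceDatabase) -> list[Assignment]:
    """Per-read argmin over genomes; ties break to the first genome in
    canonical order; reads with no valid window become UNCLASSIFIED."""
    best = np.argmin(S.values, axis=1)  # first occurrence wins ties
    out = []
    for r, rid in enumerate(S.read_ids):
        if S.n_valid[r] == 0:
            out.append(Assignment(rid, UNCLASSIFIED, math.nan, _NA_LINEAGE))
        else:
            gid = S.genome_ids[best[r]]
            out.append(Assignment(rid, gid, float(S.values[r, best[r]]),
                                  db.lineage_of(gid)))
    return out


def assignment_proportions(
    assignments: Iterable[Assignment], genome_ids: Sequence[str]
) -> np.ndarray:
    """Fraction of classified reads per genome (q); sums to 1."""
    index = {gid: i for i, gid in enumerate(genome_ids)}
    counts = np.zeros(len(genome_ids))
    for a in assignments:
        if a.classified:
            counts[index[a.genome_id]] += 1
    total = counts.sum()
    if total == 0:
        raise ValueError("no classified reads: proportions undefined")
    return counts / total


def update_weights(
    assignments: Iterable[Assignment],
    genome_ids: Sequence[str],
    alpha: float,
    iteration: int = 0,
) -> WeightVector:
    """omega_i = -alpha * q_i over classified reads."""
    q = assignment_proportions(assignments, genome_ids)
    return WeightVector(omega=-alpha * q, iteration=iteration)


def bray_curtis(u, v) -> float:
    """Bray-Curtis distance between two non-negative composition vectors."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise ValueError("vectors must have equal length")
    if np.any(u < 0) or np.any(v < 0):
        raise ValueError("entries must be non-negative")
    if u.sum() == 0 and v.sum() == 0:
        raise ValueError("Bray-Curtis undefined for two all-zero vectors")
    return float(_sp_braycurtis(u, v))


def _score_all(
    vectors: list[TransitionCountVector],
    rc_vectors: list[TransitionCountVector] | None,
    db: ReferenceDatabase,
    batch_size: int,
) -> ScoreMatrix:
    """Raw scores for all reads, batched; both-strand mode takes the
    elementwise minimum of forward and reverse-complement scores."""
    blocks = []
    for start in range(0, len(vectors), batch_size):
        batch = vectors[start:start + batch_size]
        vals = raw_scores(batch, db).values
        if rc_vectors is not None:
            rvals = raw_scores(rc_vectors[start:start + batch_size], db).values
            vals = np.minimum(vals, rvals)
        blocks.append(vals)
    return ScoreMatrix(
        read_ids=[v.read_id for v in vectors],
        genome_ids=db.genome_ids,
        values=np.vstack(blocks),
        n_valid=np.array([v.n_valid for v in vectors]),
    )


def composition_profiles(
    assignments: Iterable[Assignment], ranks: Sequence[str] = RANKS
) -> dict[str, pd.Series]:
    """Per-rank taxon proportions over classified reads.

    Reads whose assigned lineage is NA at a rank are dropped from that rank's
    profile (NA is not a taxon); proportions renormalise over named taxa.
    """
    profiles: dict[str, pd.Series] = {}
    assignments = list(assignments)
    for rank in ranks:
        names = [a.lineage.name_at(rank) for a in assignments
                 if a.classified and a.lineage.name_at(rank) != NA]
        if names:
            counts = pd.Series(names).value_counts().sort_index()
            profiles[rank] = counts / counts.sum()
        else:
            profiles[rank] = pd.Series(dtype=float)
    return profiles


def classify(
    reads,
    db: ReferenceDatabase,
    config: ClassifyConfig | None = None,
) -> ClassificationResult:
    """Classify a collection of reads with the iterative weighting loop.

    ``reads`` is any iterable of (read_id, sequence) pairs, SeqRecords, or
    strings. Raw scores are computed once; each pass re-weights them with the
    current abundance estimate, re-assigns, and updates the estimate until
    the Bray-Curtis distance between successive estimates falls below
    ``bc_cutoff`` or ``max_iter`` passes have run.
    """
    config = config or ClassifyConfig()
    pairs = _as_pairs(reads)
    if not pairs:
        raise ValueError("empty read stream")
    vectors = [encode_read(p, db.k) for p in pairs]
    rc_vectors = None
    if config.both_strands:
        rc_vectors = [
            encode_read((rid, reverse_complement(seq)), db.k) for rid, seq in pairs
        ]
    S_raw = _score_all(vectors, rc_vectors, db, config.batch_size)

    n = len(db)
    q = np.full(n, 1.0 / n)  # evenly distributed initial estimate
    trajectory: list[float] = []
    assignments: list[Assignment] = []
    converged = False
    iteration = 0
    for iteration in range(1, config.max_iter + 1):
        w = WeightVector(omega=-config.alpha * q, iteration=iteration)
        assignments = assign(apply_weights(S_raw, w), db)
        q_new = assignment_proportions(assignments, db.genome_ids)
        bc = bray_curtis(q, q_new)
        trajectory.append(bc)
        q = q_new
        if bc < config.bc_cutoff:
            converged = True
            break

    profiles = composition_profiles(assignments)
    log = {
        "iterations": iteration,
        "converged": converged,
        "bc_trajectory": trajectory,
        "n_reads": len(vectors),
        "n_unclassified": sum(1 for a in assignments if not a.classified),
        "params": {
            "k": db.k, "alpha": config.alpha, "bc_cutoff": config.bc_cutoff,
            "max_iter": config.max_iter, "batch_size": config.batch_size,
            "both_strands": config.both_strands,
        },
    }
    if not converged:
        log["warning"] = f"weight loop did not converge in {config.max_iter} passes"
    return ClassificationResult(assignments=assignments, profiles=profiles, log=log)


def _as_pairs(reads) -> list[tuple[str, str]]:
    pairs = []
    for r in reads:
        if isinstance(r, str):
            pairs.append(("", r))
        elif hasattr(r, "seq"):
            pairs.append((r.id, str(r.seq)))
        else:
            pairs.append((r[0], r[1]))
    return pairs
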