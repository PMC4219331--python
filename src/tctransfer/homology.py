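"""Pairwise homology scoring with database-size-aware E-values.

The benchmark's central quantity is the *normalized E-value*. An alignment
E-value already scales linearly with the searched database (Karlin–Altschul:
``E = K * m * n * exp(-lambda * S)`` with query length *m* and database
residue count *n*), so thresholds tuned on one database do not transfer to
another. Dividing the raw E-value by the database residue count (alignment
searches) or by the number of reported hits (probabilistic per-sequence
searches) makes thresholds comparable across databases; users who want to
apply a normalized threshold with an external tool should multiply it by
their database size.

This module provides:

* local (Smith–Waterman) and global (Needleman–Wunsch) affine-gap scoring
  over an integer substitution matrix (BLOSUM62 default);
* Karlin–Altschul E-values for local scores and a shuffle-null z-test for
  global scores;
* the two normalization rules;
* an all-vs-all search driver producing sorted :class:`HitRecord` lists;
* parsers for external 12-column tabular alignment hits and per-target
  tabular probabilistic-search output.
"""

from __future__ import annotations

import csv
import math
import warnings
import zlib
from dataclasses import dataclass, field, replace

import numpy as np
from Bio.Align import substitution_matrices
from scipy import stats

from ._align import nw_score, sw_fill
from .seqdata import AA20, ALPHABET, AnnotatedDataset

BACKENDS = (
    "builtin_local",
    "builtin_global",
    "external_alignment",
    "external_probabilistic",
    "motif_scan",
)

#: Published gapped Karlin–Altschul constants for BLOSUM62 with -11/-1 gaps.
BLOSUM62_GAPPED_LAMBDA = 0.267
BLOSUM62_GAPPED_K = 0.041


@dataclass(eq=False)
class ScoringScheme:
    """Substitution matrix, affine gap costs and Karlin–Altschul constants.

    The matrix is indexed by position in ``alphabet``; a gap of length L
    scores ``gap_open + L * gap_extend``. ``lam``/``K`` calibrate the local
    E-value; the gapped values cannot be derived in closed form, so the
    published constants for the matrix/gap combination are carried as
    configurable fields (the ungapped ``lam`` is available from
    :func:`estimate_ungapped_lambda`).
    """

    matrix: np.ndarray
    alphabet: str = ALPHABET
    gap_open: int = -11
    gap_extend: int = -1
    lam: float = BLOSUM62_GAPPED_LAMBDA
    K: float = BLOSUM62_GAPPED_K

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.int64)
        k = len(self.alphabet)
        if self.matrix.shape != (k, k):
            raise ValueError(f"matrix must be {k}x{k} for alphabet {self.alphabet!r}")
        if not np.array_equal(self.matrix, self.matrix.T):
            raise ValueError("substitution matrix must be symmetric")
        if self.gap_open >= 0 or self.gap_extend >= 0:
            raise ValueError("gap penalties must be negative")
        if self.lam <= 0 or self.K <= 0:
            raise ValueError("lambda and K must be positive")
        self._index = {ch: i for i, ch in enumerate(self.alphabet)}
        core = self.matrix[:20, :20].astype(float)
        if core.mean() >= 0:
            raise ValueError("expected score under uniform background must be < 0")

    @classmethod
    def blosum62(cls, gap_open: int = -11, gap_extend: int = -1) -> "ScoringScheme":
        blosum = substitution_matrices.load("BLOSUM62")
        k = len(ALPHABET)
        matrix = np.zeros((k, k), dtype=np.int64)
        for i, a in enumerate(ALPHABET):
            for j, b in enumerate(ALPHABET):
                matrix[i, j] = int(blosum[a, b])
        return cls(matrix=matrix, gap_open=gap_open, gap_extend=gap_extend)

    def encode(self, seq: str) -> np.ndarray:
        try:
            return np.array([self._index[ch] for ch in seq], dtype=np.int64)
        except KeyError as exc:
            raise ValueError(
                f"residue {exc.args[0]!r} outside scoring alphabet"
            ) from None


_DEFAULT_SCHEME: ScoringScheme | None = None


def default_scheme() -> ScoringScheme:
    """The shared BLOSUM62/-11/-1 scheme (constructed once)."""
    global _DEFAULT_SCHEME
    if _DEFAULT_SCHEME is None:
        _DEFAULT_SCHEME = ScoringScheme.blosum62()
    return _DEFAULT_SCHEME


@dataclass(frozen=True)
class SearchContext:
    """Karlin–Altschul lengths of one search: query length m, database n."""

    db_residues: int
    db_sequences: int
    query_length: int

    def __post_init__(self) -> None:
        if not self.db_residues >= self.db_sequences >= 1:
            raise ValueError("need db_residues >= db_sequences >= 1")
        if self.query_length < 1:
            raise ValueError("query_length must be >= 1")


@dataclass(frozen=True)
class HitRecord:
    """One query→target comparison with raw and normalized statistics."""

    query_id: str
    target_id: str
    raw_score: float
    raw_evalue: float
    normalized_evalue: float
    backend: str

    def __post_init__(self) -> None:
        if self.backend not in BACKENDS:
            raise ValueError(f"unknown backend {self.backend!r}")
        if not self.raw_evalue > 0:
            raise ValueError("raw_evalue must be > 0")
        if self.normalized_evalue < 0:
            raise ValueError("normalized_evalue must be >= 0")


def hit_sort_key(hit: HitRecord):
    """Global deterministic ordering: normalized E up, raw score down, id."""
    return (hit.normalized_evalue, -hit.raw_score, hit.target_id)


# ---------------------------------------------------------------------------
# Alignment scoring
# ---------------------------------------------------------------------------

def smith_waterman(seq_a: str, seq_b: str, scheme: ScoringScheme | None = None):
    """Optimal affine-gap local alignment.

    Returns ``(score, ((a_start, a_end), (b_start, b_end)))`` with half-open
    0-based intervals of the optimal local alignment. Ties are resolved by
    taking the first optimum in row-major order and, during traceback,
    preferring diagonal, then vertical (up), then horizontal (left) moves.
    A score of 0 corresponds to the empty alignment and empty intervals.
    """
    scheme = scheme or default_scheme()
    if not seq_a or not seq_b:
        raise ValueError("sequences must be non-empty")
    a = scheme.encode(seq_a)
    b = scheme.encode(seq_b)
    H, E, F, best, bi, bj = sw_fill(
        a, b, scheme.matrix, scheme.gap_open, scheme.gap_extend
    )
    if best == 0:
        return 0, ((0, 0), (0, 0))
    go, ge = scheme.gap_open, scheme.gap_extend
    i, j = bi, bj
    state = "H"
    while True:
        if state == "H":
            if H[i, j] == 0:
                break
            diag = H[i - 1, j - 1] + scheme.matrix[a[i - 1], b[j - 1]]
            if H[i, j] == diag:
                i -= 1
                j -= 1
            elif H[i, j] == F[i, j]:
                state = "F"
            else:
                state = "E"
        elif state == "F":  # vertical gap: consume from seq_a
            from_open = H[i - 1, j] + go + ge
            if F[i, j] == from_open:
                state = "H"
            i -= 1
        else:  # horizontal gap: consume from seq_b
            from_open = H[i, j - 1] + go + ge
            if E[i, j] == from_open:
                state = "H"
            j -= 1
    return int(best), ((int(i), int(bi)), (int(j), int(bj)))


def needleman_wunsch(seq_a: str, seq_b: str, scheme: ScoringScheme | None = None) -> int:
    """Optimal affine-gap global alignment score (may be negative)."""
    scheme = scheme or default_scheme()
    if not seq_a or not seq_b:
        raise ValueError("sequences must be non-empty")
    a = scheme.encode(seq_a)
    b = scheme.encode(seq_b)
    return int(nw_score(a, b, scheme.matrix, scheme.gap_open, scheme.gap_extend))


# ---------------------------------------------------------------------------
# Significance
# ---------------------------------------------------------------------------

def karlin_altschul_evalue(
    score: float, context: SearchContext, scheme: ScoringScheme | None = None
) -> float:
    """``E = K * m * n * exp(-lambda * S)`` for a local alignment score.

    Strictly decreasing in the score and proportional to the database
    residue count n (the property the per-residue normalization removes).
    """
    scheme = scheme or default_scheme()
    if score < 0:
        raise ValueError("local alignment score must be >= 0")
    m = context.query_length
    n = context.db_residues
    return scheme.K * m * n * math.exp(-scheme.lam * score)


def estimate_ungapped_lambda(
    matrix: np.ndarray, background: np.ndarray, tol: float = 1e-9
) -> float:
    """Solve ``sum_ij f_i f_j exp(lambda * s_ij) = 1`` for lambda > 0.

    The root exists and is unique when the expected score under the
    background is negative and some score is positive; found by bisection to
    ``|f(lambda)| < tol``.
    """
    matrix = np.asarray(matrix, dtype=float)
    background = np.asarray(background, dtype=float)
    weights = np.outer(background, background)
    expected = float((weights * matrix).sum())
    if expected >= 0:
        raise ValueError("expected score must be negative for lambda to exist")
    if matrix.max() <= 0:
        raise ValueError("some positive score is required for lambda to exist")

    def f(lam: float) -> float:
        return float((weights * np.exp(lam * matrix)).sum()) - 1.0

    lo, hi = 0.0, 0.5
    while f(hi) < 0:
        hi *= 2.0
        if hi > 1e4:
            raise RuntimeError("failed to bracket lambda")
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        val = f(mid)
        if abs(val) < tol:
            return mid
        if val < 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def shuffle_pvalue(
    seq_a: str,
    seq_b: str,
    scheme: ScoringScheme | None = None,
    n_shuffles: int = 100,
    seed: int = 0,
):
    """Significance of the global score of ``seq_a`` vs ``seq_b``.

    ``seq_b`` is shuffled ``n_shuffles`` times; ``z`` is the standardized
    observed score and ``p`` its upper-tail normal approximation. When the
    shuffle distribution is degenerate (sd = 0, e.g. homopolymers) ``p`` is
    set to 1 with a warning. Deterministic given ``seed``.
    """
    if n_shuffles < 30:
        raise ValueError("n_shuffles must be >= 30")
    scheme = scheme or default_scheme()
    rng = np.random.default_rng(seed)
    observed = needleman_wunsch(seq_a, seq_b, scheme)
    b = scheme.encode(seq_b)
    a = scheme.encode(seq_a)
    scores = np.empty(n_shuffles, dtype=float)
    for k in range(n_shuffles):
        shuffled = rng.permutation(b)
        scores[k] = nw_score(a, shuffled, scheme.matrix, scheme.gap_open, scheme.gap_extend)
    sd = float(scores.std(ddof=1))
    if sd == 0.0:
        warnings.warn("degenerate shuffle distribution (sd = 0); p set to 1")
        return 1.0, 0.0
    z = (observed - float(scores.mean())) / sd
    p = float(stats.norm.sf(z))
    return p, float(z)


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------

def normalize_per_residue(raw_evalue: float, db_residues: int) -> float:
    """Divide an alignment E-value by the searched database's residue count."""
    if db_residues < 1:
        raise ValueError("db_residues must be >= 1")
    if raw_evalue < 0:
        raise ValueError("raw_evalue must be >= 0")
    return raw_evalue / db_residues


def normalize_per_hit(raw_evalue: float, n_hits: int) -> float:
    """Divide a probabilistic-search E-value by the number of reported hits."""
    if n_hits == 0:
        raise ValueError("no hits: nothing to normalize")
    if n_hits < 0:
        raise ValueError("n_hits must be >= 1")
    return raw_evalue / n_hits


# ---------------------------------------------------------------------------
# All-vs-all search
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SearchParams:
    """Knobs of the built-in search engines.

    ``report_ceiling`` drops hits whose *raw* E-value exceeds it. For the
    global engine the raw E-value is ``p * db_sequences`` (a per-sequence
    statistic), hence the per-hit rule normalizes it; hit counts are taken
    per query (``per_hit_per_query=False`` switches to the whole run).
    """

    report_ceiling: float = 10.0
    n_shuffles: int = 50
    per_hit_per_query: bool = True
    min_raw_evalue: float = 1e-300  # floor so reported E-values stay positive


def _pair_seed(seed: int, query_id: str, target_id: str) -> int:
    return zlib.crc32(f"{seed}:{query_id}:{target_id}".encode()) & 0x7FFFFFFF


def search_all_vs_all(
    queries: AnnotatedDataset,
    reference: AnnotatedDataset,
    engine: str = "builtin_local",
    scheme: ScoringScheme | None = None,
    params: SearchParams | None = None,
    seed: int = 0,
) -> list:
    """Compare every query against every reference target.

    Local hits get Karlin–Altschul raw E-values normalized per residue of
    the reference database; global hits get shuffle-null raw E-values
    (``p * db_sequences``) normalized per reported hit. Self-comparisons
    (identical ids) are skipped. The result is sorted by the global hit
    order (normalized E ascending, raw score descending, target id).
    """
    if engine not in ("builtin_local", "builtin_global"):
        raise ValueError(f"unknown built-in engine {engine!r}")
    if len(reference) == 0:
        raise ValueError("reference dataset is empty")
    scheme = scheme or default_scheme()
    params = params or SearchParams()
    db_residues = reference.residue_count
    db_sequences = len(reference)
    hits: list = []
    for query in queries.records:
        query_hits: list = []
        for target in reference.records:
            if target.id == query.id:
                continue
            if engine == "builtin_local":
                score, _ = smith_waterman(query.sequence, target.sequence, scheme)
                context = SearchContext(
                    db_residues=db_residues,
                    db_sequences=db_sequences,
                    query_length=len(query),
                )
                raw = karlin_altschul_evalue(score, context, scheme)
                raw = max(raw, params.min_raw_evalue)
                if raw <= params.report_ceiling:
                    query_hits.append(
                        HitRecord(
                            query_id=query.id,
                            target_id=target.id,
                            raw_score=float(score),
                            raw_evalue=raw,
                            normalized_evalue=normalize_per_residue(raw, db_residues),
                            backend="builtin_local",
                        )
                    )
            else:
                score = needleman_wunsch(query.sequence, target.sequence, scheme)
                p, _z = shuffle_pvalue(
                    query.sequence,
                    target.sequence,
                    scheme,
                    n_shuffles=params.n_shuffles,
                    seed=_pair_seed(seed, query.id, target.id),
                )
                raw = max(p * db_sequences, params.min_raw_evalue)
                if raw <= params.report_ceiling:
                    query_hits.append(
                        HitRecord(
                            query_id=query.id,
                            target_id=target.id,
                            raw_score=float(score),
                            raw_evalue=raw,
                            normalized_evalue=raw,  # per-hit normalization below
                            backend="builtin_global",
                        )
                    )
        if engine == "builtin_global" and query_hits and params.per_hit_per_query:
            n_hits = len(query_hits)
            query_hits = [
                replace(h, normalized_evalue=normalize_per_hit(h.raw_evalue, n_hits))
                for h in query_hits
            ]
        hits.extend(query_hits)
    if engine == "builtin_global" and hits and not params.per_hit_per_query:
        n_hits = len(hits)
        hits = [
            replace(h, normalized_evalue=normalize_per_hit(h.raw_evalue, n_hits))
            for h in hits
        ]
    hits.sort(key=hit_sort_key)
    return hits


# ---------------------------------------------------------------------------
# External tabular parsers
# ---------------------------------------------------------------------------

def parse_alignment_tabular(path, db_residues: int) -> list:
    """Parse 12-column tabular alignment hits (query, target, %id, length,
    mismatches, gapopens, qstart, qend, tstart, tend, evalue, bitscore).

    Coordinates in the file are 1-based inclusive; only ids, E-value and bit
    score feed the benchmark. Normalization is per residue of the searched
    database.
    """
    hits: list = []
    with open(path, newline="") as fh:
        for line_num, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 12:
                raise ValueError(
                    f"{path}: line {line_num}: expected 12 columns, got {len(fields)}"
                )
            try:
                raw = float(fields[10])
                bitscore = float(fields[11])
            except ValueError as exc:
                raise ValueError(f"{path}: line {line_num}: {exc}") from None
            raw = max(raw, 1e-300)
            hits.append(
                HitRecord(
                    query_id=fields[0],
                    target_id=fields[1],
                    raw_score=bitscore,
                    raw_evalue=raw,
                    normalized_evalue=normalize_per_residue(raw, db_residues),
                    backend="external_alignment",
                )
            )
    hits.sort(key=hit_sort_key)
    return hits


def parse_probabilistic_tabular(path) -> list:
    """Parse per-target tabular output of a probabilistic homology search.

    Whitespace-delimited rows in the HMMER3 ``--tblout`` column layout
    (target id, target accession, query id, query accession, full-sequence
    E-value, full-sequence score, ...); ``#`` comment lines are ignored and
    a file with no data rows yields an empty list. Each hit's E-value is
    normalized by the number of hits reported *for its query*.
    """
    rows: list = []
    with open(path) as fh:
        for line_num, line in enumerate(fh, start=1):
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 6:
                raise ValueError(
                    f"{path}: line {line_num}: expected >= 6 whitespace-"
                    f"delimited columns, got {len(fields)}"
                )
            try:
                raw = float(fields[4])
                score = float(fields[5])
            except ValueError as exc:
                raise ValueError(f"{path}: line {line_num}: {exc}") from None
            rows.append((fields[2], fields[0], score, max(raw, 1e-300)))
    counts: dict = {}
    for query_id, *_ in rows:
        counts[query_id] = counts.get(query_id, 0) + 1
    hits = [
        HitRecord(
            query_id=query_id,
            target_id=target_id,
            raw_score=score,
            raw_evalue=raw,
            normalized_evalue=normalize_per_hit(raw, counts[query_id]),
            backend="external_probabilistic",
        )
        for query_id, target_id, score, raw in rows
    ]
    hits.sort(key=hit_sort_key)
    return hits


# ---------------------------------------------------------------------------
# Hits TSV
# ---------------------------------------------------------------------------

HITS_COLUMNS = ("query", "target", "raw_score", "raw_evalue", "normalized_evalue", "backend")


def write_hits_tsv(path, hits) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(HITS_COLUMNS)
        for h in hits:
            writer.writerow(
                [h.query_id, h.target_id, repr(h.raw_score), repr(h.raw_evalue),
                 repr(h.normalized_evalue), h.backend]
            )


def read_hits_tsv(path) -> list:
    hits = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header is None or tuple(header) != HITS_COLUMNS:
            raise ValueError(f"{path}: bad hits header {header}")
        for row in reader:
            hits.append(
                HitRecord(
                    query_id=row[0], target_id=row[1], raw_score=float(row[2]),
                    raw_evalue=float(row[3]), normalized_evalue=float(row[4]),
                    backend=row[5],
                )
            )
    return hits
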