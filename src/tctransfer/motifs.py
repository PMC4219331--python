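"""EM motif discovery (ZOOPS) and PWM scanning within transporter families.

Motif discovery follows the classic expectation-maximization scheme for the
"zero or one occurrence per sequence" (ZOOPS) site model: each sequence
either contains one motif site (uniformly located) or none, with a shared
site prior gamma. The E-step computes posterior site probabilities from the
current position weight matrix (PWM); the M-step re-estimates the PWM from
posterior-weighted counts (pseudocount ``0.01 * background``) and gamma from
the posterior site mass. Starting points are seeded MEME-style from the
W-mers present in the input: every candidate W-mer becomes a smoothed
one-hot PWM, is scored by one EM iteration, and the best candidate is
refined to convergence. After each motif its best sites are hard-masked so
successive motifs occupy disjoint sites.

Scanning mirrors the classic motif-search statistics: per-position log-odds
scores, an exact site p-value from the integer-scaled score distribution
under the background, a per-sequence p-value for the best site, and a
product-of-p-values combination over a family's motifs with the correction
``P = p * sum_{i<k} (-ln p)^i / i!``.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .seqdata import AA20

logger = logging.getLogger(__name__)

_AA_INDEX = {ch: i for i, ch in enumerate(AA20)}


@dataclass
class PWMotif:
    """A position weight matrix of width W over the 20 amino acids."""

    probs: np.ndarray  # (W, 20), rows sum to 1
    background: np.ndarray  # (20,)
    motif_id: str = "m1"
    source_family: str = ""
    n_sites: int = 0
    ll_trace: tuple = ()  # log-likelihood per EM iteration (diagnostic)

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.probs.ndim != 2 or self.probs.shape[1] != 20:
            raise ValueError("probs must be (W, 20)")
        if self.width < 4:
            raise ValueError("motif width must be >= 4")
        if not np.allclose(self.probs.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("PWM rows must sum to 1")
        if self.background.shape != (20,) or abs(self.background.sum() - 1.0) > 1e-9:
            raise ValueError("background must be a 20-vector summing to 1")

    @property
    def width(self) -> int:
        return self.probs.shape[0]

    @property
    def consensus(self) -> str:
        return "".join(AA20[i] for i in self.probs.argmax(axis=1))

    def information_content(self) -> float:
        """Total IC in bits: sum_w sum_a p log2(p / background)."""
        with np.errstate(divide="ignore", invalid="ignore"):
            terms = self.probs * np.log2(self.probs / self.background)
        return float(np.nansum(terms))


@dataclass(frozen=True)
class MotifHit:
    motif_id: str
    sequence_id: str
    position: int
    site_pvalue: float
    sequence_pvalue: float
    combined_evalue: float

    def __post_init__(self) -> None:
        if not 0 < self.site_pvalue <= 1 or not 0 < self.sequence_pvalue <= 1:
            raise ValueError("p-values must lie in (0, 1]")


# ---------------------------------------------------------------------------
# Encoding helpers
# ---------------------------------------------------------------------------

def _encode(seq: str) -> np.ndarray:
    # X (or any non-canonical residue) encodes as -1 and never seeds or
    # overlaps a motif window.
    return np.array([_AA_INDEX.get(ch, -1) for ch in seq], dtype=np.int64)


def _window_view(codes: np.ndarray, width: int):
    """(starts, windows) of all width-length windows free of masked residues."""
    if codes.size < width:
        return np.empty(0, np.int64), np.empty((0, width), np.int64)
    wins = np.lib.stride_tricks.sliding_window_view(codes, width)
    valid = (wins >= 0).all(axis=1)
    starts = np.flatnonzero(valid)
    return starts, wins[starts]


# ---------------------------------------------------------------------------
# ZOOPS EM
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EMConfig:
    """Convergence and seeding knobs of the EM search."""

    max_iter: int = 200
    rel_tol: float = 1e-6
    pseudocount: float = 0.01
    max_candidates: int = 150
    seed_match_prob: float = 0.55
    min_sequences: int = 3


def _seed_pwm(wmer: np.ndarray, match_prob: float) -> np.ndarray:
    width = wmer.size
    pwm = np.full((width, 20), (1.0 - match_prob) / 19.0)
    pwm[np.arange(width), wmer] = match_prob
    return pwm


def _odds(pwm: np.ndarray, background: np.ndarray, windows: np.ndarray) -> np.ndarray:
    """Likelihood ratio P(window | motif) / P(window | background) per window."""
    log_ratio = np.log(pwm) - np.log(background)
    width = pwm.shape[0]
    scores = log_ratio[np.arange(width)[None, :], windows].sum(axis=1)
    return np.exp(scores)


def _em_pass(pwm, gamma, background, window_sets, pseudocount):
    """One E+M iteration. Returns (pwm, gamma, log_likelihood, posteriors).

    The log-likelihood omits the additive background constant
    ``sum_i log P_bg(seq_i)``, which no iteration changes.
    """
    width = pwm.shape[0]
    counts = np.tile(pseudocount * background, (width, 1))
    site_mass = []
    posteriors = []
    ll = 0.0
    for _starts, windows in window_sets:
        m = windows.shape[0]
        if m == 0:
            site_mass.append(0.0)
            posteriors.append(np.empty(0))
            continue
        odds = _odds(pwm, background, windows)
        denom = (1.0 - gamma) + gamma / m * odds.sum()
        z = (gamma / m) * odds / denom
        ll += math.log(denom)
        posteriors.append(z)
        site_mass.append(float(z.sum()))
        for w in range(width):
            counts[w] += np.bincount(windows[:, w], weights=z, minlength=20)
    new_pwm = counts / counts.sum(axis=1, keepdims=True)
    new_gamma = float(np.clip(np.mean(site_mass), 1e-4, 1.0 - 1e-4))
    return new_pwm, new_gamma, ll, posteriors


def _candidate_wmers(window_sets, config: EMConfig, rng: np.random.Generator):
    """Distinct W-mers ordered by multiplicity (desc) then first occurrence.

    All repeated W-mers are kept; unique ones fill up to ``max_candidates``,
    subsampled with ``rng`` when there are too many (the only stochastic
    step of the search).
    """
    seen: dict = {}
    order: list = []
    for _starts, windows in window_sets:
        for row in windows:
            key = row.tobytes()
            if key in seen:
                seen[key][0] += 1
            else:
                seen[key] = [1, row.copy()]
                order.append(key)
    repeated = [k for k in order if seen[k][0] > 1]
    unique = [k for k in order if seen[k][0] == 1]
    room = max(0, config.max_candidates - len(repeated))
    if len(unique) > room:
        picked = rng.choice(len(unique), size=room, replace=False)
        unique = [unique[i] for i in sorted(picked)]
    repeated.sort(key=lambda k: -seen[k][0])
    return [seen[k][1] for k in repeated + unique]


def em_discover(
    sequences: Sequence,
    width: int = 15,
    n_motifs: int = 3,
    config: EMConfig | None = None,
    seed: int = 0,
    background: np.ndarray | None = None,
    source_family: str = "",
) -> list:
    """Discover up to ``n_motifs`` ZOOPS motifs of fixed ``width``.

    ``sequences`` is an iterable of ``(id, sequence)`` pairs or bare
    strings. After each motif converges, its best site (per sequence with
    posterior site mass >= 0.5) is hard-masked before the next motif is
    sought, so site sets are disjoint. Degenerate input (e.g. identical
    sequences) still returns motifs. Raises ``ValueError`` when fewer than
    ``config.min_sequences`` sequences are given or ``width`` exceeds the
    shortest sequence.
    """
    config = config or EMConfig()
    seqs = [s if isinstance(s, str) else s[1] for s in sequences]
    if len(seqs) < config.min_sequences:
        raise ValueError(
            f"need >= {config.min_sequences} sequences for motif discovery, "
            f"got {len(seqs)}"
        )
    if width > min(len(s) for s in seqs):
        raise ValueError("width exceeds the shortest sequence")
    bg = np.full(20, 1.0 / 20) if background is None else np.asarray(background, float)
    rng = np.random.default_rng(seed)
    codes = [_encode(s) for s in seqs]
    motifs: list = []
    for motif_index in range(n_motifs):
        window_sets = [_window_view(c, width) for c in codes]
        if all(w.shape[0] == 0 for _s, w in window_sets):
            break
        candidates = _candidate_wmers(window_sets, config, rng)
        if not candidates:
            break
        # starting-point search: one EM pass scores every candidate
        best_ll = -math.inf
        best_pwm = None
        for wmer in candidates:
            pwm0 = _seed_pwm(wmer, config.seed_match_prob)
            _pwm, _gamma, ll, _post = _em_pass(pwm0, 0.5, bg, window_sets, config.pseudocount)
            if ll > best_ll:
                best_ll = ll
                best_pwm = pwm0
        pwm, gamma = best_pwm, 0.5
        trace: list = []
        prev_ll = None
        for _ in range(config.max_iter):
            pwm, gamma, ll, posteriors = _em_pass(
                pwm, gamma, bg, window_sets, config.pseudocount
            )
            trace.append(ll)
            if prev_ll is not None and abs(ll - prev_ll) < config.rel_tol * max(1.0, abs(prev_ll)):
                break
            prev_ll = ll
        # site assignment and hard masking
        n_sites = 0
        for codes_i, (starts, _windows), z in zip(codes, window_sets, posteriors):
            if z.size == 0 or z.sum() < 0.5:
                continue
            n_sites += 1
            best = int(starts[int(np.argmax(z))])
            codes_i[best:best + width] = -1
        motifs.append(
            PWMotif(
                probs=pwm,
                background=bg,
                motif_id=f"m{motif_index + 1}",
                source_family=source_family,
                n_sites=n_sites,
                ll_trace=tuple(trace),
            )
        )
    return motifs


# ---------------------------------------------------------------------------
# Scanning
# ---------------------------------------------------------------------------

_SCORE_SCALE = 100


def _int_log_odds(motif: PWMotif) -> np.ndarray:
    lo = np.log2(motif.probs / motif.background)
    return np.rint(lo * _SCORE_SCALE).astype(np.int64)


def _score_survival(int_lo: np.ndarray, background: np.ndarray):
    """Survival function of the site score of a random background window.

    Exact dynamic-programming convolution of the per-column integer score
    distributions. Returns ``(offset, sf)`` with
    ``P(score >= s) = sf[s - offset]``.
    """
    width = int_lo.shape[0]
    lo_min = int(int_lo.min(axis=1).sum())
    lo_max = int(int_lo.max(axis=1).sum())
    size = lo_max - lo_min + 1
    # initialise with column 0, then convolve in the remaining columns
    dist = np.zeros(size)
    col_min = int(int_lo[0].min())
    for a in range(20):
        dist[int(int_lo[0, a]) - col_min] += background[a]
    cur_min = col_min
    for w in range(1, width):
        col = int_lo[w]
        col_min = int(col.min())
        nxt = np.zeros(size)
        for a in range(20):
            shift = int(col[a]) - col_min
            if background[a] > 0:
                nxt[shift:] += background[a] * dist[: size - shift or None]
        dist = nxt
        cur_min += col_min
    sf = np.cumsum(dist[::-1])[::-1]
    np.clip(sf, 0.0, 1.0, out=sf)
    return cur_min, sf


def _site_pvalue(score: int, offset: int, sf: np.ndarray) -> float:
    idx = score - offset
    if idx < 0:
        return 1.0
    if idx >= sf.size:
        idx = sf.size - 1
    return max(float(sf[idx]), 1e-300)


def combined_pvalue(pvalues: Sequence) -> float:
    """Product-of-p-values combination: ``P = p * sum_{i<k} (-ln p)^i / i!``.

    For k = 1 this is the p-value itself; for independent uniform p-values
    it is the exact distribution of their product.
    """
    pvals = [min(max(float(p), 1e-300), 1.0) for p in pvalues]
    if not pvals:
        raise ValueError("no p-values to combine")
    k = len(pvals)
    log_p = sum(math.log(p) for p in pvals)
    # sum in log space would be overkill; (-ln p)^i / i! stays modest here
    neg = -log_p
    term = 1.0
    total = 1.0
    for i in range(1, k):
        term *= neg / i
        total += term
    return float(min(1.0, math.exp(log_p) * total))


def scan(
    motifs: Sequence,
    test_sequences: Iterable,
    n_database: int | None = None,
) -> list:
    """Scan test sequences with a family's motifs.

    ``test_sequences`` is an iterable of ``(id, sequence)`` pairs. For each
    (motif, sequence): the best-site p-value is converted to a sequence
    p-value ``1 - (1 - p)^(L - W + 1)``; the family's sequence p-values are
    combined by the product rule and multiplied by the number of test
    sequences (``n_database`` override) to give the combined E-value shared
    by the sequence's hits. Sequences shorter than a motif skip that pair
    with a log entry.
    """
    if not motifs:
        raise ValueError("motifs must be non-empty")
    items = [(sid, seq) for sid, seq in test_sequences]
    n_db = len(items) if n_database is None else int(n_database)
    tables = []
    for motif in motifs:
        int_lo = _int_log_odds(motif)
        offset, sf = _score_survival(int_lo, motif.background)
        tables.append((motif, int_lo, offset, sf))
    hits: list = []
    for sid, seq in items:
        codes = _encode(seq)
        per_motif: list = []
        for motif, int_lo, offset, sf in tables:
            width = motif.width
            starts, windows = _window_view(codes, width)
            if windows.shape[0] == 0:
                logger.info(
                    "sequence %s shorter than motif %s (W=%d); pair skipped",
                    sid, motif.motif_id, width,
                )
                continue
            scores = int_lo[np.arange(width)[None, :], windows].sum(axis=1)
            best = int(np.argmax(scores))
            site_p = _site_pvalue(int(scores[best]), offset, sf)
            n_windows = windows.shape[0]
            seq_p = -math.expm1(n_windows * math.log1p(-min(site_p, 1 - 1e-16)))
            seq_p = min(max(seq_p, 1e-300), 1.0)
            per_motif.append((motif.motif_id, int(starts[best]), site_p, seq_p))
        if not per_motif:
            continue
        combined = combined_pvalue([p for *_x, p in per_motif]) * n_db
        for motif_id, position, site_p, seq_p in per_motif:
            hits.append(
                MotifHit(
                    motif_id=motif_id,
                    sequence_id=sid,
                    position=position,
                    site_pvalue=site_p,
                    sequence_pvalue=seq_p,
                    combined_evalue=combined,
                )
            )
    return hits


def combined_evalues(hits: Sequence) -> dict:
    """Map sequence id -> combined E-value (shared across a family's hits)."""
    out: dict = {}
    for hit in hits:
        out[hit.sequence_id] = hit.combined_evalue
    return out


# ---------------------------------------------------------------------------
# Regex export / matching
# ---------------------------------------------------------------------------

def pwm_to_regex(motif: PWMotif, majority_threshold: float = 0.2) -> str:
    """Export a PWM as a bracket-notation regular expression.

    Per column, residues with probability >= ``majority_threshold`` are
    emitted in descending-probability order (ties alphabetical); a single
    residue appears bare, several inside brackets. A column where no residue
    reaches the threshold falls back to its single most probable residue.
    """
    if not 0.0 < majority_threshold <= 1.0:
        raise ValueError("majority_threshold must be in (0, 1]")
    parts = []
    for row in motif.probs:
        chosen = [
            (float(-p), AA20[a]) for a, p in enumerate(row) if p >= majority_threshold
        ]
        if not chosen:
            chosen = [(float(-row.max()), AA20[int(row.argmax())])]
        chosen.sort()
        letters = "".join(ch for _p, ch in chosen)
        parts.append(letters if len(letters) == 1 else f"[{letters}]")
    return "".join(parts)


_CLASS_RE = re.compile(r"\[([A-Z]+)\]|([A-Z])")


def _parse_pattern(pattern: str) -> list:
    classes: list = []
    pos = 0
    while pos < len(pattern):
        ch = pattern[pos]
        if ch == "[":
            end = pattern.find("]", pos)
            if end == -1:
                raise ValueError(f"unclosed bracket at position {pos}")
            inner = pattern[pos + 1:end]
            if not inner or not inner.isalpha() or inner != inner.upper():
                raise ValueError(f"malformed character class {pattern[pos:end + 1]!r}")
            classes.append(frozenset(inner))
            pos = end + 1
        elif ch == "]":
            raise ValueError(f"unmatched ']' at position {pos}")
        elif ch.isalpha() and ch == ch.upper():
            classes.append(frozenset(ch))
            pos += 1
        else:
            raise ValueError(f"illegal pattern character {ch!r} at position {pos}")
    if not classes:
        raise ValueError("empty pattern")
    return classes


def regex_match(pattern: str, sequence: str) -> list:
    """All (possibly overlapping) matches of a bracket-notation pattern.

    Returns ``[(start, matched_substring), ...]`` with 0-based starts.
    Only literals and character classes are supported; malformed brackets
    raise ``ValueError``.
    """
    classes = _parse_pattern(pattern)
    width = len(classes)
    out: list = []
    for start in range(len(sequence) - width + 1):
        window = sequence[start:start + width]
        if all(ch in cls for ch, cls in zip(window, classes)):
            out.append((start, window))
    return out


# ---------------------------------------------------------------------------
# MEME minimal format
# ---------------------------------------------------------------------------

def write_meme(path, motifs: Sequence, background: np.ndarray | None = None) -> None:
    """Write motifs in MEME minimal text format."""
    if not motifs:
        raise ValueError("no motifs to write")
    bg = motifs[0].background if background is None else np.asarray(background, float)
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\n")
        fh.write(f"ALPHABET= {AA20}\n\n")
        fh.write("Background letter frequencies\n")
        fh.write(
            " ".join(f"{AA20[i]} {bg[i]:.6f}" for i in range(20)) + "\n\n"
        )
        for motif in motifs:
            name = motif.motif_id
            alt = motif.source_family or name
            fh.write(f"MOTIF {name} {alt}\n")
            fh.write(
                f"letter-probability matrix: alength= 20 w= {motif.width} "
                f"nsites= {max(motif.n_sites, 1)} E= 0\n"
            )
            for row in motif.probs:
                fh.write(" " + " ".join(f"{p:.6f}" for p in row) + "\n")
            fh.write("\n")


def read_meme(path) -> list:
    """Read motifs from MEME minimal text format."""
    motifs: list = []
    background = np.full(20, 1.0 / 20)
    with open(path) as fh:
        lines = fh.readlines()
    i = 0
    while i < len(lines):
        line = lines[i].strip()
        if line.startswith("Background letter frequencies"):
            tokens = lines[i + 1].split()
            freqs = {tokens[j]: float(tokens[j + 1]) for j in range(0, len(tokens), 2)}
            background = np.array([freqs[ch] for ch in AA20])
            i += 2
            continue
        if line.startswith("MOTIF"):
            fields = line.split()
            name = fields[1]
            family = fields[2] if len(fields) > 2 else ""
            i += 1
            while i < len(lines) and not lines[i].strip().startswith("letter-probability"):
                i += 1
            header = lines[i].strip()
            width = int(re.search(r"w=\s*(\d+)", header).group(1))
            nsites_match = re.search(r"nsites=\s*(\d+)", header)
            n_sites = int(nsites_match.group(1)) if nsites_match else 0
            rows = []
            for w in range(width):
                i += 1
                rows.append([float(x) for x in lines[i].split()])
            probs = np.asarray(rows)
            probs = probs / probs.sum(axis=1, keepdims=True)
            motifs.append(
                PWMotif(
                    probs=probs, background=background, motif_id=name,
                    source_family=family, n_sites=n_sites,
                )
            )
        i += 1
    if not motifs:
        raise ValueError(f"no motifs found in {path}")
    return motifs
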