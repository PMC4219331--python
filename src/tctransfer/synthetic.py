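"""Synthetic two-organism transporter benchmarks with known ground truth.

The generator emulates the statistical structure the annotation-transfer
benchmark assumes: each family descends from a single ancestor sequence
drawn from a background composition; every member in each "organism" is an
independent mutated copy of that ancestor (substitutions plus geometric
indels), so the divergence between two members at per-site rate *r* is
governed by two independent mutation passes. Substrate labels cross-cut the
TC-style family labels: a family listed under several substrates has its
members partitioned among them, so that sequence similarity tracks the
family label more faithfully than the substrate label — the situation the
benchmark is designed to quantify. Optionally a conserved motif is planted
at a known position in every member of selected families.

All randomness flows from one seeded :class:`numpy.random.Generator`;
identical configs yield byte-identical datasets.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .seqdata import AA20, AnnotatedDataset, TransporterRecord

_AA = np.frombuffer(AA20.encode(), dtype=np.uint8)

#: Uniform background over the 20 amino acids.
UNIFORM_BACKGROUND = np.full(20, 1.0 / 20)

#: Hydrophobic-enriched composition loosely resembling membrane proteins
#: (elevated A/F/G/I/L/V, depressed charged residues). Not the default.
MEMBRANE_BACKGROUND = np.array(
    # A     C     D     E     F     G     H     I     K     L
    [0.09, 0.02, 0.03, 0.03, 0.06, 0.08, 0.02, 0.08, 0.03, 0.12,
     # M    N     P     Q     R     S     T     V     W     Y
     0.03, 0.03, 0.04, 0.03, 0.03, 0.07, 0.06, 0.10, 0.02, 0.03]
)

_TC_PREFIXES = ("2.A", "3.A", "1.B", "2.B")


def default_substrate_plan(n_families: int) -> dict:
    """A Figure-2-style cross-cutting plan: each of the four substrate
    classes spans two families and each family serves up to two substrates."""
    n = max(1, n_families)
    plan = {}
    for i, substrate in enumerate(("metal", "phosphate", "sugar", "amino_acid")):
        members = sorted({i % n, (i + 1) % n})
        plan[substrate] = members
    return plan


@dataclass
class SimulationConfig:
    """Parameters of the synthetic benchmark.

    ``members_per_family`` and ``seq_length`` may be an int or an inclusive
    ``(low, high)`` range. ``substitution_rate`` is per site per lineage;
    each generated member is one mutation pass away from its ancestor, so
    two members are separated by two passes. ``substrate_plan`` maps a
    substrate class to the family indices that serve it (families may repeat
    across substrates); ``None`` selects :func:`default_substrate_plan`.
    ``motif_plan`` entries are ``(family_index, consensus, conservation)``.
    """

    n_families: int = 6
    members_per_family: int | tuple = 5
    seq_length: int | tuple = 400
    substitution_rate: float = 0.1
    indel_rate: float = 0.01
    indel_length_geometric_p: float = 0.5
    background: np.ndarray = field(default_factory=lambda: UNIFORM_BACKGROUND.copy())
    substrate_plan: Mapping | None = None
    motif_plan: Sequence = ()
    organisms: tuple = ("OrgA", "OrgB")
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_families < 1:
            raise ValueError("n_families must be >= 1")
        if not (0.0 <= self.substitution_rate < 1.0) and self.substitution_rate != 1.0:
            raise ValueError("substitution_rate must be in [0, 1]")
        if not 0.0 <= self.indel_rate < 1.0:
            raise ValueError("indel_rate must be in [0, 1)")
        if not 0.0 < self.indel_length_geometric_p <= 1.0:
            raise ValueError("indel_length_geometric_p must be in (0, 1]")
        bg = np.asarray(self.background, dtype=float)
        if bg.shape != (20,) or abs(bg.sum() - 1.0) > 1e-9 or (bg < 0).any():
            raise ValueError("background must be a 20-vector summing to 1")
        self.background = bg
        plan = self.substrate_plan
        if plan is not None:
            for substrate, indices in plan.items():
                for i in indices:
                    if not 0 <= int(i) < self.n_families:
                        raise ValueError(
                            f"substrate_plan[{substrate!r}] index {i} out of range"
                        )
        for fam, consensus, conservation in self.motif_plan:
            if not 0 <= int(fam) < self.n_families:
                raise ValueError(f"motif_plan family index {fam} out of range")
            if not set(consensus) <= set(AA20):
                raise ValueError("motif consensus must use the 20-AA alphabet")
            if not 0.0 < conservation <= 1.0:
                raise ValueError("motif conservation must be in (0, 1]")
        if len(self.organisms) != 2:
            raise ValueError("exactly two organisms are generated")

    def resolved_substrate_plan(self) -> dict:
        plan = self.substrate_plan
        if plan is None:
            plan = default_substrate_plan(self.n_families)
        return {s: sorted(int(i) for i in idx) for s, idx in plan.items()}


@dataclass(frozen=True)
class GroundTruthEntry:
    family: str
    substrates: frozenset
    ancestor_id: str
    motif_intervals: tuple = ()  # (start, end) half-open, post-mutation coords


@dataclass
class GroundTruth:
    """Per-record truth plus the ancestor sequences themselves."""

    entries: dict = field(default_factory=dict)
    ancestors: dict = field(default_factory=dict)

    def family_of(self, record_id: str) -> str:
        return self.entries[record_id].family


# ---------------------------------------------------------------------------
# Mutation primitives
# ---------------------------------------------------------------------------

def _draw_background(n: int, background: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    return rng.choice(20, size=n, p=background).astype(np.int8)


def mutate_sequence(
    seq: str,
    substitution_rate: float,
    indel_rate: float,
    indel_length_geometric_p: float,
    rng: np.random.Generator,
    background: np.ndarray | None = None,
) -> str:
    """One mutation pass over ``seq``.

    Each site is substituted independently with probability
    ``substitution_rate``; the replacement is drawn from the background
    *excluding* the current residue (so rate 1 leaves no site unchanged).
    Indel events occur at rate ``indel_rate`` per site, insertion or
    deletion with equal probability, with geometric lengths (parameter
    ``indel_length_geometric_p``). If deletions would consume the whole
    sequence, one residue is retained (documented floor).
    """
    if not seq:
        raise ValueError("sequence must be non-empty")
    bg = UNIFORM_BACKGROUND if background is None else np.asarray(background, float)
    codes = np.frombuffer(seq.encode(), dtype=np.uint8)
    idx = np.searchsorted(_AA, codes).astype(np.int64)
    if not np.array_equal(_AA[idx], codes):
        raise ValueError("sequence contains residues outside the 20-AA alphabet")

    # substitutions, replacement drawn from background excluding current residue
    hit = np.flatnonzero(rng.random(idx.size) < substitution_rate)
    for pos in hit:
        current = idx[pos]
        probs = bg.copy()
        probs[current] = 0.0
        total = probs.sum()
        if total <= 0.0:  # background mass entirely on the current residue
            probs = np.full(20, 1.0 / 19)
            probs[current] = 0.0
        else:
            probs /= total
        idx[pos] = rng.choice(20, p=probs)

    out = list(idx)
    if indel_rate > 0.0:
        n_events = rng.binomial(len(out), indel_rate)
        for _ in range(n_events):
            pos = int(rng.integers(0, len(out) + 1))
            length = int(rng.geometric(indel_length_geometric_p))
            if rng.random() < 0.5:  # insertion
                inserted = list(_draw_background(length, bg, rng))
                out[pos:pos] = inserted
            else:  # deletion
                if len(out) - length < 1:
                    length = len(out) - 1  # floor: never delete the last residue
                if length > 0:
                    del out[pos:pos + length]
    return "".join(AA20[i] for i in out)


def plant_motif(
    seq: str,
    consensus: str,
    conservation: float,
    position: int,
    rng: np.random.Generator,
    background: np.ndarray | None = None,
) -> str:
    """Overwrite ``seq[position:position+len(consensus)]`` with a noisy motif.

    Each motif position independently keeps the consensus residue with
    probability ``conservation`` and is otherwise drawn from the background
    (a background draw may coincide with the consensus by chance).
    """
    width = len(consensus)
    if position < 0 or position + width > len(seq):
        raise ValueError(
            f"motif of width {width} at position {position} does not fit a "
            f"length-{len(seq)} sequence"
        )
    bg = UNIFORM_BACKGROUND if background is None else np.asarray(background, float)
    site = []
    for ch in consensus:
        if rng.random() < conservation:
            site.append(ch)
        else:
            site.append(AA20[int(rng.choice(20, p=bg))])
    return seq[:position] + "".join(site) + seq[position + width:]


# ---------------------------------------------------------------------------
# Benchmark generation
# ---------------------------------------------------------------------------

def _resolve(value, rng: np.random.Generator) -> int:
    if isinstance(value, (tuple, list)):
        low, high = value
        return int(rng.integers(int(low), int(high) + 1))
    return int(value)


def _family_label(index: int) -> str:
    prefix = _TC_PREFIXES[index % len(_TC_PREFIXES)]
    return f"{prefix}.{index // len(_TC_PREFIXES) + 1}"


def _member_substrates(plan: dict, family: int, member: int) -> frozenset:
    """Substrates of the ``member``-th family member (round-robin partition).

    A family listed under several substrate classes has its members dealt
    out among those classes in member-index order, identically in both
    organisms — within-family substrate diversity, as observed for large TC
    families. Families in no substrate list fall back to ``other``.
    """
    serving = [s for s in sorted(plan) if family in plan[s]]
    if not serving:
        return frozenset({"other"})
    return frozenset({serving[member % len(serving)]})


def generate_benchmark(config: SimulationConfig):
    """Generate ``(dataset_a, dataset_b, ground_truth)`` from ``config``.

    Family *k* gets a synthetic TC-style label (``2.A.1``, ``3.A.1``, ...),
    one ancestor drawn from the background, and ``members_per_family``
    mutated copies per organism. Motifs listed in ``motif_plan`` are planted
    after mutation at a random admissible position per member, so
    ``conservation`` alone controls motif divergence.
    """
    rng = np.random.default_rng(config.seed)
    plan = config.resolved_substrate_plan()
    truth = GroundTruth()
    per_organism: dict = {org: [] for org in config.organisms}

    for fam_idx in range(config.n_families):
        label = _family_label(fam_idx)
        length = _resolve(config.seq_length, rng)
        ancestor_idx = _draw_background(length, config.background, rng)
        ancestor = "".join(AA20[i] for i in ancestor_idx)
        ancestor_id = f"F{fam_idx + 1}_ancestor"
        truth.ancestors[ancestor_id] = ancestor
        motifs_here = [
            (consensus, conservation)
            for fam, consensus, conservation in config.motif_plan
            if int(fam) == fam_idx
        ]
        for org in config.organisms:
            n_members = _resolve(config.members_per_family, rng)
            for member in range(n_members):
                seq = mutate_sequence(
                    ancestor,
                    config.substitution_rate,
                    config.indel_rate,
                    config.indel_length_geometric_p,
                    rng,
                    config.background,
                )
                intervals = []
                for consensus, conservation in motifs_here:
                    width = len(consensus)
                    if width > len(seq):
                        continue
                    pos = int(rng.integers(0, len(seq) - width + 1))
                    seq = plant_motif(
                        seq, consensus, conservation, pos, rng, config.background
                    )
                    intervals.append((pos, pos + width))
                substrates = _member_substrates(plan, fam_idx, member)
                rid = f"{org}_F{fam_idx + 1}_M{member + 1}"
                per_organism[org].append(
                    TransporterRecord(
                        id=rid, organism=org, sequence=seq,
                        tc_family=label, substrates=substrates,
                    )
                )
                truth.entries[rid] = GroundTruthEntry(
                    family=label,
                    substrates=substrates,
                    ancestor_id=ancestor_id,
                    motif_intervals=tuple(intervals),
                )

    org_a, org_b = config.organisms
    ds_a = AnnotatedDataset(records=per_organism[org_a], organism=org_a)
    ds_b = AnnotatedDataset(records=per_organism[org_b], organism=org_b)
    return ds_a, ds_b, truth
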