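"""Domain types and IO for transporter sequence datasets.

Membrane transporters are classified by the hierarchical Transporter
Classification (TC) system (``class.subclass.family.subfamily``, e.g.
``3.A.1.1.1``) and, orthogonally, by the substrate class they move (metal
ions, phosphate, sugars, amino acids, ...). This module provides the record
and dataset types the benchmark operates on, readers/writers for FASTA and
tab-separated annotation tables, and the construction of *shared-family*
datasets: given two annotated organisms, keep only the records whose family
label (TC, substrate, or combined ``substrate_TCfamily``) occurs with enough
members in both organisms.

All family comparisons operate at the 3-part TC family level
(``class.subclass.family``); longer ids are truncated, since many annotation
databases ignore the fourth digit.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from functools import cached_property
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

#: The 20 canonical amino acids, alphabetically by one-letter code.
AA20 = "ACDEFGHIKLMNPQRSTVWY"
#: Allowed residue alphabet: 20 amino acids plus the ambiguity code X.
ALPHABET = AA20 + "X"
_ALPHABET_SET = frozenset(ALPHABET)

#: Canonical substrate-class labels used throughout the benchmark.
SUBSTRATE_CLASSES = ("metal", "phosphate", "sugar", "amino_acid", "other")

#: Family-label kinds understood by the benchmark.
FAMILY_KINDS = ("tc", "substrate", "substrate_tc")

_TC_FAMILY_RE = re.compile(r"^\d+\.[A-Za-z]\.\d+$")


class NoSharedFamiliesError(ValueError):
    """Raised when two datasets share no eligible family label."""


def truncate_tc_family(tc_id: str) -> str:
    """Truncate a dotted TC id to its 3-part family (``"3.A.1.2.1"`` -> ``"3.A.1"``).

    Raises ``ValueError`` if the first three components do not follow the
    ``digit.letter.digits`` grammar.
    """
    parts = tc_id.strip().split(".")
    if len(parts) < 3:
        raise ValueError(f"TC id {tc_id!r} has fewer than 3 components")
    family = ".".join(parts[:3])
    if not _TC_FAMILY_RE.match(family):
        raise ValueError(f"TC id {tc_id!r} does not match 'digit.letter.digits'")
    return family


@dataclass(frozen=True)
class TransporterRecord:
    """One protein sequence with organism, TC family and substrate labels."""

    id: str
    organism: str
    sequence: str
    tc_family: str
    substrates: frozenset = frozenset()
    tc_full: str | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("record id must be non-empty")
        if not self.sequence:
            raise ValueError(f"record {self.id!r}: sequence must be non-empty")
        if self.sequence != self.sequence.upper():
            raise ValueError(f"record {self.id!r}: sequence must be uppercase")
        bad = sorted(set(self.sequence) - _ALPHABET_SET)
        if bad:
            raise ValueError(
                f"record {self.id!r}: illegal residue(s) {', '.join(bad)}"
            )
        if not _TC_FAMILY_RE.match(self.tc_family):
            raise ValueError(
                f"record {self.id!r}: tc_family {self.tc_family!r} does not "
                "match 'digit.letter.digits'"
            )
        object.__setattr__(self, "substrates", frozenset(self.substrates))

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class FamilyKey:
    """A family label of a given kind.

    ``substrate_tc`` labels are rendered ``"<substrate>_<TCfamily>"``
    (e.g. ``"sugar_2.A.1"``). Because substrate names may themselves contain
    underscores (``amino_acid``) the label is split from the right; TC family
    ids never contain underscores, so the round trip is unambiguous.
    """

    kind: str
    label: str

    def __post_init__(self) -> None:
        if self.kind not in FAMILY_KINDS:
            raise ValueError(f"unknown family kind {self.kind!r}")
        # must parse back into components
        self.components()

    def components(self) -> tuple:
        if self.kind == "substrate_tc":
            substrate, tc = split_substrate_tc(self.label)
            return (substrate, tc)
        if self.kind == "tc" and not _TC_FAMILY_RE.match(self.label):
            raise ValueError(f"bad TC family label {self.label!r}")
        return (self.label,)


def split_substrate_tc(label: str) -> tuple[str, str]:
    """Split ``"sugar_2.A.1"`` into ``("sugar", "2.A.1")`` (right-most underscore)."""
    if "_" not in label:
        raise ValueError(f"not a substrate_tc label: {label!r}")
    substrate, tc = label.rsplit("_", 1)
    if not substrate or not _TC_FAMILY_RE.match(tc):
        raise ValueError(f"not a substrate_tc label: {label!r}")
    return substrate, tc


def labels_for(record: TransporterRecord, kind: str) -> tuple:
    """All family labels of ``kind`` that a record carries (sorted).

    A record with several substrate annotations appears under one label per
    substrate for the ``substrate`` and ``substrate_tc`` kinds; the sequence
    itself is stored once, the duplication is label-level only.
    """
    if kind == "tc":
        return (record.tc_family,)
    if kind == "substrate":
        return tuple(sorted(record.substrates))
    if kind == "substrate_tc":
        return tuple(f"{s}_{record.tc_family}" for s in sorted(record.substrates))
    raise ValueError(f"unknown family kind {kind!r}")


@dataclass
class AnnotatedDataset:
    """An organism's annotated transporter set.

    ``residue_count`` (the summed sequence length) is the denominator used to
    normalize alignment E-values so that searches against differently sized
    databases become comparable.
    """

    records: list
    organism: str

    def __post_init__(self) -> None:
        seen = set()
        for rec in self.records:
            if rec.id in seen:
                raise ValueError(f"duplicate record id {rec.id!r} in dataset")
            seen.add(rec.id)
            if rec.organism != self.organism:
                raise ValueError(
                    f"record {rec.id!r} has organism {rec.organism!r}, "
                    f"dataset is {self.organism!r}"
                )

    @property
    def residue_count(self) -> int:
        return sum(len(r) for r in self.records)

    @cached_property
    def by_id(self) -> dict:
        return {r.id: r for r in self.records}

    def __len__(self) -> int:
        return len(self.records)

    def family_index(self, kind: str = "tc") -> dict:
        """Map each family label of ``kind`` to the record ids carrying it."""
        index: dict = {}
        for rec in self.records:
            for label in labels_for(rec, kind):
                index.setdefault(label, []).append(rec.id)
        return index

    def label_map(self, kind: str = "tc") -> dict:
        """Map record id -> frozenset of family labels of ``kind``."""
        return {r.id: frozenset(labels_for(r, kind)) for r in self.records}


# ---------------------------------------------------------------------------
# IO
# ---------------------------------------------------------------------------

def read_fasta(path) -> list:
    """Read a FASTA file into ``[(id, sequence), ...]`` in file order.

    Sequences are uppercased and a single trailing ``'*'`` (stop) is
    stripped. Raises ``ValueError`` on an empty file, a duplicate id, or a
    residue outside the 20-amino-acid + X alphabet (naming the offender).
    """
    entries: list = []
    seen: set = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate FASTA id {rec.id!r}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        if seq.endswith("*"):
            seq = seq[:-1]
        bad = sorted(set(seq) - _ALPHABET_SET)
        if bad:
            raise ValueError(
                f"FASTA record {rec.id!r}: illegal residue(s) {', '.join(bad)}"
            )
        entries.append((rec.id, seq))
    if not entries:
        raise ValueError(f"no FASTA records in {path}")
    return entries


def write_fasta(path, entries: Iterable) -> None:
    """Write ``(id, sequence)`` pairs (or TransporterRecords) as FASTA."""
    records = []
    for item in entries:
        if isinstance(item, TransporterRecord):
            records.append(SeqRecord(Seq(item.sequence), id=item.id, description=""))
        else:
            rid, seq = item
            records.append(SeqRecord(Seq(seq), id=rid, description=""))
    SeqIO.write(records, str(path), "fasta")


ANNOTATION_COLUMNS = ("id", "organism", "tc_family", "substrates")


def read_annotations(path) -> dict:
    """Read a 4-column TSV (id, organism, tc_family, substrates).

    The substrates column is comma-joined and may be empty. TC ids are
    truncated to the 3-part family; a malformed id raises ``ValueError``
    carrying the row number.
    """
    out: dict = {}
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header is None or tuple(h.strip() for h in header) != ANNOTATION_COLUMNS:
            raise ValueError(
                f"{path}: expected header {list(ANNOTATION_COLUMNS)}, got {header}"
            )
        for row_num, row in enumerate(reader, start=2):
            if not row or all(not c.strip() for c in row):
                continue
            if len(row) != 4:
                raise ValueError(f"{path}: row {row_num}: expected 4 columns")
            rid, organism, tc_id, substrates_col = (c.strip() for c in row)
            try:
                family = truncate_tc_family(tc_id)
            except ValueError as exc:
                raise ValueError(f"{path}: row {row_num}: {exc}") from exc
            substrates = frozenset(
                s.strip() for s in substrates_col.split(",") if s.strip()
            )
            if rid in out:
                raise ValueError(f"{path}: row {row_num}: duplicate id {rid!r}")
            out[rid] = (organism, family, substrates)
    return out


def write_annotations(path, records: Iterable) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(ANNOTATION_COLUMNS)
        for rec in records:
            writer.writerow(
                [rec.id, rec.organism, rec.tc_family, ",".join(sorted(rec.substrates))]
            )


def load_dataset(fasta_path, annotations_path, organism: str | None = None) -> AnnotatedDataset:
    """Join a FASTA file with its annotation table into an AnnotatedDataset.

    Every FASTA record must be annotated. If ``organism`` is given, only
    records of that organism are kept; otherwise the table must contain a
    single organism.
    """
    sequences = read_fasta(fasta_path)
    annotations = read_annotations(annotations_path)
    records = []
    organisms = set()
    for rid, seq in sequences:
        if rid not in annotations:
            raise ValueError(f"sequence {rid!r} has no annotation row")
        org, family, substrates = annotations[rid]
        if organism is not None and org != organism:
            continue
        organisms.add(org)
        records.append(
            TransporterRecord(
                id=rid, organism=org, sequence=seq, tc_family=family,
                substrates=substrates,
            )
        )
    if organism is None:
        if len(organisms) != 1:
            raise ValueError(
                f"annotation table spans organisms {sorted(organisms)}; "
                "pass organism= to select one"
            )
        organism = organisms.pop()
    if not records:
        raise ValueError(f"no records for organism {organism!r}")
    return AnnotatedDataset(records=records, organism=organism)


# ---------------------------------------------------------------------------
# Shared-family construction
# ---------------------------------------------------------------------------

def build_shared_dataset(
    ds_a: AnnotatedDataset,
    ds_b: AnnotatedDataset,
    kind: str = "tc",
    min_members: int = 2,
):
    """Restrict two datasets to the family labels they share.

    A label is *eligible* in a dataset when at least ``min_members`` records
    carry it there (matching a TC subfamily only makes sense when, with one
    sequence held out, at least one other member remains, hence the default
    of 2; motif discovery uses 3). The shared label set is the intersection
    of the two eligible sets; records carrying no shared label are dropped.

    Returns ``(ref_a, ref_b, shared)`` where ``shared`` is a frozenset of
    labels. Raises :class:`NoSharedFamiliesError` on an empty intersection.
    The label set is symmetric: ``shared(A, B) == shared(B, A)``.
    """
    if kind not in FAMILY_KINDS:
        raise ValueError(f"unknown family kind {kind!r}")
    if min_members < 1:
        raise ValueError("min_members must be >= 1")

    def eligible(ds: AnnotatedDataset) -> set:
        return {
            label
            for label, ids in ds.family_index(kind).items()
            if len(ids) >= min_members
        }

    shared = eligible(ds_a) & eligible(ds_b)
    if not shared:
        raise NoSharedFamiliesError(
            f"no shared {kind!r} families between {ds_a.organism!r} and "
            f"{ds_b.organism!r} (min_members={min_members})"
        )

    def restrict(ds: AnnotatedDataset) -> AnnotatedDataset:
        kept = [
            rec for rec in ds.records
            if any(label in shared for label in labels_for(rec, kind))
        ]
        return AnnotatedDataset(records=kept, organism=ds.organism)

    return restrict(ds_a), restrict(ds_b), frozenset(shared)


def write_shared_manifest(path, dataset: AnnotatedDataset, kind: str, shared) -> None:
    """Write a TSV manifest (id, organism, label) of a shared-family dataset."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["id", "organism", "label"])
        for rec in dataset.records:
            for label in labels_for(rec, kind):
                if label in shared:
                    writer.writerow([rec.id, rec.organism, label])
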