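"""Best-hit annotation transfer and family-weighted benchmarking.

A query sequence from organism X is assigned the family label of its best
reference hit in organism Y, provided that hit's normalized E-value passes
the threshold; otherwise it stays UNCLASSIFIED. Per family, one-vs-rest
confusion counts are accumulated over the *classified* queries only —
unclassified queries are reported separately as a percentage and excluded
from the precision/recall denominators (a query without any acceptable hit
carries no prediction to be right or wrong about). Precision, recall and
F-measure are computed per family and then averaged weighted by family
member count, so large families dominate the summary the way they dominate
the data. The whole evaluation is repeated over a threshold grid
(1e-20 ... 1e-4 by default) from a single search pass.

The substrate_TC cross-tab summarizes, for every pair of combined
``substrate_TCfamily`` labels across the two organisms, the best normalized
E-value between their members, binned on the threshold grid (4 = better
than 1e-20 ... 0 = nothing better than 1e-8).
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import homology
from .homology import HitRecord, hit_sort_key
from .seqdata import AnnotatedDataset, build_shared_dataset, labels_for

UNCLASSIFIED = "UNCLASSIFIED"

#: The benchmark's standard normalized E-value thresholds.
DEFAULT_GRID = (1e-20, 1e-16, 1e-12, 1e-8, 1e-4)


@dataclass(frozen=True)
class ClassificationResult:
    query_id: str
    true_label: str
    predicted: str  # family label or UNCLASSIFIED
    best_hit: HitRecord | None
    threshold: float


@dataclass(frozen=True)
class EvaluationCell:
    """One-vs-rest confusion counts for one family at one threshold."""

    label: str
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")


def _passes(evalue: float, threshold: float, boundary: str) -> bool:
    if boundary == "le":
        return evalue <= threshold
    if boundary == "lt":
        return evalue < threshold
    raise ValueError(f"unknown boundary convention {boundary!r}")


def classify(
    query_id: str,
    true_label: str,
    hits: Sequence,
    reference_labels: Mapping,
    threshold: float,
    boundary: str = "le",
) -> ClassificationResult:
    """Assign the best passing hit's family label to a query.

    ``reference_labels`` maps target id to a label or a set of labels
    (records duplicated under several substrate_TC labels carry a set). If
    the best target carries several labels, the true label wins when
    present, otherwise the lexicographically smallest; ties between hits are
    broken by normalized E, then raw score, then target id. A hit whose
    target has no label raises ``KeyError``.
    """
    passing = []
    for hit in hits:
        if hit.query_id != query_id:
            raise ValueError(f"hit for {hit.query_id!r} passed to query {query_id!r}")
        if hit.target_id not in reference_labels:
            raise KeyError(f"hit target {hit.target_id!r} has no family label")
        if _passes(hit.normalized_evalue, threshold, boundary):
            passing.append(hit)
    if not passing:
        return ClassificationResult(query_id, true_label, UNCLASSIFIED, None, threshold)
    best = min(passing, key=hit_sort_key)
    labels = reference_labels[best.target_id]
    if isinstance(labels, str):
        labels = {labels}
    predicted = true_label if true_label in labels else min(labels)
    return ClassificationResult(query_id, true_label, predicted, best, threshold)


def confusion_by_family(results: Sequence, shared_labels) -> list:
    """One-vs-rest :class:`EvaluationCell` per shared family.

    UNCLASSIFIED results are excluded from every cell; for family f,
    tp/fn/fp partition the classified queries with tn as the remainder, so
    ``tp + fp + fn + tn`` equals the classified count for every family.
    """
    classified = [r for r in results if r.predicted != UNCLASSIFIED]
    total = len(classified)
    cells = []
    for label in sorted(shared_labels):
        tp = sum(1 for r in classified if r.true_label == label and r.predicted == label)
        fn = sum(1 for r in classified if r.true_label == label and r.predicted != label)
        fp = sum(1 for r in classified if r.true_label != label and r.predicted == label)
        tn = total - tp - fn - fp
        cells.append(EvaluationCell(label=label, tp=tp, fp=fp, fn=fn, tn=tn))
    return cells


def precision(cell: EvaluationCell) -> float:
    """``100 * tp / (tp + fp)``; 0 when the denominator is 0."""
    denom = cell.tp + cell.fp
    return 100.0 * cell.tp / denom if denom else 0.0


def recall(cell: EvaluationCell) -> float:
    """``100 * tp / (tp + fn)``; 0 when the denominator is 0."""
    denom = cell.tp + cell.fn
    return 100.0 * cell.tp / denom if denom else 0.0


def f_measure(p: float, r: float) -> float:
    """Harmonic mean ``2pr / (p + r)`` of precision and recall (percent)."""
    if not (0.0 <= p <= 100.0 and 0.0 <= r <= 100.0):
        raise ValueError("precision and recall must be percentages in [0, 100]")
    return 2.0 * p * r / (p + r) if (p + r) else 0.0


def weighted_average(values: Mapping, sizes: Mapping) -> float:
    """Family-size-weighted mean: ``sum_f size_f * v_f / sum_f size_f``."""
    if set(values) != set(sizes):
        raise ValueError("values and sizes must cover the same families")
    total = sum(sizes.values())
    if total <= 0:
        raise ValueError("total family size must be positive")
    return sum(sizes[f] * values[f] for f in values) / total


def unclassified_fraction(results: Sequence) -> float:
    """Percentage of queries without any hit passing the threshold."""
    if not results:
        raise ValueError("no classification results")
    n = sum(1 for r in results if r.predicted == UNCLASSIFIED)
    return 100.0 * n / len(results)


# ---------------------------------------------------------------------------
# Threshold sweep
# ---------------------------------------------------------------------------

@dataclass
class BenchmarkReport:
    """Weighted metrics over a threshold grid, plus per-family cells."""

    grid: tuple
    precision: tuple
    recall: tuple
    f_measure: tuple
    unclassified: tuple
    cells: dict = field(default_factory=dict)  # threshold -> list[EvaluationCell]

    def __post_init__(self) -> None:
        n = len(self.grid)
        for name in ("precision", "recall", "f_measure", "unclassified"):
            row = getattr(self, name)
            if len(row) != n:
                raise ValueError(f"{name} row length != grid length")
            if any(not 0.0 <= v <= 100.0 for v in row):
                raise ValueError(f"{name} values must be percentages in [0, 100]")

    def to_dataframe(self) -> pd.DataFrame:
        cols = [format_threshold(t) for t in self.grid]
        return pd.DataFrame(
            [self.precision, self.recall, self.f_measure, self.unclassified],
            index=["Precision", "Recall", "F-measure", "Unclassified"],
            columns=cols,
        )

    def to_tsv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
            writer.writerow(["metric"] + [format_threshold(t) for t in self.grid])
            for name, row in (
                ("Precision", self.precision),
                ("Recall", self.recall),
                ("F-measure", self.f_measure),
                ("Unclassified", self.unclassified),
            ):
                writer.writerow([name] + [repr(v) for v in row])

    @classmethod
    def from_tsv(cls, path) -> "BenchmarkReport":
        with open(path, newline="") as fh:
            reader = csv.reader(fh, delimiter="\t")
            header = next(reader)
            grid = tuple(float(t) for t in header[1:])
            rows = {row[0]: tuple(float(v) for v in row[1:]) for row in reader}
        return cls(
            grid=grid,
            precision=rows["Precision"],
            recall=rows["Recall"],
            f_measure=rows["F-measure"],
            unclassified=rows["Unclassified"],
        )

    def cells_to_json(self, path) -> None:
        payload = {
            format_threshold(t): [
                {"family": c.label, "tp": c.tp, "fp": c.fp, "fn": c.fn, "tn": c.tn}
                for c in cells
            ]
            for t, cells in self.cells.items()
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


def format_threshold(t: float) -> str:
    exponent = int(round(math.log10(t)))
    return f"1e{exponent}" if abs(t - 10.0 ** exponent) < 1e-12 * t else repr(t)


def query_instances(queries: AnnotatedDataset, kind: str, shared) -> list:
    """Expand query records into ``(query_id, true_label)`` test instances.

    A record carrying several shared labels of the given kind (e.g. a
    multi-substrate transporter under substrate_tc) contributes one instance
    per label; the sequence itself is stored once.
    """
    out = []
    for rec in queries.records:
        for label in labels_for(rec, kind):
            if label in shared:
                out.append((rec.id, label))
    return out


def sweep_from_hits(
    hits: Sequence,
    instances: Sequence,
    reference_labels: Mapping,
    grid: Sequence = DEFAULT_GRID,
    family_sizes: Mapping | None = None,
    boundary: str = "le",
) -> BenchmarkReport:
    """Classify and evaluate the given hits at every threshold of ``grid``.

    ``instances`` are ``(query_id, true_label)`` pairs; ``family_sizes``
    defaults to the per-family instance counts on the query side (the
    test-set member counts used as averaging weights). The grid must be
    strictly increasing (loosening thresholds), which makes the unclassified
    percentage non-increasing along the row.
    """
    grid = tuple(grid)
    if any(b <= a for a, b in zip(grid, grid[1:])):
        raise ValueError("threshold grid must be strictly increasing")
    if not instances:
        raise ValueError("no query instances to evaluate")
    shared = sorted({label for _qid, label in instances})
    if family_sizes is None:
        family_sizes = {label: 0 for label in shared}
        for _qid, label in instances:
            family_sizes[label] += 1
    by_query: dict = {}
    for hit in hits:
        by_query.setdefault(hit.query_id, []).append(hit)

    p_row, r_row, f_row, u_row = [], [], [], []
    all_cells: dict = {}
    for threshold in grid:
        results = [
            classify(qid, label, by_query.get(qid, ()), reference_labels,
                     threshold, boundary)
            for qid, label in instances
        ]
        cells = confusion_by_family(results, shared)
        p_by = {c.label: precision(c) for c in cells}
        r_by = {c.label: recall(c) for c in cells}
        f_by = {c.label: f_measure(p_by[c.label], r_by[c.label]) for c in cells}
        p_row.append(weighted_average(p_by, family_sizes))
        r_row.append(weighted_average(r_by, family_sizes))
        f_row.append(weighted_average(f_by, family_sizes))
        u_row.append(unclassified_fraction(results))
        all_cells[threshold] = cells
    return BenchmarkReport(
        grid=grid,
        precision=tuple(p_row),
        recall=tuple(r_row),
        f_measure=tuple(f_row),
        unclassified=tuple(u_row),
        cells=all_cells,
    )


def threshold_sweep(
    queries: AnnotatedDataset,
    reference: AnnotatedDataset,
    kind: str = "tc",
    engine: str = "builtin_local",
    scheme=None,
    grid: Sequence = DEFAULT_GRID,
    params=None,
    min_members: int = 2,
    seed: int = 0,
    boundary: str = "le",
):
    """Full pipeline: shared families -> one search pass -> per-threshold
    evaluation. Returns ``(report, shared_labels, hits)``."""
    ref_q, ref_t, shared = build_shared_dataset(queries, reference, kind, min_members)
    hits = homology.search_all_vs_all(
        ref_q, ref_t, engine=engine, scheme=scheme, params=params, seed=seed
    )
    instances = query_instances(ref_q, kind, shared)
    reference_labels = {
        rec.id: frozenset(l for l in labels_for(rec, kind) if l in shared)
        for rec in ref_t.records
    }
    report = sweep_from_hits(hits, instances, reference_labels, grid, boundary=boundary)
    return report, shared, hits


# ---------------------------------------------------------------------------
# substrate_TC cross-tab
# ---------------------------------------------------------------------------

def bin_evalue(evalue: float | None, grid: Sequence = DEFAULT_GRID) -> int:
    """Grayscale bin of a best normalized E-value on the threshold grid.

    ``max(0, #{t in grid : E < t} - 1)``: 4 = better than 1e-20 (black),
    0 = nothing better than 1e-8 (white); a missing value bins as 0.
    """
    if evalue is None:
        return 0
    return max(0, sum(1 for t in grid if evalue < t) - 1)


def substrate_tc_crosstab(
    queries: AnnotatedDataset,
    reference: AnnotatedDataset,
    hits: Sequence | None = None,
    engine: str = "builtin_local",
    scheme=None,
    params=None,
    grid: Sequence = DEFAULT_GRID,
    seed: int = 0,
) -> pd.DataFrame:
    """Bin the best normalized E-value for every substrate_TC family pair.

    Rows are query-side labels, columns reference-side labels; values are
    the grayscale bins of :func:`bin_evalue`. Family pairs without any
    reported hit get bin 0 (no match better than the loosest threshold);
    an empty family would be marked missing (``pd.NA``), but families built
    from records always have members.
    """
    kind = "substrate_tc"
    q_index = queries.family_index(kind)
    r_index = reference.family_index(kind)
    if not q_index or not r_index:
        raise ValueError("both sides need substrate_tc labels")
    if hits is None:
        hits = homology.search_all_vs_all(
            queries, reference, engine=engine, scheme=scheme, params=params, seed=seed
        )
    q_label_of: dict = {}
    for label, ids in q_index.items():
        for rid in ids:
            q_label_of.setdefault(rid, []).append(label)
    r_label_of: dict = {}
    for label, ids in r_index.items():
        for rid in ids:
            r_label_of.setdefault(rid, []).append(label)
    best: dict = {}
    for hit in hits:
        for ql in q_label_of.get(hit.query_id, ()):
            for rl in r_label_of.get(hit.target_id, ()):
                key = (ql, rl)
                if key not in best or hit.normalized_evalue < best[key]:
                    best[key] = hit.normalized_evalue
    rows = sorted(q_index)
    cols = sorted(r_index)
    data = [
        [bin_evalue(best.get((ql, rl)), grid) for rl in cols]
        for ql in rows
    ]
    return pd.DataFrame(data, index=rows, columns=cols, dtype="Int64")


def write_crosstab_tsv(path, crosstab: pd.DataFrame) -> None:
    crosstab.to_csv(path, sep="\t", index_label="family", na_rep="NA")


def plot_crosstab(path, crosstab: pd.DataFrame, grid: Sequence = DEFAULT_GRID) -> None:
    """Grayscale heatmap of a cross-tab (white = bin 0, black = max bin)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    values = crosstab.to_numpy(dtype=float)
    max_bin = max(1, len(tuple(grid)) - 1)
    fig, ax = plt.subplots(
        figsize=(max(4, 0.45 * len(crosstab.columns)), max(3, 0.4 * len(crosstab)))
    )
    ax.imshow(values, cmap="Greys", vmin=0, vmax=max_bin, aspect="auto")
    ax.set_xticks(range(len(crosstab.columns)), crosstab.columns, rotation=90, fontsize=7)
    ax.set_yticks(range(len(crosstab.index)), crosstab.index, fontsize=7)
    ax.set_xlabel("reference substrate_TC family")
    ax.set_ylabel("query substrate_TC family")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
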