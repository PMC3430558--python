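"""Descriptor similarity, database indexing and retrieval evaluation.

Similarity between two descriptors is derived from the Minkowski L1 norm
of their probability density functions.  Two PDFs are at most L1 = 2
apart, so

    s(a, b) = 1 - ||a - b||_1 / 2

maps identity to 1 and disjoint supports to 0.

Retrieval quality is summarized by group-averaged precision-recall
curves and their trapezoidal area under curve (AUC): each database
member queries all others, precision is recorded at every relevant
(same conformational group) retrieval, linearly interpolated onto a
fixed recall grid, averaged within each group and then across groups.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .descriptors import Descriptor

logger = logging.getLogger(__name__)

#: 20 recall levels used for interpolated precision averaging.
DEFAULT_RECALL_GRID = np.round(np.linspace(0.05, 1.0, 20), 10)


@dataclass(frozen=True)
class SimilarityScore:
    """L1-derived similarity in [0, 1] with its underlying L1 distance."""

    value: float
    l1: float


@dataclass
class MoleculeRecord:
    """One database entry: id, conformational group, descriptors by method."""

    id: str
    group: str = ""
    descriptors: dict[str, Descriptor] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "id": self.id,
            "group": self.group,
            "descriptors": {m: d.to_dict() for m, d in self.descriptors.items()},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MoleculeRecord":
        return cls(
            id=d["id"],
            group=d.get("group", ""),
            descriptors={
                m: Descriptor.from_dict(dd) for m, dd in d["descriptors"].items()
            },
        )


@dataclass
class PRCurve:
    """Interpolated precision over a recall grid, with its AUC."""

    recall: np.ndarray
    precision: np.ndarray

    def __post_init__(self) -> None:
        self.recall = np.asarray(self.recall, dtype=float)
        self.precision = np.asarray(self.precision, dtype=float)
        if len(self.recall) != len(self.precision):
            raise ValueError("recall and precision lengths differ")
        if np.any(np.diff(self.recall) <= 0):
            raise ValueError("recall grid must be strictly increasing")

    @property
    def auc(self) -> float:
        return auc(self)


def similarity(a: Descriptor, b: Descriptor) -> SimilarityScore:
    """L1-of-PDF similarity; requires matching method, bins and range mode."""
    if a.method != b.method:
        raise ValueError(f"method mismatch: {a.method} vs {b.method}")
    if a.n_bins != b.n_bins:
        raise ValueError(f"bin count mismatch: {a.n_bins} vs {b.n_bins}")
    if a.mode != b.mode:
        raise ValueError(f"range mode mismatch: {a.mode} vs {b.mode}")
    l1 = float(np.abs(a.bins - b.bins).sum())
    return SimilarityScore(value=1.0 - l1 / 2.0, l1=l1)


class Index:
    """Queryable store of molecule records keyed by id."""

    def __init__(self, records: list[MoleculeRecord]):
        ids = [r.id for r in records]
        dup = {i for i in ids if ids.count(i) > 1}
        if dup:
            raise ValueError(f"duplicate record ids: {sorted(dup)}")
        self._records = {r.id: r for r in records}

    def __len__(self) -> int:
        return len(self._records)

    def __contains__(self, mol_id: str) -> bool:
        return mol_id in self._records

    def __getitem__(self, mol_id: str) -> MoleculeRecord:
        return self._records[mol_id]

    @property
    def ids(self) -> list[str]:
        return sorted(self._records)

    @property
    def records(self) -> list[MoleculeRecord]:
        return [self._records[i] for i in self.ids]

    def save(self, path: str) -> None:
        """JSON-lines serialization, one record per line."""
        with open(path, "w") as fh:
            for rec in self.records:
                fh.write(json.dumps(rec.to_dict()) + "\n")

    @classmethod
    def load(cls, path: str) -> "Index":
        records = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if line:
                    records.append(MoleculeRecord.from_dict(json.loads(line)))
        return cls(records)


def build_index(records: list[MoleculeRecord]) -> Index:
    """Build a retrieval index; ids must be unique, >=2 records."""
    if len(records) < 2:
        raise ValueError("an index needs at least 2 records")
    return Index(records)


def query(
    index: Index,
    probe: Descriptor,
    k: int = 10,
    *,
    method: str | None = None,
    exclude_id: str | None = None,
) -> list[tuple[str, float]]:
    """Top-k records by descending similarity to the probe descriptor.

    Ties break lexicographically by id; a database member probing the
    index is excluded from its own result list via ``exclude_id`` (set
    automatically when the probe carries a source id present in the
    index).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    method = method or probe.method
    if exclude_id is None and probe.source_id in index:
        exclude_id = probe.source_id
    scored = []
    for rec in index.records:
        if rec.id == exclude_id:
            continue
        if method not in rec.descriptors:
            raise KeyError(f"record {rec.id} has no {method} descriptor")
        s = similarity(probe, rec.descriptors[method])
        scored.append((rec.id, s.value))
    scored.sort(key=lambda t: (-t[1], t[0]))
    return scored[:k]


def _interpolated_precision(
    ranked_relevant: np.ndarray, n_relevant: int, recall_grid: np.ndarray
) -> np.ndarray:
    """Precision at each relevant retrieval, linearly interpolated onto the
    recall grid.

    ``ranked_relevant`` is the boolean relevance of the ranked list.
    Recall level j/R is reached at the rank of the j-th relevant item,
    where precision is j/rank.
    """
    ranks = np.nonzero(ranked_relevant)[0] + 1  # 1-based ranks of relevant hits
    j = np.arange(1, len(ranks) + 1)
    recall_pts = j / n_relevant
    precision_pts = j / ranks
    return np.interp(recall_grid, recall_pts, precision_pts)


def precision_recall(
    index: Index,
    method: str,
    *,
    recall_grid: np.ndarray | None = None,
) -> tuple[PRCurve, dict[str, PRCurve]]:
    """Group-averaged precision-recall over the whole index.

    Every molecule queries all others; relevant items are the other
    members of its conformational group.  Per-query interpolated
    precision curves are averaged within each group, and the overall
    curve is the unweighted mean of the group curves.  Singleton groups
    cannot act as queries and are excluded with a warning (they still
    appear in the rankings as distractors).

    Returns the overall curve and the per-group curves.
    """
    grid = DEFAULT_RECALL_GRID if recall_grid is None else np.asarray(recall_grid)
    groups: dict[str, list[str]] = {}
    for rec in index.records:
        groups.setdefault(rec.group, []).append(rec.id)
    multi = {g: ids for g, ids in groups.items() if len(ids) >= 2}
    singletons = sorted(set(groups) - set(multi))
    if singletons:
        warnings.warn(
            f"{len(singletons)} singleton group(s) excluded from evaluation",
            stacklevel=2,
        )
    if not multi:
        raise ValueError("no group with >=2 members; nothing to evaluate")
    group_curves: dict[str, PRCurve] = {}
    for group, members in sorted(multi.items()):
        per_query = []
        for mol_id in members:
            probe = index[mol_id].descriptors[method]
            ranked = query(index, probe, k=len(index), exclude_id=mol_id,
                           method=method)
            relevant = np.array(
                [index[rid].group == group for rid, _ in ranked], dtype=bool
            )
            per_query.append(
                _interpolated_precision(relevant, len(members) - 1, grid)
            )
        group_curves[group] = PRCurve(recall=grid, precision=np.mean(per_query, axis=0))
    overall = PRCurve(
        recall=grid,
        precision=np.mean([c.precision for c in group_curves.values()], axis=0),
    )
    return overall, group_curves


def auc(curve: PRCurve) -> float:
    """Trapezoidal area under the precision-recall curve over recall [0, 1].

    The value at recall -> 0 is extrapolated as the precision at the
    first grid level, so a perfect (precision = 1 everywhere) curve
    integrates to exactly 1.
    """
    recall = curve.recall
    precision = curve.precision
    if recall[0] > 0:
        recall = np.concatenate([[0.0], recall])
        precision = np.concatenate([[precision[0]], precision])
    return float(np.trapezoid(precision, recall))
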