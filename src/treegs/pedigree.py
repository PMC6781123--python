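"""Pedigree handling: validation, the numerator relationship matrix, and
status-number effective population size.

A pedigree is a list of trio records ``(individual, sire, dam)`` with an
optional generation tag (``P0``/``F1``/``F2``).  Unknown parents are coded by a
sentinel (``None`` internally, ``"0"`` in files) and treated as unrelated,
non-inbred founders — the standard convention of the tabular method.

The expected additive (numerator) relationship matrix ``A`` is built by the
recursive tabular method of Wright/Henderson: processing individuals in an
order where parents precede offspring,

    A[i, j] = 0.5 * (A[sire(i), j] + A[dam(i), j])      for j processed before i
    A[i, i] = 1 + 0.5 * A[sire(i), dam(i)]

with an unknown parent contributing zero.  The diagonal is ``1 + f_i`` where
``f_i`` is the inbreeding coefficient of individual *i*.

Effective population size is computed as Lindgren's status number
``Ns = 0.5 / theta`` where ``theta`` is the group coancestry: the average of
``A[i, j] / 2`` over all ordered pairs of group members, self-pairs included.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from graphlib import CycleError, TopologicalSorter
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Pedigree",
    "PedigreeError",
    "RelationshipMatrix",
    "validate_pedigree",
    "build_A",
    "status_number",
]


class PedigreeError(ValueError):
    """Raised for structurally invalid pedigrees (cycles, missing parents)."""


GENERATION_ORDER = {"P0": 0, "F1": 1, "F2": 2}


@dataclass(frozen=True)
class Pedigree:
    """An ordered collection of trio records.

    Parameters
    ----------
    records
        DataFrame with columns ``id``, ``sire``, ``dam`` and optionally
        ``generation``.  Parent entries are ``None``/NaN for unknown.
    """

    records: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.records
        required = {"id", "sire", "dam"}
        missing = required - set(df.columns)
        if missing:
            raise PedigreeError(f"pedigree table missing columns: {sorted(missing)}")
        if df["id"].duplicated().any():
            dups = df.loc[df["id"].duplicated(), "id"].tolist()
            raise PedigreeError(f"duplicate individual ids: {dups[:5]}")

    @classmethod
    def from_records(
        cls,
        trios: Iterable[tuple],
        generations: Sequence[str] | None = None,
    ) -> "Pedigree":
        """Build from an iterable of ``(id, sire, dam)`` trios.

        ``sire``/``dam`` may be ``None`` for unknown parents.
        """
        rows = list(trios)
        df = pd.DataFrame(rows, columns=["id", "sire", "dam"])
        if generations is not None:
            df["generation"] = list(generations)
        return cls(_normalise(df))

    @property
    def ids(self) -> list:
        return self.records["id"].tolist()

    def __len__(self) -> int:
        return len(self.records)

    def parent_map(self) -> dict:
        """id -> (sire or None, dam or None)."""
        return {
            r.id: (r.sire, r.dam)
            for r in self.records.itertuples(index=False)
        }

    def offspring_of(self, parents: Iterable) -> list:
        """Ids of individuals with at least one parent in ``parents``."""
        pset = set(parents)
        df = self.records
        mask = df["sire"].isin(pset) | df["dam"].isin(pset)
        return df.loc[mask, "id"].tolist()


def _normalise(df: pd.DataFrame) -> pd.DataFrame:
    """Map the unknown-parent sentinel and NaN to None, ids to str."""
    out = df.copy()
    out["id"] = out["id"].astype(str)
    for col in ("sire", "dam"):
        vals = out[col]
        out[col] = [
            None if (v is None or (isinstance(v, float) and np.isnan(v)) or str(v) in ("0", "", "nan", "NA", "."))
            else str(v)
            for v in vals
        ]
    return out


def validate_pedigree(
    pedigree: Pedigree,
    auto_insert_founders: bool = True,
) -> Pedigree:
    """Topologically sort a pedigree so that parents precede offspring.

    Parameters
    ----------
    pedigree
        Raw trio records in any order.
    auto_insert_founders
        If a parent id never appears as an individual, insert it as a founder
        record (unknown parents).  If False, such a parent is a fatal error.

    Returns
    -------
    Pedigree
        A new, ordered pedigree.

    Raises
    ------
    PedigreeError
        On cycles (an individual being its own ancestor, including direct
        self-parentage) or, with ``auto_insert_founders=False``, on parents
        absent from the records.
    """
    df = _normalise(pedigree.records)
    known = set(df["id"])
    parents = set(df["sire"].dropna()) | set(df["dam"].dropna())
    orphans = sorted(parents - known)
    if orphans:
        if not auto_insert_founders:
            raise PedigreeError(f"parent ids absent from records: {orphans[:5]}")
        extra = pd.DataFrame({"id": orphans, "sire": None, "dam": None})
        if "generation" in df.columns:
            extra["generation"] = "P0"
        df = pd.concat([extra, df], ignore_index=True)

    graph: dict = {}
    for r in df.itertuples(index=False):
        if r.id in (r.sire, r.dam):
            raise PedigreeError(f"individual {r.id!r} listed as its own parent")
        graph[r.id] = [p for p in (r.sire, r.dam) if p is not None]
    try:
        order = list(TopologicalSorter(graph).static_order())
    except CycleError as exc:
        raise PedigreeError(f"pedigree contains a cycle: {exc.args[1]}") from exc

    ordered = df.set_index("id").loc[order].reset_index()
    _check_generation_tags(ordered)
    return Pedigree(ordered)


def _check_generation_tags(df: pd.DataFrame) -> None:
    if "generation" not in df.columns:
        return
    gen = dict(zip(df["id"], df["generation"]))
    for r in df.itertuples(index=False):
        g = GENERATION_ORDER.get(r.generation)
        if g is None:
            continue
        for p in (r.sire, r.dam):
            gp = GENERATION_ORDER.get(gen.get(p)) if p is not None else None
            if gp is not None and gp >= g:
                raise PedigreeError(
                    f"generation tags inconsistent: {r.id} ({r.generation}) "
                    f"has parent {p} ({gen[p]})"
                )


@dataclass
class RelationshipMatrix:
    """Dense numerator relationship matrix with its id ordering.

    Attributes
    ----------
    ids
        Individual ids in matrix row/column order (parents before offspring).
    A
        Symmetric PSD matrix of expected additive relationships; the diagonal
        is ``1 + f`` with ``f`` the inbreeding coefficient.
    """

    ids: list
    A: np.ndarray
    _index: dict = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._index = {i: k for k, i in enumerate(self.ids)}

    @property
    def f(self) -> np.ndarray:
        """Per-individual inbreeding coefficients (diagonal minus one)."""
        return np.diag(self.A) - 1.0

    def index_of(self, ids: Iterable) -> np.ndarray:
        try:
            return np.array([self._index[str(i)] for i in ids], dtype=np.intp)
        except KeyError as exc:
            raise KeyError(f"id {exc.args[0]!r} not in relationship matrix") from exc

    def submatrix(self, ids: Sequence) -> np.ndarray:
        idx = self.index_of(ids)
        return self.A[np.ix_(idx, idx)]

    def inbreeding_of(self, ids: Sequence) -> np.ndarray:
        return self.f[self.index_of(ids)]


def build_A(pedigree: Pedigree) -> RelationshipMatrix:
    """Numerator relationship matrix by the recursive tabular method.

    The pedigree is validated/ordered first; missing parents are inserted as
    founders.  Runs in O(n^2) with vectorised row updates, adequate for the
    few-thousand-individual scale of a progeny-trial analysis.
    """
    ped = validate_pedigree(pedigree)
    df = ped.records
    n = len(df)
    index = {i: k for k, i in enumerate(df["id"])}
    sire_idx = np.array([index[s] if s is not None else -1 for s in df["sire"]], dtype=np.intp)
    dam_idx = np.array([index[d] if d is not None else -1 for d in df["dam"]], dtype=np.intp)

    A = np.zeros((n, n))
    for i in range(n):
        s, d = sire_idx[i], dam_idx[i]
        if i > 0:
            row = np.zeros(i)
            if s >= 0:
                row += A[s, :i]
            if d >= 0:
                row += A[d, :i]
            row *= 0.5
            A[i, :i] = row
            A[:i, i] = row
        A[i, i] = 1.0 + (0.5 * A[s, d] if (s >= 0 and d >= 0) else 0.0)
    return RelationshipMatrix(ids=df["id"].tolist(), A=A)


def status_number(relmat: RelationshipMatrix, group: Iterable) -> float:
    """Lindgren status number of a group: ``Ns = 0.5 / theta``.

    ``theta`` is the group coancestry, the mean of ``A[i, j] / 2`` over all
    ordered pairs of group members including self-pairs.  For *n* unrelated,
    non-inbred founders ``Ns = n``; for one infinite full-sib family it tends
    to 2.
    """
    ids = list(group)
    if not ids:
        raise ValueError("status_number: empty group")
    sub = relmat.submatrix(ids)
    theta = sub.mean() / 2.0
    return 0.5 / theta
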