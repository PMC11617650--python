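"""Additive (numerator) relationship matrix from pedigree records.

Implements the tabular method: individuals are processed in an order where
parents precede offspring, and for individual ``i`` with parents ``d, s``

    a(i, j) = 0.5 * (a(j, d) + a(j, s))   for j already processed,
    a(i, i) = 1 + 0.5 * a(d, s),

with unknown parents contributing zero. Entries are Wright's relationship
coefficients; the diagonal is 1 plus the inbreeding coefficient. Genotypes
with both parents unknown (founders, including competitor hybrids of unknown
parentage) are mutually unrelated and non-inbred.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import UNKNOWN_PARENT, SchemaError, validate_pedigree


class NumericError(ValueError):
    """A matrix fails the numerical requirements of the solver."""


@dataclass
class KinshipMatrix:
    """Ordered genotype ids and their additive relationship matrix."""

    ids: list
    values: np.ndarray
    jitter: float = 0.0

    @property
    def n(self) -> int:
        return len(self.ids)

    def index_of(self, ids) -> np.ndarray:
        lookup = {g: i for i, g in enumerate(self.ids)}
        try:
            return np.array([lookup[g] for g in ids], dtype=int)
        except KeyError as e:
            raise KeyError(f"genotype {e.args[0]!r} not in kinship matrix") from e

    def submatrix(self, ids) -> "KinshipMatrix":
        idx = self.index_of(ids)
        return KinshipMatrix(ids=list(ids), values=self.values[np.ix_(idx, idx)])

    def to_csv(self, path) -> None:
        pd.DataFrame(self.values, index=self.ids, columns=self.ids).to_csv(path)

    @classmethod
    def from_csv(cls, path) -> "KinshipMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls(ids=list(df.index.astype(str)), values=df.to_numpy(dtype=float))


def _topological_order(ped: pd.DataFrame) -> list:
    parents = {
        r.genotype_id: tuple(p for p in (r.dam_id, r.sire_id) if p != UNKNOWN_PARENT)
        for r in ped.itertuples()
    }
    order: list = []
    done: set = set()

    def visit(g: str) -> None:
        if g in done:
            return
        for p in parents.get(g, ()):
            visit(p)
        done.add(g)
        order.append(g)

    for g in sorted(parents):
        visit(g)
    return order


def additive_relationship(pedigree: pd.DataFrame) -> KinshipMatrix:
    """Compute the numerator relationship matrix A by the tabular method.

    The result is independent of the row order of the pedigree; ids are
    returned in the (sorted-rooted) topological processing order.
    """
    ped = validate_pedigree(pedigree)
    order = _topological_order(ped)
    idx = {g: i for i, g in enumerate(order)}
    dam = np.full(len(order), -1, dtype=int)
    sire = np.full(len(order), -1, dtype=int)
    for r in ped.itertuples():
        i = idx[r.genotype_id]
        dam[i] = idx.get(r.dam_id, -1)
        sire[i] = idx.get(r.sire_id, -1)

    n = len(order)
    A = np.zeros((n, n))
    for i in range(n):
        d, s = dam[i], sire[i]
        if d >= 0 and s >= 0:
            A[i, i] = 1.0 + 0.5 * A[d, s]
            row = 0.5 * (A[d, :i] + A[s, :i])
        elif d >= 0 or s >= 0:
            p = d if d >= 0 else s
            A[i, i] = 1.0
            row = 0.5 * A[p, :i]
        else:
            A[i, i] = 1.0
            row = np.zeros(i)
        A[i, :i] = row
        A[:i, i] = row
    return KinshipMatrix(ids=order, values=A)


def psd_repair(kin: KinshipMatrix, tolerance: float = 1e-8) -> KinshipMatrix:
    """Ensure A factorises: add minimal diagonal jitter if needed.

    A symmetric matrix whose minimum eigenvalue is below ``-tolerance``
    (relative to the largest eigenvalue) is considered structurally
    indefinite and rejected; small negative eigenvalues from round-off are
    lifted by adding ``jitter`` to the diagonal.
    """
    A = kin.values
    if not np.allclose(A, A.T, atol=1e-10):
        raise NumericError("kinship matrix is not symmetric")
    w = np.linalg.eigvalsh(A)
    scale = max(abs(w[-1]), 1.0)
    if w[0] < -tolerance * scale:
        raise NumericError(f"kinship matrix is indefinite (min eigenvalue {w[0]:.3g})")
    jitter = 0.0
    if w[0] < tolerance * scale:
        jitter = (tolerance * scale - w[0]) + tolerance * scale
        A = A + jitter * np.eye(kin.n)
    # confirm Cholesky succeeds
    np.linalg.cholesky(A)
    return KinshipMatrix(ids=list(kin.ids), values=A, jitter=jitter)
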