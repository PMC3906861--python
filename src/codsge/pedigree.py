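"""Pedigree handling and additive (numerator) relationship matrices.

The additive relationship matrix A is the covariance kernel of every genetic
random effect in the animal model: for individuals i, j it holds twice the
kinship coefficient, and its diagonal is 1 + F_i where F_i is the inbreeding
coefficient. Three routes are provided:

* :func:`build_A` — the recursive tabular method (dense; fine up to a few
  thousand individuals);
* :func:`inbreeding` — Meuwissen & Luo's algorithm for F without forming A;
* :func:`build_A_inverse` — Henderson's rules with inbreeding, assembling the
  sparse A⁻¹ that the mixed-model equations need directly.

Unknown parents are treated as unrelated, non-inbred founders drawn from a
single base population (no genetic groups).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse

logger = logging.getLogger(__name__)

#: tokens accepted as "parent unknown" in pedigree files
UNKNOWN_TOKENS = {"", "0", "NA", "na", ".", "nan"}

UNKNOWN = -1  # internal index for an unknown parent


class PedigreeError(ValueError):
    """Structural problem in a pedigree (cycle, duplicate, missing parent)."""


@dataclass(frozen=True)
class Pedigree:
    """A topologically sorted pedigree.

    ``ids[k]`` is the external identifier of the individual with internal
    index ``k``; ``sire[k]``/``dam[k]`` are internal indices (``-1`` for an
    unknown parent). Parents always precede offspring, so single passes in
    index order can propagate genetic quantities down the pedigree.
    """

    ids: tuple[str, ...]
    sire: np.ndarray
    dam: np.ndarray
    index: dict[str, int] = field(repr=False, compare=False, default_factory=dict)

    def __post_init__(self) -> None:
        if not self.index:
            object.__setattr__(self, "index", {s: k for k, s in enumerate(self.ids)})

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def founder_mask(self) -> np.ndarray:
        return (self.sire == UNKNOWN) & (self.dam == UNKNOWN)

    @classmethod
    def from_entries(
        cls,
        entries: list[tuple[str, str | None, str | None]],
        strict: bool = False,
    ) -> "Pedigree":
        """Build a pedigree from (id, sire, dam) triples.

        Parents referenced but never listed are auto-added as founders (with a
        logged warning) unless ``strict`` is set. Entries may come in any
        order; a topological sort puts parents first. Cycles (an individual
        being its own ancestor) raise :class:`PedigreeError`.
        """
        def norm(tok: str | None) -> str | None:
            if tok is None:
                return None
            tok = str(tok).strip()
            return None if tok in UNKNOWN_TOKENS else tok

        seen: dict[str, tuple[str | None, str | None]] = {}
        order: list[str] = []
        for ind, s, d in entries:
            ind = str(ind).strip()
            if ind in UNKNOWN_TOKENS:
                raise PedigreeError(f"invalid individual id {ind!r}")
            if ind in seen:
                raise PedigreeError(f"duplicate individual id {ind!r}")
            seen[ind] = (norm(s), norm(d))
            order.append(ind)

        for ind in order:
            for p in seen[ind]:
                if p is not None and p not in seen:
                    if strict:
                        raise PedigreeError(
                            f"parent {p!r} of {ind!r} is not defined as an individual"
                        )
                    logger.warning(
                        "parent %r referenced but never defined; added as founder", p
                    )
                    seen[p] = (None, None)

        # Kahn-style topological sort, keeping input order among ready nodes.
        all_ids = [i for i in seen if seen[i] == (None, None)] + [
            i for i in order if seen[i] != (None, None)
        ]
        placed: dict[str, int] = {}
        sorted_ids: list[str] = []
        pending = list(all_ids)
        while pending:
            progressed = False
            rest: list[str] = []
            for ind in pending:
                s, d = seen[ind]
                if (s is None or s in placed) and (d is None or d in placed):
                    placed[ind] = len(sorted_ids)
                    sorted_ids.append(ind)
                    progressed = True
                else:
                    rest.append(ind)
            if not progressed:
                raise PedigreeError(
                    f"pedigree contains a cycle involving {rest[0]!r}"
                )
            pending = rest

        sire = np.full(len(sorted_ids), UNKNOWN, dtype=np.int64)
        dam = np.full(len(sorted_ids), UNKNOWN, dtype=np.int64)
        for k, ind in enumerate(sorted_ids):
            s, d = seen[ind]
            if s is not None:
                sire[k] = placed[s]
            if d is not None:
                dam[k] = placed[d]
        return cls(ids=tuple(sorted_ids), sire=sire, dam=dam)


def read_pedigree(path, strict: bool = False) -> Pedigree:
    """Read a pedigree CSV with columns ``id,sire,dam``.

    Unknown parents are coded ``0`` or an empty field. The result is
    topologically sorted regardless of file order.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = {"id", "sire", "dam"}
    if not required.issubset(df.columns):
        raise PedigreeError(f"pedigree file must have columns {sorted(required)}")
    entries = list(zip(df["id"], df["sire"], df["dam"]))
    return Pedigree.from_entries(entries, strict=strict)


def write_pedigree(ped: Pedigree, path) -> None:
    """Write the pedigree back in the same CSV dialect (unknowns as ``0``)."""
    def ext(k: int) -> str:
        return "0" if k == UNKNOWN else ped.ids[k]

    df = pd.DataFrame(
        {
            "id": ped.ids,
            "sire": [ext(s) for s in ped.sire],
            "dam": [ext(d) for d in ped.dam],
        }
    )
    df.to_csv(path, index=False)


def build_A(ped: Pedigree) -> np.ndarray:
    """Additive relationship matrix by the recursive tabular method (dense).

    Founders get A_ii = 1; for an individual i with parents s, d:
    A_ij = (A_sj + A_dj)/2 for j < i, and A_ii = 1 + A_sd/2.
    """
    n = len(ped)
    A = np.zeros((n, n))
    for i in range(n):
        s, d = ped.sire[i], ped.dam[i]
        if i > 0:
            row = np.zeros(i)
            if s != UNKNOWN:
                row += 0.5 * A[s, :i]
            if d != UNKNOWN:
                row += 0.5 * A[d, :i]
            A[i, :i] = row
            A[:i, i] = row
        A[i, i] = 1.0
        if s != UNKNOWN and d != UNKNOWN:
            A[i, i] += 0.5 * A[s, d]
    return A


def inbreeding(ped: Pedigree) -> np.ndarray:
    """Inbreeding coefficients by Meuwissen & Luo without forming dense A.

    Traces, for each individual, the contributions of its ancestors through
    the Cholesky-style decomposition A = L D Lᵀ: F_i + 1 = Σ_j L_ij² d_j,
    accumulating L row-by-row over the ancestor set only.
    """
    import heapq

    n = len(ped)
    sire, dam = ped.sire, ped.dam
    F = np.zeros(n)
    d = np.zeros(n)  # within-family (Mendelian) variance of each individual
    memo: dict[tuple[int, int], float] = {}  # full sibs share F

    for i in range(n):
        s, di = sire[i], dam[i]
        if s == UNKNOWN and di == UNKNOWN:
            d[i] = 1.0
            continue
        fs = F[s] if s != UNKNOWN else -1.0  # -1 encodes "missing parent"
        fd = F[di] if di != UNKNOWN else -1.0
        d[i] = 0.5 - 0.25 * (fs + fd)
        key = (int(s), int(di))
        if key in memo:
            F[i] = memo[key]
            continue
        # accumulate A_ii = Σ L_ij² d_j over the ancestor set of i only
        coeff = {i: 1.0}
        heap = [-i]
        a_ii = 0.0
        while heap:
            j = -heapq.heappop(heap)
            lij = coeff.pop(j)
            for p in (sire[j], dam[j]):
                if p != UNKNOWN:
                    if p not in coeff:
                        coeff[p] = 0.0
                        heapq.heappush(heap, -int(p))
                    coeff[p] += 0.5 * lij
            a_ii += lij * lij * d[j]
        F[i] = a_ii - 1.0
        memo[key] = F[i]
    return F


def mendelian_variance(ped: Pedigree, F: np.ndarray | None = None) -> np.ndarray:
    """Per-individual within-family variance d_i (in units of σ²_A).

    d_i = 0.5 − 0.25 (F_s + F_d) with both parents known; 0.75 − 0.25 F_p with
    one; 1 for founders. |A| = Π d_i, handy for REML log-determinants.
    """
    if F is None:
        F = inbreeding(ped)
    n = len(ped)
    d = np.ones(n)
    for i in range(n):
        s, di = ped.sire[i], ped.dam[i]
        if s != UNKNOWN and di != UNKNOWN:
            d[i] = 0.5 - 0.25 * (F[s] + F[di])
        elif s != UNKNOWN:
            d[i] = 0.75 - 0.25 * F[s]
        elif di != UNKNOWN:
            d[i] = 0.75 - 0.25 * F[di]
    return d


def build_A_inverse(ped: Pedigree) -> sparse.csc_matrix:
    """Sparse A⁻¹ assembled directly by Henderson's rules with inbreeding.

    Uses Meuwissen–Luo inbreeding coefficients for the Mendelian variances;
    never forms dense A. The number of nonzeros grows linearly with pedigree
    size (≤ 9 entries contributed per individual).
    """
    F = inbreeding(ped)
    d = mendelian_variance(ped, F)
    rows: list[int] = []
    cols: list[int] = []
    vals: list[float] = []

    def add(r: int, c: int, v: float) -> None:
        rows.append(r)
        cols.append(c)
        vals.append(v)

    for i in range(len(ped)):
        alpha = 1.0 / d[i]
        s, di = ped.sire[i], ped.dam[i]
        add(i, i, alpha)
        for p in (s, di):
            if p != UNKNOWN:
                add(i, p, -0.5 * alpha)
                add(p, i, -0.5 * alpha)
        for p in (s, di):
            for q in (s, di):
                if p != UNKNOWN and q != UNKNOWN:
                    add(p, q, 0.25 * alpha)
    n = len(ped)
    return sparse.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsc()


def a_logdet(ped: Pedigree) -> float:
    """log|A| = Σ log d_i (A = L D Lᵀ with unit-triangular L)."""
    return float(np.sum(np.log(mendelian_variance(ped))))
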