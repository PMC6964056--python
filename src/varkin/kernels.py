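"""Genomic and pedigree relationship matrices under HWE and NOIA parameterizations.

The additive contrast at a locus is the centered allele dosage
``h_a = x - 2p`` in both parameterizations; they differ only in the scaling
of the kernel. The dominance contrast differs in both values and scaling:
the HWE form assumes genotype frequencies p², 2pq, q², while the NOIA
(natural and orthogonal interactions) form uses the observed genotype-class
frequencies so that the dominance column is orthogonal to the additive
column in the sample itself. Epistatic kernels are scaled Hadamard products
of the additive/dominance kernels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix, LocusStats, locus_stats

VALID_COMPONENTS = (
    "additive",
    "dominance",
    "epistatic_aa",
    "epistatic_ad",
    "epistatic_dd",
    "pedigree_A",
)


@dataclass
class ContrastMatrix:
    """n×m matrix of per-locus genotype contrasts (additive or dominance)."""

    values: np.ndarray
    kind: str  # 'additive' | 'dominance'
    approach: str  # 'hwe' | 'noia' | 'shared' (additive contrasts are identical)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.kind not in ("additive", "dominance"):
            raise ValueError(f"unknown contrast kind {self.kind!r}")
        if self.approach not in ("hwe", "noia", "shared"):
            raise ValueError(f"unknown approach {self.approach!r}")


@dataclass
class RelationshipMatrix:
    """Symmetric n×n kernel tagged by genetic component and parameterization.

    ``scale_denominator`` records the positive scalar the raw cross-product
    (or Hadamard product) was divided by.
    """

    values: np.ndarray
    component: str
    approach: str  # 'hwe' | 'noia' | 'pedigree'
    scale_denominator: float = 1.0
    ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ValueError("relationship matrix must be square")
        if self.component not in VALID_COMPONENTS:
            raise ValueError(f"unknown component {self.component!r}")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ValueError("relationship matrix must be symmetric")
        if self.ids is not None and len(self.ids) != self.values.shape[0]:
            raise ValueError("ids length must match matrix dimension")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def align(self, ids: list[str]) -> "RelationshipMatrix":
        """Subset/reorder rows and columns to the given individual ids."""
        if self.ids is None:
            raise ValueError("matrix carries no ids; cannot align")
        index = {v: k for k, v in enumerate(self.ids)}
        rows = np.array([index[i] for i in ids])
        return RelationshipMatrix(
            self.values[np.ix_(rows, rows)],
            self.component,
            self.approach,
            self.scale_denominator,
            list(ids),
        )


def additive_contrasts(g: GenotypeMatrix, stats: LocusStats | None = None) -> ContrastMatrix:
    """Centered allele dosages ``h_a[i,j] = x_ij − 2 p_j``.

    Identical for the HWE and NOIA parameterizations. Monomorphic loci give
    all-zero columns (they contribute nothing to the kernel).
    """
    if g.missing_mask.any():
        raise ValueError("genotypes contain missing calls; impute first")
    if stats is None:
        stats = locus_stats(g)
    return ContrastMatrix(g.codes.astype(float) - 2.0 * stats.p, "additive", "shared")


def dominance_contrasts(
    g: GenotypeMatrix, stats: LocusStats | None = None, approach: str = "noia"
) -> ContrastMatrix:
    """Per-locus dominance contrasts.

    HWE approach: ``h_d = (−2p², 2pq, −2q²)`` for x = 0, 1, 2 with q = 1−p.
    NOIA approach (observed genotype-class frequencies p0, p1, p2):
    ``h_d = (−2 p1 p2, 4 p0 p2, −2 p0 p1) / (p0 + p2 − (p0 − p2)²)``,
    orthogonal to the additive contrast in the sample. Loci where the NOIA
    denominator vanishes (no dominance contrast, e.g. monomorphic) get a
    zero column and a warning.
    """
    if approach not in ("hwe", "noia"):
        raise ValueError(f"approach must be 'hwe' or 'noia', got {approach!r}")
    if g.missing_mask.any():
        raise ValueError("genotypes contain missing calls; impute first")
    if stats is None:
        stats = locus_stats(g)
    x = g.codes
    if approach == "hwe":
        p, q = stats.p, 1.0 - stats.p
        vals = np.empty(x.shape, dtype=float)
        row0 = -2.0 * p**2
        row1 = 2.0 * p * q
        row2 = -2.0 * q**2
    else:
        p0, p1, p2 = stats.p0, stats.p1, stats.p2
        den = p0 + p2 - (p0 - p2) ** 2
        degenerate = den <= 1e-12
        if degenerate.any():
            names = [g.locus_ids[j] for j in np.nonzero(degenerate)[0][:10]]
            warnings.warn(
                f"{int(degenerate.sum())} loci have no dominance contrast "
                f"(zero NOIA denominator, e.g. {names}); columns set to zero",
                stacklevel=2,
            )
        safe = np.where(degenerate, 1.0, den)
        row0 = np.where(degenerate, 0.0, -2.0 * p1 * p2 / safe)
        row1 = np.where(degenerate, 0.0, 4.0 * p0 * p2 / safe)
        row2 = np.where(degenerate, 0.0, -2.0 * p0 * p1 / safe)
        vals = np.empty(x.shape, dtype=float)
    vals = np.where(x == 0, row0, np.where(x == 1, row1, row2))
    return ContrastMatrix(vals, "dominance", approach)


def build_grm(
    h: ContrastMatrix, stats: LocusStats, approach: str = "noia"
) -> RelationshipMatrix:
    """Additive genomic relationship matrix from additive contrasts.

    NOIA scaling divides the cross-product ``H_a H_aᵀ`` by its trace mean
    ``tr(H_a H_aᵀ)/n`` (unit mean diagonal by construction); HWE scaling
    divides by ``2 Σ_j p_j (1 − p_j)`` (VanRaden method 1).
    """
    if h.kind != "additive":
        raise ValueError("build_grm needs additive contrasts")
    if approach not in ("hwe", "noia"):
        raise ValueError(f"approach must be 'hwe' or 'noia', got {approach!r}")
    H = h.values
    n = H.shape[0]
    raw = H @ H.T
    if approach == "noia":
        den = float(np.trace(raw) / n)
    else:
        den = float(2.0 * np.sum(stats.p * (1.0 - stats.p)))
    if den <= 0:
        raise ValueError("zero kernel denominator: all loci monomorphic?")
    return RelationshipMatrix(raw / den, "additive", approach, den)


def build_drm(
    h: ContrastMatrix, stats: LocusStats, approach: str = "noia"
) -> RelationshipMatrix:
    """Dominance relationship matrix from dominance contrasts.

    HWE scaling: ``4 Σ_j p_j² (1 − p_j)²``; NOIA scaling: trace mean of
    ``H_d H_dᵀ`` (unit mean diagonal).
    """
    if h.kind != "dominance":
        raise ValueError("build_drm needs dominance contrasts")
    if h.approach != approach:
        raise ValueError(
            f"contrast approach {h.approach!r} does not match requested {approach!r}"
        )
    H = h.values
    n = H.shape[0]
    raw = H @ H.T
    if approach == "noia":
        den = float(np.trace(raw) / n)
        cause = "zero NOIA dominance trace (no heterozygotes in sample?)"
    else:
        den = float(4.0 * np.sum((stats.p * (1.0 - stats.p)) ** 2))
        cause = "zero HWE dominance denominator (all loci monomorphic?)"
    if den <= 0:
        raise ValueError(f"cannot scale dominance kernel: {cause}")
    return RelationshipMatrix(raw / den, "dominance", approach, den)


_EPISTATIC_PAIRS = {
    frozenset(("additive",)): "epistatic_aa",
    frozenset(("additive", "dominance")): "epistatic_ad",
    frozenset(("dominance",)): "epistatic_dd",
}


def build_epistatic(
    a: RelationshipMatrix, b: RelationshipMatrix, approach: str = "noia"
) -> RelationshipMatrix:
    """Scaled Hadamard product of two kernels (epistatic relationship matrix).

    Component pairs: (G,G) → additive-by-additive, (G,D) → additive-by-
    dominance, (D,D) → dominance-by-dominance. HWE approach uses scaling
    factor k = 1; NOIA approach divides by the trace mean so the mean
    diagonal is 1.
    """
    if a.n != b.n:
        raise ValueError(f"kernel dimensions differ: {a.n} vs {b.n}")
    if approach not in ("hwe", "noia"):
        raise ValueError(f"approach must be 'hwe' or 'noia', got {approach!r}")
    key = frozenset((a.component, b.component))
    if key not in _EPISTATIC_PAIRS:
        raise ValueError(
            f"cannot build an epistatic kernel from ({a.component}, {b.component})"
        )
    component = _EPISTATIC_PAIRS[key]
    raw = a.values * b.values
    if approach == "noia":
        den = float(np.trace(raw) / a.n)
        if den <= 0:
            raise ValueError("zero trace mean in epistatic kernel")
    else:
        den = 1.0
    return RelationshipMatrix(raw / den, component, approach, den, a.ids)


def legarra_factor(v: RelationshipMatrix | np.ndarray) -> float:
    """Reference-population rescaling factor: mean(diag V) − mean(V).

    Multiplying a variance component by this factor re-expresses it as
    genetic variance within the study population, making estimates from
    differently scaled kernels comparable. For NOIA kernels built from
    sample frequencies the factor is 1 (trace mean 1, grand mean 0).
    """
    vals = v.values if isinstance(v, RelationshipMatrix) else np.asarray(v, dtype=float)
    return float(np.mean(np.diag(vals)) - np.mean(vals))


def pedigree_numerator(ped: pd.DataFrame) -> RelationshipMatrix:
    """Pedigree numerator relationship matrix **A** by the tabular method.

    ``ped`` needs columns ``id``, ``sire``, ``dam``; unknown parents are
    missing/empty/``0``. Rows may be in any order as long as the pedigree is
    acyclic; founders are taken as non-inbred. Used for comparison with the
    genomic kernels only.
    """
    ids = [str(i) for i in ped["id"]]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate ids in pedigree")

    def _norm(v) -> str | None:
        if pd.isna(v):
            return None
        s = str(v)
        return None if s in ("", "0", "NA", ".") else s

    parents = {
        str(r["id"]): (_norm(r["sire"]), _norm(r["dam"])) for _, r in ped.iterrows()
    }
    # topological order: parents before offspring
    order: list[str] = []
    state: dict[str, int] = {}

    def visit(node: str, stack: tuple = ()) -> None:
        if state.get(node) == 2:
            return
        if state.get(node) == 1:
            raise ValueError(f"cycle in pedigree involving {node!r}")
        state[node] = 1
        for par in parents.get(node, (None, None)):
            if par is not None and par in parents:
                visit(par)
        state[node] = 2
        order.append(node)

    for node in ids:
        visit(node)

    idx = {v: k for k, v in enumerate(order)}
    n = len(order)
    A = np.zeros((n, n))
    for i, ind in enumerate(order):
        s, d = parents.get(ind, (None, None))
        si = idx.get(s) if s is not None else None
        di = idx.get(d) if d is not None else None
        asd = A[si, di] if (si is not None and di is not None) else 0.0
        A[i, i] = 1.0 + 0.5 * asd
        for j in range(i):
            val = 0.0
            if si is not None:
                val += 0.5 * A[j, si]
            if di is not None:
                val += 0.5 * A[j, di]
            A[i, j] = A[j, i] = val
    # return in the input id order
    rows = np.array([idx[i] for i in ids])
    return RelationshipMatrix(
        A[np.ix_(rows, rows)], "pedigree_A", "pedigree", 1.0, ids
    )
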