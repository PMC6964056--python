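"""SNP genotype container, QC filters, frequency-based imputation and homozygosity.

Genotypes are stored as the count of an arbitrarily chosen allele per locus
(0, 1 or 2), with a dedicated sentinel for missing calls. All locus summaries
(allele frequency, genotype frequencies, MAF, call rate) are computed over
non-missing calls only; they are the single source of frequencies for every
downstream relationship matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

#: Sentinel for a missing genotype call in :class:`GenotypeMatrix.codes`.
MISSING = -1


class EmptyPanelError(ValueError):
    """Raised when a QC filter removes every locus."""


@dataclass
class GenotypeMatrix:
    """Individuals × loci matrix of allele counts.

    Parameters
    ----------
    ids
        Unique individual identifiers, one per row.
    codes
        Integer matrix with entries in {0, 1, 2} or :data:`MISSING` (−1).
    locus_ids
        Unique SNP identifiers, one per column.
    """

    ids: list[str]
    codes: np.ndarray
    locus_ids: list[str]

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes)
        if self.codes.ndim != 2:
            raise ValueError("codes must be a 2-D matrix (individuals x loci)")
        if not np.issubdtype(self.codes.dtype, np.integer):
            if np.isnan(np.asarray(self.codes, dtype=float)).any():
                c = np.asarray(self.codes, dtype=float)
                c[np.isnan(c)] = MISSING
                self.codes = c.astype(np.int8)
            else:
                self.codes = self.codes.astype(np.int8)
        else:
            self.codes = self.codes.astype(np.int8)
        self.ids = [str(i) for i in self.ids]
        self.locus_ids = [str(s) for s in self.locus_ids]
        n, m = self.codes.shape
        if n < 1 or m < 1:
            raise ValueError("need at least one individual and one locus")
        if len(self.ids) != n:
            raise ValueError(f"{len(self.ids)} ids for {n} rows")
        if len(self.locus_ids) != m:
            raise ValueError(f"{len(self.locus_ids)} locus ids for {m} columns")
        if len(set(self.ids)) != n:
            raise ValueError("individual ids must be unique")
        if len(set(self.locus_ids)) != m:
            raise ValueError("locus ids must be unique")
        bad = ~np.isin(self.codes, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError(
                f"invalid genotype codes (not 0/1/2/missing) at {int(bad.sum())} entries"
            )

    @property
    def n(self) -> int:
        return self.codes.shape[0]

    @property
    def m(self) -> int:
        return self.codes.shape[1]

    @property
    def missing_mask(self) -> np.ndarray:
        return self.codes == MISSING

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(list(self.ids), self.codes.copy(), list(self.locus_ids))

    def subset(self, ids: list[str]) -> "GenotypeMatrix":
        """Row-subset (and reorder) to the given individual ids."""
        index = {v: k for k, v in enumerate(self.ids)}
        rows = [index[i] for i in ids]
        return GenotypeMatrix(list(ids), self.codes[rows], list(self.locus_ids))


@dataclass
class LocusStats:
    """Per-locus allele/genotype frequencies over non-missing calls.

    ``p`` is the frequency of the counted allele (the allele whose dosage the
    codes record), ``p0/p1/p2`` the observed genotype-class frequencies and
    ``valid`` flags loci with at least one non-missing call.
    """

    p: np.ndarray
    p0: np.ndarray
    p1: np.ndarray
    p2: np.ndarray
    maf: np.ndarray
    call_rate: np.ndarray
    valid: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.valid is None:
            self.valid = np.ones_like(self.p, dtype=bool)

    @property
    def m(self) -> int:
        return self.p.shape[0]

    def subset(self, keep: np.ndarray) -> "LocusStats":
        return LocusStats(
            self.p[keep], self.p0[keep], self.p1[keep], self.p2[keep],
            self.maf[keep], self.call_rate[keep], self.valid[keep],
        )


def locus_stats(g: GenotypeMatrix) -> LocusStats:
    """Compute allele and genotype frequencies per locus.

    Frequencies are computed over non-missing calls only. Loci with zero
    non-missing calls are flagged invalid (``valid=False``, frequencies NaN)
    and must be excluded from downstream kernels.
    """
    codes = g.codes
    n0 = (codes == 0).sum(axis=0).astype(float)
    n1 = (codes == 1).sum(axis=0).astype(float)
    n2 = (codes == 2).sum(axis=0).astype(float)
    called = n0 + n1 + n2
    valid = called > 0
    with np.errstate(invalid="ignore", divide="ignore"):
        p0 = np.where(valid, n0 / called, np.nan)
        p1 = np.where(valid, n1 / called, np.nan)
        p2 = np.where(valid, n2 / called, np.nan)
        p = np.where(valid, (n1 + 2.0 * n2) / (2.0 * called), np.nan)
    maf = np.minimum(p, 1.0 - p)
    call_rate = called / g.n
    if not valid.all():
        bad = [g.locus_ids[j] for j in np.nonzero(~valid)[0][:10]]
        warnings.warn(
            f"{int((~valid).sum())} loci have zero non-missing calls "
            f"(e.g. {bad}); flagged invalid",
            stacklevel=2,
        )
    return LocusStats(p, p0, p1, p2, maf, call_rate, valid)


def filter_loci(
    g: GenotypeMatrix,
    stats: LocusStats | None = None,
    maf_min: float = 0.05,
    callrate_min: float = 0.97,
) -> GenotypeMatrix:
    """Keep loci with MAF ≥ ``maf_min`` and call rate ≥ ``callrate_min`` (inclusive).

    Invalid loci (zero calls) are always removed. Raises
    :class:`EmptyPanelError` if nothing survives.
    """
    if not (0 <= maf_min <= 1 and 0 <= callrate_min <= 1):
        raise ValueError("thresholds must lie in [0, 1]")
    if stats is None:
        stats = locus_stats(g)
    with np.errstate(invalid="ignore"):
        keep = stats.valid & (stats.maf >= maf_min) & (stats.call_rate >= callrate_min)
    if not keep.any():
        raise EmptyPanelError(
            f"no loci pass QC (maf >= {maf_min}, call rate >= {callrate_min})"
        )
    return GenotypeMatrix(
        list(g.ids),
        g.codes[:, keep],
        [lid for lid, k in zip(g.locus_ids, keep) if k],
    )


def impute_missing(
    g: GenotypeMatrix, stats: LocusStats | None = None, seed: int | np.random.Generator = 0
) -> GenotypeMatrix:
    """Impute missing calls by sampling from {0,1,2} with the locus genotype frequencies.

    Observed entries are untouched; the draw is reproducible for a fixed seed.
    Raises if any locus has no non-missing call (impossible to impute).
    """
    if stats is None:
        stats = locus_stats(g)
    if not stats.valid.all():
        bad = [g.locus_ids[j] for j in np.nonzero(~stats.valid)[0][:10]]
        raise ValueError(f"cannot impute loci with zero non-missing calls: {bad}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    codes = g.codes.copy()
    miss = codes == MISSING
    if not miss.any():
        return GenotypeMatrix(list(g.ids), codes, list(g.locus_ids))
    cols = np.nonzero(miss.any(axis=0))[0]
    for j in cols:
        rows = np.nonzero(miss[:, j])[0]
        probs = np.array([stats.p0[j], stats.p1[j], stats.p2[j]])
        probs = probs / probs.sum()
        codes[rows, j] = rng.choice(3, size=rows.size, p=probs).astype(np.int8)
    return GenotypeMatrix(list(g.ids), codes, list(g.locus_ids))


def individual_homozygosity(g: GenotypeMatrix) -> np.ndarray:
    """Proportion of homozygous loci (code 0 or 2) per individual.

    Requires a complete matrix: impute first.
    """
    if g.missing_mask.any():
        raise ValueError("genotypes contain missing calls; run impute_missing first")
    return (g.codes != 1).mean(axis=1)
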