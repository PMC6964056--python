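"""Convenience pipeline: QC'd, imputed genotypes to the kernel set the model suite fits."""

from __future__ import annotations

import pandas as pd

from .genotypes import (
    GenotypeMatrix,
    filter_loci,
    impute_missing,
    individual_homozygosity,
    locus_stats,
)
from .kernels import (
    RelationshipMatrix,
    additive_contrasts,
    build_drm,
    build_epistatic,
    build_grm,
    dominance_contrasts,
)

__all__ = ["prepare_kernels"]


def prepare_kernels(
    genotypes: GenotypeMatrix,
    approach: str = "noia",
    maf_min: float = 0.05,
    callrate_min: float = 0.97,
    seed: int = 0,
    include_dominance: bool = True,
) -> tuple[dict[str, RelationshipMatrix], pd.DataFrame]:
    """QC, impute and build the additive/dominance/epistatic kernel set.

    Frequencies feeding the contrasts are recomputed from the analysis
    sample after imputation, pooled over both reciprocal crosses. Returns
    the kernels (carrying individual ids) and a per-individual genomic
    homozygosity table.
    """
    g = filter_loci(genotypes, maf_min=maf_min, callrate_min=callrate_min)
    if g.missing_mask.any():
        g = impute_missing(g, seed=seed)
    stats = locus_stats(g)
    ha = additive_contrasts(g, stats)
    G = build_grm(ha, stats, approach)
    G.ids = list(g.ids)
    kernels: dict[str, RelationshipMatrix] = {
        "additive": G,
        "epistatic_aa": build_epistatic(G, G, approach),
    }
    if include_dominance:
        D = build_drm(dominance_contrasts(g, stats, approach), stats, approach)
        D.ids = list(g.ids)
        kernels["dominance"] = D
    hom = pd.DataFrame({"id": g.ids, "homozygosity": individual_homozygosity(g)})
    return kernels, hom
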