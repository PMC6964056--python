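"""Readers and writers: VCF / PLINK .raw / CSV genotypes, phenotypes, GRM files, manifests."""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field, asdict
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from .genotypes import MISSING, GenotypeMatrix
from .kernels import RelationshipMatrix

__all__ = [
    "read_genotypes",
    "write_genotypes_csv",
    "read_phenotypes",
    "write_grm",
    "read_grm",
    "RunManifest",
]


def _read_vcf(path: str | Path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    ids = list(vcf.samples)
    codes_cols = []
    locus_ids = []
    skipped = 0
    for var in vcf:
        if len(var.ALT) != 1:
            skipped += 1
            continue
        # gts012: 0=hom-ref, 1=het, 2=hom-alt, 3=unknown
        col = np.asarray(var.gt_types, dtype=np.int8)
        col[col == 3] = MISSING
        codes_cols.append(col)
        locus_ids.append(var.ID or f"{var.CHROM}:{var.POS}")
    if skipped:
        warnings.warn(f"skipped {skipped} multi-allelic VCF records", stacklevel=3)
    if not codes_cols:
        raise ValueError(f"no usable biallelic records in {path}")
    return GenotypeMatrix(ids, np.column_stack(codes_cols), locus_ids)


def _read_plink_raw(path: str | Path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep=r"\s+")
    meta = ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"]
    missing_meta = [c for c in meta if c not in df.columns]
    if missing_meta:
        raise ValueError(f"{path}: not a PLINK .raw file (missing {missing_meta})")
    snp_cols = [c for c in df.columns if c not in meta]
    codes = df[snp_cols].to_numpy(dtype=float)
    codes = np.where(np.isnan(codes), MISSING, codes).astype(np.int8)
    return GenotypeMatrix(df["IID"].astype(str).tolist(), codes, snp_cols)


def _read_csv(path: str | Path) -> GenotypeMatrix:
    df = pd.read_csv(path, index_col=0)
    codes = df.to_numpy(dtype=float)
    codes = np.where(np.isnan(codes), MISSING, codes).astype(np.int8)
    return GenotypeMatrix(
        df.index.astype(str).tolist(), codes, [str(c) for c in df.columns]
    )


def read_genotypes(path: str | Path, format: str | None = None) -> GenotypeMatrix:
    """Read genotypes from VCF, PLINK additive-dosage ``.raw`` or plain CSV.

    The format is inferred from the file suffix when not given. Codes are the
    dosage of the VCF ALT allele (or the counted allele of the source file);
    missing calls become the internal sentinel.
    """
    path = Path(path)
    if format is None:
        suffix = path.suffix.lower()
        if suffix in (".vcf", ".gz", ".bcf"):
            format = "vcf"
        elif suffix == ".raw":
            format = "plink_raw"
        elif suffix == ".csv":
            format = "csv"
        else:
            raise ValueError(f"cannot infer genotype format from {path.name!r}")
    readers = {"vcf": _read_vcf, "plink_raw": _read_plink_raw, "csv": _read_csv}
    if format not in readers:
        raise ValueError(f"unknown format {format!r}; valid: {sorted(readers)}")
    return readers[format](path)


def write_genotypes_csv(g: GenotypeMatrix, path: str | Path) -> None:
    """Write genotypes as CSV (rows=individuals, empty cell=missing)."""
    arr = g.codes.astype(object)
    arr[g.codes == MISSING] = np.nan
    pd.DataFrame(arr, index=g.ids, columns=g.locus_ids).to_csv(path)


def read_phenotypes(
    path: str | Path,
    id_col: str = "id",
    genotype_ids: list[str] | None = None,
) -> pd.DataFrame:
    """Read the phenotype/covariate table; ids are strings, duplicates rejected.

    When ``genotype_ids`` is given, rows without genotypes are dropped with a
    warning (they cannot enter a genomic model).
    """
    df = pd.read_csv(path)
    if id_col not in df.columns:
        raise ValueError(f"{path}: missing id column {id_col!r}")
    df[id_col] = df[id_col].astype(str)
    dup = df[id_col].duplicated()
    if dup.any():
        raise ValueError(f"duplicate ids in {path}: {df.loc[dup, id_col].tolist()[:5]}")
    if genotype_ids is not None:
        known = set(genotype_ids)
        drop = ~df[id_col].isin(known)
        if drop.any():
            warnings.warn(
                f"{int(drop.sum())} phenotyped individuals have no genotype; excluded",
                stacklevel=2,
            )
            df = df[~drop]
    return df.reset_index(drop=True)


def write_grm(v: RelationshipMatrix, prefix: str | Path, format: str = "gcta", n_loci: int = 0) -> list[Path]:
    """Write a relationship matrix.

    ``gcta``: binary triple ``.grm.bin`` (lower triangle, single precision),
    ``.grm.N.bin`` (locus count per pair) and ``.grm.id``; ``csv``: plain
    matrix with ids. A sidecar JSON records component/approach/scaling.
    """
    prefix = Path(prefix)
    if not np.isfinite(v.values).all():
        raise ValueError("relationship matrix contains non-finite values")
    ids = v.ids or [str(i) for i in range(v.n)]
    meta = {
        "component": v.component,
        "approach": v.approach,
        "scale_denominator": v.scale_denominator,
        "n": v.n,
        "format": format,
    }
    written: list[Path] = []
    if format == "gcta":
        tri = v.values[np.tril_indices(v.n)]
        bin_path = prefix.with_suffix(".grm.bin")
        tri.astype("<f4").tofile(bin_path)
        nbin = prefix.with_suffix(".grm.N.bin")
        np.full(tri.shape, float(n_loci), dtype="<f4").tofile(nbin)
        id_path = prefix.with_suffix(".grm.id")
        pd.DataFrame({"fid": ids, "iid": ids}).to_csv(
            id_path, sep="\t", header=False, index=False
        )
        written += [bin_path, nbin, id_path]
    elif format == "csv":
        csv_path = prefix.with_suffix(".grm.csv")
        pd.DataFrame(v.values, index=ids, columns=ids).to_csv(csv_path)
        written.append(csv_path)
    else:
        raise ValueError(f"unknown GRM format {format!r}")
    side = prefix.with_suffix(".grm.json")
    side.write_text(json.dumps(meta, indent=1))
    written.append(side)
    return written


def read_grm(prefix: str | Path, format: str = "gcta") -> RelationshipMatrix:
    """Read a relationship matrix written by :func:`write_grm`."""
    prefix = Path(prefix)
    side = prefix.with_suffix(".grm.json")
    meta = json.loads(side.read_text()) if side.exists() else {}
    component = meta.get("component", "additive")
    approach = meta.get("approach", "noia")
    scale = float(meta.get("scale_denominator", 1.0))
    if format == "gcta":
        id_df = pd.read_csv(prefix.with_suffix(".grm.id"), sep="\t", header=None)
        ids = id_df[1].astype(str).tolist()
        n = len(ids)
        tri = np.fromfile(prefix.with_suffix(".grm.bin"), dtype="<f4")
        if tri.size != n * (n + 1) // 2:
            raise ValueError("GRM binary size does not match id count")
        vals = np.zeros((n, n))
        vals[np.tril_indices(n)] = tri
        vals = vals + np.tril(vals, -1).T
    elif format == "csv":
        df = pd.read_csv(prefix.with_suffix(".grm.csv"), index_col=0)
        ids = df.index.astype(str).tolist()
        vals = df.to_numpy(dtype=float)
        vals = 0.5 * (vals + vals.T)  # CSV round-trip symmetry
    else:
        raise ValueError(f"unknown GRM format {format!r}")
    return RelationshipMatrix(vals, component, approach, scale, ids)


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    """Record of inputs, seed and settings sufficient to re-run bit-identically."""

    seed: int
    inputs: dict[str, str] = field(default_factory=dict)  # path -> sha256
    qc: dict = field(default_factory=dict)
    approach: str = "noia"
    models: list[str] = field(default_factory=list)
    version: str = ""
    timestamp: str = ""

    def __post_init__(self) -> None:
        if not self.version:
            from . import __version__

            self.version = __version__
        if not self.timestamp:
            self.timestamp = datetime.now(timezone.utc).isoformat()

    def add_input(self, path: str | Path) -> None:
        self.inputs[str(path)] = _sha256(path)

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1))

    @classmethod
    def read(cls, path: str | Path) -> "RunManifest":
        return cls(**json.loads(Path(path).read_text()))
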