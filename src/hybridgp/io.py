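"""Readers and writers for genotypes, pedigrees, phenotypes and kinship matrices.

Formats are deliberately plain: CSV genotype matrices (header row of marker
ids, first column line id, body in {0,1}), three-column pedigree CSV, dense
or triplet kinship text, and an HDF5 container for large matrices.  VCF input
is accepted for pure lines only, and every call must be homozygous.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd

from .data import LineGenotypes, HybridPedigree, PhenotypeTable
from .kinship import KinshipMatrix

__all__ = [
    "read_line_genotypes",
    "read_pedigree",
    "read_phenotypes",
    "write_kinship",
    "read_kinship",
]


def read_line_genotypes(
    path: str | os.PathLike,
    group_label: str,
    format: str = "csv",
    impute_missing: bool = False,
) -> LineGenotypes:
    """Load a pure-line genotype matrix.

    CSV dialect: header row of marker ids, first column line ids, body in
    {0,1}.  VCF: one sample per line; all calls must be homozygous (the
    counted allele is ALT, so 1/1 -> 1 and 0/0 -> 0).

    Missing genotypes are a hard error unless ``impute_missing`` is set, in
    which case each missing call is replaced by the rounded within-group
    marker mean (explicit, logged through the returned data — never silent).
    """
    if format == "csv":
        return _read_genotypes_csv(path, group_label, impute_missing)
    if format == "vcf":
        return _read_genotypes_vcf(path, group_label)
    raise ValueError(f"unknown genotype format {format!r}")


def _read_genotypes_csv(path, group_label: str, impute_missing: bool) -> LineGenotypes:
    df = pd.read_csv(path, index_col=0)
    if df.empty:
        raise ValueError(f"no genotypes in {path}")
    calls = df.to_numpy(dtype=np.float64)
    if np.isnan(calls).any():
        if not impute_missing:
            i, j = np.argwhere(np.isnan(calls))[0]
            raise ValueError(
                f"missing genotype for line {df.index[i]!r} at marker "
                f"{df.columns[j]!r}; rerun with impute_missing to mean-impute"
            )
        col_mean = np.nanmean(calls, axis=0)
        fill = np.round(np.where(np.isnan(col_mean), 0.0, col_mean))
        idx = np.argwhere(np.isnan(calls))
        calls[idx[:, 0], idx[:, 1]] = fill[idx[:, 1]]
    bad = ~np.isin(calls, (0.0, 1.0))
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValueError(
            f"non-0/1 genotype {calls[i, j]!r} for line {df.index[i]!r} at "
            f"marker {df.columns[j]!r} in {path}"
        )
    return LineGenotypes(group_label, [str(x) for x in df.index], [str(c) for c in df.columns], calls)


def _read_genotypes_vcf(path, group_label: str) -> LineGenotypes:
    try:
        from cyvcf2 import VCF
    except ImportError as exc:  # pragma: no cover - env provides cyvcf2
        raise ImportError("VCF input requires the cyvcf2 package") from exc
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    marker_ids: list[str] = []
    rows: list[np.ndarray] = []
    for var in vcf:
        mid = var.ID if var.ID not in (None, ".") else f"{var.CHROM}:{var.POS}"
        # cyvcf2 gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
        gt = np.asarray(var.gt_types)
        het = np.flatnonzero(gt == 1)
        if het.size:
            raise ValueError(
                f"heterozygous call for line {samples[het[0]]!r} at marker "
                f"{mid!r}: inbred lines must be fully homozygous"
            )
        miss = np.flatnonzero(gt == 2)
        if miss.size:
            raise ValueError(
                f"missing call for line {samples[miss[0]]!r} at marker {mid!r}"
            )
        marker_ids.append(mid)
        rows.append((gt == 3).astype(np.float64))  # count the ALT allele
    if not rows:
        raise ValueError(f"no variant records in {path}")
    calls = np.column_stack(rows) if rows else np.empty((len(samples), 0))
    return LineGenotypes(group_label, samples, marker_ids, calls)


def read_pedigree(path: str | os.PathLike) -> HybridPedigree:
    """Read a three-column CSV (hybrid, parent1, parent2)."""
    df = pd.read_csv(path, dtype=str)
    if df.shape[1] < 3:
        raise ValueError("pedigree needs three columns: hybrid, parent1, parent2")
    df = df.iloc[:, :3]
    df.columns = ["hybrid", "parent1", "parent2"]
    if df.empty:
        raise ValueError(f"no hybrids in {path}")
    if df.isna().any().any():
        row = df[df.isna().any(axis=1)].iloc[0]
        raise ValueError(f"pedigree row for hybrid {row['hybrid']!r} has a missing field")
    hybrids = df["hybrid"].tolist()
    return HybridPedigree(
        hybrids,
        dict(zip(hybrids, df["parent1"])),
        dict(zip(hybrids, df["parent2"])),
    )


def read_phenotypes(path: str | os.PathLike, trait: str | None = None) -> PhenotypeTable:
    """Read hybrid entry means: first column hybrid id, then trait column(s).

    With several numeric columns the first is the trait unless ``trait``
    names one; remaining columns are kept as fixed covariates.
    """
    df = pd.read_csv(path, index_col=0)
    if df.empty:
        raise ValueError(f"no phenotypes in {path}")
    trait = trait or df.columns[0]
    if trait not in df.columns:
        raise KeyError(f"trait column {trait!r} not in {list(df.columns)}")
    values = df[trait].to_numpy(dtype=np.float64)
    if np.isnan(values).any():
        h = df.index[np.isnan(values)][0]
        raise ValueError(f"missing phenotype for hybrid {h!r}")
    cov = df.drop(columns=[trait])
    return PhenotypeTable(
        [str(h) for h in df.index], values, trait, cov if cov.shape[1] else None
    )


def write_kinship(K: KinshipMatrix, path: str | os.PathLike, format: str = "csv") -> None:
    """Persist a relationship matrix: ``csv`` (dense, id row/column),
    ``triplet`` (``#id1 id2 value`` text) or ``h5`` (HDF5 container).

    Round-trips are bit-exact through :func:`read_kinship` (full float
    precision is written in the text formats).
    """
    if not np.isfinite(K.values).all():
        raise ValueError(f"kinship {K.name!r} contains non-finite entries")
    if format == "csv":
        df = pd.DataFrame(K.values, index=K.ids, columns=K.ids)
        with open(path, "w") as fh:
            fh.write(f"# name={K.name} level={K.level} scale={K.scale_constant!r}\n")
            df.to_csv(fh, float_format="%.17g")
    elif format == "triplet":
        with open(path, "w") as fh:
            fh.write(f"# name={K.name} level={K.level} scale={K.scale_constant!r}\n")
            fh.write("#id1 id2 value\n")
            for i, a in enumerate(K.ids):
                for j in range(i, len(K.ids)):
                    fh.write(f"{a} {K.ids[j]} {K.values[i, j]:.17g}\n")
    elif format == "h5":
        import h5py

        with h5py.File(path, "w") as f:
            f.create_dataset("values", data=K.values)
            f.create_dataset("ids", data=np.array(K.ids, dtype="S"))
            f.attrs["name"] = K.name
            f.attrs["level"] = K.level
            f.attrs["scale_constant"] = K.scale_constant
    else:
        raise ValueError(f"unknown kinship format {format!r}")


def _parse_header(line: str) -> dict[str, str]:
    fields = dict(tok.split("=", 1) for tok in line.lstrip("# ").split() if "=" in tok)
    return fields


def read_kinship(path: str | os.PathLike, format: str = "csv") -> KinshipMatrix:
    if format == "csv":
        with open(path) as fh:
            meta = _parse_header(fh.readline())
            # round_trip parsing: the default float parser can be 1 ulp off
            df = pd.read_csv(fh, index_col=0, float_precision="round_trip")
        ids = [str(x) for x in df.index]
        return KinshipMatrix(
            meta.get("name", "K"), meta.get("level", "hybrids"),
            df.to_numpy(dtype=np.float64), float(meta.get("scale", "nan")), ids,
        )
    if format == "triplet":
        with open(path) as fh:
            meta = _parse_header(fh.readline())
            header = fh.readline()
            if not header.startswith("#id1"):
                raise ValueError("triplet kinship file lacks '#id1 id2 value' header")
            ids: list[str] = []
            pos: dict[str, int] = {}
            entries = []
            for line in fh:
                a, b, v = line.split()
                for x in (a, b):
                    if x not in pos:
                        pos[x] = len(ids)
                        ids.append(x)
                entries.append((pos[a], pos[b], float(v)))
        n = len(ids)
        values = np.zeros((n, n))
        for i, j, v in entries:
            values[i, j] = v
            values[j, i] = v
        return KinshipMatrix(
            meta.get("name", "K"), meta.get("level", "hybrids"),
            values, float(meta.get("scale", "nan")), ids,
        )
    if format == "h5":
        import h5py

        with h5py.File(path, "r") as f:
            return KinshipMatrix(
                str(f.attrs["name"]), str(f.attrs["level"]),
                f["values"][...], float(f.attrs["scale_constant"]),
                [s.decode() for s in f["ids"][...]],
            )
    raise ValueError(f"unknown kinship format {format!r}")
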