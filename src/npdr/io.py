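"""Genotype, phenotype, covariate and result file input/output.

Dosage matrices are stored as minor-allele counts (0/1/2).  The canonical
on-disk genotype format is PLINK ``.raw`` (whitespace-delimited, six meta
columns ``FID IID PAT MAT SEX PHENOTYPE`` followed by one dosage column per
variant, ``NA`` for missing).  Rectangular TSV/CSV tables with a header are
supported for genotypes, phenotypes and covariates.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeMatrix",
    "PhenotypeVector",
    "CovariateTable",
    "FormatError",
    "read_raw",
    "read_raw_phenotype",
    "write_raw",
    "read_table",
    "write_results",
    "read_results",
    "impute_mode",
]

_RAW_META_COLS = ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"]
_ALLELE_SUFFIX = re.compile(r"_[ACGTNacgtn0-9]+$")


class FormatError(ValueError):
    """Raised when an input file does not conform to its declared dialect."""


@dataclass
class GenotypeMatrix:
    """m samples x p SNPs of minor-allele dosage in {0, 1, 2}.

    ``missing_mask`` is True where the genotype is missing; masked cells hold
    a placeholder dosage of 0 and must be imputed (see :func:`impute_mode`)
    before distance-based analyses.
    """

    samples: list[str]
    snps: list[str]
    dosage: np.ndarray
    missing_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage)
        if self.dosage.ndim != 2:
            raise ValueError("dosage must be 2-dimensional (samples x SNPs)")
        m, p = self.dosage.shape
        if m < 2 or p < 1:
            raise ValueError(f"need m >= 2 samples and p >= 1 SNPs, got {m}x{p}")
        if len(self.samples) != m or len(self.snps) != p:
            raise ValueError("sample/SNP label lengths do not match dosage shape")
        if len(set(self.samples)) != m:
            raise ValueError("sample IDs must be unique")
        if len(set(self.snps)) != p:
            raise ValueError("SNP IDs must be unique")
        if self.missing_mask is not None:
            self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
            if self.missing_mask.shape != self.dosage.shape:
                raise ValueError("missing_mask shape mismatch")
        valid = np.isin(self.dosage, (0, 1, 2))
        if self.missing_mask is not None:
            valid |= self.missing_mask
        if not valid.all():
            i, j = np.argwhere(~valid)[0]
            raise ValueError(
                f"dosage outside {{0,1,2}} at sample {self.samples[i]!r}, "
                f"SNP {self.snps[j]!r}: {self.dosage[i, j]!r}"
            )
        self.dosage = self.dosage.astype(np.int8)

    @property
    def n_samples(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosage.shape[1]

    @property
    def has_missing(self) -> bool:
        return self.missing_mask is not None and bool(self.missing_mask.any())

    def subset_snps(self, indices) -> "GenotypeMatrix":
        """New matrix restricted to SNP columns ``indices`` (order kept)."""
        indices = np.asarray(indices)
        return GenotypeMatrix(
            samples=list(self.samples),
            snps=[self.snps[i] for i in indices],
            dosage=self.dosage[:, indices],
            missing_mask=None if self.missing_mask is None else self.missing_mask[:, indices],
        )

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.dosage.astype(float), index=self.samples, columns=self.snps)
        if self.missing_mask is not None:
            df = df.mask(self.missing_mask)
        return df


@dataclass
class PhenotypeVector:
    """Length-m outcome: binary case/control (1/0) or continuous trait."""

    values: np.ndarray
    kind: str  # "binary" | "continuous"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("phenotype must be a vector")
        if np.isnan(self.values).any():
            raise ValueError("phenotype contains missing values")
        if self.kind not in ("binary", "continuous"):
            raise ValueError(f"unknown phenotype kind {self.kind!r}")
        if self.kind == "binary":
            u = np.unique(self.values)
            if not np.isin(u, (0.0, 1.0)).all():
                raise ValueError("binary phenotype values must be in {0,1}")
            if len(u) != 2:
                raise ValueError("case-control phenotype needs both classes present")

    @classmethod
    def infer(cls, values) -> "PhenotypeVector":
        """Classify as binary iff all values are in {0,1} ({1,2} is remapped)."""
        v = np.asarray(values, dtype=float)
        u = np.unique(v)
        if np.isin(u, (0.0, 1.0)).all() and len(u) == 2:
            return cls(v, "binary")
        if np.isin(u, (1.0, 2.0)).all() and len(u) == 2:  # PLINK 1/2 coding
            return cls(v - 1.0, "binary")
        return cls(v, "continuous")

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class CovariateTable:
    """m x c real covariates (e.g. principal components PC1..PC10)."""

    names: list[str]
    values: np.ndarray
    samples: list[str] | None = None

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.values.shape[1] != len(self.names):
            raise ValueError("covariate names do not match number of columns")
        if np.isnan(self.values).any():
            raise ValueError("covariates must not contain missing values")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]


def _parse_dosage_frame(df: pd.DataFrame, where: str) -> tuple[np.ndarray, np.ndarray]:
    """Validate a numeric frame as dosages; returns (int dosage, missing mask)."""
    arr = np.empty(df.shape, dtype=np.int8)
    numeric = df.apply(pd.to_numeric, errors="coerce")
    missing = df.isna().to_numpy()
    bad_nonnum = numeric.isna().to_numpy() & ~missing
    if bad_nonnum.any():
        i, j = np.argwhere(bad_nonnum)[0]
        raise ValueError(
            f"{where}: non-numeric dosage {df.iat[i, j]!r} at row {df.index[i]!r}, "
            f"column {df.columns[j]!r}"
        )
    vals = numeric.to_numpy(dtype=float)
    vals_filled = np.where(missing, 0.0, vals)
    ok = np.isin(vals_filled, (0.0, 1.0, 2.0))
    if not ok.all():
        i, j = np.argwhere(~ok)[0]
        raise ValueError(
            f"{where}: dosage outside {{0,1,2,NA}} at row {df.index[i]!r}, "
            f"column {df.columns[j]!r}: {vals[i, j]!r}"
        )
    arr[:] = vals_filled.astype(np.int8)
    return arr, missing


def read_raw(path) -> GenotypeMatrix:
    """Read a PLINK ``.raw`` dosage file.

    Allele suffixes on variant column names (``rs123_A``) are stripped into
    bare SNP IDs.  ``NA`` cells set ``missing_mask``.
    """
    df = pd.read_csv(path, sep=r"\s+", dtype=str)
    if df.shape[0] < 1:
        raise FormatError(f"{path}: no data rows")
    if list(df.columns[:6]) != _RAW_META_COLS:
        raise FormatError(
            f"{path}: malformed .raw header; expected leading columns "
            f"{' '.join(_RAW_META_COLS)}, got {' '.join(df.columns[:6])}"
        )
    if df.shape[1] < 7:
        raise FormatError(f"{path}: .raw file has no genotype columns")
    geno = df.iloc[:, 6:]
    snps = [_ALLELE_SUFFIX.sub("", c) for c in geno.columns]
    samples = df["IID"].tolist()
    dosage, missing = _parse_dosage_frame(geno, str(path))
    return GenotypeMatrix(
        samples=samples,
        snps=snps,
        dosage=dosage,
        missing_mask=missing if missing.any() else None,
    )


def read_raw_phenotype(path) -> PhenotypeVector:
    """Read the PHENOTYPE column of a ``.raw`` file (PLINK 1/2 remapped to 0/1)."""
    df = pd.read_csv(path, sep=r"\s+", dtype=str)
    if "PHENOTYPE" not in df.columns:
        raise FormatError(f"{path}: no PHENOTYPE column")
    return PhenotypeVector.infer(pd.to_numeric(df["PHENOTYPE"]).to_numpy())


def write_raw(G: GenotypeMatrix, path, phenotype: PhenotypeVector | None = None) -> None:
    """Write a ``.raw`` file; binary phenotypes use PLINK 1/2 coding."""
    m = G.n_samples
    if phenotype is None:
        pheno_col = ["-9"] * m
    elif phenotype.kind == "binary":
        pheno_col = [str(int(v) + 1) for v in phenotype.values]
    else:
        pheno_col = [repr(float(v)) for v in phenotype.values]
    dos = G.dosage.astype(object)
    if G.missing_mask is not None:
        dos[G.missing_mask] = "NA"
    df = pd.DataFrame(dos, columns=G.snps)
    meta = pd.DataFrame(
        {
            "FID": G.samples,
            "IID": G.samples,
            "PAT": 0,
            "MAT": 0,
            "SEX": 0,
            "PHENOTYPE": pheno_col,
        }
    )
    pd.concat([meta, df.set_axis(meta.index)], axis=1).to_csv(path, sep=" ", index=False)


def read_table(path, delimiter: str | None = None, orientation: str = "samples-rows",
               kind: str = "genotype"):
    """Read a headered rectangular table.

    Parameters
    ----------
    delimiter : inferred from extension when None (``.csv`` comma, else tab).
    orientation : ``samples-rows`` or ``samples-columns`` (genotypes only).
    kind : ``genotype`` -> GenotypeMatrix, ``phenotype`` -> PhenotypeVector,
        ``covariate`` -> CovariateTable.
    """
    if delimiter is None:
        delimiter = "," if str(path).endswith(".csv") else "\t"
    try:
        df = pd.read_csv(path, sep=delimiter, index_col=0, dtype=str)
    except pd.errors.ParserError as e:
        raise FormatError(f"{path}: {e}") from e
    if kind == "phenotype":
        col = df.iloc[:, 0] if df.shape[1] else df.index.to_series()
        return PhenotypeVector.infer(pd.to_numeric(col).to_numpy())
    if kind == "covariate":
        return CovariateTable(
            names=list(df.columns),
            values=df.apply(pd.to_numeric).to_numpy(dtype=float),
            samples=[str(s) for s in df.index],
        )
    if kind != "genotype":
        raise ValueError(f"unknown table kind {kind!r}")
    if orientation == "samples-columns":
        df = df.T
    elif orientation != "samples-rows":
        raise ValueError(f"unknown orientation {orientation!r}")
    dosage, missing = _parse_dosage_frame(df, str(path))
    return GenotypeMatrix(
        samples=[str(s) for s in df.index],
        snps=[str(c) for c in df.columns],
        dosage=dosage,
        missing_mask=missing if missing.any() else None,
    )


_RESULT_COLS = ["snp", "beta", "se", "z", "p_one_sided", "p_adjusted", "rank"]


def write_results(result, path) -> None:
    """Write a per-SNP result table as TSV, sorted by p ascending (ties by SNP ID)."""
    table = result.table if hasattr(result, "table") else result
    if len(table) == 0:
        raise ValueError("refusing to write an empty result table")
    df = table.copy()
    stat_col = "z" if "z" in df.columns else "t"
    out = pd.DataFrame(
        {
            "snp": df["snp"],
            "beta": df["beta"],
            "se": df["se"],
            "z": df[stat_col],
            "p_one_sided": df["p_one_sided"],
            "p_adjusted": df["p_adjusted"],
            "rank": df["rank"],
        }
    )
    out = out.sort_values(["p_one_sided", "snp"], kind="stable", na_position="last")
    out.to_csv(path, sep="\t", index=False)


def read_results(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if list(df.columns) != _RESULT_COLS:
        raise FormatError(f"{path}: unexpected result columns {list(df.columns)}")
    return df


def impute_mode(G: GenotypeMatrix) -> GenotypeMatrix:
    """Replace missing genotypes with the per-SNP modal dosage.

    Ties between equally common dosages resolve to the smallest dosage.
    """
    if not G.has_missing:
        return GenotypeMatrix(list(G.samples), list(G.snps), G.dosage.copy())
    dosage = G.dosage.copy()
    mask = G.missing_mask
    for j in np.flatnonzero(mask.any(axis=0)):
        obs = dosage[~mask[:, j], j]
        if obs.size == 0:
            raise ValueError(f"SNP {G.snps[j]!r} is entirely missing; cannot impute")
        counts = np.bincount(obs, minlength=3)
        dosage[mask[:, j], j] = int(np.argmax(counts))
    return GenotypeMatrix(list(G.samples), list(G.snps), dosage)
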