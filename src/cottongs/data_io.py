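"""Genotype and phenotype table ingestion, filtering, imputation and scaling.

Genotypes are SNP dosages (count of the B / alternate allele: AA=0, AB=1,
BB=2) for a set of inbred breeding lines; calls may be missing.  Phenotypes
are long-format adjusted means per (line, site, trait), optionally with the
standard error of the adjusted mean.

The standard preprocessing chain for whole-genome regression is

    read -> filter_markers -> impute_missing_mean -> center_standardize

which yields a complete column-standardized matrix ``X`` suitable for the
regression models in :mod:`cottongs.wgr`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeMatrix",
    "StandardizedMatrix",
    "PhenotypeTable",
    "read_genotype_table",
    "read_phenotype_table",
    "write_genotype_table",
    "write_phenotype_table",
    "filter_markers",
    "impute_missing_mean",
    "center_standardize",
    "standardize_like",
]

_CALL_CODES = {"AA": 0.0, "AB": 1.0, "BB": 2.0}
_MISSING_TOKENS = {"NA", "", "NAN", ".", "--"}


@dataclass
class GenotypeMatrix:
    """Line x marker dosage matrix with an explicit missing-call mask.

    ``dosage`` holds values in [0, 2] wherever ``missing_mask`` is False;
    masked entries are NaN.  Fractional dosages appear after mean imputation.
    """

    line_ids: list[str]
    marker_ids: list[str]
    dosage: np.ndarray          # (n_lines, n_markers) float64, NaN where masked
    missing_mask: np.ndarray    # (n_lines, n_markers) bool
    chrom: np.ndarray | None = None   # optional marker chromosome labels
    pos: np.ndarray | None = None     # optional 1-based marker positions

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=float)
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        n, p = self.dosage.shape
        if len(self.line_ids) != n or len(self.marker_ids) != p:
            raise ValueError("identifier lengths do not match dosage shape")
        if len(set(self.line_ids)) != n:
            raise ValueError("duplicate line identifiers")
        if len(set(self.marker_ids)) != p:
            raise ValueError("duplicate marker identifiers")
        obs = self.dosage[~self.missing_mask]
        if obs.size and (np.isnan(obs).any() or obs.min() < 0 or obs.max() > 2):
            raise ValueError("non-missing dosages must lie in [0, 2]")

    @property
    def n_lines(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_markers(self) -> int:
        return self.dosage.shape[1]

    def allele_freq(self) -> np.ndarray:
        """Observed B-allele frequency per marker, from non-missing calls."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(np.where(self.missing_mask, np.nan, self.dosage), axis=0) / 2.0

    def call_rate(self) -> np.ndarray:
        return 1.0 - self.missing_mask.mean(axis=0)


@dataclass
class StandardizedMatrix:
    """Centered and unit-variance (sample SD) genotype matrix.

    ``col_means``/``col_sds`` are retained so that prediction-set genotypes
    can be standardized identically to the training set (training-anchored
    scaling keeps GEBVs comparable between sets).
    """

    X: np.ndarray
    col_means: np.ndarray
    col_sds: np.ndarray
    line_ids: list[str] = field(default_factory=list)
    marker_ids: list[str] = field(default_factory=list)

    @property
    def n_lines(self) -> int:
        return self.X.shape[0]

    @property
    def n_markers(self) -> int:
        return self.X.shape[1]


@dataclass
class PhenotypeTable:
    """Long-format adjusted means: one record per (line, site, trait)."""

    records: pd.DataFrame  # columns: line, site, trait, mean, se (se may be NaN)

    def __post_init__(self) -> None:
        req = ["line", "site", "trait", "mean"]
        missing = [c for c in req if c not in self.records.columns]
        if missing:
            raise ValueError(f"phenotype table missing columns {missing}")
        if "se" not in self.records.columns:
            self.records = self.records.assign(se=np.nan)
        dup = self.records.duplicated(subset=["line", "site", "trait"])
        if dup.any():
            bad = self.records.loc[dup.idxmax(), ["line", "site", "trait"]]
            raise ValueError(
                f"duplicate (line, site, trait) record: {tuple(bad)}"
            )
        se = self.records["se"].to_numpy(float)
        if np.any(se[~np.isnan(se)] <= 0):
            raise ValueError("standard errors must be positive where present")

    def sites(self) -> list[str]:
        return list(pd.unique(self.records["site"]))

    def site_slice(self, site: str, trait: str) -> pd.DataFrame:
        r = self.records
        return r[(r["site"] == site) & (r["trait"] == trait)].reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.records)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _parse_cell(token: str, dialect: str, row_id: str, marker_id: str) -> float:
    t = token.strip().upper()
    if t in _MISSING_TOKENS:
        return np.nan
    if dialect == "call_csv":
        if t not in _CALL_CODES:
            raise ValueError(
                f"malformed genotype call {token!r} at line {row_id!r}, marker {marker_id!r}"
            )
        return _CALL_CODES[t]
    try:
        v = float(t)
    except ValueError:
        raise ValueError(
            f"malformed dosage {token!r} at line {row_id!r}, marker {marker_id!r}"
        ) from None
    if not 0.0 <= v <= 2.0:
        raise ValueError(
            f"dosage {token!r} outside [0, 2] at line {row_id!r}, marker {marker_id!r}"
        )
    return v


def read_genotype_table(path: str | Path, dialect: str = "dosage_csv",
                        sep: str = ",") -> GenotypeMatrix:
    """Read a line x marker genotype table.

    Parameters
    ----------
    path:
        Delimited text file; first column is the line ID, header row holds
        marker IDs.  ``dialect='call_csv'`` expects AA/AB/BB/NA calls,
        ``dialect='dosage_csv'`` numeric dosages in [0, 2] (NA for missing).
        ``dialect='vcf'`` reads a VCF 4.x file (GT field; the first ALT
        allele is counted as the B allele).
    """
    if dialect == "vcf":
        return _read_vcf(path)
    if dialect not in ("dosage_csv", "call_csv"):
        raise ValueError(f"unknown genotype dialect {dialect!r}")
    path = Path(path)
    with path.open() as fh:
        header = fh.readline().rstrip("\n").split(sep)
        marker_ids = [m.strip() for m in header[1:]]
        line_ids: list[str] = []
        rows: list[list[float]] = []
        for raw in fh:
            raw = raw.rstrip("\n")
            if not raw:
                continue
            parts = raw.split(sep)
            if len(parts) != len(marker_ids) + 1:
                raise ValueError(
                    f"row {parts[0]!r} has {len(parts) - 1} cells, expected {len(marker_ids)}"
                )
            lid = parts[0].strip()
            line_ids.append(lid)
            rows.append([
                _parse_cell(tok, dialect, lid, marker_ids[j])
                for j, tok in enumerate(parts[1:])
            ])
    dosage = np.asarray(rows, dtype=float)
    if dosage.ndim != 2 or dosage.size == 0:
        raise ValueError(f"no genotype rows parsed from {path}")
    mask = np.isnan(dosage)
    return GenotypeMatrix(line_ids, marker_ids, dosage, mask)


def _read_vcf(path: str | Path) -> GenotypeMatrix:
    """Minimal VCF 4.x GT reader: dosage = count of the first ALT allele."""
    marker_ids: list[str] = []
    chroms: list[str] = []
    poss: list[int] = []
    rows: list[list[float]] = []
    samples: list[str] = []
    with Path(path).open() as fh:
        for raw in fh:
            if raw.startswith("##"):
                continue
            if raw.startswith("#CHROM"):
                samples = raw.rstrip("\n").split("\t")[9:]
                continue
            parts = raw.rstrip("\n").split("\t")
            if len(parts) < 10:
                continue
            chrom, pos, vid = parts[0], int(parts[1]), parts[2]
            marker_ids.append(vid if vid != "." else f"{chrom}:{pos}")
            chroms.append(chrom)
            poss.append(pos)
            fmt = parts[8].split(":")
            gt_i = fmt.index("GT")
            row = []
            for cell in parts[9:]:
                gt = cell.split(":")[gt_i].replace("|", "/")
                if "." in gt:
                    row.append(np.nan)
                else:
                    alleles = [int(a) for a in gt.split("/")]
                    row.append(float(sum(a == 1 for a in alleles)))
            rows.append(row)
    if not samples:
        raise ValueError(f"no #CHROM header found in {path}")
    dosage = np.asarray(rows, dtype=float).T  # variants x samples -> samples x variants
    mask = np.isnan(dosage)
    return GenotypeMatrix(samples, marker_ids, dosage, mask,
                          chrom=np.asarray(chroms), pos=np.asarray(poss))


def write_genotype_table(g: GenotypeMatrix, path: str | Path) -> None:
    """Write dosages as CSV (NA for masked cells); round-trips exactly."""
    df = pd.DataFrame(np.where(g.missing_mask, np.nan, g.dosage),
                      index=g.line_ids, columns=g.marker_ids)
    df.index.name = "line"
    df.to_csv(path, na_rep="NA")


def read_phenotype_table(path: str | Path, sep: str = ",") -> PhenotypeTable:
    """Read a long-format phenotype file with header ``line,site,trait,mean[,se]``."""
    df = pd.read_csv(path, sep=sep, dtype={"line": str, "site": str, "trait": str})
    df.columns = [c.strip().lower() for c in df.columns]
    if "mean" not in df.columns:
        raise ValueError("phenotype file must have a 'mean' column")
    if not np.issubdtype(df["mean"].dtype, np.number):
        bad = df.loc[pd.to_numeric(df["mean"], errors="coerce").isna(), "mean"]
        raise ValueError(f"non-numeric mean value {bad.iloc[0]!r}")
    return PhenotypeTable(df)


def write_phenotype_table(t: PhenotypeTable, path: str | Path) -> None:
    t.records.to_csv(path, index=False, na_rep="NA")


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

def filter_markers(g: GenotypeMatrix, min_call_rate: float = 0.80,
                   min_maf: float = 0.05) -> GenotypeMatrix:
    """Keep markers with call rate strictly above ``min_call_rate`` and MAF
    strictly above ``min_maf``.

    MAF is computed on non-missing calls only, as min(p, 1-p) with
    p = mean(dosage)/2, so the filter is symmetric in the allele labels.
    Returns a new matrix with marker order preserved; attaches a
    ``filter_log`` dict recording per-criterion casualty counts.
    """
    if not (0 <= min_call_rate <= 1 and 0 <= min_maf <= 1):
        raise ValueError("thresholds must lie in [0, 1]")
    cr = g.call_rate()
    p = g.allele_freq()
    with np.errstate(invalid="ignore"):
        maf = np.minimum(p, 1.0 - p)
    cr_ok = cr > min_call_rate
    maf_ok = np.where(np.isnan(maf), False, maf > min_maf)
    keep = cr_ok & maf_ok
    log = {
        "n_in": g.n_markers,
        "n_kept": int(keep.sum()),
        "removed_call_rate": int((~cr_ok).sum()),
        "removed_maf": int((~maf_ok).sum()),
    }
    if not keep.any():
        raise ValueError(
            "all markers removed: "
            f"{log['removed_call_rate']} failed call rate > {min_call_rate}, "
            f"{log['removed_maf']} failed MAF > {min_maf}"
        )
    out = GenotypeMatrix(
        list(g.line_ids),
        [m for m, k in zip(g.marker_ids, keep) if k],
        g.dosage[:, keep],
        g.missing_mask[:, keep],
        chrom=None if g.chrom is None else g.chrom[keep],
        pos=None if g.pos is None else g.pos[keep],
    )
    out.filter_log = log  # type: ignore[attr-defined]
    return out


def impute_missing_mean(g: GenotypeMatrix) -> GenotypeMatrix:
    """Replace masked calls by the marker's non-missing mean dosage."""
    n_obs = (~g.missing_mask).sum(axis=0)
    if (n_obs == 0).any():
        j = int(np.argmin(n_obs))
        raise ValueError(f"marker {g.marker_ids[j]!r} has no non-missing calls")
    filled = np.where(g.missing_mask, 0.0, g.dosage)
    col_mean = filled.sum(axis=0) / n_obs
    dosage = np.where(g.missing_mask, col_mean[None, :], g.dosage)
    return GenotypeMatrix(list(g.line_ids), list(g.marker_ids), dosage,
                          np.zeros_like(g.missing_mask),
                          chrom=g.chrom, pos=g.pos)


def center_standardize(g: GenotypeMatrix) -> StandardizedMatrix:
    """Center each marker and scale to unit sample (n-1) standard deviation."""
    if g.missing_mask.any():
        raise ValueError("impute missing calls before standardizing")
    mu = g.dosage.mean(axis=0)
    sd = g.dosage.std(axis=0, ddof=1)
    zero = sd <= 0
    if zero.any():
        j = int(np.argmax(zero))
        raise ValueError(f"marker {g.marker_ids[j]!r} has zero sample SD")
    X = (g.dosage - mu[None, :]) / sd[None, :]
    return StandardizedMatrix(X, mu, sd, list(g.line_ids), list(g.marker_ids))


def standardize_like(g: GenotypeMatrix, ref: StandardizedMatrix) -> StandardizedMatrix:
    """Standardize prediction-set genotypes with training-set means/SDs."""
    if list(g.marker_ids) != list(ref.marker_ids):
        first = next(
            (a, b) for a, b in zip(g.marker_ids, ref.marker_ids) if a != b
        ) if len(g.marker_ids) == len(ref.marker_ids) else ("length", "mismatch")
        raise ValueError(f"marker mismatch with training set: {first}")
    if g.missing_mask.any():
        raise ValueError("impute missing calls before standardizing")
    X = (g.dosage - ref.col_means[None, :]) / ref.col_sds[None, :]
    return StandardizedMatrix(X, ref.col_means, ref.col_sds,
                              list(g.line_ids), list(g.marker_ids))
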