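"""File formats, region windowing and run manifests.

Conventions: summary statistics are tab-separated with a header; the
standardized-scale marginal effect is beta_hat = z / sqrt(N) (the sufficient
reduction available from any GWAS when genotypes and phenotype are
standardized).  Coordinates are 0-based half-open internally; 1-based
inclusive positions are accepted on input and converted.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .ld import LDMatrix

logger = logging.getLogger("regpoly")

__all__ = [
    "SumstatsError",
    "RegionDefinition",
    "read_sumstats",
    "write_sumstats",
    "read_ld_matrix",
    "write_ld_matrix",
    "read_h2_table",
    "read_regions",
    "write_regions",
    "window_regions",
    "write_manifest",
    "sha256_file",
]


class SumstatsError(ValueError):
    """Malformed summary-statistics input."""


def read_sumstats(path: str | Path) -> pd.DataFrame:
    """Read a tab-separated GWAS summary-statistics table.

    Requires columns ``snp_id`` and ``n`` plus either ``z`` or both ``beta``
    and ``se``.  Returns a frame with snp_id, optional chrom/position, z, n
    and the standardized-scale effect ``beta_std = z / sqrt(n)``.  Rows with
    missing required fields are dropped (count logged).
    """
    try:
        df = pd.read_csv(path, sep="\t")
    except pd.errors.EmptyDataError as exc:
        raise SumstatsError(f"{path}: empty file or missing header") from exc
    cols = set(df.columns)
    if "snp_id" not in cols or "n" not in cols:
        raise SumstatsError(f"{path}: required columns snp_id and n not found")
    has_z = "z" in cols
    has_beta = {"beta", "se"} <= cols
    if not has_z and not has_beta:
        raise SumstatsError(f"{path}: need column z or columns beta and se")

    required = ["snp_id", "n"] + (["z"] if has_z else ["beta", "se"])
    n_before = len(df)
    df = df.dropna(subset=required).copy()
    dropped = n_before - len(df)
    if dropped:
        logger.warning("%s: dropped %d rows with missing required fields", path, dropped)
    if df.empty:
        raise SumstatsError(f"{path}: no usable rows")

    for col in ("n", "z", "beta", "se", "position"):
        if col in df.columns:
            try:
                df[col] = pd.to_numeric(df[col])
            except (ValueError, TypeError) as exc:
                raise SumstatsError(f"{path}: non-numeric values in column {col}") from exc
    if df["snp_id"].duplicated().any():
        dup = df.loc[df["snp_id"].duplicated(), "snp_id"].iloc[0]
        raise SumstatsError(f"{path}: duplicate snp_id {dup!r}")
    if (df["n"] <= 0).any():
        raise SumstatsError(f"{path}: non-positive sample size")

    if has_beta:
        if (df["se"] <= 0).any():
            raise SumstatsError(f"{path}: non-positive standard error")
        z_from_beta = df["beta"] / df["se"]
        if has_z:
            if np.max(np.abs(df["z"] - z_from_beta)) > 1e-6:
                raise SumstatsError(f"{path}: z and beta/se disagree beyond 1e-6")
        else:
            df["z"] = z_from_beta
    df["beta_std"] = df["z"] / np.sqrt(df["n"])
    if "position" in df.columns:
        df["position"] = df["position"].astype(int)
    return df.reset_index(drop=True)


def write_sumstats(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_ld_matrix(path: str | Path, snp_ids: list[str] | None = None) -> LDMatrix:
    """Read a whitespace-delimited square LD matrix.

    A sidecar file ``<path stem>.snp_ids`` (one id per line), when present,
    supplies the SNP order; if ``snp_ids`` is also given the two must match
    exactly.
    """
    path = Path(path)
    values = np.loadtxt(path, ndmin=2)
    sidecar = path.with_suffix(".snp_ids")
    file_ids: list[str] | None = None
    if sidecar.exists():
        file_ids = sidecar.read_text().split()
    if file_ids is not None and snp_ids is not None:
        if file_ids != list(snp_ids):
            raise ValueError(
                f"{path}: SNP order mismatch between LD sidecar and summary statistics"
            )
    return LDMatrix(values=values, snp_ids=file_ids or (list(snp_ids) if snp_ids else None))


def write_ld_matrix(ld: LDMatrix, path: str | Path) -> None:
    path = Path(path)
    np.savetxt(path, ld.values, fmt="%.10g")
    if ld.snp_ids is not None:
        path.with_suffix(".snp_ids").write_text("\n".join(ld.snp_ids) + "\n")


def read_h2_table(path: str | Path, floor: float = 1e-6) -> dict[str, float]:
    """Read a two-column (region_id, h2_r) table.

    Negative external estimates (possible with unbiased quadratic-form
    heritability estimators) are floored at ``floor`` with a warning; values
    >= 1 are rejected.
    """
    df = pd.read_csv(path, sep="\t")
    if not {"region_id", "h2_r"} <= set(df.columns):
        raise ValueError(f"{path}: need columns region_id and h2_r")
    out: dict[str, float] = {}
    for _, row in df.iterrows():
        h2 = float(row["h2_r"])
        if h2 >= 1.0:
            raise ValueError(f"{path}: h2_r >= 1 for region {row['region_id']}")
        if h2 < floor:
            logger.warning(
                "region %s: h2_r %.3g floored at %.1g", row["region_id"], h2, floor
            )
            h2 = floor
        out[str(row["region_id"])] = h2
    return out


@dataclass
class RegionDefinition:
    """A half-open genomic window [start, end) holding a set of SNP rows."""

    region_id: str
    chrom: str
    start: int
    end: int
    snp_indices: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    @property
    def m_r(self) -> int:
        return len(self.snp_indices)


def window_regions(
    sumstats: pd.DataFrame,
    window_bp: float = 6e6,
    one_based: bool = True,
) -> list[RegionDefinition]:
    """Divide each chromosome into consecutive fixed-width windows.

    Windows start at the first SNP's position per chromosome; empty windows
    are dropped and the trailing partial window is retained.  Positions must
    be sorted within chromosome.
    """
    if not {"chrom", "position"} <= set(sumstats.columns):
        raise ValueError("windowing needs chrom and position columns")
    window_bp = int(window_bp)
    regions: list[RegionDefinition] = []
    for chrom in sumstats["chrom"].astype(str).unique():
        mask = sumstats["chrom"].astype(str) == chrom
        idx = np.flatnonzero(mask.to_numpy())
        pos = sumstats.loc[mask, "position"].to_numpy(dtype=np.int64)
        if one_based:
            pos = pos - 1
        if np.any(np.diff(pos) < 0):
            raise ValueError(f"chromosome {chrom}: positions are not sorted")
        start0 = int(pos[0])
        win = ((pos - start0) // window_bp).astype(int)
        for w in np.unique(win):
            members = idx[win == w]
            lo = start0 + int(w) * window_bp
            hi = lo + window_bp
            regions.append(
                RegionDefinition(
                    region_id=f"{chrom}_{lo}_{hi}",
                    chrom=chrom,
                    start=lo,
                    end=hi,
                    snp_indices=members,
                )
            )
    return regions


def read_regions(path: str | Path, sumstats: pd.DataFrame) -> list[RegionDefinition]:
    """Read explicit region definitions (region_id, chrom, start, end; 0-based half-open)."""
    df = pd.read_csv(path, sep="\t")
    need = {"region_id", "chrom", "start", "end"}
    if not need <= set(df.columns):
        raise ValueError(f"{path}: need columns {sorted(need)}")
    chroms = sumstats["chrom"].astype(str).to_numpy()
    pos = sumstats["position"].to_numpy(dtype=np.int64) - 1
    regions = []
    claimed = np.zeros(len(sumstats), dtype=bool)
    for _, row in df.iterrows():
        mask = (chroms == str(row["chrom"])) & (pos >= int(row["start"])) & (
            pos < int(row["end"])
        )
        if np.any(mask & claimed):
            raise ValueError(f"{path}: overlapping regions at {row['region_id']}")
        claimed |= mask
        regions.append(
            RegionDefinition(
                region_id=str(row["region_id"]),
                chrom=str(row["chrom"]),
                start=int(row["start"]),
                end=int(row["end"]),
                snp_indices=np.flatnonzero(mask),
            )
        )
    return regions


def write_regions(regions: list[RegionDefinition], path: str | Path) -> None:
    pd.DataFrame(
        [
            {"region_id": r.region_id, "chrom": r.chrom, "start": r.start, "end": r.end}
            for r in regions
        ]
    ).to_csv(path, sep="\t", index=False)


def sha256_file(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(
    out_dir: str | Path,
    inputs: dict[str, str | Path],
    config: dict,
    seed: int,
) -> Path:
    """Write a machine-readable run manifest (inputs' checksums, config, seed).

    No timestamps: identical invocations produce byte-identical manifests.
    """
    manifest = {
        "version": __version__,
        "seed": seed,
        "config": config,
        "inputs": {
            name: {"path": str(p), "sha256": sha256_file(p)}
            for name, p in inputs.items()
            if Path(p).exists()
        },
    }
    out = Path(out_dir) / "manifest.json"
    out.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return out
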