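"""Reading and writing of methylation count data and sample metadata.

The on-disk interchange format is the Bismark-style coverage file: one row per
CpG, tab-separated ``<chrom> <start> <end> <methylation %> <count methylated>
<count unmethylated>`` with 1-based inclusive positions.  Counts are always
authoritative; the percentage column is written for human consumption and never
read back into a computation.

A :class:`CpGCountMatrix` holds the assembled per-CpG x per-library counts.
Missing library x site cells (a site absent from one library's file) are "no
coverage" (total 0), which is distinct from an observed 0% methylation.
"""

from __future__ import annotations

import gzip
import logging
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger("epiclock")

SAMPLE_SHEET_COLUMNS = ["library_id", "treatment", "age_days", "replicate", "pool_size"]


def _site_id(contig: str, pos: int) -> str:
    return f"{contig}:{pos}"


class CpGCountMatrix:
    """Per-CpG, per-library methylated and total read counts.

    Parameters
    ----------
    sites
        DataFrame indexed by site id with columns ``contig`` and ``pos``
        (1-based).  Site order is the canonical (contig, pos) order.
    meth, total
        Integer DataFrames (site x library) of methylated and total read
        counts, aligned to ``sites`` and to each other.
    """

    def __init__(self, sites: pd.DataFrame, meth: pd.DataFrame, total: pd.DataFrame,
                 validate: bool = True):
        self.sites = sites
        self.meth = meth
        self.total = total
        if validate:
            self._validate()

    def _validate(self) -> None:
        if not (self.sites.index.equals(self.meth.index) and self.meth.index.equals(self.total.index)):
            raise ValueError("sites, meth and total must share an identical site index")
        if not self.meth.columns.equals(self.total.columns):
            raise ValueError("meth and total must share identical library columns")
        if self.sites.index.has_duplicates:
            dup = self.sites.index[self.sites.index.duplicated()][:3].tolist()
            raise ValueError(f"duplicate site ids: {dup}")
        if self.meth.columns.has_duplicates:
            raise ValueError("duplicate library ids")
        m = self.meth.to_numpy()
        t = self.total.to_numpy()
        if (t < 0).any() or (m < 0).any() or (m > t).any():
            raise ValueError("counts must satisfy 0 <= methylated <= total")

    # -- basic accessors ---------------------------------------------------
    @property
    def site_ids(self) -> pd.Index:
        return self.sites.index

    @property
    def libraries(self) -> list[str]:
        return list(self.meth.columns)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_libraries(self) -> int:
        return self.meth.shape[1]

    @classmethod
    def from_arrays(cls, contigs: Iterable[str], positions: Iterable[int],
                    meth: np.ndarray, total: np.ndarray,
                    libraries: Iterable[str]) -> "CpGCountMatrix":
        contigs = list(contigs)
        positions = [int(p) for p in positions]
        idx = pd.Index([_site_id(c, p) for c, p in zip(contigs, positions)], name="site_id")
        sites = pd.DataFrame({"contig": contigs, "pos": positions}, index=idx)
        libs = list(libraries)
        return cls(sites,
                   pd.DataFrame(np.asarray(meth, dtype=np.int64), index=idx, columns=libs),
                   pd.DataFrame(np.asarray(total, dtype=np.int64), index=idx, columns=libs))

    def proportions(self, min_total: int = 1) -> pd.DataFrame:
        """Methylation proportions (meth/total); NaN where total < min_total."""
        t = self.total.to_numpy().astype(float)
        m = self.meth.to_numpy().astype(float)
        with np.errstate(divide="ignore", invalid="ignore"):
            p = np.where(t >= max(min_total, 1), m / np.where(t > 0, t, 1.0), np.nan)
        return pd.DataFrame(p, index=self.site_ids, columns=self.meth.columns)

    def subset_sites(self, site_ids: Iterable[str]) -> "CpGCountMatrix":
        ids = pd.Index(site_ids)
        missing = ids.difference(self.sites.index)
        if len(missing):
            raise KeyError(f"unknown site ids: {missing[:5].tolist()}")
        return CpGCountMatrix(self.sites.loc[ids], self.meth.loc[ids],
                              self.total.loc[ids], validate=False)

    def sort_sites(self) -> "CpGCountMatrix":
        order = self.sites.sort_values(["contig", "pos"]).index
        return CpGCountMatrix(self.sites.loc[order], self.meth.loc[order],
                              self.total.loc[order], validate=False)


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    sheet = pd.read_csv(path)
    return validate_sample_sheet(sheet)


def validate_sample_sheet(sheet: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in SAMPLE_SHEET_COLUMNS if c not in sheet.columns]
    if missing:
        raise ValueError(f"sample sheet missing columns: {missing}")
    if sheet["library_id"].duplicated().any():
        raise ValueError("sample sheet: duplicate library ids")
    if (sheet["age_days"] <= 0).any():
        raise ValueError("sample sheet: ages must be positive")
    n_treat = sheet["treatment"].nunique()
    if n_treat != 2:
        raise ValueError(f"sample sheet must contain exactly two treatment labels, found {n_treat}")
    return sheet


def write_sample_sheet(sheet: pd.DataFrame, path: str | Path) -> None:
    sheet.to_csv(path, index=False)


def _open_text(path: Path):
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_coverage_files(paths: Mapping[str, str | Path],
                        sample_sheet: pd.DataFrame) -> CpGCountMatrix:
    """Assemble a count matrix from per-library Bismark-style coverage files.

    ``paths`` maps library id -> file path.  Sites are the union across
    libraries; a site absent from a library gets total 0 there.  Site order is
    (contig, pos).  The methylation-percentage column is ignored.
    """
    validate_sample_sheet(sample_sheet)
    known = set(sample_sheet["library_id"])
    unknown = [lib for lib in paths if lib not in known]
    if unknown:
        raise ValueError(f"libraries in coverage files but not in sample sheet: {unknown}")

    per_lib: dict[str, dict[tuple[str, int], tuple[int, int]]] = {}
    for lib, p in paths.items():
        p = Path(p)
        rows: dict[tuple[str, int], tuple[int, int]] = {}
        with _open_text(p) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line:
                    continue
                parts = line.split("\t")
                if len(parts) != 6:
                    raise ValueError(f"{p}:{lineno}: expected 6 tab-separated fields, got {len(parts)}")
                try:
                    contig = parts[0]
                    pos = int(parts[1])
                    n_meth = int(parts[4])
                    n_unmeth = int(parts[5])
                except ValueError as exc:
                    raise ValueError(f"{p}:{lineno}: malformed line: {exc}") from None
                key = (contig, pos)
                if key in rows:
                    raise ValueError(f"{p}:{lineno}: duplicate site {contig}:{pos}")
                rows[key] = (n_meth, n_meth + n_unmeth)
        per_lib[lib] = rows

    all_keys = sorted({k for rows in per_lib.values() for k in rows})
    libs = list(paths)
    meth = np.zeros((len(all_keys), len(libs)), dtype=np.int64)
    total = np.zeros_like(meth)
    key_ix = {k: i for i, k in enumerate(all_keys)}
    for j, lib in enumerate(libs):
        for key, (m, t) in per_lib[lib].items():
            i = key_ix[key]
            meth[i, j] = m
            total[i, j] = t
    return CpGCountMatrix.from_arrays([k[0] for k in all_keys], [k[1] for k in all_keys],
                                      meth, total, libs)


def write_coverage_files(matrix: CpGCountMatrix, out_dir: str | Path,
                         suffix: str = ".cov") -> dict[str, Path]:
    """Write one Bismark-style coverage file per library; returns library->path.

    Rows with total 0 (no coverage in that library) are omitted, matching what
    a methylation extractor would emit.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    contigs = matrix.sites["contig"].to_numpy()
    pos = matrix.sites["pos"].to_numpy()
    for lib in matrix.libraries:
        m = matrix.meth[lib].to_numpy()
        t = matrix.total[lib].to_numpy()
        path = out_dir / f"{lib}{suffix}"
        with open(path, "wt") as fh:
            for i in range(matrix.n_sites):
                if t[i] == 0:
                    continue
                pct = 100.0 * m[i] / t[i]
                fh.write(f"{contigs[i]}\t{pos[i]}\t{pos[i]}\t{pct:.6g}\t{m[i]}\t{t[i] - m[i]}\n")
        paths[lib] = path
    return paths


def split_spikein(matrix: CpGCountMatrix, spikein_contig: str) -> tuple[CpGCountMatrix, CpGCountMatrix]:
    """Partition a matrix into (genome, spike-in) by contig name."""
    is_spike = matrix.sites["contig"] == spikein_contig
    genome_ids = matrix.sites.index[~is_spike]
    spike_ids = matrix.sites.index[is_spike]
    return matrix.subset_sites(genome_ids), matrix.subset_sites(spike_ids)


def write_clock_panel(model, sites: pd.DataFrame, path: str | Path) -> int:
    """Write the nonzero-coefficient CpG panel as BED (0-based half-open).

    Columns: contig, start, end, site id, coefficient.  Returns the row count.
    """
    panel = model.panel()
    unknown = [s for s in panel if s not in sites.index]
    if unknown:
        raise KeyError(f"panel sites not present in site table: {unknown[:5]}")
    path = Path(path)
    n = 0
    with open(path, "wt") as fh:
        for site in panel:
            contig = sites.at[site, "contig"]
            pos = int(sites.at[site, "pos"])
            coef = model.coefficients[site]
            fh.write(f"{contig}\t{pos - 1}\t{pos}\t{site}\t{coef:.10g}\n")
            n += 1
    logger.info("wrote clock panel with %d sites to %s", n, path)
    return n


def write_proportions_csv(matrix: CpGCountMatrix, path: str | Path,
                          min_total: int = 1) -> None:
    """Tidy CSV of methylation proportions (site rows, library columns)."""
    props = matrix.proportions(min_total=min_total)
    out = pd.concat([matrix.sites, props], axis=1)
    out.to_csv(path, index_label="site_id")
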