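"""Classify CpG sites as methylated versus bisulfite non-conversion background.

The unmethylated lambda spike-in estimates the per-read error rate e (an
unmethylated cytosine read as methylated).  Each genomic site is then tested
against the null "all methylated reads are non-conversion noise" with a
one-sided binomial test at rate e, and sites are retained after
Benjamini-Hochberg correction across sites.  The retained set is the analysis
universe for everything downstream.

Two pooling modes are available.  The default ("pooled") sums counts over the
libraries that meet the coverage floor before testing, which is the more
powerful choice for pooled libraries; "per_library" instead tests each library
separately and requires significance in at least ``min_samples`` of them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import binom
from statsmodels.stats.multitest import multipletests

from .io import CpGCountMatrix

logger = logging.getLogger("epiclock")


@dataclass
class ConversionEstimate:
    """Bisulfite non-conversion error rate estimated from the spike-in."""

    error_rate: float
    total_reads: int
    methylated_reads: int
    per_library: pd.Series  # per-library rate, NaN where a library has no spike-in reads


@dataclass
class MethylatedSiteSet:
    """Retained methylated sites plus the per-site test summary table."""

    site_ids: list[str]
    summary: pd.DataFrame  # site_id-indexed: n_qualifying, meth, total, p, q, methylated

    def __len__(self) -> int:
        return len(self.site_ids)


def estimate_conversion_error(spikein_matrix: CpGCountMatrix) -> ConversionEstimate:
    """Pooled non-conversion rate: methylated / total reads over all lambda sites."""
    lib_total = spikein_matrix.total.sum(axis=0)
    lib_meth = spikein_matrix.meth.sum(axis=0)
    total = int(lib_total.sum())
    if spikein_matrix.n_sites == 0 or total == 0:
        raise ValueError("no spike-in coverage: cannot estimate conversion error")
    meth = int(lib_meth.sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        per_lib = pd.Series(
            np.where(lib_total > 0, lib_meth / lib_total.replace(0, 1), np.nan),
            index=lib_total.index)
    return ConversionEstimate(error_rate=meth / total, total_reads=total,
                              methylated_reads=meth, per_library=per_lib)


def _binom_sf_pvalue(meth: np.ndarray, total: np.ndarray, error_rate: float) -> np.ndarray:
    """One-sided P(X >= meth | total, error_rate)."""
    return binom.sf(meth - 1, total, error_rate)


def call_methylated_sites(genome_matrix: CpGCountMatrix, est: ConversionEstimate,
                          min_coverage: int = 10, fdr_q: float = 0.05,
                          min_samples: int | None = None,
                          mode: str = "pooled") -> MethylatedSiteSet:
    """Retain sites whose methylated counts exceed the non-conversion background.

    Sites with no library at ``min_coverage`` are dropped before testing and
    do not enter the BH family.
    """
    if min_coverage < 1:
        raise ValueError("min_coverage must be >= 1")
    if not (0.0 < fdr_q < 1.0):
        raise ValueError("fdr_q must be in (0, 1)")
    if mode not in ("pooled", "per_library"):
        raise ValueError(f"unknown mode {mode!r}")
    n_lib = genome_matrix.n_libraries
    if min_samples is None:
        min_samples = max(1, n_lib // 2)

    if genome_matrix.n_sites == 0:
        logger.warning("call_methylated_sites: empty matrix, returning empty set")
        empty = pd.DataFrame(columns=["n_qualifying", "meth", "total", "p", "q", "methylated"])
        return MethylatedSiteSet(site_ids=[], summary=empty)

    total = genome_matrix.total.to_numpy()
    meth = genome_matrix.meth.to_numpy()
    qualifies = total >= min_coverage
    n_qual = qualifies.sum(axis=1)
    testable = n_qual > 0
    n_dropped = int((~testable).sum())
    if n_dropped:
        logger.info("call_methylated_sites: %d sites below coverage in every library, dropped", n_dropped)

    e = est.error_rate
    m_pool = np.where(qualifies, meth, 0).sum(axis=1)
    t_pool = np.where(qualifies, total, 0).sum(axis=1)

    p = np.full(genome_matrix.n_sites, np.nan)
    q = np.full(genome_matrix.n_sites, np.nan)
    if mode == "pooled":
        p[testable] = _binom_sf_pvalue(m_pool[testable], t_pool[testable], e)
        if testable.any():
            q[testable] = multipletests(p[testable], method="fdr_bh")[1]
        methylated = testable & (q <= fdr_q) & (n_qual >= min_samples)
    else:
        # per-library tests; BH over the full site x library family, then a
        # site is methylated when significant in >= min_samples libraries
        cell_p = np.full(total.shape, np.nan)
        sel = qualifies
        cell_p[sel] = _binom_sf_pvalue(meth[sel], total[sel], e)
        flat = cell_p[sel]
        cell_q = np.full(total.shape, np.nan)
        if flat.size:
            cell_q[sel] = multipletests(flat, method="fdr_bh")[1]
        n_sig = np.where(sel, cell_q <= fdr_q, False).sum(axis=1)
        methylated = testable & (n_sig >= min_samples)
        # site-level p/q reported for QC: the minimum per-library values
        with np.errstate(all="ignore"):
            p[testable] = np.nanmin(np.where(sel, cell_p, np.nan), axis=1)[testable]
            q[testable] = np.nanmin(np.where(sel, cell_q, np.nan), axis=1)[testable]

    summary = pd.DataFrame({
        "n_qualifying": n_qual,
        "meth": m_pool,
        "total": t_pool,
        "p": p,
        "q": q,
        "methylated": methylated,
    }, index=genome_matrix.site_ids)
    site_ids = list(genome_matrix.site_ids[methylated])
    logger.info("call_methylated_sites: %d / %d sites classified methylated",
                len(site_ids), genome_matrix.n_sites)
    return MethylatedSiteSet(site_ids=site_ids, summary=summary)
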