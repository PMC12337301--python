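"""Synthetic pooled-WGBS and survival data with planted ground truth.

The generator emulates a two-treatment ("control" vs "diapause") longitudinal
bisulfite-sequencing design: adults sampled at days 6, 12, 18, 24 and 30 post
emergence, four replicate libraries per treatment x timepoint, each library a
pool of 10 individuals with a 1% unmethylated lambda spike-in.

A minority of "clock" CpGs drift with age on the logit scale; the diapause
group drifts at a reduced rate (rate ratio r < 1) and carries an epigenetic-age
intercept offset at emergence.  For a clock CpG i in group g sampled at
chronological age a, the latent methylation proportion is

    p = expit(b_i + s_i * r_g * (a + o_g))

with r_1 = 1, o_1 = 0 for the reference group.  The library's latent
("true epigenetic") age is a* = r_g * (a + o_g), so the reference group's
latent age equals chronological age by construction.  Counts are beta-binomial
around p (after a one-way bisulfite non-conversion error) with negative
binomial coverage per CpG x library.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .io import CpGCountMatrix, validate_sample_sheet

GENOME_CONTIG = "synth_chr1"
SPIKEIN_CONTIG = "lambda_spikein"


@dataclass
class StudyDesign:
    """Sampling design: treatments x timepoints x replicate pooled libraries."""

    treatments: tuple[str, str] = ("control", "diapause")
    timepoints: tuple[float, ...] = (6.0, 12.0, 18.0, 24.0, 30.0)
    replicates_per_cell: int = 4
    pool_size: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.treatments) != 2:
            raise ValueError("exactly two treatment labels required")
        tp = tuple(float(t) for t in self.timepoints)
        if any(t <= 0 for t in tp) or any(b <= a for a, b in zip(tp, tp[1:])):
            raise ValueError("timepoints must be strictly positive and strictly increasing")
        self.timepoints = tp
        if self.replicates_per_cell < 1 or self.pool_size < 1:
            raise ValueError("replicates_per_cell and pool_size must be >= 1")

    @property
    def n_libraries(self) -> int:
        return len(self.treatments) * len(self.timepoints) * self.replicates_per_cell

    def sample_sheet(self) -> pd.DataFrame:
        rows = []
        for treat in self.treatments:
            for day in self.timepoints:
                for rep in range(1, self.replicates_per_cell + 1):
                    lib = f"{treat}_d{int(day):02d}_r{rep}"
                    rows.append((lib, treat, day, rep, self.pool_size))
        sheet = pd.DataFrame(rows, columns=["library_id", "treatment", "age_days",
                                            "replicate", "pool_size"])
        return validate_sample_sheet(sheet)


@dataclass
class ClockArchitecture:
    """Effect structure and noise model of the simulated methylome.

    Slope magnitudes are drawn uniformly from ``slope_logit_range`` with a
    random sign; baselines uniformly from ``baseline_logit_range``.  Defaults
    follow the study's effect sizes (rate ratio ~0.708, emergence offset
    2.8 d) with coverage/noise levels typical of pooled WGBS libraries.
    """

    n_clock_cpgs: int = 50
    n_null_cpgs: int = 950
    baseline_logit_range: tuple[float, float] = (-1.5, 1.5)
    slope_logit_range: tuple[float, float] = (0.05, 0.12)
    treatment_rate_ratio: float = 0.708
    treatment_intercept_offset_days: float = 2.8
    overdispersion_rho: float = 0.02
    conversion_error: float = 0.005
    mean_coverage: float = 30.0
    coverage_dispersion: float = 10.0

    def __post_init__(self) -> None:
        vals = [self.treatment_rate_ratio, self.treatment_intercept_offset_days,
                self.overdispersion_rho, self.conversion_error, self.mean_coverage,
                self.coverage_dispersion, *self.baseline_logit_range, *self.slope_logit_range]
        if not all(math.isfinite(v) for v in vals):
            raise ValueError("architecture parameters must be finite")
        if self.n_clock_cpgs < 1:
            raise ValueError("n_clock_cpgs must be >= 1")
        if self.n_null_cpgs < 0:
            raise ValueError("n_null_cpgs must be >= 0")
        if self.treatment_rate_ratio <= 0:
            raise ValueError("treatment_rate_ratio must be > 0")
        if not (0.0 <= self.conversion_error <= 0.05):
            raise ValueError("conversion_error must be in [0, 0.05]")
        if not (0.0 <= self.overdispersion_rho < 1.0):
            raise ValueError("overdispersion_rho must be in [0, 1)")
        if self.mean_coverage <= 0 or self.coverage_dispersion <= 0:
            raise ValueError("coverage parameters must be positive")


@dataclass
class GroundTruth:
    """Planted truth: which CpGs carry age signal and each library's latent age."""

    clock_cpg_ids: list[str]
    intercepts: pd.Series          # per-site baseline, logit scale
    slopes: pd.Series              # per-site drift, logit units per latent day
    latent_age: pd.Series          # per-library true epigenetic age, days


@dataclass
class SurvivalScenario:
    """Per-group parametric hazards for the simulated lifespan assay.

    ``hazards`` are rate parameters of S(t) = exp(-rate * t^shape); shape 1 is
    exponential, and a shared shape preserves proportional hazards with
    HR = rate_2/rate_1.  Defaults mimic the study's cohorts: control median
    22 d (rate ln2/22), diapause hazard ratio 0.35, n = 101 vs 71.  With
    ``round_to_day`` death times are rounded up to whole days, matching daily
    survival monitoring (and producing realistic ties).
    """

    hazards: dict[str, float] = field(
        default_factory=lambda: {"control": math.log(2) / 22.0,
                                 "diapause": 0.35 * math.log(2) / 22.0})
    n_per_group: dict[str, int] = field(
        default_factory=lambda: {"control": 101, "diapause": 71})
    shape: float = 1.0
    censoring_time: float | None = None
    round_to_day: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if set(self.hazards) != set(self.n_per_group):
            raise ValueError("hazards and n_per_group must name the same groups")
        if any(h <= 0 or not math.isfinite(h) for h in self.hazards.values()):
            raise ValueError("hazards must be strictly positive")
        if any(n < 1 for n in self.n_per_group.values()):
            raise ValueError("n_per_group must be >= 1")
        if self.shape <= 0:
            raise ValueError("shape must be > 0")
        if self.censoring_time is not None and self.censoring_time <= 0:
            raise ValueError("censoring_time must be positive (0 would censor every record at t=0)")


# ---------------------------------------------------------------------------
# samplers

def _beta_binomial(rng: np.random.Generator, n: np.ndarray, p: np.ndarray,
                   rho: float) -> np.ndarray:
    """Beta-binomial draws with intra-class correlation rho (rho=0: binomial)."""
    if rho == 0.0:
        return rng.binomial(n, p)
    s = (1.0 - rho) / rho
    a = np.clip(p, 0.0, 1.0) * s
    b = (1.0 - np.clip(p, 0.0, 1.0)) * s
    # degenerate p=0 or p=1 has no beta distribution; those draws are exact
    interior = (a > 0) & (b > 0)
    pp = np.where(interior, p, 0.5)  # placeholder for the beta call
    with np.errstate(invalid="ignore"):
        q = rng.beta(np.where(interior, a, 1.0), np.where(interior, b, 1.0))
    q = np.where(interior, q, np.clip(p, 0.0, 1.0))
    return rng.binomial(n, q)


def _nb_coverage(rng: np.random.Generator, mean: float, dispersion: float,
                 size) -> np.ndarray:
    """Negative-binomial coverage, mean `mean`, var mean + mean^2/dispersion; floored at 1."""
    p = dispersion / (dispersion + mean)
    cov = rng.negative_binomial(dispersion, p, size=size)
    return np.maximum(cov, 1)


# ---------------------------------------------------------------------------
# generators

def generate_methylation_dataset(design: StudyDesign, arch: ClockArchitecture
                                 ) -> tuple[CpGCountMatrix, pd.DataFrame, GroundTruth]:
    """Simulate the genome count matrix, sample sheet and planted truth."""
    rng = np.random.default_rng([design.seed, 0])
    sheet = design.sample_sheet()
    n_sites = arch.n_clock_cpgs + arch.n_null_cpgs
    positions = 1 + 100 * np.arange(n_sites)
    contigs = [GENOME_CONTIG] * n_sites

    lo, hi = arch.baseline_logit_range
    b = rng.uniform(lo, hi, size=n_sites)
    smin, smax = arch.slope_logit_range
    mag = rng.uniform(smin, smax, size=n_sites)
    sign = rng.choice([-1.0, 1.0], size=n_sites)
    s = mag * sign
    clock_ix = np.arange(arch.n_clock_cpgs)  # leading block; ids are opaque downstream
    is_clock = np.zeros(n_sites, dtype=bool)
    is_clock[clock_ix] = True
    s[~is_clock] = 0.0
    # clock CpGs drift through intermediate methylation across the sampled
    # window (age-informative sites are unsaturated by selection); the drawn
    # baseline is therefore the logit at the window's midpoint age
    mid_age = 0.5 * (design.timepoints[0] + design.timepoints[-1])
    b = b - s * mid_age

    treat2 = design.treatments[1]
    r = np.where(sheet["treatment"].to_numpy() == treat2, arch.treatment_rate_ratio, 1.0)
    o = np.where(sheet["treatment"].to_numpy() == treat2,
                 arch.treatment_intercept_offset_days, 0.0)
    latent = r * (sheet["age_days"].to_numpy() + o)  # per-library true epigenetic age

    p = expit(b[:, None] + s[:, None] * latent[None, :])
    p_obs = p + (1.0 - p) * arch.conversion_error

    shape = (n_sites, design.n_libraries)
    coverage = _nb_coverage(rng, arch.mean_coverage, arch.coverage_dispersion, shape)
    meth = _beta_binomial(rng, coverage, p_obs, arch.overdispersion_rho)

    matrix = CpGCountMatrix.from_arrays(contigs, positions, meth, coverage,
                                        sheet["library_id"])
    site_ids = matrix.site_ids
    truth = GroundTruth(
        clock_cpg_ids=list(site_ids[is_clock]),
        intercepts=pd.Series(b, index=site_ids),
        slopes=pd.Series(s, index=site_ids),
        latent_age=pd.Series(latent, index=sheet["library_id"].to_numpy()),
    )
    return matrix, sheet, truth


def generate_spikein_counts(design: StudyDesign, arch: ClockArchitecture,
                            n_lambda_cpgs: int = 300) -> CpGCountMatrix:
    """Fully unmethylated spike-in sites; methylated reads arise only from
    bisulfite non-conversion."""
    if n_lambda_cpgs < 1:
        raise ValueError("n_lambda_cpgs must be >= 1")
    rng = np.random.default_rng([design.seed, 1])
    sheet = design.sample_sheet()
    shape = (n_lambda_cpgs, design.n_libraries)
    coverage = _nb_coverage(rng, arch.mean_coverage, arch.coverage_dispersion, shape)
    meth = rng.binomial(coverage, arch.conversion_error)
    positions = 1 + 100 * np.arange(n_lambda_cpgs)
    return CpGCountMatrix.from_arrays([SPIKEIN_CONTIG] * n_lambda_cpgs, positions,
                                      meth, coverage, sheet["library_id"])


def generate_survival_cohort(scenario: SurvivalScenario) -> pd.DataFrame:
    """Per-individual time-to-event records (id, time_days, event, group)."""
    rng = np.random.default_rng([scenario.seed, 2])
    rows = []
    for group in scenario.hazards:
        rate = scenario.hazards[group]
        n = scenario.n_per_group[group]
        e = rng.exponential(1.0, size=n)
        t = (e / rate) ** (1.0 / scenario.shape)
        if scenario.round_to_day:
            t = np.ceil(t)
            t = np.maximum(t, 1.0)
        event = np.ones(n, dtype=int)
        if scenario.censoring_time is not None:
            censored = t > scenario.censoring_time
            t = np.where(censored, scenario.censoring_time, t)
            event = np.where(censored, 0, 1)
        for i in range(n):
            rows.append((f"{group}_{i + 1}", float(t[i]), int(event[i]), group))
    return pd.DataFrame(rows, columns=["id", "time_days", "event", "group"])
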