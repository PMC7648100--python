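"""Synthetic two-sample GWAS summary statistics with known ground truth.

The generator draws a set of independent SNPs instrumenting a standardized
exposure and produces the pair of summary tables a two-sample MR study
consumes: SNP-to-exposure effects from a continuous-trait GWAS of size
``n_exposure`` and SNP-to-outcome log-odds from a case-control GWAS, with
standard errors from the usual summary-statistic asymptotics,

    sx_j = 1 / sqrt(2 maf_j (1-maf_j) n_exposure)
    sy_j = 1 / sqrt(2 maf_j (1-maf_j) n_cases n_controls / N).

True instrument effects ``gamma_j`` are normal draws rescaled so the
explained exposure variance ``sum_j 2 maf_j (1-maf_j) gamma_j^2`` equals the
target R^2 exactly. The outcome model is linear on the log-odds scale with
optional horizontal pleiotropy ``alpha_j``:

    E[y_j] = theta * gamma_j + alpha_j,

where ``alpha_j`` is zero (none), centred normal (balanced), normal with a
nonzero mean (directional), or a fixed displacement of a few chosen SNPs in
outcome-SE units (outlier). Alleles are assigned with a configurable
fraction of strand-ambiguous (A/T, C/G) variants, and outcome rows are
randomly allele-swapped and strand-complemented to exercise harmonization.

What this emulates — and what it does not: effects are independent across
SNPs (no LD), the two samples do not overlap, and outcome SEs use the
effective-sample-size approximation rather than a per-SNP logistic fit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError
from .summary_io import SUMMARY_COLUMNS

#: IBD consortium outcome designs (cases, controls) used throughout.
IBD_DESIGN = (25042, 34915)
CD_DESIGN = (12194, 34915)
UC_DESIGN = (12366, 34915)

_PALINDROMIC_PAIRS = (("A", "T"), ("T", "A"), ("C", "G"), ("G", "C"))
_NONPALINDROMIC_PAIRS = (
    ("A", "C"), ("A", "G"), ("C", "A"), ("C", "T"),
    ("G", "A"), ("G", "T"), ("T", "C"), ("T", "G"),
)
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one simulated exposure-outcome pair.

    ``theta`` is the true causal log OR per SD of exposure; ``r2_target``
    the total exposure variance explained by the instrument;
    ``pleiotropy_mode`` one of ``none | balanced | directional | outlier``
    with ``pleio_sd`` / ``pleio_mean`` the pleiotropic-effect scale and mean
    and ``outlier_shift`` the displacement (in outcome-SE units) applied to
    ``n_outliers`` SNPs.
    """

    n_snp: int = 50
    theta: float = 0.0
    r2_target: float = 0.05
    n_exposure: int = 300_000
    n_cases: int = IBD_DESIGN[0]
    n_controls: int = IBD_DESIGN[1]
    maf_range: tuple[float, float] = (0.05, 0.5)
    pleiotropy_mode: str = "none"
    pleio_sd: float = 0.0
    pleio_mean: float = 0.0
    n_outliers: int = 0
    outlier_shift: float = 0.0
    palindromic_frac: float = 0.0
    seed: int = 0
    name: str = "sim"

    def __post_init__(self) -> None:
        if self.n_snp < 1:
            raise ConfigurationError("n_snp must be >= 1")
        if not 0.0 < self.r2_target < 1.0:
            raise ConfigurationError("r2_target must lie in (0, 1)")
        lo, hi = self.maf_range
        if not 0.0 < lo <= hi <= 0.5:
            raise ConfigurationError("maf_range must lie within (0, 0.5]")
        if self.pleiotropy_mode not in ("none", "balanced", "directional", "outlier"):
            raise ConfigurationError(f"unknown pleiotropy_mode {self.pleiotropy_mode!r}")
        if self.n_outliers > self.n_snp:
            raise ConfigurationError("n_outliers cannot exceed n_snp")
        if not 0.0 <= self.palindromic_frac <= 1.0:
            raise ConfigurationError("palindromic_frac must lie in [0, 1]")


@dataclass(frozen=True)
class SimTruth:
    """Ground truth of a simulated pair: causal effect and per-SNP record.

    ``table`` columns: rsid, gamma (true exposure effect), alpha (pleiotropic
    outcome effect), is_outlier, outcome_swapped, outcome_complemented.
    """

    theta: float
    table: pd.DataFrame = field(repr=False)


def _two_sided_p(beta: np.ndarray, se: np.ndarray) -> np.ndarray:
    from scipy import stats

    z = np.abs(beta / se)
    return np.clip(2.0 * stats.norm.sf(z), np.nextafter(0.0, 1.0), 1.0)


def simulate_pair(cfg: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame, SimTruth]:
    """Generate one (exposure table, outcome table, truth) triple.

    Both tables use the canonical tab-separated layout (columns
    ``rsid effect_allele other_allele eaf beta se pvalue``) and are
    bit-reproducible for a fixed ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    J = cfg.n_snp

    maf = rng.uniform(cfg.maf_range[0], cfg.maf_range[1], size=J)
    het = 2.0 * maf * (1.0 - maf)

    # Effect alleles are coded as the exposure-increasing allele (the
    # convention of curated instrument tables), so true effects are
    # half-normal draws; directional pleiotropy is directional relative to
    # this coding, as the MR-Egger model assumes.
    gamma = np.abs(rng.normal(size=J))
    scale = np.sqrt(cfg.r2_target / np.sum(het * gamma**2))
    gamma = gamma * scale  # now sum(het * gamma^2) == r2_target exactly

    sx = 1.0 / np.sqrt(het * cfg.n_exposure)
    n_eff = cfg.n_cases * cfg.n_controls / (cfg.n_cases + cfg.n_controls)
    sy = 1.0 / np.sqrt(het * n_eff)

    alpha = np.zeros(J)
    is_outlier = np.zeros(J, dtype=bool)
    if cfg.pleiotropy_mode == "balanced":
        alpha = rng.normal(0.0, cfg.pleio_sd, size=J)
    elif cfg.pleiotropy_mode == "directional":
        alpha = rng.normal(cfg.pleio_mean, cfg.pleio_sd, size=J)
    elif cfg.pleiotropy_mode == "outlier" and cfg.n_outliers > 0:
        idx = rng.choice(J, size=cfg.n_outliers, replace=False)
        is_outlier[idx] = True
        alpha[idx] = cfg.outlier_shift * sy[idx]

    x_hat = rng.normal(gamma, sx)
    y_hat = rng.normal(cfg.theta * gamma + alpha, sy)

    # Allele assignment: a requested fraction of strand-ambiguous variants,
    # plus random swap/complement scrambling of the outcome coding.
    n_pal = int(round(cfg.palindromic_frac * J))
    pal_mask = np.zeros(J, dtype=bool)
    if n_pal:
        pal_mask[rng.choice(J, size=n_pal, replace=False)] = True
    ea = np.empty(J, dtype=object)
    oa = np.empty(J, dtype=object)
    for j in range(J):
        pool = _PALINDROMIC_PAIRS if pal_mask[j] else _NONPALINDROMIC_PAIRS
        ea[j], oa[j] = pool[rng.integers(len(pool))]

    rsids = [f"rs{j + 1:06d}" for j in range(J)]
    exposure = pd.DataFrame(
        {
            "rsid": rsids,
            "effect_allele": ea,
            "other_allele": oa,
            "eaf": maf,
            "beta": x_hat,
            "se": sx,
            "pvalue": _two_sided_p(x_hat, sx),
        }
    )[list(SUMMARY_COLUMNS)]

    swapped = rng.random(J) < 0.5
    complemented = (~pal_mask) & (rng.random(J) < 0.5)
    ea_out = ea.copy()
    oa_out = oa.copy()
    y_out = y_hat.copy()
    eaf_out = maf.copy()
    for j in np.flatnonzero(swapped):
        ea_out[j], oa_out[j] = oa_out[j], ea_out[j]
        y_out[j] = -y_out[j]
        eaf_out[j] = 1.0 - eaf_out[j]
    for j in np.flatnonzero(complemented):
        ea_out[j] = _COMPLEMENT[ea_out[j]]
        oa_out[j] = _COMPLEMENT[oa_out[j]]

    outcome = pd.DataFrame(
        {
            "rsid": rsids,
            "effect_allele": ea_out,
            "other_allele": oa_out,
            "eaf": eaf_out,
            "beta": y_out,
            "se": sy,
            "pvalue": _two_sided_p(y_hat, sy),
        }
    )[list(SUMMARY_COLUMNS)]

    truth = SimTruth(
        theta=cfg.theta,
        table=pd.DataFrame(
            {
                "rsid": rsids,
                "gamma": gamma,
                "alpha": alpha,
                "is_outlier": is_outlier,
                "outcome_swapped": swapped,
                "outcome_complemented": complemented,
            }
        ),
    )
    return exposure, outcome, truth


def write_pair(
    exposure: pd.DataFrame, outcome: pd.DataFrame, truth: SimTruth, out_dir, prefix: str = "sim"
) -> dict[str, Path]:
    """Write a simulated pair to tab-separated files; returns the paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "exposure": out_dir / f"{prefix}_exposure.tsv",
        "outcome": out_dir / f"{prefix}_outcome.tsv",
        "truth": out_dir / f"{prefix}_truth.tsv",
    }
    exposure.to_csv(paths["exposure"], sep="\t", index=False, na_rep="NA")
    outcome.to_csv(paths["outcome"], sep="\t", index=False, na_rep="NA")
    truth.table.to_csv(paths["truth"], sep="\t", index=False)
    return paths


# (name, n_snp, explained variance, approximate discovery-GWAS size).
# Instrument sizes and variances follow the study designs this package is
# built around: lifestyle and nutrient instruments tested against the IBD
# consortium outcome GWAS of 25,042 cases / 34,915 controls.
_TABLE1_ROWS = (
    ("smoking_status", 331, 0.023, 1_200_000),
    ("cigarettes_per_day", 44, 0.011, 337_000),
    ("body_mass_index", 816, 0.060, 700_000),
    ("waist_to_hip_ratio", 403, 0.030, 700_000),
    ("body_fat_percentage", 378, 0.035, 360_000),
    ("physical_activity", 2, 0.0008, 91_000),
    ("vitamin_d", 5, 0.034, 80_000),
    ("vitamin_b9", 2, 0.010, 46_000),
    ("vitamin_b12", 10, 0.063, 46_000),
    ("omega3_fatty_acids", 4, 0.024, 9_000),
    ("omega6_fatty_acids", 8, 0.046, 9_000),
    ("monounsaturated_fatty_acids", 4, 0.024, 9_000),
    ("total_fatty_acids", 8, 0.037, 9_000),
)


def simulate_table1_designs(seed: int = 0) -> list[SimConfig]:
    """Thirteen configs mirroring the study's instrument designs.

    One config per exposure, with the published instrument size (number of
    SNPs) and explained variance, against the IBD case-control design.
    Useful for end-to-end dry runs shaped like the real study.
    """
    seeds = np.random.SeedSequence(seed).generate_state(len(_TABLE1_ROWS))
    return [
        SimConfig(
            n_snp=n_snp,
            theta=0.0,
            r2_target=r2,
            n_exposure=n_exp,
            n_cases=IBD_DESIGN[0],
            n_controls=IBD_DESIGN[1],
            seed=int(s % (2**31)),
            name=name,
        )
        for (name, n_snp, r2, n_exp), s in zip(_TABLE1_ROWS, seeds)
    ]
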