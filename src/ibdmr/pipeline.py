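"""Full-study orchestration: every exposure against every outcome.

For each exposure-outcome pair the pipeline harmonizes the summary
statistics, runs the likelihood-based estimate (the headline result) plus
the IVW, MR-Egger, weighted-median and mode sensitivity estimators,
Cochran's Q and MR-PRESSO, applies the Bonferroni rule across exposures to
the headline p-values, tests CD-vs-UC heterogeneity for declared subtype
pairs, and produces a power table. Method preconditions that an instrument
cannot meet (e.g. MR-Egger on a 2-SNP instrument) are recorded as NA rather
than errors, and any per-pair failure is logged and reported without
aborting the rest of the study.
"""

from __future__ import annotations

import hashlib
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import estimators, presso, power, subtype_het, summary_io
from .exceptions import IbdMrError, InsufficientInstrumentsError

logger = logging.getLogger(__name__)

PRIMARY_METHOD = "ml"
SENSITIVITY_METHODS = ("ivw", "egger", "weighted_median", "mode")


@dataclass(frozen=True)
class TraitFile:
    """One trait's summary-statistic file plus its metadata."""

    name: str
    path: str
    meta: summary_io.TraitMeta
    ld_path: str | None = None


@dataclass(frozen=True)
class StudyConfig:
    """Configuration of a full MR study.

    ``n_tests`` is the Bonferroni divisor — the number of exposures tested
    (not exposure x outcome pairs); defaults to ``len(exposures)``.
    ``cd_name``/``uc_name`` declare which outcomes form the subtype pair for
    the disease-heterogeneity test.
    """

    exposures: tuple[TraitFile, ...]
    outcomes: tuple[TraitFile, ...]
    cd_name: str | None = None
    uc_name: str | None = None
    alpha: float = 0.05
    n_tests: int | None = None
    genomewide_filter: bool = True
    gw_threshold: float = summary_io.GENOMEWIDE_P
    ld_threshold: float = summary_io.LD_R2_THRESHOLD
    drop_palindromic: bool = True
    n_boot: int = estimators.N_BOOT_DEFAULT
    presso_sims: int = presso.N_SIM_DEFAULT
    presso_outlier_alpha: float = presso.OUTLIER_ALPHA_DEFAULT
    target_power: float = 0.80
    seed: int = 0

    @property
    def bonferroni_threshold(self) -> float:
        n = self.n_tests if self.n_tests is not None else len(self.exposures)
        if n < 1:
            raise ValueError("n_tests must be >= 1")
        return self.alpha / n

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        """Load a study from a flat YAML document (see README for schema)."""
        raw = yaml.safe_load(Path(path).read_text())
        base = Path(path).parent

        def trait(entry: dict, binary: bool) -> TraitFile:
            meta = summary_io.TraitMeta(
                name=entry["name"],
                is_binary=binary or entry.get("is_binary", False),
                sd=entry.get("sd"),
                n=entry.get("n"),
                n_cases=entry.get("n_cases"),
                n_controls=entry.get("n_controls"),
                r2=entry.get("r2"),
            )
            ld = entry.get("ld_file")
            return TraitFile(
                name=entry["name"],
                path=str(base / entry["file"]),
                meta=meta,
                ld_path=None if ld is None else str(base / ld),
            )

        return cls(
            exposures=tuple(trait(e, binary=False) for e in raw["exposures"]),
            outcomes=tuple(trait(o, binary=True) for o in raw["outcomes"]),
            cd_name=raw.get("cd_uc", {}).get("cd"),
            uc_name=raw.get("cd_uc", {}).get("uc"),
            alpha=raw.get("alpha", 0.05),
            n_tests=raw.get("n_tests"),
            genomewide_filter=raw.get("genomewide_filter", True),
            gw_threshold=raw.get("gw_threshold", summary_io.GENOMEWIDE_P),
            ld_threshold=raw.get("ld_threshold", summary_io.LD_R2_THRESHOLD),
            drop_palindromic=raw.get("drop_palindromic", True),
            n_boot=raw.get("n_boot", estimators.N_BOOT_DEFAULT),
            presso_sims=raw.get("presso_sims", presso.N_SIM_DEFAULT),
            presso_outlier_alpha=raw.get("presso_outlier_alpha", presso.OUTLIER_ALPHA_DEFAULT),
            target_power=raw.get("target_power", 0.80),
            seed=raw.get("seed", 0),
        )


@dataclass
class StudyReport:
    """All result tables of one study run.

    ``primary`` has one row per exposure x outcome x method; ``sensitivity``
    collects the Egger intercept, Cochran Q and MR-PRESSO outputs;
    ``heterogeneity`` the CD-vs-UC tests; ``power`` the minimum detectable
    ORs; ``instruments`` the harmonized per-SNP data used for scatter plots.
    """

    primary: pd.DataFrame
    sensitivity: pd.DataFrame
    heterogeneity: pd.DataFrame
    power: pd.DataFrame
    instruments: dict[tuple[str, str], summary_io.HarmonizedInstrument] = field(repr=False, default_factory=dict)
    ml_theta: dict[tuple[str, str], float] = field(default_factory=dict)
    failures: list[str] = field(default_factory=list)

    def write(self, out_dir) -> dict[str, str]:
        """Write all tables plus a sha256 manifest; returns name -> digest."""
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        tables = {
            "primary.tsv": self.primary,
            "sensitivity.tsv": self.sensitivity,
            "heterogeneity.tsv": self.heterogeneity,
            "power.tsv": self.power,
        }
        digests: dict[str, str] = {}
        for fname, df in tables.items():
            path = out_dir / fname
            df.to_csv(path, sep="\t", index=False, na_rep="NA")
            digests[fname] = hashlib.sha256(path.read_bytes()).hexdigest()
        manifest = out_dir / "manifest.tsv"
        with open(manifest, "w") as fh:
            fh.write("file\tsha256\n")
            for fname in sorted(digests):
                fh.write(f"{fname}\t{digests[fname]}\n")
        if self.failures:
            (out_dir / "failures.log").write_text("\n".join(self.failures) + "\n")
        return digests


def _pair_seed(base_seed: int, i: int, j: int) -> int:
    return int((base_seed * 1_000_003 + i * 131 + j * 7 + 17) % (2**31))


def _load_instrument_side(spec: TraitFile, cfg: StudyConfig) -> list[summary_io.SnpAssociation]:
    assocs = summary_io.read_summary_table(spec.path, spec.meta)
    if not spec.meta.is_binary and spec.meta.sd is not None:
        assocs = [summary_io.standardize_to_sd(a, spec.meta) for a in assocs]
    return assocs


def run_study(cfg: StudyConfig) -> StudyReport:
    """Execute the full study; deterministic for a fixed config and seed."""
    primary_rows: list[dict] = []
    sens_rows: list[dict] = []
    het_rows: list[dict] = []
    power_rows: list[dict] = []
    instruments: dict[tuple[str, str], summary_io.HarmonizedInstrument] = {}
    ml_theta: dict[tuple[str, str], float] = {}
    ml_by_pair: dict[tuple[str, str], estimators.MrEstimate] = {}
    failures: list[str] = []

    outcomes_data = {o.name: _load_instrument_side(o, cfg) for o in cfg.outcomes}

    for i, exp in enumerate(cfg.exposures):
        t0 = time.perf_counter()
        assocs = _load_instrument_side(exp, cfg)
        if cfg.genomewide_filter:
            assocs = summary_io.filter_genomewide(assocs, cfg.gw_threshold)
        if exp.ld_path is not None:
            ld = summary_io.read_ld_matrix(exp.ld_path, assocs)
            assocs = summary_io.ld_prune(assocs, ld, cfg.ld_threshold)
        logger.info("%s: %d instrument SNPs after selection", exp.name, len(assocs))

        for j, out in enumerate(cfg.outcomes):
            pair = (exp.name, out.name)
            seed = _pair_seed(cfg.seed, i, j)
            try:
                inst = summary_io.harmonize(
                    assocs, outcomes_data[out.name], drop_palindromic=cfg.drop_palindromic
                )
            except IbdMrError as exc:
                failures.append(f"{exp.name} -> {out.name}: harmonization failed: {exc}")
                continue
            instruments[pair] = inst

            est_by_method = _run_estimators(inst, cfg, seed, failures, pair)
            for method in (PRIMARY_METHOD, *SENSITIVITY_METHODS):
                est = est_by_method.get(method)
                row = {
                    "exposure": exp.name,
                    "outcome": out.name,
                    "method": method,
                    "n_snp": inst.n_snp,
                    "theta": np.nan,
                    "se": np.nan,
                    "or": np.nan,
                    "ci_low": np.nan,
                    "ci_high": np.nan,
                    "pvalue": np.nan,
                    "bonferroni_significant": pd.NA,
                }
                if est is not None:
                    orv, lo, hi = est.or_scale
                    row.update(
                        theta=est.theta, se=est.se, pvalue=est.pvalue,
                        **{"or": orv}, ci_low=lo, ci_high=hi,
                    )
                    if method == PRIMARY_METHOD:
                        row["bonferroni_significant"] = bool(
                            est.pvalue < cfg.bonferroni_threshold
                        )
                        ml_by_pair[pair] = est
                        ml_theta[pair] = est.theta
                primary_rows.append(row)

            sens_rows.append(_sensitivity_row(pair, inst, cfg, seed, est_by_method, failures))

            if out.meta.n_cases and out.meta.n_controls and exp.meta.r2 is not None:
                spec = power.PowerSpec(
                    r2=exp.meta.r2,
                    n_cases=out.meta.n_cases,
                    n_controls=out.meta.n_controls,
                    alpha=cfg.alpha,
                    power=cfg.target_power,
                )
                power_rows.append(
                    {
                        "exposure": exp.name,
                        "outcome": out.name,
                        "r2": exp.meta.r2,
                        "n_cases": out.meta.n_cases,
                        "n_controls": out.meta.n_controls,
                        "alpha": cfg.alpha,
                        "power": cfg.target_power,
                        "min_detectable_or": power.min_detectable_or(spec),
                    }
                )
        logger.info("%s: finished in %.2f s", exp.name, time.perf_counter() - t0)

    if cfg.cd_name and cfg.uc_name:
        for exp in cfg.exposures:
            est_cd = ml_by_pair.get((exp.name, cfg.cd_name))
            est_uc = ml_by_pair.get((exp.name, cfg.uc_name))
            row = {"exposure": exp.name, "q": np.nan, "df": 1, "p_disease_het": np.nan, "pooled": np.nan}
            if est_cd is not None and est_uc is not None:
                het = subtype_het.disease_heterogeneity(est_cd, est_uc)
                row.update(q=het.q, p_disease_het=het.pvalue, pooled=het.pooled)
            het_rows.append(row)

    return StudyReport(
        primary=pd.DataFrame(primary_rows),
        sensitivity=pd.DataFrame(sens_rows),
        heterogeneity=pd.DataFrame(het_rows),
        power=pd.DataFrame(power_rows),
        instruments=instruments,
        ml_theta=ml_theta,
        failures=failures,
    )


def _run_estimators(inst, cfg: StudyConfig, seed: int, failures: list, pair) -> dict:
    """All point estimators with the NA policy for small instruments."""
    out: dict[str, estimators.MrEstimate] = {}
    calls = {
        "ml": lambda: estimators.ml_estimate(inst),
        "ivw": lambda: estimators.ivw_estimate(inst),
        "egger": lambda: estimators.egger_estimate(inst).slope,
        "weighted_median": lambda: estimators.weighted_median_estimate(
            inst, n_boot=cfg.n_boot, seed=seed
        ),
        "mode": lambda: estimators.mode_estimate(inst, n_boot=cfg.n_boot, seed=seed + 1),
    }
    for method, call in calls.items():
        try:
            out[method] = call()
        except InsufficientInstrumentsError:
            pass  # NA by design for undersized instruments
        except IbdMrError as exc:
            failures.append(f"{pair[0]} -> {pair[1]}: {method} failed: {exc}")
    return out


def _sensitivity_row(pair, inst, cfg: StudyConfig, seed: int, est_by_method, failures) -> dict:
    row = {
        "exposure": pair[0],
        "outcome": pair[1],
        "n_snp": inst.n_snp,
        "egger_intercept": np.nan,
        "egger_intercept_se": np.nan,
        "egger_intercept_p": np.nan,
        "q": np.nan,
        "q_df": pd.NA,
        "q_p": np.nan,
        "rss_obs": np.nan,
        "p_global": np.nan,
        "n_outliers": pd.NA,
        "outlier_rsids": "",
        "p_distortion": np.nan,
    }
    try:
        egger = estimators.egger_estimate(inst)
        row.update(
            egger_intercept=egger.intercept,
            egger_intercept_se=egger.intercept_se,
            egger_intercept_p=egger.intercept_p,
        )
    except InsufficientInstrumentsError:
        pass
    try:
        q = estimators.cochran_q(inst)
        row.update(q=q.q, q_df=q.df, q_p=q.pvalue)
    except InsufficientInstrumentsError:
        pass
    try:
        pres = presso.presso_test(
            inst, n_sim=cfg.presso_sims, seed=seed + 2, outlier_alpha=cfg.presso_outlier_alpha
        )
        row.update(
            rss_obs=pres.rss_obs,
            p_global=pres.p_global,
            n_outliers=len(pres.outlier_idx),
            outlier_rsids=",".join(inst.rsids[k] for k in pres.outlier_idx),
            p_distortion=np.nan if pres.p_distortion is None else pres.p_distortion,
        )
    except InsufficientInstrumentsError:
        pass
    except IbdMrError as exc:
        failures.append(f"{pair[0]} -> {pair[1]}: presso failed: {exc}")
    return row


def emit_plot_data(report: StudyReport, out_dir) -> dict[str, str]:
    """Write per-pair scatter data and per-outcome forest data.

    Scatter files carry the harmonized per-SNP effects plus the headline
    slope (constant column) so the study's scatter plots can be redrawn;
    forest files carry one row per exposure with OR, CI, p and the
    disease-heterogeneity p. Regenerating from the same report is
    byte-identical. Returns a manifest of file name -> sha256.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    digests: dict[str, str] = {}

    for (exp_name, out_name), inst in sorted(report.instruments.items()):
        df = summary_io.instrument_to_frame(inst)
        df["ml_slope"] = report.ml_theta.get((exp_name, out_name), np.nan)
        path = out_dir / f"scatter_{exp_name}_{out_name}.tsv"
        df.to_csv(path, sep="\t", index=False, na_rep="NA")
        digests[path.name] = hashlib.sha256(path.read_bytes()).hexdigest()

    het = report.heterogeneity.set_index("exposure") if len(report.heterogeneity) else None
    ml = report.primary[report.primary["method"] == PRIMARY_METHOD]
    for out_name, grp in ml.groupby("outcome", sort=True):
        forest = grp[["exposure", "or", "ci_low", "ci_high", "pvalue"]].copy()
        forest["p_disease_het"] = [
            het.loc[e, "p_disease_het"] if het is not None and e in het.index else np.nan
            for e in forest["exposure"]
        ]
        path = out_dir / f"forest_{out_name}.tsv"
        forest.to_csv(path, sep="\t", index=False, na_rep="NA")
        digests[path.name] = hashlib.sha256(path.read_bytes()).hexdigest()

    manifest = out_dir / "plot_manifest.tsv"
    with open(manifest, "w") as fh:
        fh.write("file\tsha256\n")
        for fname in sorted(digests):
            fh.write(f"{fname}\t{digests[fname]}\n")
    return digests
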