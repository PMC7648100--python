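"""Reading, validating, standardizing and harmonizing GWAS summary statistics.

The unit of work for every MR estimator in this package is a
:class:`HarmonizedInstrument`: per-SNP exposure effects (in SD units of the
exposure) aligned to outcome effects (log-odds for binary outcomes) on the
same effect allele, with standard errors.

The harmonization rules are the standard two-sample MR conventions:

* identical allele pairs are kept as-is;
* swapped allele pairs flip the sign of the outcome beta (and complement the
  effect-allele frequency);
* pairs that agree only after A<->T / C<->G strand complementation are
  complemented first, then aligned;
* palindromic SNPs (A/T or C/G) cannot be strand-resolved from the alleles
  alone and are dropped by default. An optional frequency-based resolution
  keeps them when the minor-allele frequency is informative
  (min(eaf, 1-eaf) < 0.42 on both sides);
* anything else is irreconcilable and dropped.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import (
    ConfigurationError,
    EmptyInputError,
    EmptyInstrumentError,
    ShapeError,
    SummaryFormatError,
)

logger = logging.getLogger(__name__)

#: Canonical column order of the tab-separated summary-statistic format.
SUMMARY_COLUMNS = ("rsid", "effect_allele", "other_allele", "eaf", "beta", "se", "pvalue")

#: Genome-wide significance threshold used to select instruments.
GENOMEWIDE_P = 5e-8

#: Default LD pruning threshold (squared allelic correlation).
LD_R2_THRESHOLD = 0.01

_VALID_ALLELES = frozenset("ACGT")
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


@dataclass(frozen=True)
class SnpAssociation:
    """One SNP's summary association with one trait.

    ``beta`` is the per-effect-allele effect: SD units for continuous traits
    once standardized, log-odds for binary traits. ``eaf`` may be ``None``
    when the source GWAS does not report frequencies.
    """

    rsid: str
    effect_allele: str
    other_allele: str
    eaf: float | None
    beta: float
    se: float
    pvalue: float

    def __post_init__(self) -> None:
        if self.effect_allele not in _VALID_ALLELES or self.other_allele not in _VALID_ALLELES:
            raise ValueError(f"{self.rsid}: alleles must be single bases A/C/G/T")
        if self.effect_allele == self.other_allele:
            raise ValueError(f"{self.rsid}: effect and other allele are identical")
        if not self.se > 0:
            raise ValueError(f"{self.rsid}: se must be > 0")
        if self.eaf is not None and not 0.0 < self.eaf < 1.0:
            raise ValueError(f"{self.rsid}: eaf must lie in (0, 1)")
        if not 0.0 < self.pvalue <= 1.0:
            raise ValueError(f"{self.rsid}: pvalue must lie in (0, 1]")

    @property
    def is_palindromic(self) -> bool:
        """True for A/T and C/G variants, whose strand is ambiguous."""
        return _COMPLEMENT[self.effect_allele] == self.other_allele


@dataclass(frozen=True)
class TraitMeta:
    """Metadata about one trait's GWAS: scale, design and instrument strength.

    Parameters
    ----------
    name:
        Human-readable trait name.
    is_binary:
        True for case-control traits (betas are log-odds and are never
        rescaled by ``sd``).
    sd:
        Trait standard deviation in native units; used to convert betas of
        continuous traits to SD units. ``None`` when effects are already in
        SD units.
    n, n_cases, n_controls:
        Sample design. For binary traits ``n_cases + n_controls`` must equal
        ``n`` when all three are given.
    r2:
        Proportion of exposure variance explained by the instrument
        (liability scale for binary exposures); drives power calculations.
    """

    name: str
    is_binary: bool = False
    sd: float | None = None
    n: int | None = None
    n_cases: int | None = None
    n_controls: int | None = None
    r2: float | None = None

    def __post_init__(self) -> None:
        if self.sd is not None and not self.sd > 0:
            raise ValueError(f"{self.name}: sd must be > 0")
        if self.r2 is not None and not 0.0 < self.r2 < 1.0:
            raise ValueError(f"{self.name}: r2 must lie in (0, 1)")
        if (
            self.is_binary
            and None not in (self.n, self.n_cases, self.n_controls)
            and self.n_cases + self.n_controls != self.n
        ):
            raise ValueError(f"{self.name}: n_cases + n_controls must equal n")


# Per-SNP harmonization actions.
FLAG_KEPT = "kept"
FLAG_FLIPPED = "flipped"
FLAG_COMPLEMENTED = "strand-complemented"
FLAG_DROPPED_PALINDROMIC = "dropped-palindromic"
FLAG_DROPPED_MISSING = "dropped-missing"


@dataclass(frozen=True)
class HarmonizedInstrument:
    """Aligned per-SNP exposure/outcome effect pairs, the input to all estimators.

    ``flags`` records the harmonization action for every shared rsid,
    including dropped ones; dropped SNPs never appear in the numeric arrays.
    """

    rsids: tuple[str, ...]
    x: np.ndarray  # per-SNP exposure betas, SD units
    sx: np.ndarray
    y: np.ndarray  # per-SNP outcome betas, log-odds
    sy: np.ndarray
    flags: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "x", np.asarray(self.x, dtype=float))
        object.__setattr__(self, "sx", np.asarray(self.sx, dtype=float))
        object.__setattr__(self, "y", np.asarray(self.y, dtype=float))
        object.__setattr__(self, "sy", np.asarray(self.sy, dtype=float))
        n = len(self.rsids)
        if not (len(self.x) == len(self.sx) == len(self.y) == len(self.sy) == n):
            raise ShapeError("x, sx, y, sy and rsids must have equal length")
        if n < 1:
            raise EmptyInstrumentError("instrument must contain at least one SNP")
        if not (np.all(self.sx > 0) and np.all(self.sy > 0)):
            raise ValueError("all standard errors must be > 0")
        for r in self.rsids:
            if self.flags.get(r, FLAG_KEPT).startswith("dropped"):
                raise ValueError(f"{r}: dropped SNP present in numeric arrays")

    @property
    def n_snp(self) -> int:
        return len(self.rsids)

    def subset(self, keep: Sequence[int]) -> "HarmonizedInstrument":
        """Instrument restricted to positional indices ``keep`` (order kept)."""
        keep = list(keep)
        return HarmonizedInstrument(
            rsids=tuple(self.rsids[i] for i in keep),
            x=self.x[keep],
            sx=self.sx[keep],
            y=self.y[keep],
            sy=self.sy[keep],
            flags={r: self.flags.get(r, FLAG_KEPT) for i, r in enumerate(self.rsids) if i in set(keep)},
        )


def _parse_float(value) -> float | None:
    if value is None:
        return None
    if isinstance(value, float) and math.isnan(value):
        return None
    s = str(value).strip()
    if s in ("", "NA", "NaN", "nan", "."):
        return None
    return float(s)


def read_summary_table(path, trait: TraitMeta | None = None) -> list[SnpAssociation]:
    """Read a tab-separated summary-statistic file into validated records.

    The file must carry the header ``rsid effect_allele other_allele eaf
    beta se pvalue``; missing effect-allele frequencies are encoded ``NA``.
    Rows violating the record invariants (non-positive SE, out-of-range
    p-value or frequency, multi-base alleles) are rejected with a logged
    reason rather than aborting the read.

    Raises
    ------
    SummaryFormatError
        If a mandatory column is absent.
    EmptyInputError
        If no row survives validation.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in SUMMARY_COLUMNS if c not in df.columns]
    if missing:
        raise SummaryFormatError(f"{path}: missing mandatory column(s) {missing}")

    records: list[SnpAssociation] = []
    for row in df.itertuples(index=False):
        rsid = str(row.rsid).strip()
        try:
            rec = SnpAssociation(
                rsid=rsid,
                effect_allele=str(row.effect_allele).strip().upper(),
                other_allele=str(row.other_allele).strip().upper(),
                eaf=_parse_float(row.eaf),
                beta=float(row.beta),
                se=float(row.se),
                pvalue=float(row.pvalue),
            )
        except (ValueError, TypeError) as exc:
            logger.warning("%s: rejected row %s: %s", path, rsid, exc)
            continue
        records.append(rec)
    if not records:
        raise EmptyInputError(f"{path}: no valid summary-statistic rows")
    return records


def standardize_to_sd(assoc: SnpAssociation, trait: TraitMeta) -> SnpAssociation:
    """Rescale a continuous-trait association to SD units of the trait.

    Beta and SE are divided by ``trait.sd``; the p-value (a function of
    beta/se only) is unchanged. Binary-trait effects are already log-odds
    and pass through untouched.
    """
    if trait.is_binary:
        return assoc
    if trait.sd is None:
        raise ConfigurationError(f"{trait.name}: trait SD required to standardize {assoc.rsid}")
    if trait.sd == 1.0:
        return assoc
    return replace(assoc, beta=assoc.beta / trait.sd, se=assoc.se / trait.sd)


def filter_genomewide(
    assocs: Sequence[SnpAssociation], threshold: float = GENOMEWIDE_P
) -> list[SnpAssociation]:
    """Keep SNPs with ``pvalue`` strictly below ``threshold`` (default 5e-8).

    The comparison is strict, so a SNP at exactly the threshold is excluded.
    Input order is preserved.
    """
    if not 0.0 < threshold < 1.0:
        raise ConfigurationError("significance threshold must lie in (0, 1)")
    return [a for a in assocs if a.pvalue < threshold]


def ld_prune(
    assocs: Sequence[SnpAssociation],
    ld_r2: np.ndarray,
    threshold: float = LD_R2_THRESHOLD,
) -> list[SnpAssociation]:
    """Greedy p-value-ordered LD pruning.

    SNPs are visited by ascending p-value (ties broken by input order); a
    SNP is kept only if its squared correlation with every already-kept SNP
    is below ``threshold``. This is the deterministic "clumping" behaviour
    used to enforce (near-)independent instruments. The result preserves
    input order.

    ``ld_r2`` must be a square symmetric matrix with unit diagonal, indexed
    in the same order as ``assocs``.
    """
    ld = np.asarray(ld_r2, dtype=float)
    n = len(assocs)
    if ld.shape != (n, n):
        raise ShapeError(f"LD matrix shape {ld.shape} does not match {n} SNPs")
    if not np.allclose(ld, ld.T, atol=1e-8) or not np.allclose(np.diag(ld), 1.0, atol=1e-8):
        raise ShapeError("LD matrix must be symmetric with unit diagonal")

    order = sorted(range(n), key=lambda i: (assocs[i].pvalue, i))
    kept: list[int] = []
    for i in order:
        if all(ld[i, j] < threshold for j in kept):
            kept.append(i)
    return [assocs[i] for i in sorted(kept)]


def read_ld_matrix(path, assocs: Sequence[SnpAssociation]) -> np.ndarray:
    """Read a square tab-separated LD R^2 table (rsid header row/column).

    Rows/columns are reordered to match ``assocs``.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    rsids = [a.rsid for a in assocs]
    missing = set(rsids) - set(df.index)
    if missing:
        raise ShapeError(f"LD matrix missing rsids: {sorted(missing)}")
    return df.loc[rsids, rsids].to_numpy(dtype=float)


def _orient_outcome(
    exp: SnpAssociation, out: SnpAssociation
) -> tuple[float, float | None, str] | None:
    """Align an outcome record to the exposure's allele coding.

    Returns (signed outcome beta, oriented eaf, flag) or ``None`` if the
    allele pairs are irreconcilable.
    """
    ea, oa = out.effect_allele, out.other_allele
    if (ea, oa) == (exp.effect_allele, exp.other_allele):
        return out.beta, out.eaf, FLAG_KEPT
    if (ea, oa) == (exp.other_allele, exp.effect_allele):
        return -out.beta, None if out.eaf is None else 1.0 - out.eaf, FLAG_FLIPPED
    cea, coa = _COMPLEMENT[ea], _COMPLEMENT[oa]
    if (cea, coa) == (exp.effect_allele, exp.other_allele):
        return out.beta, out.eaf, FLAG_COMPLEMENTED
    if (cea, coa) == (exp.other_allele, exp.effect_allele):
        return -out.beta, None if out.eaf is None else 1.0 - out.eaf, FLAG_COMPLEMENTED
    return None


def harmonize(
    exposure: Sequence[SnpAssociation],
    outcome: Sequence[SnpAssociation],
    drop_palindromic: bool = True,
    eaf_ambiguity_threshold: float = 0.42,
) -> HarmonizedInstrument:
    """Align exposure and outcome associations on shared rsids.

    Parameters
    ----------
    drop_palindromic:
        When True (default) A/T and C/G variants are dropped, because their
        strand cannot be resolved from alleles alone and proxy substitution
        is outside this package's scope. When False, palindromic SNPs are
        resolved from effect-allele frequencies: both frequencies must be
        informative (min(eaf, 1-eaf) < ``eaf_ambiguity_threshold``); the
        outcome beta sign is chosen so the frequencies agree on which allele
        is minor.

    Raises
    ------
    EmptyInstrumentError
        If the rsid intersection is empty, or every shared SNP was dropped.
    """
    out_by_rsid = {a.rsid: a for a in outcome}
    shared = [e for e in exposure if e.rsid in out_by_rsid]
    if not shared:
        raise EmptyInstrumentError("no shared rsids between exposure and outcome")

    rsids: list[str] = []
    x: list[float] = []
    sx: list[float] = []
    y: list[float] = []
    sy: list[float] = []
    flags: dict[str, str] = {}

    for exp in shared:
        out = out_by_rsid[exp.rsid]
        if exp.is_palindromic or out.is_palindromic:
            if drop_palindromic:
                flags[exp.rsid] = FLAG_DROPPED_PALINDROMIC
                continue
            resolved = _resolve_palindromic(exp, out, eaf_ambiguity_threshold)
            if resolved is None:
                flags[exp.rsid] = FLAG_DROPPED_PALINDROMIC
                continue
            beta_y, flag = resolved
        else:
            oriented = _orient_outcome(exp, out)
            if oriented is None:
                flags[exp.rsid] = FLAG_DROPPED_MISSING
                continue
            beta_y, _, flag = oriented
        rsids.append(exp.rsid)
        x.append(exp.beta)
        sx.append(exp.se)
        y.append(beta_y)
        sy.append(out.se)
        flags[exp.rsid] = flag

    if not rsids:
        raise EmptyInstrumentError("all shared SNPs were dropped during harmonization")
    return HarmonizedInstrument(
        rsids=tuple(rsids),
        x=np.array(x),
        sx=np.array(sx),
        y=np.array(y),
        sy=np.array(sy),
        flags=flags,
    )


def _resolve_palindromic(
    exp: SnpAssociation, out: SnpAssociation, eaf_threshold: float
) -> tuple[float, str] | None:
    """Frequency-based orientation of a palindromic SNP.

    Usable only when both frequencies are present and clearly away from 0.5.
    Alignment: if the exposure and outcome effect-allele frequencies fall on
    the same side of 0.5 the effect alleles match; otherwise the outcome
    beta is flipped.
    """
    if {exp.effect_allele, exp.other_allele} != {out.effect_allele, out.other_allele} and {
        _COMPLEMENT[out.effect_allele],
        _COMPLEMENT[out.other_allele],
    } != {exp.effect_allele, exp.other_allele}:
        return None
    if exp.eaf is None or out.eaf is None:
        return None
    if min(exp.eaf, 1 - exp.eaf) >= eaf_threshold or min(out.eaf, 1 - out.eaf) >= eaf_threshold:
        return None
    same_side = (exp.eaf < 0.5) == (out.eaf < 0.5)
    if same_side:
        return out.beta, FLAG_KEPT
    return -out.beta, FLAG_FLIPPED


def instrument_to_frame(inst: HarmonizedInstrument) -> pd.DataFrame:
    """Tabular view (one row per kept SNP) of a harmonized instrument."""
    return pd.DataFrame(
        {
            "rsid": list(inst.rsids),
            "x": inst.x,
            "sx": inst.sx,
            "y": inst.y,
            "sy": inst.sy,
            "flag": [inst.flags.get(r, FLAG_KEPT) for r in inst.rsids],
        }
    )
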