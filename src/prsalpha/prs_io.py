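"""PRS weight files, genotype scoring, standardization and summaries.

A PRS is a weighted sum of effect-allele dosages.  Weight files use the
CanRisk-style dialect: a header line naming ``variant``, ``effect_allele``
and ``weight`` columns, optionally preceded by ``#`` metadata lines carrying
``name=`` and ``alpha=`` entries.  Variant keys are GRCh37 strings
``chrom_pos_ref_alt`` (e.g. ``22_29203724_C_T``); no liftover or strand
flipping is attempted, but a weight whose effect allele equals the key's
*reference* allele is scored on the flipped dosage ``2 - d`` (logged).
"""

from __future__ import annotations

import csv
import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .datasets import CHEK2_LINKED_VARIANTS
from .errors import DomainError, EstimationError, FormatError

__all__ = [
    "PRSWeightSet",
    "GenotypeMatrix",
    "PRSSummary",
    "parse_weights",
    "exclude_variants",
    "score_prs",
    "standardize",
    "summarize_prs",
]

logger = logging.getLogger(__name__)

_KEY_RE = re.compile(r"^(?P<chrom>[0-9XYMT]+)_(?P<pos>\d+)_(?P<ref>[ACGT]+)_(?P<alt>[ACGT]+)$")

_VARIANT_ALIASES = ("variant", "variant_key", "snp", "id", "name")
_ALLELE_ALIASES = ("effect_allele", "effect", "ea")
_WEIGHT_ALIASES = ("weight", "beta", "log_or", "effect_size")


def _split_key(key: str) -> tuple[str, str, str, str]:
    m = _KEY_RE.match(key)
    if m is None:
        raise FormatError(f"variant key {key!r} is not of the form chrom_pos_ref_alt")
    return m["chrom"], m["pos"], m["ref"], m["alt"]


@dataclass(frozen=True)
class PRSWeightSet:
    """A named set of per-allele log-odds weights defining a PRS."""

    name: str
    variant_keys: tuple[str, ...]
    effect_alleles: tuple[str, ...]
    weights: tuple[float, ...]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        n = len(self.variant_keys)
        if len(self.effect_alleles) != n or len(self.weights) != n:
            raise FormatError("variant_keys, effect_alleles and weights must align")
        seen: dict[str, int] = {}
        dups = []
        for i, k in enumerate(self.variant_keys):
            if k in seen:
                dups.append(k)
            seen[k] = i
        if dups:
            raise FormatError(f"duplicate variant keys: {sorted(set(dups))}")
        for k, a in zip(self.variant_keys, self.effect_alleles):
            _, _, ref, alt = _split_key(k)
            if a not in (ref, alt):
                raise FormatError(
                    f"effect allele {a!r} of {k} is neither its ref ({ref}) nor alt ({alt})"
                )

    def __len__(self) -> int:
        return len(self.variant_keys)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "variant": self.variant_keys,
                "effect_allele": self.effect_alleles,
                "weight": self.weights,
            }
        )


@dataclass
class GenotypeMatrix:
    """Samples-by-variants dosage matrix; dosages in [0, 2], NaN flags missing."""

    sample_ids: list[str]
    variant_keys: list[str]
    dosage: np.ndarray

    def __post_init__(self):
        self.dosage = np.asarray(self.dosage, dtype=float)
        if self.dosage.shape != (len(self.sample_ids), len(self.variant_keys)):
            raise FormatError(
                f"dosage shape {self.dosage.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.variant_keys)} variants"
            )
        with np.errstate(invalid="ignore"):
            bad = (self.dosage < 0) | (self.dosage > 2)
        if np.any(bad):
            raise FormatError("dosages must lie in [0, 2] (NaN for missing)")

    @classmethod
    def from_tsv(cls, path) -> "GenotypeMatrix":
        """Read a TSV with sample ids in the first column and one column per variant key."""
        df = pd.read_csv(path, sep="\t", na_values=["NA"])
        sample_col = df.columns[0]
        return cls(
            sample_ids=df[sample_col].astype(str).tolist(),
            variant_keys=list(df.columns[1:]),
            dosage=df.iloc[:, 1:].to_numpy(dtype=float),
        )


@dataclass(frozen=True)
class PRSSummary:
    """Descriptive and effect-size summary of a PRS in a case-control sample."""

    mean_controls: float
    mean_cases: float
    sd_controls: float
    sd_cases: float
    log_or_per_sd: float
    ci_low: float
    ci_high: float
    n_cases: int
    n_controls: int

    def __post_init__(self):
        if self.sd_controls <= 0 or self.sd_cases <= 0:
            raise DomainError("group standard deviations must be positive")
        if not self.ci_low <= self.log_or_per_sd <= self.ci_high:
            raise DomainError("CI must bracket the log-OR estimate")


def parse_weights(path, name: Optional[str] = None) -> PRSWeightSet:
    """Parse a PRS weight file (TSV or CSV).

    Leading ``#`` lines may carry ``key=value`` metadata (CanRisk dialect),
    e.g. ``# name=PRS313`` and ``# alpha=0.441``.
    """
    metadata: dict[str, str] = {}
    header_lines = 0
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            header_lines += 1
            for part in re.split(r"[,\s]+", line.lstrip("#").strip()):
                if "=" in part:
                    k, v = part.split("=", 1)
                    metadata[k.strip()] = v.strip()
    try:
        df = pd.read_csv(path, sep=None, engine="python", skiprows=header_lines)
    except (pd.errors.EmptyDataError, pd.errors.ParserError, csv.Error):
        raise FormatError(f"weight file {path} is empty or unparseable") from None
    cols = {c.lower().strip(): c for c in df.columns}

    def pick(aliases, what):
        for a in aliases:
            if a in cols:
                return cols[a]
        raise FormatError(f"weight file {path} lacks a {what} column (one of {aliases})")

    vcol = pick(_VARIANT_ALIASES, "variant-key")
    acol = pick(_ALLELE_ALIASES, "effect-allele")
    wcol = pick(_WEIGHT_ALIASES, "weight")
    if df.empty:
        raise FormatError(f"weight file {path} contains no variants")

    weights = pd.to_numeric(df[wcol], errors="coerce")
    bad = df.index[weights.isna()].tolist()
    if bad:
        raise FormatError(f"unparseable weight on data line(s) {bad} of {path}")
    ws = PRSWeightSet(
        name=name or metadata.get("name", str(path)),
        variant_keys=tuple(df[vcol].astype(str)),
        effect_alleles=tuple(df[acol].astype(str).str.upper()),
        weights=tuple(weights.astype(float)),
        metadata=metadata,
    )
    logger.info("parsed %d variants from %s", len(ws), path)
    return ws


def exclude_variants(
    weights: PRSWeightSet,
    exclusion: Iterable[str] = CHEK2_LINKED_VARIANTS,
) -> PRSWeightSet:
    """Drop variants whose key is in ``exclusion``.

    The default exclusion list is the pair of chromosome-22 variants tagging
    CHEK2*1100delC, which must be removed when the PRS is used alongside
    gene-panel results.  Keys absent from the set are ignored with a notice.
    """
    excl = set(exclusion)
    missing = excl - set(weights.variant_keys)
    if missing:
        logger.info("exclusion keys not present in %s: %s", weights.name, sorted(missing))
    keep = [i for i, k in enumerate(weights.variant_keys) if k not in excl]
    return PRSWeightSet(
        name=weights.name,
        variant_keys=tuple(weights.variant_keys[i] for i in keep),
        effect_alleles=tuple(weights.effect_alleles[i] for i in keep),
        weights=tuple(weights.weights[i] for i in keep),
        metadata=dict(weights.metadata),
    )


def score_prs(
    genotypes: GenotypeMatrix,
    weights: PRSWeightSet,
    missing_policy: str = "fail",
) -> pd.Series:
    """Raw PRS per sample: sum over variants of weight x effect-allele dosage.

    ``missing_policy`` is ``fail`` (any missing dosage or absent variant is an
    error) or ``mean_impute`` (per-variant sample-mean dosage substituted).
    """
    if missing_policy not in {"fail", "mean_impute"}:
        raise DomainError(f"unknown missing_policy {missing_policy!r}")
    col_index = {k: j for j, k in enumerate(genotypes.variant_keys)}
    absent = [k for k in weights.variant_keys if k not in col_index]
    if absent and missing_policy == "fail":
        raise FormatError(f"variants absent from genotype matrix: {absent}")

    total = np.zeros(len(genotypes.sample_ids))
    for key, allele, weight in zip(
        weights.variant_keys, weights.effect_alleles, weights.weights
    ):
        j = col_index.get(key)
        if j is None:
            continue  # mean-imputing an entirely absent variant adds a constant 0
        d = genotypes.dosage[:, j].copy()
        _, _, ref, alt = _split_key(key)
        if allele == ref and ref != alt:
            logger.info("effect allele of %s is the reference allele; flipping dosage", key)
            d = 2.0 - d
        nan = np.isnan(d)
        if nan.any():
            if missing_policy == "fail":
                raise FormatError(f"missing dosages for variant {key} under policy 'fail'")
            fill = np.nanmean(d) if (~nan).any() else 0.0
            d[nan] = fill
        total += weight * d
    return pd.Series(total, index=pd.Index(genotypes.sample_ids, name="sample_id"), name="prs_raw")


def standardize(raw, ref_mean: float, ref_sd: float):
    """Z-scores (raw - ref_mean) / ref_sd against a reference population."""
    if ref_sd <= 0:
        raise DomainError(f"reference SD must be positive, got {ref_sd}")
    return (np.asarray(raw, dtype=float) - ref_mean) / ref_sd


def summarize_prs(cohort, covariates: Sequence[str] = ()) -> PRSSummary:
    """Case/control means and SDs plus the log-OR per 1 control SD.

    The effect size is the logistic-regression coefficient of the PRS scaled
    by the control-group SD (denominator n-1), adjusted for the named
    covariate columns (``country`` entered as categorical indicators, others
    as continuous), with a Wald 95% CI.
    """
    df = cohort.df if hasattr(cohort, "df") else cohort
    status = df["status"].to_numpy()
    if not (np.any(status == 1) and np.any(status == 0)):
        raise DomainError("cohort must contain both cases and controls")
    prs = df["prs_raw"].to_numpy(dtype=float)
    cases, controls = prs[status == 1], prs[status == 0]
    sd_controls = float(np.std(controls, ddof=1))
    sd_cases = float(np.std(cases, ddof=1))
    if sd_controls <= 0:
        raise DomainError("control PRS SD is zero; cannot standardize")

    X = pd.DataFrame({"prs_per_sd": prs / sd_controls}, index=df.index)
    X = _append_covariates(X, df, covariates)
    X = sm.add_constant(X, has_constant="add")
    try:
        fit = sm.Logit(status, X.astype(float)).fit(disp=0)
    except Exception as exc:  # separation, singular design
        raise EstimationError(f"logistic regression failed: {exc}") from exc
    ci = fit.conf_int().loc["prs_per_sd"]
    return PRSSummary(
        mean_controls=float(np.mean(controls)),
        mean_cases=float(np.mean(cases)),
        sd_controls=sd_controls,
        sd_cases=sd_cases,
        log_or_per_sd=float(fit.params["prs_per_sd"]),
        ci_low=float(ci[0]),
        ci_high=float(ci[1]),
        n_cases=int((status == 1).sum()),
        n_controls=int((status == 0).sum()),
    )


def _append_covariates(X: pd.DataFrame, df: pd.DataFrame, covariates: Sequence[str]) -> pd.DataFrame:
    """Attach covariate columns: 'country' as drop-first indicators, others continuous."""
    for cov in covariates:
        if cov not in df.columns:
            raise DomainError(f"covariate column {cov!r} not in cohort")
        if cov == "country" or df[cov].dtype == object:
            dummies = pd.get_dummies(df[cov], prefix=cov, drop_first=True, dtype=float)
            X = pd.concat([X, dummies], axis=1)
        else:
            X[cov] = df[cov].to_numpy(dtype=float)
    return X
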