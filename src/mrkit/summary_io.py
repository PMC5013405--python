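"""Reading, validation and harmonization of GWAS summary-statistic tables.

Two-sample Mendelian randomization combines per-SNP association estimates
from an exposure GWAS (here: body-mass index in SD units of
inverse-normal-transformed residuals) with estimates from an outcome GWAS
(binary psychiatric disorders, log odds ratios).  Before any causal
estimator can run, the two tables must refer to the *same* effect allele
for every SNP.  This module provides:

* :func:`read_association_table` — tab-delimited table reader with
  column-name synonym resolution and per-row validation,
* :func:`harmonize` — allele alignment (swap / strand-complement /
  palindromic resolution via allele frequencies), proxy substitution and
  exclusion logging,
* :func:`eaf_concordance` — effect-allele-frequency concordance check,
* :func:`instrument_strength` — per-SNP F-statistics and the
  sample-size-rescaled approximation for the outcome dataset.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("mrkit")

NUCLEOTIDES = frozenset("ACGT")
COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: Default column-name synonyms, lower-cased.  GIANT and PGC releases name
#: the same quantities differently; extend via the ``synonyms`` argument.
DEFAULT_SYNONYMS: dict[str, tuple[str, ...]] = {
    "snp_id": ("snp_id", "snp", "rsid", "rs_id", "markername", "variant_id"),
    "effect_allele": ("effect_allele", "a1", "allele1", "ea", "effect_all"),
    "other_allele": ("other_allele", "a2", "allele2", "oa", "nea",
                     "non_effect_allele", "other_all", "reference_allele"),
    "eaf": ("eaf", "freq", "frq", "effect_allele_freq", "freq_a1", "frq_a1",
            "freq1", "eaf_a1"),
    "beta": ("beta", "b", "effect", "log_odds", "logor", "beta1"),
    "se": ("se", "stderr", "standard_error", "se_beta"),
    "n": ("n", "samplesize", "sample_size", "ntotal", "n_total"),
}

MANDATORY_COLUMNS = ("snp_id", "effect_allele", "other_allele", "beta", "se")

#: Minimum distance of an allele frequency from 0.5 before it is trusted
#: to resolve the strand of a palindromic (A/T or C/G) SNP.
PALINDROME_EAF_MARGIN = 0.08

#: Proxy acceptance thresholds: LD r-squared and distance to the index SNP.
PROXY_MIN_R2 = 0.8
PROXY_MAX_DISTANCE_BP = 500_000


class FormatError(ValueError):
    """Table-level structural problem (missing column, duplicates)."""


class ValidationError(ValueError):
    """Row-level invariant violation; message lists the offending rows."""


class DiagnosticUnavailable(RuntimeError):
    """Raised when too little data exists to compute a diagnostic."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SnpAssociation:
    """One SNP's per-allele association with one trait.

    ``beta`` is in SD units for an exposure table and log-odds for an
    outcome table; ``se`` must be positive; ``eaf`` is the effect-allele
    frequency when the source GWAS reports it.
    """

    snp_id: str
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    eaf: Optional[float] = None
    n: Optional[float] = None
    categories: frozenset[str] = frozenset()

    def validate(self) -> None:
        if self.effect_allele not in NUCLEOTIDES:
            raise ValidationError(
                f"{self.snp_id}: effect allele {self.effect_allele!r} is not one of A/C/G/T")
        if self.other_allele not in NUCLEOTIDES:
            raise ValidationError(
                f"{self.snp_id}: other allele {self.other_allele!r} is not one of A/C/G/T")
        if self.effect_allele == self.other_allele:
            raise ValidationError(f"{self.snp_id}: effect and other allele are identical")
        if not math.isfinite(self.beta):
            raise ValidationError(f"{self.snp_id}: beta is not finite")
        if not (math.isfinite(self.se) and self.se > 0):
            raise ValidationError(f"{self.snp_id}: se must be finite and > 0, got {self.se}")
        if self.eaf is not None and not (0.0 <= self.eaf <= 1.0):
            raise ValidationError(f"{self.snp_id}: eaf {self.eaf} outside [0, 1]")

    @property
    def is_palindromic(self) -> bool:
        """True for A/T and C/G SNPs, whose strand cannot be inferred from alleles."""
        return COMPLEMENT[self.effect_allele] == self.other_allele

    def flipped(self) -> "SnpAssociation":
        """Return the same association expressed on the other allele."""
        return replace(
            self,
            effect_allele=self.other_allele,
            other_allele=self.effect_allele,
            beta=-self.beta,
            eaf=None if self.eaf is None else 1.0 - self.eaf,
        )

    def complemented(self) -> "SnpAssociation":
        """Return the association with both alleles strand-complemented."""
        return replace(
            self,
            effect_allele=COMPLEMENT[self.effect_allele],
            other_allele=COMPLEMENT[self.other_allele],
        )


@dataclass(frozen=True)
class HarmonizedInstrument:
    """A SNP with exposure effect ``gamma`` and outcome effect ``Gamma``
    expressed on a common effect allele."""

    snp_id: str
    gamma: float
    se_gamma: float
    Gamma: float
    se_Gamma: float
    proxy_of: str = ""
    eaf_exposure: Optional[float] = None
    eaf_outcome: Optional[float] = None
    categories: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.se_gamma <= 0 or self.se_Gamma <= 0:
            raise ValidationError(f"{self.snp_id}: standard errors must be positive")


@dataclass(frozen=True)
class ProxyRecord:
    index_snp: str
    proxy_snp: str
    r2: float
    distance_bp: int


class ProxyMap:
    """User-supplied proxy (LD surrogate) records, validated on input.

    Every record must satisfy ``r2 > 0.8`` and ``distance_bp <= 500 kb``.
    When several proxies exist for one index SNP the highest-r2 one wins.
    No LD computation is performed here — the map is an input.
    """

    def __init__(self, records: Iterable[ProxyRecord] = ()):
        self._best: dict[str, ProxyRecord] = {}
        for rec in records:
            if not (PROXY_MIN_R2 < rec.r2 <= 1.0):
                raise ValidationError(
                    f"proxy {rec.proxy_snp} for {rec.index_snp}: r2={rec.r2} "
                    f"not in ({PROXY_MIN_R2}, 1]")
            if not (0 <= rec.distance_bp <= PROXY_MAX_DISTANCE_BP):
                raise ValidationError(
                    f"proxy {rec.proxy_snp} for {rec.index_snp}: distance "
                    f"{rec.distance_bp} bp exceeds {PROXY_MAX_DISTANCE_BP}")
            cur = self._best.get(rec.index_snp)
            if cur is None or rec.r2 > cur.r2:
                self._best[rec.index_snp] = rec

    def best_proxy(self, index_snp: str) -> Optional[ProxyRecord]:
        return self._best.get(index_snp)

    def __len__(self) -> int:
        return len(self._best)

    @classmethod
    def from_table(cls, path) -> "ProxyMap":
        df = pd.read_csv(path, sep="\t")
        expected = ["index_snp", "proxy_snp", "r2", "distance_bp"]
        missing = [c for c in expected if c not in df.columns]
        if missing:
            raise FormatError(f"proxy map missing column(s): {', '.join(missing)}")
        return cls(
            ProxyRecord(str(r.index_snp), str(r.proxy_snp), float(r.r2), int(r.distance_bp))
            for r in df.itertuples()
        )


@dataclass
class InstrumentStrength:
    """Per-SNP F-statistics with summary statistics.

    When ``target_n``/``source_n`` are supplied, ``rescaled`` holds the
    approximate F in the target dataset, ``F × target_n / source_n`` —
    valid under the assumption that per-SNP associations are similar in
    the two samples.
    """

    f_stats: pd.Series
    mean: float
    sd: float
    median: float
    iqr: float
    target_n: Optional[float] = None
    source_n: Optional[float] = None
    rescaled: Optional["InstrumentStrength"] = None


# ---------------------------------------------------------------------------
# Reading
# ---------------------------------------------------------------------------

def _resolve_columns(columns: Sequence[str],
                     synonyms: Mapping[str, tuple[str, ...]]) -> dict[str, str]:
    lowered = {c.strip().lower(): c for c in columns}
    mapping: dict[str, str] = {}
    for canonical, names in synonyms.items():
        for name in names:
            if name in lowered:
                mapping[canonical] = lowered[name]
                break
    return mapping


def read_association_table(path, trait_kind: str = "exposure",
                           synonyms: Optional[Mapping[str, tuple[str, ...]]] = None,
                           ) -> list[SnpAssociation]:
    """Read a tab-delimited summary-statistic table into validated records.

    Parameters
    ----------
    path
        Tab-delimited file (gzip-transparent) with a header row naming at
        least the SNP id, effect allele, other allele, beta and se columns.
        Header names are matched case-insensitively against
        :data:`DEFAULT_SYNONYMS` (or ``synonyms`` if given).
    trait_kind
        ``"exposure"`` or ``"outcome"``; recorded for error messages only —
        betas are taken at face value (SD units vs log-odds).

    Raises
    ------
    FormatError
        A mandatory column is absent or a SNP id occurs more than once.
    ValidationError
        One or more rows violate the record invariants; the message lists
        every offending row rather than silently dropping it.
    """
    if trait_kind not in ("exposure", "outcome"):
        raise ValueError(f"trait_kind must be 'exposure' or 'outcome', got {trait_kind!r}")
    df = pd.read_csv(path, sep="\t", dtype=str)
    mapping = _resolve_columns(df.columns, synonyms or DEFAULT_SYNONYMS)
    missing = [c for c in MANDATORY_COLUMNS if c not in mapping]
    if missing:
        raise FormatError(
            f"{path}: missing mandatory column(s) {', '.join(missing)} "
            f"(recognised synonyms: {DEFAULT_SYNONYMS})")

    records: list[SnpAssociation] = []
    problems: list[str] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):  # 1-based + header
        rowd = dict(zip(df.columns, row))
        try:
            beta = float(rowd[mapping["beta"]])
            se = float(rowd[mapping["se"]])
        except (TypeError, ValueError):
            problems.append(f"row {i} ({rowd[mapping['snp_id']]}): non-numeric beta/se")
            continue
        eaf = None
        if "eaf" in mapping and pd.notna(rowd[mapping["eaf"]]):
            try:
                eaf = float(rowd[mapping["eaf"]])
            except ValueError:
                problems.append(f"row {i}: non-numeric eaf")
                continue
        n = None
        if "n" in mapping and pd.notna(rowd[mapping["n"]]):
            n = float(rowd[mapping["n"]])
        rec = SnpAssociation(
            snp_id=str(rowd[mapping["snp_id"]]).strip(),
            effect_allele=str(rowd[mapping["effect_allele"]]).strip().upper(),
            other_allele=str(rowd[mapping["other_allele"]]).strip().upper(),
            beta=beta, se=se, eaf=eaf, n=n,
        )
        try:
            rec.validate()
        except ValidationError as exc:
            problems.append(f"row {i}: {exc}")
            continue
        records.append(rec)

    if problems:
        raise ValidationError(
            f"{path} ({trait_kind} table): {len(problems)} invalid row(s):\n  "
            + "\n  ".join(problems))

    ids = pd.Series([r.snp_id for r in records])
    dup = ids[ids.duplicated()].unique().tolist()
    if dup:
        raise FormatError(f"{path}: duplicate snp_id(s): {', '.join(dup)}")
    return records


# ---------------------------------------------------------------------------
# Harmonization
# ---------------------------------------------------------------------------

@dataclass
class HarmonizationResult(Sequence):
    """Harmonized instruments plus the exclusion log and warnings.

    Behaves as a sequence of :class:`HarmonizedInstrument`, so it can be
    passed directly to the estimators.
    """

    instruments: list[HarmonizedInstrument] = field(default_factory=list)
    excluded: list[tuple[str, str]] = field(default_factory=list)  # (snp_id, reason)
    warnings: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.instruments)

    def __getitem__(self, i):
        return self.instruments[i]

    def __iter__(self) -> Iterator[HarmonizedInstrument]:
        return iter(self.instruments)


def _align_outcome(expo: SnpAssociation, outc: SnpAssociation,
                   warnings: list[str]) -> Optional[SnpAssociation]:
    """Express ``outc`` on ``expo``'s effect allele, or None if irreconcilable.

    Resolution order: direct match → allele swap → strand complement →
    complement + swap.  Palindromic SNPs are ambiguous between "same
    strand" and "opposite strand + swap"; allele frequencies decide when
    both are informative (further than :data:`PALINDROME_EAF_MARGIN` from
    0.5), otherwise the same-strand reading is kept with a warning.
    """
    if expo.is_palindromic:
        # Alleles cannot distinguish strands.  Take the same-strand reading
        # first, then check frequency concordance.
        if {outc.effect_allele, outc.other_allele} != {expo.effect_allele, expo.other_allele}:
            return None
        aligned = outc if outc.effect_allele == expo.effect_allele else outc.flipped()
        if (expo.eaf is not None and aligned.eaf is not None
                and abs(expo.eaf - 0.5) > PALINDROME_EAF_MARGIN
                and abs(aligned.eaf - 0.5) > PALINDROME_EAF_MARGIN):
            if (expo.eaf - 0.5) * (aligned.eaf - 0.5) < 0:
                # Discordant frequencies: the outcome row is on the other
                # strand, which for a palindrome is equivalent to a flip.
                return aligned.flipped()
            return aligned
        warnings.append(
            f"{expo.snp_id}: palindromic SNP with uninformative allele "
            "frequencies; assuming same strand")
        return aligned

    for cand in (outc, outc.complemented()):
        if cand.effect_allele == expo.effect_allele and cand.other_allele == expo.other_allele:
            return cand
        if cand.effect_allele == expo.other_allele and cand.other_allele == expo.effect_allele:
            return cand.flipped()
    return None


def harmonize(exposure: Sequence[SnpAssociation],
              outcome: Sequence[SnpAssociation],
              proxies: Optional[ProxyMap] = None,
              categories: Optional[Mapping[str, frozenset]] = None,
              ) -> HarmonizationResult:
    """Align outcome associations to the exposure's effect alleles.

    For each exposure SNP found in the outcome table (directly, or through
    the supplied :class:`ProxyMap` when absent), the outcome effect is
    re-expressed on the exposure's effect allele: allele-swapped rows get
    their beta sign flipped and eaf complemented; strand-complemented rows
    are complemented first.  SNPs absent from the outcome table (and
    without a usable proxy) or with irreconcilable alleles are excluded
    with a logged reason, never silently dropped.
    """
    outcome_by_id = {a.snp_id: a for a in outcome}
    result = HarmonizationResult()
    for expo in exposure:
        proxy_of = ""
        outc = outcome_by_id.get(expo.snp_id)
        if outc is None and proxies is not None:
            rec = proxies.best_proxy(expo.snp_id)
            if rec is not None and rec.proxy_snp in outcome_by_id:
                # The proxy's outcome row is used verbatim; its alleles are
                # aligned against the exposure row of the index SNP only
                # when the allele pairs are comparable, otherwise the
                # proxy's own orientation is trusted as-is.
                outc = outcome_by_id[rec.proxy_snp]
                proxy_of = expo.snp_id
        if outc is None:
            result.excluded.append((expo.snp_id, "absent from outcome table"))
            logger.info("harmonize: %s excluded (absent from outcome table)", expo.snp_id)
            continue

        if proxy_of and {outc.effect_allele, outc.other_allele} != \
                {expo.effect_allele, expo.other_allele} and \
                {COMPLEMENT[outc.effect_allele], COMPLEMENT[outc.other_allele]} != \
                {expo.effect_allele, expo.other_allele}:
            # Different variant: take the proxy's outcome coding verbatim.
            aligned = outc
        else:
            aligned = _align_outcome(expo, outc, result.warnings)
        if aligned is None:
            result.excluded.append((expo.snp_id, "allele mismatch"))
            logger.info("harmonize: %s excluded (allele mismatch)", expo.snp_id)
            continue

        snp_id = outc.snp_id if proxy_of else expo.snp_id
        result.instruments.append(HarmonizedInstrument(
            snp_id=snp_id,
            proxy_of=proxy_of,
            gamma=expo.beta, se_gamma=expo.se,
            Gamma=aligned.beta, se_Gamma=aligned.se,
            eaf_exposure=expo.eaf, eaf_outcome=aligned.eaf,
            categories=(categories or {}).get(expo.snp_id, expo.categories),
        ))
    for msg in result.warnings:
        logger.warning("harmonize: %s", msg)
    return result


# ---------------------------------------------------------------------------
# Diagnostics on the harmonized set
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EafConcordance:
    r: float
    n_pairs: int


def eaf_concordance(instruments: Sequence[HarmonizedInstrument]) -> EafConcordance:
    """Pearson correlation between exposure and outcome effect-allele
    frequencies over instruments where both are present.

    A value near 1 indicates the two datasets' allele codings agree after
    harmonization; values well below 1 flag residual strand/allele-order
    problems.  Requires at least three usable pairs.
    """
    pairs = [(i.eaf_exposure, i.eaf_outcome) for i in instruments
             if i.eaf_exposure is not None and i.eaf_outcome is not None]
    if len(pairs) < 3:
        raise DiagnosticUnavailable(
            f"eaf concordance needs >= 3 instruments with both frequencies; "
            f"got {len(pairs)}")
    x, y = np.asarray(pairs, dtype=float).T
    r = float(np.corrcoef(x, y)[0, 1])
    return EafConcordance(r=r, n_pairs=len(pairs))


def instrument_strength(instruments: Sequence[HarmonizedInstrument],
                        target_n: Optional[float] = None,
                        source_n: Optional[float] = None) -> InstrumentStrength:
    """Per-SNP F-statistics ``(gamma / se_gamma)^2`` with summaries.

    With ``target_n`` and ``source_n``, an approximate strength in the
    target (outcome) dataset is attached as ``rescaled``, computed as
    ``F × target_n / source_n`` — valid when per-allele associations are
    comparable between the two samples.
    """
    if target_n is not None and source_n is None:
        raise ValueError("target_n given without source_n")
    f = pd.Series({i.snp_id: (i.gamma / i.se_gamma) ** 2 for i in instruments})
    q75, q25 = np.percentile(f.values, [75, 25]) if len(f) else (math.nan, math.nan)
    out = InstrumentStrength(
        f_stats=f,
        mean=float(f.mean()), sd=float(f.std(ddof=1)) if len(f) > 1 else math.nan,
        median=float(f.median()), iqr=float(q75 - q25),
        target_n=target_n, source_n=source_n,
    )
    if target_n is not None:
        scale = target_n / source_n
        fs = f * scale
        q75s, q25s = np.percentile(fs.values, [75, 25])
        out.rescaled = InstrumentStrength(
            f_stats=fs,
            mean=float(fs.mean()), sd=float(fs.std(ddof=1)) if len(fs) > 1 else math.nan,
            median=float(fs.median()), iqr=float(q75s - q25s),
            target_n=target_n, source_n=source_n,
        )
    return out


# ---------------------------------------------------------------------------
# Writing
# ---------------------------------------------------------------------------

HARMONIZED_COLUMNS = ("snp_id", "proxy_of", "gamma", "se_gamma", "Gamma",
                      "se_Gamma", "eaf_exposure", "eaf_outcome", "categories")


def harmonized_frame(instruments: Sequence[HarmonizedInstrument]) -> pd.DataFrame:
    rows = [{
        "snp_id": i.snp_id, "proxy_of": i.proxy_of,
        "gamma": i.gamma, "se_gamma": i.se_gamma,
        "Gamma": i.Gamma, "se_Gamma": i.se_Gamma,
        "eaf_exposure": i.eaf_exposure, "eaf_outcome": i.eaf_outcome,
        "categories": ";".join(sorted(i.categories)),
    } for i in instruments]
    return pd.DataFrame(rows, columns=list(HARMONIZED_COLUMNS))


def write_harmonized(instruments: Sequence[HarmonizedInstrument], path) -> None:
    harmonized_frame(instruments).to_csv(path, sep="\t", index=False, float_format="%.10g")


def write_exclusions(excluded: Sequence[tuple[str, str]], path) -> None:
    pd.DataFrame(excluded, columns=["snp_id", "reason"]).to_csv(
        path, sep="\t", index=False)


def read_harmonized(path) -> list[HarmonizedInstrument]:
    """Read back a table written by :func:`write_harmonized`."""
    df = pd.read_csv(path, sep="\t")
    out = []
    for r in df.itertuples(index=False):
        cats = frozenset() if pd.isna(r.categories) or not str(r.categories) \
            else frozenset(str(r.categories).split(";"))
        out.append(HarmonizedInstrument(
            snp_id=str(r.snp_id),
            proxy_of="" if pd.isna(r.proxy_of) else str(r.proxy_of),
            gamma=float(r.gamma), se_gamma=float(r.se_gamma),
            Gamma=float(r.Gamma), se_Gamma=float(r.se_Gamma),
            eaf_exposure=None if pd.isna(r.eaf_exposure) else float(r.eaf_exposure),
            eaf_outcome=None if pd.isna(r.eaf_outcome) else float(r.eaf_outcome),
            categories=cats,
        ))
    return out
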