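"""SNP quality filtering and transition/transversion accounting.

The retained-SNP criteria follow standard resequencing practice: a site
survives iff

* total coverage depth ≥ ``min_depth`` and ≤ ``max_total_depth`` (the cap
  guards against collapsed repeats),
* root-mean-square mapping quality ≥ ``min_rms_mq``,
* mean Phred base quality of the variant allele ≥ ``min_base_quality``,
* fraction of missing genotype calls ≤ ``max_missing_frac``,
* minor allele frequency among called alleles ≥ ``min_maf``,
* the site is a biallelic single-nucleotide variant (multi-nucleotide and
  multi-allelic records are dropped when ``biallelic_snps_only``).

All comparisons are inclusive.  The filter report attributes each removed
record to the first criterion it violates, in the order listed above; the
surviving set itself does not depend on that order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .matrix import GenotypeMatrix
from .vcfio import read_vcf, write_vcf  # noqa: F401  (module surface)

#: attribution order for the filter report
CRITERIA_ORDER = [
    "not_biallelic_snp",
    "low_depth",
    "high_depth",
    "low_mapping_quality",
    "low_base_quality",
    "high_missingness",
    "low_maf",
]


@dataclass
class FilterCriteria:
    """Thresholds of the retained-SNP filter (inclusive semantics)."""

    min_depth: int = 3
    min_rms_mq: float = 20.0
    max_missing_frac: float = 0.2
    min_maf: float = 0.05
    min_base_quality: float = 20.0
    max_total_depth: int = 31_000
    biallelic_snps_only: bool = True

    def validate(self) -> None:
        if min(self.min_depth, self.min_rms_mq, self.min_base_quality) < 0:
            raise ValueError("thresholds must be non-negative")
        if not 0.0 <= self.max_missing_frac <= 1.0:
            raise ValueError("max_missing_frac must lie in [0, 1]")
        if not 0.0 <= self.min_maf <= 0.5:
            raise ValueError("min_maf must lie in [0, 0.5]")
        if self.max_total_depth < self.min_depth:
            raise ValueError("max_total_depth below min_depth")


@dataclass
class FilterReport:
    """Per-criterion removal counts plus input/output totals."""

    n_input: int
    n_retained: int
    removed: dict[str, int] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = [(c, self.removed.get(c, 0)) for c in CRITERIA_ORDER]
        rows.append(("retained", self.n_retained))
        return pd.DataFrame(rows, columns=["criterion", "n_records"])


def _is_biallelic_snp(ref: str, alt: str) -> bool:
    return (
        len(ref) == 1
        and ref in "ACGT"
        and len(alt) == 1
        and alt in "ACGT"
    )


def apply_filters(
    matrix: GenotypeMatrix, criteria: FilterCriteria | None = None
) -> tuple[GenotypeMatrix, FilterReport]:
    """Apply the retained-SNP criteria; return survivors and a report.

    Each removed record is attributed to the first violated criterion in
    :data:`CRITERIA_ORDER`; survivors are independent of that order.
    """
    criteria = criteria or FilterCriteria()
    criteria.validate()
    if matrix.n_variants == 0:
        raise ValueError("empty genotype matrix")

    v = matrix.variants
    checks: dict[str, np.ndarray] = {}
    if criteria.biallelic_snps_only:
        checks["not_biallelic_snp"] = ~np.fromiter(
            (_is_biallelic_snp(r, a) for r, a in zip(v["ref"], v["alt"])),
            dtype=bool,
            count=len(v),
        )
    else:
        checks["not_biallelic_snp"] = np.zeros(len(v), dtype=bool)
    depth = v["depth"].to_numpy()
    checks["low_depth"] = depth < criteria.min_depth
    checks["high_depth"] = depth > criteria.max_total_depth
    checks["low_mapping_quality"] = v["mq"].to_numpy() < criteria.min_rms_mq
    checks["low_base_quality"] = v["base_qual"].to_numpy() < criteria.min_base_quality
    checks["high_missingness"] = matrix.missing_fraction() > criteria.max_missing_frac
    maf = matrix.minor_allele_freqs()
    checks["low_maf"] = ~(maf >= criteria.min_maf)  # NaN (no calls) fails too

    removed: dict[str, int] = {}
    attributed = np.zeros(len(v), dtype=bool)
    for name in CRITERIA_ORDER:
        hit = checks[name] & ~attributed
        removed[name] = int(hit.sum())
        attributed |= checks[name]

    keep = ~attributed
    report = FilterReport(
        n_input=matrix.n_variants, n_retained=int(keep.sum()), removed=removed
    )
    return matrix.take_variants(keep), report


# ---------------------------------------------------------------------------
# transition / transversion accounting

_PURINES = {"A", "G"}
_PYRIMIDINES = {"C", "T"}


def is_transition(ref: str, alt: str) -> bool:
    """True for purine↔purine or pyrimidine↔pyrimidine substitutions."""
    if len(ref) != 1 or len(alt) != 1 or ref == alt:
        raise ValueError(f"not a biallelic SNP: {ref}>{alt}")
    if ref not in "ACGT" or alt not in "ACGT":
        raise ValueError(f"non-nucleotide alleles: {ref}>{alt}")
    return (ref in _PURINES) == (alt in _PURINES)


def ts_tv_counts(
    ref_alleles, alt_alleles
) -> tuple[int, int, float | None]:
    """Count transitions and transversions; return (n_ts, n_tv, ratio).

    The ratio is ``None`` when there are no transversions.
    """
    n_ts = 0
    n_tv = 0
    for ref, alt in zip(ref_alleles, alt_alleles):
        if is_transition(ref, alt):
            n_ts += 1
        else:
            n_tv += 1
    ratio = n_ts / n_tv if n_tv else None
    return n_ts, n_tv, ratio


def ts_tv_ratio_from_counts(n_transitions: int, n_transversions: int) -> float | None:
    """Ts/Tv ratio from pre-tabulated substitution counts."""
    if n_transitions < 0 or n_transversions < 0:
        raise ValueError("counts must be non-negative")
    if n_transversions == 0:
        return None
    return n_transitions / n_transversions


def matrix_ts_tv(matrix: GenotypeMatrix) -> tuple[int, int, float | None]:
    """Ts/Tv accounting over all records of a biallelic-SNP matrix."""
    return ts_tv_counts(matrix.variants["ref"], matrix.variants["alt"])
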