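"""Windowed nucleotide diversity, Hudson FST, and joint-outlier sweep calling.

The scan slides fixed-size windows (default 40 kb advancing by 20 kb, i.e.
adjacent windows overlap by half) along each contig and computes, per
window,

* θπ for the target and reference populations: the sum over SNPs of the
  unbiased per-site mean pairwise difference ``2·p̂(1−p̂)·n/(n−1)``,
  divided by the window length in base pairs (invariant sites contribute
  zero);
* Hudson's FST combined as a ratio of sums ("ratio of averages"):
  per-site numerator ``(p̂1−p̂2)² − p̂1(1−p̂1)/(n1−1) − p̂2(1−p̂2)/(n2−1)``
  and denominator ``p̂1(1−p̂2) + p̂2(1−p̂1)``, each summed over sites
  before the division.

Candidate sweep windows are those simultaneously in the top tail of the
Z-standardized log-transformed FST and of the Z-standardized
log2 θπ-ratio (reference/target, so diversity loss in the target pushes
the ratio up).  Overlapping or bookended outlier windows are merged into
regions, and genes whose transcript span intersects a region are assigned
to it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annotate import GeneModel
from .matrix import GenotypeMatrix

WINDOW_SIZE = 40_000
WINDOW_STEP = 20_000
TOP_FRAC = 0.05


@dataclass(frozen=True)
class Window:
    """Half-open genomic interval [start, end) on a contig (0-based bp)."""

    contig: str
    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class SweepRegion:
    """Merged run of joint-outlier windows, with overlapping genes."""

    contig: str
    start: int
    end: int
    peak_z_fst: float
    peak_z_log_ratio: float
    genes: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# per-site statistics


def site_pi(allele_count_alt: int, n_called_alleles: int) -> float:
    """Unbiased mean pairwise difference at one site.

    For sample ALT frequency ``p̂ = alt/n`` this is ``2·p̂(1−p̂)·n/(n−1)``,
    the fraction of the ``C(n,2)`` allele pairs that differ.
    """
    n = n_called_alleles
    if n < 2:
        raise ValueError("need at least 2 called alleles")
    if not 0 <= allele_count_alt <= n:
        raise ValueError("allele count outside [0, n]")
    p = allele_count_alt / n
    return 2.0 * p * (1.0 - p) * n / (n - 1)


def hudson_fst_site(
    p1: float, n1: int, p2: float, n2: int
) -> tuple[float, float]:
    """Hudson FST numerator and denominator for one site.

    ``n1``/``n2`` are called allele counts; sites with fewer than two
    called alleles in either population must be skipped by the caller.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("need ≥2 called alleles per population")
    num = (
        (p1 - p2) ** 2
        - p1 * (1.0 - p1) / (n1 - 1)
        - p2 * (1.0 - p2) / (n2 - 1)
    )
    den = p1 * (1.0 - p2) + p2 * (1.0 - p1)
    return num, den


# ---------------------------------------------------------------------------
# windows


def make_windows(
    contig_lengths: dict[str, int],
    size: int = WINDOW_SIZE,
    step: int = WINDOW_STEP,
) -> list[Window]:
    """Sliding windows starting at 0, step, 2·step, …

    Only windows fully contained in the contig are emitted; a contig
    shorter than *size* contributes none (terminal windows are dropped
    rather than truncated, so per-base-pair normalization stays
    comparable across windows).
    """
    if size <= 0 or not 0 < step <= size:
        raise ValueError("require size > 0 and 0 < step ≤ size")
    windows = []
    for contig, length in contig_lengths.items():
        start = 0
        while start + size <= length:
            windows.append(Window(contig, start, start + size))
            start += step
    return windows


def _window_site_index(matrix: GenotypeMatrix, window: Window) -> np.ndarray:
    pos = matrix.variants["pos"].to_numpy()
    on_contig = (matrix.variants["contig"] == window.contig).to_numpy()
    # pos is 1-based; window is 0-based half-open
    return np.flatnonzero(on_contig & (pos - 1 >= window.start) & (pos - 1 < window.end))


def window_pi(
    matrix: GenotypeMatrix, population: str | None, window: Window
) -> float:
    """Per-site nucleotide diversity of *population* in *window*.

    Sites with fewer than two called alleles are skipped; if every site is
    uncallable the value is NaN (missing).
    """
    idx = _window_site_index(matrix, window)
    if idx.size == 0:
        return 0.0
    alt, n = matrix.allele_counts(population)
    alt, n = alt[idx], n[idx]
    ok = n >= 2
    if not ok.any():
        return float("nan")
    p = alt[ok] / n[ok]
    total = np.sum(2.0 * p * (1.0 - p) * n[ok] / (n[ok] - 1))
    return float(total / window.length)


def window_fst(
    matrix: GenotypeMatrix,
    pop_target: str,
    pop_reference: str,
    window: Window,
) -> float:
    """Ratio-of-sums Hudson FST between two populations in *window*."""
    idx = _window_site_index(matrix, window)
    if idx.size == 0:
        return float("nan")
    alt1, n1 = matrix.allele_counts(pop_target)
    alt2, n2 = matrix.allele_counts(pop_reference)
    alt1, n1, alt2, n2 = alt1[idx], n1[idx], alt2[idx], n2[idx]
    ok = (n1 >= 2) & (n2 >= 2)
    if not ok.any():
        return float("nan")
    p1 = alt1[ok] / n1[ok]
    p2 = alt2[ok] / n2[ok]
    num = (
        (p1 - p2) ** 2
        - p1 * (1.0 - p1) / (n1[ok] - 1)
        - p2 * (1.0 - p2) / (n2[ok] - 1)
    )
    den = p1 * (1.0 - p2) + p2 * (1.0 - p1)
    den_sum = float(den.sum())
    if den_sum == 0.0:
        return float("nan")
    return float(num.sum() / den_sum)


def window_scan(
    matrix: GenotypeMatrix,
    pop_target: str,
    pop_reference: str,
    contig_lengths: dict[str, int],
    size: int = WINDOW_SIZE,
    step: int = WINDOW_STEP,
) -> pd.DataFrame:
    """FST and per-population θπ for every full window.

    Returns one row per window: contig, start, end, n_snps, fst,
    pi_target, pi_reference, pi_ratio (reference/target) and log2_ratio.
    """
    windows = make_windows(contig_lengths, size, step)
    alt_t, n_t = matrix.allele_counts(pop_target)
    alt_r, n_r = matrix.allele_counts(pop_reference)
    pos = matrix.variants["pos"].to_numpy()
    contig_arr = matrix.variants["contig"].to_numpy()

    rows = []
    for w in windows:
        idx = np.flatnonzero(
            (contig_arr == w.contig) & (pos - 1 >= w.start) & (pos - 1 < w.end)
        )
        n_snps = idx.size
        if n_snps == 0:
            rows.append((w.contig, w.start, w.end, 0, np.nan, 0.0, 0.0, np.nan, np.nan))
            continue
        a1, m1 = alt_t[idx], n_t[idx]
        a2, m2 = alt_r[idx], n_r[idx]

        def _pi(a, m):
            ok = m >= 2
            if not ok.any():
                return np.nan
            p = a[ok] / m[ok]
            return float(np.sum(2 * p * (1 - p) * m[ok] / (m[ok] - 1)) / w.length)

        pi_t = _pi(a1, m1)
        pi_r = _pi(a2, m2)
        ok = (m1 >= 2) & (m2 >= 2)
        if ok.any():
            p1, p2 = a1[ok] / m1[ok], a2[ok] / m2[ok]
            num = (
                (p1 - p2) ** 2
                - p1 * (1 - p1) / (m1[ok] - 1)
                - p2 * (1 - p2) / (m2[ok] - 1)
            )
            den = p1 * (1 - p2) + p2 * (1 - p1)
            fst = float(num.sum() / den.sum()) if den.sum() > 0 else np.nan
        else:
            fst = np.nan
        ratio = pi_r / pi_t if (pi_t and pi_t > 0 and not np.isnan(pi_r)) else np.nan
        log2r = np.log2(ratio) if ratio and ratio > 0 else np.nan
        rows.append((w.contig, w.start, w.end, n_snps, fst, pi_t, pi_r, ratio, log2r))
    return pd.DataFrame(
        rows,
        columns=[
            "contig",
            "start",
            "end",
            "n_snps",
            "fst",
            "pi_target",
            "pi_reference",
            "pi_ratio",
            "log2_ratio",
        ],
    )


# ---------------------------------------------------------------------------
# outlier calling


def _zscore(x: np.ndarray) -> np.ndarray:
    mu = np.nanmean(x)
    sd = np.nanstd(x)
    if sd == 0:
        return np.zeros_like(x)
    return (x - mu) / sd


def add_outlier_scores(
    stats: pd.DataFrame,
    top_frac: float = TOP_FRAC,
    log_transform_fst: bool = True,
    joint: bool = True,
) -> pd.DataFrame:
    """Add z_fst, z_log_ratio and is_outlier columns to a window table.

    FST can be ≤ 0, so before the log transform it is shifted by
    ``1 − min(fst)`` (making its minimum exactly 1, log 0); set
    ``log_transform_fst=False`` to Z-standardize raw FST instead.  A
    window is an outlier when its scores lie at or above the empirical
    ``1 − top_frac`` quantile — of both statistics when *joint* (the
    default), of either when not.
    """
    if not 0 < top_frac <= 1:
        raise ValueError("top_frac must lie in (0, 1]")
    stats = stats.copy()
    fst = stats["fst"].to_numpy(dtype=float)
    log2r = stats["log2_ratio"].to_numpy(dtype=float)
    defined = ~np.isnan(fst) & ~np.isnan(log2r)
    if defined.sum() < 20:
        raise ValueError("need ≥ 20 windows with defined statistics")

    if log_transform_fst:
        shifted = fst - np.nanmin(fst) + 1.0
        fst_t = np.log2(shifted)
    else:
        fst_t = fst
    z_fst = np.full_like(fst, np.nan)
    z_lr = np.full_like(fst, np.nan)
    z_fst[defined] = _zscore(fst_t[defined])
    z_lr[defined] = _zscore(log2r[defined])

    q_fst = np.nanquantile(z_fst[defined], 1.0 - top_frac)
    q_lr = np.nanquantile(z_lr[defined], 1.0 - top_frac)
    hit_fst = z_fst >= q_fst
    hit_lr = z_lr >= q_lr
    is_outlier = (hit_fst & hit_lr) if joint else (hit_fst | hit_lr)
    is_outlier &= defined

    stats["z_fst"] = z_fst
    stats["z_log_ratio"] = z_lr
    stats["is_outlier"] = is_outlier
    return stats


def call_sweep_regions(
    stats: pd.DataFrame,
    top_frac: float = TOP_FRAC,
    log_transform_fst: bool = True,
    joint: bool = True,
) -> tuple[pd.DataFrame, list[SweepRegion]]:
    """Score windows and merge outliers into sweep regions.

    Overlapping or bookended (adjacent) outlier windows on the same contig
    are merged; each region records the peak z-scores of its windows.
    Returns the scored window table and the region list.
    """
    scored = add_outlier_scores(stats, top_frac, log_transform_fst, joint)
    regions: list[SweepRegion] = []
    out = scored[scored["is_outlier"]].sort_values(["contig", "start"])
    for _, row in out.iterrows():
        if (
            regions
            and regions[-1].contig == row["contig"]
            and row["start"] <= regions[-1].end
        ):
            r = regions[-1]
            r.end = max(r.end, int(row["end"]))
            r.peak_z_fst = max(r.peak_z_fst, float(row["z_fst"]))
            r.peak_z_log_ratio = max(r.peak_z_log_ratio, float(row["z_log_ratio"]))
        else:
            regions.append(
                SweepRegion(
                    contig=str(row["contig"]),
                    start=int(row["start"]),
                    end=int(row["end"]),
                    peak_z_fst=float(row["z_fst"]),
                    peak_z_log_ratio=float(row["z_log_ratio"]),
                )
            )
    return scored, regions


def assign_genes(
    regions: list[SweepRegion], genes: list[GeneModel]
) -> tuple[list[SweepRegion], list[str]]:
    """Attach genes whose transcript span intersects each region.

    Returns the regions (mutated in place) and the deduplicated global
    gene list, in genomic order of first occurrence.
    """
    seen: dict[str, None] = {}
    for region in regions:
        hits = []
        for g in genes:
            if g.contig != region.contig:
                continue
            # region is 0-based half-open; transcript span 1-based inclusive
            if g.tx_start - 1 < region.end and g.tx_end > region.start:
                hits.append(g.gene_id)
                seen.setdefault(g.gene_id)
        region.genes = hits
    return regions, list(seen)


def regions_to_bed(regions: list[SweepRegion]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (
                r.contig,
                r.start,
                r.end,
                f"sweep_{i + 1}",
                f"{r.peak_z_fst:.4f}",
                f"{r.peak_z_log_ratio:.4f}",
            )
            for i, r in enumerate(regions)
        ],
        columns=["contig", "start", "end", "name", "peak_z_fst", "peak_z_log_ratio"],
    )
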