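"""Linkage disequilibrium from unphased genotypes and distance-binned decay.

Because genotypes are unphased, the default r² is the composite
(Rogers–Huff style) statistic: the squared Pearson correlation of dosage
vectors over samples called at both sites.  An EM mode is provided as a
cross-check: it estimates the four two-locus haplotype frequencies from
the 3×3 genotype table (the classic gametic-phase EM, iterating the
expected split of double heterozygotes) and returns
``D² / (p_A(1−p_A) · p_B(1−p_B))``.

The decay curve averages r² over all intra-contig pairs closer than
``max_distance``, grouped into contiguous distance bins; pairs can be
subsampled per bin (seeded) to bound runtime on dense data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .matrix import MISSING, GenotypeMatrix

MAX_DISTANCE = 500_000
DEFAULT_BIN_WIDTH = 25_000


@dataclass
class LDBin:
    """Mean r² of pairs whose separation lies in [start, end) bp."""

    start: int
    end: int
    mean_r2: float  # NaN when n_pairs == 0
    n_pairs: int

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.start + self.end)


def pair_r2(dosages_a: np.ndarray, dosages_b: np.ndarray, method: str = "composite") -> float:
    """r² between two sites from dosage vectors (MISSING = -1 excluded).

    ``method='composite'`` (default) is the squared Pearson correlation of
    dosages over pairwise-complete samples; ``method='em'`` estimates
    haplotype frequencies by EM first.  Monomorphic sites (among the
    complete samples) have undefined r² and raise ``ValueError``.
    """
    a = np.asarray(dosages_a, dtype=float)
    b = np.asarray(dosages_b, dtype=float)
    ok = (a != MISSING) & (b != MISSING)
    a, b = a[ok], b[ok]
    if a.size < 2:
        raise ValueError("need ≥ 2 samples called at both sites")
    if a.std() == 0 or b.std() == 0:
        raise ValueError("monomorphic site: r² undefined")
    if method == "composite":
        r = np.corrcoef(a, b)[0, 1]
        return float(r * r)
    if method == "em":
        return _em_r2(a.astype(int), b.astype(int))
    raise ValueError(f"unknown method {method!r}")


def _em_r2(a: np.ndarray, b: np.ndarray, n_iter: int = 100, tol: float = 1e-12) -> float:
    """Two-locus gametic-phase EM on diploid genotype counts."""
    n = a.size
    # haplotype counts are fully determined except for double heterozygotes
    # haplotypes: 00, 01, 10, 11 (allele at locus A, allele at locus B)
    n_dh = int(np.sum((a == 1) & (b == 1)))
    base = np.zeros(4)
    for ga, gb in zip(a, b):
        if ga == 1 and gb == 1:
            continue
        # outside the double heterozygote the haplotype split is unambiguous
        ha = [1] * ga + [0] * (2 - ga)
        hb = [1] * gb + [0] * (2 - gb)
        for x, y in zip(ha, hb):
            base[2 * x + y] += 1
    pA = a.sum() / (2 * n)
    pB = b.sum() / (2 * n)
    # initialize assuming linkage equilibrium split of double heterozygotes
    f = base.copy()
    f += n_dh * np.array([0.5, 0.0, 0.0, 0.5])  # any split works as a start
    f /= f.sum()
    for _ in range(n_iter):
        # E-step: split double heterozygotes between cis (00/11) and
        # trans (01/10) phase by current haplotype frequencies
        cis = f[0] * f[3]
        trans = f[1] * f[2]
        w = cis / (cis + trans) if cis + trans > 0 else 0.5
        new = base + n_dh * np.array([w, 1 - w, 1 - w, w])
        new /= new.sum()
        if np.max(np.abs(new - f)) < tol:
            f = new
            break
        f = new
    d = f[3] - (f[2] + f[3]) * (f[1] + f[3])
    denom = pA * (1 - pA) * pB * (1 - pB)
    if denom == 0:
        raise ValueError("monomorphic site: r² undefined")
    return float(d * d / denom)


def decay_curve(
    matrix: GenotypeMatrix,
    population: str | None = None,
    max_distance: int = MAX_DISTANCE,
    bin_width: int = DEFAULT_BIN_WIDTH,
    min_maf: float = 0.05,
    seed: int = 0,
    max_pairs_per_bin: int | None = 50_000,
) -> list[LDBin]:
    """Distance-binned mean composite r² within one population.

    Sites failing the MAF filter (within the population) are excluded.
    All intra-contig pairs separated by less than *max_distance* are
    binned by separation; when a bin would exceed *max_pairs_per_bin*
    pairs, a seeded uniform subsample is used.
    """
    if bin_width <= 0 or max_distance <= 0:
        raise ValueError("bin_width and max_distance must be positive")
    rows = matrix.sample_indices(population)
    maf = matrix.minor_allele_freqs(population)
    keep = maf >= min_maf
    n_bins = int(np.ceil(max_distance / bin_width))
    sums = np.zeros(n_bins)
    counts = np.zeros(n_bins, dtype=np.int64)

    # enumerate eligible pairs (site indices + bin) per contig
    pair_i: list[np.ndarray] = []
    pair_j: list[np.ndarray] = []
    pair_bin: list[np.ndarray] = []
    for contig in matrix.contigs:
        on = (matrix.variants["contig"] == contig).to_numpy() & keep
        idx = np.flatnonzero(on)
        pos = matrix.variants["pos"].to_numpy()[idx]
        for ii in range(idx.size):
            hi = int(np.searchsorted(pos, pos[ii] + max_distance, side="left"))
            if hi <= ii + 1:
                continue
            sep = pos[ii + 1 : hi] - pos[ii]
            pair_i.append(np.full(sep.size, idx[ii]))
            pair_j.append(idx[ii + 1 : hi])
            pair_bin.append(sep // bin_width)
    if pair_i:
        pi = np.concatenate(pair_i)
        pj = np.concatenate(pair_j)
        pb = np.concatenate(pair_bin).astype(np.int64)
    else:
        pi = pj = pb = np.empty(0, dtype=np.int64)

    # seeded per-bin subsampling to bound work on dense data
    rng = np.random.default_rng(seed)
    if max_pairs_per_bin is not None:
        chosen = []
        for b in range(n_bins):
            members = np.flatnonzero(pb == b)
            if members.size > max_pairs_per_bin:
                members = members[
                    rng.choice(members.size, size=max_pairs_per_bin, replace=False)
                ]
            chosen.append(members)
        sel = np.sort(np.concatenate(chosen)) if chosen else np.empty(0, dtype=np.int64)
        pi, pj, pb = pi[sel], pj[sel], pb[sel]

    # pairwise-complete Pearson r² from sufficient statistics, chunked
    d = matrix.dosages[rows]
    a = np.where(d == MISSING, 0, d).astype(np.float64)
    m_called = (d != MISSING).astype(np.float64)
    chunk = 200_000
    for lo in range(0, pi.size, chunk):
        ci, cj, cb = pi[lo : lo + chunk], pj[lo : lo + chunk], pb[lo : lo + chunk]
        ai, aj = a[:, ci], a[:, cj]
        mi, mj = m_called[:, ci], m_called[:, cj]
        both = mi * mj
        n = both.sum(axis=0)
        sx = (ai * both).sum(axis=0)
        sy = (aj * both).sum(axis=0)
        sxx = (ai * ai * both).sum(axis=0)
        syy = (aj * aj * both).sum(axis=0)
        sxy = (ai * aj * both).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            var_term = (n * sxx - sx * sx) * (n * syy - sy * sy)
            r2 = np.where(
                (n >= 2) & (var_term > 0),
                (n * sxy - sx * sy) ** 2 / var_term,
                np.nan,
            )
        ok = ~np.isnan(r2)
        np.add.at(sums, cb[ok], r2[ok])
        np.add.at(counts, cb[ok], 1)

    return [
        LDBin(
            start=b * bin_width,
            end=min((b + 1) * bin_width, max_distance),
            mean_r2=float(sums[b] / counts[b]) if counts[b] else float("nan"),
            n_pairs=int(counts[b]),
        )
        for b in range(n_bins)
    ]


def half_decay_distance(curve: list[LDBin]) -> float | None:
    """Smallest bin midpoint where mean r² falls to half the first bin's.

    Returns ``None`` when the curve never reaches half its initial level
    (or the first bin is empty).
    """
    defined = [b for b in curve if b.n_pairs > 0]
    if not defined:
        return None
    half = defined[0].mean_r2 / 2.0
    for b in defined:
        if b.mean_r2 <= half:
            return b.midpoint
    return None


def curve_to_frame(curve: list[LDBin]) -> pd.DataFrame:
    return pd.DataFrame(
        [(b.start, b.end, b.mean_r2, b.n_pairs) for b in curve],
        columns=["bin_start", "bin_end", "mean_r2", "n_pairs"],
    )
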