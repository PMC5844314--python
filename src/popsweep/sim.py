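"""Synthetic multi-population genotype data with planted selective sweeps.

The generator emulates the statistical product of a small resequencing
study: a handful of target-population samples, a reference panel of other
domestic animals and a few wild outgroup samples genotyped at biallelic
SNPs over multi-megabase contigs.  Population allele frequencies follow
the Balding–Nichols model — for ancestral frequency ``p`` and drift
coefficient ``F`` the population frequency is drawn from
``Beta(p(1-F)/F, (1-p)(1-F)/F)`` — which makes the expected Hudson FST
between two populations sharing drift ``F`` equal to ``F``, giving the
downstream window scan an analytic calibration oracle.

Selective sweeps are planted as intervals in which the target population
uses a larger drift coefficient ``F_sweep`` and its ancestral frequency is
rescaled toward fixation, reducing local diversity and elevating
differentiation — the signature the window scan is built to recover.

Linkage disequilibrium is induced by first-order haplotype copying: each
haplotype carries a latent uniform variate along the chromosome that is
retained from the previous site with probability ``exp(-d / ld_block_scale)``
and redrawn otherwise; the allele at each site is the indicator that the
latent uniform falls below the population frequency.  Copying the latent
variate rather than the realized allele preserves per-site allele-frequency
marginals exactly (so the FST calibration holds) while still producing
positive, distance-decaying r² between nearby sites.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .matrix import MISSING, VARIANT_COLUMNS, GenotypeMatrix

TRANSITIONS = {"A": "G", "G": "A", "C": "T", "T": "C"}
TRANSVERSIONS = {
    "A": ("C", "T"),
    "G": ("C", "T"),
    "C": ("A", "G"),
    "T": ("A", "G"),
}
BASES = ("A", "C", "G", "T")


@dataclass
class SweepInterval:
    """A planted sweep: target population drifts harder and loses diversity.

    Coordinates are 0-based half-open base-pair intervals on *contig*.
    ``diversity_scale`` in (0, 1] rescales the target population's ancestral
    frequency toward fixation (1 = no rescaling); ``f_sweep`` replaces the
    target population's background drift coefficient inside the interval.
    """

    contig: str
    start: int
    end: int
    target_pop: str
    f_sweep: float
    diversity_scale: float


@dataclass
class SimConfig:
    """Parameters of one synthetic dataset.

    Defaults mirror a small resequencing design: a target population of 6,
    a domestic reference panel of 20 and a wild outgroup of 4, ~1 SNP per
    300 bp, moderate drift, and a transition/transversion ratio of 2.57.
    """

    contigs: list[tuple[str, int]] = field(default_factory=lambda: [("chr1", 2_000_000)])
    pop_names: list[str] = field(
        default_factory=lambda: ["target", "reference", "outgroup"]
    )
    samples_per_pop: list[int] = field(default_factory=lambda: [6, 20, 4])
    f_per_pop: list[float] = field(default_factory=lambda: [0.10, 0.08, 0.15])
    snp_density: float = 1.0 / 300.0
    sweep_intervals: list[SweepInterval] = field(default_factory=list)
    tstv_ratio: float = 2.57
    maf_floor_ancestral: float = 0.05
    missing_rate: float = 0.02
    ld_block_scale: float = 10_000.0
    mean_depth_per_sample: float = 20.0
    rms_mapping_quality: float = 60.0
    mean_base_quality: float = 35.0
    seed: int = 0

    @property
    def n_pops(self) -> int:
        return len(self.pop_names)

    def validate(self) -> None:
        if not self.contigs:
            raise ValueError("at least one contig required")
        for name, length in self.contigs:
            if length <= 0:
                raise ValueError(f"contig {name!r} has non-positive length")
        if not (len(self.pop_names) == len(self.samples_per_pop) == len(self.f_per_pop)):
            raise ValueError("pop_names, samples_per_pop and f_per_pop lengths differ")
        if any(n <= 0 for n in self.samples_per_pop):
            raise ValueError("samples_per_pop must be positive")
        if any(not 0.0 < f < 1.0 for f in self.f_per_pop):
            raise ValueError("drift coefficients must lie in (0, 1)")
        if self.tstv_ratio <= 0:
            raise ValueError("tstv_ratio must be positive")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must lie in [0, 1)")
        if not 0.0 < self.maf_floor_ancestral < 0.5:
            raise ValueError("maf_floor_ancestral must lie in (0, 0.5)")
        lengths = dict(self.contigs)
        for sw in self.sweep_intervals:
            if sw.contig not in lengths:
                raise ValueError(f"sweep interval on unknown contig {sw.contig!r}")
            if not 0 <= sw.start < sw.end <= lengths[sw.contig]:
                raise ValueError(f"sweep interval outside contig: {sw}")
            if sw.target_pop not in self.pop_names:
                raise ValueError(f"sweep targets unknown population {sw.target_pop!r}")
            if not 0.0 < sw.diversity_scale <= 1.0:
                raise ValueError("diversity_scale must lie in (0, 1]")
            if sw.f_sweep <= self.f_per_pop[self.pop_names.index(sw.target_pop)]:
                raise ValueError("F_sweep must exceed the target population's F")

    def sample_names(self) -> list[str]:
        return [
            f"{pop}_{i}"
            for pop, n in zip(self.pop_names, self.samples_per_pop)
            for i in range(n)
        ]

    def population_map(self) -> dict[str, str]:
        return {
            f"{pop}_{i}": pop
            for pop, n in zip(self.pop_names, self.samples_per_pop)
            for i in range(n)
        }


@dataclass
class SimTruth:
    """Planted parameters of a synthetic dataset, for recovery scoring."""

    contig: np.ndarray  # per-variant contig name
    pos: np.ndarray  # per-variant 1-based position
    ancestral_freqs: np.ndarray  # per-variant, after any sweep rescaling: per-pop below
    pop_freqs: dict[str, np.ndarray]  # realized population frequency per variant
    is_transition: np.ndarray  # per-variant bool
    sweep_intervals: list[SweepInterval]
    f_per_pop: dict[str, float]

    def __post_init__(self) -> None:
        n = len(self.pos)
        for name, arr in self.pop_freqs.items():
            if len(arr) != n:
                raise ValueError(f"pop_freqs[{name!r}] length mismatch")
            if np.any((arr < 0) | (arr > 1)):
                raise ValueError(f"pop_freqs[{name!r}] outside [0, 1]")
        if len(self.is_transition) != n or len(self.ancestral_freqs) != n:
            raise ValueError("truth arrays must all have one row per variant")


def _draw_balding_nichols(
    rng: np.random.Generator, p: np.ndarray, f: float
) -> np.ndarray:
    """Population frequency draw around ancestral *p* with drift *f*."""
    a = p * (1.0 - f) / f
    b = (1.0 - p) * (1.0 - f) / f
    return rng.beta(a, b)


def simulate_dataset(config: SimConfig) -> tuple[GenotypeMatrix, SimTruth]:
    """Generate a genotype matrix plus the ground truth that produced it.

    Identical configs (including seed) give identical output.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    pop_of_sample = np.repeat(
        np.arange(config.n_pops), np.asarray(config.samples_per_pop)
    )
    n_samples = int(pop_of_sample.size)

    records: list[pd.DataFrame] = []
    dosage_blocks: list[np.ndarray] = []
    truth_contig: list[np.ndarray] = []
    truth_pos: list[np.ndarray] = []
    truth_anc: list[np.ndarray] = []
    truth_ts: list[np.ndarray] = []
    truth_pf: dict[str, list[np.ndarray]] = {p: [] for p in config.pop_names}

    p_transition = config.tstv_ratio / (1.0 + config.tstv_ratio)

    for contig, length in config.contigs:
        m = int(round(length * config.snp_density))
        if m == 0:
            continue
        pos = np.sort(rng.choice(length, size=min(m, length), replace=False)) + 1
        m = pos.size

        anc = rng.uniform(
            config.maf_floor_ancestral, 1.0 - config.maf_floor_ancestral, size=m
        )
        is_ts = rng.random(m) < p_transition
        ref = rng.integers(0, 4, size=m)
        ref_bases = np.array(BASES)[ref]
        alt_bases = np.empty(m, dtype="U1")
        tv_choice = rng.integers(0, 2, size=m)
        for j in range(m):
            rb = ref_bases[j]
            alt_bases[j] = (
                TRANSITIONS[rb] if is_ts[j] else TRANSVERSIONS[rb][tv_choice[j]]
            )

        # population frequencies, with sweep rescaling for the target pop
        pop_freq = np.empty((config.n_pops, m))
        for k, (pname, f) in enumerate(zip(config.pop_names, config.f_per_pop)):
            p_k = anc.copy()
            f_k = np.full(m, f)
            for sw in config.sweep_intervals:
                if sw.contig != contig or sw.target_pop != pname:
                    continue
                inside = (pos - 1 >= sw.start) & (pos - 1 < sw.end)
                p_k[inside] = 1.0 - sw.diversity_scale * (1.0 - p_k[inside])
                f_k[inside] = sw.f_sweep
            pop_freq[k] = np.clip(
                _draw_balding_nichols(rng, p_k, f), 1e-9, 1 - 1e-9
            )
            # re-draw sweep sites under the stronger drift coefficient
            for fval in np.unique(f_k[f_k != f]):
                idx = f_k == fval
                pop_freq[k, idx] = np.clip(
                    _draw_balding_nichols(rng, p_k[idx], float(fval)), 1e-9, 1 - 1e-9
                )

        # haplotype copying: latent uniforms persist with prob exp(-d/scale)
        freq_by_sample = pop_freq[pop_of_sample]  # (n_samples, m)
        n_haps = 2 * n_samples
        copy_prob = np.zeros(m)
        if m > 1:
            d = np.diff(pos).astype(float)
            copy_prob[1:] = np.exp(-d / config.ld_block_scale)
        fresh = rng.random((n_haps, m))
        keep = rng.random((n_haps, m)) < copy_prob[None, :]
        u = fresh
        for j in range(1, m):
            u[:, j] = np.where(keep[:, j], u[:, j - 1], u[:, j])
        hap_freq = np.repeat(freq_by_sample, 2, axis=0)
        alleles = (u < hap_freq).astype(np.int8)
        dos = alleles[0::2] + alleles[1::2]

        if config.missing_rate > 0:
            miss = rng.random((n_samples, m)) < config.missing_rate
            dos = np.where(miss, np.int8(MISSING), dos)

        depth = rng.poisson(config.mean_depth_per_sample * n_samples, size=m)
        block = pd.DataFrame(
            {
                "contig": contig,
                "pos": pos.astype(np.int64),
                "ref": ref_bases,
                "alt": alt_bases,
                "depth": depth.astype(np.int64),
                "mq": np.full(m, config.rms_mapping_quality),
                "base_qual": np.full(m, config.mean_base_quality),
            }
        )
        records.append(block)
        dosage_blocks.append(dos)
        truth_contig.append(np.full(m, contig, dtype=object))
        truth_pos.append(pos)
        truth_anc.append(anc)
        truth_ts.append(is_ts)
        for k, pname in enumerate(config.pop_names):
            truth_pf[pname].append(pop_freq[k])

    if not records:
        raise ValueError("configuration produced zero variants")

    variants = pd.concat(records, ignore_index=True)[VARIANT_COLUMNS]
    matrix = GenotypeMatrix(
        samples=config.sample_names(),
        dosages=np.concatenate(dosage_blocks, axis=1),
        variants=variants,
        populations=config.population_map(),
    )
    truth = SimTruth(
        contig=np.concatenate(truth_contig),
        pos=np.concatenate(truth_pos),
        ancestral_freqs=np.concatenate(truth_anc),
        pop_freqs={p: np.concatenate(v) for p, v in truth_pf.items()},
        is_transition=np.concatenate(truth_ts),
        sweep_intervals=list(config.sweep_intervals),
        f_per_pop=dict(zip(config.pop_names, config.f_per_pop)),
    )
    return matrix, truth


# ---------------------------------------------------------------------------
# truth table I/O


def write_truth(truth: SimTruth, path) -> None:
    """Write the planted truth as a TSV with a JSON metadata header line.

    Round-trips losslessly through :func:`read_truth`.
    """
    meta = {
        "sweep_intervals": [
            [sw.contig, sw.start, sw.end, sw.target_pop, sw.f_sweep, sw.diversity_scale]
            for sw in truth.sweep_intervals
        ],
        "f_per_pop": truth.f_per_pop,
        "populations": list(truth.pop_freqs),
    }
    df = pd.DataFrame(
        {
            "contig": truth.contig,
            "pos": truth.pos,
            "ancestral_freq": truth.ancestral_freqs,
            "is_transition": truth.is_transition.astype(int),
            **{f"freq_{p}": v for p, v in truth.pop_freqs.items()},
        }
    )
    with open(path, "w") as fh:
        fh.write("#" + json.dumps(meta, sort_keys=True) + "\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.17g")


def read_truth(path) -> SimTruth:
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("#"):
            raise ValueError(f"{path}: missing truth metadata header")
        meta = json.loads(header[1:])
        df = pd.read_csv(fh, sep="\t")
    return SimTruth(
        contig=df["contig"].to_numpy(dtype=object),
        pos=df["pos"].to_numpy(),
        ancestral_freqs=df["ancestral_freq"].to_numpy(),
        pop_freqs={p: df[f"freq_{p}"].to_numpy() for p in meta["populations"]},
        is_transition=df["is_transition"].to_numpy().astype(bool),
        sweep_intervals=[SweepInterval(*row) for row in meta["sweep_intervals"]],
        f_per_pop=meta["f_per_pop"],
    )


# ---------------------------------------------------------------------------
# toy gene models + reference sequence (for annotation and gene assignment)


def simulate_sequences(
    contigs: list[tuple[str, int]], seed: int
) -> dict[str, str]:
    """Random reference sequence per contig (uniform base composition)."""
    rng = np.random.default_rng(seed)
    out = {}
    for name, length in contigs:
        out[name] = "".join(
            np.array(BASES)[rng.integers(0, 4, size=length)]
        )
    return out


def simulate_gene_models(
    contigs: list[tuple[str, int]], n_genes: int, seed: int
):
    """Place non-overlapping toy transcripts on the contigs.

    Genes are laid out in equal slots along each contig, with 1–3 exons of
    codon-multiple length (so every CDS translates cleanly) separated by
    introns of at least 60 bp; strands alternate so both are represented.
    Returns a list of :class:`~popsweep.annotate.GeneModel`.
    """
    from .annotate import GeneModel

    if n_genes < 0:
        raise ValueError("n_genes must be non-negative")
    if n_genes == 0:
        return []
    rng = np.random.default_rng(seed)
    total = sum(length for _, length in contigs)
    genes: list[GeneModel] = []
    gi = 0
    # allocate genes to contigs proportionally to length, at least the
    # remainder going to the largest contig
    alloc = [int(round(n_genes * length / total)) for _, length in contigs]
    while sum(alloc) < n_genes:
        alloc[int(np.argmax([l for _, l in contigs]))] += 1
    while sum(alloc) > n_genes:
        alloc[int(np.argmax(alloc))] -= 1
    for (name, length), n_c in zip(contigs, alloc):
        if n_c == 0:
            continue
        slot = length // n_c
        if slot < 800:
            raise ValueError(
                f"contig {name!r} too short for {n_c} genes (slot {slot} bp)"
            )
        for i in range(n_c):
            margin = 100
            start = i * slot + margin + int(rng.integers(0, slot // 4))
            n_exons = int(rng.integers(1, 4))
            exons = []
            cursor = start
            budget = (i + 1) * slot - margin
            for e in range(n_exons):
                ex_len = 3 * int(rng.integers(10, 51))  # 30–150 bp, codon-multiple
                if cursor + ex_len > budget:
                    break
                exons.append((cursor + 1, cursor + ex_len))  # to 1-based inclusive
                cursor += ex_len + 60 + int(rng.integers(0, 241))  # intron 60–300
            if not exons:
                exons = [(start + 1, start + 30)]
            strand = "+" if gi % 2 == 0 else "-"
            genes.append(
                GeneModel(
                    gene_id=f"gene{gi:04d}",
                    contig=name,
                    strand=strand,
                    exons=exons,
                    cds=list(exons),
                )
            )
            gi += 1
    return genes


def write_fasta(sequences: dict[str, str], path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
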