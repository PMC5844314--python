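"""End-to-end orchestration: simulate → filter → annotate → scan → report.

All randomness flows from one root seed, split deterministically per stage
(stage seeds are recorded in the run manifest), so a rerun with the same
config and inputs is byte-identical.  The scan follows a three-population
convention: the *target* population is screened against the *reference*
panel; an optional *outgroup* participates in the tree/PCA/LD stages only.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import annotate as ann
from . import enrich as enr
from . import ld as ldmod
from . import phylo, scan, sim, variants, vcfio
from .matrix import GenotypeMatrix

logger = logging.getLogger(__name__)

_STAGE_SEED_SALT = {
    "simulate": 1,
    "ld": 2,
    "bootstrap": 3,
    "null": 4,
}


def stage_seed(root_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the root seed."""
    return (root_seed * 1_000_003 + _STAGE_SEED_SALT[stage] * 7919) % (2**31 - 1)


@dataclass
class PipelineConfig:
    """Inputs, population roles and stage parameters of one run."""

    vcf: str | None = None
    gff3: str | None = None
    population_map: str | None = None
    reference_fasta: str | None = None
    term_map: str | None = None

    target_pop: str = "target"
    reference_pop: str = "reference"
    outgroup_pop: str | None = "outgroup"

    filter_criteria: variants.FilterCriteria = field(default_factory=variants.FilterCriteria)
    window_size: int = scan.WINDOW_SIZE
    window_step: int = scan.WINDOW_STEP
    top_frac: float = scan.TOP_FRAC
    log_transform_fst: bool = True
    joint_outliers: bool = True

    ld_max_distance: int = ldmod.MAX_DISTANCE
    ld_bin_width: int = ldmod.DEFAULT_BIN_WIDTH
    ld_max_pairs_per_bin: int | None = 50_000

    bootstrap_replicates: int = 100
    pca_components: int = 10

    seed: int = 0
    out_dir: str = "popsweep_out"

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        fc = d.pop("filter_criteria", None)
        cfg = cls(**d)
        if fc:
            cfg.filter_criteria = variants.FilterCriteria(**fc)
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


def _validate(config: PipelineConfig, matrix: GenotypeMatrix) -> None:
    pops = set(matrix.population_labels())
    for role, name in (
        ("target", config.target_pop),
        ("reference", config.reference_pop),
    ):
        if name not in pops:
            raise ValueError(
                f"{role} population {name!r} absent from population map "
                f"(found: {sorted(pops)})"
            )
    if config.outgroup_pop is not None and config.outgroup_pop not in pops:
        raise ValueError(f"outgroup population {config.outgroup_pop!r} absent from map")


def run_pipeline(
    config: PipelineConfig, matrix: GenotypeMatrix | None = None
) -> Path:
    """Run every stage and write the output set; returns the output dir.

    If *matrix* is not supplied it is read from ``config.vcf`` +
    ``config.population_map``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    if matrix is None:
        if config.vcf is None or config.population_map is None:
            raise ValueError("config must name a VCF and a population map")
        matrix = vcfio.read_vcf(config.vcf, config.population_map)
    _validate(config, matrix)

    genes: list[ann.GeneModel] = []
    sequences = None
    if config.gff3:
        genes = ann.read_gff3(config.gff3)
    if config.reference_fasta:
        sequences = sim.read_fasta(config.reference_fasta)

    manifest: dict = {
        "config": config.to_dict(),
        "stage_seeds": {
            s: stage_seed(config.seed, s) for s in ("ld", "bootstrap")
        },
        "counts": {"input_variants": matrix.n_variants, "samples": matrix.n_samples},
    }

    # -- filter ---------------------------------------------------------
    filtered, report = variants.apply_filters(matrix, config.filter_criteria)
    report.to_frame().to_csv(out / "filter_report.tsv", sep="\t", index=False)
    vcfio.write_vcf(filtered, out / "filtered.vcf")
    manifest["counts"]["filtered_variants"] = filtered.n_variants
    n_ts, n_tv, tstv = variants.matrix_ts_tv(filtered)
    manifest["counts"]["transitions"] = n_ts
    manifest["counts"]["transversions"] = n_tv
    manifest["counts"]["tstv_ratio"] = tstv

    # -- annotate -------------------------------------------------------
    if genes:
        annotations = ann.annotate_matrix(filtered, genes, sequences)
        annotations.to_csv(out / "annotations.tsv", sep="\t", index=False)
        manifest["counts"]["annotation_categories"] = (
            ann.category_counts(annotations).to_dict()
        )

    # -- sweep scan -----------------------------------------------------
    contig_lengths = _contig_lengths(config, filtered)
    stats = scan.window_scan(
        filtered,
        config.target_pop,
        config.reference_pop,
        contig_lengths,
        size=config.window_size,
        step=config.window_step,
    )
    scored, regions = scan.call_sweep_regions(
        stats,
        top_frac=config.top_frac,
        log_transform_fst=config.log_transform_fst,
        joint=config.joint_outliers,
    )
    scored.to_csv(out / "window_stats.tsv", sep="\t", index=False, float_format="%.6g")
    regions, sweep_genes = scan.assign_genes(regions, genes)
    scan.regions_to_bed(regions).to_csv(
        out / "sweep_regions.bed", sep="\t", index=False, header=False
    )
    pd.DataFrame({"gene_id": sweep_genes}).to_csv(
        out / "sweep_genes.tsv", sep="\t", index=False
    )
    manifest["counts"]["windows"] = len(scored)
    manifest["counts"]["outlier_windows"] = int(scored["is_outlier"].sum())
    manifest["counts"]["sweep_regions"] = len(regions)
    manifest["counts"]["sweep_genes"] = len(sweep_genes)

    # -- tree -----------------------------------------------------------
    tree = phylo.bootstrap_supports(
        filtered,
        n_replicates=config.bootstrap_replicates,
        seed=stage_seed(config.seed, "bootstrap"),
    )
    phylo.write_newick(tree, out / "tree.nwk")
    with open(out / "distances.phylip", "w") as fh:
        fh.write(phylo.to_phylip(phylo.p_distance(filtered)))

    # -- PCA ------------------------------------------------------------
    pca_res = phylo.pca(filtered, n_components=config.pca_components)
    coords = pd.DataFrame(
        pca_res.coordinates,
        columns=[f"PC{i + 1}" for i in range(pca_res.coordinates.shape[1])],
    )
    coords.insert(0, "sample", pca_res.ids)
    coords.insert(
        1, "population", [filtered.populations.get(s, "") for s in pca_res.ids]
    )
    coords.to_csv(out / "pca.tsv", sep="\t", index=False, float_format="%.6g")
    pd.DataFrame(
        {
            "component": np.arange(1, len(pca_res.eigenvalues) + 1),
            "eigenvalue": pca_res.eigenvalues,
            "variance_explained": pca_res.variance_explained,
        }
    ).to_csv(out / "pca_eigenvalues.tsv", sep="\t", index=False, float_format="%.6g")

    # -- LD decay per population ---------------------------------------
    ld_tables = []
    for pop in filtered.population_labels():
        curve = ldmod.decay_curve(
            filtered,
            population=pop,
            max_distance=config.ld_max_distance,
            bin_width=config.ld_bin_width,
            seed=stage_seed(config.seed, "ld"),
            max_pairs_per_bin=config.ld_max_pairs_per_bin,
        )
        t = ldmod.curve_to_frame(curve)
        t.insert(0, "population", pop)
        ld_tables.append(t)
        hd = ldmod.half_decay_distance(curve)
        manifest["counts"].setdefault("ld_half_decay_bp", {})[pop] = hd
    pd.concat(ld_tables, ignore_index=True).to_csv(
        out / "ld_decay.tsv", sep="\t", index=False, float_format="%.6g"
    )

    # -- enrichment -----------------------------------------------------
    if config.term_map:
        tm = enr.TermMap.from_table(config.term_map)
        res = enr.binomial_enrichment(sweep_genes, tm)
        res.to_csv(out / "enrichment.tsv", sep="\t", index=False, float_format="%.6g")
        manifest["counts"]["enriched_terms_p05"] = int((res["p_value"] < 0.05).sum())

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    return out


def _contig_lengths(config: PipelineConfig, matrix: GenotypeMatrix) -> dict[str, int]:
    """Contig lengths from the VCF header when available, else max position."""
    if config.vcf:
        lengths = {}
        with open(config.vcf) as fh:
            for line in fh:
                if line.startswith("##contig"):
                    fields = dict(
                        kv.split("=")
                        for kv in line.strip()[len("##contig=<") : -1].split(",")
                    )
                    lengths[fields["ID"]] = int(fields["length"])
                elif not line.startswith("#"):
                    break
        if lengths:
            return lengths
    return {
        c: int(matrix.variants.loc[matrix.variants["contig"] == c, "pos"].max())
        for c in matrix.contigs
    }


# ---------------------------------------------------------------------------
# recovery scoring against simulation truth


def _interval_union(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    merged: list[list[int]] = []
    for s, e in sorted(intervals):
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def _overlap_bp(a: list[tuple[int, int]], b: list[tuple[int, int]]) -> int:
    total = 0
    for s1, e1 in a:
        for s2, e2 in b:
            total += max(0, min(e1, e2) - max(s1, s2))
    return total


def sweep_jaccard(
    regions: list[scan.SweepRegion], truth: sim.SimTruth, contig: str | None = None
) -> float | None:
    """Base-pair Jaccard between called regions and planted intervals.

    ``None`` when the truth contains no sweep (overlap undefined).
    """
    planted = [
        (sw.start, sw.end)
        for sw in truth.sweep_intervals
        if contig is None or sw.contig == contig
    ]
    if not planted:
        return None
    called = [
        (r.start, r.end) for r in regions if contig is None or r.contig == contig
    ]
    planted = _interval_union(planted)
    called = _interval_union(called)
    inter = _overlap_bp(planted, called)
    size = lambda ivs: sum(e - s for s, e in ivs)  # noqa: E731
    union = size(planted) + size(called) - inter
    return inter / union if union else 0.0


def pc1_silhouette(
    pca_res: phylo.PCAResult, populations: dict[str, str], pops: tuple[str, str]
) -> float:
    """Mean silhouette coefficient of two populations along PC1."""
    labels = np.array([populations.get(s) for s in pca_res.ids])
    mask = np.isin(labels, pops)
    x = pca_res.coordinates[mask, 0]
    y = labels[mask]
    sil = []
    for i in range(x.size):
        d = np.abs(x[i] - x)
        n_same = int((y == y[i]).sum())
        a = d[y == y[i]].sum() / (n_same - 1) if n_same > 1 else 0.0
        b = d[y != y[i]].mean()
        sil.append((b - a) / max(a, b) if max(a, b) > 0 else 0.0)
    return float(np.mean(sil))


def score_recovery(
    matrix: GenotypeMatrix,
    truth: sim.SimTruth,
    config: PipelineConfig,
    scored: pd.DataFrame,
    regions: list[scan.SweepRegion],
    pca_res: phylo.PCAResult,
) -> dict:
    """Recovery report: how well the analysis re-finds the planted truth."""
    f_t = truth.f_per_pop[config.target_pop]
    f_r = truth.f_per_pop[config.reference_pop]
    expected_fst = 0.5 * (f_t + f_r)
    # background windows only: exclude any overlapping a planted sweep
    bg = np.ones(len(scored), dtype=bool)
    for sw in truth.sweep_intervals:
        hit = (
            (scored["contig"] == sw.contig)
            & (scored["start"] < sw.end)
            & (scored["end"] > sw.start)
        ).to_numpy()
        bg &= ~hit
    mean_fst = float(np.nanmean(scored.loc[bg, "fst"]))

    n_ts, n_tv, tstv = variants.matrix_ts_tv(matrix)
    truth_ts = int(truth.is_transition.sum())
    truth_tv = len(truth.is_transition) - truth_ts

    return {
        "sweep_jaccard": sweep_jaccard(regions, truth),
        "mean_background_fst": mean_fst,
        "expected_fst": expected_fst,
        "fst_bias": mean_fst - expected_fst,
        "tstv_observed": tstv,
        "tstv_truth_labels": truth_ts / truth_tv if truth_tv else None,
        "pc1_silhouette": pc1_silhouette(
            pca_res, matrix.populations, (config.target_pop, config.reference_pop)
        ),
    }
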