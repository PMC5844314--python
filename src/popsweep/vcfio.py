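"""VCF and population-map I/O.

Reading goes through cyvcf2; writing emits plain VCF v4.2 text with
deterministic formatting so that identically-seeded runs are
byte-identical.  Only the fields the pipeline consumes are carried:
diploid GT per sample and the per-site INFO keys ``DP`` (total depth),
``MQ`` (root-mean-square mapping quality) and ``BQ`` (mean Phred base
quality of the variant allele).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .matrix import MISSING, VARIANT_COLUMNS, GenotypeMatrix

_GT_STRINGS = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def read_population_map(path) -> dict[str, str]:
    """Read a two-column sample <TAB> population table."""
    df = pd.read_csv(path, sep="\t", header=None, names=["sample", "population"],
                     dtype=str, comment="#")
    return dict(zip(df["sample"], df["population"]))


def write_population_map(populations: dict[str, str], path) -> None:
    with open(path, "w") as fh:
        for sample, pop in populations.items():
            fh.write(f"{sample}\t{pop}\n")


def read_vcf(path, population_map: dict[str, str] | str) -> GenotypeMatrix:
    """Load a multi-sample VCF into a :class:`GenotypeMatrix`.

    Parameters
    ----------
    path
        VCF file (plain or bgzipped).
    population_map
        ``{sample: population}`` dict, or path to a two-column TSV.

    Raises
    ------
    ValueError
        If any VCF sample is absent from the population map, or a record
        cannot be parsed.
    """
    if not isinstance(population_map, dict):
        population_map = read_population_map(population_map)

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    absent = [s for s in samples if s not in population_map]
    if absent:
        raise ValueError(f"samples missing from population map: {absent}")

    rows = []
    dosage_cols = []
    for i, rec in enumerate(vcf):
        try:
            alt = ",".join(rec.ALT) if rec.ALT else "."
            # gt_types: 0=hom-ref 1=het 2=unknown 3=hom-alt
            gt = rec.gt_types
            dos = np.select(
                [gt == 0, gt == 1, gt == 3], [0, 1, 2], default=MISSING
            ).astype(np.int8)
            rows.append(
                (
                    rec.CHROM,
                    rec.POS,
                    rec.REF,
                    alt,
                    int(rec.INFO.get("DP", 0)),
                    float(rec.INFO.get("MQ", np.nan)),
                    float(rec.INFO.get("BQ", np.nan)),
                )
            )
            dosage_cols.append(dos)
        except Exception as exc:  # pragma: no cover - malformed input
            raise ValueError(f"{path}: cannot parse record {i + 1}: {exc}") from exc
    vcf.close()

    variants = pd.DataFrame(rows, columns=VARIANT_COLUMNS)
    dosages = (
        np.stack(dosage_cols, axis=1)
        if dosage_cols
        else np.empty((len(samples), 0), dtype=np.int8)
    )
    return GenotypeMatrix(
        samples=samples,
        dosages=dosages,
        variants=variants,
        populations={s: population_map[s] for s in samples},
    )


def write_vcf(matrix: GenotypeMatrix, path, contig_lengths: dict[str, int] | None = None) -> None:
    """Write the matrix as uncompressed VCF v4.2 text."""
    lines = [
        "##fileformat=VCFv4.2",
        "##source=popsweep",
        '##INFO=<ID=DP,Number=1,Type=Integer,Description="Total read depth across samples">',
        '##INFO=<ID=MQ,Number=1,Type=Float,Description="Root-mean-square mapping quality">',
        '##INFO=<ID=BQ,Number=1,Type=Float,Description="Mean Phred base quality of the variant allele">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
    ]
    if contig_lengths:
        for name, length in contig_lengths.items():
            lines.append(f"##contig=<ID={name},length={length}>")
    else:
        for name in matrix.contigs:
            end = int(matrix.variants.loc[matrix.variants["contig"] == name, "pos"].max())
            lines.append(f"##contig=<ID={name},length={end}>")
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(matrix.samples)
    )
    v = matrix.variants
    for j in range(matrix.n_variants):
        info = (
            f"DP={int(v['depth'].iat[j])};"
            f"MQ={v['mq'].iat[j]:g};BQ={v['base_qual'].iat[j]:g}"
        )
        gts = "\t".join(_GT_STRINGS[int(d)] for d in matrix.dosages[:, j])
        lines.append(
            f"{v['contig'].iat[j]}\t{int(v['pos'].iat[j])}\t.\t"
            f"{v['ref'].iat[j]}\t{v['alt'].iat[j]}\t.\tPASS\t{info}\tGT\t{gts}"
        )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
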