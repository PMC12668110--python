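"""File-format readers and writers.

Genotypes move as VCF (GT or DS fields, via cyvcf2) or as a plain TSV
dosage matrix; phenotypes, covariates, scores and results are TSV; peaks
are BED (0-based half-open); motifs are position-count-matrix text files
(">ID TF" header, one row of four A C G T counts per position); reference
windows come from FASTA via pyfaidx.  Dosages are always oriented to the
minor allele on read: when the stored allele's frequency exceeds 0.5 the
dosage is flipped to 2 - d.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .genotypes import GenotypeMatrix
from .tfpartition import MotifModel

logger = logging.getLogger("pgsepi")

FLOAT_FMT = "%.10g"


# ---------------------------------------------------------------------------
# genotypes

def read_genotypes(path: str | Path, fmt: str | None = None) -> GenotypeMatrix:
    path = Path(path)
    if fmt is None:
        fmt = "vcf" if path.suffix in {".vcf", ".gz", ".bcf"} or path.name.endswith(".vcf.gz") else "tsv"
    if fmt == "vcf":
        return _read_vcf(path)
    if fmt == "tsv":
        return _read_dosage_tsv(path)
    raise ValueError(f"unknown genotype format {fmt!r}")


def _read_vcf(path: Path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    dosage_rows, chroms, poss, ids = [], [], [], []
    for i, v in enumerate(vcf):
        ds = v.format("DS")
        if ds is not None:
            row = np.asarray(ds, float).reshape(-1)
        else:
            gts = np.asarray(v.genotypes, dtype=object)
            alleles = np.array([[g[0], g[1]] for g in gts], float)
            if np.any((alleles > 1) & (alleles >= 0)):
                raise ValueError(f"mixed ploidy / multi-allelic record at line {i + 1}")
            alleles[alleles < 0] = np.nan
            row = alleles.sum(axis=1)
        if np.nanmax(row, initial=0.0) > 2.0 or np.nanmin(row, initial=0.0) < 0.0:
            raise ValueError(f"dosage outside [0, 2] at record {i + 1} ({v.ID})")
        dosage_rows.append(row)
        chroms.append(int(str(v.CHROM).removeprefix("chr")))
        poss.append(v.POS)
        ids.append(v.ID or f"snp{v.CHROM}_{v.POS}")
    if not dosage_rows:
        raise ValueError(f"no variant records in {path}")
    dosages = np.vstack(dosage_rows).T  # individuals x variants
    return _finalise_matrix(dosages, np.array(chroms), np.array(poss), np.array(ids, object))


def _read_dosage_tsv(path: Path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t")
    meta_cols = ["variant_id", "chrom", "pos"]
    for c in meta_cols:
        if c not in df.columns:
            raise ValueError(f"dosage TSV must contain column {c!r}")
    sample_cols = [c for c in df.columns if c not in meta_cols]
    dosages = df[sample_cols].to_numpy(float).T
    return _finalise_matrix(
        dosages,
        df["chrom"].to_numpy(int),
        df["pos"].to_numpy(np.int64),
        df["variant_id"].to_numpy(object),
    )


def _finalise_matrix(dosages, chrom, pos, ids) -> GenotypeMatrix:
    missing = np.isnan(dosages)
    missing_rate = missing.mean(axis=0)
    with np.errstate(invalid="ignore"):
        freq = np.nanmean(dosages, axis=0) / 2.0
    flip = freq > 0.5
    if flip.any():
        logger.info("flipping %d variants to minor-allele orientation", flip.sum())
        dosages[:, flip] = 2.0 - dosages[:, flip]
        freq = np.where(flip, 1.0 - freq, freq)
    order = np.lexsort((pos, chrom))
    return GenotypeMatrix(
        dosages=dosages[:, order],
        chrom=chrom[order],
        pos=pos[order],
        variant_id=ids[order],
        maf=freq[order],
        info=np.ones(len(order)),
        missing_rate=missing_rate[order],
    )


def write_genotypes_tsv(G: GenotypeMatrix, path: str | Path, sample_ids=None) -> None:
    n = G.n_individuals
    if sample_ids is None:
        sample_ids = [f"sample_{i}" for i in range(n)]
    meta = pd.DataFrame(
        {"variant_id": G.variant_id, "chrom": G.chrom, "pos": G.pos}
    )
    samples = pd.DataFrame(G.dosages.T, columns=list(sample_ids))
    pd.concat([meta, samples], axis=1).to_csv(
        path, sep="\t", index=False, float_format=FLOAT_FMT
    )


def write_genotypes_vcf(G: GenotypeMatrix, path: str | Path, sample_ids=None) -> None:
    """Plain-text VCF with a DS FORMAT field (dosage of the stored allele)."""
    n = G.n_individuals
    if sample_ids is None:
        sample_ids = [f"sample_{i}" for i in range(n)]
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,Description="Dosage">\n')
        for c in np.unique(G.chrom):
            fh.write(f"##contig=<ID={c}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(sample_ids)
            + "\n"
        )
        for j in range(G.n_variants):
            ds = "\t".join(
                "." if np.isnan(d) else f"{d:.6g}" for d in G.dosages[:, j]
            )
            fh.write(
                f"{G.chrom[j]}\t{G.pos[j]}\t{G.variant_id[j]}\tA\tC\t.\tPASS\t.\tDS\t{ds}\n"
            )


# ---------------------------------------------------------------------------
# tables

def read_phenotype_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise ValueError("phenotype TSV needs a sample-ID column and a value column")
    return df


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


# ---------------------------------------------------------------------------
# annotations

def read_bed(path: str | Path) -> dict[str, np.ndarray]:
    """Read a BED file into chrom -> (n_intervals, 2) arrays of 0-based
    half-open [start, end) intervals, sorted by start."""
    rows: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            chrom = parts[0].removeprefix("chr")
            rows.setdefault(chrom, []).append((int(parts[1]), int(parts[2])))
    return {
        c: np.array(sorted(iv), dtype=np.int64).reshape(-1, 2)
        for c, iv in rows.items()
    }


def annotate_positions(
    intervals: dict[str, np.ndarray], chrom: np.ndarray, pos: np.ndarray
) -> np.ndarray:
    """Binary overlap indicator for 1-based positions against BED intervals.

    A position p overlaps [start, end) iff start + 1 <= p <= end.
    """
    out = np.zeros(len(pos), dtype=int)
    for c in np.unique(chrom):
        iv = intervals.get(str(c))
        if iv is None or len(iv) == 0:
            continue
        mask = chrom == c
        p = pos[mask]
        hit = np.zeros(len(p), bool)
        for start, end in iv:
            hit |= (p >= start + 1) & (p <= end)
        out[mask] = hit.astype(int)
    return out


def read_pcm(path: str | Path) -> list[MotifModel]:
    """HOCOMOCO-style position count matrices: a ">MOTIF_ID [TF]" header
    followed by one whitespace-separated row of A C G T counts per
    position."""
    motifs: list[MotifModel] = []
    name, tf, rows = None, "", []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                if name is not None and rows:
                    motifs.append(MotifModel(name, tf or name, np.array(rows, float)))
                header = line[1:].split()
                name = header[0]
                tf = header[1] if len(header) > 1 else name.split("_")[0]
                rows = []
            else:
                vals = [float(x) for x in line.split()]
                if len(vals) != 4:
                    raise ValueError(f"PCM row must have 4 counts, got {line!r}")
                rows.append(vals)
    if name is not None and rows:
        motifs.append(MotifModel(name, tf or name, np.array(rows, float)))
    if not motifs:
        raise ValueError(f"no motifs found in {path}")
    return motifs


def fetch_window(fasta_path: str | Path, chrom: str, pos: int, width: int = 60) -> str:
    """Extract a ``width``-bp window centred on a 1-based position."""
    from pyfaidx import Fasta

    fa = Fasta(str(fasta_path))
    half = width // 2
    start = max(0, pos - 1 - half)
    seq = fa[str(chrom)][start : start + width]
    return str(seq)


# ---------------------------------------------------------------------------
# configuration

@dataclasses.dataclass
class PipelineConfig:
    """Paths, thresholds and seeds driving a full pipeline run."""

    genotypes: str = ""
    phenotype: str = ""
    covariates: str = ""
    output_dir: str = "pgsepi_out"
    peaks: str = ""
    motifs: str = ""
    fasta: str = ""
    significance_p: float = 5e-8
    tf_significance_p: float = 1e-5
    clump_r2_loose: float = 0.90
    clump_r2_standard: float = 0.10
    tag_r2: float = 0.75
    pairwise_tag_r2: float = 0.80
    window: int = 1_000_000
    maf_min: float = 0.001
    missing_max: float = 0.05
    hwe_p_min: float = 1e-10
    info_min: float = 0.8
    seed: int = 0
    run_pairwise: bool = True
    run_tf: bool = False

    def __post_init__(self) -> None:
        for name in ("significance_p", "tf_significance_p", "clump_r2_loose",
                     "clump_r2_standard", "tag_r2", "pairwise_tag_r2",
                     "maf_min", "missing_max", "hwe_p_min", "info_min"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} out of range: {v}")

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))
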