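"""Readers and writers for on-disk formats plus the shared genomic data model.

All internal coordinates are 0-based half-open (BED convention). Coverage
files in the wild come in two dialects: bismark's 1-based inclusive
``chrom start end pct meth unmeth`` and a 0-based half-open variant; the
reader converts on ingest according to a dialect flag.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

GENOTYPES = ("WT", "KO")
TREATMENTS = ("saline", "HDM")

COVERAGE_DIALECTS = ("bismark-1-based", "bed-0-based")


class FormatError(ValueError):
    """A file does not conform to its declared format."""


class ConfigurationError(ValueError):
    """Inputs are inconsistent with the sample design or configuration."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A genomic interval, 0-based half-open, with optional name and strand."""

    chrom: str
    start: int
    end: int
    name: str | None = field(default=None, compare=False)
    strand: str = field(default=".", compare=False)

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"interval start must be < end, got [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.start + self.end)

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def distance_to(self, other: "GenomicInterval") -> int | None:
        """Gap in bp between interval boundaries; 0 if overlapping, None if
        on different chromosomes."""
        if self.chrom != other.chrom:
            return None
        if self.overlaps(other):
            return 0
        if self.end <= other.start:
            return other.start - self.end
        return self.start - other.end


@dataclass
class SampleDesign:
    """Sample sheet: one row per sample with genotype and treatment factors."""

    frame: pd.DataFrame  # columns: sample, genotype, treatment

    def __post_init__(self) -> None:
        required = {"sample", "genotype", "treatment"}
        missing = required - set(self.frame.columns)
        if missing:
            raise ConfigurationError(f"sample sheet missing columns: {sorted(missing)}")
        if self.frame["sample"].duplicated().any():
            dups = self.frame.loc[self.frame["sample"].duplicated(), "sample"]
            raise ConfigurationError(f"duplicate sample ids: {sorted(set(dups))}")
        bad_g = set(self.frame["genotype"]) - set(GENOTYPES)
        bad_t = set(self.frame["treatment"]) - set(TREATMENTS)
        if bad_g:
            raise ConfigurationError(f"unknown genotype values: {sorted(bad_g)}")
        if bad_t:
            raise ConfigurationError(f"unknown treatment values: {sorted(bad_t)}")
        self.frame = self.frame.reset_index(drop=True)

    @property
    def samples(self) -> list[str]:
        return list(self.frame["sample"])

    def group_samples(self, genotype: str, treatment: str) -> list[str]:
        m = (self.frame["genotype"] == genotype) & (self.frame["treatment"] == treatment)
        return list(self.frame.loc[m, "sample"])

    def genotype_of(self, sample: str) -> str:
        row = self.frame.loc[self.frame["sample"] == sample]
        if row.empty:
            raise KeyError(sample)
        return str(row["genotype"].iloc[0])

    def parse_contrast(self, contrast: str) -> tuple[list[str], list[str]]:
        """Parse e.g. ``KO_HDM:WT_HDM`` into (groupA samples, groupB samples)."""
        try:
            a, b = contrast.split(":")
            ga, ta = a.split("_")
            gb, tb = b.split("_")
        except ValueError as exc:
            raise ConfigurationError(f"malformed contrast {contrast!r}") from exc
        sa = self.group_samples(ga, ta)
        sb = self.group_samples(gb, tb)
        if not sa or not sb:
            raise ConfigurationError(f"contrast {contrast!r} selects an empty group")
        return sa, sb


@dataclass
class CpGCountTable:
    """Per-CpG methylated/total counts for all samples, merged on position.

    ``meth`` and ``depth`` are (n_sites, n_samples) integer arrays aligned to
    ``chrom``/``pos`` rows and ``samples`` columns. Sites absent from a
    sample's coverage file carry depth 0 there.
    """

    chrom: np.ndarray  # (n_sites,) str
    pos: np.ndarray  # (n_sites,) int, 0-based CpG start
    samples: list[str]
    meth: np.ndarray  # (n_sites, n_samples) int
    depth: np.ndarray  # (n_sites, n_samples) int

    def __post_init__(self) -> None:
        if np.any(self.meth > self.depth) or np.any(self.meth < 0):
            raise ValueError("counts must satisfy 0 <= methylated <= depth")
        # strictly increasing positions within each chromosome
        for c in pd.unique(self.chrom):
            p = self.pos[self.chrom == c]
            if np.any(np.diff(p) <= 0):
                raise ValueError(f"positions not strictly increasing on {c}")

    @property
    def n_sites(self) -> int:
        return len(self.pos)

    def sample_index(self, sample: str) -> int:
        return self.samples.index(sample)

    def subset_samples(self, keep: Sequence[str]) -> "CpGCountTable":
        idx = [self.samples.index(s) for s in keep]
        return CpGCountTable(
            self.chrom, self.pos, list(keep), self.meth[:, idx], self.depth[:, idx]
        )


@dataclass
class ExpressionMatrix:
    """Probe x sample intensity matrix with probe genomic coordinates.

    ``probes`` has columns probe, chrom, start, end, testable; probes lacking
    coordinates are retained with testable=False (they cannot enter a cis
    scan but still count in genome-wide contrasts).
    """

    values: pd.DataFrame  # index: probe ids, columns: sample ids
    probes: pd.DataFrame  # columns: probe, chrom, start, end, testable

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            dups = self.values.index[self.values.index.duplicated()]
            raise FormatError(f"duplicated probe ids: {sorted(set(dups))[:5]}")
        self.probes = self.probes.set_index("probe", drop=False).loc[self.values.index]

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    def probe_interval(self, probe: str) -> GenomicInterval | None:
        row = self.probes.loc[probe]
        if not bool(row["testable"]):
            return None
        return GenomicInterval(str(row["chrom"]), int(row["start"]), int(row["end"]), name=probe)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_sample_sheet(path: str | Path) -> SampleDesign:
    frame = pd.read_csv(path, sep="\t", dtype=str)
    return SampleDesign(frame)


def write_sample_sheet(design: SampleDesign, path: str | Path) -> None:
    design.frame.to_csv(path, sep="\t", index=False)


def read_coverage(
    paths: Mapping[str, str | Path],
    design: SampleDesign,
    dialect: str = "bismark-1-based",
) -> CpGCountTable:
    """Merge per-sample coverage files into one multi-sample count table.

    ``paths`` maps sample id -> coverage file. Every sample in the design
    must have a file. Rows with zero total depth across all samples are
    dropped (counted in the log). The bismark dialect stores 1-based
    inclusive coordinates; they are converted to 0-based on ingest.
    """
    if dialect not in COVERAGE_DIALECTS:
        raise ConfigurationError(f"unknown coverage dialect {dialect!r}")
    missing = [s for s in design.samples if s not in paths]
    if missing:
        raise ConfigurationError(f"no coverage file for samples: {missing}")

    per_sample: dict[str, pd.DataFrame] = {}
    for sample in design.samples:
        p = Path(paths[sample])
        if not p.exists():
            raise FileNotFoundError(p)
        df = _read_one_coverage(p, dialect)
        per_sample[sample] = df

    keys = sorted(
        set().union(*(set(zip(df["chrom"], df["pos"])) for df in per_sample.values()))
        if per_sample
        else set()
    )
    if not keys:
        return CpGCountTable(
            np.array([], dtype=object),
            np.array([], dtype=int),
            design.samples,
            np.zeros((0, len(design.samples)), dtype=int),
            np.zeros((0, len(design.samples)), dtype=int),
        )
    index = pd.MultiIndex.from_tuples(keys, names=["chrom", "pos"])
    n = len(index)
    meth = np.zeros((n, len(design.samples)), dtype=int)
    depth = np.zeros_like(meth)
    for j, sample in enumerate(design.samples):
        df = per_sample[sample].set_index(["chrom", "pos"])
        aligned = df.reindex(index)
        m = aligned["meth"].to_numpy()
        d = aligned["depth"].to_numpy()
        meth[:, j] = np.nan_to_num(m, nan=0.0).astype(int)
        depth[:, j] = np.nan_to_num(d, nan=0.0).astype(int)

    total = depth.sum(axis=1)
    n_dropped = int((total == 0).sum())
    if n_dropped:
        logger.info("dropping %d sites with zero depth in all samples", n_dropped)
    keep = total > 0
    chrom = np.array([k[0] for k in keys], dtype=object)[keep]
    pos = np.array([k[1] for k in keys], dtype=int)[keep]
    return CpGCountTable(chrom, pos, design.samples, meth[keep], depth[keep])


def _read_one_coverage(path: Path, dialect: str) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 6:
                raise FormatError(
                    f"{path}:{lineno}: expected 6 tab-separated columns, got {len(fields)}"
                )
            chrom, start, _end, _pct, m, u = fields
            try:
                start_i, m_i, u_i = int(start), int(m), int(u)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer field") from exc
            if m_i < 0 or u_i < 0:
                raise FormatError(f"{path}:{lineno}: negative count")
            pos = start_i - 1 if dialect == "bismark-1-based" else start_i
            rows.append((chrom, pos, m_i, m_i + u_i))
    df = pd.DataFrame(rows, columns=["chrom", "pos", "meth", "depth"])
    if df.duplicated(["chrom", "pos"]).any():
        raise FormatError(f"{path}: duplicate CpG positions")
    return df


def write_coverage(
    table: CpGCountTable, sample: str, path: str | Path, dialect: str = "bismark-1-based"
) -> None:
    """Write one sample's counts back to a coverage TSV (sites with depth 0
    for this sample are omitted, as a real coverage file would)."""
    j = table.sample_index(sample)
    with open(path, "w") as fh:
        for i in range(table.n_sites):
            d = int(table.depth[i, j])
            if d == 0:
                continue
            m = int(table.meth[i, j])
            pos = int(table.pos[i])
            if dialect == "bismark-1-based":
                start, end = pos + 1, pos + 1
            else:
                start, end = pos, pos + 1
            pct = 100.0 * m / d
            fh.write(
                f"{table.chrom[i]}\t{start}\t{end}\t{pct:.6g}\t{m}\t{d - m}\n"
            )


def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read BED3+ intervals, validate, and return them sorted by (chrom, start)."""
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: fewer than 3 columns")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            if start >= end:
                raise FormatError(f"{path}:{lineno}: start >= end")
            name = fields[3] if len(fields) > 3 else None
            strand = fields[5] if len(fields) > 5 and fields[5] in "+-" else "."
            out.append(GenomicInterval(chrom, start, end, name=name, strand=strand))
    out.sort(key=lambda iv: (iv.chrom, iv.start, iv.end))
    return out


def write_bed(intervals: Iterable[GenomicInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            name = iv.name if iv.name is not None else "."
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t0\t{iv.strand}\n")


@dataclass
class GeneModel:
    """A gene with strand-aware exon structure and CDS bounds (tx coordinates
    0-based half-open); UTRs are exonic sequence outside [cds_start, cds_end)."""

    name: str
    chrom: str
    start: int
    end: int
    strand: str
    exon_starts: tuple[int, ...]
    exon_ends: tuple[int, ...]
    cds_start: int
    cds_end: int

    @property
    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end, name=self.name, strand=self.strand)


def read_gene_models(path: str | Path) -> list[GeneModel]:
    """Read the BED12-lite gene table: chrom, start, end, name, strand,
    cds_start, cds_end, exon_starts (comma list), exon_ends (comma list)."""
    genes = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) != 9:
                raise FormatError(f"{path}:{lineno}: expected 9 columns, got {len(f)}")
            starts = tuple(int(x) for x in f[7].rstrip(",").split(","))
            ends = tuple(int(x) for x in f[8].rstrip(",").split(","))
            if len(starts) != len(ends) or any(s >= e for s, e in zip(starts, ends)):
                raise FormatError(f"{path}:{lineno}: malformed exon blocks")
            genes.append(
                GeneModel(
                    name=f[3], chrom=f[0], start=int(f[1]), end=int(f[2]),
                    strand=f[4], exon_starts=starts, exon_ends=ends,
                    cds_start=int(f[5]), cds_end=int(f[6]),
                )
            )
    genes.sort(key=lambda g: (g.chrom, g.start))
    return genes


def write_gene_models(genes: Iterable[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(
                "\t".join(
                    [
                        g.chrom, str(g.start), str(g.end), g.name, g.strand,
                        str(g.cds_start), str(g.cds_end),
                        ",".join(map(str, g.exon_starts)),
                        ",".join(map(str, g.exon_ends)),
                    ]
                )
                + "\n"
            )


def read_expression(
    matrix_path: str | Path,
    probe_bed_path: str | Path,
    design: SampleDesign,
) -> ExpressionMatrix:
    """Join an expression TSV (probe rows, sample columns) with probe
    coordinates from a BED file; probes absent from the BED are kept but
    flagged untestable for cis analysis."""
    values = pd.read_csv(matrix_path, sep="\t", index_col=0)
    values.index = values.index.astype(str)
    if values.index.duplicated().any():
        raise FormatError(f"{matrix_path}: duplicated probe id")
    missing = set(design.samples) - set(values.columns)
    extra = set(values.columns) - set(design.samples)
    if missing or extra:
        raise ConfigurationError(
            f"expression matrix / design sample mismatch: missing={sorted(missing)} extra={sorted(extra)}"
        )
    values = values[design.samples]  # design order

    coords = {iv.name: iv for iv in read_bed(probe_bed_path) if iv.name}
    rows = []
    n_untestable = 0
    for probe in values.index:
        iv = coords.get(probe)
        if iv is None:
            n_untestable += 1
            rows.append((probe, "", -1, -1, False))
        else:
            rows.append((probe, iv.chrom, iv.start, iv.end, True))
    if n_untestable:
        logger.warning("%d probes lack coordinates; flagged untestable for cis analysis", n_untestable)
    probes = pd.DataFrame(rows, columns=["probe", "chrom", "start", "end", "testable"])
    return ExpressionMatrix(values=values, probes=probes)


def write_expression(matrix: ExpressionMatrix, matrix_path: str | Path, probe_bed_path: str | Path | None = None) -> None:
    out = matrix.values.copy()
    out.index.name = "probe"
    out.to_csv(matrix_path, sep="\t", float_format="%.6g")
    if probe_bed_path is not None:
        ivs = [
            GenomicInterval(str(r.chrom), int(r.start), int(r.end), name=str(r.probe))
            for r in matrix.probes.itertuples()
            if bool(r.testable)
        ]
        write_bed(ivs, probe_bed_path)


def read_snp_panel(path: str | Path) -> pd.DataFrame:
    """Strain-informative SNP panel: chrom, pos, then one 0/1 column per
    sample (1 = sample matches the alternate strain allele)."""
    df = pd.read_csv(path, sep="\t")
    if "chrom" not in df.columns or "pos" not in df.columns:
        raise FormatError(f"{path}: SNP panel needs chrom and pos columns")
    return df


def write_snp_panel(panel: pd.DataFrame, path: str | Path) -> None:
    panel.to_csv(path, sep="\t", index=False)
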