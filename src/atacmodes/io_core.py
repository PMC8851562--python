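"""Core data model and readers/writers shared by every analysis stage.

All genomic coordinates are 0-based half-open (BED convention) everywhere
inside the package. Inputs in 1-based inclusive dialects (GTF-like gene
tables) are converted at the boundary, on read.

Formats handled here: BED6 / ENCODE narrowPeak intervals, tab-separated
count/metadata/DE tables, FASTA (via Biopython), per-base cut-count tracks,
and a YAML analysis configuration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger("atacmodes")

STRANDS = {"+", "-", "."}


class FormatError(ValueError):
    """Malformed input file (wrong shape, dialect, or header)."""


class DataError(ValueError):
    """Well-formed file carrying invalid values (negative counts, bad strand...)."""


@dataclass(frozen=True)
class GenomicInterval:
    """A genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self):
        if not self.chrom:
            raise DataError("interval with empty chromosome name")
        if self.start < 0:
            raise DataError(f"negative start coordinate {self.start}")
        if self.end <= self.start:
            raise DataError(f"empty/inverted interval [{self.start},{self.end})")
        if self.strand not in STRANDS:
            raise DataError(f"unknown strand symbol {self.strand!r}")

    @property
    def width(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


@dataclass
class PeakSet:
    """Peak intervals with a peaks x samples raw-count matrix.

    ``sample_meta`` is a DataFrame indexed by sample name with columns
    ``condition`` and ``library_size`` (total mapped reads — supplied by the
    experiment, never recomputed from in-peak counts).
    """

    peaks: list[GenomicInterval]
    peak_ids: list[str]
    counts: np.ndarray
    sample_meta: pd.DataFrame

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2 or self.counts.shape[0] != len(self.peaks):
            raise FormatError(
                f"count matrix has {self.counts.shape[0]} rows for "
                f"{len(self.peaks)} peaks"
            )
        if self.counts.shape[1] != len(self.sample_meta):
            raise FormatError(
                f"count matrix has {self.counts.shape[1]} columns for "
                f"{len(self.sample_meta)} samples"
            )
        if len(set(self.peak_ids)) != len(self.peak_ids):
            dupes = pd.Series(self.peak_ids).value_counts()
            raise DataError(f"duplicate peak ids: {list(dupes[dupes > 1].index[:5])}")
        if (self.counts < 0).any():
            row = int(np.argwhere(self.counts < 0)[0][0])
            raise DataError(f"negative count at peak row {row}")
        if (self.sample_meta["library_size"] <= 0).any():
            raise DataError("every sample needs a positive library size")

    @property
    def n_peaks(self) -> int:
        return len(self.peaks)

    @property
    def samples(self) -> list[str]:
        return list(self.sample_meta.index)

    def sample_indices(self, condition: str) -> np.ndarray:
        idx = np.flatnonzero((self.sample_meta["condition"] == condition).to_numpy())
        if idx.size == 0:
            raise DataError(f"no samples with condition label {condition!r}")
        return idx

    def widths(self) -> np.ndarray:
        return np.array([p.width for p in self.peaks])

    def subset(self, keep: Sequence[int]) -> "PeakSet":
        keep = list(keep)
        return PeakSet(
            peaks=[self.peaks[i] for i in keep],
            peak_ids=[self.peak_ids[i] for i in keep],
            counts=self.counts[keep, :],
            sample_meta=self.sample_meta,
        )


@dataclass
class GeneModel:
    gene_id: str
    gene_name: str
    chrom: str
    strand: str
    tss: int
    exons: list[GenomicInterval] = field(default_factory=list)

    def __post_init__(self):
        if self.strand not in {"+", "-"}:
            raise DataError(f"gene {self.gene_id}: unknown strand {self.strand!r}")
        for e in self.exons:
            if e.chrom != self.chrom:
                raise DataError(f"gene {self.gene_id}: exon on {e.chrom} != {self.chrom}")

    @property
    def span(self) -> GenomicInterval:
        if not self.exons:
            return GenomicInterval(self.chrom, self.tss, self.tss + 1, self.strand)
        start = min(e.start for e in self.exons)
        end = max(e.end for e in self.exons)
        start = min(start, self.tss)
        end = max(end, self.tss + 1)
        return GenomicInterval(self.chrom, start, end, self.strand)


@dataclass
class DETable:
    """Per-gene differential-expression estimates for one contrast."""

    table: pd.DataFrame  # index gene_id; columns log2_fold_change, adjusted_p
    contrast_name: str

    def __post_init__(self):
        required = {"log2_fold_change", "adjusted_p"}
        if not required <= set(self.table.columns):
            raise FormatError(f"DE table needs columns {sorted(required)}")
        p = self.table["adjusted_p"]
        if ((p < 0) | (p > 1)).any():
            bad = self.table.index[(p < 0) | (p > 1)][0]
            raise DataError(f"adjusted p outside [0,1] for gene {bad}")
        if self.table.index.duplicated().any():
            raise DataError("duplicate gene ids in DE table")

    @property
    def genes(self) -> list[str]:
        return list(self.table.index)


@dataclass
class BindingSiteSet:
    """ChIP binding-site intervals for one condition (e.g. basal, agonist)."""

    sites: list[GenomicInterval]
    condition_label: str

    def __post_init__(self):
        self.sites = sorted(self.sites, key=lambda s: (s.chrom, s.start, s.end))


@dataclass
class AnalysisConfig:
    """All tunable thresholds of the pipeline, with their standard defaults."""

    min_total_count: int = 10          # drop peaks with < this many raw counts summed over samples
    bin_size: int = 1000               # peaks per rank bin
    top_n: int = 1000                  # size of the top loss/gain sets
    promoter_upstream: int = 1000      # bp upstream of TSS in the promoter window
    promoter_downstream: int = 100     # bp downstream of TSS
    tts_window: int = 100              # bp around transcription termination site
    de_alpha: float = 0.05             # adjusted-p cutoff for DE calls
    lfc_threshold: float = 0.0         # extra |log2FC| gate on DE calls (off by default)
    motif_similarity_threshold: float = 0.90
    pwm_score_fraction: float = 0.80   # hit threshold as fraction of max log-odds
    footprint_window: int = 100        # bp each side of motif centre
    rpkm_loss_flag: float = 10.0       # mean RPKM loss that flags a binding-site peak
    enriched_min_neglogp: float = 3.0  # "enriched anywhere" flag: -log10 p >= this in some bin
    changing_min_range: float = 1.0    # "changing" flag: max-min of -log10 p across bins
    rng_seed: int = 0

    def __post_init__(self):
        if not 0 < self.de_alpha < 1:
            raise DataError("de_alpha must lie in (0,1)")
        if not 0 < self.motif_similarity_threshold <= 1:
            raise DataError("motif_similarity_threshold must lie in (0,1]")
        for name in ("min_total_count", "bin_size", "top_n", "promoter_upstream",
                     "promoter_downstream", "footprint_window"):
            if getattr(self, name) < 0:
                raise DataError(f"{name} must be non-negative")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        unknown = set(payload) - set(cls.__dataclass_fields__)
        if unknown:
            raise FormatError(f"unknown config keys: {sorted(unknown)}")
        return cls(**payload)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


# ---------------------------------------------------------------------------
# interval / peak-set I/O
# ---------------------------------------------------------------------------

def _parse_bed_line(line: str, path: str, lineno: int) -> tuple[GenomicInterval, str | None]:
    fields = line.rstrip("\n").split("\t")
    if len(fields) < 3:
        raise FormatError(f"{path}:{lineno}: BED line with {len(fields)} fields")
    chrom, start, end = fields[0], fields[1], fields[2]
    try:
        start_i, end_i = int(start), int(end)
    except ValueError as exc:
        raise FormatError(f"{path}:{lineno}: non-integer coordinates") from exc
    name = fields[3] if len(fields) >= 4 and fields[3] not in {"", "."} else None
    strand = fields[5] if len(fields) >= 6 and fields[5] in STRANDS else "."
    try:
        iv = GenomicInterval(chrom, start_i, end_i, strand)
    except DataError as exc:
        raise DataError(f"{path}:{lineno}: {exc}") from exc
    return iv, name


def read_intervals(path: str | Path) -> tuple[list[GenomicInterval], list[str]]:
    """Read BED3/BED6/narrowPeak intervals; ids synthesized as chrom:start-end
    when the name column is absent."""
    intervals, names = [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            iv, name = _parse_bed_line(line, str(path), lineno)
            intervals.append(iv)
            names.append(name if name is not None else f"{iv.chrom}:{iv.start}-{iv.end}")
    return intervals, names


def write_intervals(intervals: Iterable[GenomicInterval], ids: Iterable[str],
                    path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv, name in zip(intervals, ids):
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t0\t{iv.strand}\n")


def read_peakset(interval_path: str | Path, counts_path: str | Path,
                 meta_path: str | Path) -> PeakSet:
    """Assemble a PeakSet from a BED/narrowPeak file, a counts TSV (first
    column peak id or rows aligned by order) and a sample-metadata TSV."""
    intervals, ids = read_intervals(interval_path)
    counts_df = pd.read_csv(counts_path, sep="\t", index_col=0)
    meta = pd.read_csv(meta_path, sep="\t", index_col=0)
    if "condition" not in meta.columns or "library_size" not in meta.columns:
        raise FormatError(f"{meta_path}: needs 'condition' and 'library_size' columns")
    if len(counts_df) != len(intervals):
        raise FormatError(
            f"{counts_path} has {len(counts_df)} rows but {interval_path} has "
            f"{len(intervals)} intervals"
        )
    missing = [s for s in counts_df.columns if s not in meta.index]
    if missing:
        raise FormatError(f"{meta_path}: samples missing from metadata: {missing}")
    if set(counts_df.index) == set(ids):
        counts_df = counts_df.loc[ids]
    counts = counts_df.to_numpy()
    if not np.issubdtype(counts.dtype, np.number):
        raise FormatError(f"{counts_path}: non-numeric counts")
    if (counts < 0).any():
        row = int(np.argwhere((counts < 0).any(axis=1))[0][0])
        raise DataError(f"{counts_path}: negative count at data row {row}")
    meta = meta.loc[list(counts_df.columns)]
    ps = PeakSet(peaks=intervals, peak_ids=ids, counts=counts.astype(np.int64),
                 sample_meta=meta)
    logger.info("read_peakset: %d peaks x %d samples", ps.n_peaks, len(ps.samples))
    return ps


def write_peakset(ps: PeakSet, interval_path: str | Path, counts_path: str | Path,
                  meta_path: str | Path) -> None:
    write_intervals(ps.peaks, ps.peak_ids, interval_path)
    pd.DataFrame(ps.counts, index=pd.Index(ps.peak_ids, name="peak_id"),
                 columns=ps.samples).to_csv(counts_path, sep="\t")
    ps.sample_meta.rename_axis("sample").to_csv(meta_path, sep="\t")


# ---------------------------------------------------------------------------
# gene models
# ---------------------------------------------------------------------------

def _exons_from_field(chrom: str, strand: str, text: str) -> list[GenomicInterval]:
    exons = []
    for part in text.split(","):
        part = part.strip()
        if not part:
            continue
        lo, hi = part.split("-")
        exons.append(GenomicInterval(chrom, int(lo), int(hi), strand))
    return exons


def read_gene_models(path: str | Path) -> list[GeneModel]:
    """Read a gene table.

    Two dialects: a TSV with header (gene_id, gene_name, chrom, strand,
    start, end, optional tss, optional comma-separated exons "lo-hi,...";
    0-based half-open), or a GTF-like 9-column file (1-based inclusive,
    converted on read). When no explicit TSS is given it is derived from the
    span by strand: start for '+', end-1 for '-'.
    """
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    if first.count("\t") == 8 and "gene_id" in first.split("\t")[8]:
        return _read_gtf_like(path)
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    required = {"gene_id", "chrom", "strand", "start", "end"}
    if not required <= set(df.columns):
        raise FormatError(f"{path}: gene table needs columns {sorted(required)}")
    genes = []
    for row in df.itertuples(index=False):
        strand = str(row.strand)
        if strand not in {"+", "-"}:
            raise DataError(f"{path}: gene {row.gene_id}: unknown strand {strand!r}")
        if "tss" in df.columns and not pd.isna(getattr(row, "tss", np.nan)):
            tss = int(row.tss)
        else:
            tss = int(row.start) if strand == "+" else int(row.end) - 1
        exon_text = getattr(row, "exons", "") if "exons" in df.columns else ""
        exons = (_exons_from_field(str(row.chrom), strand, str(exon_text))
                 if isinstance(exon_text, str) and exon_text else
                 [GenomicInterval(str(row.chrom), int(row.start), int(row.end), strand)])
        name = str(getattr(row, "gene_name", row.gene_id)) if "gene_name" in df.columns else str(row.gene_id)
        genes.append(GeneModel(str(row.gene_id), name, str(row.chrom), strand, tss, exons))
    return genes


def _read_gtf_like(path: Path) -> list[GeneModel]:
    import re

    attr_re = re.compile(r'(\w+) "([^"]*)"')
    exons: dict[str, list[GenomicInterval]] = {}
    info: dict[str, tuple[str, str, str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) != 9:
                raise FormatError(f"{path}:{lineno}: expected 9 GTF columns, got {len(f)}")
            chrom, _, feature, start, end, _, strand, _, attrs = f
            if strand not in {"+", "-"}:
                raise DataError(f"{path}:{lineno}: unknown strand {strand!r}")
            attr = dict(attr_re.findall(attrs))
            gid = attr.get("gene_id")
            if not gid:
                raise FormatError(f"{path}:{lineno}: missing gene_id attribute")
            info.setdefault(gid, (attr.get("gene_name", gid), chrom, strand))
            if feature == "exon":
                # GTF is 1-based inclusive -> 0-based half-open
                exons.setdefault(gid, []).append(
                    GenomicInterval(chrom, int(start) - 1, int(end), strand))
    genes = []
    for gid, (name, chrom, strand) in info.items():
        ex = sorted(exons.get(gid, []), key=lambda e: e.start)
        if not ex:
            raise FormatError(f"{path}: gene {gid} has no exon records")
        tss = ex[0].start if strand == "+" else ex[-1].end - 1
        genes.append(GeneModel(gid, name, chrom, strand, tss, ex))
    return genes


def write_gene_models(genes: Sequence[GeneModel], path: str | Path) -> None:
    rows = []
    for g in genes:
        span = g.span
        rows.append({
            "gene_id": g.gene_id, "gene_name": g.gene_name, "chrom": g.chrom,
            "strand": g.strand, "start": span.start, "end": span.end, "tss": g.tss,
            "exons": ",".join(f"{e.start}-{e.end}" for e in g.exons),
        })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# DE tables, binding sites, matrices, FASTA, cut tracks
# ---------------------------------------------------------------------------

def read_de_table(path: str | Path, contrast_name: str) -> DETable:
    df = pd.read_csv(path, sep="\t")
    cols = {c.lower(): c for c in df.columns}
    gene_col = cols.get("gene_id", df.columns[0])
    lfc_col = next((cols[k] for k in ("log2_fold_change", "log2foldchange", "log2fc")
                    if k in cols), None)
    p_col = next((cols[k] for k in ("adjusted_p", "padj", "adj_p", "qvalue")
                  if k in cols), None)
    if lfc_col is None or p_col is None:
        raise FormatError(f"{path}: need log2 fold-change and adjusted-p columns")
    df = df[[gene_col, lfc_col, p_col]].rename(
        columns={gene_col: "gene_id", lfc_col: "log2_fold_change", p_col: "adjusted_p"})
    dup = df.duplicated(subset="gene_id", keep=False)
    if dup.any():
        exact = df[dup].groupby("gene_id").nunique()
        conflicting = exact[(exact > 1).any(axis=1)].index.tolist()
        if conflicting:
            raise DataError(f"{path}: conflicting duplicate rows for genes {conflicting[:5]}")
        df = df.drop_duplicates(subset="gene_id")
    return DETable(df.set_index("gene_id"), contrast_name)


def write_de_table(de: DETable, path: str | Path) -> None:
    de.table.rename_axis("gene_id").to_csv(path, sep="\t")


def read_binding_sites(path: str | Path, condition_label: str) -> BindingSiteSet:
    intervals, _ = read_intervals(path)
    return BindingSiteSet(sites=intervals, condition_label=condition_label)


def write_matrix(matrix: pd.DataFrame, path: str | Path, float_format: str = "%.6g") -> None:
    """Write a named 2-D matrix as TSV (header row + row-name column)."""
    if matrix.index.duplicated().any() or matrix.columns.duplicated().any():
        raise DataError("matrix row/column names must be unique")
    matrix.to_csv(path, sep="\t", float_format=float_format)


def read_matrix(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def read_fasta(path: str | Path) -> dict[str, str]:
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise FormatError(f"{path}: duplicate FASTA id {rec.id}")
        seqs[rec.id] = str(rec.seq).upper()
    return seqs


def write_fasta(seqs: dict[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def read_cut_track(path: str | Path, chrom_sizes: dict[str, int]) -> dict[str, np.ndarray]:
    """Read a bedGraph-like per-base cut-count TSV (chrom, start, end, count)
    into dense per-chromosome arrays."""
    track = {c: np.zeros(n, dtype=np.int64) for c, n in chrom_sizes.items()}
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["chrom", "start", "end", "count"], comment="#")
    for row in df.itertuples(index=False):
        if row.chrom not in track:
            raise DataError(f"{path}: unknown chromosome {row.chrom}")
        track[str(row.chrom)][int(row.start):int(row.end)] += int(row.count)
    return track


def write_cut_track(track: dict[str, np.ndarray], path: str | Path) -> None:
    """Write dense cut counts as a run-length bedGraph-like TSV (zero runs
    omitted)."""
    with open(path, "w") as fh:
        for chrom in sorted(track):
            arr = track[chrom]
            nz = np.flatnonzero(arr)
            if nz.size == 0:
                continue
            # collapse runs of equal value
            breaks = np.flatnonzero(np.diff(nz) != 1)
            starts = np.concatenate([[0], breaks + 1])
            ends = np.concatenate([breaks, [nz.size - 1]])
            for s, e in zip(starts, ends):
                seg = arr[nz[s]:nz[e] + 1]
                pos = nz[s]
                run_start = pos
                for i in range(1, seg.size + 1):
                    if i == seg.size or seg[i] != seg[i - 1]:
                        fh.write(f"{chrom}\t{run_start}\t{nz[s] + i}\t{seg[i - 1]}\n")
                        if i < seg.size:
                            run_start = nz[s] + i


def setup_logging(level: int = logging.INFO) -> None:
    logging.basicConfig(
        level=level,
        format="%(asctime)s %(levelname)s %(name)s: %(message)s",
        datefmt="%H:%M:%S",
    )
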