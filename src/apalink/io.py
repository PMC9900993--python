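"""Readers, writers and coordinate conventions for every file the pipeline touches.

Coordinate conventions
----------------------
All genomic interval I/O (BED12, BED6, bedGraph) is 0-based half-open, the
UCSC convention.  All in-memory per-base vectors are *transcript oriented*:
index 0 is the 5' end of the 3'UTR (just downstream of the stop codon) and the
index increases toward the distal poly(A) site.  For minus-strand genes this
means genomic coverage is reversed on read and re-reversed on write.

RBP binding sites are kept in transcript-oriented 3'UTR coordinates directly:
the BED6 "chrom" column holds the gene id, and start/end are offsets into the
3'UTR.
"""

from __future__ import annotations

import io as _io
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

VALID_GROUPS = ("case", "control")


class ParseError(ValueError):
    """Malformed input file; message carries the path and line number."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class UTRAnnotation:
    """One gene's 3'UTR model.

    ``annotated_pas`` holds known poly(A)-site offsets in transcript
    orientation (each in ``(0, utr_length]``); it may be empty when the UTR is
    analysed de novo from coverage.
    """

    gene_id: str
    chrom: str
    genomic_start: int
    genomic_end: int
    strand: str
    annotated_pas: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-', got {self.strand!r}")
        if not (0 <= self.genomic_start < self.genomic_end):
            raise ValueError(f"{self.gene_id}: invalid interval [{self.genomic_start}, {self.genomic_end})")
        self.annotated_pas = sorted(int(p) for p in self.annotated_pas)
        for p in self.annotated_pas:
            if not (0 < p <= self.utr_length):
                raise ValueError(f"{self.gene_id}: PAS offset {p} outside (0, {self.utr_length}]")

    @property
    def utr_length(self) -> int:
        return self.genomic_end - self.genomic_start


@dataclass
class GroupDesign:
    """Mapping sample_id -> group, group in {case, control}."""

    groups: "pd.Series"  # index sample_id, values group

    def __post_init__(self) -> None:
        g = pd.Series(self.groups)
        if g.index.has_duplicates:
            raise ValueError("duplicate sample ids in design")
        bad = set(g.unique()) - set(VALID_GROUPS)
        if bad:
            raise ValueError(f"unknown group labels: {sorted(bad)}")
        self.groups = g.astype(str)
        if not self.case_samples or not self.control_samples:
            raise ValueError("both 'case' and 'control' groups must be non-empty")

    @property
    def samples(self) -> list[str]:
        return list(self.groups.index)

    @property
    def case_samples(self) -> list[str]:
        return list(self.groups.index[self.groups == "case"])

    @property
    def control_samples(self) -> list[str]:
        return list(self.groups.index[self.groups == "control"])

    @classmethod
    def from_tsv(cls, path: str | Path) -> "GroupDesign":
        df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
        if not {"sample_id", "group"} <= set(df.columns):
            raise ParseError(f"{path}: design file needs columns sample_id, group")
        return cls(pd.Series(df["group"].values, index=df["sample_id"].values))

    def to_tsv(self, path: str | Path, header: str | None = None) -> Path:
        path = Path(path)
        with open(path, "w") as fh:
            if header:
                fh.write(f"# {header}\n")
            fh.write("sample_id\tgroup\n")
            for s, g in self.groups.items():
                fh.write(f"{s}\t{g}\n")
        return path


@dataclass
class AbundanceMatrix:
    """Genes x samples numeric matrix with a unit tag.

    Missing values are NaN.  Empty TSV cells read as missing; zeros are kept
    as zeros (a zero is a meaningful abundance in iFOT space, absence of
    detection is not).
    """

    values: pd.DataFrame  # index gene_id, columns sample ids
    unit: str = "arbitrary"

    def __post_init__(self) -> None:
        v = self.values
        if v.index.has_duplicates:
            dup = v.index[v.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene ids: {dup[:5]}")
        if v.columns.has_duplicates:
            raise ValueError("duplicate sample ids")
        arr = v.to_numpy(dtype=float)
        if np.nanmin(arr, initial=0.0) < 0:
            raise ValueError("abundance values must be >= 0 where present")
        self.values = v.astype(float)

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    @classmethod
    def from_tsv(cls, path: str | Path, unit: str | None = None) -> "AbundanceMatrix":
        path = Path(path)
        file_unit = None
        with open(path) as fh:
            head = []
            for line in fh:
                if line.startswith("#"):
                    if "unit=" in line:
                        file_unit = line.split("unit=")[1].split()[0].strip()
                    continue
                head.append(line)
                break
            body = "".join(head) + fh.read()
        try:
            df = pd.read_csv(_io.StringIO(body), sep="\t", index_col=0)
        except pd.errors.ParserError as e:
            raise ParseError(f"{path}: {e}") from None
        if df.index.has_duplicates:
            raise ParseError(f"{path}: duplicate gene row(s)")
        return cls(df, unit=unit or file_unit or "arbitrary")

    def to_tsv(self, path: str | Path, header: str | None = None) -> Path:
        path = Path(path)
        with open(path, "w") as fh:
            fh.write(f"# {header + ' ' if header else ''}unit={self.unit}\n")
            self.values.to_csv(fh, sep="\t", index_label="gene_id",
                               float_format="%.10g", na_rep="")
        return path


@dataclass
class RBPSiteSet:
    """Named RBP -> binding intervals on transcript-oriented 3'UTR coordinates.

    Backed by a long DataFrame with columns (rbp, gene_id, start, end),
    0-based half-open.
    """

    sites: pd.DataFrame

    def __post_init__(self) -> None:
        need = {"rbp", "gene_id", "start", "end"}
        if not need <= set(self.sites.columns):
            raise ValueError(f"sites table needs columns {sorted(need)}")
        s = self.sites
        if len(s) and not ((s["start"] >= 0) & (s["start"] < s["end"])).all():
            raise ValueError("sites must satisfy 0 <= start < end")
        self.sites = s.reset_index(drop=True)

    @property
    def rbp_names(self) -> list[str]:
        return sorted(self.sites["rbp"].unique())

    def sites_for(self, rbp: str, gene_id: str | None = None) -> pd.DataFrame:
        out = self.sites[self.sites["rbp"] == rbp]
        if gene_id is not None:
            out = out[out["gene_id"] == gene_id]
        return out

    def bound_genes(self, rbp: str) -> set[str]:
        """Genes with >=1 site for this RBP anywhere in their 3'UTR."""
        return set(self.sites.loc[self.sites["rbp"] == rbp, "gene_id"])

    def validate_against(self, annotation: Mapping[str, UTRAnnotation]) -> None:
        for _, row in self.sites.iterrows():
            ann = annotation.get(row["gene_id"])
            if ann is not None and row["end"] > ann.utr_length:
                raise ValueError(
                    f"site [{row['start']},{row['end']}) of {row['rbp']} exceeds "
                    f"{row['gene_id']} UTR length {ann.utr_length}")

    @classmethod
    def from_bed6(cls, path: str | Path) -> "RBPSiteSet":
        rows = []
        with open(path) as fh:
            for i, line in enumerate(fh, 1):
                if not line.strip() or line.startswith(("#", "track")):
                    continue
                f = line.rstrip("\n").split("\t")
                if len(f) < 4:
                    raise ParseError(f"{path}:{i}: expected >=4 BED columns")
                try:
                    rows.append((f[3], f[0], int(f[1]), int(f[2])))
                except ValueError:
                    raise ParseError(f"{path}:{i}: non-integer coordinates") from None
        return cls(pd.DataFrame(rows, columns=["rbp", "gene_id", "start", "end"]))

    def to_bed6(self, path: str | Path, header: str | None = None) -> Path:
        path = Path(path)
        with open(path, "w") as fh:
            if header:
                fh.write(f"# {header}\n")
            for _, r in self.sites.iterrows():
                fh.write(f"{r['gene_id']}\t{r['start']}\t{r['end']}\t{r['rbp']}\t0\t+\n")
        return path


# ---------------------------------------------------------------------------
# annotation I/O
# ---------------------------------------------------------------------------


def read_utr_annotation(path: str | Path, dialect: str = "bed12") -> dict[str, UTRAnnotation]:
    """Read 3'UTR models, one per gene, keyed by gene id.

    ``dialect`` is ``bed12`` (name column = gene id, single block) or
    ``gtf_lite`` (9-column GTF with a ``gene_id "X"`` attribute; one feature
    line per gene).  Duplicate gene ids are an error.
    """
    path = Path(path)
    out: dict[str, UTRAnnotation] = {}
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = line.rstrip("\n").split("\t")
            try:
                if dialect == "bed12":
                    if len(f) < 6:
                        raise ValueError("expected >=6 BED columns")
                    gene, chrom = f[3], f[0]
                    start, end, strand = int(f[1]), int(f[2]), f[5]
                elif dialect == "gtf_lite":
                    if len(f) < 9:
                        raise ValueError("expected 9 GTF columns")
                    chrom, strand = f[0], f[6]
                    start, end = int(f[3]) - 1, int(f[4])  # GTF is 1-based closed
                    attrs = f[8]
                    if 'gene_id "' not in attrs:
                        raise ValueError("missing gene_id attribute")
                    gene = attrs.split('gene_id "')[1].split('"')[0]
                else:
                    raise ValueError(f"unknown dialect {dialect!r}")
            except ValueError as e:
                raise ParseError(f"{path}:{i}: {e}") from None
            if gene in out:
                raise ParseError(f"{path}:{i}: duplicate gene_id {gene!r}")
            out[gene] = UTRAnnotation(gene, chrom, start, end, strand)
    if not out:
        log.warning("annotation file %s is empty", path)
    return out


def write_utr_annotation(annotation: Mapping[str, UTRAnnotation], path: str | Path,
                         header: str | None = None) -> Path:
    """Write UTR models as single-block BED12."""
    path = Path(path)
    with open(path, "w") as fh:
        if header:
            fh.write(f"# {header}\n")
        for ann in annotation.values():
            L = ann.utr_length
            fh.write("\t".join(map(str, [
                ann.chrom, ann.genomic_start, ann.genomic_end, ann.gene_id, 0,
                ann.strand, ann.genomic_start, ann.genomic_end, "0,0,0", 1,
                f"{L},", "0,",
            ])) + "\n")
    return path


# ---------------------------------------------------------------------------
# coverage I/O
# ---------------------------------------------------------------------------


def orient_to_transcript(vec: np.ndarray, strand: str) -> np.ndarray:
    """Reverse a genomic-order per-base vector for minus-strand genes.

    Applying this twice is the identity.
    """
    return vec[::-1].copy() if strand == "-" else np.asarray(vec).copy()


def read_bedgraph_coverage(path: str | Path,
                           annotation: Mapping[str, UTRAnnotation]) -> dict[str, np.ndarray]:
    """Expand one sample's bedGraph into per-gene transcript-oriented depth vectors.

    Positions not covered by any record are 0; records outside annotated UTRs
    are ignored; overlapping records are an error (the format forbids them).
    """
    path = Path(path)
    by_chrom: dict[str, list[tuple[int, int, float]]] = {}
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 4:
                raise ParseError(f"{path}:{i}: expected 4 bedGraph columns")
            try:
                rec = (int(f[1]), int(f[2]), float(f[3]))
            except ValueError:
                raise ParseError(f"{path}:{i}: non-numeric interval or depth") from None
            by_chrom.setdefault(f[0], []).append(rec)
    for chrom, recs in by_chrom.items():
        recs.sort()
        for (s1, e1, _), (s2, _, _) in zip(recs, recs[1:]):
            if s2 < e1:
                raise ParseError(f"{path}: overlapping bedGraph records on {chrom} at {s2}")
    out: dict[str, np.ndarray] = {}
    for gene, ann in annotation.items():
        vec = np.zeros(ann.utr_length, dtype=float)
        for s, e, v in by_chrom.get(ann.chrom, []):
            lo, hi = max(s, ann.genomic_start), min(e, ann.genomic_end)
            if lo < hi:
                vec[lo - ann.genomic_start:hi - ann.genomic_start] = v
        out[gene] = orient_to_transcript(vec, ann.strand)
    return out


def write_bedgraph_coverage(coverage: Mapping[str, np.ndarray],
                            annotation: Mapping[str, UTRAnnotation],
                            path: str | Path, header: str | None = None) -> Path:
    """Run-length encode per-gene transcript-oriented depth back to bedGraph.

    Zero-depth runs are omitted (they read back as zeros).
    """
    path = Path(path)
    with open(path, "w") as fh:
        if header:
            fh.write(f"# {header}\n")
        for gene in sorted(coverage):
            ann = annotation[gene]
            vec = orient_to_transcript(np.asarray(coverage[gene], dtype=float), ann.strand)
            if vec.size != ann.utr_length:
                raise ValueError(f"{gene}: coverage length {vec.size} != UTR length {ann.utr_length}")
            change = np.flatnonzero(np.diff(vec)) + 1
            starts = np.concatenate([[0], change])
            ends = np.concatenate([change, [vec.size]])
            for s, e in zip(starts, ends):
                v = vec[s]
                if v != 0:
                    fh.write(f"{ann.chrom}\t{ann.genomic_start + s}\t{ann.genomic_start + e}\t{v:.12g}\n")
    return path


# ---------------------------------------------------------------------------
# generic tables
# ---------------------------------------------------------------------------


def read_matrix(path: str | Path, unit: str | None = None) -> AbundanceMatrix:
    """Alias for :meth:`AbundanceMatrix.from_tsv`."""
    return AbundanceMatrix.from_tsv(path, unit=unit)


def write_table(df: pd.DataFrame, path: str | Path, header: str | None = None,
                index: bool = False) -> Path:
    """Write a result table as TSV with an optional leading comment line."""
    path = Path(path)
    with open(path, "w") as fh:
        if header:
            fh.write(f"# {header}\n")
        df.to_csv(fh, sep="\t", index=index, float_format="%.10g", na_rep="")
    return path


def read_isoform_quant(path: str | Path) -> pd.DataFrame:
    """Read an isoform abundance table.

    Columns: gene_id, isoform_id, pas_offset, then one numeric column per
    sample.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    need = {"gene_id", "isoform_id", "pas_offset"}
    if not need <= set(df.columns):
        raise ParseError(f"{path}: isoform table needs columns {sorted(need)}")
    if df.duplicated(["gene_id", "isoform_id"]).any():
        raise ParseError(f"{path}: duplicate (gene_id, isoform_id) rows")
    return df
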