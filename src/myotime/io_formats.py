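"""Readers, writers and validated containers for every on-disk artifact.

All tabular artifacts are plain TSV; count matrices may alternatively be
stored as MatrixMarket.  Readers reject malformed input with an error naming
the offending record rather than repairing it silently, and every
writer/reader pair round-trips exactly on valid data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse


class FormatError(ValueError):
    """Malformed on-disk artifact."""


# ---------------------------------------------------------------------------
# Count matrices
# ---------------------------------------------------------------------------

METADATA_COLUMNS = ("cell_line", "day", "replicate")


@dataclass
class CountMatrix:
    """Integer feature-by-sample count matrix with per-sample metadata.

    Parameters
    ----------
    counts
        DataFrame of nonnegative integers, features as rows, samples as
        columns.
    metadata
        DataFrame indexed by sample id with columns ``cell_line``, ``day``
        and ``replicate``; order must match ``counts`` columns.
    library_sizes
        Optional per-sample sequencing depths; default to column sums.
    """

    counts: pd.DataFrame
    metadata: pd.DataFrame
    library_sizes: pd.Series | None = None

    def __post_init__(self) -> None:
        c = self.counts
        if c.index.duplicated().any():
            dup = c.index[c.index.duplicated()][0]
            raise FormatError(f"duplicate feature id: {dup!r}")
        if c.columns.duplicated().any():
            dup = c.columns[c.columns.duplicated()][0]
            raise FormatError(f"duplicate sample id: {dup!r}")
        arr = c.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            frac = np.asarray(arr, dtype=float)
            if not np.allclose(frac, np.round(frac), atol=0, rtol=0):
                i, j = np.argwhere(frac != np.round(frac))[0]
                raise FormatError(
                    f"non-integer count at feature {c.index[i]!r}, "
                    f"sample {c.columns[j]!r}: {frac[i, j]}"
                )
            self.counts = c.astype(np.int64)
        if (self.counts.to_numpy() < 0).any():
            raise FormatError("negative counts are not allowed")
        missing = [s for s in c.columns if s not in self.metadata.index]
        if missing:
            raise FormatError(f"metadata missing sample: {missing[0]!r}")
        for col in METADATA_COLUMNS:
            if col not in self.metadata.columns:
                raise FormatError(f"metadata missing column: {col!r}")
        self.metadata = self.metadata.loc[c.columns]
        if self.library_sizes is None:
            self.library_sizes = self.counts.sum(axis=0).astype(float)
        else:
            self.library_sizes = pd.Series(self.library_sizes, dtype=float).loc[
                c.columns
            ]
            if (self.library_sizes <= 0).any():
                bad = self.library_sizes.index[self.library_sizes <= 0][0]
                raise FormatError(f"non-positive library size for sample {bad!r}")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def subset_features(self, ids: Sequence[str]) -> "CountMatrix":
        return CountMatrix(
            self.counts.loc[list(ids)], self.metadata.copy(), self.library_sizes
        )


def write_counts(cm: CountMatrix, path: str | Path, metadata_path: str | Path) -> None:
    out = cm.counts.copy()
    out.index.name = "feature_id"
    out.to_csv(path, sep="\t")
    meta = cm.metadata.copy()
    meta.insert(0, "library_size", cm.library_sizes)
    meta = meta[["cell_line", "day", "replicate", "library_size"]]
    meta.index.name = "sample_id"
    meta.to_csv(metadata_path, sep="\t")


def read_counts(path: str | Path, metadata_path: str | Path) -> CountMatrix:
    path, metadata_path = Path(path), Path(metadata_path)
    for p in (path, metadata_path):
        if not p.exists():
            raise FormatError(f"no such file: {p}")
    counts = pd.read_csv(path, sep="\t", index_col=0)
    meta = pd.read_csv(metadata_path, sep="\t", index_col=0)
    lib = meta.pop("library_size") if "library_size" in meta.columns else None
    return CountMatrix(counts, meta, lib)


def write_counts_mtx(cm: CountMatrix, prefix: str | Path) -> None:
    """Write counts as MatrixMarket plus feature/sample id sidecar files."""
    prefix = Path(prefix)
    scipy.io.mmwrite(
        str(prefix) + ".mtx", scipy.sparse.csr_matrix(cm.counts.to_numpy())
    )
    Path(str(prefix) + ".features.txt").write_text(
        "\n".join(cm.feature_ids) + "\n"
    )
    Path(str(prefix) + ".samples.txt").write_text("\n".join(cm.sample_ids) + "\n")


def read_counts_mtx(prefix: str | Path, metadata_path: str | Path) -> CountMatrix:
    prefix = Path(prefix)
    mat = scipy.io.mmread(str(prefix) + ".mtx").toarray()
    features = Path(str(prefix) + ".features.txt").read_text().splitlines()
    samples = Path(str(prefix) + ".samples.txt").read_text().splitlines()
    meta = pd.read_csv(metadata_path, sep="\t", index_col=0)
    lib = meta.pop("library_size") if "library_size" in meta.columns else None
    counts = pd.DataFrame(mat, index=features, columns=samples)
    return CountMatrix(counts, meta, lib)


# ---------------------------------------------------------------------------
# Transcript models / GTF
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TranscriptModel:
    """Exon-chain transcript record, genomic 1-based inclusive coordinates."""

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise FormatError(f"unknown strand {self.strand!r}")
        if not self.exons:
            raise FormatError(f"{self.transcript_id}: transcript with no exons")
        exons = tuple(sorted(tuple(e) for e in self.exons))
        for start, end in exons:
            if end < start:
                raise FormatError(
                    f"{self.transcript_id}: exon end {end} < start {start}"
                )
        for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
            if s2 <= e1:
                raise FormatError(f"{self.transcript_id}: overlapping exons")
        object.__setattr__(self, "exons", exons)

    @property
    def junctions(self) -> tuple[tuple[int, int], ...]:
        """Introns as (last base of upstream exon, first base of downstream exon)."""
        return tuple(
            (e1[1], e2[0]) for e1, e2 in zip(self.exons, self.exons[1:])
        )

    def junction_keys(self) -> tuple[tuple[str, str, int, int], ...]:
        return tuple((self.chrom, self.strand, a, b) for a, b in self.junctions)


class JunctionCatalog:
    """Reference set of splice junctions keyed by (chrom, strand, left, right)."""

    def __init__(self, junctions: Iterable[tuple[str, str, int, int]] = ()) -> None:
        self._set: set[tuple[str, str, int, int]] = set(junctions)

    @classmethod
    def from_transcripts(cls, transcripts: Iterable[TranscriptModel]) -> "JunctionCatalog":
        cat = cls()
        for t in transcripts:
            cat._set.update(t.junction_keys())
        return cat

    def __contains__(self, key: tuple[str, str, int, int]) -> bool:
        return key in self._set

    def __len__(self) -> int:
        return len(self._set)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, JunctionCatalog) and self._set == other._set


def write_gtf(transcripts: Sequence[TranscriptModel], path: str | Path) -> None:
    lines = []
    for t in transcripts:
        attrs = f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}";'
        t_start = t.exons[0][0]
        t_end = t.exons[-1][1]
        lines.append(
            f"{t.chrom}\tmyotime\ttranscript\t{t_start}\t{t_end}\t.\t{t.strand}\t.\t{attrs}"
        )
        for start, end in t.exons:
            lines.append(
                f"{t.chrom}\tmyotime\texon\t{start}\t{end}\t.\t{t.strand}\t.\t{attrs}"
            )
    Path(path).write_text("\n".join(lines) + "\n")


def _parse_attrs(raw: str, lineno: int) -> dict[str, str]:
    out = {}
    for chunk in raw.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        try:
            key, value = chunk.split(" ", 1)
        except ValueError:
            raise FormatError(f"line {lineno}: bad attribute {chunk!r}")
        out[key] = value.strip().strip('"')
    return out


def read_gtf(path: str | Path) -> list[TranscriptModel]:
    exons: dict[str, dict] = {}
    order: list[str] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 9:
            raise FormatError(f"line {lineno}: expected 9 columns, got {len(fields)}")
        chrom, _, feature, start, end, _, strand, _, attr_raw = fields
        if feature != "exon":
            continue
        if strand not in ("+", "-"):
            raise FormatError(f"line {lineno}: unknown strand {strand!r}")
        start_i, end_i = int(start), int(end)
        if end_i < start_i:
            raise FormatError(f"line {lineno}: end {end_i} < start {start_i}")
        attrs = _parse_attrs(attr_raw, lineno)
        for need in ("transcript_id", "gene_id"):
            if need not in attrs:
                raise FormatError(f"line {lineno}: missing {need}")
        tid = attrs["transcript_id"]
        rec = exons.setdefault(
            tid,
            {"gene_id": attrs["gene_id"], "chrom": chrom, "strand": strand, "exons": []},
        )
        if rec["chrom"] != chrom or rec["strand"] != strand:
            raise FormatError(f"line {lineno}: {tid} spans chrom/strand records")
        rec["exons"].append((start_i, end_i))
        if tid not in order:
            order.append(tid)
    return [
        TranscriptModel(
            tid,
            exons[tid]["gene_id"],
            exons[tid]["chrom"],
            exons[tid]["strand"],
            tuple(exons[tid]["exons"]),
        )
        for tid in order
    ]


# ---------------------------------------------------------------------------
# Transcript-to-gene map
# ---------------------------------------------------------------------------


def write_t2g(t2g: pd.Series, path: str | Path) -> None:
    df = t2g.rename("gene_id").to_frame()
    df.index.name = "transcript_id"
    df.to_csv(path, sep="\t")


def read_t2g(path: str | Path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise FormatError(f"duplicate transcript id in map: {dup!r}")
    return df["gene_id"]


# ---------------------------------------------------------------------------
# Gene sets (GMT)
# ---------------------------------------------------------------------------


@dataclass
class GeneSet:
    name: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.members:
            raise FormatError(f"gene set {self.name!r} is empty")
        self.members = frozenset(self.members)


def read_gmt(path: str | Path) -> list[GeneSet]:
    sets: list[GeneSet] = []
    seen: set[str] = set()
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) < 3:
            raise FormatError(f"line {lineno}: GMT lines need >=3 fields")
        name, _desc, *genes = fields
        genes = [g for g in genes if g]
        if not genes:
            raise FormatError(f"line {lineno}: set {name!r} has no members")
        if name in seen:
            raise FormatError(f"line {lineno}: duplicate set name {name!r}")
        seen.add(name)
        sets.append(GeneSet(name, frozenset(genes)))
    return sets


def write_gmt(sets: Sequence[GeneSet], path: str | Path) -> None:
    lines = [
        "\t".join([s.name, "na", *sorted(s.members)]) for s in sets
    ]
    Path(path).write_text("\n".join(lines) + "\n")
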