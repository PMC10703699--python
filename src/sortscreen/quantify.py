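"""Spacer counting: raw screen reads -> gRNA x sample count matrix.

Reads are assigned by exact spacer lookup (optionally tolerating one
substitution) at a fixed offset or by locating a constant scaffold anchor.
Totals are conserved: assigned + unassigned == reads processed.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .library import GuideLibrary

SAMPLE_COLUMNS = ["sample_id", "donor", "bin", "arm", "marker", "fastq_path"]

AUTO = "auto"


@dataclass
class ReadExtractionSpec:
    """Where the spacer sits in a read.

    ``spacer_offset`` is a fixed 0-based offset, or :data:`AUTO` to locate
    ``anchor_prefix`` (first exact occurrence) and take the following
    ``spacer_length`` bases.  ``max_mismatch`` of 1 allows one substitution
    via the single-substitution neighbourhood of the read spacer.
    """

    spacer_offset: int | str = 0
    anchor_prefix: str = ""
    anchor_suffix: str = ""
    max_mismatch: int = 0

    def __post_init__(self):
        if self.max_mismatch not in (0, 1):
            raise ValueError("max_mismatch must be 0 or 1")
        if self.spacer_offset == AUTO and not self.anchor_prefix:
            raise ValueError("AUTO offset requires an anchor_prefix")


@dataclass
class CountMatrix:
    """gRNA x sample integer counts plus sample metadata."""

    counts: pd.DataFrame  # guides (rows) x samples (columns)
    samples: pd.DataFrame  # one row per sample, SAMPLE_COLUMNS subset
    n_unassigned: pd.Series | None = None

    def __post_init__(self):
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative counts")
        missing = set(self.counts.columns) - set(self.samples["sample_id"])
        if missing:
            raise ValueError(f"samples missing from sample sheet: {sorted(missing)}")

    @property
    def guide_ids(self) -> list[str]:
        return list(self.counts.index)

    def to_tsv(self, path) -> None:
        self.counts.rename_axis("guide_id").to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, counts_path, sample_sheet_path) -> "CountMatrix":
        counts = pd.read_csv(counts_path, sep="\t", index_col=0)
        samples = read_sample_sheet(sample_sheet_path)
        return cls(counts=counts, samples=samples)


def read_sample_sheet(path) -> pd.DataFrame:
    """Read a tab-separated sample sheet (sample_id, donor, bin, arm, ...)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("sample_id", "donor", "bin"):
        if col not in df.columns:
            raise ValueError(f"sample sheet missing required column {col!r}")
    return df


def validate_paired_design(samples: pd.DataFrame) -> None:
    """Every donor must appear in both LOW and HIGH bins exactly once."""
    combos = samples.groupby(["donor", "bin"]).size()
    if (combos > 1).any():
        raise ValueError("duplicate (donor, bin) combinations in sample sheet")
    bins_per_donor = samples.groupby("donor")["bin"].apply(set)
    incomplete = [d for d, b in bins_per_donor.items() if b != {"LOW", "HIGH"}]
    if incomplete:
        raise ValueError(f"donors missing a bin: {incomplete}")


def build_spacer_index(library: GuideLibrary) -> dict[str, str]:
    """Exact-lookup map spacer -> guide_id; collisions are an error."""
    index: dict[str, str] = {}
    for rec in library:
        if rec.spacer in index:
            raise ValueError(
                f"spacer collision: {rec.spacer} shared by "
                f"{index[rec.spacer]} and {rec.guide_id}"
            )
        index[rec.spacer] = rec.guide_id
    return index


def _open_maybe_gzip(path):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path)


def _iter_fastq(handle):
    """Yield (record_number, sequence) from a FASTQ stream; malformed
    records raise with the record number."""
    recno = 0
    while True:
        header = handle.readline()
        if not header:
            return
        recno += 1
        seq = handle.readline().rstrip("\n")
        plus = handle.readline()
        qual = handle.readline().rstrip("\n")
        if not header.startswith("@") or not plus.startswith("+") or not qual:
            raise ValueError(f"malformed FASTQ record {recno}")
        if len(qual) != len(seq):
            raise ValueError(
                f"malformed FASTQ record {recno}: sequence/quality length mismatch"
            )
        yield recno, seq.upper()


def _lookup(spacer: str, index: dict[str, str], max_mismatch: int) -> str | None:
    hit = index.get(spacer)
    if hit is not None or max_mismatch == 0:
        return hit
    # single-substitution neighbourhood
    for i, orig in enumerate(spacer):
        for b in "ACGT":
            if b == orig:
                continue
            hit = index.get(spacer[:i] + b + spacer[i + 1 :])
            if hit is not None:
                return hit
    return None


def count_fastq(
    reads,
    index: dict[str, str],
    spec: ReadExtractionSpec | None = None,
) -> tuple[pd.Series, int]:
    """Count spacer occurrences in a FASTQ stream.

    ``reads`` may be a path (optionally .gz) or an open text handle.
    Returns ``(per-guide counts, n_unassigned)``; counts cover every guide
    in the index (zeros included) and assigned + unassigned equals the
    number of reads.
    """
    if not index:
        raise ValueError("empty spacer index")
    spec = spec or ReadExtractionSpec()
    L = len(next(iter(index)))
    counts: dict[str, int] = dict.fromkeys(index.values(), 0)
    unassigned = 0
    own_handle = isinstance(reads, (str, Path))
    handle = _open_maybe_gzip(reads) if own_handle else reads
    try:
        for _, seq in _iter_fastq(handle):
            if spec.spacer_offset == AUTO:
                pos = seq.find(spec.anchor_prefix)
                if pos < 0:
                    unassigned += 1
                    continue
                off = pos + len(spec.anchor_prefix)
            else:
                off = int(spec.spacer_offset)
            spacer = seq[off : off + L]
            if len(spacer) < L:
                unassigned += 1
                continue
            hit = _lookup(spacer, index, spec.max_mismatch)
            if hit is None:
                unassigned += 1
            else:
                counts[hit] += 1
    finally:
        if own_handle:
            handle.close()
    return pd.Series(counts, name="count"), unassigned


def count_samples(
    samples: pd.DataFrame,
    library: GuideLibrary,
    spec: ReadExtractionSpec | None = None,
) -> CountMatrix:
    """Count every sample in a sample sheet into one matrix."""
    index = build_spacer_index(library)
    cols, unassigned = {}, {}
    for _, row in samples.iterrows():
        c, u = count_fastq(row["fastq_path"], index, spec)
        cols[row["sample_id"]] = c
        unassigned[row["sample_id"]] = u
    counts = pd.DataFrame(cols).loc[library.guide_ids]
    return CountMatrix(
        counts=counts, samples=samples, n_unassigned=pd.Series(unassigned)
    )


def coverage_report(
    count_matrix: CountMatrix,
    library_size: int,
    cells_sorted: dict[str, int] | None = None,
    floor: float = 300.0,
) -> pd.DataFrame:
    """Per-sample fold coverage: reads (and optionally sorted cells) per
    library guide, flagging samples below ``floor`` (default 300x, the
    screens' minimum sort coverage)."""
    if library_size <= 0:
        raise ValueError("library_size must be positive")
    totals = count_matrix.counts.sum(axis=0)
    out = pd.DataFrame(
        {
            "reads": totals,
            "coverage_reads": totals / library_size,
        }
    )
    if cells_sorted is not None:
        out["coverage_cells"] = pd.Series(cells_sorted) / library_size
        out["below_floor"] = (out["coverage_reads"] < floor) | (
            out["coverage_cells"] < floor
        )
    else:
        out["below_floor"] = out["coverage_reads"] < floor
    return out
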