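"""Strand-aware per-base counting of aligned-fragment 3' ends.

The assay's signal is the 3'-terminal base of each sequenced fragment.  For
a + strand BED record with half-open interval [start, end) the 3' end is the
1-based position ``end``; for a - strand record it would be ``start + 1``.
Only sense (+) records are counted by default, because the reference is the
transcribed strand.  Column sums of the resulting matrix always equal the
number of retained records per sample (conservation), which is asserted on
every run.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "BedParseError",
    "EndCountMatrix",
    "read_bed",
    "count_ends",
    "merge_matrix",
    "write_tracks",
    "write_matrix",
    "read_matrix",
]

_BED_COLS = ["chrom", "start", "end", "name", "score", "strand"]


class BedParseError(ValueError):
    """Malformed BED line; carries the offending line number."""

    def __init__(self, message: str, line_number: int):
        self.line_number = line_number
        super().__init__(f"line {line_number}: {message}")


@dataclasses.dataclass
class EndCountMatrix:
    """positions x samples matrix of 3'-end counts with a design table.

    ``counts`` is indexed by 1-based position 1..L; ``design`` has columns
    (sample, condition, replicate) with condition in {control, oxidized}.
    Columns are canonically ordered: controls then oxidized, by replicate.
    """

    reference_name: str
    counts: pd.DataFrame
    design: pd.DataFrame

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ValueError("counts must be nonnegative")
        if list(self.counts.columns) != list(self.design["sample"]):
            raise ValueError("count columns must match design sample order")

    @property
    def n_positions(self) -> int:
        return len(self.counts)

    def condition_samples(self, condition: str) -> list[str]:
        return list(self.design.loc[self.design["condition"] == condition, "sample"])


def read_bed(path: str | Path) -> pd.DataFrame:
    """Parse a BED6 file with per-line validation."""
    rows = []
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise BedParseError(f"expected >= 6 fields, got {len(fields)}", i)
            chrom, start_s, end_s, name, score, strand = fields[:6]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise BedParseError(f"non-integer coordinates {start_s!r}/{end_s!r}", i) from exc
            if start < 0 or start >= end:
                raise BedParseError(f"invalid interval [{start}, {end})", i)
            if strand not in ("+", "-"):
                raise BedParseError(f"invalid strand {strand!r}", i)
            rows.append((chrom, start, end, name, score, strand))
    return pd.DataFrame(rows, columns=_BED_COLS)


def count_ends(
    bed: pd.DataFrame,
    reference_length: int,
    reference_name: str | None = None,
    sense_only: bool = True,
):
    """Count fragment 3' ends per base position.

    Returns ``(vector, n_retained)`` where ``vector[i]`` is the count at
    1-based position ``i + 1``.  With ``sense_only=False`` the vector is a
    dict ``{'+': vec, '-': vec}`` and both strands are counted into separate
    tracks.  Records on other references or out of bounds are dropped.
    """
    df = bed
    if reference_name is not None and len(df):
        df = df[df["chrom"] == reference_name]
    L = reference_length

    def _count(ends_1based: np.ndarray) -> np.ndarray:
        ok = (ends_1based >= 1) & (ends_1based <= L)
        return np.bincount(ends_1based[ok], minlength=L + 1)[1:].astype(np.int64), int(ok.sum())

    plus = df[df["strand"] == "+"] if len(df) else df
    ends_plus = plus["end"].to_numpy(dtype=np.int64) if len(plus) else np.empty(0, np.int64)
    vec_plus, n_plus = _count(ends_plus)
    assert int(vec_plus.sum()) == n_plus, "conservation violated on + strand"

    if sense_only:
        return vec_plus, n_plus

    minus = df[df["strand"] == "-"] if len(df) else df
    # 3' end of a - strand fragment sits at the interval start
    ends_minus = (
        minus["start"].to_numpy(dtype=np.int64) + 1 if len(minus) else np.empty(0, np.int64)
    )
    vec_minus, n_minus = _count(ends_minus)
    assert int(vec_minus.sum()) == n_minus, "conservation violated on - strand"
    return {"+": vec_plus, "-": vec_minus}, n_plus + n_minus


def merge_matrix(
    vectors: Mapping[str, np.ndarray],
    design: pd.DataFrame,
    reference_name: str = "ref",
) -> EndCountMatrix:
    """Assemble per-sample vectors into a canonical matrix.

    ``design`` needs columns (sample, condition, replicate) covering every
    vector; the output column order is controls then oxidized, each sorted
    by replicate index, regardless of input order.
    """
    design = design.copy()
    missing = set(design["sample"]) - set(vectors)
    if missing:
        raise ValueError(f"design samples without count vectors: {sorted(missing)}")
    lengths = {len(v) for v in vectors.values()}
    if len(lengths) != 1:
        raise ValueError(f"count vectors have mismatched lengths: {sorted(lengths)}")
    for condition in ("control", "oxidized"):
        if not (design["condition"] == condition).any():
            raise ValueError(f"design has no {condition} samples")
    order = {"control": 0, "oxidized": 1}
    design["_key"] = design["condition"].map(order)
    if design["_key"].isna().any():
        bad = design.loc[design["_key"].isna(), "condition"].unique()
        raise ValueError(f"unknown condition labels: {list(bad)}")
    design = design.sort_values(["_key", "replicate"], kind="stable").drop(columns="_key")
    design = design.reset_index(drop=True)
    L = lengths.pop()
    counts = pd.DataFrame(
        {s: np.asarray(vectors[s], dtype=np.int64) for s in design["sample"]},
        index=pd.RangeIndex(1, L + 1, name="pos"),
    )
    return EndCountMatrix(reference_name=reference_name, counts=counts, design=design)


def write_tracks(
    matrix: EndCountMatrix,
    out_dir: str | Path,
    reference_sequence: str | None = None,
) -> dict[str, Path]:
    """Write one bedGraph per sample (nonzero positions only, 0-based
    half-open single-nt intervals) plus a combined TSV with 1-based positions
    (zero rows retained)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for sample in matrix.counts.columns:
        path = out_dir / f"{sample}.bedGraph"
        vec = matrix.counts[sample].to_numpy()
        with open(path, "w") as fh:
            for i in np.nonzero(vec)[0]:
                fh.write(f"{matrix.reference_name}\t{i}\t{i + 1}\t{vec[i]}\n")
        paths[sample] = path
    tsv = out_dir / "end_counts.tsv"
    write_matrix(matrix, tsv, reference_sequence)
    paths["matrix"] = tsv
    return paths


def write_matrix(
    matrix: EndCountMatrix,
    path: str | Path,
    reference_sequence: str | None = None,
) -> None:
    out = matrix.counts.copy()
    if reference_sequence is not None:
        out.insert(0, "base", list(reference_sequence[: len(out)]))
    out.to_csv(path, sep="\t")


def read_matrix(
    path: str | Path, design: pd.DataFrame, reference_name: str = "ref"
) -> EndCountMatrix:
    df = pd.read_csv(path, sep="\t", index_col="pos")
    if "base" in df.columns:
        df = df.drop(columns="base")
    vectors = {s: df[s].to_numpy(dtype=np.int64) for s in df.columns}
    return merge_matrix(vectors, design, reference_name=reference_name)
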