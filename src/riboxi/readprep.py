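"""Read preprocessing: read-through trimming, UMI extraction, PCR-duplicate
collapsing, and a toy exact mapper for closed-loop tests.

Because library inserts are often shorter than the 75 nt read length, reads
run through the insert into the library linkers; those read-through tails are
trimmed first.  Read 2 begins with the randomer (UMI) followed by the
RT-primer linker-2 segment; after stripping both, PCR duplicates are
collapsed on exact equality of (UMI, first ~5 insert bases of read 2) — the
read-2 anchor identifies the biochemical 3' end of the fragment, which is
the quantity the assay counts.

The mapper here is deliberately minimal (unique 20-mer anchored exact
matching against a single reference); it stands in for a spliced aligner
only so the simulator -> caller loop closes without external binaries.
"""

from __future__ import annotations

import dataclasses
import gzip
from collections import Counter
from pathlib import Path
from typing import Iterable, Iterator, Mapping, TextIO

import pandas as pd

from .chemsim import LINKER2, LINKER3_DNA, READ2_ADAPTER, revcomp

__all__ = [
    "PrepRecord",
    "PrepReport",
    "ReadRejected",
    "ReferenceIndex",
    "trim_readthrough",
    "extract_umi",
    "dedup",
    "toy_map",
    "map_pair",
    "run_prep",
]


class ReadRejected(Exception):
    """A read pair failing structural checks, with a categorical reason."""

    def __init__(self, reason: str):
        self.reason = reason
        super().__init__(reason)


@dataclasses.dataclass
class PrepRecord:
    """A trimmed, UMI-extracted read pair.

    ``insert1`` is the read-1 insert (sense orientation); ``insert2`` is the
    read-2 insert (reverse-complement orientation, i.e. it starts at the
    fragment's 3' end).
    """

    umi: str
    insert1: str
    insert2: str

    @property
    def key5(self) -> str:
        return self.insert2[:5]


@dataclasses.dataclass
class PrepReport:
    pairs_in: int = 0
    trimmed_read1: int = 0
    trimmed_read2: int = 0
    rejected: Counter = dataclasses.field(default_factory=Counter)
    duplicates_removed: int = 0
    unique_out: int = 0
    mapped: int = 0

    def to_frame(self) -> pd.DataFrame:
        rows = [
            ("pairs_in", self.pairs_in),
            ("trimmed_read1", self.trimmed_read1),
            ("trimmed_read2", self.trimmed_read2),
        ]
        rows += [(f"rejected_{reason}", n) for reason, n in sorted(self.rejected.items())]
        rows += [
            ("duplicates_removed", self.duplicates_removed),
            ("unique_out", self.unique_out),
            ("mapped", self.mapped),
        ]
        return pd.DataFrame(rows, columns=["metric", "count"])


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def _trim_one(read: str, adapter: str, min_overlap: int, max_error_rate: float) -> str:
    """Remove the longest adapter occurrence (full internal match, or a
    partial adapter prefix at the read 3' end) with mismatch fraction at most
    ``max_error_rate``.  Untouched reads pass through."""
    if not read or not adapter:
        return read
    i = read.find(adapter)
    if i >= 0:
        return read[:i]
    # exact partial adapter at the read end
    max_ov = min(len(adapter), len(read)) - 1
    for ov in range(max_ov, min_overlap - 1, -1):
        if read.endswith(adapter[:ov]):
            return read[: len(read) - ov]
    if max_error_rate > 0:
        # mismatch-tolerant scan, leftmost (= longest removed suffix) wins
        for start in range(0, len(read) - min_overlap + 1):
            ov = min(len(adapter), len(read) - start)
            if ov < min_overlap:
                break
            if _hamming(read[start : start + ov], adapter[:ov]) <= int(max_error_rate * ov):
                return read[:start]
    return read


def trim_readthrough(
    read1: str,
    read2: str,
    adapter1: str = LINKER3_DNA,
    adapter2: str = READ2_ADAPTER,
    min_overlap: int = 3,
    max_error_rate: float = 0.1,
) -> tuple[str, str]:
    """Trim 3' read-through sequences from both mates.

    Read 1 runs into the 3' DNA linker; read 2 runs into the reverse
    complement of the 5' RNA linker (its DNA equivalent).
    """
    return (
        _trim_one(read1, adapter1, min_overlap, max_error_rate),
        _trim_one(read2, adapter2, min_overlap, max_error_rate),
    )


def extract_umi(
    read2_raw: str,
    umi_len: int = 6,
    linker2: str = LINKER2,
    max_mismatch: int = 1,
) -> tuple[str, str]:
    """Split read 2 into (UMI, insert), verifying the linker-2 segment.

    Raises :class:`ReadRejected` with reason ``too_short`` or
    ``linker_mismatch``.
    """
    need = umi_len + len(linker2)
    if len(read2_raw) < need:
        raise ReadRejected("too_short")
    umi = read2_raw[:umi_len]
    observed = read2_raw[umi_len:need]
    if observed != linker2 and _hamming(observed, linker2) > max_mismatch:
        raise ReadRejected("linker_mismatch")
    return umi, read2_raw[need:]


def dedup(records: Iterable[PrepRecord]) -> tuple[list[PrepRecord], int]:
    """Collapse PCR duplicates on exact (UMI, key5) equality.

    The first occurrence in input order is retained; returns the unique
    records and the number of duplicates removed.
    """
    seen: set[tuple[str, str]] = set()
    unique: list[PrepRecord] = []
    n_in = 0
    for rec in records:
        n_in += 1
        key = (rec.umi, rec.key5)
        if key not in seen:
            seen.add(key)
            unique.append(rec)
    return unique, n_in - len(unique)


# ---------------------------------------------------------------------------
# toy exact mapper


class ReferenceIndex:
    """Unique-k-mer index of a single reference for exact matching."""

    def __init__(self, sequence: str, k: int = 20):
        if k < 1:
            raise ValueError("k must be >= 1")
        self.sequence = sequence
        self.k = k
        index: dict[str, int] = {}
        dup: set[str] = set()
        for i in range(len(sequence) - k + 1):
            kmer = sequence[i : i + k]
            if kmer in dup:
                continue
            if kmer in index:
                del index[kmer]
                dup.add(kmer)
            else:
                index[kmer] = i
        self._index = index

    def locate(
        self, seq: str, lead_slack: int = 0, tail_slack: int = 0
    ) -> tuple[int, int] | None:
        """0-based half-open interval of a unique exact match, else None.

        Adapter trimming cannot detect read-through shorter than its minimum
        overlap, so a trimmed insert may carry up to ``min_overlap - 1``
        foreign bases at its linker-facing edge.  ``lead_slack`` /
        ``tail_slack`` allow skipping/clipping that many unmatched bases at
        the respective edge; the opposite edge is always matched exactly.
        """
        L = len(self.sequence)
        for j in range(0, lead_slack + 1):
            core = seq[j:]
            if len(core) < self.k:
                break
            start = self._index.get(core[: self.k])
            if start is None:
                continue
            for t in range(0, tail_slack + 1):
                end = start + len(core) - t
                if end <= start or end > L:
                    continue
                if self.sequence[start:end] == core[: len(core) - t]:
                    return start, end
        return None


def toy_map(
    insert: str,
    index: ReferenceIndex,
    orientation: str = "sense",
    edge_slack: int = 0,
) -> tuple[int, int, str] | None:
    """Map an insert exactly; ``orientation='revcomp'`` maps its reverse
    complement (read-2 inserts).  Returns (start, end, strand) or None.

    ``edge_slack`` tolerates that many un-trimmable read-through bases at
    the linker-facing edge (the 3' edge of read 1, the 5' edge of the
    reverse-complemented read 2); the fragment's biochemical 3' end is
    always matched exactly.
    """
    if orientation == "sense":
        loc = index.locate(insert, tail_slack=edge_slack)
    else:
        loc = index.locate(revcomp(insert), lead_slack=edge_slack)
    if loc is None:
        return None
    return loc[0], loc[1], "+"


def map_pair(
    record: PrepRecord, index: ReferenceIndex, edge_slack: int = 2
) -> tuple[int, int] | None:
    """Infer the fragment interval of a prepped pair.

    The fragment start comes from read 1 (exact left edge); the biochemical
    3' end comes from read 2, whose first insert base is the last base of
    the fragment (exact right edge).
    """
    loc2 = toy_map(record.insert2, index, orientation="revcomp", edge_slack=edge_slack)
    if loc2 is None:
        return None
    end = loc2[1]
    loc1 = toy_map(record.insert1, index, orientation="sense", edge_slack=edge_slack)
    if loc1 is None:
        return None
    start = loc1[0]
    if start >= end:
        return None
    return start, end


# ---------------------------------------------------------------------------
# file-level driver


def _fastq_reader(path: str | Path) -> Iterator[tuple[str, str, str]]:
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "rt") as fh:
        while True:
            header = fh.readline()
            if not header:
                return
            seq = fh.readline().rstrip("\n")
            fh.readline()
            qual = fh.readline().rstrip("\n")
            yield header.rstrip("\n"), seq, qual


def run_prep(
    fastq1: str | Path,
    fastq2: str | Path,
    out_dir: str | Path | None = None,
    sample: str = "sample",
    umi_len: int = 6,
    linker2: str = LINKER2,
    adapter1: str = LINKER3_DNA,
    adapter2: str = READ2_ADAPTER,
    min_overlap: int = 3,
    max_error_rate: float = 0.1,
    max_linker_mismatch: int = 1,
    reference: str | None = None,
    reference_name: str = "ref",
    mapper_k: int = 20,
) -> tuple[list[PrepRecord], PrepReport, pd.DataFrame | None]:
    """Trim, extract, and deduplicate one paired FASTQ sample.

    If ``out_dir`` is given, writes the deduplicated paired FASTQ
    (``<sample>_R{1,2}.dedup.fastq.gz``) and a TSV prep report.  If
    ``reference`` (a sequence string) is given, unique records are mapped
    with the toy mapper and a BED6 table is returned (and written as
    ``<sample>.bed`` when ``out_dir`` is set).
    """
    report = PrepReport()
    records: list[PrepRecord] = []
    for (h1, s1, _q1), (h2, s2, _q2) in zip(_fastq_reader(fastq1), _fastq_reader(fastq2)):
        report.pairs_in += 1
        if not s1 or not s2:
            report.rejected["empty_read"] += 1
            continue
        t1, t2 = trim_readthrough(s1, s2, adapter1, adapter2, min_overlap, max_error_rate)
        if len(t1) < len(s1):
            report.trimmed_read1 += 1
        if len(t2) < len(s2):
            report.trimmed_read2 += 1
        try:
            umi, insert2 = extract_umi(t2, umi_len, linker2, max_linker_mismatch)
        except ReadRejected as exc:
            report.rejected[exc.reason] += 1
            continue
        records.append(PrepRecord(umi=umi, insert1=t1, insert2=insert2))

    unique, n_dup = dedup(records)
    report.duplicates_removed = n_dup
    report.unique_out = len(unique)

    bed: pd.DataFrame | None = None
    if reference is not None:
        index = ReferenceIndex(reference, k=mapper_k)
        rows = []
        for i, rec in enumerate(unique):
            loc = map_pair(rec, index)
            if loc is not None:
                rows.append((reference_name, loc[0], loc[1], f"{sample}_{i}", 0, "+"))
        report.mapped = len(rows)
        bed = pd.DataFrame(
            rows, columns=["chrom", "start", "end", "name", "score", "strand"]
        )

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        from .chemsim import _open_gz_text  # deterministic gzip writer

        with _open_gz_text(out_dir / f"{sample}_R1.dedup.fastq.gz") as h1, _open_gz_text(
            out_dir / f"{sample}_R2.dedup.fastq.gz"
        ) as h2:
            for i, rec in enumerate(unique):
                h1.write(f"@{sample}:{i}/1\n{rec.insert1}\n+\n{'I' * len(rec.insert1)}\n")
                h2.write(f"@{sample}:{i}/2\n{rec.insert2}\n+\n{'I' * len(rec.insert2)}\n")
        report.to_frame().to_csv(out_dir / f"{sample}.prep_report.tsv", sep="\t", index=False)
        if bed is not None:
            bed.to_csv(out_dir / f"{sample}.bed", sep="\t", index=False, header=False)

    return unique, report, bed
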