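"""Synthetic references and planted 2'-O-methylation landscapes.

A *methylation landscape* assigns each modified position of a reference a
stoichiometry: the fraction of RNA molecules carrying the 2'-O-methyl group
at that position.  Human rRNA carries roughly one ribose methylation per 60
nucleotides, a mix of fully and fractionally methylated positions, which is
what the default site planter and stoichiometry sampler emulate.

Coordinate conventions
----------------------
Internally everything is 0-based half-open (BED style).  All user-facing
TSV positions are 1-based, matching how rRNA sites are named in the
literature (e.g. 28S A3717).  A site at 1-based position ``p`` exports to
the BED interval ``[p-1, p)``.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "ReferenceSet",
    "MethylationLandscape",
    "PackingError",
    "LandscapeParseError",
    "make_reference",
    "plant_sites",
    "default_stoichiometry_sampler",
    "read_landscape",
    "write_landscape",
    "landscape_to_bed",
    "read_reference",
    "write_reference",
]

_ALPHABET = frozenset("ACGT")

#: Sites are never planted within this many nt of either reference end, so
#: fragment-boundary edge cases stay separate from the chemistry under test.
EDGE_EXCLUSION = 5


class PackingError(ValueError):
    """Requested site layout cannot be packed into the reference."""


class LandscapeParseError(ValueError):
    """Malformed landscape file; carries the offending line number."""

    def __init__(self, message: str, line_number: int | None = None):
        self.line_number = line_number
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)


@dataclasses.dataclass(frozen=True)
class ReferenceSet:
    """A named reference sequence over the DNA alphabet (U is normalised to T)."""

    name: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("reference name must be nonempty")
        seq = self.sequence.upper().replace("U", "T")
        bad = set(seq) - _ALPHABET
        if bad:
            raise ValueError(f"sequence contains invalid characters: {sorted(bad)}")
        object.__setattr__(self, "sequence", seq)

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclasses.dataclass
class MethylationLandscape:
    """Per-position methylation stoichiometry over one reference.

    ``sites`` maps 1-based position -> stoichiometry in [0, 1].
    """

    reference_name: str
    sites: dict[int, float]

    def __post_init__(self) -> None:
        self.validate()

    def validate(self, reference_length: int | None = None) -> None:
        for pos, stoich in self.sites.items():
            if not isinstance(pos, (int, np.integer)) or pos < 1:
                raise ValueError(f"site position must be a positive integer, got {pos!r}")
            if not (0.0 <= stoich <= 1.0):
                raise ValueError(f"stoichiometry at {pos} out of [0, 1]: {stoich}")
            if reference_length is not None and pos > reference_length:
                raise ValueError(f"site position {pos} beyond reference length {reference_length}")

    @property
    def positions(self) -> list[int]:
        return sorted(self.sites)

    def stoichiometry_array(self) -> tuple[np.ndarray, np.ndarray]:
        """Sorted positions and matching stoichiometries as arrays."""
        pos = np.array(self.positions, dtype=np.int64)
        return pos, np.array([self.sites[int(p)] for p in pos], dtype=float)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MethylationLandscape):
            return NotImplemented
        return self.reference_name == other.reference_name and self.sites == other.sites


def make_reference(
    length: int,
    gc_fraction: float = 0.5,
    seed: int = 0,
    name: str = "synthetic_rRNA",
) -> ReferenceSet:
    """Draw a random reference with the requested GC content.

    Each base is sampled i.i.d.: G and C with probability ``gc_fraction / 2``
    each, A and T with ``(1 - gc_fraction) / 2``.
    """
    if length < 200:
        raise ValueError(f"reference length must be >= 200, got {length}")
    if not (0.0 <= gc_fraction <= 1.0):
        raise ValueError("gc_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    probs = np.array(
        [(1 - gc_fraction) / 2, gc_fraction / 2, gc_fraction / 2, (1 - gc_fraction) / 2]
    )
    bases = np.array(list("ACGT"))
    seq = "".join(bases[rng.choice(4, size=length, p=probs)])
    return ReferenceSet(name=name, sequence=seq)


def default_stoichiometry_sampler(rng: np.random.Generator, n: int) -> np.ndarray:
    """Mixture emulating rRNA methylation: 80% fully methylated, 20% fractional
    with stoichiometry uniform on [0.3, 0.9]."""
    full = rng.random(n) < 0.8
    frac = rng.uniform(0.3, 0.9, size=n)
    return np.where(full, 1.0, frac)


def plant_sites(
    ref: ReferenceSet,
    density: float = 1.0 / 60.0,
    stoichiometries: Sequence[float] | Callable[[np.random.Generator, int], np.ndarray] | None = None,
    min_spacing: int = 5,
    n_backtoback_pairs: int = 0,
    seed: int = 0,
) -> MethylationLandscape:
    """Plant ``round(density * length)`` methylated sites on a reference.

    Exactly ``n_backtoback_pairs`` of the sites are planted as adjacent
    ``(p, p+1)`` pairs; every other pair of sites is separated by at least
    ``min_spacing`` nt.  No site is placed within ``EDGE_EXCLUSION`` nt of
    either reference end.

    ``stoichiometries`` may be an explicit list (assigned to the planted
    positions in ascending position order, recycled if shorter), a callable
    ``f(rng, n) -> array``, or None for the default mixture sampler.
    """
    length = ref.length
    n_total = int(round(density * length))
    if n_total < 1:
        raise ValueError("density * length must be >= 1")
    if min_spacing < 0:
        raise ValueError("min_spacing must be >= 0")
    if n_backtoback_pairs < 0 or 2 * n_backtoback_pairs > n_total:
        raise ValueError("n_backtoback_pairs must satisfy 0 <= 2*pairs <= total sites")

    rng = np.random.default_rng(seed)
    lo, hi = EDGE_EXCLUSION + 1, length - EDGE_EXCLUSION  # inclusive 1-based range
    if hi <= lo:
        raise PackingError("reference too short for edge exclusion")

    n_singles = n_total - 2 * n_backtoback_pairs
    spacing = max(min_spacing, 1)
    placed: list[int] = []

    def fits(p: int, width: int) -> bool:
        # unit occupies 1-based positions [p, p + width - 1]
        if p < lo or p + width - 1 > hi:
            return False
        for q in placed:
            if p - spacing < q < p + width - 1 + spacing:
                return False
        return True

    units = [2] * n_backtoback_pairs + [1] * n_singles  # pairs first: hardest to pack
    max_tries = 1000 * max(n_total, 1)
    tries = 0
    for width in units:
        while True:
            tries += 1
            if tries > max_tries:
                raise PackingError(
                    f"could not pack {n_total} sites ({n_backtoback_pairs} adjacent pairs, "
                    f"min_spacing={min_spacing}) into {length} nt"
                )
            p = int(rng.integers(lo, hi - width + 2))
            if fits(p, width):
                placed.extend(range(p, p + width))
                break

    positions = sorted(placed)
    if callable(stoichiometries):
        stoich = np.asarray(stoichiometries(rng, n_total), dtype=float)
    elif stoichiometries is not None:
        vals = list(stoichiometries)
        stoich = np.array([vals[i % len(vals)] for i in range(n_total)], dtype=float)
    else:
        stoich = default_stoichiometry_sampler(rng, n_total)
    sites = {int(p): float(s) for p, s in zip(positions, stoich)}
    return MethylationLandscape(reference_name=ref.name, sites=sites)


# ---------------------------------------------------------------------------
# serialization


def write_landscape(landscape: MethylationLandscape, path: str | Path) -> None:
    """Write a landscape as TSV with columns ref, pos (1-based), stoichiometry."""
    path = Path(path)
    lines = ["ref\tpos\tstoichiometry"]
    for pos in landscape.positions:
        lines.append(f"{landscape.reference_name}\t{pos}\t{landscape.sites[pos]:.6g}")
    path.write_text("\n".join(lines) + "\n")


def read_landscape(path: str | Path) -> MethylationLandscape:
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines:
        raise LandscapeParseError("empty landscape file")
    header = lines[0].split("\t")
    if header[:3] != ["ref", "pos", "stoichiometry"]:
        raise LandscapeParseError(f"unexpected header {header!r}", line_number=1)
    ref_name: str | None = None
    sites: dict[int, float] = {}
    for i, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) != 3:
            raise LandscapeParseError(f"expected 3 tab-separated fields, got {len(fields)}", i)
        ref, pos_s, stoich_s = fields
        try:
            pos = int(pos_s)
            stoich = float(stoich_s)
        except ValueError as exc:
            raise LandscapeParseError(str(exc), i) from exc
        if pos < 1:
            raise LandscapeParseError(f"position must be >= 1, got {pos}", i)
        if not (0.0 <= stoich <= 1.0):
            raise LandscapeParseError(f"stoichiometry out of [0, 1]: {stoich}", i)
        if ref_name is None:
            ref_name = ref
        elif ref != ref_name:
            raise LandscapeParseError(f"multiple reference names ({ref_name!r}, {ref!r})", i)
        sites[pos] = stoich
    if ref_name is None:
        raise LandscapeParseError("landscape file has no site rows")
    return MethylationLandscape(reference_name=ref_name, sites=sites)


def landscape_to_bed(landscape: MethylationLandscape, path: str | Path) -> None:
    """Export sites as BED6 single-nt intervals (0-based half-open, + strand).

    The score column encodes stoichiometry scaled to 0-1000.
    """
    path = Path(path)
    lines = []
    for pos in landscape.positions:
        stoich = landscape.sites[pos]
        lines.append(
            f"{landscape.reference_name}\t{pos - 1}\t{pos}\tNm_{pos}\t{int(round(1000 * stoich))}\t+"
        )
    path.write_text("\n".join(lines) + ("\n" if lines else ""))


def write_reference(ref: ReferenceSet, path: str | Path) -> None:
    record = SeqRecord(Seq(ref.sequence), id=ref.name, description="")
    SeqIO.write([record], str(path), "fasta")


def read_reference(path: str | Path) -> ReferenceSet:
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) != 1:
        raise ValueError(f"expected exactly one FASTA record, found {len(records)}")
    rec = records[0]
    return ReferenceSet(name=rec.id, sequence=str(rec.seq))
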