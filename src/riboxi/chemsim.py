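"""Forward simulation of the ribose-oxidation sequencing chemistry.

The assay turns 2'-O-methylated (Nm) positions into 3'-end sequencing signal
through four chemical facts, which are the rules this module encodes:

1. Benzonase digests RNA randomly but cannot cleave the phosphodiester bond
   immediately 3' of an Nm base, so no digestion fragment ever ends exactly
   at a methylated position; the closest possible 3' end is one base
   downstream.
2. Periodate oxidation converts a terminal 2',3'-diol to a dialdehyde;
   beta-elimination then removes that oxidized terminal base, walking the
   fragment end back one nucleotide per round.  A terminal Nm base is
   protected from oxidation, so the walk stops there.
3. After k oxidation/elimination rounds, a final oxidation leaves only
   Nm-terminated fragments ligatable.  Incomplete oxidation (and imperfect
   phosphatase chemistry) is lumped into a small background leak rate
   ``epsilon = 1 - oxidation_efficiency`` at which unmethylated ends survive.
4. Library construction appends a 3' DNA linker, and reverse transcription
   adds a randomer (UMI) plus a linker-2 segment that appears at the start of
   read 2, enabling PCR-duplicate collapsing downstream.

Control libraries take the raw digestion fragments (no elimination, no
oxidation); oxidized libraries take the post-selection pool.  Both are
emitted as paired FASTQ plus a truth BED of the underlying fragment
intervals on the + strand.
"""

from __future__ import annotations

import dataclasses
import gzip
import io
import json
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

from .landscape import MethylationLandscape, ReferenceSet, write_landscape, write_reference

__all__ = [
    "ChemParams",
    "Molecule",
    "Fragment",
    "FragmentBatch",
    "ReadPair",
    "revcomp",
    "realize_molecules",
    "benzonase_fragment",
    "beta_eliminate",
    "final_oxidation_select",
    "build_library",
    "simulate_fragments",
    "simulate_experiment",
    "LINKER3_DNA",
    "LINKER2",
    "READ2_ADAPTER",
    "READ1_TAIL",
]

# Library oligo structure (DNA alphabet, as the sequencer reports it).
#: 3' DNA linker ligated to ligatable fragment ends; read 1 runs into it.
LINKER3_DNA = "CTGTAGGCACCATCAAT"
#: RT-primer segment immediately 3' of the randomer; prefix of read 2 after
#: the UMI.  Reverse complement of the 3' DNA linker.
LINKER2 = "ATTGATGGTGCCTACAG"
#: DNA equivalent of the 5' RNA linker.
RNA_LINKER5_DNA = "ACACGACGCTCTTCCGATCT"
#: Read-through adapter seen at the 3' end of read 2 (revcomp of the 5' linker).
READ2_ADAPTER = "AGATCGGAAGAGCGTCGTGT"
#: Read-through tail on read 1 after the 3' linker and reverse-complemented UMI
#: (revcomp of the RT-primer 5' arm).
READ1_TAIL = "AGATCGGAAGAGCACACGTCTGAACTCCAGTCAC"

_COMPLEMENT = str.maketrans("ACGTUN", "TGCAAN")

# 3'-end chemical states
STATE_OH = "OH"
STATE_OXIDIZED = "OXIDIZED"
STATE_NM_PROTECTED = "NM_PROTECTED"


def revcomp(seq: str) -> str:
    """Reverse complement on the DNA alphabet (U treated as T)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclasses.dataclass
class ChemParams:
    """Chemistry and library parameters for one simulated experiment.

    cleavage_rate
        Per-bond Bernoulli cleavage probability of the Benzonase digest.  The
        default 0.02 centres fragment lengths inside the 25-150 nt window the
        protocol size-selects for.
    size_min, size_max
        Retained fragment length window (nt).
    beta_rounds
        Number k of oxidation + beta-elimination rounds applied to the
        oxidized arm; each round exposes one additional base upstream.
    beta_efficiency
        Per-round probability that an unprotected terminal base is actually
        removed (1.0 = complete reaction).
    oxidation_efficiency
        pi, the probability that an unmethylated 3' end is destroyed by the
        final oxidation; epsilon = 1 - pi is the background leak that turns
        into false 3'-end signal.
    ligation_bias
        Optional base -> relative ligation weight map (None = unbiased).
    n_molecules
        Input RNA molecules per replicate.
    pcr_dup_mean
        Mean PCR copies per library fragment; copies ~ 1 + Poisson(mean - 1).
    umi_length, read_length, seq_error_rate
        Randomer length, paired-read length, and optional uniform substitution
        error rate (0 = error-free reads).
    include_native_terminus
        If True, also emit the fragment running to the molecule's native 3'
        end (excluded by default to avoid an artifactual reference-end peak).
    """

    cleavage_rate: float = 0.02
    size_min: int = 25
    size_max: int = 150
    beta_rounds: int = 1
    beta_efficiency: float = 1.0
    oxidation_efficiency: float = 0.995
    ligation_bias: Mapping[str, float] | None = None
    n_molecules: int = 5000
    pcr_dup_mean: float = 1.2
    umi_length: int = 6
    read_length: int = 75
    seq_error_rate: float = 0.0
    include_native_terminus: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.cleavage_rate < 1.0):
            # 0 is allowed as the degenerate no-digestion case
            raise ValueError("cleavage_rate must be in [0, 1)")
        if self.size_min < 20:
            raise ValueError("size_min must be >= 20")
        if self.size_max < self.size_min:
            raise ValueError("size_max must be >= size_min")
        if self.beta_rounds < 0:
            raise ValueError("beta_rounds must be >= 0")
        for name in ("beta_efficiency", "oxidation_efficiency", "seq_error_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]")
        if self.pcr_dup_mean < 1.0:
            raise ValueError("pcr_dup_mean must be >= 1")
        if self.n_molecules < 1:
            raise ValueError("n_molecules must be >= 1")
        if self.umi_length < 1:
            raise ValueError("umi_length must be >= 1")

    @property
    def background_leak(self) -> float:
        return 1.0 - self.oxidation_efficiency


@dataclasses.dataclass(frozen=True)
class Molecule:
    """One RNA molecule with its realized methylation pattern (1-based positions)."""

    reference_name: str
    methylated_positions: frozenset[int]


@dataclasses.dataclass
class Fragment:
    """A digestion fragment, 0-based half-open on the reference.

    The 1-based position of the 3'-terminal nucleotide equals ``end``.
    """

    start: int
    end: int
    three_prime_state: str
    molecule_id: int = 0

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclasses.dataclass
class ReadPair:
    read1: str
    read2: str
    umi: str
    truth_fragment: Fragment


@dataclasses.dataclass
class FragmentBatch:
    """Column-oriented fragment pool (vectorized counterpart of list[Fragment])."""

    start: np.ndarray  # int64, 0-based
    end: np.ndarray  # int64, half-open
    protected: np.ndarray  # bool: 3'-terminal base methylated on its molecule
    molecule_id: np.ndarray  # int64

    def __len__(self) -> int:
        return len(self.start)


# ---------------------------------------------------------------------------
# scalar operations (the per-molecule contract; unit-test surface)


def realize_molecules(
    landscape: MethylationLandscape,
    n_molecules: int,
    seed: int | np.random.Generator = 0,
) -> Iterator[Molecule]:
    """Realize molecule-level methylation: each site is methylated
    independently per molecule with probability equal to its stoichiometry."""
    if n_molecules < 1:
        raise ValueError("n_molecules must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    pos, stoich = landscape.stoichiometry_array()
    for _ in range(n_molecules):
        hit = rng.random(len(pos)) < stoich
        yield Molecule(
            reference_name=landscape.reference_name,
            methylated_positions=frozenset(int(p) for p in pos[hit]),
        )


def benzonase_fragment(
    molecule: Molecule,
    reference_length: int,
    params: ChemParams,
    rng: np.random.Generator,
    size_select: bool = True,
) -> list[Fragment]:
    """Digest one molecule: every internal bond cleaved independently with
    probability ``cleavage_rate`` except bonds immediately 3' of a methylated
    base, which never cleave.  Fragments outside the size window are
    discarded; the native 3'-terminal fragment is dropped unless configured
    otherwise."""
    L = reference_length
    theta = params.cleavage_rate
    # bond i (1-based, i = 1..L-1) separates positions i and i+1; cleaving it
    # produces a fragment 3' end at position i.
    cut = rng.random(L - 1) < theta
    for p in molecule.methylated_positions:
        if 1 <= p <= L - 1:
            cut[p - 1] = False
    ends = np.nonzero(cut)[0] + 1
    fragments: list[Fragment] = []
    prev = 0
    for e in ends:
        fragments.append(_make_fragment(prev, int(e), molecule))
        prev = int(e)
    if params.include_native_terminus and prev < L:
        fragments.append(_make_fragment(prev, L, molecule))
    if not size_select:
        return fragments
    return [f for f in fragments if params.size_min <= f.length <= params.size_max]


def _make_fragment(start: int, end: int, molecule: Molecule) -> Fragment:
    state = STATE_NM_PROTECTED if end in molecule.methylated_positions else STATE_OH
    return Fragment(start=start, end=end, three_prime_state=state)


def beta_eliminate(
    fragment: Fragment,
    molecule: Molecule,
    k: int,
    eta: float,
    rng: np.random.Generator,
    size_min: int = 25,
) -> Fragment | None:
    """Apply k rounds of oxidation + beta-elimination to one fragment.

    Each round: a methylated terminal base is protected (no change); an
    unmethylated terminal base is removed with probability ``eta``.  Returns
    None if the fragment shrinks below ``size_min``.
    """
    if k < 0:
        raise ValueError("k must be >= 0")
    end = fragment.end
    for _ in range(k):
        if end in molecule.methylated_positions:
            break
        if rng.random() < eta:
            end -= 1
            if end - fragment.start < size_min:
                return None
    state = STATE_NM_PROTECTED if end in molecule.methylated_positions else STATE_OH
    return Fragment(
        start=fragment.start,
        end=end,
        three_prime_state=state,
        molecule_id=fragment.molecule_id,
    )


def final_oxidation_select(
    fragments: Iterable[Fragment],
    pi: float,
    rng: np.random.Generator,
) -> list[Fragment]:
    """Final oxidation: Nm-protected ends always stay ligatable; unmethylated
    (OH) ends survive only with the leak probability ``1 - pi``."""
    eps = 1.0 - pi
    kept = []
    for f in fragments:
        if f.three_prime_state == STATE_NM_PROTECTED:
            kept.append(f)
        elif rng.random() < eps:
            kept.append(f)
    return kept


# ---------------------------------------------------------------------------
# vectorized fragment engine


def _realize_batch(
    stoich: np.ndarray, n: int, rng: np.random.Generator
) -> np.ndarray:
    """(n, n_sites) boolean methylation realization."""
    return rng.random((n, len(stoich))) < stoich


def simulate_fragments(
    landscape: MethylationLandscape,
    reference_length: int,
    params: ChemParams,
    condition: str,
    rng: np.random.Generator,
    n_molecules: int | None = None,
    batch_size: int = 1000,
) -> FragmentBatch:
    """Simulate the fragment pool of one replicate.

    ``condition='control'`` returns the raw size-selected digest;
    ``condition='oxidized'`` additionally applies ``beta_rounds`` of
    oxidation/elimination and the final oxidation selection.
    """
    if condition not in ("control", "oxidized"):
        raise ValueError(f"unknown condition {condition!r}")
    L = reference_length
    n_mol = params.n_molecules if n_molecules is None else n_molecules
    site_pos, stoich = landscape.stoichiometry_array()
    # map reference position -> site column (-1 if unmethylatable)
    site_col = np.full(L + 2, -1, dtype=np.int64)
    site_col[site_pos] = np.arange(len(site_pos))

    out_start: list[np.ndarray] = []
    out_end: list[np.ndarray] = []
    out_prot: list[np.ndarray] = []
    out_mol: list[np.ndarray] = []

    blocked_cols = site_pos[site_pos <= L - 1] - 1  # bond indices blocked by Nm
    blocked_site_idx = np.nonzero(site_pos <= L - 1)[0]

    for offset in range(0, n_mol, batch_size):
        m = min(batch_size, n_mol - offset)
        meth = _realize_batch(stoich, m, rng)
        cut = rng.random((m, L - 1)) < params.cleavage_rate
        if len(blocked_cols):
            cut[:, blocked_cols] &= ~meth[:, blocked_site_idx]

        rows, bonds = np.nonzero(cut)
        ends = bonds + 1  # 1-based 3' end == half-open end coordinate
        if len(rows) == 0:
            continue
        new_row = np.empty(len(rows), dtype=bool)
        new_row[0] = True
        np.not_equal(rows[1:], rows[:-1], out=new_row[1:])
        starts = np.where(new_row, 0, np.concatenate(([0], ends[:-1])))
        frag_rows = rows
        frag_start = starts.astype(np.int64)
        frag_end = ends.astype(np.int64)

        if params.include_native_terminus:
            last_idx = np.nonzero(
                np.concatenate((new_row[1:], [True]))
            )[0]  # last fragment index per row with >=1 cut
            nat_rows = rows[last_idx]
            nat_start = ends[last_idx].astype(np.int64)
            frag_rows = np.concatenate((frag_rows, nat_rows))
            frag_start = np.concatenate((frag_start, nat_start))
            frag_end = np.concatenate((frag_end, np.full(len(nat_rows), L, dtype=np.int64)))

        length = frag_end - frag_start
        keep = (length >= params.size_min) & (length <= params.size_max)
        frag_rows, frag_start, frag_end = frag_rows[keep], frag_start[keep], frag_end[keep]

        def _is_meth_terminal(end_arr: np.ndarray, row_arr: np.ndarray) -> np.ndarray:
            sidx = site_col[end_arr]
            hit = sidx >= 0
            out = np.zeros(len(end_arr), dtype=bool)
            if hit.any():
                out[hit] = meth[row_arr[hit], sidx[hit]]
            return out

        if condition == "oxidized":
            for _ in range(params.beta_rounds):
                protected = _is_meth_terminal(frag_end, frag_rows)
                eliminate = ~protected
                if params.beta_efficiency < 1.0:
                    eliminate &= rng.random(len(frag_end)) < params.beta_efficiency
                frag_end = frag_end - eliminate.astype(np.int64)
                keep = frag_end - frag_start >= params.size_min
                frag_rows, frag_start, frag_end = (
                    frag_rows[keep],
                    frag_start[keep],
                    frag_end[keep],
                )
            protected = _is_meth_terminal(frag_end, frag_rows)
            keep = protected | (rng.random(len(frag_end)) < params.background_leak)
            frag_rows, frag_start, frag_end = frag_rows[keep], frag_start[keep], frag_end[keep]
            protected = protected[keep]
        else:
            # Benzonase cannot cleave 3' of Nm, so no digest fragment ends
            # methylated (native termini excluded above unless configured;
            # an included native terminus may be methylated).
            protected = _is_meth_terminal(frag_end, frag_rows)

        out_start.append(frag_start)
        out_end.append(frag_end)
        out_prot.append(protected)
        out_mol.append(frag_rows.astype(np.int64) + offset)

    if not out_start:
        empty = np.empty(0, dtype=np.int64)
        return FragmentBatch(empty, empty, np.empty(0, dtype=bool), empty.copy())
    return FragmentBatch(
        start=np.concatenate(out_start),
        end=np.concatenate(out_end),
        protected=np.concatenate(out_prot),
        molecule_id=np.concatenate(out_mol),
    )


# ---------------------------------------------------------------------------
# library construction


def _draw_umis(n: int, umi_length: int, rng: np.random.Generator) -> list[str]:
    bases = np.array(list("ACGT"))
    mat = bases[rng.integers(0, 4, size=(n, umi_length))]
    return ["".join(row) for row in mat]


def _ligation_keep(
    frag_end: np.ndarray,
    sequence: str,
    bias: Mapping[str, float] | None,
    rng: np.random.Generator,
) -> np.ndarray:
    if not bias:
        return np.ones(len(frag_end), dtype=bool)
    weights = {b: float(bias.get(b, 1.0)) for b in "ACGT"}
    wmax = max(weights.values())
    if wmax <= 0:
        raise ValueError("ligation_bias weights must contain a positive value")
    seq_arr = np.frombuffer(sequence.encode(), dtype="S1")
    terminal = seq_arr[frag_end - 1]
    prob = np.empty(len(frag_end))
    for b, w in weights.items():
        prob[terminal == b.encode()] = w / wmax
    return rng.random(len(frag_end)) < prob


def _apply_seq_errors(read: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return read
    arr = np.frombuffer(read.encode(), dtype="S1").copy()
    hits = np.nonzero(rng.random(len(arr)) < rate)[0]
    bases = b"ACGT"
    for i in hits:
        choices = [b for b in bases if bytes([b]) != arr[i]]
        arr[i] = bytes([choices[rng.integers(0, 3)]])
    return arr.tobytes().decode()


def _assemble_reads(
    insert: str, umi: str, read_length: int
) -> tuple[str, str]:
    r1 = insert + LINKER3_DNA + revcomp(umi) + READ1_TAIL
    r1 = r1[:read_length].ljust(read_length, "A")
    r2 = umi + LINKER2 + revcomp(insert) + READ2_ADAPTER
    r2 = r2[:read_length].ljust(read_length, "A")
    return r1, r2


def build_library(
    fragments: FragmentBatch | Sequence[Fragment],
    sequence: str,
    condition: str,
    params: ChemParams,
    rng: np.random.Generator,
) -> tuple[list[ReadPair], pd.DataFrame]:
    """Construct read pairs (with UMIs and PCR duplicates) from a ligatable
    fragment pool, and the matching truth BED table (one row per unique
    library fragment, + strand)."""
    if condition not in ("control", "oxidized"):
        raise ValueError(f"unknown condition {condition!r}")
    if isinstance(fragments, FragmentBatch):
        starts, ends, mols = fragments.start, fragments.end, fragments.molecule_id
        prot = fragments.protected
    else:
        starts = np.array([f.start for f in fragments], dtype=np.int64)
        ends = np.array([f.end for f in fragments], dtype=np.int64)
        mols = np.array([f.molecule_id for f in fragments], dtype=np.int64)
        prot = np.array(
            [f.three_prime_state == STATE_NM_PROTECTED for f in fragments], dtype=bool
        )

    keep = _ligation_keep(ends, sequence, params.ligation_bias, rng) if len(ends) else np.empty(0, bool)
    starts, ends, mols, prot = starts[keep], ends[keep], mols[keep], prot[keep]
    n = len(starts)
    umis = _draw_umis(n, params.umi_length, rng)
    if params.pcr_dup_mean > 1.0:
        copies = 1 + rng.poisson(params.pcr_dup_mean - 1.0, size=n)
    else:
        copies = np.ones(n, dtype=np.int64)

    pairs: list[ReadPair] = []
    bed_rows = []
    for i in range(n):
        insert = sequence[starts[i] : ends[i]]
        r1, r2 = _assemble_reads(insert, umis[i], params.read_length)
        frag = Fragment(
            start=int(starts[i]),
            end=int(ends[i]),
            three_prime_state=STATE_NM_PROTECTED if prot[i] else STATE_OH,
            molecule_id=int(mols[i]),
        )
        for _c in range(copies[i]):
            if params.seq_error_rate > 0:
                pairs.append(
                    ReadPair(
                        read1=_apply_seq_errors(r1, params.seq_error_rate, rng),
                        read2=_apply_seq_errors(r2, params.seq_error_rate, rng),
                        umi=umis[i],
                        truth_fragment=frag,
                    )
                )
            else:
                pairs.append(ReadPair(read1=r1, read2=r2, umi=umis[i], truth_fragment=frag))
        bed_rows.append((int(starts[i]), int(ends[i]), i))
    bed = pd.DataFrame(bed_rows, columns=["start", "end", "frag_id"])
    return pairs, bed


# ---------------------------------------------------------------------------
# experiment driver


def _open_gz_text(path: Path) -> io.TextIOWrapper:
    """Deterministic gzip writer (fixed mtime so reruns are byte-identical)."""
    raw = open(path, "wb")
    gz = gzip.GzipFile(filename="", mode="wb", fileobj=raw, compresslevel=1, mtime=0)
    return io.TextIOWrapper(gz, encoding="ascii", newline="\n")


def _write_fastq_pair(
    pairs: list[ReadPair], sample: str, fq1: Path, fq2: Path, read_length: int
) -> int:
    qual = "I" * read_length
    n = 0
    with _open_gz_text(fq1) as h1, _open_gz_text(fq2) as h2:
        for i, p in enumerate(pairs):
            name = f"@{sample}:{p.truth_fragment.molecule_id}:{i}"
            h1.write(f"{name}/1\n{p.read1}\n+\n{qual[: len(p.read1)]}\n")
            h2.write(f"{name}/2\n{p.read2}\n+\n{qual[: len(p.read2)]}\n")
            n += 1
    return n


def simulate_experiment(
    reference: ReferenceSet,
    landscape: MethylationLandscape,
    params: ChemParams,
    n_control_reps: int = 3,
    n_oxidized_reps: int = 3,
    out_dir: str | Path = ".",
    write_fastq: bool = True,
) -> pd.DataFrame:
    """Simulate a full replicated experiment and write its artifacts.

    Writes per-replicate paired FASTQ (optional) and truth BED6, plus the
    reference FASTA, the truth landscape TSV, a parameter echo (JSON) and a
    TSV manifest.  All randomness derives from ``params.seed`` via per-sample
    child seeds recorded in the manifest; reruns are byte-identical.
    """
    if n_control_reps < 1 or n_oxidized_reps < 1:
        raise ValueError("need at least one replicate per condition")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    landscape.validate(reference.length)

    ref_fa = out_dir / "reference.fa"
    truth_tsv = out_dir / "truth_landscape.tsv"
    write_reference(reference, ref_fa)
    write_landscape(landscape, truth_tsv)

    samples = [("control", r) for r in range(1, n_control_reps + 1)] + [
        ("oxidized", r) for r in range(1, n_oxidized_reps + 1)
    ]
    ss = np.random.SeedSequence(params.seed)
    children = ss.spawn(len(samples))

    rows = []
    for (condition, rep), child in zip(samples, children):
        sample = f"{condition}_{rep}"
        rng = np.random.default_rng(child)
        frags = simulate_fragments(landscape, reference.length, params, condition, rng)
        pairs, bed = build_library(frags, reference.sequence, condition, params, rng)
        bed_path = out_dir / f"{sample}.truth.bed"
        with open(bed_path, "w") as fh:
            for start, end, fid in bed.itertuples(index=False):
                fh.write(f"{reference.name}\t{start}\t{end}\t{sample}_frag{fid}\t0\t+\n")
        fq1 = fq2 = ""
        if write_fastq:
            fq1_p = out_dir / f"{sample}_R1.fastq.gz"
            fq2_p = out_dir / f"{sample}_R2.fastq.gz"
            _write_fastq_pair(pairs, sample, fq1_p, fq2_p, params.read_length)
            fq1, fq2 = fq1_p.name, fq2_p.name
        # manifest paths are relative to the output directory so reruns are
        # byte-identical wherever they land
        rows.append(
            {
                "sample": sample,
                "condition": condition,
                "replicate": rep,
                "fastq1": fq1,
                "fastq2": fq2,
                "truth_bed": bed_path.name,
                "n_fragments": len(bed),
                "n_read_pairs": len(pairs),
                "seed": int(child.generate_state(1)[0] % (2**31)),
            }
        )

    manifest = pd.DataFrame(rows)
    manifest.to_csv(out_dir / "manifest.tsv", sep="\t", index=False)
    echo = dataclasses.asdict(params)
    echo["ligation_bias"] = dict(params.ligation_bias) if params.ligation_bias else None
    (out_dir / "params.json").write_text(json.dumps(echo, indent=2, sort_keys=True) + "\n")
    return manifest
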