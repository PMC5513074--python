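# Methods

## Generative model of the assay

One simulated experiment starts from a reference sequence (i.i.d. bases at a
configurable GC fraction) and a methylation landscape: a map from 1-based
position to stoichiometry in [0, 1]. Positions are planted at a target
density (default 1/60 nt, the approximate Nm density of human cytoplasmic
rRNA), at least 5 nt from the reference ends, with a minimum spacing between
non-adjacent sites and an exact number of adjacent ("back-to-back") pairs.
Stoichiometries default to a mixture — 80 % fully methylated, 20 % uniform
on [0.3, 0.9] — reflecting that most rRNA sites are essentially complete
while a minority are fractional.

Each molecule realizes methylation independently per site with probability
equal to the stoichiometry. The chemistry is then applied per molecule:

1. **Fragmentation.** Every internal phosphodiester bond is cleaved
   independently with probability θ (default 0.02, centring fragment lengths
   in the 25–150 nt window the protocol size-selects), *except* bonds
   immediately 3′ of a methylated base, which never cleave. Fragments
   outside [size_min, size_max] = [25, 150] are discarded. The fragment
   running to the molecule's native 3′ terminus is excluded by default
   (configurable), so reference-end artifacts never mix with chemistry.
2. **Oxidation + β-elimination (oxidized arm only), k rounds.** Each round:
   a methylated 3′-terminal base is protected and unchanged; an unmethylated
   terminal base is removed with probability η (default 1.0), moving the end
   back one base. Fragments shrinking below size_min are discarded. Default
   k = 1: at rRNA site density one round suffices, because fragmentation
   leaves methylated bases at most a few nt inside the 3′ end.
3. **Final oxidation.** Methyl-terminated fragments are always retained;
   unmethylated (2′,3′-OH) ends survive with the background leak probability
   ε = 1 − π (default ε = 0.005). ε lumps every imperfection that lets an
   unprotected end reach ligation — incomplete oxidation and residual
   2′/cyclic phosphates after imperfect phosphatase treatment — since all of
   them manifest identically as uniform background 3′-end signal.
4. **Library.** Control libraries take the raw digest (the control aliquot
   is set aside before any oxidation); oxidized libraries take the
   post-selection pool. Ligation retains a fragment with probability
   proportional to a per-base weight (uniform by default; the real ligases
   are sequence-biased, which is why the assay is not quantitative across
   sites). Each library fragment receives a uniform random UMI (6 nt) and
   1 + Poisson(m − 1) PCR copies (m = `pcr_dup_mean`, default 1.2; the shift
   guarantees at least one copy). Reads are 75 + 75 nt: read 1 is the insert
   running into the 3′ DNA linker, the reverse-complemented UMI and the RT
   primer; read 2 is UMI + linker-2 + reverse-complemented insert running
   into the 5′-linker adapter. Qualities are constant; an optional uniform
   substitution rate (default 0) models sequencing errors.

All randomness flows from one master seed through `numpy.random.SeedSequence`
spawning, one child per sample; two runs with the same seed are
byte-identical (gzip members are written with a fixed mtime).

## Read preparation

Read-through adapters are removed by suffix-overlap matching (minimum
overlap 3, mismatch fraction ≤ 0.1). Read 2 must start with
[UMI][linker-2]; the linker is verified with ≤ 1 mismatch, failures are
counted by reason. PCR duplicates are collapsed on exact equality of
(UMI, first 5 bases of the read-2 insert) — the read-2 anchor encodes the
fragment's biochemical 3′ end, which is the measured quantity. First
occurrence wins; no UMI clustering is attempted, so distinct fragments
sharing a 3′ end collide at rate ≈ n²/(2·4¹¹), negligible at the depths
simulated here.

The bundled mapper is an exact unique-20-mer-anchored matcher over a single
reference — a stand-in for a real aligner that keeps the simulator→caller
loop closed without external binaries. Because overlap trimming cannot see
read-through shorter than the minimum overlap, a trimmed insert may carry
1–2 residual linker bases at its linker-facing edge; the mapper tolerates
exactly that (and nothing else) at that edge, while the fragment's 3′ end is
always matched exactly.

## Counting and testing

For a + strand BED record [start, end) the 3′ end is 1-based position
`end`; − strand records are dropped under the default sense-only counting
(the reference is the transcribed strand). Column sums always equal the
number of retained records (asserted at run time). Zero positions are kept
in the matrix; filtering is the statistics' job.

The differential stage is a deliberately transparent re-implementation of
the standard NB count-comparison workflow ("DESeq2-like", with no claim of
numerical identity — no Cox–Reid adjustment, no shrinkage prior on the
effect):

* **Size factors**: median-of-ratios over positions with strictly positive
  counts in all samples; when fewer than 50 such positions exist (very
  sparse oxidized libraries) library-size ratios are used instead.
* **Dispersion**: per-position method-of-moments α̂ = max(0, (s²−μ)/μ²) on
  normalized counts within each condition (n−1 weighting across
  conditions); a trend α(μ) = a₀ + a₁/μ is fit by least squares over
  positions with α̂ > 0 with only a loose 10-MAD outlier guard — aggressive
  robust trimming was found, in simulations with known dispersion, to bias
  the trend low because α̂ is strongly right-skewed. The final value is the
  even mixture (1−w)·α̂ + w·trend, w = 0.5, floored at 1e−8. With no
  replication anywhere a fixed fallback of 0.1 is used (with a warning).
* **Wald test**: log2FC = log₂((μ̂_oxi+c)/(μ̂_ctrl+c)) with prior count
  c = 0.5 (regularizes the expected all-zero-control signature of true
  sites), delta-method SE using Var(K_j/s_j) = μ/s_j + αμ², two-sided
  normal reference. Positions with total raw count < 10 are reported but
  excluded from testing and from the BH correction, which passes NAs
  through and enforces step-up monotonicity.
* **Calling**: high confidence iff log2FC > 7 and adjusted p < 1e−4;
  relaxed iff log2FC > 6 at the same p cutoff (both strict inequalities);
  thresholds configurable.

Back-to-back annotation: a known site whose +1 neighbour is known or called
is flagged `masking_possible`; if the site itself is uncalled while the
neighbour is called it is flagged `possibly_masked` — chemically, no
nuclease or elimination step can ever expose a 3′ end at a position whose
downstream neighbour is methylated on the same molecule.

## Detectability bound for fractional sites

A useful closed form the simulator reproduces: after normalization the
oxidized/control enrichment at an isolated site of stoichiometry *s* is
approximately

&nbsp;&nbsp;&nbsp;&nbsp;E ≈ purity · (L/Σᵢsᵢ) · s/(1−s),

where L is the reference length, Σᵢsᵢ the summed stoichiometry of all sites
(so L/Σs is the effective spacing, ≈ 65 nt at rRNA density) and purity the
methyl-terminated fraction of the oxidized library (≈ 0.76 at k = 1,
ε = 0.005). The control term (1−s) appears because the nuclease *can* cut at
the site on unmethylated molecules. Hence at rRNA density a site needs
s ≳ 0.7 to exceed the 2⁷ fold-change cutoff; fully methylated sites have a
zero control count and reach the prior-count-limited regime
log₂(μ̂_oxi/0.5) ≈ 9–10. This is a property of the assay design, not of the
implementation: fractional sites below ~0.7 stoichiometry land between the
relaxed and strict tiers, which matches the method's real-world behaviour of
missing a handful of known (presumably fractional or unmethylated) sites.

## Problem sizes and numerical choices

The test-suite and reproduction runs use a 6 kb reference with 100 sites,
3 + 3 replicates and ~3×10⁵ size-selected fragments per replicate for the
end-to-end recovery experiment; 10⁵ molecules for the exact-chemistry
assertions; ~9×10⁴ molecules per replicate (≥10⁴ oxidized reads each) for
the masking experiment; 2×10⁴ molecules per arm for the β-round scaling
ratio; and 20 runs × 5000 positions for the null calibration. These sizes
give binomial/Poisson sampling error well below every asserted margin.

Ties and degenerate inputs: dedup keeps the first record in input order;
merge always orders columns controls-then-oxidized by replicate regardless
of input order; an all-zero count matrix, a missing condition, a malformed
BED/TSV row (reported with its line number) and an unknown config key are
errors, not warnings.

## What the simulator does not model

RT drop-off, RNA secondary structure, sequence-dependent fragmentation
preference, base-resolution oxidation chemistry beyond the retain/remove
contract, quality-score degradation, and multi-copy reference collapse
(a single reference is assumed). Passing tests therefore demonstrate the
correctness of the counting and inference machinery under the stated
generative model — not that real libraries are free of these additional
effects. Quantitative comparison of stoichiometry *between* sites is out of
scope because ligation bias is unidentifiable without spike-ins.
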