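# Methods

This document records the models, algorithms, parameter defaults, and
numerical choices behind `spidrokit`, plus the scope and limitations of
the synthetic data generators.

## 1. Motif mining (`spidrokit.motifs`)

### Input parsing

Two annotation formats are accepted and auto-detected:

- **DSSP output** (detected via the `#  RESIDUE` header): fixed-column
  parsing takes the chain label, the one-letter amino acid, and the
  secondary-structure letter. `!` rows are chain breaks; lowercase
  amino-acid letters (DSSP's notation for disulfide-bonded cysteines)
  are normalized to `C`.
- **Simplified dialect**: FASTA-like records (`>id`) followed by pairs
  of lines — a sequence line and an equally long SS line (DSSP letters,
  with `-`, `.`, `C`, `S`, `T` treated as coil). Each sequence/SS pair
  is one chain of the record (`chain1`, `chain2`, …), so multi-chain
  entries keep per-chain segment boundaries. `X` is allowed in
  sequences as "unknown residue".

Strand segments are maximal runs of `E` (optionally also `B`,
isolated β-bridge, via `include_bridge`). Segment coordinates are
1-based inclusive.

### k-mer harvest and screening

All overlapping windows of length k = 4–8 inside strand segments are
counted *per occurrence* (two occurrences in one segment count twice);
windows containing `X` are skipped. Each candidate motif gets:

- **Frequency** and number of distinct source files.
- **Chou–Fasman β-sheet propensity** (mean of per-residue Pβ values;
  e.g. V 1.70, I 1.60, E 0.37).
- Composition features: valine fraction, hydrophobic fraction
  (alphabet `AVLIMFWC`), `AA` di-alanine contact, `QQ` glutamine pair,
  strict V/S alternation, valine fraction ≥ 0.5.

A motif **passes** if frequency ≥ `min_frequency` (default 10) *or*
(when `pattern_flags_rescue` is on) any of the silk-characteristic
composition flags fires. The rescue rule exists because rare motifs
(e.g. a 3× `QQ`-containing motif) can still be mechanistically
interesting. Ranking is frequency desc, propensity desc, motif asc —
fully deterministic.

## 2. Construct design (`spidrokit.design`)

### Repeat-unit editing

Poly-alanine runs are maximal `A`-runs of length ≥ 5 (threshold
chosen so that isolated `AA`/`AAA` contacts inside motifs are not
treated as crystal-forming runs). `shorten_polyA` trims qualifying runs
to a target length (default use case: 15 → 7, long enough to nucleate a
β-sheet crystal, short enough to avoid aggregation during expression).
`substitute_motif` replaces runs with a mined motif, right-to-left so
recorded run coordinates stay valid during editing.

### Protein assembly and mass

Constructs are `tag + NT + repeat^n + CT` (His6 tag, N-terminal by
default). Only the 20 canonical residues are accepted. Average
molecular weight uses Biopython's average residue masses
(`Bio.Data.IUPACData.protein_weights`) with one water (18.0153 Da) per
chain; `mw("")` is one water, and `mw(a+b) = mw(a) + mw(b) − water`
holds exactly (property-tested).

### Codon optimization

Reverse translation picks, per residue, the highest-ranked codon in a
built-in *E. coli* K-12 frequency-ranked table — deterministic by
construction. Forbidden restriction sites created at codon junctions
are repaired by demoting the leftmost codon overlapping the site to its
next-ranked synonym, iterating to a bound of `10·len + 10` steps; an
unsatisfiable window raises a configuration error rather than looping.

### Isocaudomer cloning simulation

NheI (`GCTAGC`) sits immediately upstream of the repeat block, SpeI
(`ACTAGT`) immediately downstream; both cut after position 1, leaving
compatible `CTAG` 5′ overhangs. One doubling round excises the insert
by double digest and ligates it into the acceptor cut only at NheI:

```
new = dna[:pN+1] + dna[pN+1 : pS+1] + dna[pN+1:]
```

The NheI/SpeI hybrid junction reads `ACTAGC` on the top strand
(`GCTAGT` on the bottom) and is cleavable by neither enzyme, so k
doubling rounds give `repeat_count · 2^k` repeats with
`blocks − 1` inert scars and exactly one live NheI and one live SpeI
site. Scar counting scans both strand orientations. At the protein
level the scar translates as Thr-Ser in the reading frame used here;
the scar amino acids depend on frame placement and are a design choice
of this package.

## 3. Assembly metrics (`spidrokit.assembly`)

Internal geometry is unit-agnostic; trajectory coordinates are stored
in nm (PDB input in Å is converted on read), and Rg/RMSF are reported
in Å (×10), COM distance in nm, SASA in nm².

- **Radius of gyration**: mass-weighted. By default
  (`rg_mode="per_chain"`) the reported series is the mass-weighted
  mean of per-chain Rg, so it tracks chain compaction; whole-system Rg
  (`rg_mode="system"`) would be dominated by the inter-chain
  separation during approach and is available as an option.
- **Superposition**: Kabsch algorithm via numpy SVD with the
  determinant correction for proper rotations; collinear (rank-
  deficient) point sets trigger a warning. RMSD/RMSF superpose each
  frame onto the first. RMSF is aggregated per residue,
  mass-weighted. Cross-checked in tests against
  `scipy.spatial.transform.Rotation.align_vectors`.
- **SASA**: Shrake–Rupley with a deterministic golden-spiral point
  lattice (default 960 points/bead) and `scipy.spatial.cKDTree`
  neighbor search. Defaults: bead radius 0.235 nm and bead mass 72 amu
  (a ~2-heavy-atom coarse bead), probe 0.14 nm (water). The
  single-sphere analytic value 4π(r+probe)² is reproduced to < 1%, and
  far-separated beads are exactly additive. Cross-checked in tests
  against `biotite.structure.sasa` (relative tolerance 2%).
- **Summaries**: `percent_change = 100·(first − last)/first`,
  `endpoint_delta = first − last`, `fold_change = last/first`.

### Assembly verdict

Each of the Rg, SASA, and COM-distance series is tested for monotone
decrease: Spearman rank correlation with time must be negative at
one-sided p < 0.05, **and** the drop predicted by a linear fit over the
full time span must exceed the jitter estimate (standard deviation of
residuals about that fit). The fitted drop is used instead of the raw
endpoint difference because endpoints carry single-frame noise of the
same order as the jitter; a per-step sign test was rejected because it
is blind to ramps whose per-frame decrement is below the noise — the
typical regime of long coarse-grained runs. The verdict is
`"assembly"` only if all three series decrease. Constant series never
pass.

## 4. Synthetic data (`spidrokit.synthetic`)

All generators require an explicit seed and use
`numpy.random.default_rng`; outputs are byte-identical across reruns.

- **Strand corpora**: planted motifs are placed round-robin across
  entries as isolated `E` runs inside coil background drawn from an
  alphabet guaranteed disjoint from the motif letters (fallback
  `DENPHRMFYWC` minus motif letters). This makes planted counts
  *provably exact*: no motif can arise from background, and plans with
  substring-related motifs or letter collisions are rejected up front.
  Consequence: background composition is not biologically realistic —
  the corpus is a counting oracle, not a proteome model.
- **Templates**: NT/repeat/CT parts with requested poly-A run lengths
  separated by flanks from a poly-A-free alphabet (`GSQYLP`), with
  1-based run intervals recorded in the manifest for closure tests.
- **Trajectories**: two rigid bead clusters (unit-Rg shapes scaled per
  frame) whose centers follow a linear COM-distance ramp (default
  25 → 18 nm) while per-chain Rg ramps 14.2 → 13.46 Å, plus additive
  Gaussian jitter (default σ = 0.05 nm), 50 frames at 20 ns/frame, 40
  beads/chain. The scripted series are stored in the manifest, so
  expected deltas are computable from the manifest alone. Limitations:
  rigid clusters have no internal dynamics (RMSF of the scripted part
  is ~0 beyond jitter), the ramps are linear rather than
  diffusion-like, and jitter is iid Gaussian rather than
  thermostat-correlated. File writers cover fixed-column multi-model
  PDB (Å, 3 decimals → ~5·10⁻⁵ nm round-trip error) and per-frame GRO
  (nm, 3 decimals → ~5·10⁻⁴ nm).

## 5. Numerical and testing choices

- Problem sizes in tests and the acceptance script (25-entry corpora,
  50-frame/40-bead trajectories, 960 SASA points) are chosen so the
  full suite runs in seconds on one CPU while keeping statistical
  tests (Spearman p < 0.05, 3σ closure tolerances) well-powered.
- Dual-route checks are kept independent: Kabsch vs scipy Rotation,
  Shrake–Rupley vs biotite, mined counts vs generator manifests,
  analytic sphere SASA vs numeric.
- Property-based tests (hypothesis, derandomized) cover window-count
  conservation in k-mer harvest, molecular-weight additivity, poly-A
  editing length identities, and codon round trips.
- Floating-point report output is rounded to 6 significant digits for
  stable diffs; all internal computation is double precision.
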