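# spidrokit

Computational design toolkit for high-yield spidroin mimics — engineered
spider-silk proteins intended for recombinant expression and bioinspired
fiber spinning.

Spider dragline silk owes its strength to β-sheet nanocrystals formed by
short, repetitive sequence motifs in spidroin (spider silk protein)
repeat regions. Natural spidroins are too large and too repetitive to
express well in *Escherichia coli*, so the practical route is a
*mimic*: a shorter protein that keeps the β-sheet-forming motifs but is
re-engineered for expression yield. `spidrokit` covers that design loop
in three stages:

1. **Motif mining** (`spidrokit.motifs`) — extract β-strand segments
   from secondary-structure annotations (DSSP output or a simple
   two-line sequence/SS dialect), harvest overlapping k-mers (k = 4–8)
   from the strand regions, and screen them by occurrence frequency,
   Chou–Fasman β-sheet propensity, and silk-characteristic composition
   patterns (poly-alanine `AA` contacts, glutamine pairs `QQ`,
   valine/serine alternation, high valine content).
2. **Construct design** (`spidrokit.design`) — edit the repeat unit
   (shorten poly-alanine runs, substitute mined motifs), assemble a
   tagged NT–repeatⁿ–CT protein, compute its average molecular weight,
   reverse-translate it with a deterministic *E. coli* codon choice that
   avoids chosen restriction sites, and simulate iterative
   isocaudomer cloning (NheI/SpeI) that doubles the repeat count per
   round while leaving exactly one live site at each end.
3. **Assembly metrics** (`spidrokit.assembly`) — read coarse-grained
   bead trajectories (multi-model PDB or GRO series via MDAnalysis) and
   quantify self-assembly: per-chain radius of gyration, inter-chain
   center-of-mass distance, Shrake–Rupley solvent-accessible surface
   area, RMSD/RMSF after Kabsch superposition, and a statistical
   verdict ("assembly" vs "no-assembly") based on monotone-decrease
   tests of the Rg, SASA, and COM-distance series.

A fourth module, `spidrokit.synthetic`, generates seeded synthetic
inputs (strand corpora with exactly known planted motif counts,
repeat-unit templates, and two-chain assembly trajectories with
scripted compaction ramps) so that every pipeline stage can be tested
against ground truth. All functionality is exposed both as a Python API
and through the `spidrokit` command-line tool.

## Worked example

### 1. Mine β-sheet motifs from a strand corpus

Generate a corpus with known planted motif counts, then mine it:

```sh
$ cat corpus_plan.json
{"planted": {"GVLEGV": 26, "KTAAWN": 37, "ITVQQ": 3, "SVSVSVS": 2, "VVVKI": 10},
 "seed": 7, "n_entries": 20}
$ spidrokit fixtures corpus --plan corpus_plan.json --out corpus
wrote strand_corpus to corpus
$ spidrokit mine --ss-dir corpus --min-frequency 10 --out motifs.tsv
25 motifs (24 pass) -> motifs.tsv
$ head -8 motifs.tsv
motif	k	frequency	n_sources	val_fraction	hydrophobic_fraction	has_AA	has_QQ	vs_alternating	propensity	verdict	reason
TAAW	4	37	20	0.0	0.75	True	False	False	1.055	pass	frequency 37 times; contains AA
TAAWN	5	37	20	0.0	0.6	True	False	False	1.022	pass	frequency 37 times; contains AA
KTAAW	5	37	20	0.0	0.6	True	False	False	0.992	pass	frequency 37 times; contains AA
AAWN	4	37	20	0.0	0.75	True	False	False	0.98	pass	frequency 37 times; contains AA
KTAAWN	6	37	20	0.0	0.5	True	False	False	0.975	pass	frequency 37 times; contains AA
KTAA	4	37	20	0.0	0.5	True	False	False	0.8975	pass	frequency 37 times; contains AA
VLEGV	5	26	20	0.4	0.6	False	False	False	1.164	pass	frequency 26 times
```

Every planted occurrence is recovered exactly (k-mer mining also counts
substrings of longer planted motifs, which is why 25 candidates
appear). Low-frequency motifs such as `ITVQQ` (3×) still pass via the
composition rescue rules (`contains QQ`).

### 2. Design a construct and simulate repeat doubling

```sh
$ echo '{"polyA_run_lengths": [15, 15, 15], "seed": 3}' > tmpl_plan.json
$ spidrokit fixtures template --plan tmpl_plan.json --out tmpl
wrote template to tmpl
$ spidrokit design --template tmpl/template.fasta --motif ITVQQ \
    --polya-target 7 --reps 3 --doublings 3 --out-prefix d1
3rep-wt-ITVQQ: 207 aa, 22.8 kDa, cassette 24 repeats -> d1.*
$ python -m json.tool d1.report.json
{
    "cassette": {
        "live_nhei_sites": 1,
        "live_spei_sites": 1,
        "n_scars": 7,
        "repeat_count": 24
    },
    "gc_percent": 60.7372,
    "mw_kda": 22.78,
    "n_rep": 3,
    "name": "3rep-wt-ITVQQ",
    "protein_length": 207
}
```

Three doubling rounds turn the 3-repeat cassette into 24 repeats. The
hybrid NheI/SpeI ligation scar is dead to both enzymes, so all 7
internal junctions are inert and exactly one NheI and one SpeI site
remain live for further rounds.

### 3. Analyze a coarse-grained assembly trajectory

```sh
$ echo '{"seed": 11, "n_frames": 50, "n_beads_per_chain": 40}' > traj_plan.json
$ spidrokit fixtures traj --plan traj_plan.json --out trj
wrote assembly_trajectory to trj
$ spidrokit analyze --traj trj/traj.pdb --beads trj/beads.tsv \
    --points 960 --dt-ns 20 --out-prefix a1
verdict: assembly | deltas: rg_delta=0.8152, sasa_pct_reduction=5.423, comd_delta=6.971
$ python -m json.tool a1.summary.json
{
    "deltas": {
        "comd_delta": 6.97110071828649,
        "rg_delta": 0.8152158962798062,
        "sasa_pct_reduction": 5.422794117647063
    },
    "n_frames": 50,
    "reasons": [
        "rg: decreasing (spearman rho -0.962 (one-sided p 4.7e-29), fitted drop 0.7125 vs jitter 0.06192)",
        "sasa: decreasing (spearman rho -0.813 (one-sided p 3.8e-13), fitted drop 4.187 vs jitter 0.9174)",
        "comd: decreasing (spearman rho -1.000 (one-sided p 0), fitted drop 6.997 vs jitter 0.01266)"
    ],
    "verdict": "assembly"
}
```

The synthetic trajectory scripts a two-chain approach (center-of-mass
distance 25 → 18 nm) with per-chain compaction (Rg 14.2 → 13.46 Å)
under Gaussian positional jitter; `analyze` recovers both ramps within
noise and issues the assembly verdict. `rg_delta` is in Å,
`comd_delta` in nm, `sasa_pct_reduction` in percent.

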