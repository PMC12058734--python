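"""Chimeric spidroin construct design.

Implements the sequence-engineering steps used to turn a natural major
ampullate spidroin (MaSp1) repeat into an expressible mimic:

* locate and shorten polyalanine runs (the native A_n, n 6-14, beta-sheet
  nanocrystal blocks; e.g. 15 A -> 7 A);
* replace polyalanine blocks with screened beta-sheet motifs (GVLEGV,
  KTAAWN, ITVQQ, ...);
* assemble His-tagged NT - rep_n - CT chimeras and compute their average
  molecular weight;
* simulate iterative repeat doubling with the NheI/SpeI compatible-
  cohesive-end (isocaudomer) strategy, where the hybrid ligation junction
  is cut by neither enzyme;
* reverse-translate with a ranked codon-usage table while deterministically
  avoiding forbidden restriction sites.

DNA is modelled as a linear duplex represented by its top strand; cohesive
ends are 4-nt 5' overhangs (CTAG for both enzymes used here).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

from Bio.Data.IUPACData import protein_weights
from Bio.Seq import Seq
from Bio.SeqUtils import gc_fraction

from .errors import (ConfigurationError, LigationError, TopologyError,
                     ValidationError)
from .tables import CANONICAL_AA, ECOLI_CODON_RANKS

WATER_MW = 18.0153  # average mass of one water, Da


# --------------------------------------------------------------------------
# restriction enzymes and the cohesive-end model

@dataclass(frozen=True)
class RestrictionEnzyme:
    """A 6-cutter leaving a 4-nt 5' overhang."""

    name: str
    site: str
    cut_offset: int  # top-strand cut position within the site
    overhang: str

    def __post_init__(self) -> None:
        if len(self.overhang) != 4:
            raise ValidationError("overhang must be 4 nt")
        if self.site[self.cut_offset:self.cut_offset + 4] != self.overhang:
            raise ValidationError(
                f"{self.name}: overhang inconsistent with cut offset")


NHEI = RestrictionEnzyme("NheI", "GCTAGC", 1, "CTAG")
SPEI = RestrictionEnzyme("SpeI", "ACTAGT", 1, "CTAG")

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def reverse_complement(dna: str) -> str:
    return dna.translate(_COMPLEMENT)[::-1]


def find_sites(dna: str, enzyme: RestrictionEnzyme) -> list[int]:
    """All (overlapping) 0-based match positions of the recognition site
    on the given strand.

    Both enzymes used here cut sequences whose bottom strand carries the
    site at the mirrored position, so a top-strand scan of a duplex plus a
    scan of its reverse complement covers both orientations; for palindromic
    sites the second scan is redundant.
    """
    bad = set(dna) - set("ACGT")
    if bad:
        raise ValidationError(f"non-ACGT characters in DNA: {sorted(bad)}")
    site, out, start = enzyme.site, [], 0
    while True:
        i = dna.find(site, start)
        if i < 0:
            return out
        out.append(i)
        start = i + 1


@dataclass(frozen=True)
class Fragment:
    """A linear duplex fragment (top strand) with sticky-end annotations.

    ``left_overhang`` is the single-stranded 5' extension at the left end
    (its bases are the first bases of ``top``); ``right_overhang`` is the
    extension the next fragment must present for ligation.  Empty string
    means blunt.
    """

    top: str
    left_overhang: str = ""
    right_overhang: str = ""


def digest(dna: str, enzymes: Sequence[RestrictionEnzyme]) -> list[Fragment]:
    """Cut a linear duplex with one or more enzymes.

    Returns fragments left-to-right.  Cut positions are the top-strand
    scission points (site position + cut offset).
    """
    cuts: list[tuple[int, str]] = []
    for enz in enzymes:
        for pos in find_sites(dna, enz):
            cuts.append((pos + enz.cut_offset, enz.overhang))
    cuts.sort()
    fragments = []
    prev, left_ov = 0, ""
    for cut_pos, overhang in cuts:
        fragments.append(Fragment(dna[prev:cut_pos], left_ov, overhang))
        prev, left_ov = cut_pos, overhang
    fragments.append(Fragment(dna[prev:], left_ov, ""))
    return fragments


def ligate(fragments: Sequence[Fragment]) -> str:
    """Join fragments in order, enforcing cohesive-end compatibility."""
    if not fragments:
        raise ValidationError("nothing to ligate")
    for a, b in zip(fragments, fragments[1:]):
        if a.right_overhang != b.left_overhang:
            raise LigationError(
                f"incompatible ends: {a.right_overhang!r} vs "
                f"{b.left_overhang!r}")
    return "".join(f.top for f in fragments)


@dataclass(frozen=True)
class MultimerResult:
    dna: str
    repeat_count: int
    n_scars: int


def count_scars(dna: str) -> int:
    """Hybrid NheI/SpeI junctions: read GCTAGT on one strand (equivalently
    ACTAGC on the other), cut by neither enzyme."""
    return (len(_find_all(dna, "GCTAGT")) + len(_find_all(dna, "ACTAGC")))


def _find_all(s: str, sub: str) -> list[int]:
    out, start = [], 0
    while True:
        i = s.find(sub, start)
        if i < 0:
            return out
        out.append(i)
        start = i + 1


def multimerize(cassette_dna: str, n_doublings: int,
                repeat_count_in: int = 1,
                enzymes: tuple[RestrictionEnzyme, RestrictionEnzyme] = (NHEI, SPEI),
                ) -> MultimerResult:
    """Iteratively double the repeat block between the NheI and SpeI sites.

    Each round excises the block with both enzymes and ligates it into the
    cassette opened at its single NheI site; the SpeI end anneals into the
    NheI overhang (both leave CTAG) and the resulting hybrid junction is
    recognised by neither enzyme, so exactly one live site of each survives
    every round.
    """
    if n_doublings < 0:
        raise ValidationError("n_doublings must be >= 0")
    up_enz, down_enz = enzymes
    dna = cassette_dna

    def site_positions(d: str) -> tuple[int, int]:
        ups, downs = find_sites(d, up_enz), find_sites(d, down_enz)
        if len(ups) != 1 or len(downs) != 1:
            raise TopologyError(
                f"cassette must carry exactly one {up_enz.name} and one "
                f"{down_enz.name} site (found {len(ups)} and {len(downs)})")
        if ups[0] >= downs[0]:
            raise TopologyError(
                f"{up_enz.name} site must lie upstream of {down_enz.name}")
        return ups[0], downs[0]

    site_positions(dna)
    for _ in range(n_doublings):
        frags = digest(dna, [up_enz, down_enz])
        if len(frags) != 3:
            raise TopologyError("double digest did not yield 3 fragments")
        insert = frags[1]
        v1, v2 = digest(dna, [up_enz])
        # SpeI right end of the insert carries the same CTAG overhang the
        # NheI-opened acceptor presents, so this ligation is licit; the
        # junction it creates is the dead hybrid scar.
        dna = ligate([v1, insert, v2])
        site_positions(dna)  # exactly one live site of each must survive
    return MultimerResult(dna=dna,
                          repeat_count=repeat_count_in * 2 ** n_doublings,
                          n_scars=count_scars(dna))


# --------------------------------------------------------------------------
# protein-level editing

def find_polyA_runs(sequence: str, run_threshold: int = 5,
                    ) -> list[tuple[int, int]]:
    """Maximal runs of 'A' of length >= run_threshold, 1-based inclusive."""
    _validate_protein(sequence)
    runs, i, n = [], 0, len(sequence)
    while i < n:
        if sequence[i] == "A":
            j = i
            while j < n and sequence[j] == "A":
                j += 1
            if j - i >= run_threshold:
                runs.append((i + 1, j))
            i = j
        else:
            i += 1
    return runs


@dataclass(frozen=True)
class RepeatUnit:
    """One repeat block of the spidroin core domain."""

    name: str
    sequence: str
    run_threshold: int = 5

    def __post_init__(self) -> None:
        _validate_protein(self.sequence)

    @property
    def polyA_runs(self) -> list[tuple[int, int]]:
        return find_polyA_runs(self.sequence, self.run_threshold)


def shorten_polyA(rep: RepeatUnit, target_len: int,
                  on_missing: str = "warn") -> RepeatUnit:
    """Set every qualifying polyalanine run to exactly ``target_len`` A's.

    This is the expression-friendliness edit (e.g. native 15 A -> 7 A).
    """
    if target_len < 1:
        raise ValidationError("target_len must be >= 1")
    runs = rep.polyA_runs
    if not runs:
        if on_missing == "error":
            raise ValidationError(f"no polyalanine run in {rep.name}")
        warnings.warn(f"no polyalanine run in {rep.name}; returned unchanged")
        return rep
    seq = rep.sequence
    for start, end in reversed(runs):
        seq = seq[:start - 1] + "A" * target_len + seq[end:]
    return replace(rep, sequence=seq)


def substitute_motif(rep: RepeatUnit, motif: str,
                     on_missing: str = "warn") -> RepeatUnit:
    """Replace each qualifying polyalanine run with one copy of ``motif``.

    Replacement proceeds right-to-left so earlier run coordinates stay
    valid while editing.
    """
    if not motif:
        raise ValidationError("empty replacement motif")
    _validate_protein(motif)
    runs = rep.polyA_runs
    if not runs:
        if on_missing == "error":
            raise ValidationError(f"no polyalanine run in {rep.name}")
        warnings.warn(f"no polyalanine run in {rep.name}; returned unchanged")
        return rep
    seq = rep.sequence
    for start, end in reversed(runs):
        seq = seq[:start - 1] + motif + seq[end:]
    return replace(rep, name=f"{rep.name}-{motif}", sequence=seq)


def _validate_protein(sequence: str) -> None:
    bad = set(sequence) - CANONICAL_AA
    if bad:
        raise ValidationError(
            f"non-canonical residues in protein: {sorted(bad)}")


def protein_mw(protein: str) -> float:
    """Average molecular weight in Daltons (residue masses + one water)."""
    _validate_protein(protein)
    if not protein:
        return WATER_MW
    return sum(protein_weights[c] for c in protein) - (len(protein) - 1) * WATER_MW


@dataclass(frozen=True)
class SpidroinConstruct:
    """A named NT - rep_n - CT chimera with optional tag and DNA."""

    name: str
    nt: str
    rep_unit: RepeatUnit
    n_rep: int
    ct: str
    tag: str = ""
    tag_terminus: str = "N"
    dna: str | None = None

    @property
    def protein(self) -> str:
        core = self.nt + self.rep_unit.sequence * self.n_rep + self.ct
        return self.tag + core if self.tag_terminus == "N" else core + self.tag

    @property
    def mw_da(self) -> float:
        return protein_mw(self.protein)

    @property
    def mw_kda(self) -> float:
        return self.mw_da / 1000.0


HIS6 = "HHHHHH"


def assemble_protein(nt: str, rep: RepeatUnit | str, n_rep: int, ct: str,
                     tag: str = HIS6, tag_terminus: str = "N",
                     name: str | None = None) -> SpidroinConstruct:
    """Concatenate tag/NT/rep_n/CT into a construct and compute its MW."""
    if n_rep < 1:
        raise ValidationError("n_rep must be >= 1")
    if isinstance(rep, str):
        rep = RepeatUnit("rep", rep)
    if not rep.sequence:
        raise ValidationError("empty repeat unit")
    if tag_terminus not in ("N", "C"):
        raise ValidationError("tag_terminus must be 'N' or 'C'")
    for part in (nt, ct, tag):
        _validate_protein(part)
    return SpidroinConstruct(
        name=name or f"{n_rep}rep-{rep.name}",
        nt=nt, rep_unit=rep, n_rep=n_rep, ct=ct,
        tag=tag, tag_terminus=tag_terminus)


# --------------------------------------------------------------------------
# reverse translation

@dataclass(frozen=True)
class CodonOptResult:
    dna: str
    gc_fraction: float


def translate(dna: str) -> str:
    """Translate a coding sequence, dropping a single trailing stop."""
    prot = str(Seq(dna).translate())
    return prot[:-1] if prot.endswith("*") else prot


def codon_optimize(protein: str,
                   usage_table: Mapping[str, Sequence[str]] = ECOLI_CODON_RANKS,
                   forbidden_sites: Sequence[str] = (),
                   include_stop: bool = True,
                   ) -> CodonOptResult:
    """Reverse-translate with the most-frequent codon per residue.

    When the naive choice would create a forbidden site, the leftmost codon
    overlapping the offending window is demoted to its next-ranked synonym
    (then the next codon, and so on) — a deterministic repair, so the same
    protein and table always yield the same DNA.  Appends one stop codon.
    """
    protein = protein.upper()
    if not protein:
        raise ValidationError("empty protein")
    _validate_protein(protein)
    missing = sorted({c for c in protein + "*" if c not in usage_table})
    if missing:
        raise ConfigurationError(f"codon table lacks residues: {missing}")
    residues = protein + ("*" if include_stop else "")
    choices = [0] * len(residues)

    def build() -> str:
        return "".join(usage_table[r][choices[i]]
                       for i, r in enumerate(residues))

    def first_hit(dna: str) -> tuple[int, str] | None:
        hits = [(dna.find(s), s) for s in forbidden_sites if s and s in dna]
        return min(hits) if hits else None

    for _ in range(10 * len(residues) + 10):
        dna = build()
        hit = first_hit(dna)
        if hit is None:
            return CodonOptResult(dna=dna, gc_fraction=gc_fraction(dna))
        pos, site = hit
        j0, j1 = pos // 3, (pos + len(site) - 1) // 3
        repaired = False
        for j in range(j0, min(j1, len(residues) - 1) + 1):
            options = usage_table[residues[j]]
            for alt in range(len(options)):
                if alt == choices[j]:
                    continue
                trial = choices.copy()
                trial[j] = alt
                trial_dna = "".join(usage_table[r][trial[i]]
                                    for i, r in enumerate(residues))
                window = trial_dna[max(0, pos - 5):pos + len(site) + 5]
                if not any(s in window for s in forbidden_sites if s):
                    choices = trial
                    repaired = True
                    break
            if repaired:
                break
        if not repaired:
            raise ConfigurationError(
                f"cannot avoid forbidden site {site!r} at codon window "
                f"{j0}-{j1}: all synonymous options exhausted")
    raise ConfigurationError("codon repair did not converge")
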