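"""Mining and screening of beta-strand motifs from secondary-structure data.

The workflow mirrors how candidate microcrystalline-region motifs are chosen
for recombinant spidroin design: harvest every k-mer that lies fully inside a
beta-strand (DSSP 'E') segment of an annotated corpus, tabulate occurrence
frequencies, annotate composition features that matter for beta-sheet
formation (AA / QQ dipeptides, V/S alternation, valine and hydrophobic
content), score each candidate with a strand-propensity scale, and apply an
explicit pass/fail screen.

Two input dialects are accepted: standard DSSP output files, and a simplified
FASTA-like dialect in which each sequence line is immediately followed by a
secondary-structure line of equal length.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import ConfigurationError, ParseError, ValidationError
from .tables import CANONICAL_AA, CHOU_FASMAN_BETA, HYDROPHOBIC_SET

# DSSP secondary-structure alphabet ('P' = polyproline II in recent mkdssp;
# ' ' and '-' denote loop/irregular).
_DSSP_SS_LETTERS = set("HBEGITSP")
_COIL_LETTERS = {" ", "-", "C", ".", "~"}


@dataclass(frozen=True)
class StrandSegment:
    """One maximal run of strand-labelled residues.

    Coordinates are 1-based inclusive, following DSSP convention.
    """

    source_id: str
    chain_id: str
    start: int
    end: int
    sequence: str

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValidationError(
                f"segment end {self.end} precedes start {self.start}")
        if len(self.sequence) != self.end - self.start + 1:
            raise ValidationError(
                f"segment {self.source_id}/{self.chain_id}: sequence length "
                f"{len(self.sequence)} != span {self.end - self.start + 1}")
        bad = set(self.sequence) - CANONICAL_AA - {"X"}
        if bad:
            raise ValidationError(
                f"segment contains non-canonical residues: {sorted(bad)}")

    def __len__(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class MotifFeatures:
    """Composition features of a candidate motif."""

    val_fraction: float
    hydrophobic_fraction: float
    has_AA: bool
    has_QQ: bool
    vs_alternating: bool


@dataclass
class MotifRecord:
    """A screened candidate motif with its evidence and verdict."""

    motif: str
    frequency: int
    sources: frozenset
    val_fraction: float
    hydrophobic_fraction: float
    has_AA: bool
    has_QQ: bool
    vs_alternating: bool
    propensity: float
    passed: bool
    reason: str

    @property
    def k(self) -> int:
        return len(self.motif)


@dataclass(frozen=True)
class ScreeningCriteria:
    """Explicit thresholds encoding the qualitative screening bases.

    A motif passes on raw abundance (``frequency >= min_frequency``) or, when
    ``pattern_flags_rescue`` is on, on any composition flag (AA or QQ
    dipeptide, V/S alternation, valine fraction >= 0.5).  ``min_propensity``
    additionally gates all passes; the default 0 makes it neutral.
    """

    min_frequency: int = 10
    min_propensity: float = 0.0
    pattern_flags_rescue: bool = True
    k_range: tuple[int, int] = (4, 8)
    hydrophobic_set: frozenset = HYDROPHOBIC_SET

    def __post_init__(self) -> None:
        k_min, k_max = self.k_range
        if k_min < 4 or k_max < k_min:
            raise ValidationError(f"invalid k_range {self.k_range}")
        if self.min_frequency < 1:
            raise ValidationError("min_frequency must be >= 1")


def _normalise_residue(aa: str) -> str:
    # DSSP marks disulfide-bonded cysteines with lowercase letters.
    if aa.islower():
        return "C"
    if aa in CANONICAL_AA:
        return aa
    return "X"


def _segments_from_labels(source_id: str, chain_id: str, sequence: str,
                          labels: Sequence[str], strand_letters: set,
                          offset: int = 0) -> list[StrandSegment]:
    """Extract maximal strand runs from parallel residue/label arrays."""
    segments = []
    run_start = None
    for i, lab in enumerate(labels):
        if lab in strand_letters:
            if run_start is None:
                run_start = i
        elif run_start is not None:
            segments.append(StrandSegment(
                source_id, chain_id, offset + run_start + 1, offset + i,
                sequence[run_start:i]))
            run_start = None
    if run_start is not None:
        segments.append(StrandSegment(
            source_id, chain_id, offset + run_start + 1, offset + len(labels),
            sequence[run_start:]))
    return segments


def _parse_dssp(lines: Sequence[str], source_id: str,
                strand_letters: set) -> list[StrandSegment]:
    segments: list[StrandSegment] = []
    in_data = False
    chain_seq: list[str] = []
    chain_ss: list[str] = []
    chain_id = ""

    def flush() -> None:
        if chain_seq:
            segments.extend(_segments_from_labels(
                source_id, chain_id, "".join(chain_seq), chain_ss,
                strand_letters))
        chain_seq.clear()
        chain_ss.clear()

    for lineno, line in enumerate(lines, start=1):
        if not in_data:
            if line.lstrip().startswith("#  RESIDUE"):
                in_data = True
            continue
        if not line.strip():
            continue
        if len(line) < 17:
            raise ParseError(f"line {lineno}: truncated DSSP record")
        aa = line[13]
        if aa == "!":  # chain break / new chain
            flush()
            continue
        this_chain = line[11].strip() or "A"
        if chain_seq and this_chain != chain_id:
            flush()
        chain_id = this_chain
        ss = line[16]
        if ss not in _DSSP_SS_LETTERS and ss not in _COIL_LETTERS:
            raise ParseError(
                f"line {lineno}: unknown secondary-structure letter {ss!r}")
        chain_seq.append(_normalise_residue(aa))
        chain_ss.append(ss)
    if not in_data:
        raise ParseError("no DSSP data header ('#  RESIDUE') found")
    flush()
    return segments


def _parse_simple(lines: Sequence[str], source_id: str,
                  strand_letters: set) -> list[StrandSegment]:
    # Each sequence/SS line pair is one chain of the current record.
    segments: list[StrandSegment] = []
    record_id = None
    chain_no = 0
    pending_seq: str | None = None
    pending_line = 0

    def check_closed() -> None:
        if pending_seq is not None:
            raise ParseError(
                f"line {pending_line}: sequence line without a matching "
                "secondary-structure line")

    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith(">"):
            check_closed()
            record_id = line[1:].split()[0] if line[1:].split() else source_id
            chain_no = 0
            continue
        if pending_seq is None:
            bad = set(line.upper()) - CANONICAL_AA - {"X"}
            if bad:
                raise ParseError(
                    f"line {lineno}: non-residue characters {sorted(bad)} in "
                    "sequence line")
            pending_seq = line.upper()
            pending_line = lineno
        else:
            if len(line) != len(pending_seq):
                raise ParseError(
                    f"line {lineno}: secondary-structure line length "
                    f"{len(line)} != sequence length {len(pending_seq)}")
            unknown = {c for c in line.upper()
                       if c not in _DSSP_SS_LETTERS and c not in _COIL_LETTERS}
            if unknown:
                raise ParseError(
                    f"line {lineno}: unknown secondary-structure letters "
                    f"{sorted(unknown)}")
            chain_no += 1
            segments.extend(_segments_from_labels(
                record_id or source_id, f"chain{chain_no}", pending_seq,
                line.upper(), strand_letters))
            pending_seq = None
    check_closed()
    return segments


def parse_ss_records(text: str, source_id: str = "input",
                     include_bridge: bool = False) -> list[StrandSegment]:
    """Parse secondary-structure records into strand segments.

    Accepts either a standard DSSP file or the simplified dialect (FASTA-like
    header, then sequence/SS line pairs).  Returns every maximal run of
    residues labelled 'E' (plus isolated-bridge 'B' when ``include_bridge``),
    per chain, in file order.
    """
    strand_letters = {"E", "B"} if include_bridge else {"E"}
    lines = text.splitlines()
    is_dssp = any(ln.lstrip().startswith("#  RESIDUE") for ln in lines[:60]) \
        or (lines and lines[0].startswith("===="))
    if is_dssp:
        return _parse_dssp(lines, source_id, strand_letters)
    return _parse_simple(lines, source_id, strand_letters)


def harvest_kmers(segments: Iterable[StrandSegment],
                  k_range: tuple[int, int] = (4, 8),
                  ) -> dict[str, tuple[int, frozenset]]:
    """Count every overlapping k-mer fully inside a strand segment.

    Counting is per occurrence: identical chains contribute separately.
    Windows containing 'X' are skipped.  Returns ``motif -> (frequency,
    sources)`` where sources is the set of distinct source_ids.
    """
    k_min, k_max = k_range
    if k_min > k_max:
        raise ValidationError(f"k_min {k_min} > k_max {k_max}")
    counts: dict[str, int] = {}
    sources: dict[str, set] = {}
    for seg in segments:
        seq = seg.sequence
        n = len(seq)
        for k in range(k_min, k_max + 1):
            for i in range(n - k + 1):
                window = seq[i:i + k]
                if "X" in window:
                    continue
                counts[window] = counts.get(window, 0) + 1
                sources.setdefault(window, set()).add(seg.source_id)
    return {m: (c, frozenset(sources[m])) for m, c in counts.items()}


def composition_features(motif: str,
                         hydrophobic_set: frozenset = HYDROPHOBIC_SET,
                         ) -> MotifFeatures:
    """Annotate the composition flags used by the motif screen."""
    if not motif:
        raise ValidationError("empty motif")
    motif = motif.upper()
    bad = set(motif) - CANONICAL_AA
    if bad:
        raise ValidationError(f"non-canonical residues in motif: {sorted(bad)}")
    n = len(motif)
    vs_alt = (n >= 4 and set(motif) <= {"V", "S"}
              and all(motif[i] != motif[i + 1] for i in range(n - 1)))
    return MotifFeatures(
        val_fraction=motif.count("V") / n,
        hydrophobic_fraction=sum(c in hydrophobic_set for c in motif) / n,
        has_AA="AA" in motif,
        has_QQ="QQ" in motif,
        vs_alternating=vs_alt,
    )


def beta_propensity(motif: str,
                    scale: Mapping[str, float] = CHOU_FASMAN_BETA) -> float:
    """Arithmetic-mean strand propensity of a motif under a residue scale."""
    if not motif:
        raise ValidationError("empty motif")
    motif = motif.upper()
    missing = sorted(set(motif) - set(scale))
    if missing:
        raise ConfigurationError(
            f"residues missing from propensity scale: {missing}")
    return sum(scale[c] for c in motif) / len(motif)


def _build_reason(record_freq: int, feats: MotifFeatures,
                  criteria: ScreeningCriteria) -> tuple[bool, str]:
    parts = []
    if record_freq >= criteria.min_frequency:
        parts.append(f"frequency {record_freq} times")
    if criteria.pattern_flags_rescue:
        if feats.has_AA:
            parts.append("contains AA")
        if feats.has_QQ:
            parts.append("contains QQ")
        if feats.vs_alternating:
            parts.append("V/S alternation")
        if feats.val_fraction >= 0.5:
            parts.append(f"high V content ({feats.val_fraction:.0%})")
    passed = bool(parts)
    if not passed:
        return False, (f"frequency {record_freq} below floor "
                       f"{criteria.min_frequency}; no rescue pattern")
    return True, "; ".join(parts)


def screen(db: Mapping[str, tuple[int, frozenset]],
           criteria: ScreeningCriteria = ScreeningCriteria(),
           scale: Mapping[str, float] = CHOU_FASMAN_BETA,
           ) -> list[MotifRecord]:
    """Score and rank every motif in a harvested database.

    Ranking is a total order: frequency descending, propensity descending,
    then motif lexicographically ascending.
    """
    if not db:
        raise ValidationError("empty motif database")
    records = []
    for motif, (freq, srcs) in db.items():
        feats = composition_features(motif, criteria.hydrophobic_set)
        prop = beta_propensity(motif, scale)
        passed, reason = _build_reason(freq, feats, criteria)
        if passed and prop < criteria.min_propensity:
            passed = False
            reason = (f"propensity {prop:.3f} below floor "
                      f"{criteria.min_propensity}")
        records.append(MotifRecord(
            motif=motif, frequency=freq, sources=srcs,
            val_fraction=feats.val_fraction,
            hydrophobic_fraction=feats.hydrophobic_fraction,
            has_AA=feats.has_AA, has_QQ=feats.has_QQ,
            vs_alternating=feats.vs_alternating,
            propensity=prop, passed=passed, reason=reason))
    records.sort(key=lambda r: (-r.frequency, -r.propensity, r.motif))
    return records


def records_to_frame(records: Sequence[MotifRecord]) -> pd.DataFrame:
    """Tabulate motif records with stable column order."""
    cols = ["motif", "k", "frequency", "n_sources", "val_fraction",
            "hydrophobic_fraction", "has_AA", "has_QQ", "vs_alternating",
            "propensity", "verdict", "reason"]
    rows = [{
        "motif": r.motif, "k": r.k, "frequency": r.frequency,
        "n_sources": len(r.sources), "val_fraction": round(r.val_fraction, 6),
        "hydrophobic_fraction": round(r.hydrophobic_fraction, 6),
        "has_AA": r.has_AA, "has_QQ": r.has_QQ,
        "vs_alternating": r.vs_alternating,
        "propensity": round(r.propensity, 6),
        "verdict": "pass" if r.passed else "fail", "reason": r.reason,
    } for r in records]
    return pd.DataFrame(rows, columns=cols)


def write_motif_table(records: Sequence[MotifRecord], path,
                      fmt: str = "tsv") -> None:
    frame = records_to_frame(records)
    if fmt == "tsv":
        frame.to_csv(path, sep="\t", index=False)
    elif fmt == "json":
        with open(path, "w") as fh:
            json.dump(frame.to_dict(orient="records"), fh, indent=2)
    else:
        raise ValidationError(f"unknown motif table format {fmt!r}")
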