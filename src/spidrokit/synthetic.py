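"""Deterministic synthetic-data generators.

These make the whole pipeline testable without any database download:

* strand corpora in the simplified sequence/SS dialect with exactly-known
  planted motif counts (the background alphabet is forced disjoint from the
  planted motifs' residues, so recovery of the planted counts is provable,
  not probabilistic);
* template FASTA files with the spidroin NT / rep / CT architecture and
  polyalanine runs at recorded positions;
* two-chain bead trajectories whose inter-chain distance and per-chain
  radius of gyration follow prescribed linear ramps plus seeded Gaussian
  positional jitter.

Every generator is a pure function of its plan (seeds are mandatory);
rerunning a plan yields byte-identical output.  Each generator returns (and
optionally writes) a manifest holding enough ground truth to compute every
expected metric without re-parsing the generated files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .assembly import (DEFAULT_BEAD_MASS_AMU, DEFAULT_BEAD_RADIUS_NM,
                       NM_TO_ANGSTROM, Trajectory)
from .errors import PlanError

_FALLBACK_BACKGROUND = "DENPHRMFYWC"  # drawn on only where disjoint from plants
_FLANK_ALPHABET = "GSQYLP"            # spidroin-flavoured non-A flank residues


# --------------------------------------------------------------------------
# strand corpora

@dataclass(frozen=True)
class CorpusPlan:
    """Plan for a strand corpus with planted motif counts."""

    planted: Mapping[str, int]
    seed: int
    n_entries: int = 10
    background_length: int = 60
    background_alphabet_weights: Mapping[str, float] | None = None

    def __post_init__(self) -> None:
        if self.n_entries < 1:
            raise PlanError("need at least one corpus entry")
        if any(c < 0 for c in self.planted.values()):
            raise PlanError("planted counts must be non-negative")
        motifs = list(self.planted)
        for m in motifs:
            if not m:
                raise PlanError("empty planted motif")
            for other in motifs:
                if m != other and m in other:
                    raise PlanError(
                        f"planted motif {m!r} is a substring of {other!r}")
        if self.background_alphabet_weights is not None:
            weights = self.background_alphabet_weights
            if abs(sum(weights.values()) - 1.0) > 1e-9:
                raise PlanError("background weights must sum to 1")
            motif_letters = set("".join(motifs))
            clash = motif_letters & set(weights)
            if clash:
                raise PlanError(
                    f"background alphabet shares residues with planted "
                    f"motifs: {sorted(clash)} — planted motifs could arise "
                    "from background")

    def background_distribution(self) -> tuple[list[str], list[float]]:
        if self.background_alphabet_weights is not None:
            letters = sorted(self.background_alphabet_weights)
            probs = [self.background_alphabet_weights[c] for c in letters]
            return letters, probs
        motif_letters = set("".join(self.planted))
        letters = sorted(set(_FALLBACK_BACKGROUND) - motif_letters)
        if not letters:
            raise PlanError("no residues left for a disjoint background "
                            "alphabet; supply background_alphabet_weights")
        return letters, [1.0 / len(letters)] * len(letters)


def make_strand_corpus(plan: CorpusPlan, out_dir=None,
                       ) -> tuple[dict[str, str], dict]:
    """Generate corpus entries (simplified seq/SS dialect) plus a manifest.

    Planted motifs are embedded as isolated strand ('E') runs separated by
    coil background, distributed round-robin over the entries, so every
    planted motif occurs inside strands exactly its planted count
    corpus-wide and no accidental occurrences are possible.
    """
    rng = np.random.default_rng(plan.seed)
    letters, probs = plan.background_distribution()

    occurrences: list[str] = []
    for motif in sorted(plan.planted):
        occurrences.extend([motif] * plan.planted[motif])
    per_entry: list[list[str]] = [[] for _ in range(plan.n_entries)]
    for idx, motif in enumerate(occurrences):
        per_entry[idx % plan.n_entries].append(motif)

    def background(n: int) -> str:
        if n <= 0:
            return ""
        return "".join(rng.choice(letters, size=n, p=probs))

    files: dict[str, str] = {}
    for i, plants in enumerate(per_entry):
        spacer = max(1, plan.background_length // (len(plants) + 1))
        seq_parts, ss_parts = [], []
        for motif in plants:
            pad = background(spacer)
            seq_parts.append(pad + motif)
            ss_parts.append("C" * len(pad) + "E" * len(motif))
        pad = background(max(1, plan.background_length
                             - spacer * len(plants)))
        seq_parts.append(pad)
        ss_parts.append("C" * len(pad))
        name = f"entry{i:05d}"
        files[f"{name}.ss"] = (f">{name}\n{''.join(seq_parts)}\n"
                               f"{''.join(ss_parts)}\n")

    manifest = {
        "kind": "strand_corpus",
        "seed": plan.seed,
        "n_entries": plan.n_entries,
        "planted": dict(sorted(plan.planted.items())),
        "background_alphabet": letters,
        "files": sorted(files),
    }
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for fname, text in files.items():
            (out_dir / fname).write_text(text)
        (out_dir / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True))
    return files, manifest


# --------------------------------------------------------------------------
# template sequences

def make_template(polyA_run_lengths: Sequence[int], seed: int,
                  flank_len: int = 8, nt_len: int = 30, ct_len: int = 30,
                  name: str = "template", out_dir=None,
                  ) -> tuple[dict[str, str], dict]:
    """Synthetic NT / rep / CT template with recorded polyalanine runs.

    The repeat region interleaves non-alanine flanks with the requested A
    runs, so `find_polyA_runs` must recover exactly the planted intervals.
    Returns ``(parts, manifest)`` where parts holds the nt/rep/ct strings.
    """
    if any(n < 1 for n in polyA_run_lengths):
        raise PlanError("polyalanine run lengths must be >= 1")
    rng = np.random.default_rng(seed)
    letters = list(_FLANK_ALPHABET)

    def stretch(n: int) -> str:
        return "".join(rng.choice(letters, size=n))

    rep_parts = [stretch(flank_len)]
    intervals = []
    pos = flank_len
    for run in polyA_run_lengths:
        intervals.append([pos + 1, pos + run])  # 1-based inclusive
        rep_parts.append("A" * run)
        rep_parts.append(stretch(flank_len))
        pos += run + flank_len
    parts = {
        "nt": "M" + stretch(nt_len - 1),
        "rep": "".join(rep_parts),
        "ct": stretch(ct_len),
    }
    manifest = {
        "kind": "template",
        "seed": seed,
        "name": name,
        "polyA_runs": intervals,
        "polyA_run_lengths": list(polyA_run_lengths),
        "lengths": {k: len(v) for k, v in parts.items()},
    }
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        fasta = "".join(f">{name}_{part}\n{seq}\n"
                        for part, seq in parts.items())
        (out_dir / f"{name}.fasta").write_text(fasta)
        (out_dir / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True))
    return parts, manifest


# --------------------------------------------------------------------------
# two-chain assembly trajectories

@dataclass(frozen=True)
class TrajectoryPlan:
    """Plan for a two-chain trajectory with scripted assembly trends."""

    seed: int
    n_frames: int = 50
    n_beads_per_chain: int = 40
    comd_start_nm: float = 25.0
    comd_end_nm: float = 18.0
    rg_start_angstrom: float = 14.2
    rg_end_angstrom: float = 13.46
    jitter_sigma_nm: float = 0.05
    dt_ns: float = 20.0

    def __post_init__(self) -> None:
        if self.n_frames < 2:
            raise PlanError("need at least two frames")
        if self.jitter_sigma_nm < 0:
            raise PlanError("jitter sigma must be >= 0")
        for v in (self.comd_start_nm, self.comd_end_nm,
                  self.rg_start_angstrom, self.rg_end_angstrom):
            if v <= 0:
                raise PlanError("distances and radii must be positive")


def make_assembly_traj(plan: TrajectoryPlan, out_dir=None,
                       ) -> tuple[Trajectory, dict]:
    """Two rigid bead clusters approaching and compacting on linear ramps.

    Per frame, each chain's internal scale is set so its noise-free radius
    of gyration follows the rg ramp, the chain centers of mass sit
    ``comd(t)`` apart along x, and i.i.d. Gaussian jitter of the planned
    sigma is added to every coordinate.  The manifest records the per-frame
    scripted ground truth.
    """
    rng = np.random.default_rng(plan.seed)
    n, m = plan.n_frames, plan.n_beads_per_chain
    frac = np.arange(n) / (n - 1)
    comd_script = plan.comd_start_nm + frac * (plan.comd_end_nm
                                               - plan.comd_start_nm)
    rg_script_nm = (plan.rg_start_angstrom
                    + frac * (plan.rg_end_angstrom
                              - plan.rg_start_angstrom)) / NM_TO_ANGSTROM

    masses = np.full(2 * m, DEFAULT_BEAD_MASS_AMU)
    radii = np.full(2 * m, DEFAULT_BEAD_RADIUS_NM)
    chain_ids = np.array(["A"] * m + ["B"] * m)
    residue_index = np.concatenate([np.arange(1, m + 1),
                                    np.arange(1, m + 1)])

    bases = []
    for _ in range(2):
        base = rng.normal(size=(m, 3))
        base -= base.mean(axis=0)
        base_rg = np.sqrt((base ** 2).sum(axis=1).mean())
        bases.append(base / base_rg)  # unit-Rg cluster

    coords = np.empty((n, 2 * m, 3))
    for t in range(n):
        offset = np.array([comd_script[t] / 2.0, 0.0, 0.0])
        coords[t, :m] = bases[0] * rg_script_nm[t] - offset
        coords[t, m:] = bases[1] * rg_script_nm[t] + offset
    if plan.jitter_sigma_nm > 0:
        coords += rng.normal(scale=plan.jitter_sigma_nm, size=coords.shape)

    times = np.arange(n, dtype=float) * plan.dt_ns
    traj = Trajectory(coords=coords, times=times, chain_ids=chain_ids,
                      residue_index=residue_index, masses=masses,
                      radii=radii,
                      bead_names=np.array(
                          [f"B{i + 1}" for i in range(m)] * 2))
    manifest = {
        "kind": "assembly_trajectory",
        "seed": plan.seed,
        "n_frames": n,
        "n_beads_per_chain": m,
        "jitter_sigma_nm": plan.jitter_sigma_nm,
        "times_ns": times.tolist(),
        "comd_script_nm": comd_script.tolist(),
        "rg_script_angstrom": (rg_script_nm * NM_TO_ANGSTROM).tolist(),
    }
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_multimodel_pdb(traj, out_dir / "traj.pdb")
        write_bead_table(traj, out_dir / "beads.tsv")
        (out_dir / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True))
    return traj, manifest


def write_multimodel_pdb(traj: Trajectory, path) -> None:
    """Write frames as MODEL/ENDMDL blocks; coordinates in Angstrom."""
    lines = []
    names = (traj.bead_names if traj.bead_names is not None
             else np.array([f"B{i + 1}" for i in range(traj.n_beads)]))
    for t in range(traj.n_frames):
        lines.append(f"MODEL     {t + 1:4d}")
        for i in range(traj.n_beads):
            x, y, z = traj.coords[t, i] * NM_TO_ANGSTROM
            lines.append(
                f"ATOM  {i + 1:>5d} {names[i]:<4s} BEA {traj.chain_ids[i]}"
                f"{traj.residue_index[i]:>4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
                f"          {'C':>2s}")
        lines.append("ENDMDL")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def write_gro_frames(traj: Trajectory, out_dir, stem: str = "frame",
                     ) -> list[str]:
    """Write one GRO file per frame (native nm units); returns the paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    names = (traj.bead_names if traj.bead_names is not None
             else np.array([f"B{i + 1}" for i in range(traj.n_beads)]))
    box = np.abs(traj.coords).max() * 2.0 + 2.0
    paths = []
    for t in range(traj.n_frames):
        lines = [f"synthetic frame t={traj.times[t]:g} ns",
                 f"{traj.n_beads:5d}"]
        for i in range(traj.n_beads):
            x, y, z = traj.coords[t, i]
            lines.append(f"{traj.residue_index[i]:>5d}{'BEA':<5s}"
                         f"{names[i]:>5s}{i + 1:>5d}"
                         f"{x:8.3f}{y:8.3f}{z:8.3f}")
        lines.append(f"{box:10.5f}{box:10.5f}{box:10.5f}")
        path = out_dir / f"{stem}{t:04d}.gro"
        path.write_text("\n".join(lines) + "\n")
        paths.append(str(path))
    return paths


def write_bead_table(traj: Trajectory, path) -> None:
    names = (traj.bead_names if traj.bead_names is not None
             else np.array([f"B{i + 1}" for i in range(traj.n_beads)]))
    pd.DataFrame({
        "bead_name": names,
        "chain": traj.chain_ids,
        "residue": traj.residue_index,
        "mass_amu": traj.masses,
        "radius_nm": traj.radii,
    }).to_csv(path, sep="\t", index=False)
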