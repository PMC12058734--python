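"""Shared readers, writers, and run manifests for the command-line surface."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import __version__
from .errors import ParseError


def read_fasta(path) -> dict[str, str]:
    """FASTA records as an id -> uppercase sequence mapping, file order."""
    records = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        records[rec.id] = str(rec.seq).upper()
    if not records:
        raise ParseError(f"no FASTA records in {path}")
    return records


def write_fasta(records: Mapping[str, str], path) -> None:
    SeqIO.write(
        [SeqRecord(Seq(seq), id=name, description="")
         for name, seq in records.items()],
        str(path), "fasta")


def _round_floats(obj, sig: int = 6):
    if isinstance(obj, float):
        return float(f"{obj:.{sig}g}")
    if isinstance(obj, dict):
        return {k: _round_floats(v, sig) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, sig) for v in obj]
    return obj


def write_report(payload, path, fmt: str = "json") -> None:
    """Serialize a report with stable ordering and 6-significant-digit floats.

    ``payload`` is a dict (JSON) or a DataFrame / list of row dicts (TSV).
    The same payload always produces byte-identical files.
    """
    path = Path(path)
    if fmt == "json":
        path.write_text(json.dumps(_round_floats(payload), indent=2,
                                   sort_keys=True) + "\n")
    elif fmt == "tsv":
        frame = (payload if isinstance(payload, pd.DataFrame)
                 else pd.DataFrame(list(payload)))
        frame.to_csv(path, sep="\t", index=False, float_format="%.6g")
    else:
        raise ParseError(f"unknown report format {fmt!r}")


def write_run_manifest(out_path, command: str, parameters: dict,
                       inputs: Sequence[str], outputs: Sequence[str],
                       seed: int | None = None) -> None:
    """Record what a run did: inputs, parameters, seed, version, outputs."""
    manifest = {
        "tool": "spidrokit",
        "version": __version__,
        "command": command,
        "parameters": _round_floats(parameters),
        "inputs": [str(p) for p in inputs],
        "outputs": [str(p) for p in outputs],
        "seed": seed,
    }
    Path(out_path).write_text(json.dumps(manifest, indent=2, sort_keys=True)
                              + "\n")
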