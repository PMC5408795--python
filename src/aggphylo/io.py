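"""Readers and writers for alignments, trees and result files.

Alignments come in as FASTA or sequential PHYLIP (via Biopython) and are
validated into `Alignment` (triplet length, ACGTN- characters, equal
lengths).  Trees are Newick with the PAML ``#1`` foreground-branch tag.
Results go out as JSON (machine) plus TSV (tabular), with the seed and a
schema version embedded so any output can be regenerated.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
from Bio import SeqIO

from .experiments import ExperimentReport
from .inference import FitResult, LRTResult
from .likelihood import Alignment, Tree

SCHEMA_VERSION = 1


def read_alignment(path: str | Path, format: str = "fasta") -> Alignment:
    """Read and validate a codon alignment (``fasta`` or ``phylip``)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    schema = {"fasta": "fasta", "phylip": "phylip-sequential"}.get(format)
    if schema is None:
        raise ValueError(f"unknown alignment format {format!r}")
    records = list(SeqIO.parse(str(path), schema))
    if not records:
        raise ValueError(f"no sequences found in {path}")
    names = tuple(r.id for r in records)
    seqs = tuple(str(r.seq).upper() for r in records)
    try:
        return Alignment(names=names, sequences=seqs)
    except ValueError as err:
        raise ValueError(f"{path}: {err}") from err


def write_alignment(alignment: Alignment, path: str | Path, format: str = "fasta") -> None:
    path = Path(path)
    if format == "fasta":
        with path.open("w") as fh:
            for name, seq in zip(alignment.names, alignment.sequences):
                fh.write(f">{name}\n{seq}\n")
    elif format == "phylip":
        with path.open("w") as fh:
            fh.write(f" {alignment.n_taxa} {len(alignment.sequences[0])}\n")
            for name, seq in zip(alignment.names, alignment.sequences):
                fh.write(f"{name:<10}{seq}\n")
    else:
        raise ValueError(f"unknown alignment format {format!r}")


def read_tree(path: str | Path) -> Tree:
    """Read a Newick tree; ``#1`` tags become foreground-branch flags."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    return Tree.from_newick(path.read_text())


def write_tree(tree: Tree, path: str | Path) -> None:
    Path(path).write_text(tree.to_newick() + "\n")


def _to_jsonable(obj: Any) -> Any:
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, np.bool_):
        return bool(obj)
    if isinstance(obj, dict):
        return {str(k): _to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_jsonable(v) for v in obj]
    return obj


def write_results(
    result: FitResult | LRTResult | ExperimentReport,
    out_dir: str | Path,
    stem: str = "result",
    config: dict | None = None,
) -> dict[str, Path]:
    """Write a result as ``<stem>.json`` (+ ``<stem>.tsv`` for tables).

    The JSON always carries ``schema_version`` and the run configuration;
    no timestamps, so identical runs produce byte-identical files.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    payload: dict[str, Any] = {"schema_version": SCHEMA_VERSION}
    if config:
        payload["config"] = _to_jsonable(config)
    files: dict[str, Path] = {}
    if isinstance(result, ExperimentReport):
        payload["kind"] = "experiment"
        payload["summary"] = _to_jsonable(result.summary)
        tsv_path = out_dir / f"{stem}.tsv"
        result.table.to_csv(tsv_path, sep="\t", index=False)
        files["tsv"] = tsv_path
    elif isinstance(result, (FitResult, LRTResult)):
        payload["kind"] = "fit" if isinstance(result, FitResult) else "lrt"
        payload.update(_to_jsonable(dataclasses.asdict(result)))
        tsv_path = out_dir / f"{stem}.tsv"
        pd.DataFrame([_flatten(dataclasses.asdict(result))]).to_csv(
            tsv_path, sep="\t", index=False
        )
        files["tsv"] = tsv_path
    else:
        raise TypeError(f"cannot serialise {type(result).__name__}")
    json_path = out_dir / f"{stem}.json"
    json_path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    files["json"] = json_path
    return files


def _flatten(d: dict, prefix: str = "") -> dict:
    out = {}
    for k, v in d.items():
        key = f"{prefix}{k}"
        if isinstance(v, dict):
            out.update(_flatten(v, prefix=f"{key}."))
        else:
            out[key] = v
    return out
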