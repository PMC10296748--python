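"""File formats: FASTA with labels, sidecar tables, run configs, CSV reports.

Two label dialects are supported for FASTA input:

* ``header-pipe`` — the record header is ``identifier|label``;
* ``sidecar`` — headers are plain identifiers and labels come from a
  two-column tab-separated file (id, label).

A tolerant best-effort parser for VISTA Enhancer Browser-style headers
(``>Human|chr16:86430087-86430726 | element 1 | positive | ...``) maps
species + activity annotations onto the pipeline's class labels.

Parsing preserves residue case; case folding is the encodings' concern.
"""

from __future__ import annotations

import csv
import datetime
import json
from pathlib import Path
from typing import Literal

import numpy as np
import yaml
from Bio import SeqIO
from pydantic import BaseModel, ConfigDict, field_validator, model_validator

from .dataset import LabeledDataset, NucleotideSequence
from .encodings import SCHEMES


class FastaParseError(ValueError):
    pass


def _precheck_fasta(path: Path) -> None:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped:
                continue
            if not stripped.startswith(">"):
                raise FastaParseError(
                    f"{path}: line {lineno}: sequence data before any '>' header"
                )
            return


def read_sidecar(path: str | Path) -> dict[str, str]:
    """Read an ``id<TAB>label`` table into a dict."""
    labels: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}: line {lineno}: expected 2 tab-separated columns")
            labels[parts[0]] = parts[1]
    return labels


def read_fasta(
    path: str | Path,
    label_dialect: Literal["header-pipe", "sidecar", "vista", "none"] = "header-pipe",
    sidecar_path: str | Path | None = None,
) -> LabeledDataset:
    """Parse a (possibly line-wrapped) FASTA file into a labeled dataset."""
    path = Path(path)
    _precheck_fasta(path)
    sidecar = read_sidecar(sidecar_path) if label_dialect == "sidecar" else None
    if label_dialect == "sidecar" and sidecar_path is None:
        raise ValueError("sidecar dialect requires sidecar_path")

    sequences: list[NucleotideSequence] = []
    seen: set[str] = set()
    for record in SeqIO.parse(str(path), "fasta"):
        header = record.description
        if label_dialect == "header-pipe":
            if "|" not in header:
                raise ValueError(f"record {header!r}: no '|label' in header")
            seq_id, label = (part.strip() for part in header.split("|", 1))
        elif label_dialect == "sidecar":
            seq_id = record.id
            if seq_id not in sidecar:  # type: ignore[operator]
                raise ValueError(f"record {seq_id!r}: no label in sidecar file")
            label = sidecar[seq_id]  # type: ignore[index]
        elif label_dialect == "vista":
            seq_id, label = _parse_vista_header(header)
        else:
            seq_id, label = record.id, None
        if seq_id in seen:
            raise ValueError(f"duplicate sequence id {seq_id!r}")
        seen.add(seq_id)
        sequences.append(NucleotideSequence(id=seq_id, residues=str(record.seq), label=label))
    return LabeledDataset(sequences, provenance=f"{path} [{label_dialect}]")


def _parse_vista_header(header: str) -> tuple[str, str]:
    """Best-effort mapping of a VISTA-style header to pipeline labels.

    Expects pipe-separated fields like ``Human|chr16:86430087-86430726 |
    element 1 | positive | ...``; coordinates are carried inside the id as
    opaque text. ``positive`` activity maps to ``<species>_enhancer``,
    anything else to ``no_enhancer``.
    """
    fields = [f.strip() for f in header.split("|")]
    if len(fields) < 3:
        raise ValueError(f"header {header!r} does not look like a VISTA export")
    species = fields[0].lower()
    seq_id = f"{fields[0]}:{fields[1]}:{fields[2]}".replace(" ", "_")
    activity = fields[3].lower() if len(fields) > 3 else "negative"
    label = f"{species}_enhancer" if activity.startswith("positive") else "no_enhancer"
    return seq_id, label


def write_fasta(dataset: LabeledDataset, path: str | Path, line_width: int = 60) -> None:
    """Write ``id|label`` headers and wrapped sequence lines, byte-stable."""
    if line_width < 1:
        raise ValueError("line_width must be >= 1")
    with open(path, "w") as fh:
        for seq in dataset:
            header = seq.id if seq.label is None else f"{seq.id}|{seq.label}"
            fh.write(f">{header}\n")
            for start in range(0, len(seq.residues), line_width):
                fh.write(seq.residues[start : start + line_width] + "\n")


def write_sidecar(dataset: LabeledDataset, path: str | Path) -> None:
    with open(path, "w") as fh:
        for seq in dataset:
            fh.write(f"{seq.id}\t{seq.label}\n")


# ------------------------------------------------------------------ run config

class RunConfig(BaseModel):
    """Strict-schema run configuration (unknown keys are rejected)."""

    model_config = ConfigDict(extra="forbid")

    scheme: Literal["integer", "atomic", "eiip", "bfdna"] = "bfdna"
    scenario: Literal[1, 2] = 1
    seed: int = 0
    splits: tuple[float, float, float] = (0.70, 0.15, 0.15)
    strict: bool = True
    scaled_down: bool = False
    input_length: int | None = None  # default: 1024, or 200 when scaled down
    epochs: int | None = None  # default: 500, or 30 when scaled down
    batch_size: int = 32
    learning_rate: float = 0.001
    fasta: str | None = None
    labels: str | None = None
    label_dialect: Literal["header-pipe", "sidecar", "vista"] = "header-pipe"
    out_dir: str = "runs"

    @field_validator("splits")
    @classmethod
    def _splits_sum(cls, v: tuple[float, float, float]) -> tuple[float, float, float]:
        if abs(sum(v) - 1.0) > 1e-9:
            raise ValueError(f"split fractions must sum to 1, got {v} (sum {sum(v)})")
        return v

    @model_validator(mode="after")
    def _fill_defaults(self) -> "RunConfig":
        if self.input_length is None:
            object.__setattr__(self, "input_length", 200 if self.scaled_down else 1024)
        if self.epochs is None:
            object.__setattr__(self, "epochs", 30 if self.scaled_down else 500)
        return self


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML run configuration; defaults are expanded."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return RunConfig(**raw)


# ------------------------------------------------------------------ outputs

def write_encoded_csv(matrix: np.ndarray, ids: list[str], path: str | Path) -> None:
    """One row per sequence: id followed by the encoded vector."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        for seq_id, row in zip(ids, matrix):
            writer.writerow([seq_id, *(format(v, ".10g") for v in row)])


def write_metric_report_csv(report, path: str | Path, scheme: str = "", scenario: int = 0) -> None:
    """Flat key/value table in the Tables 4/5 column order."""
    d = report.as_dict()
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["scheme", "scenario", *d.keys()])
        writer.writerow([scheme, scenario, *(("" if v is None else format(v, ".6g")) for v in d.values())])


def write_confusion_csv(table: np.ndarray, classes: list[str], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["true\\pred", *classes])
        for cls, row in zip(classes, np.asarray(table)):
            writer.writerow([cls, *row.tolist()])


def write_roc_csv(curve, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["fpr", "tpr"])
        for f, t in zip(curve.fpr, curve.tpr):
            writer.writerow([format(f, ".10g"), format(t, ".10g")])


def write_history_csv(history, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        has_val = bool(history.val_loss)
        header = ["epoch", "train_loss", "train_accuracy"]
        if has_val:
            header += ["val_loss", "val_accuracy"]
        writer.writerow(header)
        for i, epoch in enumerate(history.epoch):
            row = [epoch, history.train_loss[i], history.train_accuracy[i]]
            if has_val:
                row += [history.val_loss[i], history.val_accuracy[i]]
            writer.writerow(row)


def write_manifest(path: str | Path, subcommand: str, config: dict, started: str, seed: int | None = None) -> None:
    """Plain-text provenance record sufficient to re-run the command."""
    manifest = {
        "subcommand": subcommand,
        "config": config,
        "seed": seed,
        "started": started,
        "finished": datetime.datetime.now().isoformat(timespec="seconds"),
    }
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
        fh.write("\n")
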