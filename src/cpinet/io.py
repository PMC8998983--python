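"""Readers and writers: CPI tables, pretraining corpora, annotation tables,
FASTA, evaluation reports and screening output.

Tables are parsed by column name (never position), labels are decimal
floats, and malformed rows are rejected with their row number — either
raising (strict) or logged and skipped (lenient).  Every writer emits plain
text (CSV/TSV/JSON) so round-trips are inspectable.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Sequence

import pandas as pd
from Bio import SeqIO

from .dataset import CPIDataset, CPISample
from .metrics import EvalResult, ScreenEntry
from .molgraph import parse_smiles
from .sps import ResidueAnnotation, parse_ss_letter
from .synthetic import SynthDataset

logger = logging.getLogger("cpinet")

REQUIRED_COLUMNS = ("compound_id", "smiles", "protein_id", "sps", "label")


def _file_hash(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def read_cpi_table(path: str | Path, strict: bool = True,
                   validate_smiles: bool = True) -> CPIDataset:
    """Read a CSV/TSV CPI table into a validated dataset.

    Expected columns: compound_id, smiles, protein_id, sps (whitespace
    separated words), label; ``amino`` is optional.  Rows whose SMILES does
    not parse or whose label is not a finite decimal are rejected: strict
    mode raises on the first bad row, lenient mode skips and logs each one.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    frame = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    for col in REQUIRED_COLUMNS:
        if col not in frame.columns:
            raise ValueError(f"missing required column {col!r}")
    has_amino = "amino" in frame.columns
    samples: list[CPISample] = []
    rejected = 0
    for row_number, row in enumerate(frame.itertuples(index=False), start=2):
        try:
            label = float(getattr(row, "label"))
            smiles = getattr(row, "smiles")
            if validate_smiles:
                parse_smiles(smiles)
            samples.append(CPISample(
                smiles=smiles,
                sps=tuple(getattr(row, "sps").split()),
                amino=(getattr(row, "amino") or None) if has_amino else None,
                label=label,
                compound_id=getattr(row, "compound_id"),
                protein_id=getattr(row, "protein_id")))
        except (ValueError, OverflowError) as exc:
            if strict:
                raise ValueError(f"row {row_number}: {exc}") from exc
            rejected += 1
            logger.warning("skipping row %d: %s", row_number, exc)
    if rejected:
        logger.info("read %d samples, rejected %d rows", len(samples), rejected)
    return CPIDataset(samples, provenance={"path": str(path),
                                           "hash": _file_hash(path),
                                           "rejected_rows": rejected})


def write_cpi_table(ds: CPIDataset | SynthDataset, path: str | Path) -> None:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    rows = []
    for s in ds.samples:
        row = {"compound_id": s.compound_id, "smiles": s.smiles,
               "protein_id": s.protein_id,
               "sps": " ".join(getattr(s, "sps", getattr(s, "sps_words", ()))),
               "label": repr(float(s.label))}
        amino = getattr(s, "amino", None)
        if amino:
            row["amino"] = amino
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep=sep, index=False)


def read_corpus(path: str | Path) -> list[str]:
    """Plain-text corpus: one sequence per line, blank lines ignored."""
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    return [line.strip() for line in lines if line.strip()]


def write_corpus(sequences: Sequence[str], path: str | Path) -> None:
    Path(path).write_text("\n".join(sequences) + "\n", encoding="utf-8")


def read_annotation_table(path: str | Path) -> list[ResidueAnnotation]:
    """Per-residue annotation TSV: position (1-based), aa, ss (H/E/C), exposed (0/1)."""
    frame = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("position", "aa", "ss", "exposed"):
        if col not in frame.columns:
            raise ValueError(f"missing required column {col!r}")
    frame = frame.assign(position=frame["position"].astype(int)).sort_values("position")
    positions = frame["position"].tolist()
    if positions != list(range(1, len(positions) + 1)):
        raise ValueError("positions must be contiguous from 1")
    return [
        ResidueAnnotation(amino_acid=aa, secondary_structure=parse_ss_letter(ss),
                          exposed=bool(int(exposed)))
        for aa, ss, exposed in zip(frame["aa"], frame["ss"], frame["exposed"])
    ]


def read_fasta(path: str | Path) -> dict[str, str]:
    return {record.id: str(record.seq) for record in SeqIO.parse(str(path), "fasta")}


def write_eval_report(result: EvalResult, path: str | Path) -> None:
    Path(path).write_text(json.dumps(result.to_dict(), indent=2) + "\n")


def write_screen_tsv(entries: Sequence[ScreenEntry], path: str | Path) -> None:
    rows = [{"rank": e.rank, "compound_id": e.compound_id, "smiles": e.smiles,
             "score": "" if e.status.startswith("failed") else repr(e.score),
             "status": e.status} for e in entries]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_manifest(payload: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
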