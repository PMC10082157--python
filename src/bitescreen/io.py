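"""Typed readers and report writers for the pipeline's file formats.

Formats: reference panels as YAML (optionally pointing at a FASTA of
domain sequences), reads as FASTA/FASTQ, recovery titrations as CSV, and
reports as JSON/CSV. Readers validate eagerly and fail with messages
naming the offending record; writers are byte-stable for identical inputs
and stamp a provenance block (tool version, seed, config hash).
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Dict, Iterator, List, Optional, Sequence, Union

import pandas as pd
import yaml
from Bio import SeqIO

from . import __version__
from .amplicon_classify import CCSRead, CompositionMatrix
from .library_design import (
    ALL_ORIENTATIONS,
    AnchorSet,
    DegenerateScheme,
    LibraryDefinition,
    LinkerRef,
    ScFvRef,
    Target,
)

__all__ = [
    "DataValidationError",
    "read_panel",
    "read_reads",
    "read_recovery",
    "write_library_fasta",
    "write_calls_tsv",
    "write_json_report",
    "write_composition_csv",
    "provenance",
]


class DataValidationError(ValueError):
    """Malformed or inconsistent input data (CLI exit code 2)."""


def provenance(seed: Optional[int], config_obj) -> Dict[str, Union[str, int, None]]:
    digest = hashlib.sha256(
        json.dumps(config_obj, sort_keys=True, default=str).encode()
    ).hexdigest()
    return {
        "tool": "bitescreen",
        "version": __version__,
        "seed": seed,
        "config_sha256": digest,
        "schema_version": 1,
    }


# ---------------------------------------------------------------------------
# Panel
# ---------------------------------------------------------------------------

def _panel_sequences(doc: dict, base: Path) -> Dict[str, str]:
    """Domain sequences either inline or from a sidecar FASTA."""
    seqs: Dict[str, str] = {}
    fasta = doc.get("fasta")
    if fasta:
        path = (base / fasta) if not Path(fasta).is_absolute() else Path(fasta)
        if not path.exists():
            raise DataValidationError(f"panel FASTA not found: {path}")
        for record in SeqIO.parse(str(path), "fasta"):
            if record.id in seqs:
                raise DataValidationError(f"duplicate FASTA id {record.id!r} in {path}")
            seqs[record.id] = str(record.seq)
    return seqs


def read_panel(path: Union[str, Path]) -> LibraryDefinition:
    """Load a reference panel YAML into a :class:`LibraryDefinition`.

    Schema::

        fasta: domains.fasta            # optional; ids referenced below
        scfvs:
          - {name, target, vh, vl, cdrh3_start, cdrh3_end}   # vh/vl are
            # sequences or FASTA ids; cdrh3_* only for CD19 entries
        linkers:
          - {name, seq, rigidity, length_class}
        intra_scfv_linker: GGGGSGGGGSGGGGS   # optional
        scheme: {code, stop_policy, parent_policy}           # optional
        anchors: {signal_dna, histag2a_dna, max_mismatches}  # optional
    """
    path = Path(path)
    try:
        doc = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise DataValidationError(f"{path}: invalid YAML: {exc}") from exc
    if not isinstance(doc, dict):
        raise DataValidationError(f"{path}: panel must be a mapping")
    seqs = _panel_sequences(doc, path.parent)

    def resolve(token: str) -> str:
        return seqs.get(token, token)

    cd19: List[ScFvRef] = []
    cd3: List[ScFvRef] = []
    for i, entry in enumerate(doc.get("scfvs", [])):
        try:
            target = Target(entry["target"])
            ref = ScFvRef(
                name=entry["name"],
                target=target,
                vh_seq=resolve(entry["vh"]),
                vl_seq=resolve(entry["vl"]),
                cdrh3_start=entry.get("cdrh3_start"),
                cdrh3_end=entry.get("cdrh3_end"),
                metadata={
                    k: str(v)
                    for k, v in entry.items()
                    if k not in ("name", "target", "vh", "vl", "cdrh3_start", "cdrh3_end")
                },
            )
        except (KeyError, ValueError) as exc:
            raise DataValidationError(f"{path}: scfvs[{i}]: {exc}") from exc
        (cd19 if target is Target.CD19 else cd3).append(ref)

    linkers: List[LinkerRef] = []
    for i, entry in enumerate(doc.get("linkers", [])):
        try:
            linkers.append(
                LinkerRef(
                    entry["name"], entry["seq"], entry["rigidity"], entry["length_class"]
                )
            )
        except (KeyError, ValueError) as exc:
            raise DataValidationError(f"{path}: linkers[{i}]: {exc}") from exc

    kwargs = {}
    if "intra_scfv_linker" in doc:
        kwargs["intra_scfv_linker"] = doc["intra_scfv_linker"]
    if "scheme" in doc:
        kwargs["scheme"] = DegenerateScheme(**doc["scheme"])
    if "anchors" in doc:
        kwargs["anchors"] = AnchorSet(**doc["anchors"])
    try:
        return LibraryDefinition(
            cd19_refs=tuple(cd19),
            cd3_refs=tuple(cd3),
            linkers=tuple(linkers),
            orientations=ALL_ORIENTATIONS,
            **kwargs,
        )
    except ValueError as exc:
        raise DataValidationError(f"{path}: {exc}") from exc


# ---------------------------------------------------------------------------
# Reads and recovery observations
# ---------------------------------------------------------------------------

_FASTQ_SUFFIXES = (".fastq", ".fq")


def read_reads(path: Union[str, Path]) -> Iterator[CCSRead]:
    """Stream reads from FASTA or FASTQ (picked by file extension)."""
    path = Path(path)
    fmt = "fastq" if path.suffix.lower() in _FASTQ_SUFFIXES else "fasta"
    seen = set()
    for record in SeqIO.parse(str(path), fmt):
        if record.id in seen:
            raise DataValidationError(f"{path}: duplicate read id {record.id!r}")
        seen.add(record.id)
        quals = record.letter_annotations.get("phred_quality")
        try:
            yield CCSRead(record.id, str(record.seq).upper(), quals)
        except ValueError as exc:
            raise DataValidationError(f"{path}: {exc}") from exc


RECOVERY_COLUMNS = ("run_id", "abundance_percent", "copies_spiked", "copies_recovered")


def read_recovery(path: Union[str, Path]) -> pd.DataFrame:
    """Load and validate a recovery-titration CSV."""
    path = Path(path)
    df = pd.read_csv(path)
    missing = set(RECOVERY_COLUMNS) - set(df.columns)
    if missing:
        raise DataValidationError(f"{path}: missing columns {sorted(missing)}")
    for line, row in df.iterrows():
        where = f"{path}: row {line + 2}"  # +2: header plus 1-based
        if row["abundance_percent"] <= 0:
            raise DataValidationError(f"{where}: abundance must be > 0")
        if row["copies_spiked"] < 0 or row["copies_recovered"] < 0:
            raise DataValidationError(f"{where}: negative copy count")
        if row["copies_recovered"] > row["copies_spiked"]:
            raise DataValidationError(
                f"{where}: copies_recovered > copies_spiked "
                f"({row['copies_recovered']} > {row['copies_spiked']})"
            )
    return df


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------

def write_library_fasta(variants, path: Union[str, Path], kind: str = "protein") -> int:
    """Write enumerated variants as FASTA with structured headers.

    Header: ``name|cd19=<id>|cdrh3=<posaa>|cd3=<id>|linker=<id>|orient=<label>``.
    Returns the number of records written.
    """
    if kind not in ("protein", "dna"):
        raise ValueError(f"kind {kind!r}")
    n = 0
    with open(path, "w") as fh:
        for v in variants:
            seq = v.protein_seq if kind == "protein" else v.dna_seq
            if not seq:
                raise ValueError(f"{v.label}: {kind} sequence not assembled")
            cdrh3 = (
                "parent"
                if v.cd19_variant.is_parent
                else f"{v.cd19_variant.cdrh3_pos}{v.cd19_variant.aa}"
            )
            header = (
                f"bite{n:06d}|cd19={v.cd19_variant.parent.name}|cdrh3={cdrh3}"
                f"|cd3={v.cd3.name}|linker={v.linker.name}|orient={v.orientation.label}"
            )
            fh.write(f">{header}\n{seq}\n")
            n += 1
    return n


def write_calls_tsv(calls, path: Union[str, Path]) -> None:
    rows = [
        {
            "read_id": c.read_id,
            "status": c.status,
            "strand": c.strand or "",
            "cd19_id": c.cd19_id or "",
            "cd3_id": c.cd3_id or "",
            "linker_id": c.linker_id or "",
            "orientation": c.orientation_label or "",
            "cdrh3_mutations": c.mutations_str(),
        }
        for c in calls
    ]
    pd.DataFrame(
        rows,
        columns=[
            "read_id",
            "status",
            "strand",
            "cd19_id",
            "cd3_id",
            "linker_id",
            "orientation",
            "cdrh3_mutations",
        ],
    ).to_csv(path, sep="\t", index=False)


def write_json_report(report: dict, path: Union[str, Path]) -> None:
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True, default=str) + "\n")


def write_composition_csv(matrix: CompositionMatrix, path: Union[str, Path]) -> None:
    matrix.matrix.to_csv(path, float_format="%.6f")
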