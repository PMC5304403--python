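"""Readers/writers for the plain-text formats the pipeline exchanges.

FASTA/FASTQ go through Biopython's SeqIO; tabular data through pandas
(tab-separated, header row, '.' decimal). Gzip is handled transparently by
extension. Every result JSON carries a provenance block (package version,
config hash, seed) so two runs with equal configurations are verifiable as
identical.
"""

from __future__ import annotations

import gzip
import hashlib
import json
from dataclasses import asdict, is_dataclass
from pathlib import Path
from typing import Any, Iterable

import numpy as np
import pandas as pd
from Bio import SeqIO

from . import __version__
from .annotate import MatureReference, Read
from .errors import InputError, ParseError


def _open_text(path: str | Path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_fasta(path: str | Path) -> tuple[dict[str, str], bool]:
    """FASTA -> ordered id->sequence dict; returns (entries, had_u) where
    ``had_u`` records that RNA bases were normalised U->T on load."""
    entries: dict[str, str] = {}
    had_u = False
    with _open_text(path) as handle:
        for record in SeqIO.parse(handle, "fasta"):
            if record.id in entries:
                raise ParseError(f"{path}: duplicate FASTA id {record.id!r}")
            seq = str(record.seq).upper()
            if "U" in seq:
                had_u = True
                seq = seq.replace("U", "T")
            entries[record.id] = seq
    return entries, had_u


def read_mature_reference(path: str | Path) -> MatureReference:
    entries, _ = read_fasta(path)
    return MatureReference(entries.items())


def write_fasta(entries: dict[str, str], path: str | Path) -> None:
    with _open_text(path, "wt") as handle:
        for seq_id, seq in entries.items():
            handle.write(f">{seq_id}\n{seq}\n")


def read_fastq(path: str | Path) -> list[Read]:
    """FASTQ (Phred+33) -> list of reads; malformed records name themselves."""
    reads: list[Read] = []
    with _open_text(path) as handle:
        try:
            for title, seq, qual in SeqIO.QualityIO.FastqGeneralIterator(handle):
                read_id = title.split()[0]
                if len(seq) != len(qual):
                    raise ParseError(
                        f"{path}: record {read_id!r} has sequence/quality "
                        "length mismatch"
                    )
                reads.append(Read(read_id, seq.upper(), qual))
        except ValueError as exc:  # Biopython's own malformed-record error
            at = reads[-1].id if reads else "<first record>"
            raise ParseError(f"{path}: malformed FASTQ near record {at!r}: {exc}") from exc
    return reads


def write_fastq(reads: Iterable[Read], path: str | Path) -> None:
    with _open_text(path, "wt") as handle:
        for r in reads:
            handle.write(f"@{r.id}\n{r.seq}\n+\n{r.qual}\n")


def read_tsv_matrix(path: str | Path) -> pd.DataFrame:
    """Gene x sample matrix: first column gene id, header row sample ids."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise ParseError(f"{path}: duplicate gene id {dup!r}")
    try:
        return df.astype(float)
    except ValueError as exc:
        bad = df.apply(pd.to_numeric, errors="coerce")
        rows, cols = np.where(bad.isna() & df.notna())
        where = (
            f"gene {df.index[rows[0]]!r}, sample {df.columns[cols[0]]!r}"
            if len(rows) else "unknown cell"
        )
        raise ParseError(f"{path}: non-numeric matrix cell at {where}") from exc


def write_tsv_matrix(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t")


def read_deg_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    for col in ("gene_id", "log2FC"):
        if col not in df.columns:
            raise ParseError(f"{path}: DEG table lacks column {col!r}")
    return df


def write_deg_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_gene_set(path: str | Path) -> set[str]:
    with _open_text(path) as handle:
        return {line.strip() for line in handle if line.strip()}


def config_hash(config: Any) -> str:
    """Stable sha256 over a JSON-serialisable (or dataclass) configuration."""
    if is_dataclass(config) and not isinstance(config, type):
        config = asdict(config)
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def provenance(config: Any, seed: int | None = None) -> dict[str, Any]:
    return {
        "package": "mirage",
        "version": __version__,
        "config_hash": config_hash(config),
        "rng_seed": seed,
    }


class _ResultEncoder(json.JSONEncoder):
    def default(self, o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (set, frozenset)):
            return sorted(o)
        if is_dataclass(o) and not isinstance(o, type):
            return asdict(o)
        return super().default(o)


def write_results(results: dict[str, Any], path: str | Path,
                  config: Any = None, seed: int | None = None) -> None:
    """Write a JSON results file with a provenance block prepended."""
    payload = {"provenance": provenance(config, seed), **results}
    with open(path, "w") as handle:
        json.dump(payload, handle, indent=2, cls=_ResultEncoder)
        handle.write("\n")


def read_results(path: str | Path) -> dict[str, Any]:
    with open(path) as handle:
        return json.load(handle)


def check_exists(path: str | Path) -> Path:
    path = Path(path)
    if not path.exists():
        raise InputError(f"required input file does not exist: {path}")
    return path
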