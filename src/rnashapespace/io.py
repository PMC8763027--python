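"""File formats and run manifests.

Formats: FASTA in/out (via Biopython; the raw reader does not normalize —
T->U mapping happens at pipeline ingestion), spectrum TSV with a JSON
manifest sidecar, and comparison-result JSON.  Spectrum TSV is
tab-separated precisely because shape strings contain brackets that would
need quoting in CSV; UTF-8, Unix newlines.

On read, frequencies and NSS estimates are recomputed from the counts and
checked against the file (tolerance 1e-9): derived columns are never
trusted.
"""

from __future__ import annotations

import datetime as _dt
import hashlib
import json
from dataclasses import dataclass, field
from typing import Iterable, Optional, TextIO, Union

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .gsampling import ShapeSpectrum

SPECTRUM_COLUMNS = ["shape", "level", "L", "count", "n_samples", "freq",
                    "ci_low", "ci_high", "nss_est"]


class SpectrumFormatError(ValueError):
    """Spectrum TSV malformed or internally inconsistent."""


def read_fasta(source: Union[str, TextIO]) -> list[tuple[str, str]]:
    """Read (header, residue-text) records; residues returned verbatim."""
    return [(rec.description, str(rec.seq))
            for rec in SeqIO.parse(source, "fasta")]


def write_fasta(records: Iterable[tuple[str, str]],
                sink: Union[str, TextIO]) -> None:
    seqrecords = [
        SeqRecord(Seq(seq), id=header.split()[0] if header else f"seq{i}",
                  description=header)
        for i, (header, seq) in enumerate(records, 1)
    ]
    SeqIO.write(seqrecords, sink, "fasta")


def write_spectrum(spec: ShapeSpectrum, path: str,
                   manifest: Optional["RunManifest"] = None) -> None:
    """Write the canonical spectrum TSV (+ optional manifest sidecar)."""
    spec.to_frame().to_csv(path, sep="\t", index=False, lineterminator="\n")
    if manifest is not None:
        manifest.write(path + ".manifest.json")


def read_spectrum(path: str) -> ShapeSpectrum:
    """Read a spectrum TSV; recompute and verify all derived columns."""
    df = pd.read_csv(path, sep="\t", dtype={"shape": str})
    missing = [c for c in SPECTRUM_COLUMNS if c not in df.columns]
    if missing:
        raise SpectrumFormatError(f"missing columns: {missing}")
    if df.empty:
        raise SpectrumFormatError("empty spectrum file")
    for col in ("level", "L", "n_samples"):
        if df[col].nunique() != 1:
            raise SpectrumFormatError(f"column {col!r} is not constant")
    n_samples = int(df["n_samples"].iloc[0])
    counts = {str(r.shape): int(r.count)
              for r in df.itertuples(index=False)}
    spec = ShapeSpectrum(int(df["L"].iloc[0]), int(df["level"].iloc[0]),
                         n_samples, counts)
    for row in df.itertuples(index=False):
        expected = counts[str(row.shape)] / n_samples
        if abs(float(row.freq) - expected) > 1e-9:
            raise SpectrumFormatError(
                f"freq for shape {row.shape!r} inconsistent with its count"
            )
    return spec


def merge_spectrum_files(paths: Iterable[str]) -> ShapeSpectrum:
    """Sum spectra recorded under identical (L, level) configuration."""
    specs = [read_spectrum(p) for p in paths]
    merged = specs[0]
    for s in specs[1:]:
        merged = merged.merge(s)
    return merged


def file_digest(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(65536), b""):
            h.update(block)
    return h.hexdigest()


@dataclass
class RunManifest:
    """Provenance record sufficient to re-run a pipeline step bit-identically
    (for deterministic backends)."""

    command: str
    config: dict = field(default_factory=dict)
    seed: Optional[int] = None
    backend_id: Optional[str] = None
    input_digests: dict[str, str] = field(default_factory=dict)
    skipped: dict[str, int] = field(default_factory=dict)
    timestamp: str = field(
        default_factory=lambda: _dt.datetime.now(_dt.timezone.utc).isoformat()
    )

    def to_dict(self) -> dict:
        return {
            "command": self.command,
            "config": self.config,
            "seed": self.seed,
            "backend_id": self.backend_id,
            "input_digests": self.input_digests,
            "skipped": self.skipped,
            "timestamp": self.timestamp,
        }

    def write(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)
            fh.write("\n")

    @staticmethod
    def read(path: str) -> "RunManifest":
        with open(path) as fh:
            data = json.load(fh)
        return RunManifest(**data)
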