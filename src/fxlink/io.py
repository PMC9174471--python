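"""Readers and writers for the standard formats the pipeline consumes.

FASTA via Biopython, MGF via pyteomics, tables via pandas. Only thin
adapters live here; all science is elsewhere.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from Bio import SeqIO
from pyteomics import mgf as _mgf


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a (possibly line-wrapped) FASTA file.

    Returns (accession, sequence) pairs; the accession is the first
    whitespace-delimited token of the header line.
    """
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append((rec.id, str(rec.seq).upper()))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return records


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path, width: int = 60) -> None:
    lines = []
    for acc, seq in records:
        lines.append(f">{acc}")
        lines.extend(seq[i : i + width] for i in range(0, len(seq), width))
    Path(path).write_text("\n".join(lines) + "\n")


def read_mgf(path: str | Path) -> list[dict]:
    """Read MS2 spectra from a Mascot generic format file.

    Returns dicts with spectrum_id, precursor_mz, precursor_charge and a
    peaks array of shape (n, 2) sorted by m/z.
    """
    spectra = []
    with _mgf.MGF(str(path)) as reader:
        for spec in reader:
            params = spec["params"]
            charge = int(params["charge"][0])
            mz = np.asarray(spec["m/z array"], dtype=float)
            inten = np.asarray(spec["intensity array"], dtype=float)
            order = np.argsort(mz)
            spectra.append(
                {
                    "spectrum_id": str(params.get("title", "")),
                    "precursor_mz": float(params["pepmass"][0]),
                    "precursor_charge": charge,
                    "peaks": np.column_stack([mz[order], inten[order]]),
                }
            )
    return spectra


def write_mgf(spectra: Iterable[dict], path: str | Path) -> None:
    """Write spectra dicts (as produced by read_mgf / the generators) to MGF.

    Written manually so output is byte-stable across library versions.
    """
    out = []
    for spec in spectra:
        out.append("BEGIN IONS")
        out.append(f"TITLE={spec['spectrum_id']}")
        out.append(f"PEPMASS={spec['precursor_mz']:.6f}")
        out.append(f"CHARGE={spec['precursor_charge']}+")
        for mz, inten in np.asarray(spec["peaks"]):
            out.append(f"{mz:.6f} {inten:.2f}")
        out.append("END IONS")
    Path(path).write_text("\n".join(out) + "\n")


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_table(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index)


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Gene-set file: one set per line, name<TAB>description<TAB>genes..."""
    sets: dict[str, set[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line: {line[:60]!r}")
        sets[parts[0]] = set(parts[2:])
    return sets
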