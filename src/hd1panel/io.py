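"""Readers and writers: FASTA sequences, panel tables (TSV), newick trees.

Also exposes the packaged transcription of the published allele-panel table
(44 Miscanthus accessions with per-allele classification codes, provenance
and heading dates) via :func:`load_table1`.
"""

from __future__ import annotations

import datetime as _dt
import re
from importlib import resources
from os import PathLike
from typing import Iterable, TextIO

import pandas as pd
from Bio.SeqIO.FastaIO import SimpleFastaParser

from .model import (
    DID_NOT_HEAD,
    AccessionMeta,
    AlleleCode,
    AlleleRecord,
    Locus,
    PanelTable,
    region_from_country,
)

_VALID_ALPHABET = set("ACGTN")


def read_fasta(path: str | PathLike | TextIO) -> list[tuple[str, str]]:
    """Read a FASTA file into ``[(id, sequence), ...]``.

    Sequences are uppercased and restricted to the {A, C, G, T, N} alphabet;
    duplicate record ids and illegal characters raise ``ValueError``.
    """
    if hasattr(path, "read"):
        records = list(SimpleFastaParser(path))
    else:
        with open(path) as fh:
            records = list(SimpleFastaParser(fh))
    out: list[tuple[str, str]] = []
    seen: set[str] = set()
    for title, seq in records:
        rid = title.split()[0] if title.split() else title
        if rid in seen:
            raise ValueError(f"duplicate FASTA id: {rid!r}")
        seen.add(rid)
        seq = seq.upper()
        bad = set(seq) - _VALID_ALPHABET
        if bad:
            raise ValueError(
                f"record {rid!r} contains illegal characters: {sorted(bad)}"
            )
        out.append((rid, seq))
    return out


def write_fasta(records: Iterable[tuple[str, str]], path: str | PathLike, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


_PANEL_COLUMNS = [
    "accession_id", "species", "country", "latitude", "longitude",
    "locus", "code", "note", "heading_2012", "heading_2014",
]

_MONTHS = {m: i + 1 for i, m in enumerate(
    ["Jan", "Feb", "Mar", "Apr", "May", "Jun",
     "Jul", "Aug", "Sep", "Oct", "Nov", "Dec"])}

_MISSING_CELL = re.compile(r"^[-–—]*$")  # '', '-', en/em dashes


def _parse_heading(cell: str, year: int):
    cell = cell.strip()
    if _MISSING_CELL.match(cell):
        return None
    if cell.lower() == "non":
        return DID_NOT_HEAD
    m = re.match(r"^(\d{1,2})\s+([A-Za-z]{3})$", cell)
    if not m or m.group(2).capitalize() not in _MONTHS:
        raise ValueError(f"unparseable heading date: {cell!r}")
    return _dt.date(year, _MONTHS[m.group(2).capitalize()], int(m.group(1)))


_CODE_TOKEN = re.compile(r"^(F|R|N|M[1-5])(?:/([1-5]))?$")


def _parse_code(token: str) -> tuple[AlleleCode, list[str]]:
    """Parse a code cell.  'M2/3' denotes one allele carrying both the MITE2
    and MITE3 elements in tandem; the primary code is M2 with a note."""
    m = _CODE_TOKEN.match(token.strip())
    if not m:
        raise ValueError(f"unknown allele code token: {token!r}")
    code = AlleleCode(m.group(1))
    notes = []
    if m.group(2):
        if not m.group(1).startswith("M"):
            raise ValueError(f"unknown allele code token: {token!r}")
        notes.append(f"also MITE{m.group(2)}")
    return code, notes


_CODE_FUNCTIONAL = {
    AlleleCode.F: True, AlleleCode.R: True, AlleleCode.M5: True,
    AlleleCode.N: False, AlleleCode.M1: False, AlleleCode.M2: False,
    AlleleCode.M3: False, AlleleCode.M4: False,
}


def load_panel_table(path: str | PathLike | TextIO) -> PanelTable:
    """Load a TSV allele panel (one row per allele call) into a PanelTable.

    Heading cells: dashes are missing, ``non`` is the did-not-head sentinel.
    An allele printed as R but annotated ``footprint+LOF`` (a footprint with an
    additional loss-of-function mutation) is normalised to code N,
    functional=False.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in _PANEL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"panel table missing columns: {missing}")

    accessions: list[AccessionMeta] = []
    calls: list[AlleleRecord] = []
    counter: dict[str, int] = {}
    seen: dict[str, AccessionMeta] = {}
    for row in df.itertuples(index=False):
        acc_id = row.accession_id
        if acc_id not in seen:
            heading = {
                2012: _parse_heading(row.heading_2012, 2012),
                2014: _parse_heading(row.heading_2014, 2014),
            }
            meta = AccessionMeta(
                accession_id=acc_id,
                species=row.species,
                country=row.country,
                region=region_from_country(row.country),
                latitude=float(row.latitude) if row.latitude.strip() else None,
                longitude=float(row.longitude) if row.longitude.strip() else None,
                heading_date_by_year=heading,
            )
            seen[acc_id] = meta
            accessions.append(meta)
        code, notes = _parse_code(row.code)
        if row.note.strip():
            notes.append(row.note.strip())
        functional = _CODE_FUNCTIONAL[code]
        if "footprint+LOF" in notes:
            # a footprint with an additional loss-of-function mutation is not
            # a revertant: required code is N
            code, functional = AlleleCode.N, False
        counter[acc_id] = counter.get(acc_id, 0) + 1
        calls.append(
            AlleleRecord(
                allele_id=f"{acc_id}_a{counter[acc_id]}",
                accession_id=acc_id,
                locus=Locus(row.locus),
                code=code,
                functional=functional,
                notes=notes,
            )
        )
    return PanelTable(accessions=accessions, calls=calls)


def load_table1() -> PanelTable:
    """The packaged transcription of the published 44-accession panel table."""
    with resources.files("hd1panel.data").joinpath("table1.tsv").open() as fh:
        return load_panel_table(fh)


def write_panel_table(panel: PanelTable, path: str | PathLike) -> None:
    """Write a PanelTable back to the one-row-per-allele TSV layout."""
    rows = []
    for call in panel.calls:
        acc = panel.accession(call.accession_id)

        def fmt(year: int) -> str:
            v = acc.heading_date_by_year.get(year)
            if v is None:
                return "-"
            if v is DID_NOT_HEAD:
                return "non"
            return f"{v.day} {v.strftime('%b')}"

        rows.append({
            "accession_id": acc.accession_id,
            "species": acc.species,
            "country": acc.country,
            "latitude": "" if acc.latitude is None else acc.latitude,
            "longitude": "" if acc.longitude is None else acc.longitude,
            "locus": call.locus.value,
            "code": "" if call.code is None else call.code.value,
            "note": ";".join(call.notes),
            "heading_2012": fmt(2012),
            "heading_2014": fmt(2014),
        })
    pd.DataFrame(rows, columns=_PANEL_COLUMNS).to_csv(path, sep="\t", index=False)


def write_newick(tree, path: str | PathLike) -> None:
    """Serialise a PhyloTree to newick (lengths and support labels kept)."""
    with open(path, "w") as fh:
        fh.write(tree.to_newick() + "\n")
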