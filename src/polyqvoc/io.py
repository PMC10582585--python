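"""Reading and writing the formats the pipeline touches.

Protein ortholog panels arrive as FASTA; per-species phenotype compilations
(vocalization frequencies in kHz, cochlear ratios, body mass in g) arrive as
comma- or tab-delimited text.  FASTA headers carry the sequence id as the
first token and optional ``key=value`` tokens (``species=``, ``taxon=``); when
no species token is present the sequence id doubles as the species label.
"""

from __future__ import annotations

import io as _stdio
import logging
import math
import os
from dataclasses import dataclass, fields
from typing import Iterable, Optional

import pandas as pd
from Bio import SeqIO

from .errors import FormatError

logger = logging.getLogger("polyqvoc")

GENES = ("FOXP2", "FOXP1")

#: 20 canonical residues plus X for ambiguous positions.
VALID_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWYX")

CALL_TYPES = ("NE", "CF", "FM1", "FM2")


@dataclass(frozen=True)
class OrthologRecord:
    """One species' protein sequence with gene and taxon labels."""

    species_label: str
    gene: str
    sequence_id: str
    sequence: str
    taxon: Optional[str] = None

    def __post_init__(self):
        if self.gene not in GENES:
            raise ValueError(f"unknown gene {self.gene!r}; expected one of {GENES}")
        if not self.sequence:
            raise ValueError(f"record {self.sequence_id!r} has an empty sequence")


@dataclass(frozen=True)
class PhenotypeRecord:
    """Per-species vocalization/hearing/morphology/body-mass values.

    Missing values are ``None``, never zero; frequencies (kHz) and masses (g)
    must be strictly positive when present.
    """

    species_label: str
    call_type: Optional[str] = None
    collen_type_code: Optional[int] = None
    char_freq_khz: Optional[float] = None
    min_freq_khz: Optional[float] = None
    max_freq_khz: Optional[float] = None
    bandwidth_khz: Optional[float] = None
    cw_over_bw: Optional[float] = None
    cochlear_height_over_width: Optional[float] = None
    body_mass_g: Optional[float] = None
    max_audible_freq_khz: Optional[float] = None


#: numeric phenotype columns that must be strictly positive when present
_POSITIVE_COLUMNS = (
    "char_freq_khz",
    "min_freq_khz",
    "max_freq_khz",
    "bandwidth_khz",
    "cw_over_bw",
    "cochlear_height_over_width",
    "body_mass_g",
    "max_audible_freq_khz",
)

_SPECIES_COLUMNS = ("species", "species_label")


def _looks_like_path(path_or_text: str) -> bool:
    if "\n" in path_or_text or path_or_text.lstrip().startswith(">"):
        return False
    return os.path.exists(path_or_text)


def read_fasta(path_or_text: str, gene: str) -> list[OrthologRecord]:
    """Parse a protein FASTA into :class:`OrthologRecord` objects.

    ``path_or_text`` may be a filesystem path or the FASTA text itself.
    Sequences are uppercased and whitespace-stripped; entry order is kept.

    Raises
    ------
    FormatError
        If the input contains no FASTA entries, an entry has an empty body,
        an illegal residue occurs (the error names the record and position),
        or ``(species_label, sequence_id)`` pairs collide.
    """
    if _looks_like_path(path_or_text):
        with open(path_or_text) as fh:
            text = fh.read()
    else:
        text = path_or_text

    try:
        entries = list(SeqIO.parse(_stdio.StringIO(text), "fasta"))
    except ValueError as exc:
        raise FormatError(f"not FASTA-formatted input: {exc}") from exc
    if not entries:
        raise FormatError("input contains no FASTA entries")

    records: list[OrthologRecord] = []
    seen: set[tuple[str, str]] = set()
    for entry in entries:
        seq = str(entry.seq).upper().replace(" ", "").replace("\t", "")
        sequence_id = entry.id
        if not seq:
            raise FormatError(f"record {sequence_id!r} has an empty sequence")
        for pos, ch in enumerate(seq):
            if ch not in VALID_RESIDUES:
                raise FormatError(
                    f"illegal residue {ch!r} at position {pos} in record {sequence_id!r}"
                )
        species = sequence_id
        taxon = None
        for token in entry.description.split()[1:]:
            if "=" in token:
                key, _, value = token.partition("=")
                if key == "species":
                    species = value
                elif key == "taxon":
                    taxon = value
        key = (species, sequence_id)
        if key in seen:
            raise FormatError(f"duplicate (species, sequence_id) pair {key}")
        seen.add(key)
        records.append(
            OrthologRecord(
                species_label=species,
                gene=gene,
                sequence_id=sequence_id,
                sequence=seq,
                taxon=taxon,
            )
        )
    return records


def write_fasta(records: Iterable[OrthologRecord]) -> str:
    """Serialize records to FASTA text that :func:`read_fasta` round-trips."""
    chunks = []
    for rec in records:
        header = f">{rec.sequence_id} species={rec.species_label}"
        if rec.taxon is not None:
            header += f" taxon={rec.taxon}"
        body = "\n".join(
            rec.sequence[i : i + 60] for i in range(0, len(rec.sequence), 60)
        )
        chunks.append(f"{header}\n{body}\n")
    return "".join(chunks)


def read_phenotype_table(path_or_text: str) -> list[PhenotypeRecord]:
    """Read a delimited per-species phenotype table.

    The delimiter is auto-detected from the header line (tab if it contains a
    tab, else comma).  A ``species`` (or ``species_label``) column is
    required; any subset of the phenotype columns may be present.  Unknown
    columns are ignored with a logged warning; empty cells become missing
    values.  Non-numeric values in numeric columns raise :class:`FormatError`
    naming the row.
    """
    if _looks_like_path(path_or_text):
        with open(path_or_text) as fh:
            text = fh.read()
    else:
        text = path_or_text
    if not text.strip():
        raise FormatError("phenotype table is empty")

    header = text.splitlines()[0]
    sep = "\t" if "\t" in header else ","
    df = pd.read_csv(_stdio.StringIO(text), sep=sep, dtype=str)

    species_col = next((c for c in df.columns if c in _SPECIES_COLUMNS), None)
    if species_col is None:
        raise FormatError(
            f"no species column (expected one of {_SPECIES_COLUMNS}); got {list(df.columns)}"
        )

    known = {f.name for f in fields(PhenotypeRecord)} - {"species_label"}
    for col in df.columns:
        if col != species_col and col not in known:
            logger.warning("ignoring unknown phenotype column %r", col)

    records = []
    for row_number, (_, row) in enumerate(df.iterrows(), start=2):
        kwargs: dict = {"species_label": str(row[species_col]).strip()}
        for col in known:
            if col not in df.columns:
                continue
            raw = row[col]
            if raw is None or (isinstance(raw, float) and math.isnan(raw)):
                continue
            raw = str(raw).strip()
            if not raw:
                continue
            if col == "call_type":
                if raw not in CALL_TYPES:
                    raise FormatError(
                        f"row {row_number}: unknown call_type {raw!r}"
                    )
                kwargs[col] = raw
            elif col == "collen_type_code":
                try:
                    kwargs[col] = int(float(raw))
                except ValueError:
                    raise FormatError(
                        f"row {row_number}: non-numeric collen_type_code {raw!r}"
                    ) from None
            else:
                try:
                    value = float(raw)
                except ValueError:
                    raise FormatError(
                        f"row {row_number}: non-numeric value {raw!r} in column {col!r}"
                    ) from None
                if col in _POSITIVE_COLUMNS and value <= 0:
                    raise FormatError(
                        f"row {row_number}: column {col!r} must be strictly "
                        f"positive, got {value}"
                    )
                kwargs[col] = value
        records.append(PhenotypeRecord(**kwargs))
    return records


def phenotypes_to_frame(records: Iterable[PhenotypeRecord]) -> pd.DataFrame:
    """Tabulate phenotype records (missing values as NaN/None)."""
    return pd.DataFrame([vars(r) if not hasattr(r, "__dataclass_fields__")
                         else {f.name: getattr(r, f.name) for f in fields(r)}
                         for r in records])
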