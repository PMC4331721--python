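"""HLA allele reference panel: nomenclature parsing and indexing.

HLA alleles are named hierarchically, e.g. ``A*01:01:01:01``: the locus
(``A``) followed by up to four colon-separated fields.  The first field
is the serological group (2-digit resolution), the second the protein
(4-digit), the third synonymous coding differences (6-digit) and the
fourth non-coding differences (8-digit).  Typing "at d-digit resolution"
means comparing alleles after truncating their names to the first d/2
fields.  Expression suffixes (e.g. the ``N`` of null alleles) are kept
verbatim inside the field string and compared verbatim.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO

__all__ = [
    "AlleleName",
    "AlleleRecord",
    "AlleleDatabase",
    "parse_allele_name",
    "parse_allele_fasta",
    "truncate_resolution",
    "match_at_resolution",
]

_VALID_BASES = frozenset("ACGTN")
_RESOLUTIONS = (2, 4, 6, 8)


@dataclass(frozen=True)
class AlleleName:
    """A parsed HLA allele name such as ``DQB1*05:01:01:02``."""

    locus: str
    fields: tuple[str, ...]
    raw: str

    def __post_init__(self) -> None:
        if not self.locus:
            raise ValueError(f"allele name {self.raw!r}: empty locus")
        if not 1 <= len(self.fields) <= 4:
            raise ValueError(
                f"allele name {self.raw!r}: expected 1-4 fields, got {len(self.fields)}"
            )
        if any(not f for f in self.fields):
            raise ValueError(f"allele name {self.raw!r}: empty field")

    def __str__(self) -> str:
        return f"{self.locus}*{':'.join(self.fields)}"

    @property
    def resolution(self) -> int:
        """Digit resolution this name is specified to (2, 4, 6 or 8)."""
        return 2 * len(self.fields)


def parse_allele_name(token: str) -> AlleleName:
    """Parse an HLA nomenclature token (``locus*f1[:f2[:f3[:f4]]]``)."""
    token = token.strip()
    if token.count("*") != 1:
        raise ValueError(f"not an HLA allele name: {token!r}")
    locus, rest = token.split("*")
    # IMGT headers may carry an "HLA-" prefix on the locus.
    if locus.upper().startswith("HLA-"):
        locus = locus[4:]
    fields = tuple(rest.split(":"))
    return AlleleName(locus=locus, fields=fields, raw=token)


@dataclass(frozen=True)
class AlleleRecord:
    """One reference allele: its name and genomic DNA sequence."""

    name: AlleleName
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"allele {self.name}: empty sequence")
        bad = set(self.sequence) - _VALID_BASES
        if bad:
            raise ValueError(
                f"allele {self.name}: invalid sequence characters {sorted(bad)}"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class AlleleDatabase:
    """Indexed panel of HLA allele reference sequences.

    ``records[t]`` is the allele with index ``t``; ``by_locus`` maps each
    locus to the record indices it contains.
    """

    records: list[AlleleRecord]
    by_locus: dict[str, list[int]] = field(init=False)
    _by_name: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.by_locus = {}
        self._by_name = {}
        for t, rec in enumerate(self.records):
            key = str(rec.name)
            if key in self._by_name:
                raise ValueError(f"duplicate allele name in panel: {key}")
            self._by_name[key] = t
            self.by_locus.setdefault(rec.name.locus, []).append(t)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def n_alleles(self) -> int:
        return len(self.records)

    @property
    def loci(self) -> list[str]:
        return list(self.by_locus)

    def index_of(self, name: str | AlleleName) -> int:
        key = str(name) if isinstance(name, AlleleName) else str(parse_allele_name(name))
        try:
            return self._by_name[key]
        except KeyError:
            raise KeyError(f"allele {key!r} not in panel") from None

    def resolve_reference(self, ref_name: str) -> int:
        """Map a SAM reference name to an allele index.

        Accepts a plain allele name or an IMGT-style header line
        (``HLA:HLA00001 A*01:01:01:01 3503 bp``) whose first ``*``-bearing
        token is the allele name.
        """
        for token in ref_name.split():
            if "*" in token:
                return self.index_of(str(parse_allele_name(token)))
        raise KeyError(f"no allele name found in reference {ref_name!r}")

    def lengths(self) -> list[int]:
        return [rec.length for rec in self.records]


def _extract_name(header: str) -> AlleleName:
    """First whitespace-delimited ``*``-bearing token of a FASTA header."""
    for token in header.split():
        if "*" in token:
            return parse_allele_name(token)
    raise ValueError(f"FASTA header has no parsable allele name: {header!r}")


def parse_allele_fasta(path: str | Path) -> AlleleDatabase:
    """Read an allele panel FASTA into an :class:`AlleleDatabase`.

    Headers may be bare allele names (``>A*01:01:01:01``) or IMGT-style
    (``>HLA:HLA00001 A*01:01:01:01 3503 bp``).  Sequences are uppercased;
    duplicate allele names raise.
    """
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.strip():
                if not line.startswith(">"):
                    raise ValueError(
                        f"{path}: malformed FASTA at line {lineno}: "
                        f"expected '>' header, got {line.strip()[:40]!r}"
                    )
                break
        else:
            raise ValueError(f"{path}: empty FASTA file")

    records: list[AlleleRecord] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        name = _extract_name(rec.description)
        records.append(AlleleRecord(name=name, sequence=str(rec.seq).upper()))
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    return AlleleDatabase(records=records)


def write_allele_fasta(db: AlleleDatabase, path: str | Path, width: int = 60) -> None:
    """Write a panel to FASTA with fixed line wrapping (byte-deterministic)."""
    with open(path, "w") as fh:
        for rec in db.records:
            fh.write(f">{rec.name}\n")
            for i in range(0, rec.length, width):
                fh.write(rec.sequence[i : i + width] + "\n")


def _check_digits(digits: int) -> int:
    if digits not in _RESOLUTIONS:
        raise ValueError(f"resolution must be one of {_RESOLUTIONS}, got {digits}")
    return digits // 2


def truncate_resolution(name: AlleleName, digits: int) -> tuple[AlleleName, bool]:
    """Truncate an allele name to ``digits``-digit resolution.

    Returns ``(truncated_name, under_resolved)``.  ``under_resolved`` is
    True when the name has fewer fields than the requested resolution, in
    which case it is returned unchanged.
    """
    n = _check_digits(digits)
    if len(name.fields) <= n:
        return name, len(name.fields) < n
    fields = name.fields[:n]
    return AlleleName(locus=name.locus, fields=fields, raw=f"{name.locus}*{':'.join(fields)}"), False


def match_at_resolution(a: AlleleName, b: AlleleName, digits: int) -> bool:
    """True iff two allele names agree at ``digits``-digit resolution.

    An under-resolved name (fewer fields than the resolution asks for)
    matches on the fields it has.
    """
    n = _check_digits(digits)
    if a.locus != b.locus:
        return False
    k = min(n, len(a.fields), len(b.fields))
    return a.fields[:k] == b.fields[:k]
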