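"""Restriction enzyme definitions.

An enzyme is a recognition sequence (IUPAC DNA) plus the position of the
top-strand cut within it (``cut_offset``).  TaqI, the workhorse 4-cutter of
this package, recognises TCGA and cuts T^CGA, i.e. ``cut_offset = 1``.

The built-in table (``data/enzymes.yaml``) covers representative 4-, 5- and
6-cutters; users can extend or override it with their own YAML file of the
same shape.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources

import yaml

# IUPAC nucleotide codes -> the concrete bases they stand for.  Note that a
# reference 'N' is *not* listed as a match target: an ambiguous genome base
# never satisfies a recognition sequence.
IUPAC_CODES: dict[str, str] = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


class EnzymeError(ValueError):
    """Invalid enzyme configuration (bad IUPAC code, cut offset, ...)."""


def iupac_complement(seq: str) -> str:
    """Reverse complement of an IUPAC DNA string."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class EnzymeSpec:
    """A type II restriction enzyme.

    Parameters
    ----------
    name
        Short enzyme name (e.g. ``"TaqI"``).
    recognition
        Recognition sequence in IUPAC DNA codes, top strand.
    cut_offset
        Number of recognition bases left of the top-strand cut
        (``0 <= cut_offset <= len(recognition)``); TaqI T^CGA is 1.
    """

    name: str
    recognition: str
    cut_offset: int

    def __post_init__(self) -> None:
        rec = self.recognition.upper()
        if not rec:
            raise EnzymeError(f"{self.name}: empty recognition sequence")
        bad = set(rec) - set(IUPAC_CODES)
        if bad:
            raise EnzymeError(
                f"{self.name}: invalid IUPAC code(s) {sorted(bad)} in {rec!r}"
            )
        if not 0 <= self.cut_offset <= len(rec):
            raise EnzymeError(
                f"{self.name}: cut_offset {self.cut_offset} outside recognition "
                f"sequence of length {len(rec)}"
            )
        object.__setattr__(self, "recognition", rec)

    @property
    def length(self) -> int:
        return len(self.recognition)

    @property
    def is_palindromic(self) -> bool:
        """True when the recognition sequence equals its reverse complement.

        A palindromic recognition matches identically on both strands, so a
        top-strand scan finds every site.
        """
        return iupac_complement(self.recognition) == self.recognition

    def regex(self) -> re.Pattern[str]:
        """Overlap-tolerant compiled pattern for the recognition sequence."""
        body = "".join(
            c if len(IUPAC_CODES[c]) == 1 else f"[{IUPAC_CODES[c]}]"
            for c in self.recognition
        )
        return re.compile(f"(?={body})")


def _load_table(stream) -> dict[str, EnzymeSpec]:
    raw = yaml.safe_load(stream) or {}
    table = {}
    for name, spec in raw.items():
        table[name] = EnzymeSpec(
            name=name,
            recognition=spec["recognition"],
            cut_offset=int(spec["cut_offset"]),
        )
    return table


def builtin_enzymes() -> dict[str, EnzymeSpec]:
    """The packaged enzyme table, keyed by name."""
    text = resources.files("ditagdel").joinpath("data/enzymes.yaml").read_text()
    return _load_table(text)


def load_enzymes(path: str | None = None) -> dict[str, EnzymeSpec]:
    """Built-in table, optionally merged with a user YAML file.

    User entries override built-ins of the same name.
    """
    table = builtin_enzymes()
    if path is not None:
        with open(path) as fh:
            table.update(_load_table(fh))
    return table


def get_enzyme(name: str, path: str | None = None) -> EnzymeSpec:
    table = load_enzymes(path)
    try:
        return table[name]
    except KeyError:
        raise EnzymeError(
            f"unknown enzyme {name!r}; known: {', '.join(sorted(table))}"
        ) from None
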