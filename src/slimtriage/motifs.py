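"""Fixed-length motif patterns and proteome scanning.

Short linear motifs (SLiMs) are defined in the ELM resource by regular
expressions over the 20 standard amino acids.  Only fixed-length classes are
supported: every consumed position is a literal, a character class
``[...]``/``[^...]``, or a wildcard (``.`` / ELM's ``x``).  Quantifiers and
alternation make the match length variable and are rejected.

Each position is typed *rigid* or *flexible*.  A position is flexible iff it
is written as a wildcard or as ``[^P]`` (anything but proline); every other
position constrains the residue set and is rigid.  This distinction drives
which substitution-matrix cells are consulted in the different triage cycles.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

from Bio import SeqIO

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
AA_SET = frozenset(AMINO_ACIDS)

__all__ = [
    "AMINO_ACIDS",
    "AA_SET",
    "PatternError",
    "PositionSpec",
    "MotifClass",
    "MotifMatch",
    "compile_motif_pattern",
    "scan_sequence",
    "scan_proteome",
    "read_proteome",
    "read_motif_classes",
]


class PatternError(ValueError):
    """Raised for patterns that are empty, variable-length, or malformed."""


@dataclass(frozen=True)
class PositionSpec:
    """One consumed position of a motif pattern.

    index is 1-based within the motif; allowed is the permitted residue set;
    kind is "rigid" or "flexible".
    """

    index: int
    allowed: frozenset[str]
    kind: str

    def __post_init__(self) -> None:
        if not self.allowed:
            raise PatternError(f"position {self.index}: empty residue set")
        if not self.allowed <= AA_SET:
            bad = "".join(sorted(self.allowed - AA_SET))
            raise PatternError(f"position {self.index}: non-standard residues {bad!r}")
        if self.kind not in ("rigid", "flexible"):
            raise ValueError(f"bad position kind {self.kind!r}")


@dataclass(frozen=True)
class MotifClass:
    """A compiled fixed-length motif class."""

    identifier: str
    elm_regex: str
    length: int
    positions: tuple[PositionSpec, ...]
    anchored_start: bool = False
    anchored_end: bool = False
    _compiled: re.Pattern = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.length <= 0 or self.length != len(self.positions):
            raise PatternError("length must be positive and match positions")
        body = "".join(_class_for(p) for p in self.positions)
        pat = ("^" if self.anchored_start else "") + f"(?=({body}))"
        object.__setattr__(self, "_compiled", re.compile(pat))

    @property
    def rigid_indices(self) -> tuple[int, ...]:
        return tuple(p.index for p in self.positions if p.kind == "rigid")

    @property
    def flexible_indices(self) -> tuple[int, ...]:
        return tuple(p.index for p in self.positions if p.kind == "flexible")

    def matches(self, fragment: str) -> bool:
        """True iff *fragment* (exactly motif-length) satisfies the pattern."""
        if len(fragment) != self.length:
            return False
        return all(c in p.allowed for c, p in zip(fragment, self.positions))


@dataclass(frozen=True)
class MotifMatch:
    """One occurrence of a motif class in a protein (1-based inclusive)."""

    protein_id: str
    motif_class: str
    start: int
    end: int
    sequence: str

    @property
    def key(self) -> str:
        return f"{self.protein_id}:{self.motif_class}:{self.start}-{self.end}"

    def motif_position(self, residue_index: int) -> int | None:
        """Map a 1-based protein residue index into the motif (1-based), or None."""
        if self.start <= residue_index <= self.end:
            return residue_index - self.start + 1
        return None


def _class_for(pos: PositionSpec) -> str:
    if pos.allowed == AA_SET:
        return f"[{AMINO_ACIDS}]"
    return "[" + "".join(sorted(pos.allowed)) + "]"


_TOKEN = re.compile(
    r"""(?P<anchor_start>\^)
      | (?P<anchor_end>\$)
      | (?P<wild>[.x])
      | \[(?P<neg>\^?)(?P<members>[A-Za-z]+)\]
      | (?P<literal>[A-Z])
      | (?P<bad>.)
    """,
    re.VERBOSE,
)

_VARIABLE_LENGTH = re.compile(r"[{}*+?|()]")


def compile_motif_pattern(elm_regex: str, identifier: str | None = None) -> MotifClass:
    """Compile an ELM-dialect pattern into a :class:`MotifClass`.

    Supported constructs: literals, ``[...]``, ``[^...]``, ``.`` (or ELM ``x``,
    normalized to ``.``), and the anchors ``^`` (pattern start) / ``$``
    (pattern end).  Anchors occupy no position.  Variable-length constructs
    raise :class:`PatternError`.
    """
    if not elm_regex:
        raise PatternError("empty pattern")
    if _VARIABLE_LENGTH.search(elm_regex):
        raise PatternError(
            f"unsupported variable-length construct in {elm_regex!r}: "
            "only fixed-length motif patterns are supported"
        )
    positions: list[PositionSpec] = []
    anchored_start = anchored_end = False
    idx = 0
    for i, m in enumerate(_TOKEN.finditer(elm_regex)):
        if m.group("anchor_start"):
            if m.start() != 0:
                raise PatternError("'^' allowed only at pattern start (or inside [^..])")
            anchored_start = True
            continue
        if m.group("anchor_end"):
            if m.end() != len(elm_regex):
                raise PatternError("'$' allowed only at pattern end")
            anchored_end = True
            continue
        idx += 1
        if m.group("wild"):
            positions.append(PositionSpec(idx, AA_SET, "flexible"))
        elif m.group("members") is not None:
            members = frozenset(m.group("members").upper())
            if m.group("neg"):
                allowed = AA_SET - members
                kind = "flexible" if members == {"P"} else "rigid"
                positions.append(PositionSpec(idx, allowed, kind))
            else:
                positions.append(PositionSpec(idx, members, "rigid"))
        elif m.group("literal"):
            positions.append(PositionSpec(idx, frozenset(m.group("literal")), "rigid"))
        else:
            raise PatternError(f"unexpected character {m.group('bad')!r} in {elm_regex!r}")
    if not positions:
        raise PatternError(f"pattern {elm_regex!r} consumes no positions")
    return MotifClass(
        identifier=identifier or elm_regex,
        elm_regex=elm_regex,
        length=len(positions),
        positions=tuple(positions),
        anchored_start=anchored_start,
        anchored_end=anchored_end,
    )


def scan_sequence(protein_id: str, sequence: str, motif: MotifClass) -> list[MotifMatch]:
    """All (possibly overlapping) occurrences of *motif* in *sequence*.

    Coordinates are 1-based inclusive; results are sorted by start.
    Non-standard letters in the sequence never match.
    """
    sequence = sequence.upper()
    out: list[MotifMatch] = []
    for m in motif._compiled.finditer(sequence):
        start0 = m.start()
        frag = m.group(1)
        if len(frag) != motif.length:
            continue  # truncated at sequence end
        if motif.anchored_end and start0 + motif.length != len(sequence):
            continue
        out.append(
            MotifMatch(
                protein_id=protein_id,
                motif_class=motif.identifier,
                start=start0 + 1,
                end=start0 + motif.length,
                sequence=frag,
            )
        )
    return out


def scan_proteome(
    proteome: Iterable[tuple[str, str]] | dict[str, str],
    motifs: Sequence[MotifClass],
    log: list[str] | None = None,
) -> list[MotifMatch]:
    """Scan every protein with every motif class: the Initial Set.

    *proteome* is (protein_id, sequence) pairs or a mapping.  Duplicate
    protein identifiers raise ``ValueError``.  Per-class match counts are
    appended to *log* when given.
    """
    if isinstance(proteome, dict):
        items = list(proteome.items())
    else:
        items = list(proteome)
    seen: set[str] = set()
    for pid, _ in items:
        if pid in seen:
            raise ValueError(f"duplicate protein identifier {pid!r}")
        seen.add(pid)
    matches: list[MotifMatch] = []
    for motif in motifs:
        n = 0
        for pid, seq in items:
            hits = scan_sequence(pid, seq, motif)
            n += len(hits)
            matches.extend(hits)
        if log is not None:
            log.append(f"{motif.identifier}: {n} matches")
    matches.sort(key=lambda m: (m.protein_id, m.motif_class, m.start))
    return matches


def read_proteome(path) -> dict[str, str]:
    """Read a FASTA proteome; UniProt-style ``db|ACC|NAME`` headers yield ACC."""
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        pid = rec.id.split("|")[1] if rec.id.count("|") >= 2 else rec.id
        if pid in out:
            raise ValueError(f"duplicate protein identifier {pid!r}")
        out[pid] = str(rec.seq).upper()
    return out


def read_motif_classes(path) -> list[MotifClass]:
    """Read a TSV of (elm_identifier, regex) into compiled motif classes."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"elm_identifier", "regex"} <= set(df.columns):
        raise ValueError("motif class table needs columns: elm_identifier, regex")
    return [
        compile_motif_pattern(row.regex, identifier=row.elm_identifier)
        for row in df.itertuples()
    ]


def _iter_windows(sequence: str, length: int) -> Iterator[tuple[int, str]]:
    for i in range(len(sequence) - length + 1):
        yield i + 1, sequence[i : i + length]
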