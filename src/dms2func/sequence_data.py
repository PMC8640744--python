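"""Variant notation, wild-type sequences, dataset I/O and distance utilities.

Variants are sets of amino-acid substitutions relative to a wild-type
reference, written in the conventional ``E19Q`` notation (wild-type letter,
1-based position, mutant letter).  Multi-mutants are comma-separated, e.g.
``E19Q,A24Y``; the empty string denotes the wild type itself.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional

import numpy as np
from Bio import SeqIO

from dms2func.alphabet import AA20, ALPHABET21, STOP

_SUB_RE = re.compile(r"^([A-Z])(\d+)([A-Z*])$")


class VariantError(ValueError):
    """Raised for malformed or inconsistent variant notation."""


@dataclass(frozen=True)
class WildType:
    """A wild-type reference sequence over the 20 standard amino acids."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if len(self.sequence) < 1:
            raise VariantError("wild-type sequence must be non-empty")
        bad = sorted({c for c in self.sequence if c not in AA20})
        if bad:
            raise VariantError(
                f"wild-type sequence contains non-standard letters: {bad}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True, order=True)
class Substitution:
    """A single amino-acid substitution: wild-type letter, 1-based position, mutant."""

    position: int
    wt_aa: str = field(compare=False)
    mut_aa: str

    def __post_init__(self) -> None:
        if self.wt_aa not in AA20:
            raise VariantError(f"invalid wild-type letter {self.wt_aa!r}")
        if self.mut_aa not in ALPHABET21:
            raise VariantError(f"invalid mutant letter {self.mut_aa!r}")
        if self.mut_aa == self.wt_aa:
            raise VariantError(
                f"substitution at position {self.position} does not change the letter"
            )
        if self.position < 1:
            raise VariantError(f"position {self.position} is not 1-based")

    def __str__(self) -> str:
        return f"{self.wt_aa}{self.position}{self.mut_aa}"


@dataclass(frozen=True)
class Variant:
    """A set of substitutions (possibly empty = wild type) with an optional score."""

    substitutions: frozenset[Substitution] = frozenset()
    score: Optional[float] = None

    def __post_init__(self) -> None:
        positions = [s.position for s in self.substitutions]
        if len(positions) != len(set(positions)):
            raise VariantError("two substitutions share a position")

    @property
    def n_mutations(self) -> int:
        return len(self.substitutions)

    def sorted_substitutions(self) -> list[Substitution]:
        return sorted(self.substitutions, key=lambda s: s.position)

    def to_string(self) -> str:
        """Canonical comma-separated notation, ascending position."""
        return ",".join(str(s) for s in self.sorted_substitutions())

    def with_score(self, score: float) -> "Variant":
        return Variant(self.substitutions, float(score))

    def mutated_positions(self) -> frozenset[int]:
        return frozenset(s.position for s in self.substitutions)

    def __str__(self) -> str:
        return self.to_string()


def parse_variant(text: str, wt: WildType, score: Optional[float] = None) -> Variant:
    """Parse a comma-separated substitution string against a wild type.

    The empty string (or whitespace) yields the wild-type variant.  Raises
    :class:`VariantError` on malformed codes, out-of-range positions,
    wild-type letter mismatches, or duplicated positions.
    """
    text = text.strip()
    if not text:
        return Variant(frozenset(), score)
    subs = []
    seen: set[int] = set()
    for code in text.split(","):
        code = code.strip()
        m = _SUB_RE.match(code)
        if not m:
            raise VariantError(f"malformed substitution code {code!r}")
        wt_aa, pos_s, mut_aa = m.groups()
        pos = int(pos_s)
        if not 1 <= pos <= len(wt):
            raise VariantError(
                f"position {pos} out of range for wild type of length {len(wt)}"
            )
        actual = wt.sequence[pos - 1]
        if wt_aa != actual:
            raise VariantError(
                f"wt mismatch at position {pos}: code says {wt_aa!r}, "
                f"wild type has {actual!r}"
            )
        if pos in seen:
            raise VariantError(f"duplicate position {pos} in variant {text!r}")
        seen.add(pos)
        if mut_aa == wt_aa:
            raise VariantError(f"substitution {code!r} does not change the letter")
        subs.append(Substitution(pos, wt_aa, mut_aa))
    return Variant(frozenset(subs), score)


def validate_variant(v: Variant, wt: WildType) -> None:
    """Raise VariantError unless every substitution matches the wild type."""
    for s in v.substitutions:
        if not 1 <= s.position <= len(wt):
            raise VariantError(f"position {s.position} out of range")
        if wt.sequence[s.position - 1] != s.wt_aa:
            raise VariantError(
                f"wt mismatch at position {s.position}: variant says {s.wt_aa!r}"
            )


def apply_variant(v: Variant, wt: WildType) -> str:
    """Return the full mutated sequence string."""
    validate_variant(v, wt)
    seq = list(wt.sequence)
    for s in v.substitutions:
        seq[s.position - 1] = s.mut_aa
    return "".join(seq)


def hamming_distance(a: str, b: str) -> int:
    """Number of positions at which two equal-length sequences differ."""
    if len(a) != len(b):
        raise ValueError(f"sequences have unequal lengths {len(a)} and {len(b)}")
    return sum(x != y for x, y in zip(a, b))


@dataclass
class DMSDataset:
    """An ordered collection of scored variants against one wild type."""

    wild_type: WildType
    variants: list[Variant]

    def __post_init__(self) -> None:
        for v in self.variants:
            validate_variant(v, self.wild_type)
            if v.score is not None and not np.isfinite(v.score):
                raise VariantError(f"non-finite score for variant {v}")

    def __len__(self) -> int:
        return len(self.variants)

    def __iter__(self) -> Iterator[Variant]:
        return iter(self.variants)

    def __getitem__(self, i):
        return self.variants[i]

    def scores(self) -> np.ndarray:
        return np.array(
            [np.nan if v.score is None else v.score for v in self.variants]
        )

    def subset(self, indices: Iterable[int]) -> "DMSDataset":
        return DMSDataset(self.wild_type, [self.variants[i] for i in indices])


def read_wild_type(path: str | Path) -> WildType:
    """Read a wild-type sequence from a single-record FASTA file."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) != 1:
        raise VariantError(f"expected exactly one FASTA record, found {len(records)}")
    rec = records[0]
    return WildType(id=rec.id, sequence=str(rec.seq).upper())


def write_wild_type(wt: WildType, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f">{wt.id}\n{wt.sequence}\n")


def read_dataset(path: str | Path, wt: WildType) -> DMSDataset:
    """Read a TSV with header columns ``variant`` and ``score``.

    Malformed rows raise VariantError annotated with the 1-based line number.
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        try:
            vcol = header.index("variant")
            scol = header.index("score")
        except ValueError as exc:
            raise VariantError(
                f"{path}: missing required column in header {header}"
            ) from exc
        variants = []
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != len(header):
                raise VariantError(
                    f"{path}:{lineno}: expected {len(header)} fields, got {len(fields)}"
                )
            try:
                score = float(fields[scol]) if fields[scol] != "" else None
                variants.append(parse_variant(fields[vcol], wt, score))
            except (ValueError, VariantError) as exc:
                raise VariantError(f"{path}:{lineno}: {exc}") from exc
    return DMSDataset(wt, variants)


def write_dataset(ds: DMSDataset, path: str | Path) -> None:
    """Write a dataset as TSV (columns ``variant``, ``score``); lossless round trip."""
    with open(path, "w") as fh:
        fh.write("variant\tscore\n")
        for v in ds.variants:
            score = "" if v.score is None else repr(v.score)
            fh.write(f"{v.to_string()}\t{score}\n")
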