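"""Missense variant sets in one-letter substitution notation (e.g. G215R)."""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import pandas as pd

from mlof.errors import ParseError

AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWY")

_VARIANT_RE = re.compile(r"^([A-Za-z])(\d+)([A-Za-z])$")


@dataclass(frozen=True, order=True)
class Variant:
    """A single amino-acid substitution on the reference sequence."""

    position: int
    wt_aa: str
    mut_aa: str

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"variant position must be >= 1: {self}")
        if self.wt_aa == self.mut_aa:
            raise ValueError(f"synonymous 'variant' not allowed: {self}")

    def __str__(self) -> str:
        return f"{self.wt_aa}{self.position}{self.mut_aa}"


def parse_variant(token: str) -> Variant:
    """Parse one-letter substitution notation (G215R).

    Three-letter notation (Gly215Arg) is rejected with a pointer to the
    expected format.
    """
    token = token.strip()
    m = _VARIANT_RE.match(token)
    if not m:
        hint = ""
        if re.match(r"^[A-Za-z]{3}\d+[A-Za-z]{3}$", token):
            hint = " (three-letter notation not accepted; use one-letter, e.g. G215R)"
        raise ParseError(f"malformed variant token {token!r}{hint}")
    wt, pos, mut = m.group(1).upper(), int(m.group(2)), m.group(3).upper()
    for aa in (wt, mut):
        if aa not in AA_ALPHABET:
            raise ParseError(f"unknown amino-acid letter {aa!r} in variant {token!r}")
    if wt == mut:
        raise ParseError(f"synonymous substitution {token!r} is not a missense variant")
    return Variant(pos, wt, mut)


@dataclass
class VariantSet:
    """The missense variants of one gene/phenotype, duplicates collapsed."""

    protein_id: str
    variants: list[Variant] = field(default_factory=list)
    label: str = ""

    def __post_init__(self) -> None:
        self.variants = sorted(set(self.variants))

    @classmethod
    def from_tokens(cls, protein_id: str, tokens, label: str = "") -> "VariantSet":
        if isinstance(tokens, str):
            tokens = [t for t in tokens.split(",") if t.strip()]
        tokens = list(tokens)
        if not tokens:
            raise ParseError("empty variant list")
        return cls(protein_id, [parse_variant(t) for t in tokens], label)

    @property
    def positions(self) -> set[int]:
        return {v.position for v in self.variants}

    def triples(self) -> set[tuple[int, str, str]]:
        return {(v.position, v.wt_aa, v.mut_aa) for v in self.variants}

    def __len__(self) -> int:
        return len(self.variants)


def read_variant_table(path: str) -> list[VariantSet]:
    """Read a delimited variant table into VariantSets grouped by (protein, label).

    Expected columns: protein_id, variant (one token, e.g. G215R), label
    (optional).  Separator is sniffed among tab/comma/whitespace.
    """
    df = pd.read_csv(path, sep=None, engine="python")
    required = {"protein_id", "variant"}
    if not required <= set(df.columns):
        raise ParseError(f"{path}: expected columns {sorted(required)}, got {list(df.columns)}")
    if "label" not in df.columns:
        df["label"] = ""
    df["label"] = df["label"].fillna("")
    out = []
    for (pid, label), grp in df.groupby(["protein_id", "label"], sort=True):
        out.append(VariantSet(pid, [parse_variant(t) for t in grp["variant"]], str(label)))
    return out
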