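"""Per-protein ΔΔG landscapes and the mean ΔΔG_rank metric.

Predicted folding stability changes (ΔΔG, kcal/mol; FoldX-style output)
are consumed as tables, one value per amino-acid substitution.  Because
raw ΔΔG scales differ between proteins, values are rank-normalised within
each protein so that 0 is the mildest substitution in the structure and 1
the most damaging; a variant set is summarised by the mean of its
per-variant ranks (mean ΔΔG_rank).

The substitution universe is restricted to amino-acid changes reachable by
a single nucleotide change.  Two reachability modes are provided:
``"all"`` (default) considers every codon of the standard genetic code for
the wild-type amino acid, while ``"frequent"`` considers only the most
frequently used human codon per amino acid — a sensitivity-analysis mode,
since codon-usage restriction can only shrink the universe.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from Bio.Data.CodonTable import standard_dna_table

from mlof.errors import AlphabetError, DataError, ParseError
from mlof.variants import AA_ALPHABET, Variant, VariantSet, parse_variant

#: most frequently used human codon per amino acid (genomic codon-usage tables)
MOST_FREQUENT_HUMAN_CODON = {
    "A": "GCC", "R": "AGA", "N": "AAC", "D": "GAC", "C": "TGC",
    "Q": "CAG", "E": "GAG", "G": "GGC", "H": "CAC", "I": "ATC",
    "L": "CTG", "K": "AAG", "M": "ATG", "F": "TTC", "P": "CCC",
    "S": "AGC", "T": "ACC", "W": "TGG", "Y": "TAC", "V": "GTG",
}

_BASES = "ACGT"


def _codons_for(aa: str, mode: str) -> list[str]:
    if aa not in AA_ALPHABET:
        raise AlphabetError(f"unknown amino-acid letter {aa!r}")
    if mode == "frequent":
        return [MOST_FREQUENT_HUMAN_CODON[aa]]
    if mode != "all":
        raise ValueError(f"unknown codon mode {mode!r}")
    return [c for c, a in standard_dna_table.forward_table.items() if a == aa]


def single_nucleotide_neighbours(aa: str, mode: str = "all") -> set[str]:
    """Amino acids reachable from ``aa`` by one nucleotide change.

    Stop gains and the synonymous identity are excluded.
    """
    fwd = standard_dna_table.forward_table
    out: set[str] = set()
    for codon in _codons_for(aa, mode):
        for i, b in product(range(3), _BASES):
            if codon[i] == b:
                continue
            mutant = codon[:i] + b + codon[i + 1:]
            target = fwd.get(mutant)  # None for stop codons
            if target is not None and target != aa:
                out.add(target)
    return out


def substitution_universe(sequence: str, mode: str = "all") -> set[tuple[int, str, str]]:
    """All (position, wt, mut) substitutions one nucleotide change away.

    Positions are 1-based along ``sequence``; an ``X`` placeholder (gap in
    a fragment reconstruction) yields no substitutions.
    """
    universe: set[tuple[int, str, str]] = set()
    neighbour_cache: dict[str, set[str]] = {}
    for pos, aa in enumerate(sequence, start=1):
        if aa == "X":
            continue
        if aa not in neighbour_cache:
            neighbour_cache[aa] = single_nucleotide_neighbours(aa, mode)
        for mut in neighbour_cache[aa]:
            universe.add((pos, aa, mut))
    return universe


@dataclass
class DdgTable:
    """Per-protein ΔΔG values, one entry per substitution (and fragment)."""

    protein_id: str
    entries: pd.DataFrame  # columns: position, wt_aa, mut_aa, ddg, fragment_id[, rank]
    universe_tag: str = "single-nucleotide"

    REQUIRED = ("position", "wt_aa", "mut_aa", "ddg", "fragment_id")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.entries.columns]
        if missing:
            raise ValueError(f"DdgTable missing columns {missing}")
        if not np.isfinite(self.entries["ddg"]).all():
            raise ValueError("non-finite ddg values")
        dup = self.entries.duplicated(subset=["position", "wt_aa", "mut_aa", "fragment_id"])
        if dup.any():
            raise ValueError("duplicate (position, wt, mut, fragment) entries")

    @property
    def ranked(self) -> bool:
        return "rank" in self.entries.columns

    def __len__(self) -> int:
        return len(self.entries)


@dataclass(frozen=True)
class DdgRankResult:
    mean_rank: float
    n_variants: int
    dropped: tuple[str, ...] = field(default_factory=tuple)


def merge_fragments(tables: list[DdgTable]) -> DdgTable:
    """Collapse per-fragment tables to one entry per substitution.

    A substitution present in several fragments takes the mean ΔΔG over
    the fragments carrying it.  Merging must precede rank normalisation.
    """
    if not tables:
        raise ValueError("no tables to merge")
    pids = {t.protein_id for t in tables}
    if len(pids) > 1:
        raise ValueError(f"tables span multiple proteins: {sorted(pids)}")
    df = pd.concat([t.entries[list(DdgTable.REQUIRED)] for t in tables], ignore_index=True)
    merged = (
        df.groupby(["position", "wt_aa", "mut_aa"], as_index=False)["ddg"]
        .mean()
        .assign(fragment_id=0)  # 0 marks the merged pseudo-fragment
        .sort_values(["position", "wt_aa", "mut_aa"], ignore_index=True)
    )
    return DdgTable(tables[0].protein_id, merged, tables[0].universe_tag)


def rank_normalise(table: DdgTable) -> DdgTable:
    """Add a ``rank`` column: (r-1)/(m-1) with mean ranks for ties.

    0 is the mildest substitution in the protein, 1 the most damaging.
    """
    m = len(table)
    if m < 2:
        raise DataError(f"{table.protein_id}: cannot rescale ranks with {m} entry")
    r = rankdata(table.entries["ddg"].to_numpy(), method="average")
    out = table.entries.copy()
    out["rank"] = (r - 1.0) / (m - 1.0)
    return DdgTable(table.protein_id, out, table.universe_tag)


def mean_ddg_rank(table: DdgTable, variants: VariantSet) -> DdgRankResult:
    """Mean ΔΔG_rank over a variant set.

    Variants absent from the table's substitution universe are dropped
    (reported in ``dropped``) and do not count toward ``n_variants``.
    """
    if not table.ranked:
        raise ValueError("table must be rank-normalised first (rank_normalise)")
    idx = {
        (int(p), w, m): rk
        for p, w, m, rk in zip(
            table.entries["position"], table.entries["wt_aa"],
            table.entries["mut_aa"], table.entries["rank"],
        )
    }
    ranks, dropped = [], []
    for v in variants.variants:
        key = (v.position, v.wt_aa, v.mut_aa)
        if key in idx:
            ranks.append(idx[key])
        else:
            dropped.append(str(v))
    if not ranks:
        raise DataError(
            f"{table.protein_id}: none of the {len(variants)} variants resolvable in the ΔΔG table"
        )
    return DdgRankResult(float(np.mean(ranks)), len(ranks), tuple(dropped))


def read_ddg_table(path: str, protein_id: str | None = None) -> DdgTable:
    """Read a delimited ΔΔG table.

    Header columns: protein_id, position, wt_aa, mut_aa, ddg, fragment_id —
    or the substitution written as one token in a ``variant`` column
    (G215R).  fragment_id defaults to 1 when absent.
    """
    df = pd.read_csv(path, sep=None, engine="python")
    if "variant" in df.columns and not {"position", "wt_aa", "mut_aa"} <= set(df.columns):
        parsed = [parse_variant(t) for t in df["variant"]]
        df["position"] = [v.position for v in parsed]
        df["wt_aa"] = [v.wt_aa for v in parsed]
        df["mut_aa"] = [v.mut_aa for v in parsed]
    if "fragment_id" not in df.columns:
        df["fragment_id"] = 1
    missing = [c for c in DdgTable.REQUIRED if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    if protein_id is None:
        if "protein_id" not in df.columns or df["protein_id"].nunique() != 1:
            raise ParseError(f"{path}: supply protein_id or a single-protein table")
        protein_id = str(df["protein_id"].iloc[0])
    elif "protein_id" in df.columns:
        df = df[df["protein_id"] == protein_id]
        if df.empty:
            raise ParseError(f"{path}: no rows for protein {protein_id}")
    return DdgTable(protein_id, df[list(DdgTable.REQUIRED)].reset_index(drop=True))


def write_ddg_table(table: DdgTable, path: str) -> None:
    out = table.entries.copy()
    out.insert(0, "protein_id", table.protein_id)
    out.to_csv(path, sep="\t", index=False)
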