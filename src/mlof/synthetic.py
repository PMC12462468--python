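"""Seeded synthetic-data generators.

Every input format the pipeline consumes can be generated here
deterministically: toy CA-trace structures with controllable geometry and
pLDDT profiles, ΔΔG tables emulating the statistics of FoldX output,
LOF/non-LOF reference cohorts with class-separated EDC and mean ΔΔG_rank
distributions, multi-phenotype gene cohorts with planted hybrid status,
and toy ontologies with annotation corpora.

The cohort defaults encode the direction and rough degree of class
separation seen in real disease genes: LOF-mechanism genes carry
dispersed, destabilising variants (EDC near 1, high mean ΔΔG_rank) while
non-LOF genes carry clustered, mild variants (EDC above 1, low mean
ΔΔG_rank).  All generators are pure functions of their arguments plus the
seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from mlof.ddg import DdgTable, single_nucleotide_neighbours, substitution_universe
from mlof.phenotypes import Ontology, PhenotypeRecord
from mlof.structure import ResidueSite, StructureModel
from mlof.variants import Variant, VariantSet

_AAS = "ACDEFGHIKLMNPQRSTVWY"
CA_SPACING = 3.8  # Angstrom, consecutive CA-CA distance along a chain


# ---------------------------------------------------------------------------
# Structures
# ---------------------------------------------------------------------------

def _chain_coords(n: int, geometry: str, rng: np.random.Generator) -> np.ndarray:
    if geometry == "line":
        xyz = np.zeros((n, 3))
        xyz[:, 0] = np.arange(n) * CA_SPACING
        return xyz
    if geometry == "ring":
        radius = CA_SPACING / (2.0 * math.sin(math.pi / n))
        ang = 2.0 * math.pi * np.arange(n) / n
        return np.column_stack([radius * np.cos(ang), radius * np.sin(ang), np.zeros(n)])
    if geometry == "helix":
        # ideal alpha-helix CA parameters: 2.3 A radius, 1.5 A rise, 100 deg turn
        ang = np.deg2rad(100.0) * np.arange(n)
        return np.column_stack([2.3 * np.cos(ang), 2.3 * np.sin(ang), 1.5 * np.arange(n)])
    if geometry == "globule":
        radius = CA_SPACING * max(2.0, 0.8 * n ** (1.0 / 3.0) * 1.6)
        coords: list[np.ndarray] = []
        for _ in range(n):
            for _attempt in range(5000):
                p = rng.uniform(-radius, radius, 3)
                if np.linalg.norm(p) > radius:
                    continue
                if all(np.linalg.norm(p - q) >= CA_SPACING for q in coords):
                    coords.append(p)
                    break
            else:
                raise RuntimeError(f"globule packing failed at residue {len(coords) + 1}")
        return np.array(coords)
    raise ValueError(f"unknown geometry {geometry!r}")


def make_toy_structure(
    n_residues: int,
    geometry: str = "helix",
    plddt_profile=90.0,
    seed: int = 0,
    protein_id: str = "TOY",
    fragment_id: int = 1,
) -> StructureModel:
    """Generate a CA-trace model with a chosen geometry and pLDDT profile.

    ``plddt_profile`` is a scalar (constant), a length-n sequence, or
    ``("noisy", mean, sd)`` for seeded Gaussian noise clipped to [0, 100].
    """
    if n_residues < 4:
        raise ValueError("need n_residues >= 4")
    rng = np.random.default_rng(seed)
    coords = _chain_coords(n_residues, geometry, rng)
    if np.isscalar(plddt_profile):
        plddt = np.full(n_residues, float(plddt_profile))
    elif isinstance(plddt_profile, tuple) and plddt_profile and plddt_profile[0] == "noisy":
        _, mean, sd = plddt_profile
        plddt = np.clip(rng.normal(mean, sd, n_residues), 0.0, 100.0)
    else:
        plddt = np.asarray(plddt_profile, dtype=float)
        if plddt.shape != (n_residues,):
            raise ValueError("pLDDT profile length mismatch")
    seq = "".join(rng.choice(list(_AAS), n_residues))
    residues = [
        ResidueSite(i + 1, seq[i], tuple(np.round(coords[i], 3)), float(plddt[i]))
        for i in range(n_residues)
    ]
    return StructureModel(protein_id, residues, fragment_id=fragment_id, sequence=seq)


def make_clustered_variants(
    model: StructureModel,
    n_positions: int,
    clustering: float,
    seed: int = 0,
    label: str = "",
    mode: str = "spatial",
) -> VariantSet:
    """Plant variant positions with tunable spatial clustering.

    ``clustering`` in [0, 1]: 0 spreads the positions over the whole
    structure, 1 concentrates them maximally.  Two constructions:

    * ``"spatial"`` — the candidate pool is the residues nearest a seeded
      focal residue, shrinking with the parameter; picks are spread evenly
      through the pool.  Works on any geometry and concentrates positions
      in a contracting ball, but the discrete re-assignment of picks can
      wiggle EDC by a few hundredths between adjacent parameter values.
    * ``"stride"`` — deterministic chain-index picks ``{0, s, 2s, ...}``
      with the stride shrinking from even coverage down to 3 (so every
      disease residue keeps a non-disease neighbour).  On chain geometries
      (line) this makes EDC provably non-decreasing in the parameter: the
      far-tail distances grow linearly with each stride step while the
      within-gap distances shrink sublinearly.

    Mutant amino acids are drawn (seeded) from the single-nucleotide
    neighbourhood of the wild type.
    """
    if not 0.0 <= clustering <= 1.0:
        raise ValueError("clustering must be in [0, 1]")
    rng = np.random.default_rng(seed)
    n = len(model)
    if n_positions > n:
        raise ValueError("more positions than residues")
    if mode == "stride":
        if 3 * (n_positions - 1) >= n:
            raise ValueError("stride mode needs n_residues > 3*(n_positions-1)")
        smax = max(3, int((n - 1) / (n_positions - 0.5)))
        s = 3 + round((1.0 - clustering) * (smax - 3))
        picks = np.arange(n_positions) * s
    elif mode == "spatial":
        coords = np.array([r.ca_xyz for r in model.residues])
        focal = int(rng.integers(0, n))
        order = np.argsort(np.linalg.norm(coords - coords[focal], axis=1), kind="stable")
        pool_size = int(round(n_positions + (1.0 - clustering) * (n - n_positions)))
        pool = order[:pool_size]
        picks = pool[np.linspace(0, pool_size - 1, n_positions).round().astype(int)]
    else:
        raise ValueError(f"unknown mode {mode!r}")
    variants = []
    for idx in sorted(set(int(i) for i in picks)):
        site = model.residues[idx]
        # mutants drawn from the single-nucleotide neighbourhood so the
        # planted variants resolve in generated ΔΔG tables
        reachable = sorted(single_nucleotide_neighbours(site.aa))
        mut = rng.choice(reachable)
        variants.append(Variant(site.position, site.aa, str(mut)))
    return VariantSet(model.protein_id, variants, label)


# ---------------------------------------------------------------------------
# ΔΔG tables
# ---------------------------------------------------------------------------

def make_ddg_table(
    model: StructureModel,
    effect: str = "lof_like",
    seed: int = 0,
    pathogenic_positions=(),
) -> DdgTable:
    """Synthetic per-protein ΔΔG table over the full single-nucleotide universe.

    ``lof_like`` draws strongly destabilising values (high ΔΔG) at the
    designated pathogenic positions against a mild background;
    ``nonlof_like`` draws mild values everywhere, slightly milder still at
    the pathogenic positions (functional-site variants barely perturb
    stability).
    """
    if effect not in ("lof_like", "nonlof_like"):
        raise ValueError(f"unknown effect {effect!r}")
    rng = np.random.default_rng(seed)
    pathogenic = set(pathogenic_positions)
    rows = []
    for pos, wt, mut in sorted(substitution_universe(model.sequence)):
        if effect == "lof_like" and pos in pathogenic:
            ddg = rng.normal(3.0, 1.0)
        elif effect == "lof_like":
            ddg = rng.normal(0.8, 0.9)
        elif pos in pathogenic:
            ddg = rng.normal(0.2, 0.4)
        else:
            ddg = rng.normal(0.8, 0.9)
        rows.append((pos, wt, mut, float(ddg), model.fragment_id))
    df = pd.DataFrame(rows, columns=["position", "wt_aa", "mut_aa", "ddg", "fragment_id"])
    return DdgTable(model.protein_id, df)


# ---------------------------------------------------------------------------
# Reference cohorts
# ---------------------------------------------------------------------------

@dataclass
class CohortSpec:
    """Parameters of a synthetic LOF / non-LOF reference cohort.

    EDC values are normal per class, mean ΔΔG_rank values beta per class;
    the defaults separate the classes in the directions seen in disease
    genes (LOF: EDC near 1 and high ΔΔG rank; non-LOF: clustered variants,
    EDC ~1.25, low ΔΔG rank).
    """

    n_lof: int = 150
    n_nonlof: int = 150
    edc_params: dict = field(
        default_factory=lambda: {"LOF": (1.02, 0.10), "NONLOF": (1.25, 0.15)}
    )
    ddg_params: dict = field(
        default_factory=lambda: {"LOF": (6.0, 3.0), "NONLOF": (3.0, 6.0)}
    )
    n_variants_range: tuple[int, int] = (3, 25)
    sequence_length: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_lof < 1 or self.n_nonlof < 1:
            raise ValueError("class counts must be >= 1")


def make_cohort(spec: CohortSpec) -> tuple[pd.DataFrame, dict[str, VariantSet]]:
    """Draw a labelled per-gene (EDC, mean ΔΔG_rank) table plus variant sets.

    Returns a DataFrame with columns gene, class, edc, mean_ddg_rank,
    n_variants and a dict of per-gene VariantSets (ground-truth labels are
    the ``class`` column).
    """
    rng = np.random.default_rng(spec.seed)
    rows = []
    variant_sets: dict[str, VariantSet] = {}
    lo, hi = spec.n_variants_range
    for cls, count in (("LOF", spec.n_lof), ("NONLOF", spec.n_nonlof)):
        loc, scale = spec.edc_params[cls]
        a, b = spec.ddg_params[cls]
        for i in range(count):
            gene = f"{cls}{i + 1:04d}"
            edc = float(np.clip(rng.normal(loc, scale), 0.1, None))
            ddg = float(rng.beta(a, b))
            n_var = int(rng.integers(lo, hi + 1))
            positions = rng.choice(spec.sequence_length, size=n_var, replace=False) + 1
            variants = []
            for pos in sorted(int(p) for p in positions):
                wt, mut = rng.choice(list(_AAS), 2, replace=False)
                variants.append(Variant(pos, str(wt), str(mut)))
            variant_sets[gene] = VariantSet(gene, variants, label=cls)
            rows.append((gene, cls, edc, ddg, n_var))
    df = pd.DataFrame(rows, columns=["gene", "class", "edc", "mean_ddg_rank", "n_variants"])
    return df, variant_sets


def make_hybrid_cohort(
    n_genes: int,
    hybrid_fraction: float,
    threshold: float,
    seed: int = 0,
    phenotypes_per_gene: tuple[int, int] = (2, 4),
) -> tuple[list[PhenotypeRecord], dict[str, bool]]:
    """Multi-phenotype genes with planted hybrid status.

    A hybrid gene gets at least one phenotype scored on each side of the
    threshold; a non-hybrid gene gets all phenotypes on one side.  Returns
    the phenotype records (mlof filled in) and the ground-truth map.
    """
    rng = np.random.default_rng(seed)
    records: list[PhenotypeRecord] = []
    truth: dict[str, bool] = {}
    margin = 0.05
    for i in range(n_genes):
        gene = f"G{i + 1:04d}"
        is_hybrid = bool(rng.random() < hybrid_fraction)
        k = int(rng.integers(*phenotypes_per_gene))
        k = max(k, 2)
        if is_hybrid:
            sides = [True, False] + [bool(rng.random() < 0.5) for _ in range(k - 2)]
        else:
            side = bool(rng.random() < 0.5)
            sides = [side] * k
        rng.shuffle(sides)
        for j, above in enumerate(sides):
            if above:
                score = float(rng.uniform(threshold + margin, min(1.0, threshold + 0.4)))
            else:
                score = float(rng.uniform(max(0.0, threshold - 0.4), threshold - margin))
            records.append(
                PhenotypeRecord(
                    phenotype_id=f"{gene}.P{j + 1}",
                    gene=gene,
                    hpo_inheritance=frozenset({"AD"}),
                    gene_omim_inheritance=frozenset({"AD"}),
                    mlof=score,
                )
            )
        truth[gene] = is_hybrid
    return records, truth


# ---------------------------------------------------------------------------
# Ontologies
# ---------------------------------------------------------------------------

def make_toy_ontology(
    depth: int = 3,
    branching: int = 2,
    n_phenotypes: int = 6,
    seed: int = 0,
) -> tuple[Ontology, nx.DiGraph, dict[str, set[str]]]:
    """A rooted is_a tree with a random phenotype annotation corpus.

    Returns the Ontology plus the raw graph and annotations (for writing
    to OBO and re-reading).
    """
    if depth < 2:
        raise ValueError("depth must be >= 2")
    rng = np.random.default_rng(seed)
    g = nx.DiGraph()
    root = "T:0001"
    g.add_node(root, name="root")
    counter = 1
    level = [root]
    for _d in range(depth - 1):
        nxt = []
        for parent in level:
            for _b in range(branching):
                counter += 1
                term = f"T:{counter:04d}"
                g.add_node(term, name=f"term {counter}")
                g.add_edge(term, parent)  # child -> parent
                nxt.append(term)
        level = nxt
    non_root = [t for t in g.nodes if t != root]
    annotations: dict[str, set[str]] = {}
    for i in range(n_phenotypes):
        k = int(rng.integers(1, 4))
        terms = rng.choice(non_root, size=min(k, len(non_root)), replace=False)
        annotations[f"P:{i + 1:04d}"] = {str(t) for t in terms}
    return Ontology(g, annotations), g, annotations


def write_obo(graph: nx.DiGraph, path: str) -> None:
    """Write a child->parent is_a DiGraph as a minimal OBO file."""
    with open(path, "w") as fh:
        fh.write("format-version: 1.2\n\n")
        for node in sorted(graph.nodes):
            fh.write("[Term]\n")
            fh.write(f"id: {node}\n")
            fh.write(f"name: {graph.nodes[node].get('name', node)}\n")
            for _child, parent in sorted(graph.out_edges(node)):
                fh.write(f"is_a: {parent}\n")
            fh.write("\n")
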