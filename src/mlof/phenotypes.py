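"""Phenotype-level analyses.

Disease phenotypes are classified by inheritance (using gene-level OMIM
inheritance and phenotype-level HPO annotations) and, for dominant
phenotypes, by reported molecular mechanism.  On top of per-phenotype
mLOF scores this module estimates mechanism composition with credible
intervals, the fraction of "hybrid" genes accommodating both LOF and
non-LOF mechanisms, ranks the most mechanistically divergent phenotype
pairs within multi-phenotype genes, and prioritises candidate
dominant-negative phenotypes among AD-AR pairs using ontology semantic
similarity (Lin).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import obonet

from mlof.bayes import PosteriorRecord, PriorRecord, posterior
from mlof.errors import DataError
from mlof.evaluation import set_relationship
from mlof.variants import VariantSet

#: phenotype classes, inheritance-based then mechanism-based
INHERITANCE_CLASSES = ("AR", "AR_of_mixed", "AD_of_mixed", "AD_AR_same", "XLR", "AD")
MECHANISM_CLASSES = ("LOF", "GOF", "DN", "Unknown")

#: minimum distinct missense positions for a phenotype to count as scored
MIN_POSITIONS = 3


@dataclass
class PhenotypeRecord:
    phenotype_id: str
    gene: str
    hpo_inheritance: frozenset = frozenset()          # subset of {AD, AR, XL, XLR}
    gene_omim_inheritance: frozenset = frozenset()    # subset of {AD, AR, XL}
    mechanism_label: str | None = None                # LOF / GOF / DN
    dosage_sufficient: bool = False
    variant_set: VariantSet | None = None
    mlof: float | None = None
    posteriors: PosteriorRecord | None = None

    def __post_init__(self) -> None:
        self.hpo_inheritance = frozenset(self.hpo_inheritance)
        self.gene_omim_inheritance = frozenset(self.gene_omim_inheritance)

    @property
    def n_positions(self) -> int:
        return len(self.variant_set.positions) if self.variant_set is not None else 0

    @property
    def sufficient_variants(self) -> bool:
        return self.n_positions >= MIN_POSITIONS


def _gene_is_mixed(gene_context: Sequence[PhenotypeRecord]) -> bool:
    """Gene has >=1 AD and >=1 AR phenotype, each with sufficient variants."""
    has_ad = any("AD" in r.hpo_inheritance and r.sufficient_variants for r in gene_context)
    has_ar = any("AR" in r.hpo_inheritance and r.sufficient_variants for r in gene_context)
    return has_ad and has_ar


def classify_inheritance(
    record: PhenotypeRecord, gene_context: Sequence[PhenotypeRecord]
) -> str | None:
    """Inheritance-based phenotype class.

    Rule precedence (the underlying definitions can overlap): X-linked
    genes are taken out first (XLR), then phenotypes annotated with both
    inheritance modes (AD_AR_same), then the mixed-inheritance gene rules,
    then the exclusive AR / AD rules.  Unclassifiable records return None.
    """
    gene_inh = record.gene_omim_inheritance
    pheno_inh = record.hpo_inheritance
    if "XL" in gene_inh or "XLR" in gene_inh:
        return "XLR"
    if {"AD", "AR"} <= pheno_inh:
        return "AD_AR_same"
    if _gene_is_mixed(gene_context):
        if "AR" in pheno_inh:
            return "AR_of_mixed"
        if "AD" in pheno_inh:
            return "AD_of_mixed"
        return None
    if gene_inh == {"AR"} and "AR" in pheno_inh:
        return "AR"
    if gene_inh == {"AD"} and "AD" in pheno_inh:
        return "AD"
    return None


def classify_mechanism(
    record: PhenotypeRecord, gene_context: Sequence[PhenotypeRecord]
) -> str | None:
    """Mechanism-based class of an AD phenotype.

    LOF requires a reported LOF mechanism or sufficient dosage-pathogenicity
    (haploinsufficiency) evidence and excludes DN/GOF-labelled genes; GOF
    and DN require the respective reported mechanism and exclude
    mixed-inheritance genes; Unknown covers AD phenotypes of exclusively AD
    genes without any reported mechanism.
    """
    if "AD" not in record.hpo_inheritance:
        return None
    label = record.mechanism_label
    mixed = _gene_is_mixed(gene_context)
    if (label == "LOF" or record.dosage_sufficient) and label not in ("DN", "GOF"):
        return "LOF"
    if label == "GOF" and not mixed:
        return "GOF"
    if label == "DN" and not mixed:
        return "DN"
    if label is None and record.gene_omim_inheritance == {"AD"} and not record.dosage_sufficient:
        return "Unknown"
    return None


# ---------------------------------------------------------------------------
# Composition and hybrid genes
# ---------------------------------------------------------------------------

def _argmax_mechanism(post: PosteriorRecord) -> str:
    scores = {"LOF": post.post_lof, "DN": post.post_dn, "GOF": post.post_gof}
    order = ("LOF", "DN", "GOF")
    return max(order, key=lambda m: (scores[m], -order.index(m)))


def mechanism_composition(
    records: Sequence[PhenotypeRecord],
    threshold_boot: Sequence[float] | None = None,
    level: float = 0.95,
    bootstrap_rule: str = "threshold",
) -> dict:
    """Fractions of predicted LOF/GOF/DN mechanisms with credible intervals.

    Point estimates assign each phenotype its argmax posterior mechanism.
    Credible intervals propagate the uncertainty of the optimal-threshold
    estimate: under each bootstrapped threshold t_b, a phenotype is called
    LOF when its mLOF score >= t_b and otherwise takes the better of its
    DN/GOF posteriors (``bootstrap_rule="threshold"``); with
    ``bootstrap_rule="argmax"`` the assignment ignores the threshold and
    the intervals degenerate to the point fractions.
    """
    recs = [r for r in records if r.posteriors is not None]
    if not recs:
        raise DataError("no phenotypes with posterior scores")
    n = len(recs)
    point = {m: 0.0 for m in ("LOF", "GOF", "DN")}
    for r in recs:
        point[_argmax_mechanism(r.posteriors)] += 1.0
    point = {m: c / n for m, c in point.items()}

    out = {m: {"fraction": point[m], "ci_low": point[m], "ci_high": point[m]} for m in point}
    if threshold_boot:
        alpha = (1.0 - level) / 2.0
        boot_fracs = {m: [] for m in point}
        for t_b in threshold_boot:
            counts = {m: 0.0 for m in point}
            for r in recs:
                if bootstrap_rule == "threshold" and r.mlof is not None:
                    if r.mlof >= t_b:
                        mech = "LOF"
                    else:
                        p = r.posteriors
                        mech = "DN" if p.post_dn >= p.post_gof else "GOF"
                else:
                    mech = _argmax_mechanism(r.posteriors)
                counts[mech] += 1.0
            for m in counts:
                boot_fracs[m].append(counts[m] / n)
        for m in point:
            lo, hi = np.quantile(boot_fracs[m], [alpha, 1.0 - alpha])
            out[m]["ci_low"], out[m]["ci_high"] = float(lo), float(hi)
    return out


def hybrid_gene_fraction(
    records: Sequence[PhenotypeRecord],
    threshold: float,
    threshold_boot: Sequence[float] | None = None,
    level: float = 0.95,
) -> dict:
    """Fraction of multi-phenotype genes straddling the mLOF threshold.

    A gene is hybrid when at least one of its phenotypes scores >= t and
    at least one < t, i.e. the gene accommodates both a LOF and a non-LOF
    mechanism.  The credible interval recomputes the fraction under each
    bootstrapped threshold estimate.
    """
    by_gene: dict[str, list[float]] = {}
    for r in records:
        if r.mlof is not None:
            by_gene.setdefault(r.gene, []).append(r.mlof)
    genes = {g: s for g, s in by_gene.items() if len(s) >= 2}
    if not genes:
        raise DataError("no multi-phenotype genes with scores")

    def frac(t: float) -> float:
        hyb = sum(
            1 for s in genes.values() if any(v >= t for v in s) and any(v < t for v in s)
        )
        return hyb / len(genes)

    out = {"fraction": frac(threshold), "n_genes": len(genes),
           "ci_low": frac(threshold), "ci_high": frac(threshold)}
    if threshold_boot:
        alpha = (1.0 - level) / 2.0
        fracs = [frac(t) for t in threshold_boot]
        lo, hi = np.quantile(fracs, [alpha, 1.0 - alpha])
        out["ci_low"], out["ci_high"] = float(lo), float(hi)
    return out


# ---------------------------------------------------------------------------
# Divergent pairs
# ---------------------------------------------------------------------------

@dataclass
class PairReport:
    gene: str
    phenotype_a: str
    phenotype_b: str
    mlof_a: float
    mlof_b: float
    relationship: str | None = None
    similarity: float | None = None
    flags: list[str] = field(default_factory=list)

    @property
    def delta(self) -> float:
        return abs(self.mlof_a - self.mlof_b)


def rank_divergent_pairs(
    records: Sequence[PhenotypeRecord],
    threshold: float,
    percentile: float = 95.0,
) -> list[PairReport]:
    """Rank within-gene phenotype pairs by mLOF difference.

    Genes with only recessive inheritance are excluded, as are pairs whose
    variant sets are identical or in a subset relation (their scores are
    not independent).  A pair is flagged ``divergent`` when its delta
    exceeds the given percentile of all pair deltas *and* one phenotype
    scores above and the other below the threshold.
    """
    by_gene: dict[str, list[PhenotypeRecord]] = {}
    for r in records:
        if r.mlof is not None:
            by_gene.setdefault(r.gene, []).append(r)

    pairs: list[PairReport] = []
    for gene, recs in sorted(by_gene.items()):
        if len(recs) < 2:
            continue
        if not any(
            "AD" in r.hpo_inheritance or "XL" in r.gene_omim_inheritance for r in recs
        ):
            continue  # only-recessive gene
        for a, b in itertools.combinations(sorted(recs, key=lambda r: r.phenotype_id), 2):
            rel = None
            if a.variant_set is not None and b.variant_set is not None:
                rel = set_relationship(a.variant_set, b.variant_set)
                if rel not in ("distinct", "intersect"):
                    continue
            pairs.append(
                PairReport(gene, a.phenotype_id, b.phenotype_id, a.mlof, b.mlof, rel)
            )
    if not pairs:
        return []
    deltas = np.array([p.delta for p in pairs])
    cut = float(np.percentile(deltas, percentile))
    for p in pairs:
        straddles = (min(p.mlof_a, p.mlof_b) < threshold) and (
            max(p.mlof_a, p.mlof_b) >= threshold
        )
        if straddles:
            p.flags.append("straddles_threshold")
        if p.delta > cut and straddles:
            p.flags.append("divergent")
    pairs.sort(key=lambda p: (-p.delta, p.gene, p.phenotype_a, p.phenotype_b))
    return pairs


# ---------------------------------------------------------------------------
# Ontology semantic similarity (Lin)
# ---------------------------------------------------------------------------

class Ontology:
    """A DAG of is_a term links with an annotation corpus and IC values.

    Information content of a term is -ln of the fraction of corpus
    phenotypes annotated to the term or any of its descendants; the root
    (annotated to everything, directly or by propagation) has IC 0.
    """

    def __init__(self, graph: nx.DiGraph, annotations: dict[str, set[str]]):
        # edges point child -> parent (obonet convention)
        if not nx.is_directed_acyclic_graph(graph):
            raise ValueError("ontology graph must be acyclic")
        self.graph = graph
        self.annotations = {p: set(ts) for p, ts in annotations.items()}
        self._anc_cache: dict[str, frozenset] = {}
        self.ic = self._compute_ic()

    @classmethod
    def from_obo(cls, path: str, annotations: dict[str, set[str]]) -> "Ontology":
        g = obonet.read_obo(path)
        is_a = nx.DiGraph()
        is_a.add_nodes_from(g.nodes)
        for child, parent, key in g.edges(keys=True):
            if key == "is_a":
                is_a.add_edge(child, parent)
        return cls(is_a, annotations)

    def ancestors(self, term: str) -> frozenset:
        """The term and all its is_a ancestors."""
        if term not in self.graph:
            raise KeyError(f"unknown ontology term {term!r}")
        if term not in self._anc_cache:
            self._anc_cache[term] = frozenset(nx.descendants(self.graph, term)) | {term}
        return self._anc_cache[term]

    def _compute_ic(self) -> dict[str, float]:
        n = len(self.annotations)
        counts: dict[str, int] = {}
        for terms in self.annotations.values():
            covered: set[str] = set()
            for t in terms:
                covered |= self.ancestors(t)
            for t in covered:
                counts[t] = counts.get(t, 0) + 1
        if n == 0:
            return {}
        return {t: -float(np.log(c / n)) for t, c in counts.items()}

    def term_ic(self, term: str) -> float:
        if term not in self.graph:
            raise KeyError(f"unknown ontology term {term!r}")
        if term not in self.ic:
            raise DataError(f"term {term!r} has no annotation frequency; IC undefined")
        return self.ic[term]


def lin_similarity(term_a: str, term_b: str, ontology: Ontology) -> float:
    """Lin similarity: 2*IC(MICA) / (IC(a) + IC(b)); 0 when both ICs are 0."""
    ic_a = ontology.term_ic(term_a)
    ic_b = ontology.term_ic(term_b)
    common = ontology.ancestors(term_a) & ontology.ancestors(term_b)
    mica_ic = max((ontology.ic.get(t, 0.0) for t in common), default=0.0)
    denom = ic_a + ic_b
    if denom == 0.0:
        return 0.0
    return 2.0 * mica_ic / denom


def phenotype_similarity(
    terms_a: Iterable[str], terms_b: Iterable[str], ontology: Ontology
) -> float:
    """Symmetric best-match-average of pairwise Lin similarities."""
    ta, tb = list(terms_a), list(terms_b)
    if not ta or not tb:
        raise DataError("phenotype term sets must be non-empty")
    sim = np.array([[lin_similarity(a, b, ontology) for b in tb] for a in ta])
    return float((sim.max(axis=1).mean() + sim.max(axis=0).mean()) / 2.0)


# ---------------------------------------------------------------------------
# DN prioritisation among AD-AR pairs
# ---------------------------------------------------------------------------

def prioritise_dn_pairs(
    pairs: Sequence[PairReport],
    threshold: float,
    priors: dict[str, PriorRecord],
    similarity_min: float = 0.5,
) -> list[PairReport]:
    """Prioritise dominant-negative candidates among AD-AR phenotype pairs.

    ``phenotype_a``/``mlof_a`` must be the dominant phenotype and
    ``phenotype_b``/``mlof_b`` the recessive one.  A pair is
    high-confidence non-LOF when the AD phenotype scores below the
    threshold and below the AR phenotype.  Retained genes must have a DN
    prior exceeding their GOF prior; one pair per gene (highest
    similarity); the final list keeps pairs with similarity >
    ``similarity_min``, sorted by descending similarity.
    """
    flagged: list[PairReport] = []
    for p in pairs:
        if p.mlof_a < threshold and p.mlof_a < p.mlof_b:
            if "high_confidence_nonlof" not in p.flags:
                p.flags.append("high_confidence_nonlof")
            flagged.append(p)
    kept = []
    for p in flagged:
        prior = priors.get(p.gene)
        if prior is None or not prior.p_dn > prior.p_gof:
            continue
        if p.similarity is None:
            continue
        kept.append(p)
    best: dict[str, PairReport] = {}
    for p in kept:
        cur = best.get(p.gene)
        if cur is None or p.similarity > cur.similarity:
            best[p.gene] = p
    out = [p for p in best.values() if p.similarity > similarity_min]
    out.sort(key=lambda p: (-p.similarity, p.gene))
    return out


def attach_posteriors(
    records: Sequence[PhenotypeRecord],
    priors: dict[str, PriorRecord],
) -> None:
    """Compute posteriors in place for records with a score and a prior."""
    for r in records:
        if r.mlof is None:
            continue
        prior = priors.get(r.gene)
        if prior is not None:
            r.posteriors = posterior(r.mlof, prior)
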