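"""Bayesian update of gene-level mechanism priors with the mLOF score.

Gene-level priors pDN, pGOF and pLOF (from an upstream proteome-scale
model) express how likely each mechanism is for pathogenic missense
variants in a gene, before any structural evidence.  They are three
independent binary probabilities, not a simplex.  The mLOF score acts as
the likelihood of LOF and is composed with each prior on the odds scale:

    post_LOF = m*p / (m*p + (1-m)*(1-p))            (m = mLOF, p = pLOF)
    post_DN  = (1-m)*q / ((1-m)*q + m*(1-q))        (q = pDN; pGOF alike)

so that logit(post_LOF) = logit(m) + logit(pLOF).  An uninformative score
(m = 0.5) returns the priors; an uninformative prior returns the score.

A ``literal`` compatibility mode reproduces a published typeset variant of
these update rules whose post_LOF algebraically collapses to the mLOF
score itself and whose post_GOF denominator mixes the DN prior into the
GOF update; it is retained only for comparison and is not the default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from mlof.errors import ParseError

#: mLOF threshold separating LOF-like from non-LOF-like variant sets,
#: derived from ROC analysis of dominant single-phenotype disease genes.
DEFAULT_THRESHOLD = 0.508

#: below this maximum prior, the gene is flagged as atypical for the
#: prior-generating model's training data.
DEFAULT_PRIOR_FLOOR = 0.2

MECHANISMS = ("LOF", "DN", "GOF")  # argmax tie-break order


@dataclass(frozen=True)
class PriorRecord:
    gene: str
    p_dn: float
    p_gof: float
    p_lof: float

    def __post_init__(self) -> None:
        for name in ("p_dn", "p_gof", "p_lof"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{self.gene}: prior {name}={v} outside [0, 1]")


@dataclass
class PosteriorRecord:
    post_dn: float
    post_gof: float
    post_lof: float
    suggested: str | None = None
    warnings: list[str] = field(default_factory=list)


def _odds_update(likelihood: float, prior: float) -> float:
    """p(mechanism | evidence) by composing odds; boundary cases by limits."""
    num = likelihood * prior
    den = num + (1.0 - likelihood) * (1.0 - prior)
    if den == 0.0:  # (likelihood, prior) at opposing certainties
        return prior
    return num / den


def posterior(mlof: float, prior: PriorRecord, literal: bool = False) -> PosteriorRecord:
    """Update the three mechanism priors with the mLOF score.

    With ``literal=True`` the typeset variant described in the module
    docstring is applied instead of the corrected odds form.
    """
    if not 0.0 <= mlof <= 1.0:
        raise ValueError(f"mlof={mlof} outside [0, 1]")
    if literal:
        return _posterior_literal(mlof, prior)
    return PosteriorRecord(
        post_dn=_odds_update(1.0 - mlof, prior.p_dn),
        post_gof=_odds_update(1.0 - mlof, prior.p_gof),
        post_lof=_odds_update(mlof, prior.p_lof),
    )


def _posterior_literal(m: float, prior: PriorRecord) -> PosteriorRecord:
    # postLOF denominator factors P_LOF out -> collapses to m wherever defined
    den_lof = m * prior.p_lof + (1.0 - m) * prior.p_lof
    post_lof = (m * prior.p_lof / den_lof) if den_lof else prior.p_lof
    den_gof = (1.0 - m) * prior.p_dn + m * (1.0 - prior.p_gof)  # DN prior in the GOF update
    post_gof = ((1.0 - m) * prior.p_gof / den_gof) if den_gof else prior.p_gof
    return PosteriorRecord(
        post_dn=_odds_update(1.0 - m, prior.p_dn),
        post_gof=post_gof,
        post_lof=post_lof,
    )


def suggest_mechanism(
    post: PosteriorRecord,
    mlof: float,
    prior: PriorRecord,
    threshold: float = DEFAULT_THRESHOLD,
    prior_floor: float = DEFAULT_PRIOR_FLOOR,
    extra_warnings: list[str] | None = None,
) -> PosteriorRecord:
    """Attach the suggested mechanism (argmax posterior) and warnings.

    Warning codes:

    * ``ALL_PRIORS_LOW`` — every prior falls below ``prior_floor``; the
      gene may have atypical features not represented in the prior
      model's training data.
    * ``DISCORDANT`` — the prior's favoured side (LOF vs non-LOF)
      contradicts the side of the threshold the mLOF score falls on.
    * ``DDG_ONLY`` — propagated by the caller when EDC was uncomputable
      and the score rests on the energetic component alone.
    """
    scores = {"LOF": post.post_lof, "DN": post.post_dn, "GOF": post.post_gof}
    suggested = max(MECHANISMS, key=lambda mech: (scores[mech], -MECHANISMS.index(mech)))

    warn = list(extra_warnings or [])
    priors = {"LOF": prior.p_lof, "DN": prior.p_dn, "GOF": prior.p_gof}
    if max(priors.values()) < prior_floor:
        warn.append("ALL_PRIORS_LOW")
    top_prior = max(MECHANISMS, key=lambda mech: (priors[mech], -MECHANISMS.index(mech)))
    prior_says_lof = top_prior == "LOF"
    score_says_lof = mlof >= threshold
    if prior_says_lof != score_says_lof:
        warn.append("DISCORDANT")
    return PosteriorRecord(
        post_dn=post.post_dn,
        post_gof=post.post_gof,
        post_lof=post.post_lof,
        suggested=suggested,
        warnings=warn,
    )


def read_prior_table(path: str) -> dict[str, PriorRecord]:
    """Read a delimited prior table with columns gene, pDN, pGOF, pLOF."""
    df = pd.read_csv(path, sep=None, engine="python")
    cols = {c.lower(): c for c in df.columns}
    try:
        gene_c, dn_c, gof_c, lof_c = cols["gene"], cols["pdn"], cols["pgof"], cols["plof"]
    except KeyError as exc:
        raise ParseError(f"{path}: expected columns gene, pDN, pGOF, pLOF") from exc
    out = {}
    for _, row in df.iterrows():
        rec = PriorRecord(str(row[gene_c]), float(row[dn_c]), float(row[gof_c]), float(row[lof_c]))
        out[rec.gene] = rec
    return out
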