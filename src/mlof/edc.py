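"""Extent of disease clustering (EDC).

EDC compares, over all confidently modelled residues of a protein, the
average distance to the nearest disease-variant position against the
average distance to the nearest non-disease residue:

    EDC = log10( mean_i  min_j d(i, disease_j) )
          -----------------------------------------
          log10( mean_i  min_k d(i, non-disease_k) )

with CA-CA Euclidean distances in Angstroms and a residue always excluded
from its own nearest-neighbour search.  When disease positions cluster
spatially, most residues sit far from the nearest disease position while
the non-disease set covers the whole structure, so EDC > 1; dispersed
disease positions give EDC near 1.

Residues below the pLDDT confidence floor (default 70) are removed before
any distance is measured: pathogenic missense variants concentrate in
structured regions, and a small structured core would otherwise make any
variant set look clustered relative to the full model volume.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from mlof.errors import (
    DegenerateGeometryError,
    EmptyStructureError,
    InsufficientPositionsError,
)
from mlof.structure import StructureModel
from mlof.variants import VariantSet


@dataclass(frozen=True)
class EdcResult:
    edc: float
    n_disease_positions: int
    n_residues_used: int


def compute_edc(
    model: StructureModel,
    variants: VariantSet,
    plddt_min: float = 70.0,
    min_positions: int = 3,
) -> EdcResult:
    """Compute EDC for a variant set on a structure model.

    Parameters
    ----------
    plddt_min : residues with pLDDT below this are dropped entirely.
    min_positions : minimum number of distinct, confidently modelled
        variant positions required (mirrors the >=3-position eligibility
        rule used throughout; 5 and 10 are stricter tiers).

    Raises
    ------
    InsufficientPositionsError
        if fewer than ``min_positions`` variant positions survive the
        confidence filter (energetic impact may still be computable).
    EmptyStructureError
        if the filter leaves no non-disease residue.
    DegenerateGeometryError
        if a mean nearest distance is <= 1 Angstrom (log ratio undefined).
    """
    kept = [r for r in model.residues if r.plddt >= plddt_min]
    if not kept:
        raise EmptyStructureError(
            f"{model.protein_id}: no residues with pLDDT >= {plddt_min}"
        )
    kept_positions = np.array([r.position for r in kept])
    coords = np.array([r.ca_xyz for r in kept], dtype=float)

    disease_mask = np.isin(kept_positions, sorted(variants.positions))
    n_disease = int(disease_mask.sum())
    if n_disease < min_positions:
        raise InsufficientPositionsError(
            f"{model.protein_id}: {n_disease} variant positions with "
            f"pLDDT >= {plddt_min}; need >= {min_positions}"
        )
    if disease_mask.all():
        raise EmptyStructureError(
            f"{model.protein_id}: no non-disease residues remain"
        )

    dmat = cdist(coords, coords)
    np.fill_diagonal(dmat, np.inf)  # self-exclusion in both searches

    d_dis = dmat[:, disease_mask].min(axis=1)
    d_non = dmat[:, ~disease_mask].min(axis=1)
    # a lone disease/non-disease residue paired only with itself yields inf;
    # guarded by min_positions >= 3 and the non-disease check above, but a
    # single non-disease residue can still self-pair:
    finite = np.isfinite(d_dis) & np.isfinite(d_non)
    d_dis, d_non = d_dis[finite], d_non[finite]
    if d_dis.size == 0:
        raise EmptyStructureError(f"{model.protein_id}: no residues usable for EDC")

    mean_dis = float(d_dis.mean())
    mean_non = float(d_non.mean())
    if mean_dis <= 1.0 or mean_non <= 1.0:
        raise DegenerateGeometryError(
            f"{model.protein_id}: mean nearest distance <= 1 A "
            f"(disease {mean_dis:.3f}, non-disease {mean_non:.3f})"
        )
    edc = float(np.log10(mean_dis) / np.log10(mean_non))
    return EdcResult(edc=edc, n_disease_positions=n_disease, n_residues_used=int(finite.sum()))
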