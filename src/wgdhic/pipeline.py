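"""End-to-end composition of the per-species and cross-species analyses."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .compartments import (CompartmentTrack, FeatureTrack, call_compartments,
                           compartment_fractions, feature_track_from_positions,
                           trans_compartment_preference)
from .hic_matrix import (ContactMatrix, DecayProfile, expected_by_distance,
                         ice_normalize, oe_normalize)
from .tads import TADSet, call_tads


@dataclass
class NormalizedStack:
    ice: ContactMatrix
    bias: np.ndarray
    decay: DecayProfile
    oe: ContactMatrix


def normalize_stack(M_raw: ContactMatrix, max_iter: int = 200, tol: float = 1e-5,
                    low_coverage_frac: float = 0.02) -> NormalizedStack:
    """raw -> ICE -> distance decay -> O/E."""
    ice, bias = ice_normalize(M_raw, max_iter=max_iter, tol=tol,
                              low_coverage_frac=low_coverage_frac)
    decay = expected_by_distance(ice)
    oe = oe_normalize(ice, decay)
    return NormalizedStack(ice=ice, bias=bias, decay=decay, oe=oe)


@dataclass
class SpeciesAnalysis:
    hi: NormalizedStack            # analysis resolution (TADs, paralogs)
    lo: NormalizedStack            # compartment resolution
    gene_density: FeatureTrack
    track: CompartmentTrack
    fractions: dict
    trans_preference: dict
    tads: TADSet


def analyze_species(matrix_hi: ContactMatrix, matrix_lo: ContactMatrix,
                    genes: pd.DataFrame, w: int = 5,
                    boundary_filter: str = "wilcoxon") -> SpeciesAnalysis:
    """Normalization, compartment calling and TAD calling for one species."""
    hi = normalize_stack(matrix_hi)
    lo = normalize_stack(matrix_lo)
    mid = pd.DataFrame({
        "chrom": genes["chrom"],
        "pos": (genes["start"] + genes["end"]) // 2,
    })
    gene_density = feature_track_from_positions(matrix_lo.bins, mid)
    track = call_compartments(lo.oe, gene_density)
    fractions = compartment_fractions(track)
    trans_pref = trans_compartment_preference(lo.ice, track)
    tads = call_tads(hi.ice, w=w, filter=boundary_filter)
    return SpeciesAnalysis(hi=hi, lo=lo, gene_density=gene_density, track=track,
                           fractions=fractions, trans_preference=trans_pref,
                           tads=tads)
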