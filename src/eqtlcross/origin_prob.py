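"""Breed-of-origin probabilities and the additive line-cross coefficient.

For an F2 from a cross of two breeds assumed fixed for alternative QTL
alleles, the expected additive genotype code at a scan position x is

    c_a(x) = P(DD at x) - P(PP at x)

where D/P denote Duroc/Pietrain origin of the two homologs.  Marker-level
origin probabilities come from exhaustive enumeration of F1 gamete phases
compatible with the three-generation genotypes; positions between markers
are interpolated per gamete by Markov conditioning on the nearest
informative flanking markers (interval-mapping convention), combining the
two gametes independently.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .maps import LinkageMap, recombination_fraction
from .synthetic_cross import GenotypeTable, Pedigree

__all__ = [
    "ScanGrid",
    "build_scan_grid",
    "OriginInference",
    "infer_marker_origins",
    "origin_probabilities_at",
    "additive_coefficient",
    "compute_ca_matrix",
    "F2_PRIOR",
]

logger = logging.getLogger(__name__)

#: Prior origin-state probabilities (DD, DP, PP) for an F2 individual.
F2_PRIOR = (0.25, 0.5, 0.25)

_INFORMATIVE_TOL = 1e-9


# ---------------------------------------------------------------------------
# Scan grid
# ---------------------------------------------------------------------------

@dataclass
class ScanGrid:
    """Ordered scan positions: every marker plus k equidistant positions
    strictly inside each adjacent marker interval."""

    positions: pd.DataFrame  # chromosome, cM, kind, left_marker, right_marker

    def __len__(self):
        return len(self.positions)

    def chromosome_positions(self, chrom) -> pd.DataFrame:
        return self.positions[self.positions["chromosome"] == chrom]


def build_scan_grid(lmap: LinkageMap, k_intermediate: int = 11) -> ScanGrid:
    """Build the putative-QTL position grid.

    A chromosome with m markers contributes m + k*(m-1) positions.
    """
    if k_intermediate < 0:
        raise ValueError("k_intermediate must be >= 0")
    rows = []
    for chrom in lmap.chromosomes:
        sub = lmap.chromosome_markers(chrom)
        ids = list(sub["marker"])
        pos = sub["cM"].to_numpy(float)
        for i, (mid, p) in enumerate(zip(ids, pos)):
            rows.append((chrom, float(p), "marker", mid, mid))
            if i + 1 < len(ids):
                left, right = p, pos[i + 1]
                step = (right - left) / (k_intermediate + 1)
                for j in range(1, k_intermediate + 1):
                    rows.append((chrom, float(left + j * step), "inter-marker",
                                 mid, ids[i + 1]))
    df = pd.DataFrame(rows, columns=["chromosome", "cM", "kind",
                                     "left_marker", "right_marker"])
    return ScanGrid(df)


# ---------------------------------------------------------------------------
# Marker-level origin inference (exhaustive enumeration)
# ---------------------------------------------------------------------------

def _transmit_prob(allele: int, parent_pair: tuple) -> float:
    """P(parent transmits `allele`) for an unphased parent genotype."""
    return (int(allele == parent_pair[0]) + int(allele == parent_pair[1])) / 2.0


def _ordered_pairs(pair: tuple):
    a, b = pair
    return [(a, b)] if a == b else [(a, b), (b, a)]


def _marker_origin_single(
    f2_pair: tuple,
    sire_pair: tuple, sire_f0: tuple, dam_f0_of_sire: tuple,
    dam_pair: tuple, sire_f0_of_dam: tuple, dam_f0_of_dam: tuple,
):
    """Enumerate phases/transmissions at one marker for one F2.

    Returns (triple (pDD,pDP,pPP), (pD_paternal, pD_maternal), consistent).
    The F1 parents' ordered genotypes put the Duroc-origin allele (from the
    F0 Duroc grandsire) first; phase weights come from F0 transmission
    probabilities, transmission of either F1 homolog has probability 1/2.
    """
    joint = np.zeros((2, 2))  # [paternal origin D=0/P=1, maternal origin]
    for g_s, g_d in _ordered_pairs(f2_pair):          # which F2 allele came from which parent
        for u_D, u_P in _ordered_pairs(sire_pair):     # sire-F1 phase
            w_s_phase = _transmit_prob(u_D, sire_f0) * _transmit_prob(u_P, dam_f0_of_sire)
            if w_s_phase == 0:
                continue
            for v_D, v_P in _ordered_pairs(dam_pair):  # dam-F1 phase
                w_d_phase = _transmit_prob(v_D, sire_f0_of_dam) * _transmit_prob(v_P, dam_f0_of_dam)
                if w_d_phase == 0:
                    continue
                for hs, allele_s in enumerate((u_D, u_P)):
                    if allele_s != g_s:
                        continue
                    for hd, allele_d in enumerate((v_D, v_P)):
                        if allele_d != g_d:
                            continue
                        joint[hs, hd] += w_s_phase * w_d_phase * 0.25
    total = joint.sum()
    if total <= 0:
        return np.array(F2_PRIOR), np.full((2, 2), 0.25), False
    joint /= total
    triple = np.array([joint[0, 0], joint[0, 1] + joint[1, 0], joint[1, 1]])
    return triple, joint, True


@dataclass
class OriginInference:
    """Per-F2, per-marker origin-state posteriors.

    triples[i, m] = (pDD, pDP, pPP); joints[i, m] is the 2x2 joint over
    (paternal, maternal) gamete origin (D first); flags mark Mendelian-
    inconsistent records that were reset to the F2 prior.
    """

    f2_ids: list
    lmap: LinkageMap
    triples: np.ndarray       # (n_f2, n_markers, 3)
    joints: np.ndarray        # (n_f2, n_markers, 2, 2)
    inconsistent: np.ndarray  # (n_f2, n_markers) bool

    @property
    def gamete_pD(self) -> np.ndarray:
        """Per-gamete marginal P(Duroc origin): (n_f2, n_markers, 2)."""
        return np.stack([self.joints.sum(axis=3)[..., 0],
                         self.joints.sum(axis=2)[..., 0]], axis=-1)

    def index_of(self, f2_id) -> int:
        return self.f2_ids.index(f2_id)


def infer_marker_origins(
    pedigree: Pedigree, genotypes: GenotypeTable, lmap: LinkageMap
) -> OriginInference:
    """Marker-by-marker origin probabilities for every F2.

    Fully informative markers yield degenerate triples; markers whose
    allele sets do not distinguish the breeds yield the F2 prior
    (1/4, 1/2, 1/4).  Mendelian inconsistencies are flagged, logged, and
    assigned the prior.
    """
    f2_ids = pedigree.f2_ids
    n_mark = lmap.n_markers
    triples = np.empty((len(f2_ids), n_mark, 3))
    joints = np.empty((len(f2_ids), n_mark, 2, 2))
    inconsistent = np.zeros((len(f2_ids), n_mark), dtype=bool)

    for i, f2 in enumerate(f2_ids):
        sire_f1, dam_f1 = pedigree.parents_of(f2)
        s_gf, s_gm = pedigree.parents_of(sire_f1)
        d_gf, d_gm = pedigree.parents_of(dam_f1)
        for m in range(n_mark):
            triple, joint, ok = _marker_origin_single(
                genotypes.alleles(f2, m),
                genotypes.alleles(sire_f1, m),
                genotypes.alleles(s_gf, m), genotypes.alleles(s_gm, m),
                genotypes.alleles(dam_f1, m),
                genotypes.alleles(d_gf, m), genotypes.alleles(d_gm, m),
            )
            triples[i, m] = triple
            joints[i, m] = joint
            if not ok:
                inconsistent[i, m] = True
                logger.warning(
                    "Mendelian inconsistency for %s at marker %s; using F2 prior",
                    f2, lmap.markers["marker"].iloc[m],
                )
    return OriginInference(f2_ids, lmap, triples, joints, inconsistent)


# ---------------------------------------------------------------------------
# Interval conditioning
# ---------------------------------------------------------------------------

def _transition2(r: float) -> np.ndarray:
    return np.array([[1 - r, r], [r, 1 - r]])


def _joint_at(x: float, marker_pos: np.ndarray, joints: np.ndarray,
              map_function: str) -> np.ndarray:
    """Joint (paternal x maternal) origin distribution at position x.

    Conditions on the nearest informative flanking marker per side
    (interval-mapping convention) under independent two-state Markov
    transmission per gamete:

        J_x(S) ∝ [Σ_SL J_L(SL) T_d1(SL,S)] · [Σ_SR T_d2(S,SR) J_R(SR)]

    with the four-state transition the Kronecker product of per-gamete
    transitions, and J the marker's joint posterior (uniform prior, so
    posterior ∝ likelihood).  Keeping the joint preserves information at
    markers that certify heterozygosity without resolving which gamete is
    which; it reduces to independent per-gamete conditioning whenever the
    marker evidence factorizes.
    """
    flat = joints.reshape(len(joints), 4)
    informative = np.abs(flat - 0.25).max(axis=1) > _INFORMATIVE_TOL
    if not informative.any():
        return np.full((2, 2), 0.25)
    pos = marker_pos[informative]
    J = flat[informative]
    iL = int(np.searchsorted(pos, x, side="right")) - 1
    iR = int(np.searchsorted(pos, x, side="left"))
    if iL >= 0 and iL == iR:
        return J[iL].reshape(2, 2)  # x coincides with an informative marker
    score = np.ones(4)
    if iL >= 0:
        T = _transition2(float(recombination_fraction(x - pos[iL], map_function)))
        T4 = np.kron(T, T)
        score *= J[iL] @ T4
    if iR < len(pos):
        T = _transition2(float(recombination_fraction(pos[iR] - x, map_function)))
        T4 = np.kron(T, T)
        score *= T4 @ J[iR]
    return (score / score.sum()).reshape(2, 2)


def origin_probabilities_at(
    x_cM: float,
    marker_pos: np.ndarray,
    marker_evidence: np.ndarray,
    map_function: str = "haldane",
) -> tuple:
    """Origin-state triple (pDD, pDP, pPP) and c_a at one scan position.

    Parameters
    ----------
    x_cM : query position on the chromosome.
    marker_pos : cM positions of the chromosome's markers.
    marker_evidence : either an (n_markers, 2) array of per-gamete
        P(Duroc origin) at each marker (paternal gamete in column 0),
        which is expanded to product joints, or an (n_markers, 2, 2)
        array of joint posteriors over (paternal, maternal) origin.
    """
    marker_pos = np.asarray(marker_pos, float)
    ev = np.asarray(marker_evidence, float)
    if ev.ndim == 2:
        pat = np.stack([ev[:, 0], 1 - ev[:, 0]], axis=1)
        mat = np.stack([ev[:, 1], 1 - ev[:, 1]], axis=1)
        joints = pat[:, :, None] * mat[:, None, :]
    else:
        joints = ev
    J = _joint_at(x_cM, marker_pos, joints, map_function)
    pDD = float(J[0, 0])
    pPP = float(J[1, 1])
    pDP = float(J[0, 1] + J[1, 0])
    return (pDD, pDP, pPP), pDD - pPP


def additive_coefficient(triple) -> float:
    """c_a = P(DD) - P(PP)."""
    pDD, _, pPP = triple
    return float(pDD - pPP)


def compute_ca_matrix(
    inference: OriginInference,
    grid: ScanGrid,
    map_function: str = "haldane",
    return_triples: bool = False,
):
    """Additive coefficients for every F2 at every grid position.

    Returns a DataFrame (individuals x positions); columns are labelled
    ``chrom@cM`` with cM printed at 0.1 resolution, ordered as the grid.
    With ``return_triples`` also returns an (n_f2, n_pos, 3) array.
    """
    lmap = inference.lmap
    n_f2 = len(inference.f2_ids)
    n_pos = len(grid)
    ca = np.empty((n_f2, n_pos))
    triples = np.empty((n_f2, n_pos, 3)) if return_triples else None

    col = 0
    labels = []
    for chrom in lmap.chromosomes:
        sub = lmap.chromosome_markers(chrom)
        midx = sub.index.to_numpy()
        mpos = sub["cM"].to_numpy(float)
        gpos = grid.chromosome_positions(chrom)["cM"].to_numpy(float)
        for x in gpos:
            labels.append(f"{chrom}@{x:.1f}")
        for i in range(n_f2):
            gp = inference.joints[i, midx]
            for j, x in enumerate(gpos):
                triple, c = origin_probabilities_at(x, mpos, gp, map_function)
                ca[i, col + j] = c
                if return_triples:
                    triples[i, col + j] = triple
        col += len(gpos)

    df = pd.DataFrame(ca, index=inference.f2_ids, columns=labels)
    if return_triples:
        return df, triples
    return df
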