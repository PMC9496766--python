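"""Base-pair center geometry and nucleosomal DNA unwrapping metrics.

Base-pair centers are the midpoints of paired C1′ atoms (within ~1 Å of
the full base-pair reference point for Watson–Crick pairs, far below the
7 Å unwrapping cutoff that consumes this geometry).  A terminal DNA
segment counts as unwrapped when every base pair in it has moved more
than the cutoff away from *all* base-pair positions of the wrapped
reference — so DNA that slid along the superhelical path without leaving
it is not called unwrapped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

__all__ = [
    "BasePairPath",
    "UnwrapCriteria",
    "basepair_centers",
    "unwrapped_length",
]


@dataclass
class BasePairPath:
    """Ordered base-pair centers, indexed symmetrically around the dyad."""

    indices: np.ndarray  # dyad-centred bp indices, contiguous
    centers: np.ndarray  # (N, 3) Å
    pairing: list | None = None  # [((chain_i, resid), (chain_j, resid)), ...]

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=int)
        self.centers = np.asarray(self.centers, dtype=float)
        if self.centers.ndim != 2 or self.centers.shape[1] != 3:
            raise ValueError("centers must be (N, 3)")
        if len(self.indices) != len(self.centers):
            raise ValueError("indices and centers length mismatch")
        if len(self.indices) > 1 and not np.all(np.diff(self.indices) == 1):
            raise ValueError("bp indices must be contiguous and increasing")
        if not np.all(np.isfinite(self.centers)):
            raise ValueError("centers must be finite")

    def __len__(self) -> int:
        return len(self.indices)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "bp": self.indices,
            "x": self.centers[:, 0],
            "y": self.centers[:, 1],
            "z": self.centers[:, 2],
        })


@dataclass(frozen=True)
class UnwrapCriteria:
    """Displacement cutoff defining an unwrapped base pair."""

    displacement_cutoff: float = 7.0  # Å

    def __post_init__(self) -> None:
        if self.displacement_cutoff <= 0:
            raise ValueError("cutoff must be positive")


def _dyad_indices(n: int) -> np.ndarray:
    """Contiguous bp indices with 0 at the central base pair."""
    half = n // 2
    return np.arange(n) - half


def basepair_centers(structure, mapping=None, pairing=None,
                     max_c1_distance: float = 12.0) -> BasePairPath:
    """Base-pair center path of a double-stranded DNA from C1′ midpoints.

    Expects a :class:`~dimerframe.structure_io.MolecularStructure` (first
    model) with exactly two DNA chains.  Pairing defaults to
    ``i ↔ (N+1−i)`` along equal-length complementary chains; when lengths
    differ, each residue of the shorter chain is paired with the nearest
    C1′ of the other chain, and unpaired overhang nucleotides are dropped
    with a warning.
    """
    import warnings

    atoms = structure.atoms
    dna_chains = [cid for cid, kind in structure.chains if kind == "dna"]
    if len(dna_chains) != 2:
        raise ValueError(f"need exactly 2 DNA chains, found {len(dna_chains)}")

    def c1_list(cid):
        sel = atoms[(atoms["chain"] == cid) & (atoms["name"] == "C1'")]
        if sel.empty:
            raise ValueError(f"chain {cid} has no C1' atoms")
        sel = sel.sort_values("resid")
        coords = structure.coords[0][sel.index.to_numpy()]
        return sel["resid"].to_numpy(), coords

    (res_i, xyz_i) = c1_list(dna_chains[0])
    (res_j, xyz_j) = c1_list(dna_chains[1])

    if pairing is None:
        if len(res_i) == len(res_j):
            pairing = [((dna_chains[0], res_i[k]), (dna_chains[1], res_j[len(res_j) - 1 - k]))
                       for k in range(len(res_i))]
        else:
            # distance-based fallback; drop overhangs
            short_first = len(res_i) <= len(res_j)
            a_res, a_xyz = (res_i, xyz_i) if short_first else (res_j, xyz_j)
            b_res, b_xyz = (res_j, xyz_j) if short_first else (res_i, xyz_i)
            d = cdist(a_xyz, b_xyz)
            pairing = []
            used = set()
            for k in range(len(a_res)):
                m = int(np.argmin(d[k]))
                if d[k, m] > max_c1_distance or m in used:
                    warnings.warn(
                        f"unpaired nucleotide {a_res[k]} excluded", stacklevel=2)
                    continue
                used.add(m)
                pa = (dna_chains[0] if short_first else dna_chains[1], a_res[k])
                pb = (dna_chains[1] if short_first else dna_chains[0], b_res[m])
                pairing.append((pa, pb) if short_first else (pb, pa))
            n_over = max(len(res_i), len(res_j)) - len(used)
            if n_over:
                warnings.warn(f"{n_over} overhang nucleotide(s) excluded",
                              stacklevel=2)

    lookup_i = dict(zip(res_i, xyz_i))
    lookup_j = dict(zip(res_j, xyz_j))
    centers = []
    for (ci, ri), (cj, rj) in pairing:
        a = lookup_i[ri] if ci == dna_chains[0] else lookup_j[ri]
        b = lookup_j[rj] if cj == dna_chains[1] else lookup_i[rj]
        centers.append(0.5 * (a + b))
    centers = np.asarray(centers)
    return BasePairPath(indices=_dyad_indices(len(centers)), centers=centers,
                        pairing=list(pairing))


def unwrapped_length(frame_path: BasePairPath, reference_path: BasePairPath,
                     criteria: UnwrapCriteria | None = None) -> tuple:
    """Unwrapped bp counts at the two DNA ends of a frame.

    For each end, the longest terminal run of base pairs whose centers are
    each farther than the cutoff from *every* base-pair center of the
    reference path.  Runs are counted strictly from the terminus inward:
    an interior excursion does not count.
    """
    if criteria is None:
        criteria = UnwrapCriteria()
    if len(frame_path) != len(reference_path) or \
            not np.array_equal(frame_path.indices, reference_path.indices):
        raise ValueError("frame and reference paths use different bp indexing")
    dmin = cdist(frame_path.centers, reference_path.centers).min(axis=1)
    away = dmin > criteria.displacement_cutoff

    def run_from(side):
        count = 0
        order = range(len(away)) if side == 0 else range(len(away) - 1, -1, -1)
        for k in order:
            if away[k]:
                count += 1
            else:
                break
        return count

    n1, n2 = run_from(0), run_from(1)
    if n1 == len(away):  # fully displaced path: split between the two ends
        return len(away), 0
    return n1, n2
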