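"""Scalar and profile metrics of H2A-H2B dimer plasticity.

All ensemble metrics assume frames already superposed into a common frame
(typically the DRF); pairwise quantities are then plain coordinate
differences with no further superposition round.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist

from .core import ConformationEnsemble, DimerModel, ReferenceFrame

__all__ = [
    "FluctuationProfile",
    "alpha2_angle",
    "alpha2_angle_series",
    "helix_amplitude",
    "max_pairwise_rmsd",
    "rmsf_profile",
    "rmsv_profile",
    "project_2d",
]


@dataclass
class FluctuationProfile:
    """Per-atom (or per-residue) positional fluctuation, Å."""

    labels: list  # [(chain, resid), ...]
    values: np.ndarray  # Å, >= 0
    kind: str  # rmsf_traj | rmsv_structs | rmsf_bfactor

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values < -1e-12):
            raise ValueError("fluctuation values must be non-negative")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "chain": [c for c, _ in self.labels],
            "resid": [r for _, r in self.labels],
            "value": self.values,
            "kind": self.kind,
        })


def _vector_angle(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na < 1e-12 or nb < 1e-12:
        raise ValueError("zero-length helix vector")
    c = np.clip((a @ b) / (na * nb), -1.0, 1.0)
    return float(np.degrees(np.arccos(c)))


def alpha2_angle(dimer: DimerModel) -> float:
    """α2-α2 bending angle of a dimer conformation, degrees.

    Angle between the vectors connecting the first and last Cα atoms of
    the two α2-helices, both taken N→C.  Values near 140–150° reflect the
    nearly antiparallel arrangement of the helices in the handshake fold.
    """
    chain_a, chain_b = dimer.chains[0], dimer.chains[-1]
    a0, a1 = dimer.alpha2_endpoints(chain_a)
    b0, b1 = dimer.alpha2_endpoints(chain_b)
    return _vector_angle(a1 - a0, b1 - b0)


def alpha2_angle_series(ensemble: ConformationEnsemble,
                        template: DimerModel) -> np.ndarray:
    """Per-frame α2-α2 angle over an ensemble, degrees."""
    chain_a, chain_b = template.chains[0], template.chains[-1]
    fa, la = template.segment_range(chain_a, "alpha2")
    fb, lb = template.segment_range(chain_b, "alpha2")
    ia0 = ensemble.atom_index(chain_a, fa)
    ia1 = ensemble.atom_index(chain_a, la)
    ib0 = ensemble.atom_index(chain_b, fb)
    ib1 = ensemble.atom_index(chain_b, lb)
    va = ensemble.frames[:, ia1] - ensemble.frames[:, ia0]
    vb = ensemble.frames[:, ib1] - ensemble.frames[:, ib0]
    num = np.einsum("ij,ij->i", va, vb)
    den = np.linalg.norm(va, axis=1) * np.linalg.norm(vb, axis=1)
    if np.any(den < 1e-12):
        raise ValueError("zero-length helix vector in ensemble")
    return np.degrees(np.arccos(np.clip(num / den, -1.0, 1.0)))


def helix_amplitude(ensemble: ConformationEnsemble, chain: str, resid: int,
                    mode: str = "max_pairwise") -> float:
    """Fluctuation amplitude of one terminal Cα across an aligned ensemble, Å.

    ``max_pairwise`` (default) is the maximum distance between the atom's
    positions over all frame pairs; ``max_from_first`` measures the maximum
    excursion from the first frame instead.
    """
    ensemble.require_aligned("helix_amplitude")
    idx = ensemble.atom_index(chain, resid)
    pos = ensemble.frames[:, idx]
    if mode == "max_pairwise":
        if len(pos) < 2:
            return 0.0
        return float(pdist(pos).max())
    if mode == "max_from_first":
        return float(np.linalg.norm(pos - pos[0], axis=1).max())
    raise ValueError(f"unknown amplitude mode {mode!r}")


def max_pairwise_rmsd(ensemble: ConformationEnsemble,
                      selection: np.ndarray | None = None) -> float:
    """Maximum RMSD between any two frames on the selection, Å.

    Uses post-alignment coordinates directly: the pairwise RMSD between
    frames i and j is the plain coordinate RMSD with no re-superposition.
    """
    ensemble.require_aligned("max_pairwise_rmsd")
    coords = ensemble.frames
    if selection is not None:
        coords = coords[:, np.asarray(selection, dtype=int)]
    T, N, _ = coords.shape
    if T < 2:
        return 0.0
    flat = coords.reshape(T, N * 3)
    return float(pdist(flat).max() / np.sqrt(N))


def rmsf_profile(ensemble: ConformationEnsemble) -> FluctuationProfile:
    """Per-atom RMSF about the ensemble mean position, Å."""
    ensemble.require_aligned("rmsf_profile")
    if ensemble.n_frames < 2:
        raise ValueError("RMSF needs at least 2 frames")
    mean = ensemble.frames.mean(axis=0)
    dev = ensemble.frames - mean
    values = np.sqrt(np.mean(np.sum(dev * dev, axis=2), axis=0))
    return FluctuationProfile(labels=list(ensemble.labels), values=values,
                              kind="rmsf_traj")


def rmsv_profile(structures: list) -> FluctuationProfile:
    """Root-mean-square variation of Cα positions across aligned structures.

    The ensemble analog of RMSF for a survey of experimental structures:
    only residues present in every structure enter the profile.  All
    structures must already be superposed onto the reference dimer in its
    DRF.
    """
    if len(structures) < 2:
        raise ValueError("RMSV needs at least 2 structures")
    common = set(structures[0].labels)
    for s in structures[1:]:
        common &= set(s.labels)
    if not common:
        raise ValueError("no residues common to all structures")
    labels = [lab for lab in structures[0].labels if lab in common]
    stack = np.stack([
        np.array([s.coords[s.atom_index(*lab)] for lab in labels])
        for s in structures
    ])
    mean = stack.mean(axis=0)
    dev = stack - mean
    values = np.sqrt(np.mean(np.sum(dev * dev, axis=2), axis=0))
    return FluctuationProfile(labels=labels, values=values, kind="rmsv_structs")


_PLANES = {"xy": ("x", "y"), "xz": ("x", "z"), "yz": ("y", "z")}


def project_2d(points: np.ndarray, frame: ReferenceFrame,
               plane: str = "xy") -> np.ndarray:
    """Coordinates of points on two named frame axes (e.g. the DRF XY plane)."""
    if plane not in _PLANES:
        raise ValueError(f"plane must be one of {sorted(_PLANES)}")
    a, b = _PLANES[plane]
    rel = np.atleast_2d(np.asarray(points, dtype=float)) - frame.origin
    out = np.stack([rel @ getattr(frame, a), rel @ getattr(frame, b)], axis=1)
    return out if np.asarray(points).ndim == 2 else out[0]
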