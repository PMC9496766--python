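"""Shared in-memory containers for dimer/nucleosome conformational analysis.

The containers here are deliberately light: coordinates are plain numpy
arrays in Ångström, atoms are identified by ``(chain, residue)`` labels in
the canonical histone reference numbering, and secondary-structure segments
are annotated as inclusive residue ranges.  Everything downstream (reference
frames, plasticity metrics, PCA modes) operates on these objects.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "RigidTransform",
    "ReferenceFrame",
    "DimerModel",
    "ConformationEnsemble",
]


@dataclass(frozen=True)
class RigidTransform:
    """A proper rigid-body motion ``x -> R x + t``."""

    rotation: np.ndarray  # (3, 3) proper orthogonal
    translation: np.ndarray  # (3,) Å

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float)
        if R.shape != (3, 3) or t.shape != (3,):
            raise ValueError("rotation must be 3x3 and translation length 3")
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-9):
            raise ValueError("rotation is not orthogonal within 1e-9")
        if np.linalg.det(R) < 0:
            raise ValueError("rotation is improper (det < 0)")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    def apply(self, coords: np.ndarray) -> np.ndarray:
        """Transform an (N, 3) coordinate array (or a single point)."""
        xyz = np.asarray(coords, dtype=float)
        return xyz @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return the transform equivalent to applying *other* first, then self."""
        return RigidTransform(
            rotation=self.rotation @ other.rotation,
            translation=self.rotation @ other.translation + self.translation,
        )

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))


@dataclass(frozen=True)
class ReferenceFrame:
    """Origin plus right-handed orthonormal axes (X, Y, Z).

    The dimer reference frame (DRF) and nucleosome reference frame (NRF)
    are both instances: X along the dimer pseudosymmetry axis (DRF) or
    ``Y × Z`` (NRF); Z along ``X × Y`` (DRF) or the DNA superhelical axis
    (NRF); Y the in-plane axis (DRF) or the dyad axis (NRF).
    """

    origin: np.ndarray
    x: np.ndarray
    y: np.ndarray
    z: np.ndarray

    def __post_init__(self) -> None:
        o = np.asarray(self.origin, dtype=float)
        axes = [np.asarray(a, dtype=float) for a in (self.x, self.y, self.z)]
        for a in axes:
            if a.shape != (3,):
                raise ValueError("axes must be 3-vectors")
            if not np.isclose(np.linalg.norm(a), 1.0, atol=1e-6):
                raise ValueError("axes must be unit vectors")
        M = np.stack(axes)
        if not np.allclose(M @ M.T, np.eye(3), atol=1e-6):
            raise ValueError("axes must be orthonormal")
        if not np.allclose(np.cross(axes[0], axes[1]), axes[2], atol=1e-6):
            raise ValueError("frame must be right-handed (Z = X × Y)")
        object.__setattr__(self, "origin", o)
        object.__setattr__(self, "x", axes[0])
        object.__setattr__(self, "y", axes[1])
        object.__setattr__(self, "z", axes[2])

    @property
    def axes(self) -> np.ndarray:
        """Rows are X, Y, Z."""
        return np.stack([self.x, self.y, self.z])

    def to_local(self, coords: np.ndarray) -> np.ndarray:
        """Express world coordinates in this frame."""
        return (np.asarray(coords, dtype=float) - self.origin) @ self.axes.T

    def transformed(self, transform: RigidTransform) -> "ReferenceFrame":
        R = transform.rotation
        return ReferenceFrame(
            origin=transform.apply(self.origin),
            x=R @ self.x, y=R @ self.y, z=R @ self.z,
        )

    def to_dict(self) -> dict:
        return {
            "origin": self.origin.tolist(),
            "x": self.x.tolist(),
            "y": self.y.tolist(),
            "z": self.z.tolist(),
        }


# Secondary-structure segment names used in annotations.
SEGMENT_NAMES = (
    "alpha1", "alpha2", "alpha3", "L1", "L2", "alpha1ext", "alphaC", "docking",
)
FOLD_SEGMENTS = ("alpha1", "alpha2", "alpha3")


@dataclass
class DimerModel:
    """An H2A-H2B (or variant) dimer reduced to labelled Cα coordinates.

    ``labels`` carries one ``(chain, resid)`` per atom where *chain* is the
    histone type ("H2A"/"H2B", or "H2A.Z") and *resid* the canonical
    reference residue index.  ``segments[chain][name]`` gives the inclusive
    canonical residue range of each annotated structural element.
    """

    labels: list  # [(chain, resid), ...]
    coords: np.ndarray  # (N, 3) Å
    segments: dict  # chain -> {segment_name: (first_resid, last_resid)}
    name: str = "dimer"

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must be (N, 3)")
        if len(self.labels) != len(self.coords):
            raise ValueError("labels and coords length mismatch")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")
        self._index = {lab: i for i, lab in enumerate(self.labels)}

    @property
    def n_atoms(self) -> int:
        return len(self.labels)

    @property
    def chains(self) -> list:
        seen = dict.fromkeys(c for c, _ in self.labels)
        return list(seen)

    def atom_index(self, chain: str, resid: int) -> int:
        try:
            return self._index[(chain, resid)]
        except KeyError:
            raise KeyError(f"no atom for chain {chain!r} residue {resid}") from None

    def segment_range(self, chain: str, segment: str) -> tuple:
        try:
            return self.segments[chain][segment]
        except KeyError:
            raise KeyError(f"segment {segment!r} not annotated for chain {chain!r}") from None

    def segment_indices(self, chain: str, segment: str) -> np.ndarray:
        first, last = self.segment_range(chain, segment)
        idx = [i for i, (c, r) in enumerate(self.labels)
               if c == chain and first <= r <= last]
        if not idx:
            raise KeyError(f"no atoms in segment {segment!r} of chain {chain!r}")
        return np.asarray(idx, dtype=int)

    def fold_indices(self, chain: str | None = None) -> np.ndarray:
        """Indices of histone-fold α-helix (α1, α2, α3) Cα atoms."""
        chains = [chain] if chain is not None else self.chains
        idx: list = []
        for c in chains:
            for seg in FOLD_SEGMENTS:
                if seg in self.segments.get(c, {}):
                    idx.extend(self.segment_indices(c, seg).tolist())
        return np.asarray(sorted(idx), dtype=int)

    def alpha2_endpoints(self, chain: str) -> tuple:
        """(first, last) Cα coordinates of the chain's α2-helix."""
        first, last = self.segment_range(chain, "alpha2")
        return (self.coords[self.atom_index(chain, first)],
                self.coords[self.atom_index(chain, last)])

    def transformed(self, transform: RigidTransform) -> "DimerModel":
        return replace(self, coords=transform.apply(self.coords))

    def copy(self) -> "DimerModel":
        return replace(self, coords=self.coords.copy())


@dataclass
class ConformationEnsemble:
    """Ordered frames of coordinates for a fixed labelled atom selection."""

    frames: np.ndarray  # (T, N, 3) Å
    labels: list  # [(chain, resid), ...]
    aligned: bool = False
    frame_spacing: float | None = None  # e.g. ns between frames, metadata only
    segments: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise ValueError("frames must be (T, N, 3)")
        if self.frames.shape[1] != len(self.labels):
            raise ValueError("labels and frame width mismatch")
        self._index = {lab: i for i, lab in enumerate(self.labels)}

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.frames.shape[1]

    def atom_index(self, chain: str, resid: int) -> int:
        try:
            return self._index[(chain, resid)]
        except KeyError:
            raise KeyError(f"no atom for chain {chain!r} residue {resid}") from None

    def frame_as_dimer(self, i: int, template: DimerModel) -> DimerModel:
        """View frame *i* as a DimerModel using *template*'s annotations."""
        if self.labels != template.labels:
            raise ValueError("ensemble labels do not match template")
        return replace(template, coords=self.frames[i].copy())

    def require_aligned(self, what: str) -> None:
        if not self.aligned:
            raise ValueError(
                f"{what} requires an ensemble aligned to a common frame; "
                "run frames.align_ensemble first"
            )
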