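"""Synthetic generators for every input the analysis pipeline consumes.

Each generator plants a known geometric or statistical structure — a C2
symmetry axis, a requested bending angle, PCA variance fractions, an
unwrapped DNA segment, an H-bond/turn odds ratio — so that every pipeline
stage can be tested by parameter recovery without external data.  All
generators are deterministic under their seed.

Presets (``data/presets.yaml``) encode the study conditions: bending-angle
distribution parameters per simulation context, leading-mode variance
fractions, helix amplitudes and the wrapped-DNA superhelix geometry.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import yaml
from scipy.spatial.transform import Rotation

from .core import ConformationEnsemble, DimerModel
from .dna import BasePairPath
from .ss_hbonds import BackboneChain, reconstruct_amide_hydrogens

__all__ = [
    "GeneratorSpec",
    "load_presets",
    "ideal_helix",
    "ideal_helix_backbone",
    "synthetic_dimer",
    "bending_ensemble",
    "arc_excursion_ensemble",
    "angle_samples",
    "synthetic_ncp_dna",
    "correlated_state_series",
]


@lru_cache(maxsize=1)
def load_presets() -> dict:
    """Bundled generator presets."""
    text = (importlib.resources.files("dimerframe") / "data" / "presets.yaml").read_text()
    return yaml.safe_load(text)


@dataclass(frozen=True)
class GeneratorSpec:
    """Seed + preset name + numeric overrides; same spec ⇒ identical output."""

    seed: int = 0
    preset: str | None = None
    params: dict = field(default_factory=dict)

    def resolve(self, section: str) -> dict:
        out: dict = {}
        if self.preset is not None:
            out.update(load_presets()[section][self.preset])
        out.update(self.params)
        return out


# ---------------------------------------------------------------------------
# helices and dimers

def ideal_helix(n_res: int, rise: float = 1.5, twist_per_res: float = 100.0,
                radius: float = 2.3) -> np.ndarray:
    """Canonical α-helical Cα point set, helix axis along z.

    Defaults give the textbook α-helix: 1.5 Å rise and 100° twist per
    residue on a 2.3 Å radius, i.e. 3.6 residues per turn and consecutive
    Cα separations of 3.8 Å.
    """
    if n_res < 4:
        raise ValueError("a helix needs at least 4 residues")
    k = np.arange(n_res)
    phi = np.radians(twist_per_res) * k
    return np.stack([radius * np.cos(phi), radius * np.sin(phi), rise * k], axis=1)


def _nerf(a: np.ndarray, b: np.ndarray, c: np.ndarray,
          bond: float, angle: float, dihedral: float) -> np.ndarray:
    """Place atom d given three predecessors and internal coordinates (degrees)."""
    ang = np.radians(angle)
    dih = np.radians(dihedral)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array([
        -bond * np.cos(ang),
        bond * np.sin(ang) * np.cos(dih),
        bond * np.sin(ang) * np.sin(dih),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def ideal_helix_backbone(n_res: int, phi: float = -57.0,
                         psi: float = -47.0) -> BackboneChain:
    """Full-backbone ideal α-helix built from standard internal coordinates.

    Bond lengths/angles are canonical peptide values; (φ, ψ) default to the
    α-helical minimum, so the Kabsch–Sander assignment of the interior is H.
    Amide hydrogens are included (reconstructed geometrically).
    """
    if n_res < 4:
        raise ValueError("a helix needs at least 4 residues")
    N, CA, C, O = [], [], [], []
    N.append(np.zeros(3))
    CA.append(np.array([1.458, 0.0, 0.0]))
    # first C placed in the xy-plane at the N-CA-C angle
    ang = np.radians(111.2)
    C.append(CA[0] + 1.525 * np.array([-np.cos(ang), np.sin(ang), 0.0]))
    for i in range(1, n_res):
        N.append(_nerf(N[i - 1], CA[i - 1], C[i - 1], 1.329, 116.2, psi))
        CA.append(_nerf(CA[i - 1], C[i - 1], N[i], 1.458, 121.7, 180.0))
        C.append(_nerf(C[i - 1], N[i], CA[i], 1.525, 111.2, phi))
    for i in range(n_res):
        # carbonyl O opposite the outgoing peptide bond (ψ + 180 dihedral)
        O.append(_nerf(N[i], CA[i], C[i], 1.231, 120.8, psi + 180.0))
    chain = BackboneChain(
        resids=np.arange(1, n_res + 1),
        n=np.array(N), ca=np.array(CA), c=np.array(C), o=np.array(O),
    )
    chain.h = reconstruct_amide_hydrogens(chain)
    return chain


# segment layout of the synthetic dimer: (canonical first resid, length)
_SEGMENTS = {
    "H2A": {"alpha1": (27, 11), "alpha2": (46, 28), "alpha3": (79, 10)},
    "H2B": {"alpha1": (37, 11), "alpha2": (55, 28), "alpha3": (88, 10)},
}
# local placement of chain A segments: (center xyz, axis direction)
_CHAIN_A_LAYOUT = {
    "alpha1": (np.array([-9.0, -5.0, 7.0]), np.array([0.3, -0.7, 0.65])),
    "alpha3": (np.array([9.0, -4.0, 7.0]), np.array([-0.6, 0.4, 0.7])),
}
_ALPHA2_CENTER_A = np.array([0.0, 2.0, 4.0])
_C2_AXIS = np.array([1.0, 0.0, 0.0])  # planted pseudosymmetry axis


def _oriented_helix(n_res: int, direction: np.ndarray,
                    center: np.ndarray) -> np.ndarray:
    """Ideal helix piece whose first→last Cα chord points along *direction*."""
    pts = ideal_helix(n_res)
    chord = pts[-1] - pts[0]
    d = np.asarray(direction, dtype=float)
    d = d / np.linalg.norm(d)
    rot, _ = Rotation.align_vectors(d[None, :], (chord / np.linalg.norm(chord))[None, :])
    pts = pts @ rot.as_matrix().T
    mid = 0.5 * (pts[0] + pts[-1])
    return pts + (center - mid)


def synthetic_dimer(angle: float = 142.0, preset: str | None = None,
                    noise_sigma: float = 0.0, seed: int = 0,
                    chain_types: tuple = ("H2A", "H2B")) -> DimerModel:
    """Two-chain model dimer with annotated α1/α2/α3 helices.

    The two chains are exact C2 images about the planted x-axis, with each
    α2 chord at ``angle/2`` from the axis so that the α2-α2 angle equals
    the request exactly.  ``preset`` may name an extreme conformation
    (e.g. ``angle_max_dna_bound``), overriding ``angle``.  Optional
    isotropic Gaussian noise (σ in Å, seeded) breaks the exact symmetry.
    """
    if preset is not None:
        angle = float(load_presets()["extreme_conformations"][preset])
    if not 0.0 < angle < 180.0:
        raise ValueError("requested α2-α2 angle must lie in (0°, 180°)")
    half = np.radians(angle / 2.0)
    d_a2 = np.array([np.cos(half), np.sin(half), 0.0])

    chain_a_coords = {}
    chain_a_coords["alpha2"] = _oriented_helix(
        _SEGMENTS["H2A"]["alpha2"][1], d_a2, _ALPHA2_CENTER_A)
    for seg, (center, direction) in _CHAIN_A_LAYOUT.items():
        chain_a_coords[seg] = _oriented_helix(
            _SEGMENTS["H2A"][seg][1], direction, center)

    c2 = np.diag([1.0, -1.0, -1.0])  # 180° about x
    labels, coords, segments = [], [], {}
    for chain_type, image in ((chain_types[0], False), (chain_types[1], True)):
        seg_key = "H2A" if not image else "H2B"
        segments[chain_type] = {}
        for seg in ("alpha1", "alpha2", "alpha3"):
            first, length = _SEGMENTS[seg_key][seg]
            pts = chain_a_coords[seg]
            if image:
                pts = pts @ c2.T
            segments[chain_type][seg] = (first, first + length - 1)
            for k in range(length):
                labels.append((chain_type, first + k))
                coords.append(pts[k])
    coords = np.asarray(coords)
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        coords = coords + rng.normal(0.0, noise_sigma, coords.shape)
    return DimerModel(labels=labels, coords=coords, segments=segments,
                      name=f"synthetic_dimer_{angle:g}")


# ---------------------------------------------------------------------------
# ensembles

def _hinge_field(dimer: DimerModel, direction: np.ndarray) -> np.ndarray:
    """Unit 3N displacement field bending both α2 C-halves along *direction*.

    Piecewise linear with a hinge at mid-helix: the N-terminal half of each
    α2-helix stays put, the C-terminal half moves increasingly far along
    the given direction, reaching full weight at the C-end.
    """
    field_arr = np.zeros((dimer.n_atoms, 3))
    d = np.asarray(direction, dtype=float)
    d = d / np.linalg.norm(d)
    for chain in dimer.chains:
        idx = dimer.segment_indices(chain, "alpha2")
        L = len(idx)
        mid = L // 2
        for pos, atom in enumerate(idx):
            if pos > mid:
                field_arr[atom] = d * (pos - mid) / (L - 1 - mid)
    flat = field_arr.ravel()
    return flat / np.linalg.norm(flat)


def bending_ensemble(dimer: DimerModel, mode_fractions=(0.24, 0.11),
                     total_variance: float = 10.0, n_frames: int = 20000,
                     seed: int = 0, preset: str | None = None) -> ConformationEnsemble:
    """Gaussian ensemble with planted bending modes and isotropic residual.

    The leading planted direction bends both α2 C-ends along the dimer
    pseudosymmetry (x) axis; the second bends them perpendicular (z).
    Planted variance fractions are exact in expectation: the residual
    ``(1 − Σf)·total_variance`` is spread isotropically over the orthogonal
    complement of the planted modes.  Frames are generated in the dimer's
    own frame, i.e. already mutually aligned.
    """
    if preset is not None:
        cfg = load_presets()["mode_presets"][preset]
        mode_fractions = tuple(cfg["fractions"])
        total_variance = float(cfg.get("total_variance", total_variance))
    fractions = np.asarray(mode_fractions, dtype=float)
    if np.any(fractions < 0) or fractions.sum() > 1.0 + 1e-12:
        raise ValueError("mode fractions must be non-negative and sum to at most 1")
    if total_variance < 0:
        raise ValueError("total variance must be non-negative")
    if n_frames < 1:
        raise ValueError("need at least one frame")

    base = dimer.coords.ravel()
    dim = base.size
    if total_variance == 0:
        frames = np.repeat(base[None, :], n_frames, axis=0)
        return ConformationEnsemble(frames=frames.reshape(n_frames, -1, 3),
                                    labels=list(dimer.labels), aligned=True,
                                    segments=dict(dimer.segments))

    modes = [_hinge_field(dimer, _C2_AXIS)]
    if len(fractions) > 1:
        perp = np.array([0.0, 0.0, 1.0])
        m2 = _hinge_field(dimer, perp)
        for m in modes:  # Gram-Schmidt (fields are orthogonal by construction)
            m2 = m2 - (m2 @ m) * m
        modes.append(m2 / np.linalg.norm(m2))
    if len(fractions) > len(modes):
        raise ValueError("at most 2 planted mode fractions are supported")
    E = np.stack(modes[:len(fractions)])  # (K, 3N)

    rng = np.random.default_rng(seed)
    K = E.shape[0]
    resid_var = (1.0 - fractions.sum()) * total_variance / (dim - K)
    noise = rng.normal(0.0, np.sqrt(resid_var), (n_frames, dim))
    noise -= (noise @ E.T) @ E  # confine residual to the orthogonal complement
    coeffs = rng.normal(0.0, np.sqrt(fractions * total_variance), (n_frames, K))
    frames = base[None, :] + coeffs @ E + noise
    return ConformationEnsemble(frames=frames.reshape(n_frames, -1, 3),
                                labels=list(dimer.labels), aligned=True,
                                segments=dict(dimer.segments))


def arc_excursion_ensemble(dimer: DimerModel, chain: str = "H2A",
                           resid: int | None = None,
                           amplitude: float | None = None,
                           preset: str | None = "free_dimer_h2a_amp",
                           n_frames: int = 200, arc_span: float = 60.0,
                           rigid_jitter: bool = True,
                           seed: int = 0) -> tuple:
    """Deterministic ensemble whose planted maximal Cα excursion is exact.

    One terminal Cα (default: the H2A α2 C-end) sweeps a circular arc whose
    endpoints are exactly ``amplitude`` apart; every other atom is static.
    Optional rigid jitter applies a random rigid motion to each frame so
    that alignment does real work; aligning on the static atoms recovers
    the constructed conformations exactly.

    Returns ``(ensemble, static_selection)``; the ensemble is unaligned.
    """
    if amplitude is None:
        amplitude = float(load_presets()["amplitude_presets"][preset])
    if resid is None:
        resid = dimer.segment_range(chain, "alpha2")[1]
    if not 0 < arc_span <= 180.0:
        raise ValueError("arc span must lie in (0°, 180°]")
    idx = dimer.atom_index(chain, resid)
    p0 = dimer.coords[idx]
    # chord of an arc spanning `arc_span` at radius r is 2 r sin(span/2)
    r = amplitude / (2.0 * np.sin(np.radians(arc_span) / 2.0))
    e1, e2 = np.array([0.0, 1.0, 0.0]), np.array([0.0, 0.0, 1.0])
    center = p0 - r * e1
    phis = np.radians(np.linspace(0.0, arc_span, n_frames))
    frames = np.repeat(dimer.coords[None, :, :], n_frames, axis=0)
    frames[:, idx, :] = center + r * (np.cos(phis)[:, None] * e1 +
                                      np.sin(phis)[:, None] * e2)
    if rigid_jitter:
        rng = np.random.default_rng(seed)
        for t in range(n_frames):
            R = Rotation.random(random_state=rng).as_matrix()
            shift = rng.normal(0.0, 5.0, 3)
            frames[t] = frames[t] @ R.T + shift
    static = np.array([i for i in range(dimer.n_atoms) if i != idx], dtype=int)
    ens = ConformationEnsemble(frames=frames, labels=list(dimer.labels),
                               aligned=False, segments=dict(dimer.segments))
    return ens, static


def angle_samples(preset: str, n: int = 5000, seed: int = 0) -> np.ndarray:
    """Gaussian α2-α2 angle sample from a named distribution preset."""
    cfg = load_presets()["angle_presets"][preset]
    rng = np.random.default_rng(seed)
    return rng.normal(cfg["mean"], cfg["std"], n)


def angle_sample_pair(preset_a: str, preset_b: str, n: int = 5000,
                      seed: int = 0) -> tuple:
    """Paired angle samples from two presets sharing one noise realization.

    Both samples are affine transforms of the same standard-normal draw
    (common random numbers), so the comparison of their distribution
    modes isolates the planted parameter difference instead of compounding
    two independent sampling errors — the paired design one would use to
    compare two simulation contexts of the same system.
    """
    presets = load_presets()["angle_presets"]
    ca, cb = presets[preset_a], presets[preset_b]
    z = np.random.default_rng(seed).standard_normal(n)
    return ca["mean"] + ca["std"] * z, cb["mean"] + cb["std"] * z


# ---------------------------------------------------------------------------
# DNA paths

def synthetic_ncp_dna(n_bp: int = 147, radius: float = 41.9,
                      pitch: float = 25.9, rise: float = 3.4,
                      unwrap_end1: int = 0, unwrap_end2: int = 0,
                      displacement: float = 15.0,
                      cutoff_check: float = 7.0) -> tuple:
    """Superhelical bp-center path with optionally unwrapped straight ends.

    Returns ``(frame_path, reference_path)``.  The reference is the fully
    wrapped superhelix; in the frame path the requested terminal segments
    are replaced by straight B-DNA continuations, displaced outward from
    the superhelix so that every unwrapped center is farther than
    ``cutoff_check`` from all reference centers (raises if the requested
    construction cannot satisfy that).
    """
    if n_bp < 20:
        raise ValueError("need at least 20 base pairs")
    for u in (unwrap_end1, unwrap_end2):
        if not 0 <= u < n_bp // 2:
            raise ValueError("unwrap counts must be below half the bp count")

    # arc length `rise` per bp along a helix of given radius and pitch
    turn_len = np.hypot(2 * np.pi * radius, pitch)
    dphi = 2 * np.pi * rise / turn_len
    dz = pitch * rise / turn_len
    k = np.arange(n_bp)
    phi = (k - n_bp // 2) * dphi
    ref = np.stack([radius * np.cos(phi), radius * np.sin(phi),
                    (k - n_bp // 2) * dz], axis=1)
    reference = BasePairPath(indices=k - n_bp // 2, centers=ref)

    centers = ref.copy()
    for end, count in ((0, unwrap_end1), (1, unwrap_end2)):
        if count == 0:
            continue
        junction = count if end == 0 else n_bp - 1 - count
        step = -1 if end == 0 else 1
        tangent = ref[junction + (1 if end == 0 else 0)] - \
            ref[junction - (0 if end == 0 else 1)]
        tangent = (tangent / np.linalg.norm(tangent)) * (-1 if end == 0 else 1)
        radial = ref[junction].copy()
        radial[2] = 0.0
        radial /= np.linalg.norm(radial)
        start = ref[junction] + displacement * radial
        for m in range(1, count + 1):
            centers[junction + step * m] = start + rise * m * tangent
    frame = BasePairPath(indices=k - n_bp // 2, centers=centers)

    from scipy.spatial.distance import cdist
    moved = np.ones(n_bp, dtype=bool)
    moved[unwrap_end1:n_bp - unwrap_end2] = False
    if moved.any():
        dmin = cdist(centers[moved], ref).min(axis=1)
        if np.any(dmin <= cutoff_check):
            raise ValueError(
                "infeasible unwrap request: a displaced base pair remains "
                f"within {cutoff_check} Å of the wrapped reference"
            )
    return frame, reference


# ---------------------------------------------------------------------------
# coupled state series

def correlated_state_series(n_frames: int, p_bond: float = 0.5,
                            odds_ratio: float = 1.0, p_turn: float = 0.5,
                            seed: int = 0) -> tuple:
    """Paired Bernoulli series with requested marginals and odds ratio.

    Emulates coupled H-bond presence and turn formation: the joint cell
    probabilities are solved from the marginals and the odds ratio
    (quadratic root of the 2×2 association identity), then frames are
    drawn independently.  Returns ``(bond_series, turn_series)``.
    """
    if not (0.0 < p_bond < 1.0 and 0.0 < p_turn < 1.0):
        raise ValueError("marginal probabilities must lie in (0, 1)")
    if odds_ratio <= 0:
        raise ValueError("odds ratio must be positive")
    if n_frames < 1:
        raise ValueError("need at least one frame")

    if abs(odds_ratio - 1.0) < 1e-12:
        p11 = p_bond * p_turn
    else:
        a = odds_ratio - 1.0
        s = 1.0 + (p_bond + p_turn) * a
        disc = s * s - 4.0 * a * odds_ratio * p_bond * p_turn
        p11 = (s - np.sqrt(disc)) / (2.0 * a)
    p10 = p_bond - p11
    p01 = p_turn - p11
    p00 = 1.0 - p11 - p10 - p01
    probs = np.array([p11, p10, p01, p00])
    if np.any(probs < -1e-12):
        raise ValueError("requested marginals and odds ratio are incompatible")
    probs = np.clip(probs, 0.0, 1.0)
    probs /= probs.sum()

    rng = np.random.default_rng(seed)
    cell = rng.choice(4, size=n_frames, p=probs)
    bond = (cell == 0) | (cell == 1)
    turn = (cell == 0) | (cell == 2)
    return bond, turn
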