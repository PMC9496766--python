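"""Rigid-body superposition and pseudosymmetry-based reference frames.

The dimer reference frame (DRF) exploits the two-fold pseudosymmetry of the
H2A-H2B handshake: the two histone folds are structurally equivalent, so
superposing one fold onto the other yields a rotation of almost exactly
180°, whose axis is the pseudosymmetry (X) axis.  The Y axis is the
in-plane direction along which the long α2-helices extend the furthest, and
Z = X × Y.  The nucleosome reference frame (NRF) instead uses the DNA
superhelical axis (Z) and the dyad direction (Y).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import least_squares, minimize_scalar
from scipy.spatial.transform import Rotation

from .core import ConformationEnsemble, DimerModel, ReferenceFrame, RigidTransform

__all__ = [
    "AxisEstimate",
    "kabsch_superpose",
    "fold_equivalences",
    "pseudosymmetry_axis",
    "build_drf",
    "build_nrf",
    "align_ensemble",
]


@dataclass(frozen=True)
class AxisEstimate:
    """Rotation axis relating the two histone folds of a dimer."""

    direction: np.ndarray  # unit 3-vector
    point_on_axis: np.ndarray  # Å
    rotation_angle: float  # degrees, in (0, 180]
    fit_rmsd: float  # Å

    def __post_init__(self) -> None:
        d = np.asarray(self.direction, dtype=float)
        n = np.linalg.norm(d)
        if not np.isclose(n, 1.0, atol=1e-6):
            raise ValueError("direction must be a unit vector")
        object.__setattr__(self, "direction", d / n)
        object.__setattr__(self, "point_on_axis",
                           np.asarray(self.point_on_axis, dtype=float))
        if not 0.0 < self.rotation_angle <= 180.0 + 1e-9:
            raise ValueError("rotation_angle must lie in (0°, 180°]")


def kabsch_superpose(mobile, target, weights=None):
    """Least-squares superposition of *mobile* onto *target*.

    Returns ``(RigidTransform, rmsd)`` where the transform applied to
    *mobile* minimizes the (weighted) RMSD to *target*.  A proper rotation
    is always enforced, so a mirror image cannot be superposed exactly.
    """
    P = np.asarray(mobile, dtype=float)
    Q = np.asarray(target, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ValueError("mobile and target must be matching (N, 3) arrays")
    n = P.shape[0]
    if n < 3:
        raise ValueError("superposition needs at least 3 points")
    if weights is None:
        w = np.full(n, 1.0 / n)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (n,) or np.any(w < 0) or w.sum() <= 0:
            raise ValueError("weights must be non-negative with positive sum")
        w = w / w.sum()

    cp = w @ P
    cq = w @ Q
    P0 = P - cp
    Q0 = Q - cq
    # collinear point sets leave a rotational degree of freedom undetermined
    if np.linalg.matrix_rank(P0, tol=1e-8 * max(1.0, np.abs(P0).max())) < 2:
        raise ValueError("degenerate (collinear) point configuration")

    H = (P0 * w[:, None]).T @ Q0
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cq - R @ cp
    transform = RigidTransform(R, t)
    diff = transform.apply(P) - Q
    rmsd = float(np.sqrt(np.sum(w * np.sum(diff * diff, axis=1))))
    return transform, rmsd


def fold_equivalences(dimer: DimerModel, chain_a: str | None = None,
                      chain_b: str | None = None) -> list:
    """Default Cα equivalence table pairing the two histone folds.

    Pairs α1↔α1, α2↔α2, α3↔α3 position-by-position (N- to C-terminal)
    between the two chains, trimming each pair of segments to the shorter
    length.  Returns ``[((chain_a, resid), (chain_b, resid)), ...]``.
    """
    chains = dimer.chains
    if chain_a is None or chain_b is None:
        if len(chains) != 2:
            raise ValueError(
                f"dimer must have exactly 2 chains, found {len(chains)}"
            )
        chain_a, chain_b = chains
    pairs = []
    for seg in ("alpha1", "alpha2", "alpha3"):
        fa, la = dimer.segment_range(chain_a, seg)
        fb, lb = dimer.segment_range(chain_b, seg)
        length = min(la - fa, lb - fb) + 1
        for k in range(length):
            pairs.append(((chain_a, fa + k), (chain_b, fb + k)))
    return pairs


def pseudosymmetry_axis(dimer: DimerModel, equivalences=None) -> AxisEstimate:
    """Two-fold pseudosymmetry axis of an H2A-H2B dimer.

    Superposes the first fold's Cα atoms onto their structural equivalents
    in the second fold and extracts the axis and angle of the optimal
    rotation.  For a perfectly C2-symmetric dimer the angle is 180° and the
    fit RMSD zero.
    """
    if equivalences is None:
        equivalences = fold_equivalences(dimer)
    if len(equivalences) < 20:
        raise ValueError("need at least 20 equivalent Cα pairs")
    try:
        mob = np.array([dimer.coords[dimer.atom_index(*a)] for a, _ in equivalences])
        tgt = np.array([dimer.coords[dimer.atom_index(*b)] for _, b in equivalences])
    except KeyError as exc:
        raise ValueError(f"equivalence table mismatch: {exc}") from exc

    transform, rmsd = kabsch_superpose(mob, tgt)
    rotvec = Rotation.from_matrix(transform.rotation).as_rotvec()
    angle = float(np.degrees(np.linalg.norm(rotvec)))
    if angle <= 1e-9:
        raise ValueError("folds are related by a pure translation; no axis")
    u = rotvec / np.linalg.norm(rotvec)

    # Point on the screw axis: solve (I - R) p = t_perp in least squares,
    # where t_perp is the translation with its axial component removed.
    t = transform.translation
    t_perp = t - (u @ t) * u
    p, *_ = np.linalg.lstsq(np.eye(3) - transform.rotation, t_perp, rcond=None)
    # deterministic orientation: positive component on the first non-zero axis
    for comp in u:
        if abs(comp) > 1e-12:
            if comp < 0:
                u = -u
            break
    return AxisEstimate(direction=u, point_on_axis=p,
                        rotation_angle=min(angle, 180.0), fit_rmsd=rmsd)


def _alpha2_criterion(dimer: DimerModel, origin, x_axis, criterion):
    """Objective over candidate Y directions as a function of in-plane angle."""
    idx = np.concatenate([dimer.segment_indices(c, "alpha2") for c in dimer.chains])
    pts = dimer.coords[idx] - origin
    # orthonormal basis of the plane perpendicular to X
    ref = np.array([0.0, 0.0, 1.0])
    if abs(x_axis @ ref) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(x_axis, ref)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(x_axis, e1)
    p1 = pts @ e1
    p2 = pts @ e2

    if criterion == "mean_abs":
        def objective(phi):
            return float(np.mean(np.abs(np.cos(phi) * p1 + np.sin(phi) * p2)))
    elif criterion == "variance":
        def objective(phi):
            proj = np.cos(phi) * p1 + np.sin(phi) * p2
            return float(np.var(proj))
    else:
        raise ValueError(f"unknown criterion {criterion!r}")
    return objective, e1, e2


def build_drf(dimer: DimerModel, axis: AxisEstimate,
              criterion: str = "mean_abs", n_grid: int = 3600) -> ReferenceFrame:
    """Dimer reference frame from the pseudosymmetry axis.

    X is the pseudosymmetry axis; Y is the direction perpendicular to X
    maximizing either the mean absolute projection (default) or the
    variance of the α2-helix Cα projections; Z = X × Y.  The origin is the
    centroid of histone-fold α-helix Cα atoms.  Signs are fixed so the
    first chain's α2 N→C vector has non-negative X component and the second
    chain's α2 centroid positive Y, making the frame reproducible.
    """
    fold_idx = dimer.fold_indices()
    origin = dimer.coords[fold_idx].mean(axis=0)
    x = np.asarray(axis.direction, dtype=float)
    x = x / np.linalg.norm(x)

    objective, e1, e2 = _alpha2_criterion(dimer, origin, x, criterion)
    # dense grid over half the circle (Y and -Y give the same objective)
    phis = np.linspace(0.0, np.pi, n_grid, endpoint=False)
    values = np.array([objective(p) for p in phis])
    best = int(np.argmax(values))
    span = np.pi / n_grid
    res = minimize_scalar(lambda p: -objective(p),
                          bounds=(phis[best] - span, phis[best] + span),
                          method="bounded")
    phi = float(res.x)
    y = np.cos(phi) * e1 + np.sin(phi) * e2

    chain_a, chain_b = dimer.chains[0], dimer.chains[-1]
    # sign conventions
    a_first, a_last = dimer.alpha2_endpoints(chain_a)
    if (a_last - a_first) @ x < 0:
        x = -x
    b_centroid = dimer.coords[dimer.segment_indices(chain_b, "alpha2")].mean(axis=0)
    if (b_centroid - origin) @ y < 0:
        y = -y
    # re-orthogonalize Y against the possibly flipped X (numerical hygiene)
    y = y - (y @ x) * x
    y /= np.linalg.norm(y)
    z = np.cross(x, y)
    return ReferenceFrame(origin=origin, x=x, y=y, z=z)


def _fit_cylinder_axis(points: np.ndarray):
    """Axis (unit vector, point) minimizing the spread of radial distances."""
    center = points.mean(axis=0)
    centered = points - center
    # initial guess: smallest principal axis of the low-pitch superhelix
    _, _, Vt = np.linalg.svd(centered, full_matrices=False)
    axis0 = Vt[-1]

    def residuals(params):
        theta, phi, px, py = params
        d = np.array([np.sin(theta) * np.cos(phi),
                      np.sin(theta) * np.sin(phi),
                      np.cos(theta)])
        # anchor point parametrized in the plane through the centroid
        basis = _plane_basis(d)
        p = center + px * basis[0] + py * basis[1]
        rel = points - p
        radial = rel - np.outer(rel @ d, d)
        r = np.linalg.norm(radial, axis=1)
        return r - r.mean()

    theta0 = float(np.arccos(np.clip(axis0[2], -1, 1)))
    phi0 = float(np.arctan2(axis0[1], axis0[0]))
    sol = least_squares(residuals, x0=[theta0, phi0, 0.0, 0.0], method="lm")
    theta, phi, px, py = sol.x
    d = np.array([np.sin(theta) * np.cos(phi),
                  np.sin(theta) * np.sin(phi),
                  np.cos(theta)])
    d /= np.linalg.norm(d)
    basis = _plane_basis(d)
    p = center + px * basis[0] + py * basis[1]
    return d, p


def _plane_basis(normal: np.ndarray):
    ref = np.array([1.0, 0.0, 0.0])
    if abs(normal @ ref) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(normal, ref)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(normal, e1)
    return e1, e2


def build_nrf(bp_centers: np.ndarray) -> ReferenceFrame:
    """Nucleosome reference frame from an ordered base-pair center path.

    Z is the best-fit superhelical (cylinder) axis of the path, Y points
    from the axis through the central base pair (the dyad) orthogonalized
    against Z, X = Y × Z, and the origin sits on the axis at the dyad's
    axial position.
    """
    pts = np.asarray(bp_centers, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ValueError("bp_centers must be (N, 3)")
    if len(pts) < 20:
        raise ValueError("need at least 20 base pairs to fit the superhelix")
    z, anchor = _fit_cylinder_axis(pts)

    dyad = pts[len(pts) // 2]
    axial = (dyad - anchor) @ z
    origin = anchor + axial * z
    y = dyad - origin
    y = y - (y @ z) * z
    ny = np.linalg.norm(y)
    if ny < 1e-9:
        raise ValueError("dyad base pair lies on the superhelical axis")
    y /= ny
    # orient Z so the path winds right-handedly when viewed along +Z
    mid = len(pts) // 2
    winding = np.cross(pts[mid] - origin, pts[min(mid + 5, len(pts) - 1)] - origin) @ z
    if winding < 0:
        z = -z
        y = y - (y @ z) * z
        y /= np.linalg.norm(y)
    x = np.cross(y, z)
    return ReferenceFrame(origin=origin, x=x, y=y, z=z)


def align_ensemble(ensemble: ConformationEnsemble, reference: np.ndarray,
                   selection: np.ndarray) -> ConformationEnsemble:
    """Superpose every frame onto *reference* using only *selection* atoms.

    The returned ensemble has its ``aligned`` flag set; downstream RMSD
    computations between frames use the coordinates as-is, with no further
    round of pairwise superposition.
    """
    sel = np.asarray(selection, dtype=int)
    if sel.size == 0:
        raise ValueError("selection must be nonempty")
    if sel.max() >= ensemble.n_atoms or sel.min() < 0:
        raise ValueError("selection atom missing from ensemble")
    ref = np.asarray(reference, dtype=float)
    if ref.shape == (ensemble.n_atoms, 3):
        ref_sel = ref[sel]
    elif ref.shape == (sel.size, 3):
        ref_sel = ref
    else:
        raise ValueError("reference shape matches neither the ensemble nor the selection")

    out = np.empty_like(ensemble.frames)
    for i, frame in enumerate(ensemble.frames):
        transform, _ = kabsch_superpose(frame[sel], ref_sel)
        out[i] = transform.apply(frame)
    return replace(ensemble, frames=out, aligned=True)
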