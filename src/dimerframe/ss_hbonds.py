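"""Hydrogen-bond detection and Kabsch–Sander secondary-structure assignment.

Two hydrogen-bond notions coexist here, as they do in practice:

* a *geometric* criterion (donor-acceptor distance ≤ 3 Å and
  donor-H-acceptor angle ≥ 120°) used to track individual bonds such as
  the H2A A48(O)–V52(N) bond at the α2 N-end, and
* the Kabsch–Sander *electrostatic* criterion (E < −0.5 kcal/mol) used for
  secondary-structure assignment, with backbone amide hydrogens rebuilt
  geometrically when absent (crystal structures carry no hydrogens).

Only the helix/turn subset of the assignment taxonomy is implemented
(H, G, I, T, a minimal E via bridge detection, else '-'): the biological
question is the α-helix ↔ H-bonded-turn transition at the N-end of the
H2A α2-helix, which distinguishes H2A from H2A.Z dynamics.
"""

from __future__ import annotations

from dataclasses import dataclass
import numpy as np
from scipy import stats as sps

__all__ = [
    "HBondCriteria",
    "BackboneChain",
    "find_hbonds",
    "reconstruct_amide_hydrogens",
    "kabsch_sander_energies",
    "assign_ss",
    "ss_occupancy",
    "hbond_ss_association",
]

SS_CLASSES = ("H", "G", "I", "T", "E", "-")

# Kabsch–Sander electrostatic model constants
_KS_Q1Q2_F = 0.084 * 332.0  # kcal/mol·Å
_KS_CUTOFF = -0.5  # kcal/mol
_PEPTIDE_BOND_MAX = 2.5  # Å, C(i)-N(i+1) distance above this flags a chain break


@dataclass(frozen=True)
class HBondCriteria:
    """Geometric hydrogen-bond criterion."""

    max_donor_acceptor: float = 3.0  # Å
    min_dha_angle: float = 120.0  # degrees

    def __post_init__(self) -> None:
        if self.max_donor_acceptor <= 0:
            raise ValueError("distance cutoff must be positive")
        if not 0.0 < self.min_dha_angle <= 180.0:
            raise ValueError("angle cutoff must lie in (0°, 180°]")


def find_hbonds(coords: np.ndarray, donors, hydrogens, acceptors,
                criteria: HBondCriteria | None = None) -> list:
    """Hydrogen bonds satisfying the geometric criterion.

    *donors* and *hydrogens* are paired atom-index sequences (hydrogen k is
    covalently bound to donor k); *acceptors* is an independent index list.
    Returns ``(donor, hydrogen, acceptor)`` index triples with
    D–A ≤ cutoff and D-H-A angle ≥ cutoff.
    """
    if criteria is None:
        criteria = HBondCriteria()
    xyz = np.asarray(coords, dtype=float)
    donors = list(donors)
    hydrogens = list(hydrogens)
    if len(donors) != len(hydrogens):
        raise ValueError("each donor needs exactly one paired hydrogen")
    out = []
    for d, h in zip(donors, hydrogens):
        for a in acceptors:
            if a == d or a == h:
                continue
            da = xyz[a] - xyz[d]
            dist = np.linalg.norm(da)
            if dist > criteria.max_donor_acceptor:
                continue
            hd = xyz[d] - xyz[h]
            ha = xyz[a] - xyz[h]
            denom = np.linalg.norm(hd) * np.linalg.norm(ha)
            if denom < 1e-12:
                raise ValueError("degenerate donor/hydrogen/acceptor geometry")
            ang = np.degrees(np.arccos(np.clip(hd @ ha / denom, -1.0, 1.0)))
            if ang >= criteria.min_dha_angle:
                out.append((d, h, a))
    return out


@dataclass
class BackboneChain:
    """Backbone N/Cα/C/O coordinates of one polypeptide chain.

    ``h`` may be None (crystal structures); amide hydrogens are then
    reconstructed.  Proline residues (by ``resnames``) have no amide H and
    never donate.
    """

    resids: np.ndarray
    n: np.ndarray  # (L, 3)
    ca: np.ndarray
    c: np.ndarray
    o: np.ndarray
    h: np.ndarray | None = None
    resnames: list | None = None

    def __post_init__(self) -> None:
        self.resids = np.asarray(self.resids, dtype=int)
        for name in ("n", "ca", "c", "o"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (len(self.resids), 3):
                raise ValueError(f"backbone array {name!r} must be (L, 3)")
            setattr(self, name, arr)

    def __len__(self) -> int:
        return len(self.resids)


def reconstruct_amide_hydrogens(chain: BackboneChain) -> np.ndarray:
    """Place missing amide hydrogens 1.01 Å from N, trans to the previous carbonyl.

    The H direction bisects the N←C(i−1) and N←O(i−1) unit vectors, the
    standard DSSP-style reconstruction.  The first residue (no preceding
    carbonyl) gets NaN and never donates.
    """
    L = len(chain)
    H = np.full((L, 3), np.nan)
    for i in range(1, L):
        v1 = chain.n[i] - chain.c[i - 1]
        v2 = chain.n[i] - chain.o[i - 1]
        v1 /= np.linalg.norm(v1)
        v2 /= np.linalg.norm(v2)
        d = v1 + v2
        nrm = np.linalg.norm(d)
        if nrm < 1e-9:
            continue
        H[i] = chain.n[i] + 1.01 * d / nrm
    return H


def _chain_breaks(chain: BackboneChain) -> np.ndarray:
    """Boolean mask over peptide links: True where C(i)-N(i+1) is broken."""
    gaps = np.linalg.norm(chain.n[1:] - chain.c[:-1], axis=1) > _PEPTIDE_BOND_MAX
    gaps |= np.diff(chain.resids) != 1
    return gaps


def kabsch_sander_energies(chain: BackboneChain) -> np.ndarray:
    """E[i, j] = electrostatic energy (kcal/mol) of CO(i) accepting NH(j).

    E = 0.084·332·(1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN).  Entries are +inf
    where no bond is possible (adjacent residues, missing hydrogen,
    proline donor).
    """
    L = len(chain)
    H = chain.h if chain.h is not None else reconstruct_amide_hydrogens(chain)
    E = np.full((L, L), np.inf)
    is_pro = np.zeros(L, dtype=bool)
    if chain.resnames is not None:
        is_pro = np.array([str(r).upper() == "PRO" for r in chain.resnames])
    for i in range(L):  # acceptor CO
        for j in range(L):  # donor NH
            if abs(i - j) < 2 or is_pro[j] or not np.all(np.isfinite(H[j])):
                continue
            r_on = np.linalg.norm(chain.o[i] - chain.n[j])
            r_ch = np.linalg.norm(chain.c[i] - H[j])
            r_oh = np.linalg.norm(chain.o[i] - H[j])
            r_cn = np.linalg.norm(chain.c[i] - chain.n[j])
            if min(r_on, r_ch, r_oh, r_cn) < 0.5:
                E[i, j] = -9.9  # clashing atoms: treat as bonded, like DSSP
            else:
                E[i, j] = _KS_Q1Q2_F * (1 / r_on + 1 / r_ch - 1 / r_oh - 1 / r_cn)
    return E


def assign_ss(chain: BackboneChain) -> np.ndarray:
    """Per-residue secondary-structure class from the Kabsch–Sander rules.

    n→n+4 turn patterns give α-helix (H), n→n+3 give 3₁₀ (G), n→n+5 give
    π (I); isolated turns give T; β-bridges detected from the ladder rules
    give E.  Priority H > E > G > I > T.  Residues flanking a chain break
    are left unassigned ('-').
    """
    L = len(chain)
    ss = np.full(L, "-", dtype="<U1")
    if L < 3:
        return ss
    E = kabsch_sander_energies(chain)
    hbond = E < _KS_CUTOFF  # hbond[i, j]: CO(i) ... HN(j)

    breaks = _chain_breaks(chain)
    broken = np.zeros(L, dtype=bool)
    broken[:-1] |= breaks
    broken[1:] |= breaks

    # n-turns: turn[n][i] iff CO(i) bonds NH(i+n)
    turn = {}
    for n in (3, 4, 5):
        t = np.zeros(L, dtype=bool)
        for i in range(L - n):
            if hbond[i, i + n] and not np.any(broken[i:i + n + 1]):
                t[i] = True
        turn[n] = t

    def helix_mask(n: int) -> np.ndarray:
        mask = np.zeros(L, dtype=bool)
        for i in range(1, L - n):
            if turn[n][i - 1] and turn[n][i]:
                mask[i:i + n] = True
        return mask

    h_mask = helix_mask(4)
    g_mask = helix_mask(3)
    i_mask = helix_mask(5)

    # minimal β-bridge detection (parallel and antiparallel ladder rules)
    e_mask = np.zeros(L, dtype=bool)
    for i in range(1, L - 1):
        for j in range(i + 3, L - 1):
            parallel = (hbond[i - 1, j] and hbond[j, i + 1]) or \
                       (hbond[j - 1, i] and hbond[i, j + 1])
            anti = (hbond[i, j] and hbond[j, i]) or \
                   (hbond[i - 1, j + 1] and hbond[j - 1, i + 1])
            if parallel or anti:
                e_mask[i] = e_mask[j] = True

    t_mask = np.zeros(L, dtype=bool)
    for n in (3, 4, 5):
        for i in np.flatnonzero(turn[n]):
            t_mask[i + 1:i + n] = True

    for mask, label in ((t_mask, "T"), (i_mask, "I"), (g_mask, "G"),
                        (e_mask, "E"), (h_mask, "H")):
        ss[mask] = label
    ss[broken] = "-"
    return ss


def ss_occupancy(assignments, residue_pos: int) -> dict:
    """Empirical per-class frequency of one residue over frames.

    *assignments* is a sequence of per-frame class arrays (as returned by
    :func:`assign_ss`); *residue_pos* indexes into those arrays.
    """
    if len(assignments) == 0:
        raise ValueError("need at least one frame of assignments")
    counts = dict.fromkeys(SS_CLASSES, 0)
    for frame in assignments:
        if residue_pos >= len(frame):
            raise KeyError(f"residue position {residue_pos} absent from assignment")
        counts[str(frame[residue_pos])] += 1
    total = len(assignments)
    return {k: v / total for k, v in counts.items()}


def hbond_ss_association(bond_present, turn_present):
    """Fisher exact association between an H-bond state and a turn state.

    Builds the 2×2 contingency table of the two boolean series and returns
    ``(odds_ratio, two_sided_p)`` from the exact hypergeometric test.  Used
    to test whether loss of the A48–V52 hydrogen bond coincides with
    formation of the H-bonded turn at the α2 N-end.
    """
    b = np.asarray(bond_present, dtype=bool)
    t = np.asarray(turn_present, dtype=bool)
    if b.shape != t.shape or b.ndim != 1:
        raise ValueError("series must be equal-length 1D")
    if b.all() or (~b).all() or t.all() or (~t).all():
        raise ValueError("constant series: association undefined")
    table = np.array([
        [np.sum(b & t), np.sum(b & ~t)],
        [np.sum(~b & t), np.sum(~b & ~t)],
    ])
    res = sps.fisher_exact(table, alternative="two-sided")
    return float(res.statistic), float(res.pvalue)
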