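"""Structure file I/O, chain mapping and survey classification.

Reads PDB/mmCIF files into a light tabular container, maps protein chains
onto the canonical histone references by pairwise sequence alignment,
classifies whole structures into survey groups (free dimer, dimer complex,
free nucleosome core particle, NCP complex, other), classifies nucleosomal
DNA against the canonical positioning sequences, and converts
crystallographic B-factors to fluctuation estimates.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path

import gemmi
import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Align import PairwiseAligner, substitution_matrices
from Bio.SeqUtils import seq1

__all__ = [
    "MolecularStructure",
    "ChainMapping",
    "DnaClass",
    "STRUCTURE_GROUPS",
    "read_structure",
    "canonical_references",
    "canonical_dna_references",
    "map_chains",
    "classify_structure",
    "classify_dna",
    "filter_by_resolution",
    "rmsf_from_bfactor",
    "write_ca_pdb",
    "dimer_to_ca_chains",
]

STRUCTURE_GROUPS = ("free_dimer", "dimer_complex", "free_ncp", "ncp_complex", "other")

_WATER = {"HOH", "WAT", "DOD", "H2O"}
_DNA_RESNAMES = {"DA", "DC", "DG", "DT", "DN", "DU", "A", "C", "G", "T", "U"}
_AA3 = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
    "MSE", "SEC", "PYL",
}


@dataclass
class MolecularStructure:
    """Chains/residues/atoms plus per-model coordinates.

    ``atoms`` is one row per atom (identical ordering in every model);
    ``coords`` is (n_models, n_atoms, 3) in Å.  ``chains`` lists
    ``(chain_id, polymer_type)`` with polymer_type in {protein, dna, other}.
    """

    atoms: pd.DataFrame
    coords: np.ndarray
    chains: list
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must be (n_models, n_atoms, 3)")
        if self.coords.shape[1] != len(self.atoms):
            raise ValueError("coords width does not match the atom table")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")

    @property
    def n_models(self) -> int:
        return self.coords.shape[0]

    def polymer_type(self, chain_id: str) -> str:
        for cid, kind in self.chains:
            if cid == chain_id:
                return kind
        raise KeyError(f"no chain {chain_id!r}")

    def chain_sequence(self, chain_id: str) -> str:
        """One-letter sequence (protein) or ACGT string (DNA) of a chain."""
        kind = self.polymer_type(chain_id)
        sel = self.atoms[(self.atoms["chain"] == chain_id) & ~self.atoms["is_water"]]
        anchor = "CA" if kind == "protein" else "C1'"
        sel = sel[sel["name"] == anchor].sort_values(["resid", "icode"])
        letters = []
        for rn in sel["resname"]:
            if kind == "protein":
                one = seq1(rn.capitalize()) if rn in _AA3 or len(rn) == 3 else "X"
                if one == "X" and rn not in _AA3:
                    warnings.warn(f"non-standard residue {rn} skipped", stacklevel=2)
                    continue
                letters.append(one)
            else:
                letters.append(rn[-1] if rn[-1] in "ACGTUN" else "N")
        return "".join(letters)


def _resolve_altlocs(df: pd.DataFrame) -> pd.DataFrame:
    """Keep the highest-occupancy altloc of each atom."""
    if (df["altloc"] == "").all():
        return df
    df = df.sort_values("occupancy", ascending=False, kind="stable")
    df = df.drop_duplicates(subset=["chain", "resid", "icode", "name"], keep="first")
    return df.sort_index()


def read_structure(path, fmt: str | None = None) -> MolecularStructure:
    """Read a PDB or mmCIF file (all models, altlocs resolved, waters flagged)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"file not found: {path}")
    try:
        if fmt is None:
            st = gemmi.read_structure(str(path))
        else:
            coor = {"pdb": gemmi.CoorFormat.Pdb,
                    "mmcif": gemmi.CoorFormat.Mmcif}.get(fmt)
            if coor is None:
                raise ValueError(f"unknown format {fmt!r}")
            st = gemmi.read_structure(str(path), format=coor)
    except (RuntimeError, ValueError) as exc:
        if isinstance(exc, ValueError) and "unknown format" in str(exc):
            raise
        raise ValueError(f"malformed structure file {path}: {exc}") from exc
    if len(st) == 0:
        raise ValueError(f"no models in {path}")

    frames = []
    tables = []
    for model in st:
        rows = []
        xyz = []
        for chain in model:
            for res in chain:
                for atom in res:
                    rows.append((
                        chain.name, res.seqid.num, res.seqid.icode.strip(),
                        res.name, atom.name, atom.element.name,
                        float(atom.b_iso), float(atom.occ), atom.altloc.strip(),
                        res.het_flag == "H", res.name in _WATER,
                    ))
                    xyz.append((atom.pos.x, atom.pos.y, atom.pos.z))
        df = pd.DataFrame(rows, columns=[
            "chain", "resid", "icode", "resname", "name", "element",
            "bfactor", "occupancy", "altloc", "hetero", "is_water",
        ])
        df["xyz_row"] = range(len(df))
        df = _resolve_altlocs(df)
        tables.append(df.reset_index(drop=True))
        frames.append(np.asarray(xyz)[df["xyz_row"].to_numpy()])

    key_cols = ["chain", "resid", "icode", "resname", "name"]
    first_key = tables[0][key_cols]
    for t in tables[1:]:
        if len(t) != len(first_key) or not t[key_cols].equals(first_key):
            raise ValueError("models contain inconsistent atom lists")
    atoms = tables[0].drop(columns="xyz_row")

    chain_kinds = []
    for cid in dict.fromkeys(atoms["chain"]):
        res = atoms[(atoms["chain"] == cid) & ~atoms["is_water"]]
        names = res.drop_duplicates(subset=["resid", "icode"])["resname"]
        if len(names) == 0:
            continue
        n_aa = names.isin(_AA3).sum()
        n_dna = names.isin(_DNA_RESNAMES).sum()
        if n_aa >= max(1, 0.5 * len(names)) and n_aa >= n_dna:
            chain_kinds.append((cid, "protein"))
        elif n_dna >= max(1, 0.5 * len(names)):
            chain_kinds.append((cid, "dna"))
        else:
            chain_kinds.append((cid, "other"))

    resolution = float(st.resolution) if st.resolution and st.resolution > 0 else None
    info = dict(st.info)
    method = info.get("_exptl.method") or None
    return MolecularStructure(
        atoms=atoms, coords=np.stack(frames), chains=chain_kinds,
        metadata={"resolution": resolution, "experimental_method": method,
                  "path": str(path)},
    )


# ---------------------------------------------------------------------------
# sequence mapping and classification

@lru_cache(maxsize=1)
def canonical_references() -> dict:
    """Bundled canonical histone sequences (H2A, H2A.Z, H2B, H3, H4)."""
    import importlib.resources
    path = importlib.resources.files("dimerframe") / "data" / "canonical_histones.fasta"
    with path.open() as fh:
        return {rec.id: str(rec.seq) for rec in SeqIO.parse(fh, "fasta")}


@lru_cache(maxsize=1)
def canonical_dna_references() -> dict:
    """Bundled canonical nucleosome-positioning DNA sequences."""
    import importlib.resources
    path = importlib.resources.files("dimerframe") / "data" / "canonical_dna.fasta"
    with path.open() as fh:
        return {rec.id: str(rec.seq) for rec in SeqIO.parse(fh, "fasta")}


def _protein_aligner() -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -0.5
    return aligner


def _dna_aligner() -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = -1.0
    aligner.open_gap_score = -5.0
    aligner.extend_gap_score = -1.0
    return aligner


def _alignment_identity_and_map(alignment):
    """(identity over aligned columns, query position → target position map)."""
    matches = 0
    columns = 0
    pos_map = {}
    q = alignment.query if hasattr(alignment, "query") else None
    target, query = alignment.target, alignment.query
    for (ts, te), (qs, qe) in zip(*alignment.aligned):
        for k in range(te - ts):
            columns += 1
            pos_map[qs + k] = ts + k
            if target[ts + k] == query[qs + k]:
                matches += 1
    if columns == 0:
        return 0.0, {}
    return matches / columns, pos_map


@dataclass
class ChainMapping:
    """Per-chain histone assignment and residue map into canonical numbering.

    ``residue_map[chain]`` maps author residue number → 1-based canonical
    reference index; ``histone_type[chain]`` is "none" when the best
    identity falls below the threshold.
    """

    histone_type: dict
    residue_map: dict
    alignment_identity: dict
    threshold: float

    def histone_chains(self) -> dict:
        return {c: t for c, t in self.histone_type.items() if t != "none"}


def map_chains(structure: MolecularStructure, references: dict | None = None,
               identity_threshold: float = 0.60) -> ChainMapping:
    """Assign each protein chain to a histone type by best global alignment.

    Identity is computed over aligned (non-gap) columns; chains below the
    threshold are left unassigned.  The residue map is injective: author
    residue numbers map one-to-one onto canonical 1-based indices of the
    best-matching reference.
    """
    if references is None:
        references = canonical_references()
    protein_chains = [cid for cid, kind in structure.chains if kind == "protein"]
    if not protein_chains:
        raise ValueError("structure has no protein chains")
    aligner = _protein_aligner()

    histone_type, residue_map, identity = {}, {}, {}
    for cid in protein_chains:
        seq = structure.chain_sequence(cid)
        if not seq:
            raise ValueError(f"chain {cid} has an empty sequence")
        best = ("none", 0.0, {})
        for name, ref in references.items():
            aln = aligner.align(ref, seq)[0]
            ident, pos_map = _alignment_identity_and_map(aln)
            if ident > best[1]:
                best = (name, ident, pos_map)
        name, ident, pos_map = best
        sel = structure.atoms[(structure.atoms["chain"] == cid) &
                              (structure.atoms["name"] == "CA") &
                              ~structure.atoms["is_water"]]
        sel = sel.drop_duplicates(subset=["resid", "icode"]).sort_values(["resid", "icode"])
        author_resids = sel["resid"].tolist()
        if ident >= identity_threshold:
            histone_type[cid] = name
            residue_map[cid] = {author_resids[q]: t + 1 for q, t in pos_map.items()
                                if q < len(author_resids)}
        else:
            histone_type[cid] = "none"
            residue_map[cid] = {}
        identity[cid] = ident
    return ChainMapping(histone_type=histone_type, residue_map=residue_map,
                        alignment_identity=identity, threshold=identity_threshold)


def classify_structure(structure: MolecularStructure, mapping: ChainMapping) -> str:
    """Survey group of a structure (total function over the five labels).

    A free NCP has exactly the octamer's 8 histone chains (2 × H2A or
    H2A.Z, 2 × H2B, 2 × H3, 2 × H4) and 2 DNA chains; with additional
    non-histone protein chains it is an NCP complex.  A single H2A+H2B
    pair alone is a free dimer; with extra non-histone proteins, a dimer
    complex.  Everything else is "other".
    """
    n_dna = sum(1 for _, kind in structure.chains if kind == "dna")
    counts = {"H2A": 0, "H2B": 0, "H3": 0, "H4": 0}
    n_other_protein = 0
    for cid, kind in structure.chains:
        if kind != "protein":
            continue
        htype = mapping.histone_type.get(cid, "none")
        if htype in ("H2A", "H2A.Z"):
            counts["H2A"] += 1
        elif htype in counts:
            counts[htype] += 1
        else:
            n_other_protein += 1

    octamer = (counts["H2A"] == 2 and counts["H2B"] == 2 and
               counts["H3"] == 2 and counts["H4"] == 2)
    single_dimer = (counts["H2A"] == 1 and counts["H2B"] == 1 and
                    counts["H3"] == 0 and counts["H4"] == 0)
    if octamer and n_dna == 2:
        return "ncp_complex" if n_other_protein else "free_ncp"
    if single_dimer and n_dna == 0:
        return "dimer_complex" if n_other_protein else "free_dimer"
    return "other"


@dataclass(frozen=True)
class DnaClass:
    """Best-matching canonical DNA sequence, or excluded below threshold."""

    label: str  # widom601 | alphasat146 | alphasat147 | excluded
    best_identity: float


def classify_dna(sequence: str, canon: dict | None = None,
                 identity_threshold: float = 0.80) -> DnaClass:
    """Classify a nucleosomal DNA sequence against the canonical references."""
    seq = str(sequence).upper().replace("U", "T")
    if not seq:
        raise ValueError("empty DNA sequence")
    if set(seq) - set("ACGTN"):
        raise ValueError("sequence must be over {A, C, G, T, N}")
    if canon is None:
        canon = canonical_dna_references()
    aligner = _dna_aligner()
    best_label, best_ident = "excluded", 0.0
    for name, ref in canon.items():
        aln = aligner.align(ref.upper(), seq)[0]
        ident, _ = _alignment_identity_and_map(aln)
        if ident > best_ident:
            best_label, best_ident = name, ident
    if best_ident < identity_threshold:
        return DnaClass(label="excluded", best_identity=best_ident)
    return DnaClass(label=best_label, best_identity=best_ident)


def filter_by_resolution(entries, cutoff: float = 4.0) -> list:
    """Keep entries resolved to the cutoff or finer; flag resolution-less ones.

    Returns ``[(entry, no_resolution_flag), ...]``: diffraction/EM entries
    with resolution ≤ cutoff are retained unflagged, entries without a
    resolution value (NMR models) are retained with the flag set, and
    coarser entries are dropped.
    """
    if cutoff <= 0:
        raise ValueError("resolution cutoff must be positive")
    out = []
    for entry in entries:
        res = entry.metadata.get("resolution")
        if res is None:
            out.append((entry, True))
        elif res <= cutoff:
            out.append((entry, False))
    return out


def rmsf_from_bfactor(b) -> float:
    """RMSF (Å) from a crystallographic B-factor (Ų): √(3B / 8π²)."""
    b_arr = np.asarray(b, dtype=float)
    if np.any(b_arr < 0):
        raise ValueError("B-factor must be non-negative")
    out = np.sqrt(3.0 * b_arr / (8.0 * math.pi ** 2))
    return float(out) if np.isscalar(b) or b_arr.ndim == 0 else out


# ---------------------------------------------------------------------------
# fixture/ensemble PDB emission

def dimer_to_ca_chains(dimer, chain_ids=("A", "B")) -> list:
    """Convert a DimerModel into chain records with canonical residue names.

    Residue names are taken from the bundled canonical sequence of each
    chain's histone type at the canonical residue index (ALA where the
    index exceeds the reference), so the emitted file round-trips through
    sequence mapping.
    """
    from Bio.SeqUtils import seq3

    refs = canonical_references()
    out = []
    for cid, chain in zip(chain_ids, dimer.chains):
        ref = refs.get(chain, "")
        resids, resnames, rows = [], [], []
        for i, (c, r) in enumerate(dimer.labels):
            if c != chain:
                continue
            resids.append(r)
            one = ref[r - 1] if 0 < r <= len(ref) else "A"
            resnames.append(seq3(one).upper())
            rows.append(i)
        out.append({"chain_id": cid, "resids": resids, "resnames": resnames,
                    "atom_rows": rows, "atom_name": "CA"})
    return out


def write_ca_pdb(path, chains: list, models: list | np.ndarray) -> None:
    """Write a (multi-)model PDB of single-atom-per-residue chains.

    *chains* holds dicts with ``chain_id``, ``resids``, ``resnames``,
    ``atom_rows`` (indices into each model's coordinate array) and
    ``atom_name``; *models* is an iterable of (N, 3) coordinate arrays.
    """
    models = np.asarray(models, dtype=float)
    if models.ndim == 2:
        models = models[None]
    lines = []
    multi = len(models) > 1
    for m, coords in enumerate(models, start=1):
        if multi:
            lines.append(f"MODEL     {m:4d}")
        serial = 1
        for ch in chains:
            name = ch.get("atom_name", "CA")
            element = name[0]
            for resid, resname, row in zip(ch["resids"], ch["resnames"],
                                           ch["atom_rows"]):
                x, y, z = coords[row]
                atom_field = f" {name:<3s}" if len(name) < 4 else name
                lines.append(
                    f"ATOM  {serial:5d} {atom_field}{'':1s}{resname:>3s} "
                    f"{ch['chain_id']:1s}{resid:4d}    "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
                    f"          {element:>2s}"
                )
                serial += 1
            lines.append("TER")
        if multi:
            lines.append("ENDMDL")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")
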