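"""End-to-end analysis flows: ensemble analysis and structure surveys.

``analyze_dimer_ensemble`` reproduces the trajectory workflow: map the
input to the canonical dimer, build the dimer reference frame from the
first conformation, align all frames on the histone-fold α-helix Cα atoms,
then compute the bending-angle series, PCA modes, mode projections,
helix amplitudes, RMSF profile and the angle-distribution statistics.

``survey_structures`` reproduces the structure-survey workflow: classify
each file into a survey group, extract and align every mappable H2A-H2B
dimer to a common reference positioned in its DRF, and compute per-group
RMSV profiles and 2D projections.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import frames as frames_mod
from . import modes as modes_mod
from . import plasticity, stats, structure_io
from .core import ConformationEnsemble, DimerModel

__all__ = [
    "AnalysisConfig",
    "DimerEnsembleReport",
    "SurveyResult",
    "structure_to_dimer",
    "ensemble_from_structure",
    "analyze_dimer_ensemble",
    "survey_structures",
]

# canonical residue ranges (inclusive) of the annotated structural elements
DEFAULT_SEGMENTS = {
    "H2A": {
        "alpha1ext": (16, 22), "alpha1": (27, 37), "L1": (38, 45),
        "alpha2": (46, 73), "L2": (74, 78), "alpha3": (79, 88),
        "alphaC": (91, 97), "docking": (92, 119),
    },
    "H2B": {
        "alpha1": (37, 47), "L1": (48, 54), "alpha2": (55, 82),
        "L2": (83, 87), "alpha3": (88, 97), "alphaC": (100, 120),
    },
}


@dataclass
class AnalysisConfig:
    """Thresholds, annotations and numeric choices of the analysis flows."""

    segments: dict = field(default_factory=lambda: {
        c: dict(v) for c, v in DEFAULT_SEGMENTS.items()})
    identity_threshold: float = 0.60
    resolution_cutoff: float = 4.0  # Å
    hbond_max_da: float = 3.0  # Å
    hbond_min_angle: float = 120.0  # degrees
    unwrap_cutoff: float = 7.0  # Å
    kde_bandwidth: float | None = None  # None = Scott's rule
    n_modes: int = 10
    drf_criterion: str = "mean_abs"  # or "variance"
    seed: int = 0

    def __post_init__(self) -> None:
        for chain, segs in self.segments.items():
            ranges = sorted((tuple(v) for k, v in segs.items() if k != "docking"))
            for (a1, b1), (a2, b2) in zip(ranges, ranges[1:]):
                if a2 <= b1:
                    raise ValueError(
                        f"overlapping segment ranges in chain {chain}")
        for name in ("identity_threshold", "resolution_cutoff", "hbond_max_da",
                     "unwrap_cutoff"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if "segments" in data:
            data["segments"] = {
                c: {k: tuple(v) for k, v in segs.items()}
                for c, segs in data["segments"].items()
            }
        return cls(**data)

    def digest(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


_CHAIN_KEY = {"H2A": "H2A", "H2A.Z": "H2A", "H2B": "H2B"}


def structure_to_dimer(structure, mapping=None,
                       config: AnalysisConfig | None = None,
                       model: int = 0) -> DimerModel:
    """Extract one H2A(-variant)-H2B dimer as a canonical-numbered model.

    Picks the first chain mapped to H2A/H2A.Z and the first mapped to H2B,
    takes their Cα atoms, relabels residues with canonical indices and
    annotates segments from the config, clipped to the residues present.
    """
    config = config or AnalysisConfig()
    if mapping is None:
        mapping = structure_io.map_chains(
            structure, identity_threshold=config.identity_threshold)
    picked = {}
    variant = None
    for cid, htype in mapping.histone_type.items():
        key = _CHAIN_KEY.get(htype)
        if key and key not in picked:
            picked[key] = cid
            if htype == "H2A.Z":
                variant = "H2A.Z"
    if set(picked) != {"H2A", "H2B"}:
        raise ValueError("structure does not map to an H2A(-variant)-H2B dimer")

    atoms = structure.atoms
    labels, rows = [], []
    for key in ("H2A", "H2B"):
        cid = picked[key]
        rmap = mapping.residue_map[cid]
        sel = atoms[(atoms["chain"] == cid) & (atoms["name"] == "CA") &
                    ~atoms["is_water"]]
        sel = sel.drop_duplicates(subset=["resid", "icode"]).sort_values(
            ["resid", "icode"])
        for idx, resid in zip(sel.index, sel["resid"]):
            if resid in rmap:
                labels.append((key, int(rmap[resid])))
                rows.append(idx)
    coords = structure.coords[model][rows]

    segments = {}
    present = {}
    for chain, resid in labels:
        present.setdefault(chain, set()).add(resid)
    for chain in ("H2A", "H2B"):
        segments[chain] = {}
        for seg, (first, last) in config.segments[chain].items():
            inside = sorted(r for r in present[chain] if first <= r <= last)
            if inside:
                segments[chain][seg] = (inside[0], inside[-1])
    name = Path(structure.metadata.get("path", "structure")).stem
    dimer = DimerModel(labels=labels, coords=coords, segments=segments, name=name)
    dimer.variant = variant or "H2A"
    return dimer


def ensemble_from_structure(structure, mapping=None,
                            config: AnalysisConfig | None = None):
    """All models of a multi-model structure as a (template, ensemble) pair."""
    config = config or AnalysisConfig()
    template = structure_to_dimer(structure, mapping, config, model=0)
    if mapping is None:
        mapping = structure_io.map_chains(
            structure, identity_threshold=config.identity_threshold)
    frames_list = [structure_to_dimer(structure, mapping, config, model=m).coords
                   for m in range(structure.n_models)]
    ens = ConformationEnsemble(frames=np.stack(frames_list),
                               labels=list(template.labels),
                               segments=dict(template.segments))
    return template, ens


@dataclass
class DimerEnsembleReport:
    """Bundle of every quantity the ensemble analysis computes."""

    template: DimerModel
    drf: object
    ensemble: ConformationEnsemble  # aligned, in DRF coordinates
    angles: np.ndarray  # degrees, per frame
    decomposition: object
    projections: np.ndarray  # frames onto mode 1, sign-canonicalized
    angle_mode_r: float
    amplitudes: pd.DataFrame
    rmsf: object
    density: object
    angle_mode: float
    angle_spread: float
    free_energy: object
    provenance: dict

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        pd.DataFrame({"frame": np.arange(len(self.angles)),
                      "theta_deg": self.angles,
                      "mode1_projection": self.projections}).to_csv(
            out / "angles.tsv", sep="\t", index=False)
        fr = self.decomposition.variance_fractions
        pd.DataFrame({"mode": np.arange(1, len(fr) + 1),
                      "eigenvalue_A2": self.decomposition.eigenvalues,
                      "variance_fraction": fr}).to_csv(
            out / "modes.tsv", sep="\t", index=False)
        self.amplitudes.to_csv(out / "amplitudes.tsv", sep="\t", index=False)
        self.rmsf.to_frame().to_csv(out / "rmsf.tsv", sep="\t", index=False)
        pd.DataFrame({"theta_deg": self.density.grid,
                      "density": self.density.density,
                      "delta_g_kt": self.free_energy.delta_g}).to_csv(
            out / "angle_distribution.tsv", sep="\t", index=False)
        (out / "report.yaml").write_text(yaml.safe_dump({
            "drf": self.drf.to_dict(),
            "angle_mode_deg": float(self.angle_mode),
            "angle_spread_deg": float(self.angle_spread),
            "angle_mode_correlation": float(self.angle_mode_r),
            "provenance": self.provenance,
        }))


def analyze_dimer_ensemble(structure, config: AnalysisConfig | None = None,
                           out_dir=None) -> DimerEnsembleReport:
    """Full bending analysis of a multi-model dimer structure or ensemble.

    Accepts a :class:`MolecularStructure`, a path, or a prebuilt
    ``(template, ensemble)`` pair.  The first conformation defines the DRF;
    all frames are aligned on the histone-fold α-helix Cα atoms to that
    conformation positioned in the DRF.
    """
    config = config or AnalysisConfig()
    if isinstance(structure, (str, Path)):
        structure = structure_io.read_structure(structure)
    if isinstance(structure, tuple):
        template, ensemble = structure
    else:
        template, ensemble = ensemble_from_structure(structure, config=config)
    if ensemble.n_frames < 2:
        raise ValueError("ensemble analysis needs at least 2 frames")

    axis = frames_mod.pseudosymmetry_axis(template)
    drf = frames_mod.build_drf(template, axis, criterion=config.drf_criterion)
    # express the reference conformation in DRF coordinates, then align
    reference = drf.to_local(template.coords)
    template_drf = DimerModel(labels=list(template.labels), coords=reference,
                              segments=dict(template.segments),
                              name=template.name)
    fold = template.fold_indices()
    aligned = frames_mod.align_ensemble(ensemble, reference, fold)

    angles = plasticity.alpha2_angle_series(aligned, template_drf)
    decomposition = modes_mod.pca_modes(aligned)
    raw_proj = modes_mod.project_trajectory(
        aligned, decomposition.eigenvectors[:, 0],
        decomposition.mean_conformation)
    r, projections = modes_mod.angle_mode_correlation(angles, raw_proj)

    rows = []
    for chain in ("H2A", "H2B"):
        for end, resid in zip(("N", "C"), template_drf.segment_range(chain, "alpha2")):
            rows.append({
                "chain": chain, "helix": "alpha2", "end": end,
                "amplitude_A": plasticity.helix_amplitude(aligned, chain, resid),
            })
    amplitudes = pd.DataFrame(rows)
    rmsf = plasticity.rmsf_profile(aligned)

    density = stats.kde(angles, bandwidth=config.kde_bandwidth)
    angle_mode = stats.kde_mode(angles, bandwidth=config.kde_bandwidth)
    angle_spread = stats.spread(angles)
    fe = stats.free_energy(angles, bandwidth=config.kde_bandwidth)

    report = DimerEnsembleReport(
        template=template_drf, drf=drf, ensemble=aligned, angles=angles,
        decomposition=decomposition, projections=projections, angle_mode_r=r,
        amplitudes=amplitudes, rmsf=rmsf, density=density,
        angle_mode=angle_mode, angle_spread=angle_spread, free_energy=fe,
        provenance={"config_digest": config.digest(), "seed": config.seed,
                    "n_frames": int(aligned.n_frames),
                    "n_atoms": int(aligned.n_atoms)},
    )
    if out_dir is not None:
        report.write(out_dir)
    return report


@dataclass
class SurveyResult:
    """Per-file classification plus per-group variation profiles."""

    table: pd.DataFrame  # path, group, dna_class, resolution
    rmsv: dict  # group -> FluctuationProfile
    projections: pd.DataFrame  # path, group, chain, resid, x, y (DRF plane)
    reference: DimerModel

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.table.to_csv(out / "groups.tsv", sep="\t", index=False)
        for group, profile in self.rmsv.items():
            profile.to_frame().to_csv(out / f"rmsv_{group}.tsv", sep="\t",
                                      index=False)
        self.projections.to_csv(out / "projections.tsv", sep="\t", index=False)


def survey_structures(paths, config: AnalysisConfig | None = None,
                      reference: DimerModel | None = None,
                      out_dir=None) -> SurveyResult:
    """Classify structure files and compare their dimers in a common DRF."""
    config = config or AnalysisConfig()
    paths = list(paths)
    if len(paths) < 2:
        raise ValueError("a survey needs at least 2 input files")
    if reference is None:
        from .synthetic import synthetic_dimer
        reference = synthetic_dimer(angle=142.0)
    axis = frames_mod.pseudosymmetry_axis(reference)
    drf = frames_mod.build_drf(reference, axis, criterion=config.drf_criterion)
    ref_drf = DimerModel(labels=list(reference.labels),
                         coords=drf.to_local(reference.coords),
                         segments=dict(reference.segments), name="reference")
    ref_fold = ref_drf.fold_indices()
    ref_fold_labels = [ref_drf.labels[i] for i in ref_fold]

    rows, aligned_dimers, proj_rows = [], [], []
    for path in paths:
        st = structure_io.read_structure(path)
        mapping = structure_io.map_chains(
            st, identity_threshold=config.identity_threshold)
        group = structure_io.classify_structure(st, mapping)
        dna_label = ""
        dna_chains = [cid for cid, kind in st.chains if kind == "dna"]
        if dna_chains:
            seqs = [st.chain_sequence(c) for c in dna_chains]
            dna_label = structure_io.classify_dna(max(seqs, key=len)).label
        rows.append({"path": str(path), "group": group, "dna_class": dna_label,
                     "resolution": st.metadata.get("resolution")})
        try:
            dimer = structure_to_dimer(st, mapping, config)
        except ValueError:
            continue
        # superpose on the fold Cα atoms shared with the reference
        shared = [lab for lab in ref_fold_labels if lab in set(dimer.labels)]
        if len(shared) < 3:
            continue
        mob = np.array([dimer.coords[dimer.atom_index(*lab)] for lab in shared])
        tgt = np.array([ref_drf.coords[ref_drf.atom_index(*lab)] for lab in shared])
        transform, _ = frames_mod.kabsch_superpose(mob, tgt)
        placed = dimer.transformed(transform)
        placed.group = group
        aligned_dimers.append(placed)
        for chain in placed.chains:
            if "alpha2" not in placed.segments.get(chain, {}):
                continue
            for i in placed.segment_indices(chain, "alpha2"):
                x, y = plasticity.project_2d(placed.coords[i], drf_identity(), "xy")
                proj_rows.append({"path": str(path), "group": group,
                                  "chain": chain, "resid": placed.labels[i][1],
                                  "x": x, "y": y})
    if not aligned_dimers:
        raise ValueError("no mappable H2A-H2B dimers among the inputs")

    rmsv = {}
    by_group: dict = {}
    for d in aligned_dimers:
        by_group.setdefault(d.group, []).append(d)
    for group, members in by_group.items():
        if len(members) >= 2:
            rmsv[group] = plasticity.rmsv_profile(members)

    result = SurveyResult(table=pd.DataFrame(rows), rmsv=rmsv,
                          projections=pd.DataFrame(proj_rows),
                          reference=ref_drf)
    if out_dir is not None:
        result.write(out_dir)
    return result


def drf_identity():
    """The lab frame (identity DRF) for coordinates already expressed in a DRF."""
    from .core import ReferenceFrame
    return ReferenceFrame(origin=np.zeros(3), x=np.array([1.0, 0, 0]),
                          y=np.array([0, 1.0, 0]), z=np.array([0, 0, 1.0]))
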