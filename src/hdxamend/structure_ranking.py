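"""HDX-guided ranking of structural decoys and native-fold classification.

Protection factors are estimated from a single conformation with the
phenomenological contacts + hydrogen-bonds model

    lnP_i = beta_c * N_c(i) + beta_h * N_h(i)

where ``N_c(i)`` counts heavy atoms within ``contact_cutoff`` of residue i's
amide nitrogen (sequence-adjacent residues excluded) and ``N_h(i)`` counts
backbone carbonyl oxygens hydrogen-bonded to that amide (N...O distance
criterion; inputs need not contain hydrogens).  Uptake simulated from each
decoy's profile is scored by RMSE against a reference uptake table; ranking
quality over native/non-native labels is quantified by ROC/AUC, i.e. the
probability that a randomly chosen native decoy outranks a randomly chosen
non-native one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage
from sklearn.metrics import roc_auc_score, roc_curve

from Bio.PDB import PDBIO, PDBParser, StructureBuilder
from Bio.SVDSuperimposer import SVDSuperimposer
from Bio.SeqUtils import seq1

from .core_io import (
    AlignmentError,
    HdxError,
    ProtectionProfile,
    StructuralError,
    UptakeTable,
    get_logger,
    make_rng,
)
from .forward_model import simulate_dataset
from .intrinsic_rates import RateSet
from .core_io import compare_uptake

logger = get_logger(__name__)

BACKBONE_ATOMS = ("N", "CA", "C", "O")

DEFAULT_BETA_CONTACTS = 0.35
DEFAULT_BETA_HBONDS = 2.0
DEFAULT_CONTACT_CUTOFF = 6.5  # Angstrom
DEFAULT_HBOND_CUTOFF = 2.4  # Angstrom, N...O
NATIVE_RMSD_THRESHOLD = 2.5  # Angstrom


@dataclass
class Structure:
    """Flat atom-record view of a single-chain protein conformation."""

    structure_id: str
    atom_names: np.ndarray  # (n_atoms,) str
    res_indices: np.ndarray  # (n_atoms,) int, 1-based and contiguous
    res_names: np.ndarray  # (n_atoms,) 3-letter str
    coords: np.ndarray  # (n_atoms, 3) Angstrom
    elements: np.ndarray  # (n_atoms,) str

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if not np.all(np.isfinite(self.coords)):
            raise StructuralError("non-finite coordinates")
        idx = np.unique(self.res_indices)
        if idx.size and not np.array_equal(idx, np.arange(idx[0], idx[0] + idx.size)):
            raise StructuralError("residue indices must be contiguous")

    @property
    def n_residues(self) -> int:
        return int(np.unique(self.res_indices).size)

    @property
    def sequence(self) -> str:
        order = []
        seen = set()
        for ri, rn in zip(self.res_indices, self.res_names):
            if ri not in seen:
                seen.add(ri)
                order.append(rn)
        return "".join(seq1(rn) for rn in order)

    def backbone_coords(self) -> np.ndarray:
        """(4 * n_residues, 3) backbone coordinates in N, CA, C, O order."""
        rows = []
        for ri in np.unique(self.res_indices):
            sel = self.res_indices == ri
            for name in BACKBONE_ATOMS:
                hit = np.flatnonzero(sel & (self.atom_names == name))
                if hit.size != 1:
                    raise StructuralError(
                        f"residue {ri}: expected one {name} atom, found {hit.size}"
                    )
                rows.append(self.coords[hit[0]])
        return np.asarray(rows)

    def atom_coords(self, name: str) -> np.ndarray:
        """(n_residues, 3) coordinates of one named backbone atom per residue;
        rows of NaN where the atom is absent."""
        out = np.full((self.n_residues, 3), np.nan)
        start = int(np.min(self.res_indices))
        for i, ri in enumerate(range(start, start + self.n_residues)):
            hit = np.flatnonzero((self.res_indices == ri) & (self.atom_names == name))
            if hit.size:
                out[i] = self.coords[hit[0]]
        return out

    def with_coords(self, coords: np.ndarray, structure_id: str) -> "Structure":
        return Structure(structure_id, self.atom_names.copy(), self.res_indices.copy(),
                         self.res_names.copy(), np.asarray(coords, float),
                         self.elements.copy())


def read_structure(path: str | Path, structure_id: str | None = None) -> Structure:
    """Read the first model / first chain of a PDB file (heavy atoms only)."""
    parser = PDBParser(QUIET=True)
    model = next(parser.get_structure(structure_id or Path(path).stem, str(path)).get_models())
    chain = next(model.get_chains())
    names, resi, resn, xyz, elem = [], [], [], [], []
    for res in chain:
        if res.id[0] != " ":  # skip heteroatoms/waters
            continue
        for atom in res:
            if atom.element == "H":
                continue
            names.append(atom.get_name())
            resi.append(res.id[1])
            resn.append(res.get_resname())
            xyz.append(atom.coord)
            elem.append(atom.element)
    return Structure(structure_id or Path(path).stem, np.array(names), np.array(resi),
                     np.array(resn), np.array(xyz, dtype=float), np.array(elem))


def write_structure(s: Structure, path: str | Path) -> None:
    builder = StructureBuilder.StructureBuilder()
    builder.init_structure(s.structure_id)
    builder.init_model(0)
    builder.init_chain("A")
    builder.init_seg("    ")
    current = None
    serial = 1
    for i in range(s.res_indices.size):
        ri = int(s.res_indices[i])
        if ri != current:
            builder.init_residue(str(s.res_names[i]), " ", ri, " ")
            current = ri
        builder.init_atom(str(s.atom_names[i]), s.coords[i].astype(np.float32),
                          0.0, 1.0, " ", str(s.atom_names[i]).ljust(3), serial,
                          element=str(s.elements[i]))
        serial += 1
    io = PDBIO()
    io.set_structure(builder.get_structure())
    io.save(str(path))


# ---------------------------------------------------------------------------
# Protection factors from structure
# ---------------------------------------------------------------------------


def protection_from_structure(
    s: Structure,
    beta_contacts: float = DEFAULT_BETA_CONTACTS,
    beta_hbonds: float = DEFAULT_BETA_HBONDS,
    contact_cutoff: float = DEFAULT_CONTACT_CUTOFF,
    hbond_cutoff: float = DEFAULT_HBOND_CUTOFF,
) -> ProtectionProfile:
    """Phenomenological lnP = beta_c * N_c + beta_h * N_h per residue.

    Contacts exclude atoms of the residue itself and its sequence
    neighbours; hydrogen bonds are carbonyl oxygens within ``hbond_cutoff``
    of the amide nitrogen (same exclusion).  Prolines, residue 1 and
    residues without an amide nitrogen are masked.
    """
    n_res = s.n_residues
    start = int(np.min(s.res_indices))
    amide_n = s.atom_coords("N")
    carbonyl_o = s.atom_coords("O")
    lnp = np.full(n_res, np.nan)
    mask = np.ones(n_res, dtype=bool)
    seq = s.sequence
    for i in range(n_res):
        if i == 0 or seq[i] == "P":
            continue
        if not np.all(np.isfinite(amide_n[i])):
            warnings.warn(f"residue {start + i}: missing amide nitrogen; masked",
                          stacklevel=2)
            continue
        ri = start + i
        keep = np.abs(s.res_indices - ri) > 1  # exclude i-1, i, i+1
        d = np.linalg.norm(s.coords[keep] - amide_n[i], axis=1)
        n_c = int(np.sum(d <= contact_cutoff))
        keep_o = np.abs(np.arange(start, start + n_res) - ri) > 1
        do = np.linalg.norm(carbonyl_o[keep_o] - amide_n[i], axis=1)
        n_h = int(np.sum(do[np.isfinite(do)] <= hbond_cutoff))
        lnp[i] = beta_contacts * n_c + beta_hbonds * n_h
        mask[i] = False
    return ProtectionProfile(s.structure_id, lnp, mask)


# ---------------------------------------------------------------------------
# Superposition RMSD, decoy labelling, ranking
# ---------------------------------------------------------------------------


def backbone_rmsd(a: Structure, b: Structure) -> float:
    """Least-squares optimal-superposition RMSD over backbone atoms (A)."""
    if a.n_residues != b.n_residues:
        raise AlignmentError("structures have different residue counts")
    x, y = a.backbone_coords(), b.backbone_coords()
    if x.shape != y.shape:
        raise AlignmentError("backbone atom counts differ")
    sup = SVDSuperimposer()
    sup.set(x, y)
    sup.run()
    return float(sup.get_rms())


@dataclass
class DecoySet:
    structures: list
    reference: Structure
    labels: np.ndarray | None = None  # True = native
    scores: np.ndarray | None = None  # RMSE (RFU), lower = more native-like
    rmsd: np.ndarray | None = None
    meta: dict = field(default_factory=dict)


def label_decoys(decoys: DecoySet, threshold: float = NATIVE_RMSD_THRESHOLD) -> DecoySet:
    """Native iff backbone RMSD to the reference is strictly below threshold."""
    rmsd = np.array([backbone_rmsd(d, decoys.reference) for d in decoys.structures])
    decoys.rmsd = rmsd
    decoys.labels = rmsd < threshold
    return decoys


def rank_and_auc(
    reference_uptake: UptakeTable,
    decoys: DecoySet,
    rates: RateSet,
    times=None,
    beta_contacts: float = DEFAULT_BETA_CONTACTS,
    beta_hbonds: float = DEFAULT_BETA_HBONDS,
    contact_cutoff: float = DEFAULT_CONTACT_CUTOFF,
    hbond_cutoff: float = DEFAULT_HBOND_CUTOFF,
) -> tuple[DecoySet, float, np.ndarray]:
    """Score every decoy by simulated-uptake RMSE against the reference and
    compute the ROC/AUC of the resulting native/non-native ranking.

    Returns (decoys with scores, auc, roc) where roc is an (n, 2) array of
    (false positive rate, true positive rate) points.
    """
    if decoys.labels is None:
        raise StructuralError("label decoys before ranking")
    times = reference_uptake.times if times is None else np.asarray(times, float)
    scores = np.full(len(decoys.structures), np.nan)
    for i, d in enumerate(decoys.structures):
        try:
            profile = protection_from_structure(
                d, beta_contacts, beta_hbonds, contact_cutoff, hbond_cutoff
            )
            sim = simulate_dataset(reference_uptake.map, profile, rates, times)
            _, scores[i] = compare_uptake(sim, reference_uptake)
        except HdxError as exc:
            logger.warning("decoy %s excluded: %s", d.structure_id, exc)
    ok = np.isfinite(scores)
    labels = decoys.labels[ok]
    # lower RMSE = more native-like; negate for the standard score convention
    auc = float(roc_auc_score(labels, -scores[ok]))
    fpr, tpr, _ = roc_curve(labels, -scores[ok])
    decoys.scores = scores
    decoys.meta["auc"] = auc
    decoys.meta["n_excluded"] = int((~ok).sum())
    return decoys, auc, np.column_stack([fpr, tpr])


# ---------------------------------------------------------------------------
# Decoy generation and a synthetic reference fold
# ---------------------------------------------------------------------------


def perturb_decoys(
    reference: Structure,
    n: int,
    scale_schedule=None,
    seed=None,
    smoothing: float = 4.0,
) -> DecoySet:
    """Decoys from seeded smooth correlated coordinate perturbations.

    Each decoy displaces every residue by a random 3-vector field smoothed
    along the sequence (``smoothing`` residues) and scaled so the decoy set
    spans a graded range of backbone RMSDs.  ``scale_schedule`` gives the
    RMS displacement magnitude (A) per decoy; the default ramps linearly
    from 0 to 5 A.
    """
    if n < 2:
        raise ValueError("need at least 2 decoys")
    rng = make_rng(seed)
    scales = (np.linspace(0.0, 5.0, n) if scale_schedule is None
              else np.asarray(scale_schedule, dtype=float))
    if scales.size != n:
        raise ValueError("scale_schedule length must equal n")
    n_res = reference.n_residues
    start = int(np.min(reference.res_indices))
    structures = []
    for i in range(n):
        field_ = ndimage.gaussian_filter1d(rng.normal(size=(n_res, 3)), sigma=smoothing,
                                           axis=0, mode="nearest")
        rms = np.sqrt(np.mean(np.sum(field_**2, axis=1)))
        disp = field_ * (scales[i] / rms) if rms > 0 else field_ * 0.0
        per_atom = disp[reference.res_indices - start]
        structures.append(
            reference.with_coords(reference.coords + per_atom, f"decoy_{i:04d}")
        )
    return DecoySet(structures, reference, meta={"scales": scales, "seed": seed})


_HELIX_RISE = 1.5
_HELIX_RADIUS = 2.3
_HELIX_TWIST = np.deg2rad(100.0)

_AA3 = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS", "Q": "GLN",
    "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE", "L": "LEU", "K": "LYS",
    "M": "MET", "F": "PHE", "P": "PRO", "S": "SER", "T": "THR", "W": "TRP",
    "Y": "TYR", "V": "VAL",
}


def make_synthetic_structure(sequence: str, structure_id: str = "synthetic") -> Structure:
    """Synthetic helix-hairpin fold (two packed antiparallel helices).

    A stand-in reference conformation for tests and synthetic benchmarks:
    the CA trace runs up one ideal alpha-helix, turns, and returns down a
    second helix packed 10 A away, producing both local and tertiary
    contacts.  Backbone N, C and O positions are placed geometrically from
    the CA trace; the geometry is idealised, not energy-minimised.
    """
    n = len(sequence)
    half = n // 2
    ca = np.zeros((n, 3))
    for i in range(n):
        if i < half:
            t = i
            ca[i] = [_HELIX_RADIUS * np.cos(_HELIX_TWIST * t),
                     _HELIX_RADIUS * np.sin(_HELIX_TWIST * t),
                     _HELIX_RISE * t]
        else:
            t = i - half
            ca[i] = [10.0 + _HELIX_RADIUS * np.cos(-_HELIX_TWIST * t),
                     _HELIX_RADIUS * np.sin(-_HELIX_TWIST * t),
                     _HELIX_RISE * (half - 1 - t)]
    names, resi, resn, xyz, elem = [], [], [], [], []
    for i in range(n):
        prev_dir = ca[i] - ca[i - 1] if i > 0 else ca[1] - ca[0]
        next_dir = ca[i + 1] - ca[i] if i < n - 1 else ca[-1] - ca[-2]
        prev_dir = prev_dir / np.linalg.norm(prev_dir)
        next_dir = next_dir / np.linalg.norm(next_dir)
        perp = np.cross(prev_dir, next_dir)
        if np.linalg.norm(perp) < 1e-6:
            perp = np.cross(prev_dir, [0.0, 0.0, 1.0])
        perp = perp / np.linalg.norm(perp)
        positions = {
            "N": ca[i] - 1.45 * prev_dir,
            "CA": ca[i],
            "C": ca[i] + 1.52 * next_dir,
            "O": ca[i] + 1.52 * next_dir + 1.23 * perp,
        }
        for name in BACKBONE_ATOMS:
            names.append(name)
            resi.append(i + 1)
            resn.append(_AA3[sequence[i]])
            xyz.append(positions[name])
            elem.append(name[0])
    return Structure(structure_id, np.array(names), np.array(resi), np.array(resn),
                     np.array(xyz), np.array(elem))
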