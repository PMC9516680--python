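"""Structure containers, PDB I/O, loop selection and synthetic fixtures.

The package operates on single protein chains with a designated flexible
loop.  A :class:`Structure` is a flat table of heavy atoms; a
:class:`LoopSpec` names the flexible span; :func:`select_loop` partitions
the atoms into the *mobile* set (loop heavy atoms plus the N/CA/C of the
rigid C-terminal anchor residue) and the fixed *environment* set (heavy
atoms of all other residues near the loop) that grounds the elastic
network in the context of the whole protein.

:func:`build_synthetic_loop` constructs ideal-geometry poly-alanine loops
(standard bond lengths and angles, caller-chosen phi/psi) embedded between
two rigid anchor residues, optionally decorated with a scaffold shell, so
that every downstream module can be exercised without any deposited
structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from Bio.Data.IUPACData import atom_weights
from Bio.PDB import PDBParser

from .errors import (
    ChainBreakError,
    LoopModesError,
    MissingAtomError,
    PDBFormatError,
)

BACKBONE_NAMES = ("N", "CA", "C", "O")

#: ideal backbone geometry used by the fixture generator (Engh--Huber-style)
IDEAL_GEOMETRY = {
    "b_N_CA": 1.458,
    "b_CA_C": 1.525,
    "b_C_N": 1.329,
    "b_C_O": 1.231,
    "b_CA_CB": 1.530,
    "a_N_CA_C": 111.2,
    "a_CA_C_N": 116.6,
    "a_C_N_CA": 121.9,
    "a_CA_C_O": 120.8,
    "a_C_CA_CB": 110.1,
    "omega": 180.0,
}


@dataclass
class Structure:
    """Flat heavy-atom table of a protein structure.

    Attributes
    ----------
    coords : (M, 3) float array, Angstrom
    element : list of element symbols ("C", "N", "O", "S", ...)
    mass : (M,) float array, amu
    chain : list of chain identifiers
    resseq : (M,) int array, deposited residue numbering
    resname : list of three-letter residue names
    atname : list of PDB atom names
    is_backbone : (M,) bool array, True for N/CA/C/O
    """

    coords: np.ndarray
    element: list
    mass: np.ndarray
    chain: list
    resseq: np.ndarray
    resname: list
    atname: list
    is_backbone: np.ndarray
    _index: dict = field(init=False, repr=False)

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        self.mass = np.asarray(self.mass, dtype=float)
        self.resseq = np.asarray(self.resseq, dtype=int)
        self.is_backbone = np.asarray(self.is_backbone, dtype=bool)
        if not np.all(np.isfinite(self.coords)):
            raise LoopModesError("non-finite coordinates")
        if np.any(self.mass <= 0):
            raise LoopModesError("non-positive atomic mass")
        self._index = {}
        for i in range(self.natoms):
            key = (self.chain[i], int(self.resseq[i]), self.atname[i])
            if key in self._index:
                raise LoopModesError(f"duplicate atom {key}")
            self._index[key] = i

    @property
    def natoms(self) -> int:
        return self.coords.shape[0]

    def index(self, chain: str, resseq: int, atname: str) -> int:
        """Global index of one atom; raises :class:`MissingAtomError`."""
        try:
            return self._index[(chain, int(resseq), atname)]
        except KeyError:
            raise MissingAtomError(chain, int(resseq), atname) from None

    def has_atom(self, chain: str, resseq: int, atname: str) -> bool:
        return (chain, int(resseq), atname) in self._index

    def residue_atoms(self, chain: str, resseq: int) -> np.ndarray:
        """Global indices of every atom in one residue."""
        mask = (self.resseq == int(resseq)) & np.array(
            [c == chain for c in self.chain]
        )
        return np.flatnonzero(mask)

    def residues(self, chain: str | None = None):
        """Ordered unique (chain, resseq) pairs."""
        seen, out = set(), []
        for i in range(self.natoms):
            key = (self.chain[i], int(self.resseq[i]))
            if chain is not None and key[0] != chain:
                continue
            if key not in seen:
                seen.add(key)
                out.append(key)
        return out

    def copy(self) -> "Structure":
        return Structure(
            self.coords.copy(),
            list(self.element),
            self.mass.copy(),
            list(self.chain),
            self.resseq.copy(),
            list(self.resname),
            list(self.atname),
            self.is_backbone.copy(),
        )


@dataclass(frozen=True)
class LoopSpec:
    """Designates the flexible loop: chain, inclusive residue range.

    ``first``..``last`` are the N flexible residues in deposited numbering;
    the residue ``last + 1`` is the rigid C-terminal anchor.  The torsional
    degree-of-freedom count is ``2N + 1`` (phi/psi of each flexible residue
    plus phi of the anchor), or ``3N + 1`` when omega angles are included.
    """

    chain: str
    first: int
    last: int
    include_omega: bool = False

    def __post_init__(self):
        if self.last - self.first + 1 < 2:
            raise LoopModesError("loop must have at least 2 flexible residues")

    @property
    def n_residues(self) -> int:
        return self.last - self.first + 1

    @property
    def n_dof(self) -> int:
        n = self.n_residues
        return (3 * n + 1) if self.include_omega else (2 * n + 1)

    @property
    def ct_resseq(self) -> int:
        return self.last + 1


@dataclass
class LoopModel:
    """A selected loop with its mobile and fixed-environment atom sets."""

    structure: Structure
    spec: LoopSpec
    mobile_idx: np.ndarray  # global indices, loop heavy atoms + Ct N/CA/C
    env_idx: np.ndarray  # global indices, fixed elastic-network atoms

    def __post_init__(self):
        if np.intersect1d(self.mobile_idx, self.env_idx).size:
            raise LoopModesError("mobile and environment sets overlap")

    @property
    def n_mobile(self) -> int:
        return self.mobile_idx.size

    def mobile_pos(self, idx_global: int) -> int:
        """Position of a global atom index inside the mobile block."""
        where = np.flatnonzero(self.mobile_idx == idx_global)
        if where.size != 1:
            raise LoopModesError(f"atom {idx_global} is not mobile")
        return int(where[0])


# ---------------------------------------------------------------------------
# PDB I/O


def read_structure(path) -> Structure:
    """Read heavy protein atoms from a PDB file.

    ATOM records only; hydrogens, deuteriums and waters are excluded;
    alternate locations are resolved to the highest occupancy; insertion
    codes are rejected.  Standard atomic masses are assigned by element.
    """
    parser = PDBParser(QUIET=True)
    model = next(parser.get_structure("s", str(path)).get_models())
    coords, element, mass, chain, resseq, resname, atname, bb = (
        [], [], [], [], [], [], [], []
    )
    for ch in model:
        for res in ch:
            hetflag, seq, icode = res.get_id()
            if hetflag != " ":  # HETATM (includes waters)
                continue
            if icode != " ":
                raise PDBFormatError(
                    f"insertion code {icode!r} at {ch.id}:{seq} is not supported"
                )
            for atom in res.get_unpacked_list():
                if atom.get_altloc() not in (" ", ""):
                    # keep only the highest-occupancy alternate
                    disordered = res[atom.get_name()]
                    best = max(
                        disordered.disordered_get_list(),
                        key=lambda a: (a.get_occupancy() or 0.0),
                    )
                    if atom is not best:
                        continue
                el = (atom.element or "").strip().capitalize()
                if el in ("H", "D", ""):
                    continue
                coords.append(atom.get_coord())
                element.append(el)
                mass.append(atom_weights[el])
                chain.append(ch.id)
                resseq.append(seq)
                resname.append(res.get_resname())
                atname.append(atom.get_name())
                bb.append(atom.get_name() in BACKBONE_NAMES)
    if not coords:
        raise PDBFormatError(f"no heavy protein atoms found in {path}")
    return Structure(
        np.array(coords, dtype=float), element, np.array(mass),
        chain, np.array(resseq), resname, atname, np.array(bb),
    )


def _format_atom_line(serial, atname, resname, chain, resseq, xyz, element):
    name = atname if len(atname) >= 4 else f" {atname:<3s}"
    return (
        f"ATOM  {serial:>5d} {name:<4s} {resname:>3s} {chain:1s}{resseq:>4d}    "
        f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{1.0:6.2f}{0.0:6.2f}"
        f"          {element:>2s}\n"
    )


def write_structure(structure: Structure, path) -> None:
    """Write a single-model PDB file."""
    with open(path, "w") as fh:
        _write_model_atoms(fh, structure, structure.coords)
        fh.write("END\n")


def _write_model_atoms(fh, structure: Structure, coords: np.ndarray) -> None:
    for i in range(structure.natoms):
        fh.write(
            _format_atom_line(
                i + 1,
                structure.atname[i],
                structure.resname[i],
                structure.chain[i],
                int(structure.resseq[i]),
                coords[i],
                structure.element[i],
            )
        )


def write_multimodel(structure: Structure, coords_list, path) -> None:
    """Write an ensemble of coordinate frames as a multi-model PDB."""
    coords_list = list(coords_list)
    if not coords_list:
        raise LoopModesError("cannot write an empty ensemble")
    with open(path, "w") as fh:
        for k, coords in enumerate(coords_list, start=1):
            fh.write(f"MODEL     {k:>4d}\n")
            _write_model_atoms(fh, structure, coords)
            fh.write("ENDMDL\n")
        fh.write("END\n")


def write_ensemble(ensemble, path) -> None:
    """Write an :class:`~loopmodes.sampling.Ensemble` as a multi-model PDB.

    One MODEL per conformation; environment atoms are constant across
    models by construction.
    """
    if len(ensemble) == 0:
        raise LoopModesError("cannot write an empty ensemble")
    write_multimodel(
        ensemble.structure,
        (ensemble.full_coords(k) for k in range(len(ensemble))),
        path,
    )


def read_ensemble_coords(path) -> list[Structure]:
    """Read every model of a multi-model PDB as a list of Structures."""
    parser = PDBParser(QUIET=True)
    models = []
    for model in parser.get_structure("e", str(path)).get_models():
        coords, element, mass, chain, resseq, resname, atname, bb = (
            [], [], [], [], [], [], [], []
        )
        for ch in model:
            for res in ch:
                if res.get_id()[0] != " ":
                    continue
                for atom in res.get_unpacked_list():
                    el = (atom.element or "").strip().capitalize()
                    if el in ("H", "D", ""):
                        continue
                    coords.append(atom.get_coord())
                    element.append(el)
                    mass.append(atom_weights[el])
                    chain.append(ch.id)
                    resseq.append(res.get_id()[1])
                    resname.append(res.get_resname())
                    atname.append(atom.get_name())
                    bb.append(atom.get_name() in BACKBONE_NAMES)
        models.append(
            Structure(
                np.array(coords, dtype=float), element, np.array(mass),
                chain, np.array(resseq), resname, atname, np.array(bb),
            )
        )
    return models


# ---------------------------------------------------------------------------
# Loop selection


def select_loop(
    structure: Structure, spec: LoopSpec, env_cutoff: float = 10.0
) -> LoopModel:
    """Partition atoms into the mobile loop and its fixed environment.

    The mobile set holds every heavy atom of the N flexible residues plus
    the N/CA/C atoms of the C-terminal anchor residue.  The environment
    set holds the heavy atoms of every other residue that has at least one
    atom within ``env_cutoff`` (Angstrom) of a mobile atom.
    """
    ch = spec.chain
    # complete backbones on the flexible span and the Ct anchor
    for r in range(spec.first, spec.last + 1):
        for name in ("N", "CA", "C", "O"):
            structure.index(ch, r, name)
    for name in ("N", "CA", "C"):
        structure.index(ch, spec.ct_resseq, name)
    # chain continuity through the loop and into the anchor
    for r in range(spec.first, spec.ct_resseq):
        c_i = structure.coords[structure.index(ch, r, "C")]
        n_j = structure.coords[structure.index(ch, r + 1, "N")]
        d = float(np.linalg.norm(n_j - c_i))
        if d > 2.0:
            raise ChainBreakError(
                f"chain break between {ch}:{r} and {ch}:{r + 1} "
                f"(C-N distance {d:.2f} A)"
            )

    mobile = []
    for r in range(spec.first, spec.last + 1):
        mobile.extend(structure.residue_atoms(ch, r).tolist())
    mobile.extend(
        structure.index(ch, spec.ct_resseq, nm) for nm in ("N", "CA", "C")
    )
    mobile = np.array(sorted(set(mobile)), dtype=int)

    mobile_xyz = structure.coords[mobile]
    env = []
    loop_range = set(range(spec.first, spec.last + 1))
    for chain_id, r in structure.residues():
        if chain_id == ch and r in loop_range:
            continue
        res_atoms = structure.residue_atoms(chain_id, r)
        res_atoms = np.setdiff1d(res_atoms, mobile)
        if res_atoms.size == 0:
            continue
        d = np.linalg.norm(
            structure.coords[res_atoms][:, None, :] - mobile_xyz[None, :, :],
            axis=-1,
        )
        if env_cutoff > 0 and d.min() <= env_cutoff:
            env.extend(res_atoms.tolist())
    return LoopModel(structure, spec, mobile, np.array(sorted(env), dtype=int))


# ---------------------------------------------------------------------------
# Synthetic ideal-geometry fixtures


def place_atom(a, b, c, bond: float, angle_deg: float, torsion_deg: float):
    """NeRF placement: position d with |c-d|=bond, angle(b,c,d), torsion(a,b,c,d)."""
    a, b, c = (np.asarray(x, dtype=float) for x in (a, b, c))
    theta = np.deg2rad(angle_deg)
    chi = np.deg2rad(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    nn = np.linalg.norm(n)
    if nn < 1e-10:
        raise LoopModesError("collinear reference atoms in NeRF placement")
    n /= nn
    m = np.cross(n, bc)
    d_local = np.array(
        [
            -bond * np.cos(theta),
            bond * np.sin(theta) * np.cos(chi),
            bond * np.sin(theta) * np.sin(chi),
        ]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def build_synthetic_loop(
    N: int,
    phi_psi: Sequence[tuple] | None = None,
    seed: int = 0,
    sequence: str | None = None,
    scaffold_shells: Iterable[tuple] = (),
    chain: str = "A",
    anchor_psi: float = -47.0,
    ct_phi: float = -57.0,
) -> Structure:
    """Build an ideal-geometry loop of ``N`` flexible residues.

    The chain holds ``N + 2`` residues: a rigid N-terminal anchor (residue
    1), the flexible residues 2..N+1 with the requested ``phi_psi`` pairs
    (degrees), and a rigid C-terminal anchor.  All residues are alanine
    (N, CA, C, O, CB) unless ``sequence`` (one-letter, length N) marks a
    position as glycine ("G", no CB).  Bond lengths/angles follow
    :data:`IDEAL_GEOMETRY`; all omega angles are 180 degrees.

    ``scaffold_shells`` is an iterable of ``(distance_A, count)`` pairs:
    each shell adds ``count`` single-atom pseudo-residues on chain "S",
    placed ``distance_A`` outward of evenly chosen loop CA atoms.  The
    construction is fully deterministic; ``seed`` is accepted for API
    stability but does not alter the output.

    Extracting dihedrals from the result returns the requested phi/psi.
    """
    if N < 2:
        raise LoopModesError("need at least 2 flexible residues")
    if phi_psi is None:
        phi_psi = [(-57.0, -47.0)] * N
    phi_psi = list(phi_psi)
    if len(phi_psi) != N:
        raise LoopModesError("phi_psi must list one (phi, psi) pair per residue")
    for phi, psi in phi_psi:
        if not (-180.0 < phi <= 180.0 and -180.0 < psi <= 180.0):
            raise LoopModesError("angles must lie in (-180, 180]")
    if sequence is None:
        sequence = "A" * N
    if len(sequence) != N:
        raise LoopModesError("sequence length must equal N")

    g = IDEAL_GEOMETRY
    n_res = N + 2
    # per-residue torsions; anchors get fixed helical-like values
    phis = [-57.0] + [p for p, _ in phi_psi] + [ct_phi]
    psis = [anchor_psi] + [s for _, s in phi_psi] + [-47.0]
    resnames = ["ALA"] + ["GLY" if s == "G" else "ALA" for s in sequence] + ["ALA"]

    pos = {}  # (resseq, atname) -> xyz
    # residue 1 backbone seeded in a canonical frame
    pos[(1, "N")] = np.array([0.0, 0.0, 0.0])
    pos[(1, "CA")] = np.array([g["b_N_CA"], 0.0, 0.0])
    th = np.deg2rad(180.0 - g["a_N_CA_C"])
    pos[(1, "C")] = pos[(1, "CA")] + g["b_CA_C"] * np.array(
        [np.cos(th), np.sin(th), 0.0]
    )
    for r in range(2, n_res + 1):
        pos[(r, "N")] = place_atom(
            pos[(r - 1, "N")], pos[(r - 1, "CA")], pos[(r - 1, "C")],
            g["b_C_N"], g["a_CA_C_N"], psis[r - 2],
        )
        pos[(r - 1, "O")] = place_atom(
            pos[(r - 1, "N")], pos[(r - 1, "CA")], pos[(r - 1, "C")],
            g["b_C_O"], g["a_CA_C_O"], psis[r - 2] + 180.0,
        )
        pos[(r, "CA")] = place_atom(
            pos[(r - 1, "CA")], pos[(r - 1, "C")], pos[(r, "N")],
            g["b_N_CA"], g["a_C_N_CA"], g["omega"],
        )
        pos[(r, "C")] = place_atom(
            pos[(r - 1, "C")], pos[(r, "N")], pos[(r, "CA")],
            g["b_CA_C"], g["a_N_CA_C"], phis[r - 1],
        )
    pos[(n_res, "O")] = place_atom(
        pos[(n_res, "N")], pos[(n_res, "CA")], pos[(n_res, "C")],
        g["b_C_O"], g["a_CA_C_O"], psis[n_res - 1] + 180.0,
    )
    for r in range(1, n_res + 1):
        if resnames[r - 1] == "GLY":
            continue
        pos[(r, "CB")] = place_atom(
            pos[(r, "N")], pos[(r, "C")], pos[(r, "CA")],
            g["b_CA_CB"], g["a_C_CA_CB"], 122.6,
        )

    coords, element, mass, chains, resseq, resname, atname, bb = (
        [], [], [], [], [], [], [], []
    )
    atom_order = ("N", "CA", "C", "O", "CB")
    for r in range(1, n_res + 1):
        for nm in atom_order:
            if (r, nm) not in pos:
                continue
            coords.append(pos[(r, nm)])
            el = "N" if nm == "N" else ("O" if nm == "O" else "C")
            element.append(el)
            mass.append(atom_weights[el])
            chains.append(chain)
            resseq.append(r)
            resname.append(resnames[r - 1])
            atname.append(nm)
            bb.append(nm in BACKBONE_NAMES)

    # deterministic outward scaffold spikes anchored on flexible-residue CAs
    loop_ca = [pos[(r, "CA")] for r in range(2, N + 2)]
    centroid = np.mean([pos[(r, "CA")] for r in range(1, n_res + 1)], axis=0)
    serial = 0
    for dist, count in scaffold_shells:
        for k in range(count):
            base = loop_ca[k % len(loop_ca)]
            direction = base - centroid
            nrm = np.linalg.norm(direction)
            direction = (
                direction / nrm if nrm > 1e-8 else np.array([0.0, 0.0, 1.0])
            )
            # tilt successive spikes so shells do not collapse onto a line
            tilt = np.array(
                [np.cos(2.399963 * k), np.sin(2.399963 * k), 0.3]
            )
            direction = direction + 0.25 * tilt
            direction /= np.linalg.norm(direction)
            serial += 1
            coords.append(base + dist * direction)
            element.append("C")
            mass.append(atom_weights["C"])
            chains.append("S")
            resseq.append(1000 + serial)
            resname.append("SCA")
            atname.append("CA")
            bb.append(False)

    return Structure(
        np.array(coords, dtype=float), element, np.array(mass),
        chains, np.array(resseq), resname, atname, np.array(bb),
    )
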