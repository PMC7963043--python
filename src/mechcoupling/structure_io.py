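"""Cα-level structure handling: PDB reading, residue mapping, superposition.

The whole coupling analysis runs on one bead per residue placed at the Cα
position, identified by author numbering (chain, residue number, insertion
code). Author numbering is kept verbatim because region definitions (P-loops,
switch regions, cofactor ligands) are written in that coordinate system.
"""

from __future__ import annotations

import io
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

logger = logging.getLogger(__name__)

__all__ = [
    "Residue",
    "Structure",
    "ResidueMap",
    "RegionSet",
    "read_calpha_structure",
    "common_residue_map",
    "superpose_rmsd",
    "write_pdb",
    "write_bfactor_pdb",
]


@dataclass(frozen=True)
class Residue:
    """One Cα bead: author identity plus coordinate (Å)."""

    chain_id: str
    resnum: int
    icode: str
    resname: str
    coord: tuple[float, float, float]

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.resnum, self.icode)

    @property
    def label(self) -> str:
        return f"{self.chain_id}:{self.resnum}{self.icode.strip()}"


@dataclass
class Structure:
    """Ordered list of Cα residues from one model of one structure file.

    Order is file order; (chain_id, resnum, icode) is unique per entry.
    """

    residues: list[Residue]
    source_id: str = ""

    def __post_init__(self) -> None:
        keys = [r.key for r in self.residues]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate (chain, resnum, icode) residue identity")
        coords = self.coords
        if coords.size and not np.all(np.isfinite(coords)):
            raise ValueError("non-finite coordinates")

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def coords(self) -> np.ndarray:
        """N×3 float array of Cα coordinates in Å."""
        return np.array([r.coord for r in self.residues], dtype=float).reshape(-1, 3)

    @property
    def labels(self) -> list[str]:
        return [r.label for r in self.residues]

    def index_of(self, chain_id: str, resnum: int, icode: str = " ") -> int:
        for i, r in enumerate(self.residues):
            if r.key == (chain_id, resnum, icode):
                return i
        raise KeyError(f"residue {chain_id}:{resnum}{icode.strip()} not in structure")


@dataclass
class ResidueMap:
    """Pairing of residues between two structures by shared author identity."""

    pairs: list[tuple[int, int]]
    unmatched_a: list[int] = field(default_factory=list)
    unmatched_b: list[int] = field(default_factory=list)
    coverage: float = 0.0

    @property
    def a_indices(self) -> np.ndarray:
        return np.array([p[0] for p in self.pairs], dtype=int)

    @property
    def b_indices(self) -> np.ndarray:
        return np.array([p[1] for p in self.pairs], dtype=int)


@dataclass
class RegionSet:
    """Named residue selection, e.g. a P-loop or a cofactor ligand sphere.

    selectors: list of (chain_id, ranges) where ranges is a list of
    (start_resnum, end_resnum) inclusive intervals.
    """

    name: str
    selectors: list[tuple[str, list[tuple[int, int]]]] = field(default_factory=list)
    resolved_indices: np.ndarray | None = None

    def resolve(self, structure: Structure) -> "RegionSet":
        idx = []
        for i, r in enumerate(structure.residues):
            for chain, ranges in self.selectors:
                if r.chain_id != chain:
                    continue
                if any(lo <= r.resnum <= hi for lo, hi in ranges):
                    idx.append(i)
                    break
        if not idx:
            raise ValueError(f"region {self.name!r} resolves to no residues")
        self.resolved_indices = np.array(sorted(set(idx)), dtype=int)
        return self

    @classmethod
    def from_indices(cls, name: str, indices) -> "RegionSet":
        rs = cls(name=name)
        rs.resolved_indices = np.asarray(sorted(set(int(i) for i in indices)), dtype=int)
        return rs


def _check_atom_lines(pdb_text: str) -> None:
    """Locate the first ATOM record with malformed coordinate fields."""
    for lineno, line in enumerate(pdb_text.splitlines(), start=1):
        if not line.startswith(("ATOM", "HETATM")):
            continue
        if len(line) < 54:
            raise ValueError(f"parse error at line {lineno}: truncated ATOM record")
        try:
            float(line[30:38])
            float(line[38:46])
            float(line[46:54])
        except ValueError:
            raise ValueError(
                f"parse error at line {lineno}: malformed coordinate fields"
            ) from None


def read_calpha_structure(pdb_text: str, model: int = 0, source_id: str = "") -> Structure:
    """Extract one Cα per residue from PDB-format text.

    HETATM and non-Cα atoms are ignored; for alternate locations the
    first-listed altloc is kept; residues without a Cα are dropped with a
    warning. `model` selects the MODEL index (0 = first).
    """
    from Bio.PDB import PDBParser
    from Bio.PDB.PDBExceptions import PDBConstructionException

    parser = PDBParser(QUIET=True)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            bio_structure = parser.get_structure(source_id or "structure", io.StringIO(pdb_text))
    except (PDBConstructionException, ValueError):
        _check_atom_lines(pdb_text)
        raise
    models = list(bio_structure)
    if not models:
        raise ValueError("empty structure: no ATOM records")
    if model >= len(models):
        raise ValueError(f"model index {model} out of range ({len(models)} models)")

    residues: list[Residue] = []
    for chain in models[model]:
        for res in chain:
            hetflag, resnum, icode = res.id
            if hetflag.strip():
                continue  # HETATM
            if "CA" not in res:
                logger.warning(
                    "residue %s:%s%s has no CA atom; dropped",
                    chain.id, resnum, icode.strip(),
                )
                continue
            atom = res["CA"]
            if atom.is_disordered():
                # first-listed altloc, i.e. smallest serial number in the file
                atom = min(atom.disordered_get_list(), key=lambda a: a.serial_number)
            x, y, z = atom.coord
            residues.append(
                Residue(chain.id, int(resnum), icode or " ", res.resname, (float(x), float(y), float(z)))
            )
    if not residues:
        raise ValueError("empty structure: no Cα records")
    return Structure(residues=residues, source_id=source_id)


def common_residue_map(a: Structure, b: Structure) -> ResidueMap:
    """Pair residues of `a` and `b` sharing (chain_id, resnum, icode).

    Indices are strictly increasing in `a`; each residue is used at most once
    on each side. Raises if the structures share no residues.
    """
    if len(a) == 0 or len(b) == 0:
        raise ValueError("cannot map empty structures")
    b_by_key = {}
    for j, r in enumerate(b.residues):
        b_by_key.setdefault(r.key, j)
    pairs, used_b = [], set()
    for i, r in enumerate(a.residues):
        j = b_by_key.get(r.key)
        if j is not None and j not in used_b:
            pairs.append((i, j))
            used_b.add(j)
    if not pairs:
        raise ValueError("zero common residues between structures")
    matched_a = {i for i, _ in pairs}
    return ResidueMap(
        pairs=pairs,
        unmatched_a=[i for i in range(len(a)) if i not in matched_a],
        unmatched_b=[j for j in range(len(b)) if j not in used_b],
        coverage=len(pairs) / len(a),
    )


def superpose_rmsd(
    a_coords: np.ndarray,
    b_coords: np.ndarray,
    fit_subset=None,
    eval_subset=None,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid-body superposition of `b_coords` onto `a_coords`.

    The optimal proper rotation is fitted on `fit_subset` (default: all
    residues); the RMSD is evaluated over `eval_subset` (default: all).
    Returns (rotation 3×3 with det +1, translation, rmsd in Å); the
    transform maps b as ``b @ R.T + t``.
    """
    a = np.asarray(a_coords, dtype=float)
    b = np.asarray(b_coords, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 3:
        raise ValueError(f"coordinate shape mismatch: {a.shape} vs {b.shape}")
    n = a.shape[0]
    if n < 3:
        raise ValueError("need at least 3 residues to superpose")
    fit = np.arange(n) if fit_subset is None else np.asarray(fit_subset, dtype=int)
    ev = np.arange(n) if eval_subset is None else np.asarray(eval_subset, dtype=int)
    if fit.size < 3:
        raise ValueError("fit subset must contain at least 3 points")

    a_c = a[fit].mean(axis=0)
    b_c = b[fit].mean(axis=0)
    rot, _ = Rotation.align_vectors(a[fit] - a_c, b[fit] - b_c)
    R = rot.as_matrix()  # proper rotation by construction
    t = a_c - b_c @ R.T
    b_fit = b @ R.T + t
    rmsd = float(np.sqrt(np.mean(np.sum((b_fit[ev] - a[ev]) ** 2, axis=1))))
    return R, t, rmsd


def apply_transform(coords: np.ndarray, rotation: np.ndarray, translation: np.ndarray) -> np.ndarray:
    return np.asarray(coords, dtype=float) @ np.asarray(rotation).T + np.asarray(translation)


_ATOM_FMT = (
    "ATOM  {serial:>5d}  CA  {resname:<3s} {chain:1s}{resnum:>4d}{icode:1s}"
    "   {x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{b:6.2f}           C\n"
)


def write_pdb(structure: Structure, bfactors=None) -> str:
    """Serialize a Cα Structure to PDB-format text.

    `bfactors`, if given, is a per-residue scalar stored in the B-factor
    column (for coloring in molecular viewers). Round-trips through
    :func:`read_calpha_structure` to the printed precision.
    """
    if bfactors is None:
        bfactors = np.zeros(len(structure))
    bfactors = np.asarray(bfactors, dtype=float)
    if bfactors.shape != (len(structure),):
        raise ValueError("one B-factor per residue required")
    out = []
    for serial, (r, b) in enumerate(zip(structure.residues, bfactors), start=1):
        x, y, z = r.coord
        out.append(
            _ATOM_FMT.format(
                serial=serial, resname=r.resname[:3], chain=r.chain_id[:1] or "A",
                resnum=r.resnum, icode=r.icode[:1] or " ", x=x, y=y, z=z,
                occ=1.0, b=float(b),
            )
        )
    out.append("END\n")
    return "".join(out)


def write_bfactor_pdb(structure: Structure, values, path) -> None:
    """Write `structure` with per-residue `values` in the B-factor column."""
    with open(path, "w") as fh:
        fh.write(write_pdb(structure, bfactors=values))
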