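"""Structure parsing, Calpha superposition and buried-surface analysis.

Parsing goes through gemmi (PDB and mmCIF dialects); the in-memory carrier
is a plain :class:`StructureModel` of flat arrays so that downstream code
(bead-model construction, superposition, SASA) stays independent of the
parser.  Superposition is a standard Kabsch least-squares rigid fit with the
proper-rotation determinant fix.  Solvent-accessible surface areas use the
Shrake-Rupley sphere-point method with a deterministic golden-spiral point
set; interface (buried) area between two chain groups is

    (SASA(A alone) + SASA(B alone) - SASA(A u B)) / 2.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "StructureModel",
    "SuperpositionResult",
    "THREE_TO_ONE",
    "VDW_RADII",
    "parse_structure",
    "match_ca",
    "kabsch_superpose",
    "apply_transform",
    "sasa",
    "interface_area",
]

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}

# Bondi-style van der Waals radii (A); single embedded table.
VDW_RADII = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80,
    "P": 1.80, "SE": 1.90, "F": 1.47, "CL": 1.75, "BR": 1.85,
    "I": 1.98, "MG": 1.73, "ZN": 1.39, "CA": 2.31, "K": 2.75,
    "NA": 2.27, "FE": 1.52, "MN": 1.61,
}
DEFAULT_RADIUS = 1.80


@dataclass
class StructureModel:
    """Flat-array structure: per-atom chain, residue, name, element, xyz."""

    chain: np.ndarray
    resnum: np.ndarray
    icode: np.ndarray
    resname: np.ndarray
    atname: np.ndarray
    element: np.ndarray
    coords: np.ndarray
    het: np.ndarray  # True for non-polymer (ligand) atoms
    source_id: str = ""

    def __post_init__(self) -> None:
        n = len(self.coords)
        self.coords = np.asarray(self.coords, dtype=float).reshape(n, 3)
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates")
        for name in ("chain", "resnum", "icode", "resname", "atname", "element", "het"):
            arr = np.asarray(getattr(self, name))
            if len(arr) != n:
                raise ValueError(f"{name} length mismatch")
            setattr(self, name, arr)

    def __len__(self) -> int:
        return len(self.coords)

    @property
    def chains(self) -> list[str]:
        seen: dict[str, None] = {}
        for c in self.chain:
            seen.setdefault(str(c), None)
        return list(seen)

    def subset(self, mask: np.ndarray, source_id: str | None = None) -> "StructureModel":
        return StructureModel(
            self.chain[mask], self.resnum[mask], self.icode[mask],
            self.resname[mask], self.atname[mask], self.element[mask],
            self.coords[mask], self.het[mask],
            source_id=source_id if source_id is not None else self.source_id,
        )

    def select(
        self,
        chains: Sequence[str] | None = None,
        residues: tuple[int, int] | None = None,
        het: bool | None = None,
    ) -> "StructureModel":
        mask = np.ones(len(self), dtype=bool)
        if chains is not None:
            mask &= np.isin(self.chain, list(chains))
        if residues is not None:
            lo, hi = residues
            mask &= (self.resnum >= lo) & (self.resnum <= hi)
        if het is not None:
            mask &= self.het == het
        return self.subset(mask)

    def iter_ca(self) -> Iterator[tuple[str, int, str, np.ndarray]]:
        """Yield (chain, resnum, resname, xyz) for each Calpha atom."""
        for i in np.flatnonzero(self.atname == "CA"):
            if self.element[i] == "C":  # exclude calcium ions named CA
                yield (str(self.chain[i]), int(self.resnum[i]),
                       str(self.resname[i]), self.coords[i])


def parse_structure(path: str, keep_waters: bool = False) -> StructureModel:
    """Read a PDB or mmCIF file into a StructureModel.

    First model only; for alternate conformations the highest-occupancy
    altloc of each residue is kept; waters are excluded by default while
    hetero ligands are retained (flagged ``het``).
    """
    import gemmi

    try:
        st = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError) as exc:
        raise ValueError(f"malformed structure file {path}: {exc}") from exc
    if len(st) == 0:
        raise ValueError(f"no models in {path}")
    st.setup_entities()
    model = st[0]
    chains, resnums, icodes, resnames, atnames, elements, coords, het = \
        [], [], [], [], [], [], [], []
    for chain in model:
        for residue in chain:
            if residue.name in ("HOH", "DOD", "WAT") and not keep_waters:
                continue
            is_het = residue.het_flag == "H" and residue.name not in THREE_TO_ONE
            # highest-occupancy altloc per (residue, atom name)
            best: dict[str, "gemmi.Atom"] = {}
            for atom in residue:
                prev = best.get(atom.name)
                if prev is None or atom.occ > prev.occ:
                    best[atom.name] = atom
            for name, atom in best.items():
                chains.append(chain.name)
                resnums.append(residue.seqid.num)
                icodes.append(residue.seqid.icode.strip())
                resnames.append(residue.name)
                atnames.append(name)
                elements.append(atom.element.name.upper())
                coords.append([atom.pos.x, atom.pos.y, atom.pos.z])
                het.append(is_het)
    if not coords:
        raise ValueError(f"no atoms parsed from {path}")
    return StructureModel(
        np.array(chains), np.array(resnums), np.array(icodes),
        np.array(resnames), np.array(atnames), np.array(elements),
        np.array(coords), np.array(het), source_id=str(path),
    )


def match_ca(
    a: StructureModel,
    b: StructureModel,
    chain_map: dict[str, str] | None = None,
    residues: tuple[int, int] | None = None,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Pair Calpha atoms present in both structures by residue number.

    ``chain_map`` maps chain ids of ``a`` to chain ids of ``b`` (default:
    identical ids).  ``residues`` optionally restricts to an inclusive
    author-numbering range.  Returns (coords_a, coords_b, n_pairs).
    """
    def ca_table(s: StructureModel, chains: Iterable[str] | None):
        table = {}
        for ch, num, _rn, xyz in s.iter_ca():
            if chains is not None and ch not in chains:
                continue
            if residues is not None and not (residues[0] <= num <= residues[1]):
                continue
            table[(ch, num)] = xyz
        return table

    if chain_map is None:
        common = [c for c in a.chains if c in b.chains]
        chain_map = {c: c for c in common}
    ta = ca_table(a, set(chain_map))
    tb = ca_table(b, set(chain_map.values()))
    pa, pb = [], []
    for (ch, num), xyz in ta.items():
        key = (chain_map[ch], num)
        if key in tb:
            pa.append(xyz)
            pb.append(tb[key])
    if not pa:
        raise ValueError("no common Calpha pairs under the given selection")
    return np.array(pa), np.array(pb), len(pa)


@dataclass(frozen=True)
class SuperpositionResult:
    rmsd: float
    n_pairs: int
    rotation: np.ndarray  # applied to the mobile set
    translation: np.ndarray

    def __post_init__(self) -> None:
        if self.rmsd < 0:
            raise ValueError("rmsd must be non-negative")


def kabsch_superpose(
    fixed: np.ndarray,
    mobile: np.ndarray,
    score_fixed: np.ndarray | None = None,
    score_mobile: np.ndarray | None = None,
) -> SuperpositionResult:
    """Least-squares rigid superposition (Kabsch, proper rotation enforced).

    The transform is fitted on (fixed, mobile); when score selections are
    given the RMSD is evaluated over those pairs instead (fit on one
    selection, score on another, as in domain-aligned comparisons).
    """
    P = np.asarray(fixed, dtype=float)
    Q = np.asarray(mobile, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[0] < 3:
        raise ValueError("need two equal (N>=3, 3) coordinate sets")
    cp = P.mean(axis=0)
    cq = Q.mean(axis=0)
    H = (Q - cq).T @ (P - cp)
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    # degenerate geometry: all points collinear -> rank < 2
    if S[1] < 1e-9 * max(S[0], 1e-30):
        raise ValueError("degenerate (collinear) geometry")
    t = cp - R @ cq
    if score_fixed is None:
        score_fixed, score_mobile = P, Q
    sf = np.asarray(score_fixed, dtype=float)
    sm = np.asarray(score_mobile, dtype=float) @ R.T + t
    rmsd = float(np.sqrt(np.mean(np.sum((sf - sm) ** 2, axis=1))))
    return SuperpositionResult(rmsd=rmsd, n_pairs=len(sf), rotation=R, translation=t)


def apply_transform(result: SuperpositionResult, coords: np.ndarray) -> np.ndarray:
    return np.asarray(coords, dtype=float) @ result.rotation.T + result.translation


def _sphere_points(n: int) -> np.ndarray:
    """Deterministic golden-spiral unit-sphere point set."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * i / n)
    theta = np.pi * (1 + 5**0.5) * i
    return np.column_stack([
        np.cos(theta) * np.sin(phi),
        np.sin(theta) * np.sin(phi),
        np.cos(phi),
    ])


def sasa(
    model: StructureModel,
    probe_radius: float = 1.4,
    n_points: int = 960,
    radii: dict[str, float] | None = None,
    strict_elements: bool = False,
) -> np.ndarray:
    """Per-atom Shrake-Rupley solvent-accessible areas (A^2).

    Deterministic for a given ``n_points``.  Unknown elements fall back to a
    default radius unless ``strict_elements`` is set.
    """
    radii = radii or VDW_RADII
    r = np.empty(len(model))
    for i, el in enumerate(model.element):
        el = str(el).upper()
        if el in radii:
            r[i] = radii[el]
        elif strict_elements:
            raise ValueError(f"unknown element {el!r} and strict_elements=True")
        else:
            r[i] = DEFAULT_RADIUS
    r = r + probe_radius
    pts = _sphere_points(n_points)
    coords = model.coords
    tree = cKDTree(coords)
    max_r = r.max()
    areas = np.empty(len(model))
    for i in range(len(model)):
        neigh = tree.query_ball_point(coords[i], r[i] + max_r)
        neigh = [j for j in neigh if j != i
                 and np.linalg.norm(coords[j] - coords[i]) < r[i] + r[j]]
        sphere = coords[i] + r[i] * pts
        if neigh:
            nb = coords[neigh]
            nr = r[neigh]
            d2 = ((sphere[:, None, :] - nb[None, :, :]) ** 2).sum(axis=2)
            buried = (d2 < nr**2).any(axis=1)
            n_acc = int((~buried).sum())
        else:
            n_acc = n_points
        areas[i] = 4.0 * np.pi * r[i] ** 2 * n_acc / n_points
    return areas


def interface_area(
    model: StructureModel,
    group_a: Sequence[str],
    group_b: Sequence[str],
    probe_radius: float = 1.4,
    n_points: int = 960,
    include_het: bool = False,
) -> float:
    """Buried interface area between two disjoint chain groups (A^2).

    (SASA(A alone) + SASA(B alone) - SASA(A u B)) / 2.  Hetero (ligand)
    atoms are excluded from both groups by default, so e.g. a covalent
    nucleotide adduct does not count towards the protein-protein interface.
    """
    ga, gb = set(group_a), set(group_b)
    if not ga or not gb:
        raise ValueError("both groups must be non-empty")
    if ga & gb:
        raise ValueError(f"overlapping groups: {sorted(ga & gb)}")
    het = None if include_het else False
    sub_a = model.select(chains=sorted(ga), het=het)
    sub_b = model.select(chains=sorted(gb), het=het)
    mask_ab = np.isin(model.chain, sorted(ga | gb))
    if het is not None:
        mask_ab &= model.het == het
    sub_ab = model.subset(mask_ab)
    a_alone = sasa(sub_a, probe_radius, n_points).sum()
    b_alone = sasa(sub_b, probe_radius, n_points).sum()
    together = sasa(sub_ab, probe_radius, n_points).sum()
    return float((a_alone + b_alone - together) / 2.0)
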