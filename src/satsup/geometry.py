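"""Residue-level structural geometry.

Side-chain centroids and inter-residue distances, Kabsch superposition and
backbone RMSD, per-residue RMSF of multi-model ensembles, Shrake-Rupley
solvent-accessible surface area, and residue depth.

Conventions
-----------
* Only heavy atoms enter any calculation.
* The side-chain centroid is the unweighted mean of heavy side-chain atom
  coordinates (everything except N, CA, C, O and OXT); glycine, which has
  no heavy side-chain atom, falls back to its CA position.  This fallback
  makes the contact score reproducible for glycine-containing pairs.
* "Backbone" for superposition means N, CA, C (O can be included
  explicitly but is excluded by default).
* Residue depth is the mean (or minimum, by option) over a residue's
  heavy atoms of the distance to the nearest solvent-accessible surface
  point, where the surface is approximated by probe-inflated sphere
  points of atoms with nonzero accessibility.  This is a deterministic,
  dependency-free stand-in for explicit-water depth definitions and is
  validated by ordering properties (buried deeper than exposed), not by
  exact agreement with any particular server.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist
from scipy.spatial.transform import Rotation

from satsup.structio import Residue, StructureEnsemble, StructureModel
from satsup.refdata import MAX_ASA, VDW_RADII

logger = logging.getLogger(__name__)

BACKBONE_ATOMS = ("N", "CA", "C")
_NON_SIDECHAIN = frozenset({"N", "CA", "C", "O", "OXT"})


@dataclass
class SuperpositionResult:
    """Optimal rigid-body superposition: rotation, translation, RMSD."""

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float
    n_atoms: int = 0

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


@dataclass
class DepthProfile:
    """Per-residue depth (Angstrom) keyed by (chain_id, seq_num, icode)."""

    depths: dict[tuple[str, int, str], float]

    def by_position(self) -> dict[int, float]:
        """Average depth per author position across chains (homo-oligomers)."""
        acc: dict[int, list[float]] = {}
        for (_c, seq, _i), d in self.depths.items():
            acc.setdefault(seq, []).append(d)
        return {p: float(np.mean(v)) for p, v in acc.items()}


@dataclass
class SasaProfile:
    """Per-residue absolute (A^2) and relative (%) accessible surface area."""

    absolute: dict[tuple[str, int, str], float]
    relative: dict[tuple[str, int, str], float]
    total: float


def _heavy_coords(res: Residue) -> np.ndarray:
    coords = res.coords_array()
    if coords.size == 0:
        raise ValueError(f"residue {res.key} has no heavy atoms")
    return coords


def shortest_heavy_atom_distance(res_a: Residue, res_b: Residue) -> float:
    """Minimum pairwise heavy-atom distance between two residues (Angstrom)."""
    return float(cdist(_heavy_coords(res_a), _heavy_coords(res_b)).min())


def sidechain_centroid(res: Residue) -> np.ndarray:
    """Unweighted mean of heavy side-chain atom coordinates.

    Glycine (and any residue whose side-chain heavy atoms are missing)
    returns the CA position.
    """
    side = [a.coords for a in res.heavy_atoms if a.name not in _NON_SIDECHAIN]
    if side:
        return np.mean(side, axis=0)
    ca = res.atom("CA")
    if ca is None:
        raise ValueError(f"residue {res.key} has neither side-chain atoms nor CA")
    return np.asarray(ca.coords, dtype=float)


def centroid_distance(res_a: Residue, res_b: Residue) -> float:
    """Euclidean distance between side-chain centroids (Angstrom)."""
    return float(np.linalg.norm(sidechain_centroid(res_a) - sidechain_centroid(res_b)))


def min_pair_distance(
    model: StructureModel,
    pos_x: int,
    pos_y: int,
    metric: str = "centroid",
    chains: list[str] | None = None,
) -> float:
    """Distance between two author positions, minimised over chain pairings.

    For homo-oligomers the same position exists once per protomer; the
    reported distance is the minimum over all within- and cross-protomer
    residue pairings (distinct residues only).  ``metric`` is ``centroid``
    or ``shortest`` (heavy atom).  Residues with code 'X' are skipped.
    """
    fn = centroid_distance if metric == "centroid" else shortest_heavy_atom_distance
    ra = [r for r in model.residues_at(pos_x, chains) if r.aa != "X"]
    rb = [r for r in model.residues_at(pos_y, chains) if r.aa != "X"]
    if not ra or not rb:
        raise KeyError(
            f"position {pos_x if not ra else pos_y} not resolvable in model"
        )
    best = np.inf
    for a in ra:
        for b in rb:
            if a is b:
                continue
            best = min(best, fn(a, b))
    if not np.isfinite(best):
        raise KeyError(f"no distinct residue pairing for positions {pos_x},{pos_y}")
    return float(best)


def _shared_atom_coords(
    mobile: StructureModel, reference: StructureModel, atom_names: tuple[str, ...]
) -> tuple[np.ndarray, np.ndarray]:
    ref_by_key = {r.key: r for r in reference.residues}
    mob_pts, ref_pts = [], []
    n_missing = 0
    for rm in mobile.residues:
        rr = ref_by_key.get(rm.key)
        if rr is None:
            continue
        for name in atom_names:
            am, ar = rm.atom(name), rr.atom(name)
            if am is None or ar is None:
                n_missing += 1
                continue
            mob_pts.append(am.coords)
            ref_pts.append(ar.coords)
    if n_missing:
        logger.warning("superpose: skipped %d missing atoms", n_missing)
    return np.array(mob_pts, float), np.array(ref_pts, float)


def superpose(
    mobile: StructureModel,
    reference: StructureModel,
    atom_set: str = "backbone",
) -> SuperpositionResult:
    """Least-squares (Kabsch) superposition of shared residues.

    ``atom_set`` is ``backbone`` (N, CA, C), ``backbone_o`` (plus O) or
    ``CA``.  Residues are matched by (chain, seq_num, icode); missing
    atoms are skipped with a warning.  Requires >=3 shared residues.
    """
    names = {
        "backbone": BACKBONE_ATOMS,
        "backbone_o": BACKBONE_ATOMS + ("O",),
        "CA": ("CA",),
    }.get(atom_set)
    if names is None:
        raise ValueError(f"unknown atom_set {atom_set!r}")
    mob, ref = _shared_atom_coords(mobile, reference, names)
    shared_res = len({r.key for r in mobile.residues} & {r.key for r in reference.residues})
    if shared_res < 3:
        raise ValueError(f"only {shared_res} shared residues; need >=3")
    mob_c, ref_c = mob.mean(axis=0), ref.mean(axis=0)
    rot, rssd = Rotation.align_vectors(ref - ref_c, mob - mob_c)
    rmsd = rssd / np.sqrt(len(mob))
    rotation = rot.as_matrix()
    translation = ref_c - rotation @ mob_c
    return SuperpositionResult(
        rotation=rotation, translation=translation, rmsd=float(rmsd), n_atoms=len(mob)
    )


def ensemble_rmsf(
    ensemble: StructureEnsemble, atom: str = "CA"
) -> dict[tuple[str, int, str], float]:
    """Per-residue RMSF of a multi-model ensemble about the mean structure.

    Models are first superposed (on the chosen atom) onto model 1, the
    mean structure is taken as reference, and the root-mean-square
    fluctuation of each residue's atom about its mean position is
    returned.  Requires >=2 models.
    """
    if ensemble.n_models < 2:
        raise ValueError("RMSF needs an ensemble with >=2 models")
    first = ensemble.models[0]
    keys = [r.key for r in first.residues if r.atom(atom) is not None]
    keyset = set(keys)
    per_model: list[np.ndarray] = []
    for model in ensemble.models:
        res_by_key = {r.key: r for r in model.residues}
        if not keyset <= set(res_by_key):
            raise ValueError("models do not share residue identities")
        sup = superpose(model, first, atom_set="CA" if atom == "CA" else "backbone")
        coords = np.array([res_by_key[k].atom(atom).coords for k in keys])
        per_model.append(sup.apply(coords))
    stack = np.stack(per_model)          # (n_models, n_res, 3)
    mean = stack.mean(axis=0)
    sq = ((stack - mean) ** 2).sum(axis=2)   # squared displacement
    rmsf = np.sqrt(sq.mean(axis=0))
    return dict(zip(keys, map(float, rmsf)))


def _atom_table(model: StructureModel):
    coords, radii, res_index = [], [], []
    for i, res in enumerate(model.residues):
        for a in res.heavy_atoms:
            r = VDW_RADII.get(a.element)
            if r is None:
                raise ValueError(f"unknown element {a.element!r} for atom {a.name} in {res.key}")
            coords.append(a.coords)
            radii.append(r)
            res_index.append(i)
    return np.array(coords, float), np.array(radii, float), np.array(res_index)


def _sphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform points on the unit sphere (Fibonacci)."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * i / n)
    theta = np.pi * (1 + 5 ** 0.5) * i
    return np.column_stack(
        (np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi))
    )


def _per_atom_sasa(
    coords: np.ndarray, radii: np.ndarray, probe: float, n_points: int
) -> tuple[np.ndarray, list[np.ndarray]]:
    """Shrake-Rupley: per-atom area and the exposed surface points."""
    inflated = radii + probe
    unit = _sphere_points(n_points)
    tree = cKDTree(coords)
    areas = np.zeros(len(coords))
    exposed_points: list[np.ndarray] = []
    rmax = inflated.max()
    for i in range(len(coords)):
        pts = coords[i] + inflated[i] * unit
        neighbours = tree.query_ball_point(coords[i], inflated[i] + rmax)
        neighbours = [j for j in neighbours if j != i]
        if neighbours:
            d = cdist(pts, coords[neighbours])
            buried = (d < inflated[neighbours] - 1e-9).any(axis=1)
        else:
            buried = np.zeros(len(pts), dtype=bool)
        n_exposed = int((~buried).sum())
        areas[i] = 4.0 * np.pi * inflated[i] ** 2 * n_exposed / n_points
        if n_exposed:
            exposed_points.append(pts[~buried])
    return areas, exposed_points


def sasa(model: StructureModel, probe: float = 1.4, n_points: int = 960) -> SasaProfile:
    """Shrake-Rupley solvent-accessible surface area per residue.

    Per-atom areas are summed within each residue; relative ASA divides
    by a per-residue-type reference maximum (theoretical Gly-X-Gly
    values), so extended termini can exceed 100%.
    """
    coords, radii, res_index = _atom_table(model)
    areas, _pts = _per_atom_sasa(coords, radii, probe, n_points)
    absolute: dict[tuple[str, int, str], float] = {}
    relative: dict[tuple[str, int, str], float] = {}
    for i, res in enumerate(model.residues):
        area = float(areas[res_index == i].sum())
        absolute[res.key] = area
        ref = MAX_ASA.get(res.aa)
        relative[res.key] = 100.0 * area / ref if ref else float("nan")
    return SasaProfile(absolute=absolute, relative=relative, total=float(areas.sum()))


def residue_depth(
    model: StructureModel,
    probe: float = 1.4,
    n_points: int = 240,
    aggregate: str = "mean",
) -> DepthProfile:
    """Per-residue depth from the solvent-accessible surface (Angstrom).

    The accessible surface is approximated by the exposed probe-inflated
    sphere points of the Shrake-Rupley calculation; each residue's depth
    is the mean (default) or minimum over its heavy atoms of the distance
    to the nearest surface point.  An isolated atom has depth equal to
    its own inflated radius (atom radius + probe).
    """
    if aggregate not in ("mean", "min"):
        raise ValueError(f"unknown aggregate {aggregate!r}")
    coords, radii, res_index = _atom_table(model)
    _areas, exposed = _per_atom_sasa(coords, radii, probe, n_points)
    if not exposed:
        raise ValueError("structure has no solvent-accessible surface points")
    surface = np.vstack(exposed)
    tree = cKDTree(surface)
    atom_depth, _idx = tree.query(coords)
    depths: dict[tuple[str, int, str], float] = {}
    for i, res in enumerate(model.residues):
        vals = atom_depth[res_index == i]
        depths[res.key] = float(vals.mean() if aggregate == "mean" else vals.min())
    return DepthProfile(depths=depths)
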