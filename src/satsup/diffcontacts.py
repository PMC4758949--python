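"""Differential contact analysis of two rival structures of one protein.

When the same protein has two incompatible experimental structures (for
example an X-ray crystal structure and a domain-swapped NMR model),
residue pairs in contact in one but not the other ("differential
contacts") identify positions where second-site suppressor experiments
can arbitrate: a suppressor restoring a parent inactive mutant is
expected only at positions that actually pack against it in the
functional conformer.

Contacts are defined by side-chain centroid distance <= 7 A (minimised
over chain pairings of the oligomer).  Candidate parent-inactive-mutant
positions pass five filters: (i) not charged; (ii) no side-chain
hydrogen bond to a partner; (iii) at least two contact partners in one
of the structures; (iv) sequence separation from partners > 30; (v)
positionally divergent partner sets between the structures (minimum
cross-structure partner index difference > 6).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from satsup import geometry
from satsup.structio import StructureEnsemble, StructureModel

logger = logging.getLogger(__name__)

CHARGED = set("DEKR")
#: side-chain nitrogen/oxygen atoms that can donate or accept H-bonds
_SC_POLAR_ELEMENTS = ("N", "O")
HBOND_CUTOFF = 3.5


@dataclass
class ContactMap:
    """Position-level contacts: (x, y) -> minimum centroid distance (A)."""

    distances: dict[tuple[int, int], float]
    cutoff: float
    inter_helical: bool = False

    def __post_init__(self) -> None:
        fixed = {}
        for (x, y), d in self.distances.items():
            if x == y:
                continue
            fixed[(min(x, y), max(x, y))] = d
        self.distances = fixed

    @property
    def pairs(self) -> set[tuple[int, int]]:
        return set(self.distances)

    def partners_of(self, pos: int) -> set[int]:
        out = set()
        for x, y in self.distances:
            if x == pos:
                out.add(y)
            elif y == pos:
                out.add(x)
        return out

    def positions(self) -> set[int]:
        return {p for pair in self.distances for p in pair}


@dataclass
class CandidateRecord:
    """Per-candidate filter outcome."""

    position: int
    partners_a: set[int]
    partners_b: set[int]
    charged_removed: bool = False
    hbond_excluded: bool = False
    min_partner_count: bool = False
    seq_separation: bool = False
    partner_divergence: bool = False
    selected: bool = False


@dataclass
class DifferentialContactReport:
    """All candidate positions with criteria flags."""

    candidates: list[CandidateRecord] = field(default_factory=list)

    @property
    def selected_positions(self) -> set[int]:
        return {c.position for c in self.candidates if c.selected}

    def record(self, position: int) -> CandidateRecord:
        for c in self.candidates:
            if c.position == position:
                return c
        raise KeyError(position)


@dataclass
class SuppressorSupport:
    """Verdict for one (parent-inactive-mutant, suppressor) pair."""

    pim_pos: int
    sup_pos: int
    dist_a: float
    dist_b: float
    verdict: str  # supports_A | supports_B | both | neither


def _helix_of(pos: int, helices: list[tuple[str, int, int]]) -> set[tuple[int, int]]:
    """Helix segments (as seq ranges) containing the position."""
    return {(start, end) for (_c, start, end) in helices if start <= pos <= end}


def _position_min_centroid_matrix(
    models: list[StructureModel],
) -> tuple[list[int], np.ndarray]:
    """Minimum centroid distance between author positions over chain
    pairings and over the given poses."""
    positions = sorted({r.seq_num for r in models[0].residues if r.aa != "X"})
    pos_index = {p: i for i, p in enumerate(positions)}
    n = len(positions)
    best = np.full((n, n), np.inf)
    for model in models:
        residues = [r for r in model.residues if r.aa != "X"]
        cents = np.array([geometry.sidechain_centroid(r) for r in residues])
        idx = np.array([pos_index[r.seq_num] for r in residues])
        d = cdist(cents, cents)
        np.fill_diagonal(d, np.inf)  # a residue is not its own partner
        for i in range(len(residues)):
            row = d[i]
            pi = idx[i]
            np.minimum.at(best[pi], idx, row)
    best = np.minimum(best, best.T)
    return positions, best


def contact_map(
    structure: StructureEnsemble,
    cutoff: float = 7.0,
    pose: int | str = 1,
    inter_helical_only: bool = False,
    exclude_range: tuple[int, int] | None = None,
) -> ContactMap:
    """Position-level contact map of a structure.

    Pairs with minimum-over-chain-pairings side-chain centroid distance
    <= ``cutoff`` are contacts.  ``pose`` selects one model (1-based) or
    ``"min_over_poses"`` to take the per-pair minimum over every pose of
    an ensemble.  ``inter_helical_only`` removes pairs lying within one
    helix segment (requires helix annotations).  ``exclude_range``
    removes pairs touching a residue interval, e.g. a mobile terminus
    identified by high ensemble RMSF.
    """
    if pose == "min_over_poses":
        models = structure.models
    else:
        if not 1 <= int(pose) <= structure.n_models:
            raise IndexError(f"pose {pose} out of range 1..{structure.n_models}")
        models = [structure.models[int(pose) - 1]]
    if inter_helical_only and not structure.helices:
        raise ValueError("inter_helical_only requires helix annotations")

    positions, dmat = _position_min_centroid_matrix(models)
    distances: dict[tuple[int, int], float] = {}
    for i, x in enumerate(positions):
        for j in range(i + 1, len(positions)):
            y = positions[j]
            d = dmat[i, j]
            if d > cutoff:
                continue
            if exclude_range is not None:
                lo, hi = exclude_range
                if lo <= x <= hi or lo <= y <= hi:
                    continue
            if inter_helical_only:
                shared = _helix_of(x, structure.helices) & _helix_of(y, structure.helices)
                if shared:
                    continue
            distances[(x, y)] = float(d)
    return ContactMap(distances=distances, cutoff=cutoff, inter_helical=inter_helical_only)


def _sidechain_polar_coords(model: StructureModel, pos: int) -> np.ndarray:
    pts = []
    for res in model.residues_at(pos):
        for a in res.heavy_atoms:
            if a.name in ("N", "O", "OXT"):
                continue
            if a.element in _SC_POLAR_ELEMENTS:
                pts.append(a.coords)
    return np.array(pts, float) if pts else np.empty((0, 3))


def _has_sidechain_hbond(model: StructureModel, x: int, y: int) -> bool:
    a = _sidechain_polar_coords(model, x)
    b = _sidechain_polar_coords(model, y)
    if a.size == 0 or b.size == 0:
        return False
    return bool(cdist(a, b).min() <= HBOND_CUTOFF)


def select_pim_candidates(
    map_a: ContactMap,
    map_b: ContactMap,
    struct_a: StructureEnsemble,
    struct_b: StructureEnsemble,
    min_partners: int = 2,
    min_sep: int = 30,
    min_partner_shift: int = 6,
) -> DifferentialContactReport:
    """Select candidate parent-inactive-mutant positions.

    Candidates are positions appearing in at least one contact map with
    differing partner sets between the two structures; the five filters
    described in the module docstring are then applied in order.  When a
    position has partners left in only one structure after the
    sequence-separation filter, the partner sets are maximally divergent
    and the divergence criterion passes vacuously.
    """
    seq_a = struct_a.first.sequence
    seq_b = struct_b.first.sequence
    if len(seq_a) != len(seq_b):
        raise ValueError(
            f"sequence length mismatch between structures ({len(seq_a)} vs {len(seq_b)})"
        )
    aa_at = {r.seq_num: r.aa for r in struct_a.first.residues}

    report = DifferentialContactReport()
    all_positions = sorted(map_a.positions() | map_b.positions())
    for x in all_positions:
        pa, pb = map_a.partners_of(x), map_b.partners_of(x)
        if pa == pb:
            continue  # not a differential-contact position
        rec = CandidateRecord(position=x, partners_a=set(pa), partners_b=set(pb))
        report.candidates.append(rec)
        # (i) charged parent positions removed
        rec.charged_removed = aa_at.get(x, "X") not in CHARGED
        # (ii) no side-chain hydrogen bond between X and any partner
        hb_a = any(_has_sidechain_hbond(struct_a.first, x, y) for y in pa)
        hb_b = any(_has_sidechain_hbond(struct_b.first, x, y) for y in pb)
        rec.hbond_excluded = not (hb_a or hb_b)
        # (iii) >=2 partners in at least one structure
        rec.min_partner_count = max(len(pa), len(pb)) >= min_partners
        # (iv) sequence separation |X - Y| > min_sep, per structure
        sep_a = {y for y in pa if abs(x - y) > min_sep}
        sep_b = {y for y in pb if abs(x - y) > min_sep}
        rec.seq_separation = bool(sep_a or sep_b)
        # (v) partner sets positionally divergent
        if sep_a and sep_b:
            shift = min(abs(yb - ya) for ya in sep_a for yb in sep_b)
            rec.partner_divergence = shift > min_partner_shift
        else:
            rec.partner_divergence = True  # vacuous: partners in one structure only
        rec.selected = all(
            (
                rec.charged_removed,
                rec.hbond_excluded,
                rec.min_partner_count,
                rec.seq_separation,
                rec.partner_divergence,
            )
        )
    return report


def evaluate_suppressor_support(
    pairs: list[tuple[int, int]],
    struct_a: StructureEnsemble,
    struct_b: StructureEnsemble,
    cutoff: float = 7.0,
    pose: int | str = 1,
) -> list[SuppressorSupport]:
    """Judge which structure each suppressor pair supports.

    Per pair, the minimum side-chain centroid distance is measured in
    each structure (pose 1 of an ensemble by default); a pair supports
    the structure(s) in which it lies within the cutoff.  Unresolvable
    positions yield a per-pair error entry; other pairs proceed.
    """

    def _min_dist(struct: StructureEnsemble, x: int, y: int) -> float:
        models = struct.models if pose == "min_over_poses" else [struct.models[int(pose) - 1]]
        return min(geometry.min_pair_distance(m, x, y, metric="centroid") for m in models)

    out: list[SuppressorSupport] = []
    for x, y in pairs:
        try:
            da = _min_dist(struct_a, x, y)
            db = _min_dist(struct_b, x, y)
        except KeyError as exc:
            logger.error("pair (%d, %d) skipped: %s", x, y, exc)
            out.append(
                SuppressorSupport(
                    pim_pos=x, sup_pos=y, dist_a=float("nan"), dist_b=float("nan"),
                    verdict="error",
                )
            )
            continue
        close_a, close_b = da <= cutoff, db <= cutoff
        verdict = {
            (True, True): "both",
            (True, False): "supports_A",
            (False, True): "supports_B",
            (False, False): "neither",
        }[(close_a, close_b)]
        out.append(
            SuppressorSupport(pim_pos=x, sup_pos=y, dist_a=da, dist_b=db, verdict=verdict)
        )
    return out
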