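"""Seeded synthetic inputs for every pipeline stage.

Each generator is a pure function of its parameters and a seed, and
returns its ground truth alongside the data, so every downstream
operation has a closed-loop recovery test that needs no external
download:

* helical-bundle "native" structures and decoy sets spanning a target
  backbone-RMSD range (Cartesian window-correlated noise);
* paired rival conformations of one bundle, where two helices exchange
  packing interfaces ("domain swap"), with the list of residue pairs
  close in conformation A and far in B returned as truth;
* per-mutant read-count tables whose fivefold-drop structure encodes
  planted MS_seq values, with optional overdispersed counting noise;
* depth-dependent mutational-sensitivity tables following the
  buried/exposed substitution motifs (aliphatics tolerated when buried,
  everything tolerated when exposed);
* four-parameter sigmoid melt curves with known Tm.

Decoy perturbation operates in Cartesian space (per-residue displacement
shared within a correlation window) rather than in dihedral space: it
guarantees coverage of a target RMSD range without a folding engine, and
none of the scorers here consume covalent geometry.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from satsup import geometry
from satsup.geometry import DepthProfile
from satsup.mutsens import AA_GROUPS, MutSensTable, ReadCountTable
from satsup.meltfit import MeltCurve, sigmoid
from satsup.structio import Atom, Residue, StructureEnsemble, StructureModel

import pandas as pd

_HELIX_RADIUS = 2.3        # A, CA distance from helix axis
_HELIX_RISE = 1.5          # A per residue
_HELIX_TURN = np.deg2rad(100.0)
_BUNDLE_RADIUS = 6.5       # A, ring-layout helix axes from bundle axis
_PACKED_RADIUS = 9.5       # A, ring radius around the central helix
_CB_EXTENSION = 1.5        # A, CB radially beyond CA


@dataclass
class DecoySpec:
    """Decoy-set recipe: model count, displacement amplitudes, smoothing."""

    n_models: int = 100
    noise_amplitudes: tuple[float, ...] = (0.5, 1.0, 2.0, 4.0, 8.0)
    correlation_length: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_models < 1:
            raise ValueError("n_models must be >= 1")
        if any(a < 0 for a in self.noise_amplitudes):
            raise ValueError("amplitudes must be non-negative")


@dataclass
class SynthMutSpec:
    """Depth-to-sensitivity mapping for synthetic MS_seq tables."""

    slope: float = 1.0
    intercept: float = 0.0
    noise_sd: float = 0.1
    mutants_per_position: int = 19
    seed: int = 0

    def __post_init__(self) -> None:
        if not 1 <= self.mutants_per_position <= 19:
            raise ValueError("mutants_per_position must be in 1..19")


def _helix_frame(slot: int, n_helices: int, layout: str) -> tuple[np.ndarray, float, int]:
    if layout == "packed" and slot == 0:
        return np.zeros(3), 0.0, 1  # buried central helix
    if layout == "packed":
        phi = 2.0 * np.pi * (slot - 1) / (n_helices - 1)
        radius = _PACKED_RADIUS
    else:
        phi = 2.0 * np.pi * slot / n_helices
        radius = _BUNDLE_RADIUS
    axis_origin = radius * np.array([np.cos(phi), np.sin(phi), 0.0])
    direction = 1 if slot % 2 == 0 else -1  # antiparallel packing
    return axis_origin, phi, direction


def _build_helix(
    slot: int,
    n_helices: int,
    helix_len: int,
    start_seq: int,
    chain_id: str = "A",
    layout: str = "ring",
) -> list[Residue]:
    """Idealised poly-alanine helix (N, CA, C, O, CB) at a bundle slot."""
    origin, phi, direction = _helix_frame(slot, n_helices, layout)
    z0 = -0.5 * _HELIX_RISE * (helix_len - 1)
    residues = []
    for i in range(helix_len):
        t = float(i)

        def on_curve(tt: float, radius: float = _HELIX_RADIUS) -> np.ndarray:
            ang = _HELIX_TURN * tt + phi  # phase offset keeps slots asymmetric
            local = np.array(
                [radius * np.cos(ang), radius * np.sin(ang),
                 z0 + _HELIX_RISE * tt * direction]
            )
            return origin + local

        ca = on_curve(t)
        n = on_curve(t - 0.35)
        c = on_curve(t + 0.45)
        o = on_curve(t + 0.45, radius=_HELIX_RADIUS + 1.2)
        # CB points radially away from the helix axis
        radial = ca - origin
        radial[2] = 0.0
        radial /= np.linalg.norm(radial)
        cb = ca + _CB_EXTENSION * radial + np.array([0.0, 0.0, 0.5 * direction])
        residues.append(
            Residue(
                chain_id=chain_id,
                seq_num=start_seq + i,
                icode="",
                aa="A",
                atoms=[
                    Atom("N", "N", n),
                    Atom("CA", "C", ca),
                    Atom("C", "C", c),
                    Atom("O", "O", o),
                    Atom("CB", "C", cb),
                ],
            )
        )
    return residues


def helical_bundle(
    n_helices: int = 4,
    helix_len: int = 15,
    seq_gap: int = 5,
    slot_of_helix: list[int] | None = None,
    jitter_sd: float = 0.0,
    seed: int = 0,
    layout: str = "ring",
) -> StructureEnsemble:
    """An idealised antiparallel helical bundle as a single-chain model.

    Helix k occupies bundle slot ``slot_of_helix[k]`` (identity by
    default); residue numbering leaves a ``seq_gap`` between helices to
    mimic omitted loops.  ``jitter_sd`` adds seeded Gaussian coordinate
    noise.  ``layout="ring"`` places all helix axes on one circle;
    ``layout="packed"`` buries slot 0 at the bundle axis inside a ring
    of the remaining helices, giving the structure a genuinely buried
    core (useful wherever residue depth must vary).
    """
    if n_helices < 2:
        raise ValueError("need >= 2 helices")
    slots = slot_of_helix if slot_of_helix is not None else list(range(n_helices))
    if sorted(slots) != list(range(n_helices)):
        raise ValueError("slot_of_helix must be a permutation of 0..n_helices-1")
    rng = np.random.default_rng(seed)
    residues: list[Residue] = []
    helices: list[tuple[str, int, int]] = []
    for k in range(n_helices):
        start = 1 + k * (helix_len + seq_gap)
        residues.extend(_build_helix(slots[k], n_helices, helix_len, start, layout=layout))
        helices.append(("A", start, start + helix_len - 1))
    if jitter_sd > 0:
        for res in residues:
            for atom in res.atoms:
                atom.coords = atom.coords + rng.normal(0.0, jitter_sd, 3)
    model = StructureModel(model_index=1, residues=residues)
    return StructureEnsemble(id="bundle", models=[model], helices=helices)


def synthetic_native(n_helices: int = 7, helix_len: int = 10, seed: int = 0) -> StructureModel:
    """A compact synthetic globule used as the decoy-set reference.

    Packed layout (central helix plus a ring) so that depth varies from
    a buried core to an exposed shell.
    """
    return helical_bundle(
        n_helices=n_helices, helix_len=helix_len, seed=seed, layout="packed"
    ).first


def compact_globule(n_residues: int = 60, seed: int = 0, spacing: float = 3.6) -> StructureModel:
    """A space-filling synthetic globule with a real buried core.

    Residues sit on the innermost points of a jittered cubic lattice
    (CA spacing ~3.6 A) with small fixed offsets for N, C, O and CB, so
    the interior is probe-excluded and residue depth spans from the
    probe floor at the surface to several Angstrom in the core.  Used
    wherever depth or accessibility must vary; the helical bundles stay
    hollow and nearly uniformly exposed.
    """
    if n_residues < 2:
        raise ValueError("need >= 2 residues")
    rng = np.random.default_rng(seed)
    half = int(np.ceil((n_residues ** (1 / 3)))) + 2
    grid = np.array(
        [(i, j, k) for i in range(-half, half + 1)
         for j in range(-half, half + 1) for k in range(-half, half + 1)],
        dtype=float,
    )
    grid *= spacing
    order = np.argsort((grid ** 2).sum(axis=1), kind="stable")
    points = grid[order[:n_residues]] + rng.normal(0.0, 0.25, (n_residues, 3))
    offsets = {
        "N": np.array([-1.2, 0.0, 0.0]),
        "CA": np.zeros(3),
        "C": np.array([1.2, 0.0, 0.0]),
        "O": np.array([1.2, 1.0, 0.0]),
        "CB": np.array([0.0, -1.0, 1.0]),
    }
    elements = {"N": "N", "CA": "C", "C": "C", "O": "O", "CB": "C"}
    residues = [
        Residue(
            chain_id="A", seq_num=i + 1, icode="", aa="A",
            atoms=[Atom(n, elements[n], points[i] + off) for n, off in offsets.items()],
        )
        for i in range(n_residues)
    ]
    return StructureModel(model_index=1, residues=residues)


def generate_decoys(
    native: StructureModel, spec: DecoySpec
) -> tuple[list[tuple[str, StructureModel]], list[float]]:
    """Perturbed copies of a native model with known backbone RMSD.

    Each decoy displaces every residue by a spatially correlated Gaussian
    vector (moving-average smoothing over ``correlation_length``
    residues, rescaled to the model's amplitude, drawn cyclically from
    ``noise_amplitudes``).  Returns (id, model) pairs and the true
    backbone RMSD of each decoy to the native, computed by Kabsch
    superposition.
    """
    if len(native.residues) < 20:
        raise ValueError("native must have >= 20 residues")
    rng = np.random.default_rng(spec.seed)
    n_res = len(native.residues)
    w = max(1, int(spec.correlation_length))
    kernel = np.ones(w) / w
    decoys: list[tuple[str, StructureModel]] = []
    rmsds: list[float] = []
    for m in range(spec.n_models):
        amplitude = spec.noise_amplitudes[m % len(spec.noise_amplitudes)]
        raw = rng.normal(size=(n_res, 3))
        disp = np.column_stack(
            [np.convolve(raw[:, k], kernel, mode="same") for k in range(3)]
        )
        rms = np.sqrt((disp ** 2).sum(axis=1).mean())
        if rms > 0 and amplitude > 0:
            disp *= amplitude / rms
        else:
            disp[:] = 0.0
        residues = []
        for i, res in enumerate(native.residues):
            residues.append(
                Residue(
                    chain_id=res.chain_id,
                    seq_num=res.seq_num,
                    icode=res.icode,
                    aa=res.aa,
                    atoms=[
                        Atom(a.name, a.element, a.coords + disp[i], a.altloc, a.occupancy)
                        for a in res.atoms
                    ],
                )
            )
        model = StructureModel(model_index=m + 1, residues=residues)
        model_id = f"decoy_{m:04d}"
        decoys.append((model_id, model))
        rmsds.append(geometry.superpose(model, native, atom_set="backbone").rmsd)
    return decoys, rmsds


def generate_toy_conformation_pair(
    n_helices: int = 4,
    swap: bool = True,
    seed: int = 0,
    helix_len: int = 15,
    cutoff: float = 7.0,
    close_margin: float = 0.5,
    far_margin: float = 1.0,
) -> tuple[StructureEnsemble, StructureEnsemble, list[tuple[int, int]]]:
    """Two rival conformations of one bundle with known differential pairs.

    Conformation A is the plain bundle; in conformation B two helices
    exchange bundle slots (a domain-swap-like rearrangement), so residue
    pairs packed together in A end up across the bundle in B.  The
    returned truth lists inter-helix pairs with centroid distance
    <= cutoff - close_margin in A and > cutoff + far_margin in B; with
    ``swap=False`` the structures are identical and the list is empty.
    """
    ens_a = helical_bundle(
        n_helices=n_helices, helix_len=helix_len, jitter_sd=0.1, seed=seed
    )
    if swap and n_helices >= 3:
        slots = list(range(n_helices))
        slots[1], slots[2] = slots[2], slots[1]
    else:
        slots = list(range(n_helices))
    ens_b = helical_bundle(
        n_helices=n_helices, helix_len=helix_len, slot_of_helix=slots,
        jitter_sd=0.1, seed=seed + 1,
    )
    planted: list[tuple[int, int]] = []
    if swap and n_helices >= 3:
        a, b = ens_a.first, ens_b.first
        res_a = {r.seq_num: r for r in a.residues}
        res_b = {r.seq_num: r for r in b.residues}
        helix_of = {}
        for h, (_c, start, end) in enumerate(ens_a.helices):
            for s in range(start, end + 1):
                helix_of[s] = h
        nums = sorted(res_a)
        for i, x in enumerate(nums):
            for y in nums[i + 1:]:
                if helix_of[x] == helix_of[y]:
                    continue
                da = geometry.centroid_distance(res_a[x], res_a[y])
                db = geometry.centroid_distance(res_b[x], res_b[y])
                if da <= cutoff - close_margin and db > cutoff + far_margin:
                    planted.append((x, y))
    return ens_a, ens_b, planted


def simulate_reads(
    ms_truth: MutSensTable,
    depth_of_coverage: int = 1000,
    noise: float = 0.02,
    seed: int = 0,
    mid_levels: tuple[int, ...] = tuple(range(1, 10)),
    drop_ratio: float = 8.0,
) -> ReadCountTable:
    """Read-count tables whose drop structure encodes planted MS_seq.

    MID level 1 is the fully repressed condition at which every obtained
    mutant survives; a mutant with MS_seq = k keeps ~``depth_of_coverage``
    reads up to level k-1 and drops by ``drop_ratio`` (> the fivefold
    detection threshold) from level k onwards.  ``noise`` is a
    negative-binomial overdispersion (variance = mu + noise * mu^2);
    zero noise gives exact deterministic counts.  Planted MS_seq 0 rows
    are all-zero.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for (pos, mut), ms in sorted(ms_truth.values.items()):
        row = {"position": pos, "wt_aa": ms_truth.wt.get(pos, "X"), "mut_aa": mut}
        for level in mid_levels:
            if ms == 0:
                mu = 0.0
            elif level < ms:
                mu = float(depth_of_coverage)
            else:
                mu = depth_of_coverage / drop_ratio
            if mu == 0.0:
                count = 0
            elif noise <= 0:
                count = int(round(mu))
            else:
                n_param = 1.0 / noise
                p_param = n_param / (n_param + mu)
                count = int(rng.negative_binomial(n_param, p_param))
            row[f"mid_{level}"] = count
        rows.append(row)
    frame = pd.DataFrame(rows)
    return ReadCountTable(frame=frame)


_MS_SPAN = {  # substitution-class sensitivity span with burial
    "aliphatic": 2.0,
    "aromatic": 5.0,
    "polar": 7.0,
    "charged": 7.0,
    "gly_pro": 7.0,
}


def generate_ms_from_depth(
    depths: DepthProfile, spec: SynthMutSpec, wt_aa: str = "A"
) -> MutSensTable:
    """Synthetic MS_seq tables whose position means track residue depth.

    Depth is normalised to [0, 1]; the burial signal u = clip(intercept
    + slope * depth_norm + noise).  Substitutions follow the canonical
    motifs: aliphatic replacements stay tolerated even when buried
    (MS_seq 2-4), polar/charged ones become highly sensitive with burial
    (up to 9), so mean sensitivity -- and hence RankScore -- increases
    with depth.
    """
    depth_by_pos = depths.by_position()
    if not depth_by_pos:
        raise ValueError("empty depth profile")
    rng = np.random.default_rng(spec.seed)
    vals = np.array(list(depth_by_pos.values()))
    lo, hi = vals.min(), vals.max()
    span = hi - lo if hi > lo else 1.0
    choices = [a for a in "ACDEFGHIKLMNPQRSTVWY" if a != wt_aa]
    values: dict[tuple[int, str], int] = {}
    wt: dict[int, str] = {}
    for pos, depth in sorted(depth_by_pos.items()):
        z = (depth - lo) / span
        wt[pos] = wt_aa
        if spec.mutants_per_position >= len(choices):
            aas = choices
        else:
            aas = sorted(rng.choice(choices, spec.mutants_per_position, replace=False))
        for j, aa in enumerate(aas):
            u = spec.intercept + spec.slope * z
            if spec.noise_sd > 0:
                u += rng.normal(0.0, spec.noise_sd)
            u = float(np.clip(u, 0.0, 1.0))
            # deterministic per-substitution dither so the position mean
            # varies smoothly with burial instead of in coarse steps
            dither = (j + 0.5) / len(aas)
            ms = 2 + int(np.floor(_MS_SPAN[AA_GROUPS[aa]] * u + dither))
            values[(pos, aa)] = int(np.clip(ms, 2, 9))
    return MutSensTable(values=values, wt=wt)


def simulate_melt(
    params: tuple[float, float, float, float],
    T_grid: np.ndarray,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> MeltCurve:
    """A melt curve from the four-parameter sigmoid plus Gaussian noise."""
    LL, UL, a, Tm = params
    T = np.asarray(T_grid, float)
    if not np.all(np.diff(T) > 0):
        raise ValueError("temperature grid must be ascending")
    y = sigmoid(T, LL, UL, a, Tm)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        y = y + rng.normal(0.0, noise_sd, size=T.shape)
    return MeltCurve(T=T, y=y)


def random_ms_truth(
    n_positions: int = 30,
    mutants_per_position: int = 10,
    p_absent: float = 0.05,
    seed: int = 0,
) -> MutSensTable:
    """A random MS_seq table (uniform strata, a few absent mutants)."""
    rng = np.random.default_rng(seed)
    values: dict[tuple[int, str], int] = {}
    wt: dict[int, str] = {}
    aas = list("CDEFGHIKLMNPQRSTVWY")
    for pos in range(1, n_positions + 1):
        wt[pos] = "A"
        for aa in rng.choice(aas, size=min(mutants_per_position, len(aas)), replace=False):
            if rng.random() < p_absent:
                values[(pos, str(aa))] = 0
            else:
                values[(pos, str(aa))] = int(rng.integers(2, 10))
    return MutSensTable(values=values, wt=wt)
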