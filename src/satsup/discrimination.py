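"""Decoy-model discrimination by experimentally derived constraints.

Three per-model metrics are computed over a decoy set of known backbone
RMSD to a reference structure:

* **ContactScore (CSc)** - the number of experimentally determined
  (parent-inactive-mutant, proximal-suppressor) residue pairs whose
  side-chain centroids lie within a cutoff (default strict < 7 A) in the
  model.  With n pairs the score is an integer in [0, n].
* **rdepthscore** - the correlation coefficient (Pearson by default) of
  per-position RankScore against model-derived residue depth, computed
  over non-active-site positions.  Native-like models bury the
  mutation-sensitive residues and score higher.
* **R_s** - a packing-deviation statistic: the summed relative deviation
  of per-residue accessible surface area from reference average values,
  ``sum_i |ASA_xi - <ASA_x>| / <ASA_x>``; lower means more native-like
  packing.

Recovery histograms report, per 0.5-A RMSD bin, the fraction of models
selected by a metric predicate; bins are half-open (lower, upper] and
labelled by their upper edge.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import pearsonr, spearmanr

from satsup import geometry
from satsup.geometry import DepthProfile, SasaProfile
from satsup.mutsens import RankScoreTable
from satsup.structio import StructureModel, read_pdb

logger = logging.getLogger(__name__)

#: CcdB active-site positions deducible from mutational-sensitivity
#: patterns alone; excluded from depth-correlation scoring because their
#: sensitivity reflects function, not burial.
CCDB_ACTIVE_SITE = frozenset({2, 3, 6, 22, 24, 95, 99, 100, 101})


@dataclass
class ContactPairSet:
    """Experimentally derived residue-pair constraints."""

    pairs: list[tuple[int, int]]
    cutoff: float = 7.0
    annotations: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        for x, y in self.pairs:
            if x == y:
                raise ValueError(f"degenerate pair ({x}, {y})")
        if not self.pairs:
            logger.warning("empty contact pair set")

    @property
    def n(self) -> int:
        return len(self.pairs)


@dataclass
class ReferenceAsaTable:
    """Per-residue-type average ASA <ASA_x> (A^2)."""

    values: dict[str, float]

    def __post_init__(self) -> None:
        missing = set("ACDEFGHIKLMNPQRSTVWY") - set(self.values)
        if missing:
            raise ValueError(f"reference ASA table missing residue types {sorted(missing)}")
        if any(v <= 0 for v in self.values.values()):
            raise ValueError("reference ASA values must be positive")

    @classmethod
    def default(cls) -> "ReferenceAsaTable":
        from satsup.refdata import default_mean_asa

        return cls(values=default_mean_asa())


@dataclass
class ModelScore:
    """Per-decoy metrics."""

    model_id: str
    rmsd: float
    contact_score: int
    rdepth_score: float | None = None
    r_s: float | None = None
    error: str | None = None


@dataclass
class RecoveryHistogram:
    """Per-RMSD-bin recovery of models selected by a predicate."""

    edges: np.ndarray            # bin edges, len = n_bins + 1
    totals: np.ndarray           # models per bin
    selected: np.ndarray         # selected models per bin
    recovery: np.ndarray         # selected/total, NaN where the bin is empty

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_upper": self.edges[1:],
                "models_total": self.totals,
                "models_selected": self.selected,
                "recovery": self.recovery,
            }
        )


def contact_score(model: StructureModel, pairs: ContactPairSet) -> int:
    """Count constraint pairs satisfied in the model.

    A pair (x, y) is satisfied when the side-chain centroid distance,
    minimised over chain pairings for oligomers, is strictly below the
    pair set's cutoff.
    """
    if pairs.n == 0:
        raise ValueError("contact_score needs >=1 pair")
    unresolved = []
    score = 0
    for x, y in pairs.pairs:
        try:
            d = geometry.min_pair_distance(model, x, y, metric="centroid")
        except KeyError:
            unresolved.append((x, y))
            continue
        if d < pairs.cutoff:
            score += 1
    if unresolved:
        raise KeyError(f"positions unresolvable in model: {unresolved}")
    return score


def rdepth_score(
    ranks: RankScoreTable,
    depths: DepthProfile,
    exclude: Iterable[int] = (),
    method: str = "pearson",
) -> float:
    """Correlation of RankScore vs residue depth over shared positions.

    ``exclude`` removes active-site positions, whose mutational
    sensitivity reflects function rather than burial.  Raises on fewer
    than 3 shared positions or zero variance in either vector.
    """
    exclude = set(exclude)
    depth_by_pos = depths.by_position()
    shared = [p for p in ranks.positions() if p in depth_by_pos and p not in exclude]
    if len(shared) < 3:
        raise ValueError(f"only {len(shared)} shared positions after exclusions; need >=3")
    x = np.array([ranks[p] for p in shared])
    y = np.array([depth_by_pos[p] for p in shared])
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance: rdepthscore undefined")
    if method == "pearson":
        r = pearsonr(x, y).statistic
    elif method == "spearman":
        r = spearmanr(x, y).statistic
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(r)


def rs_score(sasa_profile: SasaProfile, ref: ReferenceAsaTable, model: StructureModel) -> float:
    """Packing-deviation score R_s over all chain residues.

    ``sum_i |ASA_xi - <ASA_x>| / <ASA_x>`` with x the residue type at
    position i.  Residues of unknown type ('X') are skipped.
    """
    total = 0.0
    for res in model.residues:
        if res.aa == "X":
            continue
        mean = ref.values.get(res.aa)
        if mean is None:
            raise KeyError(f"no reference ASA for residue type {res.aa!r}")
        total += abs(sasa_profile.absolute[res.key] - mean) / mean
    return total


def _iter_decoys(decoys) -> Iterable[tuple[str, StructureModel]]:
    if isinstance(decoys, (str, Path)):
        paths = sorted(Path(decoys).glob("*.pdb"))
        for p in paths:
            yield p.stem, read_pdb(p).first
    else:
        for item in decoys:
            if isinstance(item, tuple):
                yield item
            else:
                yield getattr(item, "model_id", str(item.model_index)), item


def score_decoys(
    decoys,
    reference: StructureModel,
    pairs: ContactPairSet,
    ranks: RankScoreTable | None = None,
    ref_asa: ReferenceAsaTable | None = None,
    exclude_active_site: Iterable[int] = (),
    atom_set: str = "backbone",
) -> list[ModelScore]:
    """Score a decoy set against a reference structure.

    ``decoys`` is a directory of PDB files or an iterable of
    (id, StructureModel) pairs.  Per model: backbone RMSD to the
    reference after superposition, ContactScore, and optionally
    rdepthscore (if ``ranks`` given; depth recomputed per model) and R_s
    (if ``ref_asa`` given).  Per-model failures are logged and recorded
    on the returned entry; the run continues.
    """
    out: list[ModelScore] = []
    for model_id, model in _iter_decoys(decoys):
        try:
            sup = geometry.superpose(model, reference, atom_set=atom_set)
            csc = contact_score(model, pairs)
            rdepth = None
            if ranks is not None:
                depths = geometry.residue_depth(model)
                rdepth = rdepth_score(ranks, depths, exclude=exclude_active_site)
            rs = None
            if ref_asa is not None:
                prof = geometry.sasa(model)
                rs = rs_score(prof, ref_asa, model)
            out.append(
                ModelScore(
                    model_id=model_id,
                    rmsd=sup.rmsd,
                    contact_score=csc,
                    rdepth_score=rdepth,
                    r_s=rs,
                )
            )
        except Exception as exc:  # per-model failure must not kill the run
            logger.error("decoy %s failed: %s", model_id, exc)
            out.append(
                ModelScore(
                    model_id=model_id, rmsd=float("nan"), contact_score=-1, error=str(exc)
                )
            )
    return out


def recovery_histogram(
    scores: Sequence[ModelScore],
    select: Callable[[ModelScore], bool],
    bin_width: float = 0.5,
) -> RecoveryHistogram:
    """Fraction of models per RMSD bin satisfying a selection predicate.

    Bins are half-open (lower, upper] of fixed width starting at 0;
    recovery is NaN in empty bins.
    """
    good = [s for s in scores if s.error is None and np.isfinite(s.rmsd)]
    if not good:
        raise ValueError("no scored models")
    rmsds = np.array([s.rmsd for s in good])
    n_bins = int(np.ceil(rmsds.max() / bin_width)) or 1
    edges = np.arange(0, (n_bins + 1) * bin_width - 1e-12, bin_width)
    if len(edges) < n_bins + 1:
        edges = np.append(edges, n_bins * bin_width)
    # (lower, upper]: subtract tiny epsilon so exact multiples land below
    idx = np.clip(np.ceil(rmsds / bin_width - 1e-9).astype(int) - 1, 0, n_bins - 1)
    totals = np.zeros(n_bins, int)
    chosen = np.zeros(n_bins, int)
    for s, b in zip(good, idx):
        totals[b] += 1
        if select(s):
            chosen[b] += 1
    with np.errstate(invalid="ignore"):
        recovery = np.where(totals > 0, chosen / np.maximum(totals, 1), np.nan)
    return RecoveryHistogram(edges=edges, totals=totals, selected=chosen, recovery=recovery)


def rank_models_by(scores: Sequence[ModelScore], key: str) -> list[ModelScore]:
    """Order models by a metric, best first.

    ``r_s`` sorts ascending (lower = better packing); ``contact_score``
    and ``rdepth_score`` sort descending.  Ties break by model id; models
    with an undefined key value are excluded with a warning.
    """
    if key not in ("r_s", "contact_score", "rdepth_score"):
        raise ValueError(f"unknown key {key!r}")
    defined = []
    for s in scores:
        v = getattr(s, key)
        if v is None or (isinstance(v, float) and not np.isfinite(v)) or s.error:
            logger.warning("model %s excluded from ranking: %s undefined", s.model_id, key)
            continue
        defined.append(s)
    ascending = key == "r_s"
    return sorted(
        defined,
        key=lambda s: (getattr(s, key) if ascending else -getattr(s, key), s.model_id),
    )


def scores_to_frame(scores: Sequence[ModelScore]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "model_id": s.model_id,
                "rmsd": s.rmsd,
                "contact_score": s.contact_score,
                "rdepth_score": s.rdepth_score,
                "r_s": s.r_s,
                "error": s.error,
            }
            for s in scores
        ]
    )


def plot_recovery(hist: RecoveryHistogram, path: str | Path, title: str = "") -> None:
    """Bar plot of per-bin recovery (optional convenience output)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 3))
    uppers = hist.edges[1:]
    ax.bar(uppers, np.nan_to_num(hist.recovery), width=0.8 * np.diff(hist.edges))
    ax.set_xlabel("backbone RMSD bin upper edge (A)")
    ax.set_ylabel("recovery")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
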