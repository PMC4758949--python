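"""Mutational-sensitivity scoring from multi-expression-level screens.

A single-site saturation mutagenesis library screened at increasing
expression levels yields, per mutant, read counts across MID-tagged
conditions.  The mutational sensitivity score MS_seq is the expression
level (MID) at which the mutant first shows an active (lethal) phenotype,
detected as a fivefold-or-more drop in reads relative to the previous
level.  MS_seq ranges over {0} u [2, 9]: 2 = most active (dies at the
lowest induction), 9 = least active (never shows a qualifying drop),
0 = mutant absent from the library.

RankScore aggregates MS_seq to positions: mutants are ranked by the
cumulative percentage of the mutant population strictly below their
MS_seq stratum plus one (so the MS_seq=2 stratum has rank 1), and a
position's RankScore is the mean rank of its observed mutants.  At
non-active-site positions RankScore tracks residue depth, which is what
makes it usable both for classifying suppressors as proximal (buried,
high RankScore) versus distal (surface, RankScore ~1) and as the basis
of the depth-correlation model discriminator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

AA_GROUPS: dict[str, str] = {
    **{a: "gly_pro" for a in "GP"},
    **{a: "aliphatic" for a in "ACVLIM"},
    **{a: "aromatic" for a in "HFYW"},
    **{a: "polar" for a in "STNQ"},
    **{a: "charged" for a in "DEKR"},
}


@dataclass
class ReadCountTable:
    """Per-mutant read counts across ordered MID expression levels."""

    frame: pd.DataFrame  # columns: position, wt_aa, mut_aa, mid_<k>...

    def __post_init__(self) -> None:
        mids = self.mid_levels
        if sorted(mids) != mids:
            raise ValueError("MID levels must be strictly ordered")
        counts = self.frame[self.mid_columns].select_dtypes("number")
        if not counts.empty and (counts.to_numpy() < 0).any():
            raise ValueError("read counts must be non-negative")

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ReadCountTable":
        return cls(frame=df.copy())

    @property
    def mid_columns(self) -> list[str]:
        cols = [c for c in self.frame.columns if c.startswith("mid_")]
        return sorted(cols, key=lambda c: int(c.split("_")[1]))

    @property
    def mid_levels(self) -> list[int]:
        return [int(c.split("_")[1]) for c in self.mid_columns]


@dataclass
class MutSensTable:
    """(position, mut_aa) -> MS_seq, with wild-type identity per position."""

    values: dict[tuple[int, str], int]
    wt: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for key, v in self.values.items():
            if v != 0 and not (2 <= v <= 9):
                raise ValueError(f"MS_seq {v} for {key} outside {{0}} u [2, 9]")

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "MutSensTable":
        values = {
            (int(r.position), str(r.mut_aa)): int(r.ms_seq) for r in df.itertuples()
        }
        wt = {int(r.position): str(r.wt_aa) for r in df.itertuples()}
        return cls(values=values, wt=wt)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"position": p, "wt_aa": self.wt.get(p, "X"), "mut_aa": a, "ms_seq": v}
            for (p, a), v in sorted(self.values.items())
        ]
        return pd.DataFrame(rows, columns=["position", "wt_aa", "mut_aa", "ms_seq"])

    def observed(self) -> list[tuple[int, str, int]]:
        """(position, mut_aa, ms_seq) for obtained, non-wild-type mutants."""
        return [
            (p, a, v)
            for (p, a), v in self.values.items()
            if v != 0 and self.wt.get(p) != a
        ]


@dataclass
class RankScoreTable:
    """Per-position RankScore (mean mutant rank) and mutant count."""

    scores: dict[int, float]
    n_mutants: dict[int, int]

    def __getitem__(self, position: int) -> float:
        return self.scores[position]

    def __contains__(self, position: int) -> bool:
        return position in self.scores

    def positions(self) -> list[int]:
        return sorted(self.scores)


@dataclass
class SuppressorCall:
    """Proximal/distal/ambiguous call for one suppressor position."""

    position: int
    call: str
    rank_score: float
    cutoffs: tuple[float, float]


def ms_seq_from_reads(reads: ReadCountTable, drop_factor: float = 5.0) -> MutSensTable:
    """Assign MS_seq per mutant from the fivefold-drop rule.

    Scanning MID levels in ascending order, MS_seq is the first level at
    which the read count drops by ``drop_factor`` or more relative to the
    previous level.  A drop from positive reads to zero qualifies (complete
    killing); zero to zero does not.  Mutants with zero reads everywhere
    get the absent-mutant sentinel 0; mutants with no qualifying drop get
    9 (active at every expression level, i.e. maximally insensitive).
    """
    cols = reads.mid_columns
    if len(cols) < 2:
        raise ValueError("need >=2 MID columns")
    levels = reads.mid_levels
    values: dict[tuple[int, str], int] = {}
    wt: dict[int, str] = {}
    for row in reads.frame.itertuples():
        counts = [getattr(row, c) for c in cols]
        try:
            counts = [float(c) for c in counts]
        except (TypeError, ValueError) as exc:
            raise ValueError(f"non-numeric read count in row {row.Index}: {exc}") from exc
        pos, mut = int(row.position), str(row.mut_aa)
        wt[pos] = str(row.wt_aa)
        if all(c == 0 for c in counts):
            values[(pos, mut)] = 0
            continue
        ms = 9
        for prev, curr, level in zip(counts, counts[1:], levels[1:]):
            if prev > 0 and (curr == 0 or prev / max(curr, 1e-300) >= drop_factor):
                ms = min(level, 9)
                break
        values[(pos, mut)] = ms
    return MutSensTable(values=values, wt=wt)


def rank_scores(ms: MutSensTable) -> RankScoreTable:
    """Aggregate MS_seq to per-position RankScores.

    Each MS_seq stratum k gets rank = (cumulative percentage of observed
    mutants with MS_seq < k) + 1, so the MS_seq=2 stratum has rank 1.
    Percentages are used unrounded.  A position's RankScore is the mean
    rank over its observed mutants; absent mutants (MS_seq 0) and
    wild-type self-substitutions are excluded.
    """
    observed = ms.observed()
    if not observed:
        raise ValueError("no observed mutants with MS_seq >= 2")
    total = len(observed)
    strata = np.array([v for (_p, _a, v) in observed])
    rank_of: dict[int, float] = {}
    for k in range(2, 10):
        below_pct = 100.0 * (strata < k).sum() / total
        rank_of[k] = below_pct + 1.0
    scores: dict[int, float] = {}
    counts: dict[int, int] = {}
    for pos in sorted({p for (p, _a, _v) in observed}):
        ranks = [rank_of[v] for (p, _a, v) in observed if p == pos]
        scores[pos] = float(np.mean(ranks))
        counts[pos] = len(ranks)
    return RankScoreTable(scores=scores, n_mutants=counts)


def classify_suppressor(
    position: int,
    ranks: RankScoreTable,
    distal_max: float = 1.0,
    proximal_min: float = 25.0,
) -> SuppressorCall:
    """Call a suppressor position distal, proximal or ambiguous.

    Distal suppressors act globally from the protein surface and carry
    RankScore at the floor (<= ``distal_max``, default 1); proximal
    suppressors pack against the parent inactive mutant in the core and
    carry RankScore >= ``proximal_min`` (default 25, which selects only
    buried residues).  Anything between is ambiguous.
    """
    if position not in ranks:
        raise KeyError(f"position {position} absent from RankScore table")
    rs = ranks[position]
    if rs <= distal_max:
        call = "distal"
    elif rs >= proximal_min:
        call = "proximal"
    else:
        call = "ambiguous"
    return SuppressorCall(
        position=position, call=call, rank_score=rs, cutoffs=(distal_max, proximal_min)
    )


def classify_position(
    position: int,
    ms: MutSensTable,
    groups: dict[str, str] | None = None,
    high_ms: int = 7,
    tol_fraction: float = 0.5,
) -> str:
    """Classify a position as buried / active_site / exposed / ambiguous.

    Rule-based reading of the substitution pattern: at buried positions
    aliphatic substitutions are tolerated (low MS_seq) while polar and
    charged ones are not; at active-site positions even aliphatics are
    poorly tolerated; at exposed positions nearly everything (bar G, P)
    is tolerated.  ``high_ms`` is the sensitivity threshold, and
    ``tol_fraction`` the fraction of a group that must agree.
    """
    groups = groups or AA_GROUPS
    subs = [
        (a, v) for (p, a), v in ms.values.items()
        if p == position and v != 0 and ms.wt.get(p) != a
    ]
    if len(subs) < 5:
        raise ValueError(f"position {position}: only {len(subs)} observed mutants (<5)")

    def frac(group_names: set[str], sensitive: bool) -> float:
        vals = [v for a, v in subs if groups.get(a) in group_names]
        if not vals:
            return float("nan")
        hit = [v >= high_ms if sensitive else v < high_ms for v in vals]
        return sum(hit) / len(vals)

    ali_tol = frac({"aliphatic"}, sensitive=False)
    ali_sens = frac({"aliphatic"}, sensitive=True)
    pc_sens = frac({"polar", "charged"}, sensitive=True)
    all_tol_vals = [v for a, v in subs if groups.get(a) != "gly_pro"]
    all_tol = (
        sum(v < high_ms for v in all_tol_vals) / len(all_tol_vals)
        if all_tol_vals else float("nan")
    )

    if ali_sens >= tol_fraction and pc_sens >= tol_fraction:
        return "active_site"
    if ali_tol >= tol_fraction and pc_sens >= tol_fraction:
        return "buried"
    if all_tol >= tol_fraction:
        return "exposed"
    return "ambiguous"
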