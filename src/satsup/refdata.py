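"""Packaged reference tables: van der Waals radii and reference ASA values.

``MAX_ASA`` holds theoretical maximum per-residue accessible surface areas
(Gly-X-Gly, theoretical values of Tien et al. 2013), used to express
per-residue ASA as a percentage.  Relative values above 100% are possible
for extended termini.

``default_mean_asa()`` returns a packaged default for the per-residue-type
average ASA ``<ASA_x>`` used by the packing-deviation score R_s.  The
default is the theoretical maximum scaled by a typical mean relative
accessibility of globular-protein residues (0.35); it is a documented
approximation, not a reproduction of any published survey.  For serious
use compute a bespoke table from a curated structure set with
:func:`reference_asa_from_models`.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

VDW_RADII: dict[str, float] = {
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "P": 1.80,
    "SE": 1.90,
    "F": 1.47,
    "CL": 1.75,
    "BR": 1.85,
    "I": 1.98,
}

_MEAN_REL_ACCESSIBILITY = 0.35


def _load_tsv(name: str) -> dict[str, float]:
    with resources.files("satsup.data").joinpath(name).open() as fh:
        df = pd.read_csv(fh, sep="\t")
    return dict(zip(df["aa"], df["value"].astype(float)))


MAX_ASA: dict[str, float] = _load_tsv("max_asa.tsv")


def default_mean_asa() -> dict[str, float]:
    """Packaged default ``<ASA_x>`` table (scaled theoretical maxima)."""
    return {aa: v * _MEAN_REL_ACCESSIBILITY for aa, v in MAX_ASA.items()}


def reference_asa_from_models(models, probe: float = 1.4, n_points: int = 960) -> dict[str, float]:
    """Mean per-residue-type absolute ASA over a set of structure models.

    Intended for building a bespoke ``<ASA_x>`` reference from a curated
    set of structures.  Residue types never observed are filled from the
    packaged default so the returned table always covers all 20 types.
    """
    from satsup.geometry import sasa

    acc: dict[str, list[float]] = {}
    for model in models:
        prof = sasa(model, probe=probe, n_points=n_points)
        for res in model.residues:
            if res.aa == "X":
                continue
            acc.setdefault(res.aa, []).append(prof.absolute[res.key])
    table = default_mean_asa()
    for aa, vals in acc.items():
        table[aa] = float(np.mean(vals))
    return table
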