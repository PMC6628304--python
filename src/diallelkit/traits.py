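"""Derived fruit-quality traits: browning, colour, enzyme activity.

Flesh browning of cut fruit is tracked in CIELAB colour space (L* lightness,
a* green-red, b* blue-yellow) by reading each sample immediately after
cutting (t = 0) and again 10 minutes later.  From the paired readings we
derive:

* ``CD``  — colour difference, the Euclidean (Delta-E style) distance between
  the two readings;
* ``DW``  — degree of whiteness, the distance of the 0-min reading from the
  CIELAB white point (100, 0, 0); lower values mean whiter flesh;
* ``DB``  — degree of browning, taken here as the lightness drop
  ``L*_0 - L*_10`` (a configurable convention; browning darkens the flesh).

Polyphenol-oxidase (PPO) activity is the rate of absorbance increase at
420 nm, expressed in units of 0.1 absorbance per minute per mg dry weight.
Dry matter and the chlorogenic-acid chromatogram area share simple ratio
definitions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simulate import PLOT_COLUMNS

#: Canonical names of the trait panel consumed by the diallel analysis.
TRAIT_NAMES = [
    "DryMatter", "Phenolics", "CGA", "AreaPct",
    "L0", "a0", "b0", "DW0", "PPO", "DB", "CD",
]


@dataclass(frozen=True)
class ColourReading:
    """One CIELAB reading; ``t`` is the time label in minutes (0 or 10)."""

    L: float
    a: float
    b: float
    t: float = 0.0

    def __post_init__(self):
        if not 0.0 <= self.L <= 100.0:
            raise ValueError("L* must lie in [0, 100]")


def _lab(r) -> np.ndarray:
    if isinstance(r, ColourReading):
        return np.array([r.L, r.a, r.b], dtype=float)
    return np.asarray(r, dtype=float)


def compute_cd(r0, r10) -> float:
    """Colour difference between 0-min and 10-min readings.

    The standard three-term Euclidean distance in CIELAB::

        CD = sqrt((L10 - L0)^2 + (a10 - a0)^2 + (b10 - b0)^2)

    Symmetric in its arguments and zero iff the readings coincide.
    """
    return float(np.linalg.norm(_lab(r10) - _lab(r0)))


def compute_dw(r0) -> float:
    """Degree of whiteness: distance from the CIELAB white point (100, 0, 0).

    Zero for pure white; increases as the flesh darkens or gains chroma.  The
    white point is a convention (a measured white tile could be substituted).
    """
    L, a, b = _lab(r0)
    return float(np.sqrt((100.0 - L) ** 2 + a ** 2 + b ** 2))


def compute_db(r0, r10) -> float:
    """Degree of browning as the lightness drop ``L*_0 - L*_10``.

    Positive when the flesh darkens over the 10 minutes.  This is the
    ``lightness_drop`` convention; when a* and b* do not move, |DB| equals CD.
    """
    return float(_lab(r0)[0] - _lab(r10)[0])


def compute_ppo_units(absorbance_series, sample_mg_dw: float) -> float:
    """PPO activity in 0.1-absorbance-unit/min/mg-dry-weight units.

    ``absorbance_series`` is a sequence of (time_min, A420) pairs with at
    least two strictly increasing time points.  The activity is the ordinary
    least-squares slope of A420 against time, divided by 0.1 and by the dry
    mass.  A negative slope is reported as is (no clamping).
    """
    arr = np.asarray(absorbance_series, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 2:
        raise ValueError("need >= 2 (time, absorbance) pairs")
    t, a420 = arr[:, 0], arr[:, 1]
    if np.ptp(t) == 0:
        raise ValueError("all timestamps identical: slope undefined")
    if sample_mg_dw <= 0:
        raise ValueError("sample mass must be positive")
    slope = np.polyfit(t, a420, 1)[0]
    return float(slope / 0.1 / sample_mg_dw)


def compute_dry_matter(fresh_w: float, lyo_w: float) -> float:
    """Dry matter percent: lyophilized weight over fresh weight x 100."""
    if lyo_w <= 0 or fresh_w <= 0:
        raise ValueError("weights must be positive")
    if lyo_w > fresh_w:
        raise ValueError("lyophilized weight exceeds fresh weight")
    return 100.0 * lyo_w / fresh_w


def compute_area_pct(cga_peak: float, total_area: float) -> float:
    """Chlorogenic-acid peak area as percent of the total chromatogram area."""
    if total_area <= 0:
        raise ValueError("total_area must be positive")
    if cga_peak <= 0:
        raise ValueError("cga_peak must be positive")
    if cga_peak > total_area:
        raise ValueError("peak area exceeds total area")
    return 100.0 * cga_peak / total_area


def derive_colour_traits(kinetics: pd.DataFrame, db_formula: str = "lightness_drop") -> pd.DataFrame:
    """Expand a colour-kinetics table into tidy plot-level colour traits.

    Input columns: ``parent_a, parent_b, block, L0, a0, b0, L10, a10, b10``
    (one row per plot, as produced by
    :func:`diallelkit.simulate.simulate_colour_kinetics`).  Output is a tidy
    plot table (block, parent_a, parent_b, trait, value) holding the traits
    ``L0, a0, b0, DW0, DB, CD``.
    """
    if db_formula != "lightness_drop":
        raise ValueError(f"unknown db_formula: {db_formula!r}")
    need = {"parent_a", "parent_b", "block", "L0", "a0", "b0", "L10", "a10", "b10"}
    missing = need - set(kinetics.columns)
    if missing:
        raise ValueError(f"kinetics table missing columns: {sorted(missing)}")
    rows = []
    for rec in kinetics.itertuples(index=False):
        r0 = (rec.L0, rec.a0, rec.b0)
        r10 = (rec.L10, rec.a10, rec.b10)
        vals = {
            "L0": rec.L0,
            "a0": rec.a0,
            "b0": rec.b0,
            "DW0": compute_dw(r0),
            "DB": compute_db(r0, r10),
            "CD": compute_cd(r0, r10),
        }
        for trait, v in vals.items():
            rows.append((rec.block, rec.parent_a, rec.parent_b, trait, v))
    return pd.DataFrame(rows, columns=PLOT_COLUMNS)
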