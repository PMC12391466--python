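"""Drug-combination scoring: Bliss independence and the Chou-Talalay
combination index.

Viability grids are fractions relative to vehicle (row 0 / column 0 are
the monotherapies, cell (0, 0) the vehicle). Effects are E = 1 −
viability; under Bliss independence the expected combined effect is
E_A + E_B − E_A·E_B, and the per-dose-pair excess E_AB − expected is
positive for synergy. The combination index uses the median-effect
model: per drug, log(fa/fu) = m·(log D − log Dm) fitted by least
squares; CI = d1/Dx1 + d2/Dx2 at the combination's affected fraction
(CI < 1 synergy, = 1 additive, > 1 antagonism; mutually exclusive
form).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class BlissResult:
    effect_a: np.ndarray  # (n_a,) monotherapy effects of drug A (rows)
    effect_b: np.ndarray  # (n_b,) monotherapy effects of drug B (cols)
    effect_ab: pd.DataFrame  # observed combined effects
    expected: pd.DataFrame  # Bliss-independent expectation
    excess: pd.DataFrame  # observed − expected
    mean_excess: float  # over true combination cells (both doses > 0)


def bliss_scores(viability: pd.DataFrame) -> BlissResult:
    """Bliss excess over a dose grid of viability fractions.

    ``viability`` rows are drug-A doses, columns drug-B doses, with dose
    0 first in each (vehicle at (0, 0)). Values are normalized to the
    vehicle cell; viability above vehicle is clipped to 1 (effect 0)
    with a warning.
    """
    v = viability.values.astype(float)
    if v.shape[0] < 2 or v.shape[1] < 2:
        raise ValueError("grid needs monotherapy rows/columns plus vehicle")
    vehicle = v[0, 0]
    if vehicle <= 0:
        raise ValueError("vehicle viability must be positive")
    eff = 1.0 - v / vehicle
    if (eff < 0).any():
        warnings.warn("viability above vehicle; effects clipped to 0")
    eff = np.clip(eff, 0.0, 1.0)
    e_a = eff[:, 0]
    e_b = eff[0, :]
    expected = e_a[:, None] + e_b[None, :] - e_a[:, None] * e_b[None, :]
    excess = eff - expected
    combo = excess[1:, 1:]
    return BlissResult(
        effect_a=e_a,
        effect_b=e_b,
        effect_ab=pd.DataFrame(eff, index=viability.index, columns=viability.columns),
        expected=pd.DataFrame(expected, index=viability.index, columns=viability.columns),
        excess=pd.DataFrame(excess, index=viability.index, columns=viability.columns),
        mean_excess=float(combo.mean()) if combo.size else np.nan,
    )


@dataclass
class MedianEffectFit:
    m: float  # slope of the median-effect line
    dm: float  # median-effect dose (fa = 0.5)

    def dose_for_fa(self, fa: float) -> float:
        """Dose producing affected fraction fa: Dx = Dm (fa/fu)^(1/m)."""
        if not 0 < fa < 1:
            raise ValueError("fa must lie strictly in (0, 1)")
        return self.dm * (fa / (1 - fa)) ** (1.0 / self.m)

    def fa_at_dose(self, dose: float) -> float:
        r = (dose / self.dm) ** self.m
        return r / (1 + r)


def fit_median_effect(doses: np.ndarray, fa: np.ndarray) -> MedianEffectFit:
    """Least-squares fit of log(fa/fu) vs log dose.

    Doses with fa of exactly 0 or 1 are uninformative on the log scale
    and excluded; at least 3 informative doses are required.
    """
    doses = np.asarray(doses, dtype=float)
    fa = np.asarray(fa, dtype=float)
    ok = (doses > 0) & (fa > 0) & (fa < 1)
    if ok.sum() < 3:
        raise ValueError("need >= 3 doses with 0 < fa < 1")
    x = np.log(doses[ok])
    y = np.log(fa[ok] / (1 - fa[ok]))
    m, intercept = np.polyfit(x, y, 1)
    dm = float(np.exp(-intercept / m))
    if dm <= 0 or not np.isfinite(dm):
        raise ValueError("median-effect fit degenerate (Dm <= 0)")
    return MedianEffectFit(m=float(m), dm=dm)


def combination_index(
    doses_a: np.ndarray,
    fa_a: np.ndarray,
    doses_b: np.ndarray,
    fa_b: np.ndarray,
    combo_points: pd.DataFrame,
) -> pd.DataFrame:
    """Chou-Talalay CI for combination points.

    ``combo_points`` columns: dose_a, dose_b, fa (affected fraction of
    the combination). Returns the input with Dx per drug and CI
    appended.
    """
    fit_a = fit_median_effect(doses_a, fa_a)
    fit_b = fit_median_effect(doses_b, fa_b)
    out = combo_points.copy()
    dx_a, dx_b, ci = [], [], []
    for row in combo_points.itertuples(index=False):
        xa = fit_a.dose_for_fa(row.fa)
        xb = fit_b.dose_for_fa(row.fa)
        dx_a.append(xa)
        dx_b.append(xb)
        ci.append(row.dose_a / xa + row.dose_b / xb)
    out["dx_a"] = dx_a
    out["dx_b"] = dx_b
    out["ci"] = ci
    return out
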