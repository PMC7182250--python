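"""Association between kinematic deviation and misplacement magnitude.

The misplacement magnitude is expressed as a percentage of an
anthropometric reference (leg length by default, knee width as an
alternative); RMSD is related to it by Pearson correlation (with
Altman's interpretation bands) and ordinary least-squares regression
(slope m in deg per % leg length, intercept b in deg). The fitted line
predicts the kinematic deviation expected for a given misplacement on
a subject of given leg length, applied as a +/- curve offset for the
offset-dominated angles.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

from .datamodel import Anthropometry, SensitivityTable

__all__ = [
    "normalize_magnitude",
    "pearson_r",
    "altman_category",
    "fit_regression",
    "predict_deviation",
    "apply_predicted_shift",
    "associate",
]


def normalize_magnitude(eps: float, reference: float) -> float:
    """Misplacement magnitude as a percentage of a reference length."""
    if reference <= 0:
        raise ValueError("reference length must be positive")
    return 100.0 * eps / reference


def pearson_r(x: Sequence[float], y: Sequence[float]) -> Tuple[float, float]:
    """Pearson correlation coefficient and two-sided p (t transform)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3 or x.size != y.size:
        raise ValueError("need >= 3 paired observations")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance input")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)


def altman_category(r: float) -> str:
    """Altman's interpretation of a correlation coefficient.

    Applied to |r|: poor <= 0.2 < fair <= 0.4 < moderate <= 0.6 <
    good <= 0.8 < very good. Negative correlations keep their sign in
    reports but are categorized by magnitude.
    """
    a = abs(float(r))
    if a > 1.0:
        raise ValueError("correlation outside [-1, 1]")
    if a <= 0.2:
        return "poor"
    if a <= 0.4:
        return "fair"
    if a <= 0.6:
        return "moderate"
    if a <= 0.8:
        return "good"
    return "very good"


def fit_regression(x: Sequence[float], y: Sequence[float]) -> Tuple[float, float]:
    """OLS line ``y = m x + b``; x in % of reference length, y in deg."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or np.ptp(x) == 0:
        raise ValueError("need >= 2 distinct x values")
    res = sps.linregress(x, y)
    return float(res.slope), float(res.intercept)


def predict_deviation(
    m: float, b: float, eps: float, leg_length: float, sense: float = 1.0
) -> float:
    """Predicted curve shift (deg) for a misplacement of eps mm.

    ``RMSD_hat = m * (100 eps / leg_length) + b`` signed by ``sense``
    (+1 anterior-type shift, -1 posterior). Note b is the regression
    intercept, not forced to zero, so the eps = 0 prediction equals b.
    """
    return float(sense) * (m * normalize_magnitude(eps, leg_length) + b)


def apply_predicted_shift(reference_curve: np.ndarray, shift: float) -> np.ndarray:
    """Offset-model kinematic prediction: reference curve + shift."""
    return np.asarray(reference_curve, dtype=float) + shift


def associate(
    tables: Iterable[Tuple[SensitivityTable, Anthropometry]],
    normalize_by: str = "leg_length",
    kind: str = "gait-cycle",
) -> pd.DataFrame:
    """Pooled per-(angle, direction) correlation and regression table.

    ``tables`` pairs each subject's sensitivity table with their
    anthropometry. Records of all subjects are pooled (each direction
    kept separate, per the reporting convention); for every joint
    angle and misplacement direction the Pearson r (with p-value and
    Altman category) and the OLS slope/intercept of RMSD against the
    normalized magnitude are returned as a tidy frame.
    """
    rows = []
    for table, anthro in tables:
        frame = table.to_frame()
        frame = frame[frame["kind"] == kind].copy()
        if normalize_by == "leg_length":
            ref = {s: anthro.leg_length[s] for s in anthro.leg_length}
            frame["pct_magnitude"] = [
                normalize_magnitude(m, ref[s])
                for m, s in zip(frame["magnitude_mm"], frame["side"])
            ]
        elif normalize_by == "knee_width":
            frame["pct_magnitude"] = [
                normalize_magnitude(m, anthro.knee_width) for m in frame["magnitude_mm"]
            ]
        else:
            raise ValueError("normalize_by must be 'leg_length' or 'knee_width'")
        rows.append(frame)
    pooled = pd.concat(rows, ignore_index=True)

    out = []
    for (joint, plane, direction), grp in pooled.groupby(["joint", "plane", "direction"]):
        if grp["pct_magnitude"].nunique() < 2:
            continue
        try:
            r, p = pearson_r(grp["pct_magnitude"], grp["rmsd_deg"])
            category = altman_category(r)
        except ValueError:
            # e.g. an angle with identically zero RMSD in this direction
            r, p, category = float("nan"), float("nan"), "undefined"
        m, b = fit_regression(grp["pct_magnitude"], grp["rmsd_deg"])
        out.append(
            {
                "joint": joint,
                "plane": plane,
                "direction": direction,
                "n": len(grp),
                "r": r,
                "p": p,
                "category": category,
                "slope_deg_per_pct": m,
                "intercept_deg": b,
            }
        )
    return pd.DataFrame(out).sort_values(["joint", "plane", "direction"]).reset_index(drop=True)
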