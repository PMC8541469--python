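"""Model/Results front end for the energy-window scatter correction.

`EnergyWindowScatterModel` wraps the calibration of the window coefficients
as a model fitted to ground-truth-labelled list-mode data, in the style of
statsmodels: construct from data, ``fit()`` returns a results object that
carries the estimates, rough standard errors, diagnostics and a
``summary()`` table, and knows how to apply the correction to new data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import calibration as cal
from .calibration import EnergyWindowConfig, ScatterCoefficients
from .geometry import LORBinner, VirtualPixelGrid
from .listmode import ListModeSet
from .scatter import (ScatterFractionMap, additive_term, estimate_scatter,
                      labeled_scatter_fraction)

__all__ = ["EnergyWindowScatterModel", "ScatterCorrectionResults"]


class EnergyWindowScatterModel:
    """Window-coefficient model built from labelled calibration acquisitions.

    Parameters
    ----------
    calibration_data : ListModeSet or sequence of ListModeSet
        Truth-labelled acquisitions (e.g. the cylinder ensemble).
    window_config : EnergyWindowConfig, optional
        Defaults to the TEW configuration.
    pixel_pitch : float
        Virtual-pixel pitch (mm) of the LOR binning used when the fitted
        coefficients are applied.
    """

    def __init__(self, calibration_data, window_config: EnergyWindowConfig | None = None,
                 pixel_pitch: float = 2.0):
        self.data = (list(calibration_data)
                     if isinstance(calibration_data, (list, tuple))
                     else [calibration_data])
        if not self.data:
            raise ValueError("need at least one calibration set")
        for lm in self.data:
            if not lm.has_truth:
                raise ValueError("calibration sets must carry truth labels")
        self.geometry = self.data[0].geometry
        self.cfg = window_config or EnergyWindowConfig(
            mode="TEW", acceptance=self.geometry.acceptance_window)
        grid = VirtualPixelGrid(pixel_pitch, self.geometry.block_width,
                                self.geometry.block_height)
        self.binner = LORBinner(self.geometry, grid)

    def fit(self, mode: str = "global", count_floor: int = 50) -> "ScatterCorrectionResults":
        coeff = cal.fit_coefficients(self.data, self.cfg, mode=mode,
                                     binner=self.binner, count_floor=count_floor)
        members = []
        rows = []
        for lm in self.data:
            labels = cal.classify_events(lm.energy, self.cfg)
            sc = lm.event_scattered
            rows.append((int((labels == cal.LEW).sum()),
                         int((labels == cal.UEW).sum()),
                         int(((labels == cal.PHOTOPEAK) & sc).sum())))
            members.append(dict(n_events=len(lm),
                                truth_sf=labeled_scatter_fraction(lm),
                                phantom=lm.meta.get("phantom")))
        bse = _coefficient_se(np.asarray(rows, dtype=float), coeff, self.cfg)
        return ScatterCorrectionResults(self, coeff, bse, members)


def _coefficient_se(rows: np.ndarray, coeff: ScatterCoefficients,
                    cfg: EnergyWindowConfig) -> dict:
    """Rough standard errors of the global coefficients.

    DEW: delta-method error of the Poisson-count quotient.  TEW: linear
    least-squares covariance of the ensemble regression (residual variance
    over the member equations).
    """
    n_lew = rows[:, 0].sum()
    n_uew = rows[:, 1].sum()
    n_scat = rows[:, 2].sum()
    if cfg.mode == "DEW" or len(rows) < 3:
        out = {}
        if cal.LEW in coeff.k and n_lew > 0 and n_scat > 0:
            out[cal.LEW] = coeff.k[cal.LEW] * np.sqrt(1.0 / n_scat + 1.0 / n_lew)
        if cal.UEW in coeff.k and n_uew > 0 and n_scat > 0:
            out[cal.UEW] = coeff.k[cal.UEW] * np.sqrt(1.0 / n_scat + 1.0 / n_uew)
        return out
    X = rows[:, :2]
    y = rows[:, 2]
    beta = np.array([coeff.k.get(cal.LEW, 0.0), coeff.k.get(cal.UEW, 0.0)])
    resid = y - X @ beta
    dof = max(len(rows) - 2, 1)
    s2 = float(resid @ resid) / dof
    try:
        cov = s2 * np.linalg.inv(X.T @ X)
        se = np.sqrt(np.maximum(np.diag(cov), 0.0))
        return {cal.LEW: float(se[0]), cal.UEW: float(se[1])}
    except np.linalg.LinAlgError:
        return {}


@dataclass
class ScatterCorrectionResults:
    """Fitted coefficients plus application and reporting helpers."""

    model: EnergyWindowScatterModel
    coefficients: ScatterCoefficients
    bse: dict = field(default_factory=dict)
    members: list = field(default_factory=list)

    @property
    def params(self) -> dict:
        return {cal.WINDOW_NAMES[w]: v for w, v in self.coefficients.k.items()}

    def estimate(self, lm: ListModeSet, **kw) -> ScatterFractionMap:
        """Scatter-fraction map of an acquisition under the fitted model."""
        return estimate_scatter(lm, self.model.cfg, self.coefficients,
                                self.model.binner, **kw)

    def global_scatter_fraction(self, lm: ListModeSet, **kw) -> float:
        return self.estimate(lm, **kw).global_sf

    def additive_term(self, lm: ListModeSet, sf_map: ScatterFractionMap | None = None):
        """Per-event additive scatter term for reconstruction."""
        if sf_map is None:
            sf_map = self.estimate(lm)
        return additive_term(sf_map, lm)

    def summary(self) -> str:
        cfg = self.model.cfg
        lines = ["Energy-window scatter correction", "=" * 48]
        lines.append(f"window configuration : {cfg.mode}")
        lines.append(f"  LEW       {cfg.lew[0]:6.0f} - {cfg.lew[1]:.0f} keV")
        lines.append(f"  photopeak {cfg.photopeak[0]:6.0f} - {cfg.photopeak[1]:.0f} keV")
        if cfg.uew:
            lines.append(f"  UEW       {cfg.uew[0]:6.0f} - {cfg.uew[1]:.0f} keV")
        lines.append(f"coefficient mode     : {self.coefficients.mode}")
        lines.append("")
        lines.append(f"{'coef':>10} {'value':>10} {'std err':>10}")
        for w in sorted(self.coefficients.k):
            se = self.bse.get(w)
            lines.append(f"{'k_' + cal.WINDOW_NAMES[w]:>10} "
                         f"{self.coefficients.k[w]:>10.4f} "
                         f"{'' if se is None else format(se, '>10.4f')}")
        lines.append("")
        lines.append(f"calibration members  : {len(self.members)}")
        for i, m in enumerate(self.members):
            lines.append(f"  [{i}] n={m['n_events']:>8d}  "
                         f"truth SF={m['truth_sf']:.3f}")
        return "\n".join(lines)
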