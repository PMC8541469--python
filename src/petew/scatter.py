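"""Per-LOR-bin scatter fraction and the additive reconstruction term.

Combines the calibrated window coefficients with KDE-smoothed window counts:

* photopeak scatter per bin: ``C_ph,scatter = k_LEW C~_LEW`` (DEW) or
  ``k_LEW C~_LEW + k_HEW C~_UEW`` (TEW), non-negative (an optional cap at
  the bin's smoothed photopeak content exists for dense acquisitions);
* scatter fraction per bin:
  ``SF = (C~_LEW + C_ph,scatter) / C_Total`` clamped to [0, 1], where
  ``C_Total`` sums all accepted windows of the bin (LEW + photopeak + UEW);
* the additive term for reconstruction: each measured event in bin ``b``
  carries ``S = SF(b) * C_raw(b)``, the expected scatter count of its bin
  (raw, unsmoothed counts set the magnitude; smoothing only shapes the
  ratio).

The literal low-window numerator counts the whole LEW as scatter even
though a small share of LEW events is true; ``lew_true_fraction`` enables
the purity-corrected variant (off by default).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .calibration import (LEW, PHOTOPEAK, UEW, EnergyWindowConfig,
                          ScatterCoefficients, WindowCounts, count_windows,
                          event_bins)
from .geometry import LORBinner
from .kde import SmoothedCounts, smooth_window_counts
from .listmode import ListModeSet

__all__ = [
    "ScatterFractionMap",
    "estimate_scatter",
    "photopeak_scatter_pair",
    "global_scatter_fraction",
    "labeled_scatter_fraction",
    "AdditiveScatterTerm",
    "additive_term",
    "event_scatter_fractions",
]

log = logging.getLogger(__name__)


@dataclass
class ScatterFractionMap:
    """Scatter fraction per occupied LOR bin plus global aggregates.

    ``bin_ids`` (sorted global keys) cover the bins holding at least one
    raw event — the bins reconstruction will ask about.  ``sf`` is clamped
    to [0, 1]; bins whose smoothed total vanished carry NaN (sentinel,
    excluded from correction).  The global numerator/denominator sums run
    over the whole smoothed lattice, giving the count-weighted global SF.
    """

    binner: LORBinner
    cfg: EnergyWindowConfig
    bin_ids: np.ndarray
    sf: np.ndarray
    c_raw: np.ndarray            # raw (unsmoothed) total counts per bin
    c_ph_scatter: np.ndarray     # smoothed scatter estimate per bin
    numerator_sum: float
    denominator_sum: float
    n_clamped: int = 0
    provenance: dict = field(default_factory=dict)

    @property
    def global_sf(self) -> float:
        if self.denominator_sum <= 0:
            raise ValueError("empty scatter-fraction map")
        return self.numerator_sum / self.denominator_sum

    def sf_for_bins(self, bin_ids: np.ndarray) -> np.ndarray:
        """SF per requested bin id; NaN where no estimate exists."""
        pos = np.searchsorted(self.bin_ids, bin_ids)
        pos = np.clip(pos, 0, max(len(self.bin_ids) - 1, 0))
        out = np.full(len(bin_ids), np.nan)
        if len(self.bin_ids):
            hit = self.bin_ids[pos] == bin_ids
            out[hit] = self.sf[pos[hit]]
        return out

    def to_dataframe(self) -> pd.DataFrame:
        bpp = self.binner.bins_per_pair
        return pd.DataFrame(dict(pair_id=self.bin_ids // bpp,
                                 flat=self.bin_ids % bpp,
                                 sf=self.sf, c_raw=self.c_raw,
                                 c_ph_scatter=self.c_ph_scatter))


def photopeak_scatter_pair(smoothed: SmoothedCounts, coeff: ScatterCoefficients,
                           pair_id: int, dense: dict | None = None,
                           clamp_photopeak: bool = False) -> np.ndarray:
    """Dense per-bin photopeak-scatter estimate of one block pair.

    Implements the window-coefficient estimate literally;
    ``clamp_photopeak`` additionally caps it at the bin's smoothed
    photopeak content.  The cap is off by default: at desk-scale counts the
    smoothed per-bin statistics are sparse enough that it binds on noise
    and biases the estimate down (the method's intended regime is
    acquisitions orders of magnitude denser, where the cap is inert).
    ``dense`` may carry the precomputed smoothed lattices of this pair
    (from :meth:`SmoothedCounts.pair_all`) to avoid recomputation.
    """
    cfg = smoothed.counts.cfg
    binner = smoothed.binner
    shape = binner.pair_shape
    if dense is None:
        dense = smoothed.pair_all(pair_id)
    est = np.zeros(shape)
    base = pair_id * binner.bins_per_pair
    for w in cfg.auxiliary:
        if w not in coeff.k:
            continue
        k = coeff.k[w]
        if coeff.mode == "per_bin":
            ids = base + np.arange(binner.bins_per_pair, dtype=np.int64)
            k = coeff.k_for_bins(w, ids).reshape(shape)
        est += k * dense[w]
    if clamp_photopeak:
        return np.clip(est, 0.0, dense[PHOTOPEAK])
    return np.maximum(est, 0.0)


def estimate_scatter(data, cfg: EnergyWindowConfig,
                     coeff: ScatterCoefficients, binner: LORBinner,
                     bandwidths: dict | None = None,
                     lew_true_fraction: float = 0.0,
                     clamp_photopeak: bool = False) -> ScatterFractionMap:
    """Run the estimation chain: bin, smooth, apply coefficients, form SF.

    ``data`` is a :class:`ListModeSet` or precomputed :class:`WindowCounts`.
    ``lew_true_fraction`` switches on the purity-corrected numerator
    ``(1 - f_true) C~_LEW + C_ph,scatter`` (0 = the literal definition);
    ``clamp_photopeak`` caps the per-bin scatter estimate at the smoothed
    photopeak content (see :func:`photopeak_scatter_pair`).
    """
    counts = (data if isinstance(data, WindowCounts)
              else count_windows(data, cfg, binner))
    smoothed = smooth_window_counts(counts, bandwidths)
    num_sum = 0.0
    den_sum = 0.0
    n_clamped = 0
    ids_out, sf_out, raw_out, cps_out = [], [], [], []
    bpp = binner.bins_per_pair
    for pair_id in smoothed.occupied_pairs():
        pair_id = int(pair_id)
        dense = smoothed.pair_all(pair_id)
        lew_s = dense[LEW]
        ph_s = dense[PHOTOPEAK]
        total = lew_s + ph_s
        if cfg.mode == "TEW":
            total = total + dense[UEW]
        cps = photopeak_scatter_pair(smoothed, coeff, pair_id, dense=dense,
                                     clamp_photopeak=clamp_photopeak)
        if coeff.mode == "global":
            # diagnostic: how often the photopeak ceiling would bind (a
            # high rate on dense data signals mis-calibration)
            unc = np.zeros_like(ph_s)
            for w in cfg.auxiliary:
                if w in coeff.k:
                    unc += coeff.k[w] * dense[w]
            n_clamped += int(((unc > ph_s) & (total > 0)).sum())
        num = (1.0 - lew_true_fraction) * lew_s + cps
        with np.errstate(invalid="ignore", divide="ignore"):
            sf = np.where(total > 0, num / np.maximum(total, 1e-300), np.nan)
        sf = np.clip(sf, 0.0, 1.0)
        num_sum += float(num[total > 0].sum())
        den_sum += float(total[total > 0].sum())

        # record occupied (raw) bins for reconstruction use
        lo = np.searchsorted(counts.bin_ids, pair_id * bpp)
        hi = np.searchsorted(counts.bin_ids, (pair_id + 1) * bpp)
        ids = counts.bin_ids[lo:hi]
        flat = ids - pair_id * bpp
        ids_out.append(ids)
        sf_out.append(sf.reshape(-1)[flat])
        raw_out.append(counts.counts[lo:hi].sum(axis=1).astype(float))
        cps_out.append(cps.reshape(-1)[flat])
    if n_clamped:
        log.info("estimate_scatter: %d bins clamped at the photopeak ceiling",
                 n_clamped)
    empty = np.empty(0)
    return ScatterFractionMap(
        binner, cfg,
        bin_ids=np.concatenate(ids_out) if ids_out else empty.astype(np.int64),
        sf=np.concatenate(sf_out) if sf_out else empty,
        c_raw=np.concatenate(raw_out) if raw_out else empty,
        c_ph_scatter=np.concatenate(cps_out) if cps_out else empty,
        numerator_sum=num_sum, denominator_sum=den_sum, n_clamped=n_clamped,
        provenance=dict(window_mode=cfg.mode, coeff_mode=coeff.mode,
                        k={int(w): v for w, v in coeff.k.items()},
                        lew_true_fraction=lew_true_fraction),
    )


def global_scatter_fraction(sf_map: ScatterFractionMap) -> float:
    """Count-weighted global scatter fraction of the estimate."""
    return sf_map.global_sf


def labeled_scatter_fraction(lm: ListModeSet) -> float:
    """Ground-truth global scatter fraction from the simulator's labels."""
    if len(lm) == 0:
        raise ValueError("empty list-mode set")
    return float(lm.event_scattered.mean())


def event_scatter_fractions(sf_map: ScatterFractionMap, lm: ListModeSet) -> np.ndarray:
    """Per-event scatter fraction looked up from the event's LOR bin.

    Events whose bin carries no estimate (sentinel) get 0 (no correction).
    """
    pair, flat, ok = event_bins(lm, sf_map.binner)
    key = pair.astype(np.int64) * sf_map.binner.bins_per_pair + flat
    sf_event = np.zeros(len(lm))
    if len(sf_map.bin_ids):
        pos = np.searchsorted(sf_map.bin_ids, key)
        pos = np.clip(pos, 0, len(sf_map.bin_ids) - 1)
        hit = ok & (sf_map.bin_ids[pos] == key)
        sf_event[hit] = np.nan_to_num(sf_map.sf[pos[hit]], nan=0.0)
    return sf_event


@dataclass
class AdditiveScatterTerm:
    """Additive scatter term, per LOR bin and resolved per measured event.

    ``s_bin[b] = SF(b) * C_raw(b)`` is the expected scatter count of bin
    ``b``; ``per_event`` aligns one value with each event of the set the
    term was built for (0 where no estimate exists).
    """

    bin_ids: np.ndarray
    s_bin: np.ndarray
    per_event: np.ndarray

    def __post_init__(self):
        if (self.s_bin < 0).any() or not np.isfinite(self.s_bin).all():
            raise ValueError("additive term must be finite and non-negative")


def additive_term(sf_map: ScatterFractionMap, lm: ListModeSet,
                  recon_binner: LORBinner | None = None) -> AdditiveScatterTerm:
    """Resolve the additive scatter term for each event of ``lm``.

    The scatter fraction comes from the (fine) estimation bins of
    ``sf_map``; the count magnitude from the raw counts at the
    discretisation the reconstruction actually uses (``recon_binner``,
    default: the estimation binner).  The forward model's expected counts
    live at that discretisation, so ``S`` must too.  Bins without an SF
    estimate (sentinel) contribute no correction.
    """
    # per-event SF from the estimation bins
    pair, flat, ok = event_bins(lm, sf_map.binner)
    key = pair.astype(np.int64) * sf_map.binner.bins_per_pair + flat
    sf_event = np.zeros(len(lm))
    if len(sf_map.bin_ids):
        pos = np.searchsorted(sf_map.bin_ids, key)
        pos = np.clip(pos, 0, len(sf_map.bin_ids) - 1)
        hit = ok & (sf_map.bin_ids[pos] == key)
        sf_event[hit] = np.nan_to_num(sf_map.sf[pos[hit]], nan=0.0)
    # count magnitude at the reconstruction discretisation
    rb = recon_binner if recon_binner is not None else sf_map.binner
    rpair, rflat, rok = event_bins(lm, rb)
    rkey = rpair.astype(np.int64) * rb.bins_per_pair + rflat
    bins, inverse = np.unique(rkey, return_inverse=True)
    c_raw = np.bincount(inverse, weights=rok.astype(float))
    sf_sum = np.bincount(inverse, weights=sf_event * rok)
    with np.errstate(invalid="ignore"):
        sf_bin = np.where(c_raw > 0, sf_sum / np.maximum(c_raw, 1), 0.0)
    s_bin = sf_bin * c_raw
    per_event = np.where(rok, s_bin[inverse], 0.0)
    return AdditiveScatterTerm(bins, s_bin, per_event)
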