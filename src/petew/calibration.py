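"""Energy-window classification and scatter-coefficient calibration.

The correction estimates photopeak scatter from auxiliary energy windows:

* DEW (dual energy window): low window (LEW) 350-430 keV, photopeak
  430-650 keV.  ``C_ph,scatter = k_LEW * C_LEW`` per LOR bin.
* TEW (triple energy window): LEW 350-430, photopeak 430-550, upper window
  (UEW) 550-650.  ``C_ph,scatter = k_LEW * C_LEW + k_HEW * C_UEW``.

An event is a photopeak event when both photons fall in the photopeak
window; it belongs to an auxiliary window when one of its photons does.  A
photon in the LEW has lost at least 81 keV and has therefore almost surely
scattered, so mixed LEW/UEW events are classified LEW (priority
LEW > UEW > photopeak); the full truth table is exercised in the tests.

The coefficients ``k_w`` are calibrated on ground-truth-labelled
(simulated) data: for DEW the quotient of scattered-photopeak counts over
LEW counts; for TEW a joint non-negative least squares of scattered
photopeak counts on (LEW, UEW) counts across the calibration ensemble, so
that the two windows together estimate the scattered photopeak total once.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import nnls

from .geometry import LORBinner
from .listmode import ListModeSet

__all__ = [
    "EnergyWindowConfig",
    "classify_events",
    "classify_event",
    "WindowCounts",
    "count_windows",
    "ScatterCoefficients",
    "fit_coefficients",
    "true_counts",
    "true_count_total",
]

log = logging.getLogger(__name__)

LEW, PHOTOPEAK, UEW = 0, 1, 2
WINDOW_NAMES = {LEW: "lew", PHOTOPEAK: "photopeak", UEW: "uew"}


@dataclass(frozen=True)
class EnergyWindowConfig:
    """Contiguous window partition of the acceptance range (keV).

    ``mode`` is "DEW" (photopeak 430-650) or "TEW" (photopeak 430-550 plus
    upper window 550-650).
    """

    mode: str = "TEW"
    lew_upper: float = 430.0
    uew_lower: float = 550.0
    acceptance: tuple[float, float] = (350.0, 650.0)

    def __post_init__(self):
        if self.mode not in ("DEW", "TEW"):
            raise ValueError("mode must be 'DEW' or 'TEW'")
        lo, hi = self.acceptance
        if not lo < self.lew_upper < hi:
            raise ValueError("LEW boundary outside acceptance window")
        if self.mode == "TEW" and not self.lew_upper < self.uew_lower < hi:
            raise ValueError("UEW boundary must lie between LEW edge and cut-off")

    @property
    def lew(self) -> tuple[float, float]:
        return (self.acceptance[0], self.lew_upper)

    @property
    def photopeak(self) -> tuple[float, float]:
        hi = self.uew_lower if self.mode == "TEW" else self.acceptance[1]
        return (self.lew_upper, hi)

    @property
    def uew(self) -> tuple[float, float] | None:
        if self.mode == "DEW":
            return None
        return (self.uew_lower, self.acceptance[1])

    @property
    def windows(self) -> list[int]:
        return [LEW, PHOTOPEAK] + ([UEW] if self.mode == "TEW" else [])

    @property
    def auxiliary(self) -> list[int]:
        return [LEW] + ([UEW] if self.mode == "TEW" else [])


def classify_events(energy: np.ndarray, cfg: EnergyWindowConfig) -> np.ndarray:
    """Window label per event from the (n, 2) photon energies.

    Precondition: energies already passed the acceptance cut.  Total: every
    event receives exactly one label.
    """
    e = np.asarray(energy)
    in_lew = (e >= cfg.lew[0]) & (e < cfg.lew_upper)
    labels = np.full(len(e), PHOTOPEAK, dtype=np.int8)
    if cfg.mode == "TEW":
        in_uew = e >= cfg.uew_lower
        labels[in_uew.any(axis=1)] = UEW
    labels[in_lew.any(axis=1)] = LEW  # LEW has priority
    return labels


def classify_event(event, cfg: EnergyWindowConfig) -> str:
    """Window name ("lew" | "photopeak" | "uew") of a single event."""
    e = np.array([[event.p1.energy, event.p2.energy]])
    return WINDOW_NAMES[int(classify_events(e, cfg)[0])]


@dataclass
class WindowCounts:
    """Sparse per-(LOR bin, window) integer counts.

    ``bin_ids`` are global bin keys ``pair_id * bins_per_pair + flat``;
    ``counts`` has one row per occupied bin and one column per window index
    (LEW, photopeak, UEW).  ``totals[w]`` is the per-window event total.
    """

    binner: LORBinner
    cfg: EnergyWindowConfig
    bin_ids: np.ndarray          # (B,) int64, sorted
    counts: np.ndarray           # (B, 3) int64
    n_events: int
    n_unbinnable: int = 0

    @property
    def totals(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def pair_dense(self, pair_id: int, window: int) -> np.ndarray:
        """Dense 4-D count array of one block pair and window."""
        bpp = self.binner.bins_per_pair
        lo = np.searchsorted(self.bin_ids, pair_id * bpp)
        hi = np.searchsorted(self.bin_ids, (pair_id + 1) * bpp)
        dense = np.zeros(bpp)
        flat = self.bin_ids[lo:hi] - pair_id * bpp
        dense[flat] = self.counts[lo:hi, window]
        return dense.reshape(self.binner.pair_shape)

    def occupied_pairs(self) -> np.ndarray:
        return np.unique(self.bin_ids // self.binner.bins_per_pair)


def event_bins(lm: ListModeSet, binner: LORBinner):
    """Per-event (pair_id, flat, ok) bin assignment."""
    return binner.bin_arrays(lm.block, lm.u, lm.v)


def count_windows(lm: ListModeSet, cfg: EnergyWindowConfig,
                  binner: LORBinner) -> WindowCounts:
    """Tally events into (LOR bin, energy window) cells.

    Events on disallowed block pairs are excluded and counted in
    ``n_unbinnable``; the remaining counts sum to the accepted event total.
    """
    labels = classify_events(lm.energy, cfg)
    pair, flat, ok = event_bins(lm, binner)
    n_bad = int((~ok).sum())
    if n_bad:
        log.warning("count_windows: %d events not on an allowed block pair", n_bad)
    key = pair[ok].astype(np.int64) * binner.bins_per_pair + flat[ok]
    lab = labels[ok]
    bin_ids, inverse = np.unique(key, return_inverse=True)
    counts = np.zeros((len(bin_ids), 3), dtype=np.int64)
    np.add.at(counts, (inverse, lab), 1)
    return WindowCounts(binner, cfg, bin_ids, counts,
                        n_events=int(ok.sum()), n_unbinnable=n_bad)


@dataclass
class ScatterCoefficients:
    """Calibrated ``k_w`` mapping auxiliary-window counts to photopeak scatter.

    ``k[w]`` are the global coefficients.  In per-bin mode, bins with enough
    calibration counts carry their own value (``bin_ids``/``bin_k``); all
    other bins fall back to the global coefficient.
    """

    mode: str                    # "global" | "per_bin"
    window_mode: str             # "DEW" | "TEW"
    k: dict                      # window index -> float
    bin_ids: np.ndarray | None = None    # (B,) global bin keys
    bin_k: np.ndarray | None = None      # (B, n_aux) per-bin coefficients
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        for w, v in self.k.items():
            if v < 0:
                raise ValueError("coefficients must be non-negative")

    def k_for_bins(self, window: int, bin_ids: np.ndarray) -> np.ndarray:
        """Coefficient per requested bin (global fallback applied)."""
        out = np.full(len(bin_ids), self.k[window])
        if self.mode == "per_bin" and self.bin_ids is not None:
            col = {w: i for i, w in enumerate(sorted(self.k))}[window]
            pos = np.searchsorted(self.bin_ids, bin_ids)
            pos = np.clip(pos, 0, len(self.bin_ids) - 1)
            hit = self.bin_ids[pos] == bin_ids
            out[hit] = self.bin_k[pos[hit], col]
        return out

    def save(self, path) -> None:
        doc = dict(mode=self.mode, window_mode=self.window_mode,
                   k={WINDOW_NAMES[w]: float(v) for w, v in self.k.items()},
                   provenance=self.provenance)
        if self.bin_ids is not None:
            doc["bin_ids"] = self.bin_ids.tolist()
            doc["bin_k"] = self.bin_k.tolist()
        with open(path, "w") as f:
            json.dump(doc, f, indent=1)

    @classmethod
    def load(cls, path) -> "ScatterCoefficients":
        with open(path) as f:
            doc = json.load(f)
        names = {v: k for k, v in WINDOW_NAMES.items()}
        return cls(
            mode=doc["mode"], window_mode=doc["window_mode"],
            k={names[n]: float(v) for n, v in doc["k"].items()},
            bin_ids=None if "bin_ids" not in doc else np.asarray(doc["bin_ids"]),
            bin_k=None if "bin_k" not in doc else np.asarray(doc["bin_k"]),
            provenance=doc.get("provenance", {}),
        )


def _ensure_list(sets) -> list[ListModeSet]:
    return list(sets) if isinstance(sets, (list, tuple)) else [sets]


def fit_coefficients(labeled, cfg: EnergyWindowConfig,
                     mode: str = "global",
                     binner: LORBinner | None = None,
                     count_floor: int = 50) -> ScatterCoefficients:
    """Fit ``k_w`` from truth-labelled list-mode sets.

    ``labeled`` is one set or the calibration ensemble (e.g. the seven
    cylinder phantoms).  DEW: the quotient of scattered-photopeak events
    over LEW events.  TEW: joint non-negative least squares of per-member
    scattered-photopeak counts on (LEW, UEW) counts.  In ``per_bin`` mode
    the same estimators run per LOR bin (pooled over members), with bins
    under ``count_floor`` events falling back to the global value.
    """
    if mode not in ("global", "per_bin"):
        raise ValueError("mode must be 'global' or 'per_bin'")
    sets = _ensure_list(labeled)
    if binner is None and mode == "per_bin":
        raise ValueError("per_bin mode requires a binner")

    rows = []  # per member: (n_lew, n_uew, n_scattered_photopeak)
    for lm in sets:
        if not lm.has_truth:
            raise ValueError("calibration requires truth labels")
        labels = classify_events(lm.energy, cfg)
        sc = lm.event_scattered
        rows.append((
            int((labels == LEW).sum()),
            int((labels == UEW).sum()),
            int(((labels == PHOTOPEAK) & sc).sum()),
        ))
    rows = np.asarray(rows, dtype=float)

    k = _solve_k(rows, cfg)
    prov = dict(n_members=len(sets),
                members=[lm.meta.get("phantom") for lm in sets],
                window_mode=cfg.mode)

    if mode == "global":
        return ScatterCoefficients("global", cfg.mode, k, provenance=prov)

    # per-bin: pooled per-bin counts with floor fallback
    per_bin: dict[int, np.ndarray] = {}
    for lm in sets:
        labels = classify_events(lm.energy, cfg)
        sc = lm.event_scattered
        pair, flat, ok = event_bins(lm, binner)
        key = pair[ok].astype(np.int64) * binner.bins_per_pair + flat[ok]
        lab, scat = labels[ok], sc[ok]
        bin_ids, inv = np.unique(key, return_inverse=True)
        acc = np.zeros((len(bin_ids), 4))
        np.add.at(acc, (inv, np.minimum(lab, 2)), 1)
        np.add.at(acc[:, 3], inv[(lab == PHOTOPEAK) & scat], 1)
        for bid, row in zip(bin_ids, acc):
            per_bin[bid] = per_bin.get(bid, 0) + row
    bids = np.array(sorted(per_bin), dtype=np.int64)
    aux = cfg.auxiliary
    bin_k = np.zeros((len(bids), len(aux)))
    n_fallback = 0
    for i, bid in enumerate(bids):
        row = per_bin[bid]
        total = row[:3].sum()
        if total < count_floor:
            bin_k[i] = [k[w] for w in aux]
            n_fallback += 1
            continue
        member = np.array([[row[LEW], row[UEW], row[3]]])
        kb = _solve_k(member, cfg)
        for j, w in enumerate(aux):
            denom = member[0, 0 if w == LEW else 1]
            bin_k[i, j] = kb[w] if denom > 0 else k[w]
    prov["n_bins_fallback"] = n_fallback
    log.info("fit_coefficients per_bin: %d bins, %d below floor (fallback)",
             len(bids), n_fallback)
    return ScatterCoefficients("per_bin", cfg.mode, k, bids, bin_k, prov)


def _solve_k(rows: np.ndarray, cfg: EnergyWindowConfig) -> dict:
    """Coefficients from (n_lew, n_uew, n_scattered_pp) ensemble rows."""
    n_lew = rows[:, 0].sum()
    n_uew = rows[:, 1].sum()
    n_scat = rows[:, 2].sum()
    if n_scat == 0:
        return {w: 0.0 for w in cfg.auxiliary}
    if cfg.mode == "DEW":
        if n_lew == 0:
            log.warning("zero LEW counts with nonzero scatter; k set to 0")
            return {LEW: 0.0}
        return {LEW: float(n_scat / n_lew)}
    design = rows[:, :2]
    target = rows[:, 2]
    usable = design.sum(axis=0) > 0
    if len(rows) == 1 or usable.sum() < 2:
        # single member (or degenerate design): fall back to the quotient
        # estimator per auxiliary window, halving to avoid double counting
        k_lew = 0.5 * n_scat / n_lew if n_lew > 0 else 0.0
        k_hew = 0.5 * n_scat / n_uew if n_uew > 0 else 0.0
        return {LEW: float(k_lew), UEW: float(k_hew)}
    sol, _res = nnls(design, target)
    return {LEW: float(sol[0]), UEW: float(sol[1])}


def true_counts(counts: WindowCounts, coeff: ScatterCoefficients):
    """Estimated unscattered photopeak counts per bin.

    ``C_true(b) = C_ph(b) - sum_w k_w C_w(b)``, clamped at zero (counts are
    physical).  Returns ``(bin_ids, c_true)``.
    """
    c_ph = counts.counts[:, PHOTOPEAK].astype(float)
    est = np.zeros_like(c_ph)
    for w in counts.cfg.auxiliary:
        if w in coeff.k:
            est += coeff.k_for_bins(w, counts.bin_ids) * counts.counts[:, w]
    return counts.bin_ids, np.maximum(c_ph - est, 0.0)


def true_count_total(counts: WindowCounts, coeff: ScatterCoefficients) -> float:
    """Estimated unscattered photopeak total, no per-bin clamping.

    ``C_ph,total - sum_w k_w C_w,total``.  With global DEW coefficients on
    their own calibration data this reproduces the labelled unscattered
    photopeak total exactly (the quotient estimator is self-consistent).
    """
    tot = counts.totals
    est = sum(coeff.k[w] * tot[w] for w in counts.cfg.auxiliary if w in coeff.k)
    val = float(tot[PHOTOPEAK] - est)
    if val < 0:
        log.warning("true_count_total: negative estimate %.1f", val)
    return val
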