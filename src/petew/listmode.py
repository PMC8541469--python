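"""List-mode coincidence data model and file formats.

A coincidence is two photon impacts (block id, in-block position, optional
depth of interaction, deposited energy) plus a time stamp, optionally carrying
ground-truth scatter labels when produced by the bundled simulator.  Storage
is columnar (:class:`ListModeSet`); :class:`CoincidenceEvent` is a per-event
view for single-event code.

Formats
-------
CSV
    Header line with the documented column order
    ``block1,u1,v1,doi1,energy1,block2,u2,v2,doi2,energy2,time`` followed by
    the truth columns
    ``scat1,scat2,nscat1,nscat2,origin_in_fov,source_id,origin_z`` when truth
    is present.  Floats are printed with enough digits for a bit-exact
    round trip.
binary
    Columnar: magic ``PETEWLM``, a length-prefixed JSON header (version,
    event count, truth flag, geometry hash, provenance) and the raw column
    blocks in header order.

Both readers apply the scanner's hardware acceptance window to each photon
and drop failing events; the rejected count is logged and recorded in the
set's provenance so that ``kept + rejected`` equals the file's rows.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .geometry import ScannerGeometry, global_to_local

__all__ = [
    "PhotonImpact",
    "CoincidenceEvent",
    "ListModeSet",
    "write_listmode",
    "read_listmode",
    "read_gate_ascii",
]

log = logging.getLogger(__name__)

_MAGIC = b"PETEWLM"
_VERSION = 1

# column name -> (dtype, shape-per-event) in serialization order
_CORE_COLUMNS = [
    ("block", np.int16, 2),
    ("u", np.float32, 2),
    ("v", np.float32, 2),
    ("doi", np.float32, 2),
    ("energy", np.float32, 2),
    ("time", np.float64, 1),
]
_TRUTH_COLUMNS = [
    ("scattered", np.bool_, 2),
    ("n_scatters", np.int16, 2),
    ("origin_in_fov", np.bool_, 1),
    ("source_id", np.int16, 1),
    ("origin_z", np.float32, 1),
]


@dataclass(frozen=True)
class PhotonImpact:
    block_id: int
    u: float       # mm, transaxial face coordinate
    v: float       # mm, axial face coordinate
    doi: float     # mm, depth of interaction (0 = inner face)
    energy: float  # keV, measured (blurred) energy
    time: float = 0.0  # ns


@dataclass(frozen=True)
class CoincidenceEvent:
    """Per-event view; ``truth`` fields are None without ground truth."""

    p1: PhotonImpact
    p2: PhotonImpact
    scattered: Optional[tuple[bool, bool]] = None
    n_scatters: Optional[tuple[int, int]] = None
    origin_in_fov: Optional[bool] = None
    source_id: Optional[int] = None
    origin_z: Optional[float] = None


class ListModeSet:
    """Columnar collection of coincidences tied to a scanner geometry.

    Arrays with one row per event: ``block``/``u``/``v``/``doi``/``energy``
    have shape ``(n, 2)`` (photon 1, photon 2), ``time`` shape ``(n,)``.
    Truth arrays are all present or all absent.  ``meta`` carries provenance
    (simulation parameters, seed, rejection counts).
    """

    def __init__(self, geometry: ScannerGeometry, *, block, u, v, doi, energy,
                 time=None, scattered=None, n_scatters=None,
                 origin_in_fov=None, source_id=None, origin_z=None,
                 meta: dict | None = None):
        self.geometry = geometry
        self.block = np.asarray(block, dtype=np.int16).reshape(-1, 2)
        n = len(self.block)
        self.u = np.asarray(u, dtype=np.float32).reshape(n, 2)
        self.v = np.asarray(v, dtype=np.float32).reshape(n, 2)
        self.doi = np.asarray(doi, dtype=np.float32).reshape(n, 2)
        self.energy = np.asarray(energy, dtype=np.float32).reshape(n, 2)
        self.time = (np.zeros(n, dtype=np.float64) if time is None
                     else np.asarray(time, dtype=np.float64).reshape(n))
        truth_given = [scattered, n_scatters, origin_in_fov, source_id, origin_z]
        if any(t is not None for t in truth_given):
            if any(t is None for t in truth_given[:4]):
                raise ValueError("truth arrays must be given together")
            self.scattered = np.asarray(scattered, dtype=bool).reshape(n, 2)
            self.n_scatters = np.asarray(n_scatters, dtype=np.int16).reshape(n, 2)
            self.origin_in_fov = np.asarray(origin_in_fov, dtype=bool).reshape(n)
            self.source_id = np.asarray(source_id, dtype=np.int16).reshape(n)
            self.origin_z = (np.zeros(n, dtype=np.float32) if origin_z is None
                             else np.asarray(origin_z, dtype=np.float32).reshape(n))
        else:
            self.scattered = None
            self.n_scatters = None
            self.origin_in_fov = None
            self.source_id = None
            self.origin_z = None
        self.meta = dict(meta or {})

    # -- basics -----------------------------------------------------------

    def __len__(self) -> int:
        return len(self.block)

    @property
    def has_truth(self) -> bool:
        return self.scattered is not None

    def event(self, i: int) -> CoincidenceEvent:
        p = [PhotonImpact(int(self.block[i, j]), float(self.u[i, j]),
                          float(self.v[i, j]), float(self.doi[i, j]),
                          float(self.energy[i, j]), float(self.time[i]))
             for j in (0, 1)]
        if not self.has_truth:
            return CoincidenceEvent(p[0], p[1])
        return CoincidenceEvent(
            p[0], p[1],
            scattered=(bool(self.scattered[i, 0]), bool(self.scattered[i, 1])),
            n_scatters=(int(self.n_scatters[i, 0]), int(self.n_scatters[i, 1])),
            origin_in_fov=bool(self.origin_in_fov[i]),
            source_id=int(self.source_id[i]),
            origin_z=float(self.origin_z[i]),
        )

    def __iter__(self):
        return (self.event(i) for i in range(len(self)))

    def select(self, mask) -> "ListModeSet":
        """Subset by boolean mask or index array; truth follows along."""
        kw = {}
        if self.has_truth:
            kw = dict(scattered=self.scattered[mask],
                      n_scatters=self.n_scatters[mask],
                      origin_in_fov=self.origin_in_fov[mask],
                      source_id=self.source_id[mask],
                      origin_z=self.origin_z[mask])
        return ListModeSet(self.geometry, block=self.block[mask],
                           u=self.u[mask], v=self.v[mask], doi=self.doi[mask],
                           energy=self.energy[mask], time=self.time[mask],
                           meta=self.meta, **kw)

    @property
    def event_scattered(self) -> np.ndarray:
        """Per-event truth flag: at least one photon scattered in the phantom."""
        if not self.has_truth:
            raise ValueError("set carries no truth labels")
        return self.scattered.any(axis=1)

    def equals(self, other: "ListModeSet") -> bool:
        if len(self) != len(other) or self.has_truth != other.has_truth:
            return False
        same = (np.array_equal(self.block, other.block)
                and np.array_equal(self.u, other.u)
                and np.array_equal(self.v, other.v)
                and np.array_equal(self.doi, other.doi)
                and np.array_equal(self.energy, other.energy)
                and np.array_equal(self.time, other.time))
        if same and self.has_truth:
            same = (np.array_equal(self.scattered, other.scattered)
                    and np.array_equal(self.n_scatters, other.n_scatters)
                    and np.array_equal(self.origin_in_fov, other.origin_in_fov)
                    and np.array_equal(self.source_id, other.source_id)
                    and np.array_equal(self.origin_z, other.origin_z))
        return same

    # -- dataframe bridge --------------------------------------------------

    def to_dataframe(self) -> pd.DataFrame:
        cols = {
            "block1": self.block[:, 0], "u1": self.u[:, 0], "v1": self.v[:, 0],
            "doi1": self.doi[:, 0], "energy1": self.energy[:, 0],
            "block2": self.block[:, 1], "u2": self.u[:, 1], "v2": self.v[:, 1],
            "doi2": self.doi[:, 1], "energy2": self.energy[:, 1],
            "time": self.time,
        }
        if self.has_truth:
            cols.update({
                "scat1": self.scattered[:, 0].astype(np.int8),
                "scat2": self.scattered[:, 1].astype(np.int8),
                "nscat1": self.n_scatters[:, 0],
                "nscat2": self.n_scatters[:, 1],
                "origin_in_fov": self.origin_in_fov.astype(np.int8),
                "source_id": self.source_id,
                "origin_z": self.origin_z,
            })
        return pd.DataFrame(cols)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, geometry: ScannerGeometry,
                       meta: dict | None = None) -> "ListModeSet":
        kw = {}
        if "scat1" in df.columns:
            kw = dict(
                scattered=np.stack([df["scat1"], df["scat2"]], axis=1).astype(bool),
                n_scatters=np.stack([df["nscat1"], df["nscat2"]], axis=1),
                origin_in_fov=df["origin_in_fov"].to_numpy().astype(bool),
                source_id=df["source_id"].to_numpy(),
                origin_z=df["origin_z"].to_numpy(dtype=np.float32),
            )
        return cls(
            geometry,
            block=np.stack([df["block1"], df["block2"]], axis=1),
            u=np.stack([df["u1"], df["u2"]], axis=1).astype(np.float32),
            v=np.stack([df["v1"], df["v2"]], axis=1).astype(np.float32),
            doi=np.stack([df["doi1"], df["doi2"]], axis=1).astype(np.float32),
            energy=np.stack([df["energy1"], df["energy2"]], axis=1).astype(np.float32),
            time=df["time"].to_numpy(dtype=np.float64),
            meta=meta, **kw,
        )


def _apply_acceptance(lm: ListModeSet) -> ListModeSet:
    lo, hi = lm.geometry.acceptance_window
    ok = ((lm.energy >= lo) & (lm.energy <= hi)).all(axis=1)
    n_rej = int((~ok).sum())
    if n_rej:
        log.info("acceptance window %s keV rejected %d of %d events",
                 lm.geometry.acceptance_window, n_rej, len(lm))
    out = lm.select(ok)
    out.meta = dict(lm.meta)
    out.meta["n_rejected_acceptance"] = n_rej
    return out


def write_listmode(lm: ListModeSet, path, format: str = "binary") -> None:
    """Write a list-mode set; ``format`` is ``"csv"`` or ``"binary"``.

    Both formats round-trip bit-exactly through :func:`read_listmode`.
    """
    if format == "csv":
        df = lm.to_dataframe()
        df.to_csv(path, index=False, float_format="%.9g")
    elif format == "binary":
        columns = _CORE_COLUMNS + (_TRUTH_COLUMNS if lm.has_truth else [])
        header = {
            "version": _VERSION,
            "n_events": len(lm),
            "has_truth": lm.has_truth,
            "geometry": lm.geometry.to_dict(),
            "geometry_hash": lm.geometry.hash(),
            "meta": _jsonable(lm.meta),
            "columns": [[name, np.dtype(dt).str, width] for name, dt, width in columns],
        }
        hdr = json.dumps(header).encode()
        with open(path, "wb") as f:
            f.write(_MAGIC)
            f.write(np.uint32(len(hdr)).tobytes())
            f.write(hdr)
            for name, dt, width in columns:
                arr = _column(lm, name)
                f.write(np.ascontiguousarray(arr, dtype=dt).tobytes())
    else:
        raise ValueError(f"unknown list-mode format {format!r}")


def read_listmode(path, format: str | None = None,
                  geometry: ScannerGeometry | None = None,
                  apply_acceptance: bool = True) -> ListModeSet:
    """Read a list-mode file written by :func:`write_listmode`.

    ``format`` is inferred from the magic bytes when omitted.  For CSV the
    geometry must be supplied (CSV carries no geometry block).  The hardware
    acceptance cut is applied unless ``apply_acceptance`` is False; the
    rejected count lands in ``meta["n_rejected_acceptance"]``.
    """
    if format is None:
        with open(path, "rb") as f:
            format = "binary" if f.read(len(_MAGIC)) == _MAGIC else "csv"
    if format == "csv":
        if geometry is None:
            raise ValueError("reading CSV list-mode requires a geometry")
        df = pd.read_csv(path)
        dtypes = {"block1": np.int16, "block2": np.int16,
                  "u1": np.float32, "u2": np.float32,
                  "v1": np.float32, "v2": np.float32,
                  "doi1": np.float32, "doi2": np.float32,
                  "energy1": np.float32, "energy2": np.float32}
        for c, dt in dtypes.items():
            df[c] = df[c].astype(dt)
        if "origin_z" in df.columns:
            df["origin_z"] = df["origin_z"].astype(np.float32)
        lm = ListModeSet.from_dataframe(df, geometry)
    elif format == "binary":
        with open(path, "rb") as f:
            magic = f.read(len(_MAGIC))
            if magic != _MAGIC:
                raise ValueError("not a petew list-mode binary file")
            (hdr_len,) = np.frombuffer(f.read(4), dtype=np.uint32)
            header = json.loads(f.read(int(hdr_len)).decode())
            if header["version"] != _VERSION:
                raise ValueError(f"unsupported list-mode version {header['version']}")
            n = header["n_events"]
            geom = ScannerGeometry.from_dict(header["geometry"])
            data = {}
            for name, dtstr, width in header["columns"]:
                dt = np.dtype(dtstr)
                count = n * width
                arr = np.frombuffer(f.read(count * dt.itemsize), dtype=dt)
                data[name] = arr.reshape(n, width) if width > 1 else arr
        lm = ListModeSet(geom, meta=header.get("meta") or {}, **data)
    else:
        raise ValueError(f"unknown list-mode format {format!r}")
    return _apply_acceptance(lm) if apply_acceptance else lm


def _column(lm: ListModeSet, name: str) -> np.ndarray:
    return getattr(lm, name)


def _jsonable(meta: dict) -> dict:
    out = {}
    for k, v in meta.items():
        if isinstance(v, (np.integer,)):
            v = int(v)
        elif isinstance(v, (np.floating,)):
            v = float(v)
        elif isinstance(v, np.ndarray):
            v = v.tolist()
        out[k] = v
    return out


def read_gate_ascii(path, column_map: dict, geometry: ScannerGeometry,
                    energy_unit: str = "MeV",
                    apply_acceptance: bool = True) -> ListModeSet:
    """Read a GATE-style whitespace-delimited coincidence ASCII file.

    ``column_map`` gives 0-based column indices; mandatory keys are
    ``x1 y1 z1 e1 x2 y2 z2 e2``, optional ``t1``, ``comptonPhantom1``,
    ``comptonPhantom2``, ``sourcez``.  Global positions are converted to
    block-local coordinates by nearest-azimuth block assignment; a per-photon
    phantom-Compton counter > 0 marks the photon as scattered in the phantom.
    Energies are converted to keV from ``energy_unit`` ("MeV" or "keV").
    Malformed rows are skipped with a logged count; a missing mandatory
    column aborts.
    """
    mandatory = ["x1", "y1", "z1", "e1", "x2", "y2", "z2", "e2"]
    for key in mandatory:
        if key not in column_map:
            raise ValueError(f"column_map is missing mandatory key {key!r}")
    scale = {"MeV": 1000.0, "keV": 1.0}[energy_unit]
    rows, n_bad = [], 0
    max_col = max(column_map.values())
    with open(path) as f:
        for line in f:
            parts = line.split()
            if not parts:
                continue
            if len(parts) <= max_col:
                n_bad += 1
                continue
            try:
                rows.append([float(parts[i]) for i in column_map.values()])
            except ValueError:
                n_bad += 1
    if n_bad:
        log.warning("read_gate_ascii: skipped %d malformed rows", n_bad)
    keys = list(column_map.keys())
    arr = np.asarray(rows, dtype=float).reshape(len(rows), len(keys))
    col = {k: arr[:, i] for i, k in enumerate(keys)}
    n = len(rows)

    blocks = np.zeros((n, 2), dtype=np.int16)
    u = np.zeros((n, 2), dtype=np.float32)
    v = np.zeros((n, 2), dtype=np.float32)
    doi = np.zeros((n, 2), dtype=np.float32)
    for j, sfx in enumerate(("1", "2")):
        p = np.stack([col["x" + sfx], col["y" + sfx], col["z" + sfx]], axis=1)
        phi = np.arctan2(p[:, 1], p[:, 0])
        k = np.round(phi / (2 * np.pi / geometry.n_blocks)).astype(int) % geometry.n_blocks
        uu, vv, dd = global_to_local(geometry, k, p)
        blocks[:, j] = k
        u[:, j] = uu
        v[:, j] = vv
        doi[:, j] = np.clip(dd, 0.0, geometry.block_depth)
    energy = np.stack([col["e1"], col["e2"]], axis=1).astype(np.float32) * scale
    time = col.get("t1", np.zeros(n))

    kw = {}
    if "comptonPhantom1" in col and "comptonPhantom2" in col:
        nsc = np.stack([col["comptonPhantom1"], col["comptonPhantom2"]],
                       axis=1).astype(np.int16)
        origin_z = col.get("sourcez", np.zeros(n)).astype(np.float32)
        kw = dict(scattered=nsc > 0, n_scatters=nsc,
                  origin_in_fov=np.abs(origin_z) <= geometry.axial_fov / 2,
                  source_id=np.zeros(n, dtype=np.int16), origin_z=origin_z)
    lm = ListModeSet(geometry, block=blocks, u=u, v=v, doi=doi, energy=energy,
                     time=time, meta={"source": "gate_ascii",
                                      "n_malformed_rows": n_bad}, **kw)
    return _apply_acceptance(lm) if apply_acceptance else lm
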