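"""File readers and writers for the pipeline's input and output formats.

* Mass-photometry events: HDF5 ("eventsFitted"-style, one-dimensional
  numeric dataset, default names masses_kDa / masses / contrasts) or a
  one-column CSV (header optional, comma or tab).
* nanoDSF processed curves: wide CSV with a temperature column and
  per-capillary ``<label>:F330`` / ``<label>:F350`` /
  ``<label>:Scattering`` columns.
* DLS correlograms: two-column CSV (tau_s, g2), with an explicit flag
  for the g2-1 dialect (never guessed from values).
"""

from __future__ import annotations

import csv
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .dls import Correlogram, Environment, Optics
from .nanodsf import ThermalRamp
from .photomol import MPEventSet

__all__ = [
    "read_events",
    "write_events",
    "read_thermal_ramps",
    "write_thermal_ramps",
    "read_correlogram",
    "write_correlogram",
    "DEFAULT_DATASET_NAMES",
]

DEFAULT_DATASET_NAMES = ("masses_kDa", "masses", "contrasts")


def _find_dataset(h5: h5py.File, names) -> tuple[str, np.ndarray] | None:
    found: dict[str, np.ndarray] = {}

    def visit(name, obj):
        if isinstance(obj, h5py.Dataset) and obj.ndim == 1 and obj.dtype.kind in "fiu":
            found[name.split("/")[-1]] = obj[...]

    h5.visititems(visit)
    for want in names:
        if want in found:
            return want, found[want]
    return None


def read_events(
    path: str | Path, dataset_preference=DEFAULT_DATASET_NAMES
) -> MPEventSet:
    """Load mass-photometry events from HDF5 or CSV.

    HDF5: the first 1-D numeric dataset among ``dataset_preference`` is
    used; a name containing "contrast" yields kind="contrast", otherwise
    kind="mass".  CSV: a single numeric column, optional header, comma or
    tab delimited; kind from the header when it names contrasts, else mass.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if h5py.is_hdf5(path):
        with h5py.File(path, "r") as h5:
            hit = _find_dataset(h5, dataset_preference)
            if hit is None:
                raise ValueError(
                    f"{path}: no 1-D numeric dataset among {list(dataset_preference)}"
                )
            name, values = hit
        kind = "contrast" if "contrast" in name.lower() else "mass"
        return MPEventSet(values=np.asarray(values, dtype=float), kind=kind,
                          source=str(path), meta={"dataset": name})
    # CSV route
    text = path.read_text()
    try:
        dialect = csv.Sniffer().sniff(text[:2048], delimiters=",\t")
        sep = dialect.delimiter
    except csv.Error:
        sep = ","
    first = text.splitlines()[0] if text.strip() else ""
    has_header = False
    try:
        float(first.split(sep)[0])
    except (ValueError, IndexError):
        has_header = bool(first.strip())
    df = pd.read_csv(
        path, sep=sep, header=0 if has_header else None,
        float_precision="round_trip",
    )
    if df.shape[1] != 1:
        raise ValueError(f"{path}: expected a single event column, got {df.shape[1]}")
    col = df.iloc[:, 0]
    if not pd.api.types.is_numeric_dtype(col):
        raise ValueError(
            f"{path}: non-numeric event column; searched datasets "
            f"{list(dataset_preference)} / one numeric CSV column"
        )
    header_name = str(df.columns[0]).lower() if has_header else ""
    kind = "contrast" if "contrast" in header_name else "mass"
    return MPEventSet(values=col.to_numpy(dtype=float), kind=kind, source=str(path))


def write_events(events: MPEventSet, path: str | Path) -> Path:
    """Write events as HDF5 (.h5/.hdf5) or one-column CSV, by extension."""
    path = Path(path)
    if path.suffix.lower() in (".h5", ".hdf5"):
        name = "masses_kDa" if events.kind == "mass" else "contrasts"
        with h5py.File(path, "w") as h5:
            h5.create_dataset(name, data=events.values)
    else:
        header = "mass_kDa" if events.kind == "mass" else "contrast"
        # %.17g keeps doubles bit-exact through the text round trip
        pd.DataFrame({header: events.values}).to_csv(
            path, index=False, float_format="%.17g"
        )
    return path


# ---------------------------------------------------------------------------
# nanoDSF curves


_TEMP_ALIASES = ("temperature", "temp", "t", "temperature_c")


def read_thermal_ramps(path: str | Path) -> list[ThermalRamp]:
    """Read a wide-format processed-curve CSV into per-capillary ramps.

    Expected columns: one temperature column plus ``<label>:F330``,
    ``<label>:F350`` and optionally ``<label>:Scattering`` per capillary.
    Rows are sorted by temperature if needed (with a warning).
    """
    path = Path(path)
    df = pd.read_csv(path)
    temp_col = next(
        (c for c in df.columns if str(c).strip().lower() in _TEMP_ALIASES), None
    )
    if temp_col is None:
        raise ValueError(f"{path}: no temperature column (tried {_TEMP_ALIASES})")
    labels: dict[str, dict[str, str]] = {}
    for c in df.columns:
        if c == temp_col or ":" not in str(c):
            continue
        label, channel = str(c).rsplit(":", 1)
        labels.setdefault(label.strip(), {})[channel.strip().lower()] = c
    ramps = []
    for label, chans in labels.items():
        if "f330" not in chans or "f350" not in chans:
            raise ValueError(f"{path}: capillary {label!r} missing F330/F350 columns")
        scat = df[chans["scattering"]].to_numpy(float) if "scattering" in chans else None
        ramps.append(
            ThermalRamp(
                temperature=df[temp_col].to_numpy(float),
                f330=df[chans["f330"]].to_numpy(float),
                f350=df[chans["f350"]].to_numpy(float),
                scattering=scat,
                label=label,
            )
        )
    if not ramps:
        raise ValueError(f"{path}: no capillary columns found")
    return ramps


def write_thermal_ramps(ramps: list[ThermalRamp], path: str | Path) -> Path:
    """Write ramps in the wide-format CSV accepted by :func:`read_thermal_ramps`."""
    path = Path(path)
    base = ramps[0].temperature
    data = {"Temperature": base}
    for r in ramps:
        if r.temperature.size != base.size or not np.allclose(r.temperature, base):
            raise ValueError("all ramps must share one temperature grid for wide CSV")
        data[f"{r.label}:F330"] = r.f330
        data[f"{r.label}:F350"] = r.f350
        if r.scattering is not None:
            data[f"{r.label}:Scattering"] = r.scattering
    pd.DataFrame(data).to_csv(path, index=False)
    return path


# ---------------------------------------------------------------------------
# DLS correlograms


def read_correlogram(
    path: str | Path,
    g2_minus_one: bool = False,
    optics: Optics | None = None,
    environment: Environment | None = None,
    label: str | None = None,
) -> Correlogram:
    """Read a (tau_s, g2) CSV.  With ``g2_minus_one`` the second column is
    the g2-1 dialect and is shifted by +1 (baseline convention B=1)."""
    path = Path(path)
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: need lag-time and g2 columns")
    tau = df.iloc[:, 0].to_numpy(float)
    g2 = df.iloc[:, 1].to_numpy(float)
    if np.any(np.diff(tau) <= 0):
        raise ValueError(f"{path}: lag times must be strictly increasing")
    if g2_minus_one:
        g2 = g2 + 1.0
    return Correlogram(
        tau=tau,
        g2=g2,
        optics=optics or Optics(),
        environment=environment or Environment(),
        label=label if label is not None else path.stem,
    )


def write_correlogram(corr: Correlogram, path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame({"tau_s": corr.tau, "g2": corr.g2}).to_csv(path, index=False)
    return path
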