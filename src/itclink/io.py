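"""Plain-text readers and writers for titration data.

Thermogram files are delimiter-separated tables (comma by default) with a
'#'-prefixed ``key=value`` header block carrying the titration protocol::

    # cell_volume=200.0
    # injection_volume=2.0
    # n_injections=19
    # cell_macromolecule_total=10.0
    # syringe_titrant_total=100.0
    # effector_conc=0.0
    # temperature=25.0
    # cell_conc_basis=monomer
    # monomer_per_site=2
    # units=ucal
    injection_index,injection_volume,heat
    1,2.0,-1.23
    ...

Linkage datasets are three-column tables (oxo_mM, kdapp_uM, se_uM; the SE
column optional). Writers emit exactly what the readers accept, so simulated
data round-trips and is indistinguishable from imported data.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import numpy as np
import pandas as pd

from .binding import Thermogram, TitrationProtocol
from .fitting import LinkageDataset

__all__ = [
    "read_thermogram",
    "write_thermogram",
    "read_linkage_dataset",
    "write_linkage_dataset",
    "ThermogramFormatError",
]

_REQUIRED_PROTOCOL_KEYS = (
    "cell_volume",
    "injection_volume",
    "n_injections",
    "cell_macromolecule_total",
    "syringe_titrant_total",
    "effector_conc",
    "temperature",
)
_OPTIONAL_PROTOCOL_KEYS = {
    "cell_conc_basis": str,
    "monomer_per_site": int,
    "injection_interval_s": float,
    "label": str,
}


class ThermogramFormatError(ValueError):
    """Malformed thermogram file."""


def _parse_header(lines: list[str]) -> dict[str, str]:
    meta: dict[str, str] = {}
    for ln in lines:
        body = ln.lstrip("#").strip()
        if not body or "=" not in body:
            continue
        key, _, val = body.partition("=")
        meta[key.strip()] = val.strip()
    return meta


def read_thermogram(
    path, *, delimiter: str = ",", exclude_first: bool = False
) -> Thermogram:
    """Read a thermogram table with its protocol header.

    ``exclude_first=True`` drops the first injection's heat after validation
    (the usual treatment of the unreliable first peak).

    Raises
    ------
    ThermogramFormatError
        Missing protocol keys (listed by name), non-contiguous injection
        indices, or a row count disagreeing with ``n_injections``.
    """
    path = Path(path)
    text = path.read_text()
    header = [ln for ln in text.splitlines() if ln.startswith("#")]
    meta = _parse_header(header)

    missing = [k for k in _REQUIRED_PROTOCOL_KEYS if k not in meta]
    if missing:
        raise ThermogramFormatError(
            f"{path.name}: missing protocol keys: {', '.join(missing)}"
        )

    kwargs = {
        "cell_volume": float(meta["cell_volume"]),
        "injection_volume": float(meta["injection_volume"]),
        "n_injections": int(meta["n_injections"]),
        "cell_macromolecule_total": float(meta["cell_macromolecule_total"]),
        "syringe_titrant_total": float(meta["syringe_titrant_total"]),
        "effector_conc": float(meta["effector_conc"]),
        "temperature": float(meta["temperature"]),
    }
    for key, conv in _OPTIONAL_PROTOCOL_KEYS.items():
        if key in meta:
            kwargs[key] = conv(meta[key])
    protocol = TitrationProtocol(**kwargs)

    units = meta.get("units", "ucal")
    df = pd.read_csv(_io.StringIO(text), comment="#", sep=delimiter,
                     float_precision="round_trip")
    expected_cols = {"injection_index", "injection_volume", "heat"}
    if not expected_cols.issubset(df.columns):
        raise ThermogramFormatError(
            f"{path.name}: expected columns {sorted(expected_cols)}, "
            f"got {list(df.columns)}"
        )
    idx = df["injection_index"].to_numpy()
    if not np.array_equal(idx, np.arange(1, len(idx) + 1)):
        raise ThermogramFormatError(
            f"{path.name}: injection_index must be contiguous ascending from 1"
        )
    if (df["injection_volume"] <= 0).any():
        raise ThermogramFormatError(f"{path.name}: injection volumes must be positive")
    if len(df) != protocol.n_injections:
        raise ThermogramFormatError(
            f"{path.name}: {len(df)} rows but protocol says "
            f"n_injections={protocol.n_injections}"
        )

    tg = Thermogram(
        heats=df["heat"].to_numpy(dtype=float), protocol=protocol, units=units
    )
    return tg.exclude_first() if exclude_first else tg


def write_thermogram(thermogram: Thermogram, path, *, delimiter: str = ",") -> None:
    """Write a thermogram with its full protocol header (raw heats only)."""
    if thermogram.first_injection_excluded:
        raise ValueError(
            "cannot write a truncated thermogram; write before excluding"
        )
    p = thermogram.protocol
    lines = [
        f"# cell_volume={p.cell_volume}",
        f"# injection_volume={p.injection_volume}",
        f"# n_injections={p.n_injections}",
        f"# cell_macromolecule_total={p.cell_macromolecule_total}",
        f"# syringe_titrant_total={p.syringe_titrant_total}",
        f"# effector_conc={p.effector_conc}",
        f"# temperature={p.temperature}",
        f"# cell_conc_basis={p.cell_conc_basis}",
        f"# monomer_per_site={p.monomer_per_site}",
        f"# injection_interval_s={p.injection_interval_s}",
        f"# label={p.label}",
        f"# units={thermogram.units}",
        delimiter.join(("injection_index", "injection_volume", "heat")),
    ]
    for i, q in enumerate(thermogram.heats, start=1):
        lines.append(delimiter.join((str(i), repr(p.injection_volume), repr(float(q)))))
    Path(path).write_text("\n".join(lines) + "\n")


def read_linkage_dataset(path, *, delimiter: str = ",") -> LinkageDataset:
    """Read a (oxo_mM, kdapp_uM[, se_uM]) table; '#' lines may carry a label."""
    path = Path(path)
    text = path.read_text()
    meta = _parse_header([ln for ln in text.splitlines() if ln.startswith("#")])
    df = pd.read_csv(_io.StringIO(text), comment="#", sep=delimiter,
                     float_precision="round_trip")
    for col in ("oxo_mM", "kdapp_uM"):
        if col not in df.columns:
            raise ValueError(f"{path.name}: missing column '{col}'")
    se = df["se_uM"].to_numpy(dtype=float) if "se_uM" in df.columns else None
    if se is not None and np.isnan(se).all():
        se = None
    return LinkageDataset.from_arrays(
        df["oxo_mM"].to_numpy(dtype=float),
        df["kdapp_uM"].to_numpy(dtype=float),
        se,
        label=meta.get("label", path.stem),
    )


def write_linkage_dataset(dataset: LinkageDataset, path, *, delimiter: str = ",") -> None:
    lines = [f"# label={dataset.label}"]
    se = dataset.se
    if se is None:
        lines.append(delimiter.join(("oxo_mM", "kdapp_uM")))
        for p in dataset.points:
            lines.append(delimiter.join((repr(p.oxo), repr(p.kdapp))))
    else:
        lines.append(delimiter.join(("oxo_mM", "kdapp_uM", "se_uM")))
        for p in dataset.points:
            lines.append(delimiter.join((repr(p.oxo), repr(p.kdapp), repr(p.se_kdapp))))
    Path(path).write_text("\n".join(lines) + "\n")
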