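"""Reading and writing localization tables.

The canonical on-disk format is a CSV/TSV file with header
``trace_id,t,x,y,z,efo,valid`` where coordinates are in nanometres,
time in seconds and EFO (effective photon frequency at offset) in Hz.
Imspector ``.mat`` exports, which store coordinates in metres, are
supported read-only.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from mfxtools import cluster as cl
from mfxtools import preprocess as pp
from mfxtools import tracking as tk
from mfxtools import trimer as tm

logger = logging.getLogger(__name__)

#: canonical column order for localization tables
COLUMNS = ["trace_id", "t", "x", "y", "z", "efo", "valid"]

_DTYPES = {
    "trace_id": np.int64,
    "t": np.float64,
    "x": np.float64,
    "y": np.float64,
    "z": np.float64,
    "efo": np.float64,
    "valid": np.bool_,
}

#: metres -> nanometres
M_TO_NM = 1e9


class SchemaError(ValueError):
    """A required column is missing or malformed."""


def validate_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check schema and basic invariants of a localization table.

    Returns the table with canonical column order and dtypes. Raises
    :class:`SchemaError` naming the first missing column. Non-monotone
    timestamps within a trace trigger a warning and a stable sort.
    """
    for col in COLUMNS:
        if col not in table.columns:
            raise SchemaError(f"missing required column: {col!r}")
    out = table[COLUMNS].astype(_DTYPES, copy=True)
    if not np.isfinite(out[["x", "y", "z"]].to_numpy()).all():
        raise SchemaError("non-finite coordinate values")
    if (out["efo"] < 0).any():
        raise SchemaError("negative efo values")
    if len(out) and (out.groupby("trace_id", sort=False)["t"].diff().dropna() < 0).any():
        warnings.warn(
            "non-monotone timestamps within a trace; applying stable sort by time",
            stacklevel=2,
        )
        out = out.sort_values(["trace_id", "t"], kind="stable").reset_index(drop=True)
    out.attrs = dict(table.attrs)
    return out


def empty_table() -> pd.DataFrame:
    return pd.DataFrame({c: pd.Series(dtype=_DTYPES[c]) for c in COLUMNS})


def read_localizations(
    path: str | Path,
    dialect: str = "csv",
    unit: str = "nm",
    drop_invalid: bool = True,
) -> pd.DataFrame:
    """Read a localization table.

    Parameters
    ----------
    path
        Input file.
    dialect
        One of ``csv``, ``tsv`` or ``imspector-mat``.
    unit
        Coordinate unit of the file: ``nm`` (canonical) or ``m``
        (converted to nm on read). Ignored for ``imspector-mat``,
        which is always in metres.
    drop_invalid
        Drop rows whose validity flag is false (the count is logged).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "csv":
        table = pd.read_csv(path)
    elif dialect == "tsv":
        table = pd.read_csv(path, sep="\t")
    elif dialect == "imspector-mat":
        table = _read_imspector_mat(path)
        unit = "nm"  # already converted
    else:
        raise ValueError(f"unknown dialect: {dialect!r}")

    table = validate_table(table)
    if unit == "m":
        table[["x", "y", "z"]] *= M_TO_NM
    elif unit != "nm":
        raise ValueError(f"unknown unit: {unit!r}")

    if drop_invalid:
        n_invalid = int((~table["valid"]).sum())
        if n_invalid:
            logger.info("dropping %d invalid-flagged localizations", n_invalid)
            table = table[table["valid"]].reset_index(drop=True)
        table.attrs["n_invalid_dropped"] = n_invalid
    return table


def _squeeze(a) -> np.ndarray:
    return np.asarray(a).squeeze()


def _read_imspector_mat(path: Path) -> pd.DataFrame:
    """Read an Imspector MAT export (coordinates in metres).

    Tolerates both struct-of-arrays and array-of-structs layouts, and
    top-level variables. Expected fields: ``loc`` (N x 3, metres),
    ``tid``, ``tim``, ``efo``, ``vld``.
    """
    from scipy.io import loadmat

    raw = loadmat(str(path), squeeze_me=True, struct_as_record=False)
    fields = {k: v for k, v in raw.items() if not k.startswith("__")}

    def extract(obj) -> dict | None:
        names = ("loc", "tid", "tim", "efo", "vld")
        if hasattr(obj, "_fieldnames") and all(n in obj._fieldnames for n in names):
            return {n: getattr(obj, n) for n in names}
        return None

    rec = None
    if all(n in fields for n in ("loc", "tid", "tim", "efo", "vld")):
        rec = {n: fields[n] for n in ("loc", "tid", "tim", "efo", "vld")}
    else:
        for v in fields.values():
            arr = np.atleast_1d(v)
            if arr.dtype == object or hasattr(v, "_fieldnames"):
                for item in arr.ravel() if arr.dtype == object else [v]:
                    rec = extract(item)
                    if rec is not None:
                        break
            if rec is not None:
                break
    if rec is None:
        raise SchemaError("missing required column: 'loc' (no recognised MAT layout)")

    loc = np.atleast_2d(_squeeze(rec["loc"]).astype(float))
    if loc.shape[1] != 3:
        loc = loc.T
    return pd.DataFrame(
        {
            "trace_id": _squeeze(rec["tid"]).astype(np.int64),
            "t": _squeeze(rec["tim"]).astype(float),
            "x": loc[:, 0] * M_TO_NM,
            "y": loc[:, 1] * M_TO_NM,
            "z": loc[:, 2] * M_TO_NM,
            "efo": _squeeze(rec["efo"]).astype(float),
            "valid": _squeeze(rec["vld"]).astype(bool),
        }
    )


@dataclasses.dataclass
class PipelineConfig:
    """All pipeline parameters, serializable to/from YAML losslessly."""

    preprocess: "pp.PreprocessParams" = dataclasses.field(default_factory=lambda: pp.PreprocessParams())
    cluster: "cl.ClusterParams" = dataclasses.field(default_factory=lambda: cl.ClusterParams())
    trimer: "tm.TrimerParams" = dataclasses.field(default_factory=lambda: tm.TrimerParams())
    tracking: "tk.TrackFilterParams" = dataclasses.field(default_factory=lambda: tk.TrackFilterParams())
    rng_seed: int = 0
    output_dir: str = "."

    def to_yaml(self, path: str | Path) -> None:
        import yaml

        def clean(obj):
            d = dataclasses.asdict(obj)
            return {k: list(v) if isinstance(v, tuple) else v for k, v in d.items()}

        payload = {
            "preprocess": clean(self.preprocess),
            "cluster": clean(self.cluster),
            "trimer": clean(self.trimer),
            "tracking": clean(self.tracking),
            "rng_seed": self.rng_seed,
            "output_dir": self.output_dir,
        }
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text())

        def tup(d, key):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(d[key])
            return d

        return cls(
            preprocess=pp.PreprocessParams(**tup(raw["preprocess"], "z_window")),
            cluster=cl.ClusterParams(**raw["cluster"]),
            trimer=tm.TrimerParams(**raw["trimer"]),
            tracking=tk.TrackFilterParams(
                **tup(tup(raw["tracking"], "micro_window"), "macro_window")
            ),
            rng_seed=raw["rng_seed"],
            output_dir=raw["output_dir"],
        )


def write_table(table: pd.DataFrame, path: str | Path, format: str = "csv") -> None:
    """Write a table in canonical column order.

    Full float precision is kept so that ``read(write(T)) == T``;
    this comfortably exceeds the 0.01 nm requirement.
    """
    path = Path(path)
    if format == "csv":
        sep = ","
    elif format == "tsv":
        sep = "\t"
    else:
        raise ValueError(f"unknown format: {format!r}")
    cols = [c for c in COLUMNS if c in table.columns]
    out = table[cols + [c for c in table.columns if c not in cols]]
    out.to_csv(path, sep=sep, index=False)
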