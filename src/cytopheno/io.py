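"""Standard-format I/O: FCS 3.1, tab-delimited tables, multi-page TIFF, config.

Feature tables travel as tab-separated text (header row, UTF-8, "." decimal)
and as FCS 3.1 list-mode files with one parameter per feature; condition
metadata (treatment, time_h, replicate) is carried in FCS keywords and as
companion delimited columns, because keyword support varies across readers.
Image events are written as one multi-page TIFF per cell (one page per
channel) plus a sidecar metadata table.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

FCS_VERSION = b"FCS3.1"
_DELIM = "/"
CHANNEL_ORDER = ("brightfield", "nuclear_stain", "tfeb", "lamp1")

REQUIRED_METADATA = ("treatment", "time_h", "replicate")


# ---------------------------------------------------------------------------
# FCS 3.1 (minimal list-mode float writer/reader)
# ---------------------------------------------------------------------------


def write_fcs(df: pd.DataFrame, path, keywords: dict | None = None) -> None:
    """Write numeric columns of ``df`` as an FCS 3.1 list-mode file.

    Data are little-endian float32 ($DATATYPE F, $MODE L); column names become
    $PnN short names.  Extra ``keywords`` are stored verbatim in the TEXT
    segment (values must not contain the delimiter '/').
    """
    numeric = df.select_dtypes(include=[np.number])
    if numeric.shape[1] == 0:
        raise ValueError("no numeric columns to write")
    data = numeric.to_numpy(dtype="<f4")
    n_events, n_par = data.shape

    kw = {
        "$BEGINANALYSIS": "0",
        "$ENDANALYSIS": "0",
        "$BEGINSTEXT": "0",
        "$ENDSTEXT": "0",
        "$BYTEORD": "1,2,3,4",
        "$DATATYPE": "F",
        "$MODE": "L",
        "$NEXTDATA": "0",
        "$PAR": str(n_par),
        "$TOT": str(n_events),
    }
    for i, name in enumerate(numeric.columns, start=1):
        kw[f"$P{i}N"] = str(name)
        kw[f"$P{i}B"] = "32"
        kw[f"$P{i}E"] = "0,0"
        col_max = float(np.nanmax(data[:, i - 1])) if n_events else 0.0
        kw[f"$P{i}R"] = str(int(max(col_max, 1)) + 1)
    for key, value in (keywords or {}).items():
        sval = str(value)
        if _DELIM in sval or _DELIM in str(key):
            raise ValueError(f"keyword {key!r} contains the delimiter {_DELIM!r}")
        kw[str(key)] = sval

    # fixed-width offsets so the TEXT length is stable across the two passes
    text_start = 256
    placeholder = {"$BEGINDATA": "0" * 12, "$ENDDATA": "0" * 12}
    body = _DELIM + _DELIM.join(
        f"{k}{_DELIM}{v}" for k, v in {**kw, **placeholder}.items()
    ) + _DELIM
    text_end = text_start + len(body) - 1
    data_start = text_end + 1
    data_end = data_start + data.nbytes - 1
    filled = {"$BEGINDATA": str(data_start).rjust(12, "0"),
              "$ENDDATA": str(data_end).rjust(12, "0")}
    body = _DELIM + _DELIM.join(
        f"{k}{_DELIM}{v}" for k, v in {**kw, **filled}.items()
    ) + _DELIM
    assert text_start + len(body) - 1 == text_end

    header = FCS_VERSION + b"    "
    for lo, hi in ((text_start, text_end), (data_start, data_end), (0, 0)):
        header += f"{lo:>8d}".encode() + f"{hi:>8d}".encode()
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(b" " * (text_start - len(header)))
        fh.write(body.encode("ascii"))
        fh.write(data.tobytes())


def read_fcs(path):
    """Read an FCS 3.0/3.1 list-mode file -> (DataFrame, keywords dict).

    Supports float32/float64 data ($DATATYPE F/D) in either byte order.
    """
    raw = Path(path).read_bytes()
    if not raw[:3] == b"FCS":
        raise ValueError(f"{path}: not an FCS file (bad magic at offset 0)")
    try:
        text_start = int(raw[10:18])
        text_end = int(raw[18:26])
    except ValueError as exc:
        raise ValueError(f"{path}: malformed header offsets at bytes 10-26") from exc
    text = raw[text_start:text_end + 1].decode("ascii", errors="replace")
    delim = text[0]
    parts = text.strip(delim).split(delim)
    if len(parts) % 2:
        raise ValueError(
            f"{path}: odd keyword/value count in TEXT segment at offset {text_start}"
        )
    kw = dict(zip(parts[::2], parts[1::2]))

    data_start = int(kw.get("$BEGINDATA") or raw[26:34])
    data_end = int(kw.get("$ENDDATA") or raw[34:42])
    n_par = int(kw["$PAR"])
    n_tot = int(kw["$TOT"])
    dtype_char = kw.get("$DATATYPE", "F")
    byteord = kw.get("$BYTEORD", "1,2,3,4")
    endian = "<" if byteord.startswith("1") else ">"
    np_dtype = {"F": "f4", "D": "f8"}.get(dtype_char)
    if np_dtype is None:
        raise ValueError(f"{path}: unsupported $DATATYPE {dtype_char!r}")
    blob = raw[data_start:data_end + 1]
    expected = n_par * n_tot * int(np_dtype[1])
    if len(blob) < expected:
        raise ValueError(
            f"{path}: DATA segment truncated at offset {data_start + len(blob)} "
            f"(expected {expected} bytes)"
        )
    arr = np.frombuffer(blob[:expected], dtype=endian + np_dtype)
    arr = arr.reshape(n_tot, n_par)
    names = [kw.get(f"$P{i}N", f"P{i}") for i in range(1, n_par + 1)]
    return pd.DataFrame(arr, columns=names), kw


# ---------------------------------------------------------------------------
# Delimited feature tables
# ---------------------------------------------------------------------------


def write_table(df: pd.DataFrame, path) -> None:
    """Tab-separated text with a header row."""
    df.to_csv(path, sep="\t", index=False)


def read_feature_table(path, fmt: str = "auto",
                       require_metadata: bool = True) -> pd.DataFrame:
    """Read a per-event feature table from delimited text or FCS.

    Checks that the condition metadata columns are present (unless
    ``require_metadata`` is False) and that feature values are finite.
    """
    path = Path(path)
    if fmt == "auto":
        fmt = "fcs" if path.suffix.lower() == ".fcs" else "delimited"
    if fmt == "fcs":
        df, kw = read_fcs(path)
        for key in REQUIRED_METADATA:
            upper = key.upper()
            if key not in df.columns and upper in kw:
                df[key] = _coerce(kw[upper])
    elif fmt == "delimited":
        df = pd.read_csv(path, sep="\t")
    else:
        raise ValueError(f"unknown format {fmt!r} (use 'fcs' or 'delimited')")

    if require_metadata:
        missing = [c for c in REQUIRED_METADATA if c not in df.columns]
        if missing:
            raise ValueError(f"{path}: missing metadata column(s): {missing}")
    numeric = df.select_dtypes(include=[np.number])
    bad_cols = [c for c in numeric.columns
                if not np.isfinite(numeric[c].to_numpy()).all()]
    if bad_cols:
        raise ValueError(f"{path}: non-finite values in column(s): {bad_cols}")
    return df


def _coerce(value: str):
    for cast in (int, float):
        try:
            return cast(value)
        except ValueError:
            continue
    return value


# ---------------------------------------------------------------------------
# Image stacks
# ---------------------------------------------------------------------------


def write_cell_images(images: list, outdir) -> Path:
    """One multi-page TIFF per event (page order: brightfield, nuclear stain,
    TFEB, LAMP1) plus a sidecar ``metadata.tsv``."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, img in enumerate(images):
        stack = np.stack([img.channel(name).astype(np.float32)
                          for name in CHANNEL_ORDER])
        fname = f"event_{i:05d}.tif"
        tifffile.imwrite(out / fname, stack, photometric="minisblack")
        rows.append({
            "file": fname,
            "cell_id": img.cell_id,
            "treatment": img.treatment,
            "time_h": img.time_h,
            "replicate": img.replicate,
            "pixel_size_um": img.pixel_size_um,
        })
    write_table(pd.DataFrame(rows), out / "metadata.tsv")
    return out


def read_cell_images(indir) -> list:
    """Read back an image directory written by :func:`write_cell_images`."""
    from .features import CellImage

    indir = Path(indir)
    meta = pd.read_csv(indir / "metadata.tsv", sep="\t")
    images = []
    for _, row in meta.iterrows():
        stack = tifffile.imread(indir / row["file"])
        channels = {name: np.asarray(stack[i], dtype=float)
                    for i, name in enumerate(CHANNEL_ORDER)}
        images.append(CellImage(
            channels=channels,
            pixel_size_um=float(row["pixel_size_um"]),
            cell_id=str(row["cell_id"]),
            treatment=str(row["treatment"]),
            time_h=float(row["time_h"]),
            replicate=int(row["replicate"]),
        ))
    return images


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """End-to-end pipeline configuration (see docs/methods.md for parameter
    meaning and defaults)."""

    seed: int = 1
    profile: str = "default"  # "default" (10000 cells/condition) or "fast" (2000)
    training_treatments: tuple = ("FM", "Torin1")
    feature_combos: tuple = (
        ("mean_pixel_nuc_cyto",),
        ("mean_pixel_nuc_cyto", "concentration_cell"),
    )
    k_values: tuple = (2, 3, 4)
    ranking_feature: str = "mean_pixel_nuc_cyto"
    arcsinh_cofactor: float = 5.0
    neighborhood_size: float = 5.0
    density_approx_factor: float = 1.5
    max_pooled: int = 50000
    target_remaining: int = 20000
    n_restarts: int = 10
    c1_threshold: float = 0.10
    c2_r_threshold: float = 0.9
    separation_p: float = 1e-3
    erosion_px: int = 2
    n_rings: int = 8
    pixel_size_um: float = 0.5

    def to_yaml(self, path) -> None:
        data = asdict(self)
        data["training_treatments"] = list(self.training_treatments)
        data["feature_combos"] = [list(c) for c in self.feature_combos]
        data["k_values"] = list(self.k_values)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        if not isinstance(data, dict):
            raise ValueError(f"{path}: expected a mapping at top level")
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"{path}: unknown config key(s): {sorted(unknown)}")
        if "training_treatments" in data:
            data["training_treatments"] = tuple(data["training_treatments"])
        if "feature_combos" in data:
            data["feature_combos"] = tuple(tuple(c) for c in data["feature_combos"])
        if "k_values" in data:
            data["k_values"] = tuple(int(k) for k in data["k_values"])
        return cls(**data)

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=list)
        return hashlib.sha256(blob.encode("utf-8")).hexdigest()[:16]
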