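"""Readers, writers, alignment and configuration plumbing.

All tabular formats are delimited text with a header row (TSV by default,
sniffed from the file extension).  The 10x Visium ``tissue_positions_list.csv``
convention is supported for coordinates.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .types import EmbeddingMatrix, LabelVector, MpMimConfig, SpotCoordinates

logger = logging.getLogger("mpmim")

__all__ = [
    "read_embedding",
    "write_embedding",
    "read_coordinates",
    "write_coordinates",
    "read_labels",
    "write_labels",
    "align",
    "read_config",
    "write_config",
]

#: columns of the (header-less) 10x tissue_positions_list.csv file
_VISIUM_COLUMNS = [
    "barcode",
    "in_tissue",
    "array_row",
    "array_col",
    "pixel_row",
    "pixel_col",
]


def _sep_for(path: str | Path) -> str:
    return "," if str(path).endswith(".csv") else "\t"


def read_embedding(path: str | Path, id_column: str | None = None) -> EmbeddingMatrix:
    """Read a spots x dimensions embedding from delimited text.

    The first column is taken as the spot identifier unless ``id_column``
    names another one.  All remaining columns are coerced to float; a
    non-numeric cell is an error identifying its row and column.
    """
    df = pd.read_csv(path, sep=_sep_for(path))
    if df.shape[1] < 2:
        raise ValueError(f"{path}: need an id column plus >=1 numeric column")
    idc = id_column if id_column is not None else df.columns[0]
    if idc not in df.columns:
        raise ValueError(f"{path}: id column {idc!r} not found")
    ids = df[idc].astype(str).tolist()
    dup = df[idc][df[idc].duplicated()].astype(str).unique().tolist()
    if dup:
        raise ValueError(f"{path}: duplicate spot ids {dup}")
    value_df = df.drop(columns=[idc])
    values = np.empty(value_df.shape, dtype=float)
    for j, col in enumerate(value_df.columns):
        coerced = pd.to_numeric(value_df[col], errors="coerce")
        bad = coerced.isna() & value_df[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValueError(
                f"{path}: non-numeric value {value_df[col].iloc[row]!r} "
                f"at row {row} column {col!r}"
            )
        if coerced.isna().any():
            row = int(np.flatnonzero(coerced.isna().to_numpy())[0])
            raise ValueError(f"{path}: missing value at row {row} column {col!r}")
        values[:, j] = coerced.to_numpy(dtype=float)
    return EmbeddingMatrix(tuple(ids), values, name=Path(path).stem)


def write_embedding(emb: EmbeddingMatrix, path: str | Path, id_column: str = "spot_id") -> None:
    df = pd.DataFrame(emb.values, columns=[f"dim{j}" for j in range(emb.n_dims)])
    df.insert(0, id_column, list(emb.spot_ids))
    df.to_csv(path, sep=_sep_for(path), index=False, float_format="%.17g")


def read_coordinates(path: str | Path, dialect: str = "generic") -> SpotCoordinates:
    """Read spot coordinates.

    ``generic``: header with id, x, y (first three columns).
    ``visium_positions``: header-less 10x ``tissue_positions_list.csv``
    (barcode, in_tissue, array_row, array_col, pixel_row, pixel_col);
    only ``in_tissue == 1`` rows are kept and array coordinates are used.
    """
    if dialect == "generic":
        df = pd.read_csv(path, sep=_sep_for(path))
        if df.shape[1] < 3:
            raise ValueError(f"{path}: generic dialect needs id,x,y columns")
        ids = df.iloc[:, 0].astype(str).tolist()
        xy = df.iloc[:, 1:3].to_numpy(dtype=float)
    elif dialect == "visium_positions":
        df = pd.read_csv(path, sep=",", header=None)
        if df.shape[1] < len(_VISIUM_COLUMNS):
            raise ValueError(
                f"{path}: visium_positions dialect needs {len(_VISIUM_COLUMNS)} columns, "
                f"got {df.shape[1]}"
            )
        df.columns = _VISIUM_COLUMNS + [f"extra{i}" for i in range(df.shape[1] - 6)]
        kept = df[df["in_tissue"].astype(int) == 1]
        n_dropped = len(df) - len(kept)
        if n_dropped:
            logger.info("dropped %d out-of-tissue barcodes", n_dropped)
        ids = kept["barcode"].astype(str).tolist()
        xy = kept[["array_row", "array_col"]].to_numpy(dtype=float)
    else:
        raise ValueError(f"unknown coordinates dialect {dialect!r}")
    return SpotCoordinates(tuple(ids), xy)


def write_coordinates(coords: SpotCoordinates, path: str | Path) -> None:
    df = pd.DataFrame({"spot_id": list(coords.spot_ids)})
    df["x"] = coords.xy[:, 0]
    df["y"] = coords.xy[:, 1]
    df.to_csv(path, sep=_sep_for(path), index=False, float_format="%.17g")


def read_labels(path: str | Path) -> LabelVector:
    df = pd.read_csv(path, sep=_sep_for(path))
    if df.shape[1] < 2:
        raise ValueError(f"{path}: labels need id and annotation columns")
    return LabelVector(
        tuple(df.iloc[:, 0].astype(str)), tuple(df.iloc[:, 1].astype(str))
    )


def write_labels(labels: LabelVector, path: str | Path) -> None:
    pd.DataFrame(
        {"spot_id": list(labels.spot_ids), "label": list(labels.labels)}
    ).to_csv(path, sep=_sep_for(path), index=False)


def align(
    emb: EmbeddingMatrix,
    coords: SpotCoordinates,
    labels: LabelVector | None = None,
) -> tuple[EmbeddingMatrix, SpotCoordinates, LabelVector | None]:
    """Restrict all inputs to the common spot set, ordered as in ``emb``.

    Embedding row order is canonical: coordinates (and labels, if given) are
    reordered to it.  Spots absent from the coordinates are dropped from the
    embedding (logged).  Labels may cover a subset; missing labels surface
    only when evaluation asks for them.
    """
    coord_index = {s: i for i, s in enumerate(coords.spot_ids)}
    keep = [s for s in emb.spot_ids if s in coord_index]
    if not keep:
        raise ValueError("embedding and coordinates share no spot ids")
    n_dropped = emb.n_spots - len(keep)
    if n_dropped:
        logger.info("alignment dropped %d embedding spots without coordinates", n_dropped)
    if len(keep) < emb.n_spots:
        rows = [i for i, s in enumerate(emb.spot_ids) if s in coord_index]
        emb = EmbeddingMatrix(tuple(keep), emb.values[rows], emb.name)
    aligned_coords = SpotCoordinates(
        tuple(keep), coords.xy[[coord_index[s] for s in keep]]
    )
    aligned_labels: LabelVector | None = None
    if labels is not None:
        label_map = dict(zip(labels.spot_ids, labels.labels))
        sub_ids = [s for s in keep if s in label_map]
        aligned_labels = LabelVector(
            tuple(sub_ids), tuple(label_map[s] for s in sub_ids)
        )
    return emb, aligned_coords, aligned_labels


def read_config(path: str | Path) -> MpMimConfig:
    """Read a ``key=value`` config file mirroring :class:`MpMimConfig`."""
    kw: dict = {}
    fields = {f.name: f for f in dataclasses.fields(MpMimConfig)}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected key=value, got {line!r}")
        key, _, raw = line.partition("=")
        key, raw = key.strip(), raw.strip()
        if key not in fields:
            raise ValueError(f"{path}:{lineno}: unknown config key {key!r}")
        kw[key] = _coerce_config_value(key, raw)
    return MpMimConfig(**kw)


def _coerce_config_value(key: str, raw: str):
    if key in ("k_num", "l_num", "knn_w", "seed"):
        return int(raw)
    if key in ("include_self", "prune"):
        return raw.lower() in ("1", "true", "yes")
    if key == "overflow_guard":
        return float(raw)
    if key == "radius":
        return raw if raw == "auto" else float(raw)
    return raw


def write_config(cfg: MpMimConfig, path: str | Path) -> None:
    lines = [f"{f.name}={getattr(cfg, f.name)}" for f in dataclasses.fields(MpMimConfig)]
    Path(path).write_text("\n".join(lines) + "\n")
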