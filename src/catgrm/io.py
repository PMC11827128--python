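"""File formats and run configuration.

Response CSV: first column respondent id, remaining columns one item
each, integer categories 1..K, blank cells are missing. Metadata CSV is
keyed by respondent id with an optional ``group`` column plus any number
of external score columns. Item banks are JSON (see :mod:`catgrm.grm`).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
import yaml

from .screening import ResponseMatrix


@dataclass
class RunConfig:
    """All pipeline cutoffs, defaulting to the method's standard cutoffs."""

    item_remainder: float = 0.3
    pca_first_proportion: float = 0.20
    pca_ratio: float = 4.0
    residual_correlation: float = 0.2
    scalability: float = 0.3
    item_fit_alpha: float = 0.01
    dif_alpha: float = 0.01
    sem_threshold: float = 0.32
    min_items: int = 3
    max_items: int | None = None
    seed: int = 0
    em_tol: float = 1e-4
    em_max_iter: int = 500
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("item_remainder", "pca_first_proportion", "pca_ratio",
                     "residual_correlation", "scalability", "sem_threshold"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("item_fit_alpha", "dif_alpha"):
            if not 0 < getattr(self, name) < 1:
                raise ValueError(f"{name} must be in (0, 1)")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__ if f != "extra"}
        kwargs = {k: v for k, v in payload.items() if k in known}
        extra = {k: v for k, v in payload.items() if k not in known}
        return cls(**kwargs, extra=extra)

    def to_dict(self) -> dict:
        return asdict(self)


def read_response_csv(path, n_categories: int = 5) -> ResponseMatrix:
    """Parse a response CSV, rejecting out-of-range or non-integer cells."""
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    if frame.shape[1] < 2:
        raise ValueError(f"{path}: need a respondent-id column plus at least one item")
    respondent_ids = frame.iloc[:, 0].astype(str).tolist()
    item_ids = list(frame.columns[1:])
    values = np.full((len(frame), len(item_ids)), np.nan)
    for j, col in enumerate(item_ids):
        for i, raw in enumerate(frame[col]):
            raw = raw.strip()
            if raw in ("", "NA", "na", "NaN"):
                continue
            try:
                v = int(raw)
            except ValueError as exc:
                raise ValueError(f"{path}: non-integer value {raw!r} at row {i + 2}, column {col!r}") from exc
            if not 1 <= v <= n_categories:
                raise ValueError(f"{path}: value {v} outside 1..{n_categories} at row {i + 2}, column {col!r}")
            values[i, j] = v
    return ResponseMatrix(values, tuple(item_ids), tuple(respondent_ids), n_categories)


def write_response_csv(data: ResponseMatrix, path) -> None:
    frame = data.to_frame()
    out = frame.map(lambda v: "" if np.isnan(v) else str(int(v)))
    out.index.name = "respondent_id"
    out.to_csv(path)


def attach_metadata(data: ResponseMatrix, path) -> ResponseMatrix:
    """Join a metadata CSV (group + external score columns) by respondent id."""
    meta = pd.read_csv(path)
    key = meta.columns[0]
    meta = meta.set_index(meta[key].astype(str)).drop(columns=[key])
    missing = [r for r in data.respondent_ids if r not in meta.index]
    if missing:
        raise ValueError(f"metadata missing respondents: {missing[:5]}")
    meta = meta.loc[list(data.respondent_ids)]
    group = meta["group"].to_numpy() if "group" in meta.columns else None
    score_cols = [c for c in meta.columns if c != "group"]
    external = meta[score_cols].reset_index(drop=True).astype(float) if score_cols else None
    from dataclasses import replace

    return replace(data, group=group, external_scores=external)


def write_metadata_csv(data: ResponseMatrix, path) -> None:
    frame = pd.DataFrame(index=pd.Index(list(data.respondent_ids), name="respondent_id"))
    if data.group is not None:
        frame["group"] = data.group
    if data.external_scores is not None:
        for col in data.external_scores.columns:
            frame[col] = data.external_scores[col].to_numpy()
    frame.to_csv(path)


def write_json(payload: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, default=_default)


def _default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, pd.DataFrame):
        return json.loads(obj.to_json(orient="index"))
    raise TypeError(f"not JSON serializable: {type(obj)}")
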