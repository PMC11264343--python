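"""Consecutive disparity index for interannual seed-crop series.

Mast seeding — highly variable, intermittent seed production — is summarised
per species by the consecutive disparity index

    D = (1/(n-1)) * sum_{i=1}^{n-1} | ln( (p_{i+1} + k) / (p_i + k) ) |

where p_1..p_n are annual seed or fruit crops and k is a pseudo-count
(default 1) that keeps zero crops in the domain of the logarithm. D captures
both the temporal variability of a series and its lag-1 structure: a
constant series has D = 0, and alternation between boom and bust years
drives D up faster than slow drifts of the same amplitude.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import InvalidInputError

__all__ = [
    "SeedCropSeries",
    "DisparityResult",
    "consecutive_disparity",
    "log10_transform",
    "screen_series",
    "read_series_csv",
    "disparity_table",
]


@dataclass(frozen=True)
class SeedCropSeries:
    """One species' ordered annual seed/fruit production record."""

    species_id: str
    values: tuple

    def __post_init__(self):
        vals = tuple(float(v) for v in self.values)
        if len(vals) < 2:
            raise InvalidInputError(
                f"{self.species_id}: series needs >= 2 observations, got {len(vals)}")
        if any(not math.isfinite(v) for v in vals):
            raise InvalidInputError(f"{self.species_id}: non-finite value in series "
                                    "(missing years must be resolved upstream)")
        if any(v < 0 for v in vals):
            raise InvalidInputError(f"{self.species_id}: negative production value")
        object.__setattr__(self, "values", vals)

    @property
    def n(self) -> int:
        return len(self.values)

    def is_constant(self) -> bool:
        return len(set(self.values)) == 1


@dataclass(frozen=True)
class DisparityResult:
    species_id: str
    D: float
    k: float
    n_used: int
    flags: tuple = field(default_factory=tuple)


def consecutive_disparity(series: SeedCropSeries, k: float = 1.0) -> DisparityResult:
    """Consecutive disparity index D of one series.

    ``k`` must be positive, or zero only when every observation is strictly
    positive (with ``k = 0`` the index is exactly scale invariant).
    Constant series give D = 0 with a ``zero-variance`` flag.
    """
    if k < 0:
        raise InvalidInputError(f"{series.species_id}: k must be non-negative")
    p = np.asarray(series.values)
    if k == 0 and np.any(p == 0):
        raise InvalidInputError(
            f"{series.species_id}: k=0 requires strictly positive crops (invalid-k)")
    shifted = p + k
    d = float(np.mean(np.abs(np.log(shifted[1:] / shifted[:-1]))))
    flags = ("zero-variance",) if series.is_constant() else ()
    if flags:
        warnings.warn(f"{series.species_id}: constant series, D = 0", stacklevel=2)
    return DisparityResult(series.species_id, D=d, k=float(k),
                           n_used=series.n, flags=flags)


def log10_transform(values, labels: Sequence[str] | None = None) -> np.ndarray:
    """Base-10 logarithm used to correct trait skewness before analysis.

    Raises with the offending label when a value is not strictly positive.
    """
    arr = np.asarray(values, dtype=float)
    bad = np.where(~(arr > 0))[0]
    if bad.size:
        who = [labels[i] if labels is not None else int(i) for i in bad[:10]]
        raise InvalidInputError(f"log10 requires positive values; offending: {who}")
    return np.log10(arr)


def screen_series(series_set: Iterable[SeedCropSeries], min_length: int = 2):
    """Filter a collection of series before computing D.

    Drops series shorter than ``min_length`` (monocarpic species — a single
    fruiting record — are the motivating case). Series with fewer than two
    distinct observations are retained but flagged ``zero-variance``.

    Returns
    -------
    (retained, exclusion_log) : (list[SeedCropSeries], pandas.DataFrame)
        The log has columns ``species``, ``reason``; retained-but-flagged
        series also appear there with reason ``zero-variance``.
    """
    retained, log_rows = [], []
    n_in = 0
    for s in series_set:
        n_in += 1
        if s.n < min_length:
            log_rows.append({"species": s.species_id, "reason": "too-short",
                             "retained": False})
            continue
        if s.is_constant():
            log_rows.append({"species": s.species_id, "reason": "zero-variance",
                             "retained": True})
        retained.append(s)
    if n_in == 0:
        warnings.warn("screen_series received an empty series set", stacklevel=2)
    log = pd.DataFrame(log_rows, columns=["species", "reason", "retained"])
    return retained, log


def read_series_csv(path) -> list:
    """Read seed-crop series from CSV.

    Long format needs columns ``species``, ``year``, ``crop``; any other
    header is interpreted as wide format (one row per species, first column
    the species name, remaining columns years). Gaps (NaN) inside a series
    are a hard error — no imputation rule is defined for masting records.
    """
    df = pd.read_csv(path)
    cols = {c.lower(): c for c in df.columns}
    out = []
    if {"species", "year", "crop"} <= set(cols):
        df = df.rename(columns={cols["species"]: "species", cols["year"]: "year",
                                cols["crop"]: "crop"})
        for sp, grp in df.groupby("species", sort=True):
            grp = grp.sort_values("year")
            years = grp["year"].to_numpy()
            if len(years) > 1 and np.any(np.diff(years) != 1):
                raise InvalidInputError(f"{sp}: missing years inside series "
                                        f"({years.min()}..{years.max()})")
            if grp["crop"].isna().any():
                raise InvalidInputError(f"{sp}: missing crop values in series")
            out.append(SeedCropSeries(str(sp), tuple(grp["crop"])))
    else:
        first = df.columns[0]
        for _, row in df.iterrows():
            vals = row.drop(first).astype(float)
            if vals.isna().any():
                raise InvalidInputError(f"{row[first]}: missing crop values in series")
            out.append(SeedCropSeries(str(row[first]), tuple(vals)))
    return out


def disparity_table(series_set: Iterable[SeedCropSeries], k: float = 1.0,
                    min_length: int = 2) -> pd.DataFrame:
    """Screen series and compute D for the survivors.

    Returns a DataFrame with columns ``species``, ``n_used``, ``D``,
    ``flags`` (semicolon-joined), sorted by species.
    """
    retained, _log = screen_series(series_set, min_length=min_length)
    rows = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # zero-variance already logged by screen
        for s in retained:
            r = consecutive_disparity(s, k=k)
            rows.append({"species": r.species_id, "n_used": r.n_used, "D": r.D,
                         "flags": ";".join(r.flags)})
    return pd.DataFrame(rows, columns=["species", "n_used", "D", "flags"]) \
             .sort_values("species").reset_index(drop=True)
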