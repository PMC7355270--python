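"""Twin-pair records and conversions between record and wide-frame form.

The canonical in-memory container is a wide pandas DataFrame (one row per
pair: ``pair_id, zygosity, sex1, sex2, same_teacher, <pheno>_1, <pheno>_2``
with NaN for missing scores).  :class:`TwinPairRecord` is the per-pair view
used by the casewise likelihood and the CSV readers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["TwinPairRecord", "frame_to_records", "records_to_frame", "phenotypes_of"]


@dataclass
class TwinPairRecord:
    """One twin pair: design variables plus two phenotype vectors (NaN = missing)."""

    pair_id: object
    zygosity: str
    sex1: int
    sex2: int
    same_teacher: bool
    y1: np.ndarray
    y2: np.ndarray

    def __post_init__(self) -> None:
        self.y1 = np.asarray(self.y1, dtype=float).ravel()
        self.y2 = np.asarray(self.y2, dtype=float).ravel()
        if self.y1.shape != self.y2.shape:
            raise ValueError("y1 and y2 must have the same length")
        self.zygosity = str(self.zygosity).upper()
        if self.zygosity not in ("MZ", "DZ"):
            raise ValueError(f"unknown zygosity {self.zygosity!r}")

    @property
    def y(self) -> np.ndarray:
        """Stacked 2M phenotype vector (twin 1 first)."""
        return np.concatenate([self.y1, self.y2])

    @property
    def n_observed(self) -> int:
        return int(np.sum(~np.isnan(self.y)))


def phenotypes_of(data: pd.DataFrame) -> tuple[str, ...]:
    """Phenotype labels inferred from paired ``<name>_1`` / ``<name>_2`` columns."""
    ones = [c[:-2] for c in data.columns if c.endswith("_1") and c != "sex_1"]
    return tuple(p for p in ones if f"{p}_2" in data.columns)


def frame_to_records(
    data: pd.DataFrame, phenotypes: tuple[str, ...] | None = None
) -> list[TwinPairRecord]:
    if phenotypes is None:
        phenotypes = phenotypes_of(data)
    c1 = [f"{p}_1" for p in phenotypes]
    c2 = [f"{p}_2" for p in phenotypes]
    y1 = data[c1].to_numpy(dtype=float)
    y2 = data[c2].to_numpy(dtype=float)
    st = data["same_teacher"].to_numpy().astype(bool) if "same_teacher" in data else np.zeros(len(data), bool)
    return [
        TwinPairRecord(
            pair_id=row.pair_id,
            zygosity=row.zygosity,
            sex1=int(row.sex1),
            sex2=int(row.sex2),
            same_teacher=bool(st[i]),
            y1=y1[i],
            y2=y2[i],
        )
        for i, row in enumerate(data.itertuples(index=False))
    ]


def records_to_frame(
    records: list[TwinPairRecord], phenotypes: tuple[str, ...]
) -> pd.DataFrame:
    rows = {
        "pair_id": [r.pair_id for r in records],
        "zygosity": [r.zygosity for r in records],
        "sex1": [r.sex1 for r in records],
        "sex2": [r.sex2 for r in records],
        "same_teacher": [r.same_teacher for r in records],
    }
    y1 = np.array([r.y1 for r in records]) if records else np.empty((0, len(phenotypes)))
    y2 = np.array([r.y2 for r in records]) if records else np.empty((0, len(phenotypes)))
    for j, p in enumerate(phenotypes):
        rows[f"{p}_1"] = y1[:, j]
        rows[f"{p}_2"] = y2[:, j]
    return pd.DataFrame(rows)
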