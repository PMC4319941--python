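"""Presence/absence matrix analytics: pan/core accumulation curves and power fits.

The accumulation curve averages pan (running union) and core (running
intersection) sizes over random genome orderings; with six or fewer genomes
all orderings are enumerated exactly.  The mean marginal pan-genome gain per
added genome is reported alongside.  Curves are summarised by least-squares
power-function fits on the log-log scale.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .io import InvalidInputError


class PresenceAbsenceMatrix:
    """Boolean families-by-genomes matrix.

    Rows are family ids, columns genome ids; every family must be present in
    at least one genome and ids must be unique.
    """

    def __init__(self, data: pd.DataFrame):
        if data.index.has_duplicates or data.columns.has_duplicates:
            raise InvalidInputError("duplicate family or genome ids")
        values = data.astype(bool)
        if len(values) and not values.any(axis=1).all():
            missing = values.index[~values.any(axis=1)].tolist()
            raise InvalidInputError(f"families present in no genome: {missing[:5]}")
        self._df = values

    @property
    def df(self) -> pd.DataFrame:
        return self._df

    @property
    def family_ids(self) -> list[str]:
        return list(self._df.index)

    @property
    def genome_ids(self) -> list[str]:
        return list(self._df.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self._df.shape

    def families_of(self, genome_id: str) -> set[str]:
        if genome_id not in self._df.columns:
            raise InvalidInputError(f"unknown genome id {genome_id!r}")
        col = self._df[genome_id]
        return set(col.index[col])

    def subset(self, genome_ids: Sequence[str]) -> "PresenceAbsenceMatrix":
        unknown = [g for g in genome_ids if g not in self._df.columns]
        if unknown:
            raise InvalidInputError(f"unknown genome ids: {unknown}")
        sub = self._df[list(genome_ids)]
        return PresenceAbsenceMatrix(sub[sub.any(axis=1)])

    @classmethod
    def from_sets(cls, family_sets: dict[str, set[str]]) -> "PresenceAbsenceMatrix":
        """Build from ``{genome_id: set of family ids}``."""
        families = sorted(set().union(*family_sets.values())) if family_sets else []
        data = {
            g: [f in fams for f in families]
            for g, fams in sorted(family_sets.items())
        }
        return cls(pd.DataFrame(data, index=families))

    def to_tsv(self, path: str | Path) -> None:
        out = self._df.astype(int)
        out.index.name = "family_id"
        out.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "PresenceAbsenceMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(df.astype(bool))


@dataclass
class AccumulationCurve:
    n: np.ndarray                 # genome counts 1..N
    pan_mean: np.ndarray
    core_mean: np.ndarray
    pan_traces: np.ndarray        # (orderings, N)
    core_traces: np.ndarray
    new_per_genome_mean: float
    exhaustive: bool


def _curve_for_order(values: np.ndarray, order: Sequence[int]) -> tuple[np.ndarray, np.ndarray]:
    pan = np.zeros(len(order), dtype=np.int64)
    core = np.zeros(len(order), dtype=np.int64)
    union = np.zeros(values.shape[0], dtype=bool)
    inter = np.ones(values.shape[0], dtype=bool)
    for i, g in enumerate(order):
        union |= values[:, g]
        inter &= values[:, g]
        pan[i] = union.sum()
        core[i] = inter.sum()
    return pan, core


def accumulation_curves(
    matrix: PresenceAbsenceMatrix,
    n_permutations: int = 100,
    seed: int = 0,
    exhaustive_limit: int = 6,
) -> AccumulationCurve:
    """Pan/core accumulation averaged over genome orderings.

    Enumerates all orderings exactly when the genome count is at most
    ``exhaustive_limit``; otherwise averages over ``n_permutations`` seeded
    random orderings.
    """
    n_genomes = matrix.shape[1]
    if n_genomes < 2:
        raise InvalidInputError("need at least 2 genomes")
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    values = matrix.df.to_numpy()
    if n_genomes <= exhaustive_limit:
        orders: Iterable[Sequence[int]] = itertools.permutations(range(n_genomes))
        exhaustive = True
    else:
        rng = np.random.default_rng(seed)
        orders = [rng.permutation(n_genomes) for _ in range(n_permutations)]
        exhaustive = False
    pan_rows, core_rows = [], []
    for order in orders:
        pan, core = _curve_for_order(values, order)
        pan_rows.append(pan)
        core_rows.append(core)
    pan_traces = np.array(pan_rows)
    core_traces = np.array(core_rows)
    gains = (pan_traces[:, -1] - pan_traces[:, 0]) / (n_genomes - 1)
    return AccumulationCurve(
        n=np.arange(1, n_genomes + 1),
        pan_mean=pan_traces.mean(axis=0),
        core_mean=core_traces.mean(axis=0),
        pan_traces=pan_traces,
        core_traces=core_traces,
        new_per_genome_mean=float(gains.mean()),
        exhaustive=exhaustive,
    )


def core_families(
    matrix: PresenceAbsenceMatrix,
    genome_subset: Optional[Sequence[str]] = None,
) -> set[str]:
    """Families present in every genome of the subset (default: all genomes)."""
    subset = list(genome_subset) if genome_subset is not None else matrix.genome_ids
    if not subset:
        raise InvalidInputError("genome subset is empty")
    unknown = [g for g in subset if g not in matrix.df.columns]
    if unknown:
        raise InvalidInputError(f"unknown genome ids: {unknown}")
    mask = matrix.df[subset].all(axis=1)
    return set(matrix.df.index[mask])


def pan_families(
    matrix: PresenceAbsenceMatrix,
    genome_subset: Optional[Sequence[str]] = None,
) -> set[str]:
    """Families present in at least one genome of the subset."""
    subset = list(genome_subset) if genome_subset is not None else matrix.genome_ids
    if not subset:
        raise InvalidInputError("genome subset is empty")
    mask = matrix.df[subset].any(axis=1)
    return set(matrix.df.index[mask])


@dataclass
class PowerFitParams:
    """Parameters of ``y = kappa * n**gamma`` fitted by log-log least squares."""

    kappa: float
    gamma: float
    fit_rmse: float


def fit_power(n: Sequence[float], y: Sequence[float]) -> PowerFitParams:
    n_arr = np.asarray(n, dtype=float)
    y_arr = np.asarray(y, dtype=float)
    if n_arr.size < 3:
        raise ValueError("need at least 3 points")
    if np.any(y_arr <= 0) or np.any(n_arr < 1):
        raise ValueError("all y must be > 0 and n >= 1")
    gamma, log_kappa = np.polyfit(np.log(n_arr), np.log(y_arr), 1)
    kappa = math.exp(log_kappa)
    resid = y_arr - kappa * n_arr**gamma
    return PowerFitParams(kappa=float(kappa), gamma=float(gamma),
                          fit_rmse=float(np.sqrt(np.mean(resid**2))))


def curve_to_frame(curve: AccumulationCurve) -> pd.DataFrame:
    return pd.DataFrame(
        {"n": curve.n, "pan_mean": curve.pan_mean, "core_mean": curve.core_mean}
    )
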