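"""Shared conventions for the tabular containers used across the package.

A *sample table* is a :class:`pandas.DataFrame` with one row per measured
solution and columns::

    sample_id     unique string identifier
    sequence_id   addition sequence / run the sample belongs to
    c_<ion>       concentration of each declared ion in mol/L
    role          train | test | application | calibration | selectivity |
                  unassigned

A *potential matrix* is a DataFrame indexed by ``sample_id`` with one column
per sensor id, values in mV.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .activity import IonSpec
from .errors import InputError

ROLES = ("train", "test", "application", "calibration", "selectivity", "unassigned")


def conc_column(ion: IonSpec | str) -> str:
    name = ion.name if isinstance(ion, IonSpec) else ion
    return f"c_{name}"


def concentration_matrix(table: pd.DataFrame, ions: Sequence[IonSpec]) -> np.ndarray:
    """Extract an (n_samples, n_ions) concentration array in mol/L."""
    cols = []
    for ion in ions:
        col = conc_column(ion)
        if col not in table.columns:
            raise InputError(f"sample table lacks column {col!r} for ion {ion.name!r}")
        cols.append(col)
    return table[cols].to_numpy(dtype=float)


def make_sample_table(
    ions: Sequence[IonSpec],
    concentrations: np.ndarray,
    *,
    sample_ids: Iterable[str] | None = None,
    sequence_id: object = 0,
    role: str = "unassigned",
) -> pd.DataFrame:
    conc = np.atleast_2d(np.asarray(concentrations, dtype=float))
    n = conc.shape[0]
    if conc.shape[1] != len(ions):
        raise InputError("concentration array width must match number of ions")
    if sample_ids is None:
        sample_ids = [f"{sequence_id}-{i + 1}" for i in range(n)]
    data: dict[str, object] = {
        "sample_id": list(sample_ids),
        "sequence_id": [sequence_id] * n,
    }
    for j, ion in enumerate(ions):
        data[conc_column(ion)] = conc[:, j]
    data["role"] = [role] * n
    return pd.DataFrame(data)
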