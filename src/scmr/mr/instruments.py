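"""Instrument selection and greedy LD clumping."""

from __future__ import annotations

import warnings
from typing import Callable, Union

import numpy as np
import pandas as pd

from ..errors import InputError

LDInput = Union[pd.DataFrame, np.ndarray, Callable[[str, str], float]]


def select_instruments(assocs: pd.DataFrame,
                       p_threshold: float = 1e-8) -> pd.DataFrame:
    """Rows with ``pval`` strictly below the significance threshold."""
    if len(assocs) == 0:
        raise InputError("association table is empty")
    out = assocs[assocs["pval"] < p_threshold].reset_index(drop=True)
    if len(out) == 0:
        warnings.warn(
            f"no variants pass p < {p_threshold:g}", stacklevel=2)
    return out


def _ld_lookup(ld: LDInput, assocs: pd.DataFrame):
    """Return a (snp_a, snp_b) -> r2-or-None lookup over the given table."""
    if callable(ld):
        return lambda a, b: ld(a, b)
    if isinstance(ld, pd.DataFrame):
        def lookup(a, b):
            if a in ld.index and b in ld.columns:
                v = ld.at[a, b]
                return None if pd.isna(v) else float(v)
            return None
        return lookup
    mat = np.asarray(ld, dtype=float)
    if mat.shape[0] != len(assocs) or mat.shape[1] != len(assocs):
        raise InputError("LD matrix shape does not match the association table")
    pos_of = {s: i for i, s in enumerate(assocs["snp"])}

    def lookup(a, b):
        v = mat[pos_of[a], pos_of[b]]
        return None if np.isnan(v) else float(v)
    return lookup


def ld_clump(assocs: pd.DataFrame, ld: LDInput,
             r2_max: float = 0.001, window_kb: float = 10_000.0) -> pd.DataFrame:
    """Greedy clumping: accept variants in ascending p-value order.

    A candidate is accepted iff its r-squared with every already-accepted
    variant on the same chromosome within +/- ``window_kb`` of its position
    is strictly below ``r2_max``.  Ties in p-value break by variant id.
    A missing r-squared for an in-window pair is an input error naming the
    pair.
    """
    if len(assocs) == 0:
        return assocs.copy()
    lookup = _ld_lookup(ld, assocs)
    window_bp = window_kb * 1000.0
    ordered = assocs.sort_values(["pval", "snp"], kind="mergesort")
    accepted: list[int] = []
    for idx, row in ordered.iterrows():
        ok = True
        for j in accepted:
            other = assocs.loc[j]
            if other["chr"] != row["chr"]:
                continue
            if abs(float(other["pos"]) - float(row["pos"])) > window_bp:
                continue
            r2 = lookup(row["snp"], other["snp"])
            if r2 is None:
                raise InputError(
                    f"missing r2 for in-window pair ({row['snp']}, {other['snp']})")
            if r2 >= r2_max:
                ok = False
                break
        if ok:
            accepted.append(idx)
    return assocs.loc[sorted(accepted)].reset_index(drop=True)
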