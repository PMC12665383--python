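"""Leave-one-out sensitivity analysis."""

from __future__ import annotations

import numpy as np
import pandas as pd

from ..errors import EstimationError
from .data import HarmonizedInstrumentSet
from .estimators import ivw


def leave_one_out(h: HarmonizedInstrumentSet) -> pd.DataFrame:
    """Recompute the random-effects IVW estimate excluding each variant.

    Returns one row per excluded variant plus an ``All`` row with the
    full-sample estimate.  With two instruments the reduced sets fall back
    to the Wald ratio (via ``ivw``).
    """
    if h.nsnp < 2:
        raise EstimationError("leave-one-out needs at least 2 instruments")
    rows = []
    snps = h.data["snp"].tolist()
    for i, snp in enumerate(snps):
        mask = np.arange(h.nsnp) != i
        est = ivw(h.subset(mask))
        rows.append({"excluded": snp, **est.to_dict()})
    full = ivw(h)
    rows.append({"excluded": "All", **full.to_dict()})
    return pd.DataFrame(rows)
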