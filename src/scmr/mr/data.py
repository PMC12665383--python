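"""Core MR data containers."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

VALID_ALLELES = frozenset("ACGT")

#: columns of the harmonized per-variant table
HARMONIZED_COLUMNS = [
    "snp", "beta_exp", "se_exp", "beta_out", "se_out",
    "eaf_exp", "eaf_out", "flipped", "palindromic",
]


@dataclass
class HarmonizedInstrumentSet:
    """Exposure/outcome effects aligned to a common effect allele."""

    exposure_id: str
    outcome_id: str
    data: pd.DataFrame
    log: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(
        columns=["snp", "action", "reason"]))

    @property
    def nsnp(self) -> int:
        return len(self.data)

    def arrays(self):
        d = self.data
        return (d["beta_exp"].to_numpy(dtype=float),
                d["se_exp"].to_numpy(dtype=float),
                d["beta_out"].to_numpy(dtype=float),
                d["se_out"].to_numpy(dtype=float))

    def subset(self, mask) -> "HarmonizedInstrumentSet":
        return HarmonizedInstrumentSet(
            self.exposure_id, self.outcome_id,
            self.data[mask].reset_index(drop=True), self.log)

    @classmethod
    def from_arrays(cls, beta_exp, se_exp, beta_out, se_out,
                    exposure_id: str = "exposure",
                    outcome_id: str = "outcome") -> "HarmonizedInstrumentSet":
        beta_exp = np.asarray(beta_exp, dtype=float)
        n = beta_exp.size
        data = pd.DataFrame({
            "snp": [f"snp{i + 1}" for i in range(n)],
            "beta_exp": beta_exp,
            "se_exp": np.broadcast_to(np.asarray(se_exp, dtype=float), (n,)),
            "beta_out": np.asarray(beta_out, dtype=float),
            "se_out": np.broadcast_to(np.asarray(se_out, dtype=float), (n,)),
            "eaf_exp": np.nan,
            "eaf_out": np.nan,
            "flipped": False,
            "palindromic": False,
        })
        return cls(exposure_id, outcome_id, data)


@dataclass
class MREstimate:
    """One estimator's output on the log-odds scale plus the OR scale."""

    method: str
    beta: float
    se: float
    ci_low: float
    ci_high: float
    pval: float
    nsnp: int

    @property
    def or_(self) -> float:
        return float(np.exp(self.beta))

    @property
    def or_ci_low(self) -> float:
        return float(np.exp(self.ci_low))

    @property
    def or_ci_high(self) -> float:
        return float(np.exp(self.ci_high))

    def to_dict(self) -> dict:
        return {
            "method": self.method, "nsnp": self.nsnp, "beta": self.beta,
            "se": self.se, "ci_low": self.ci_low, "ci_high": self.ci_high,
            "or": self.or_, "or_ci_low": self.or_ci_low,
            "or_ci_high": self.or_ci_high, "pval": self.pval,
        }


@dataclass
class SensitivityReport:
    """Heterogeneity, pleiotropy, and leave-one-out diagnostics for one
    gene-trait pair."""

    q_ivw: tuple | None = None          # (Q, df, p)
    q_egger: tuple | None = None
    egger_intercept: MREstimate | None = None
    leave_one_out: pd.DataFrame | None = None
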