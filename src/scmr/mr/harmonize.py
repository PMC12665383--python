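"""Allele harmonization of exposure and outcome summary statistics.

Both tables are joined on variant id and the outcome effect is re-expressed
relative to the exposure's effect allele:

* same alleles: unchanged;
* swapped alleles: outcome beta negated, eaf -> 1 - eaf;
* strand flip (complementary alleles): complemented, then the two rules
  above apply;
* palindromic variants (A/T, C/G): strand cannot be resolved from alleles
  alone — dropped when the effect-allele frequency is missing or
  uninformative (within the configured window around 0.5) on either side,
  otherwise oriented by frequency;
* any other allele combination: dropped and logged.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ..errors import InputError
from .data import HarmonizedInstrumentSet, VALID_ALLELES

COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


def _is_palindromic(ea: str, oa: str) -> bool:
    return COMPLEMENT.get(ea) == oa


def harmonize(exposure: pd.DataFrame, outcome: pd.DataFrame,
              palindrome_window: tuple[float, float] = (0.42, 0.58),
              exposure_id: str = "exposure",
              outcome_id: str = "outcome") -> HarmonizedInstrumentSet:
    """Align outcome effects to the exposure effect alleles.

    Returns a :class:`HarmonizedInstrumentSet`; dropped variants are listed
    in its ``log`` with the reason.
    """
    for name, df in (("exposure", exposure), ("outcome", outcome)):
        if df["snp"].duplicated().any():
            dup = df.loc[df["snp"].duplicated(), "snp"].iloc[0]
            raise InputError(f"duplicate variant id in {name} table: {dup}")
    merged = exposure.merge(outcome, on="snp", suffixes=("_exp", "_out"))
    lo, hi = palindrome_window

    rows, log = [], []

    def drop(snp, reason):
        log.append({"snp": snp, "action": "dropped", "reason": reason})

    for _, r in merged.iterrows():
        ea_x, oa_x = str(r["effect_allele_exp"]), str(r["other_allele_exp"])
        ea_y, oa_y = str(r["effect_allele_out"]), str(r["other_allele_out"])
        if not ({ea_x, oa_x} <= VALID_ALLELES and {ea_y, oa_y} <= VALID_ALLELES):
            drop(r["snp"], "invalid_alleles")
            continue
        beta_out = float(r["beta_out"])
        eaf_out = float(r["eaf_out"]) if "eaf_out" in r and pd.notna(r["eaf_out"]) else np.nan
        eaf_exp = float(r["eaf_exp"]) if "eaf_exp" in r and pd.notna(r["eaf_exp"]) else np.nan
        flipped = False

        if _is_palindromic(ea_x, oa_x):
            # strand flip is unobservable; resolve by frequency or drop
            if {ea_y, oa_y} != {ea_x, oa_x}:
                drop(r["snp"], "incompatible_alleles")
                continue
            if (np.isnan(eaf_exp) or np.isnan(eaf_out)
                    or lo < eaf_exp < hi or lo < eaf_out < hi):
                drop(r["snp"], "palindromic_ambiguous")
                continue
            same_side = (eaf_exp - 0.5) * (eaf_out - 0.5) > 0
            if ea_y == ea_x:
                aligned_eaf = eaf_out
            else:  # reported with alleles swapped
                beta_out = -beta_out
                aligned_eaf = 1.0 - eaf_out
                same_side = (eaf_exp - 0.5) * (aligned_eaf - 0.5) > 0
            if not same_side:
                # frequencies disagree: the outcome is on the other strand
                # with effect/other labels crossed; flip the sign back
                beta_out = -beta_out
                aligned_eaf = 1.0 - aligned_eaf
                flipped = True
            eaf_out = aligned_eaf
            palindromic = True
        else:
            palindromic = False
            if {ea_y, oa_y} == {ea_x, oa_x}:
                pass  # same strand
            elif {COMPLEMENT[ea_y], COMPLEMENT[oa_y]} == {ea_x, oa_x}:
                ea_y, oa_y = COMPLEMENT[ea_y], COMPLEMENT[oa_y]
                flipped = True
            else:
                drop(r["snp"], "incompatible_alleles")
                continue
            if ea_y == ea_x:
                pass
            else:  # swapped: negate and flip frequency
                beta_out = -beta_out
                if not np.isnan(eaf_out):
                    eaf_out = 1.0 - eaf_out

        rows.append({
            "snp": r["snp"],
            "beta_exp": float(r["beta_exp"]),
            "se_exp": float(r["se_exp"]),
            "beta_out": beta_out,
            "se_out": float(r["se_out"]),
            "eaf_exp": eaf_exp,
            "eaf_out": eaf_out,
            "flipped": flipped,
            "palindromic": palindromic,
        })

    data = pd.DataFrame(rows, columns=[
        "snp", "beta_exp", "se_exp", "beta_out", "se_out",
        "eaf_exp", "eaf_out", "flipped", "palindromic"])
    log_df = pd.DataFrame(log, columns=["snp", "action", "reason"])
    return HarmonizedInstrumentSet(exposure_id, outcome_id, data, log_df)
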