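"""Stem-loop RT-qPCR relative quantification by the ddCt method.

Ct tables carry one row per (target, treatment, biological replicate,
technical replicate).  Technical replicates are collapsed by mean; the
delta-Ct normalises each target against the mean Ct of the invariant
reference miRNAs in the same treatment/replicate; the delta-delta-Ct
compares against the calibrator treatment; relative abundance is
RQ = 2^(-ddCt), assuming an amplification efficiency of 2.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = ["RelativeAbundance", "select_reference", "ddct", "ddct_table"]

REQUIRED_COLS = ("target_id", "treatment", "bio_rep", "tech_rep", "ct")


def _validate(ct_table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in REQUIRED_COLS if c not in ct_table.columns]
    if missing:
        raise ValueError(f"Ct table lacks columns: {missing}")
    if (ct_table["ct"] <= 0).any():
        raise ValueError("Ct values must be positive")
    return ct_table


def _collapse_technical(ct_table: pd.DataFrame) -> pd.DataFrame:
    """Mean Ct per (target, treatment, biological replicate)."""
    return (
        ct_table.groupby(["target_id", "treatment", "bio_rep"], sort=True)["ct"]
        .mean()
        .reset_index()
    )


def select_reference(
    ct_table: pd.DataFrame,
    candidates: Sequence[str],
    stability_threshold: float = 0.5,
) -> list[str]:
    """Rank candidate reference miRNAs by Ct stability across treatments.

    Stability is the variance of the treatment-mean Ct; candidates below
    ``stability_threshold`` (cycles^2) are returned, most stable first.
    Raises with the full ranking when none passes.
    """
    ct = _collapse_technical(_validate(ct_table))
    if ct["treatment"].nunique() < 2:
        raise ValueError("need >= 2 treatments to assess stability")
    variances = {}
    for cand in candidates:
        sub = ct[ct["target_id"] == cand]
        if sub.empty:
            raise KeyError(f"candidate {cand!r} absent from Ct table")
        variances[cand] = float(sub.groupby("treatment")["ct"].mean().var(ddof=1))
    ranking = sorted(variances.items(), key=lambda kv: kv[1])
    stable = [c for c, v in ranking if v < stability_threshold]
    if not stable:
        report = ", ".join(f"{c}: {v:.3f}" for c, v in ranking)
        raise ValueError(
            f"no candidate passes stability threshold {stability_threshold}; "
            f"variance ranking: {report}"
        )
    return stable


@dataclass
class RelativeAbundance:
    """RQ = 2^(-ddCt) for one target in one treatment, with its standard
    error across biological replicates."""

    target_id: str
    treatment: str
    rq: float
    spread: float
    n_bio: int


def ddct(
    ct_table: pd.DataFrame,
    reference_ids: Sequence[str],
    calibrator_treatment: str,
) -> list[RelativeAbundance]:
    """Relative abundance of every non-reference target by ddCt.

    dCt(treatment, rep) = Ct(target) − mean Ct over the reference
    miRNAs; ddCt = mean dCt(treatment) − mean dCt(calibrator);
    RQ = 2^(−ddCt).  Using several references is equivalent to averaging
    their Ct before the dCt.  The spread is the standard error of the
    per-replicate RQ within the treatment.
    """
    ct = _collapse_technical(_validate(ct_table))
    treatments = ct["treatment"].unique()
    if calibrator_treatment not in treatments:
        raise ValueError(f"calibrator {calibrator_treatment!r} absent")
    refs = ct[ct["target_id"].isin(reference_ids)]
    for t in treatments:
        if set(refs.loc[refs["treatment"] == t, "target_id"]) != set(reference_ids):
            raise ValueError(f"reference miRNAs incomplete in treatment {t!r}")
    ref_ct = (
        refs.groupby(["treatment", "bio_rep"])["ct"].mean().rename("ref_ct")
    )
    merged = ct[~ct["target_id"].isin(reference_ids)].join(
        ref_ct, on=["treatment", "bio_rep"]
    )
    if merged["ref_ct"].isna().any():
        raise ValueError("reference Ct missing for some replicate")
    merged["dct"] = merged["ct"] - merged["ref_ct"]
    out = []
    for target, sub in merged.groupby("target_id", sort=True):
        cal = sub[sub["treatment"] == calibrator_treatment]["dct"]
        if cal.empty:
            raise ValueError(f"{target}: no calibrator measurements")
        cal_mean = cal.mean()
        for treatment, tsub in sub.groupby("treatment", sort=True):
            ddct_mean = tsub["dct"].mean() - cal_mean
            per_rep_rq = 2.0 ** (-(tsub["dct"] - cal_mean))
            n = len(tsub)
            spread = float(per_rep_rq.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0
            out.append(
                RelativeAbundance(
                    target_id=target,
                    treatment=treatment,
                    rq=float(2.0 ** (-ddct_mean)),
                    spread=spread,
                    n_bio=n,
                )
            )
    return out


def ddct_table(results: Sequence[RelativeAbundance]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "target_id": r.target_id,
                "treatment": r.treatment,
                "RQ": r.rq,
                "spread": r.spread,
                "n_bio": r.n_bio,
            }
            for r in results
        ]
    )
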