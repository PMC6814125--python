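"""Joint interpretation of miRNA, degradome and transcript evidence.

Degradome-valid miRNA–transcript pairs are sorted into coherence
classes by their differential-abundance behaviour across water-deficit
contrasts: the target may be unchanged, co-regulated with its miRNA
(positively correlated) or regulated opposite to it (inversely
correlated — the signature expected of genuine miRNA-guided cleavage).
Sequencing-based fold changes can also be checked against an orthogonal
platform (stem-loop RT-qPCR) by Spearman rank correlation.
"""

from __future__ import annotations

from itertools import permutations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "build_pairs",
    "classify_coherence",
    "cross_platform_correlation",
]

TARGET_UNCHANGED = "target-unchanged"
POSITIVE = "positive-correlated"
INVERSE = "inverse-correlated"


def build_pairs(
    valid_targets: pd.DataFrame,
    mirna_de: Mapping[str, pd.DataFrame],
    transcript_de: Mapping[str, pd.DataFrame],
) -> pd.DataFrame:
    """Join degradome-valid pairs with per-contrast DE statistics.

    ``valid_targets`` needs columns mirna_id/transcript_id (one row per
    pair); the DE mappings give one frame per contrast, indexed by id
    with columns log2FC and FDR.  Pairs lacking a DE record in a
    contrast get NaN there and are logged in the result's ``attrs``.
    """
    pairs = valid_targets[["mirna_id", "transcript_id"]].drop_duplicates()
    rows, missing = [], []
    for _, p in pairs.iterrows():
        for contrast in mirna_de:
            m_de = mirna_de[contrast]
            t_de = transcript_de[contrast]
            row = {
                "mirna_id": p.mirna_id,
                "transcript_id": p.transcript_id,
                "contrast": contrast,
                "mirna_log2FC": np.nan,
                "mirna_FDR": np.nan,
                "transcript_log2FC": np.nan,
                "transcript_FDR": np.nan,
            }
            if p.mirna_id in m_de.index:
                row["mirna_log2FC"] = float(m_de.loc[p.mirna_id, "log2FC"])
                row["mirna_FDR"] = float(m_de.loc[p.mirna_id, "FDR"])
            else:
                missing.append((p.mirna_id, contrast))
            if p.transcript_id in t_de.index:
                row["transcript_log2FC"] = float(t_de.loc[p.transcript_id, "log2FC"])
                row["transcript_FDR"] = float(t_de.loc[p.transcript_id, "FDR"])
            else:
                missing.append((p.transcript_id, contrast))
            rows.append(row)
    out = pd.DataFrame(rows)
    out.attrs["missing_de_records"] = missing
    return out


def classify_coherence(
    pairs: pd.DataFrame, alpha: float = 0.05
) -> tuple[pd.DataFrame, dict]:
    """Assign each miRNA–transcript pair to a coherence class.

    ``pairs`` is the long frame from :func:`build_pairs` (one row per
    pair x contrast).  A pair whose transcript is not significant
    (FDR < ``alpha``) in any contrast is ``target-unchanged``; otherwise
    the pair is classified within the contrast of strongest transcript
    significance by the sign agreement of the miRNA and transcript fold
    changes (same sign -> positively correlated, opposite -> inversely
    correlated).  Returns the per-pair table and class counts.
    """
    records = []
    for (mid, tid), sub in pairs.groupby(["mirna_id", "transcript_id"], sort=True):
        known = sub.dropna(subset=["transcript_FDR"])
        if known.empty:
            records.append(
                {
                    "mirna_id": mid,
                    "transcript_id": tid,
                    "contrast": None,
                    "class": None,
                }
            )
            continue
        sig = known[known["transcript_FDR"] < alpha]
        if sig.empty:
            best = known.loc[known["transcript_FDR"].idxmin()]
            cls, contrast = TARGET_UNCHANGED, best["contrast"]
        else:
            best = sig.loc[sig["transcript_FDR"].idxmin()]
            same = np.sign(best["mirna_log2FC"]) == np.sign(
                best["transcript_log2FC"]
            )
            cls = POSITIVE if same else INVERSE
            contrast = best["contrast"]
        records.append(
            {
                "mirna_id": mid,
                "transcript_id": tid,
                "contrast": contrast,
                "class": cls,
                "mirna_log2FC": best["mirna_log2FC"],
                "mirna_FDR": best["mirna_FDR"],
                "transcript_log2FC": best["transcript_log2FC"],
                "transcript_FDR": best["transcript_FDR"],
            }
        )
    table = pd.DataFrame(records)
    counts = table["class"].value_counts(dropna=True).to_dict()
    counts.setdefault(TARGET_UNCHANGED, 0)
    counts.setdefault(POSITIVE, 0)
    counts.setdefault(INVERSE, 0)
    return table, counts


def _spearman_rho(xr: np.ndarray, yr: np.ndarray) -> float:
    xr = xr - xr.mean()
    yr = yr - yr.mean()
    return float((xr * yr).sum() / np.sqrt((xr ** 2).sum() * (yr ** 2).sum()))


def cross_platform_correlation(
    logfc_a: Sequence[float],
    logfc_b: Sequence[float],
    exact_max_n: int = 8,
    mc_max_n: int = 10,
    mc_resamples: int = 100_000,
    seed: int = 0,
) -> tuple[float, float]:
    """Spearman rank correlation between two platforms' fold changes.

    Two-sided p by exhaustive permutation for n <= ``exact_max_n``,
    seeded Monte-Carlo permutation up to ``mc_max_n``, and the
    asymptotic t approximation beyond.  Ties take average ranks.
    """
    x = np.asarray(logfc_a, dtype=float)
    y = np.asarray(logfc_b, dtype=float)
    if x.size != y.size:
        raise ValueError("paired vectors must have equal length")
    n = x.size
    if n < 5:
        raise ValueError("need at least 5 paired values")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant vector")
    xr, yr = stats.rankdata(x), stats.rankdata(y)
    rho = _spearman_rho(xr, yr)
    if n <= exact_max_n:
        perms = np.array(list(permutations(range(n))), dtype=np.intp)
        rhos = np.array([_spearman_rho(xr, yr[p]) for p in perms])
        p = float(np.mean(np.abs(rhos) >= abs(rho) - 1e-12))
    elif n <= mc_max_n:
        rng = np.random.default_rng(seed)
        hits = 1  # count the observed arrangement
        for _ in range(mc_resamples):
            if abs(_spearman_rho(xr, rng.permutation(yr))) >= abs(rho) - 1e-12:
                hits += 1
        p = hits / (mc_resamples + 1)
    else:
        p = float(stats.spearmanr(x, y).pvalue)
    return rho, p
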