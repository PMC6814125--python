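"""TMM normalisation and negative-binomial differential abundance.

The testing chain mirrors the classical small-sample RNA-seq workflow:

1. between-library scaling by the weighted trimmed mean of M-values
   (TMM; 30% M-trim, 5% A-trim, inverse-asymptotic-variance weights,
   factors re-centred to geometric mean 1);
2. negative-binomial dispersion phi estimated by maximising the
   conditional likelihood on counts equalised to a common library size,
   with per-miRNA estimates shrunk toward the common value by a weighted
   likelihood;
3. an exact two-group NB test conditional on the per-feature total,
   with Benjamini–Hochberg control of the false discovery rate.

Replicate quality control (BCV, leading log-fold-change ordination,
outlier flagging) and the mild/severe contrast set algebra live here
too.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

__all__ = [
    "NormalizationState",
    "DispersionEstimate",
    "tmm_factors",
    "estimate_dispersion",
    "nb_test",
    "bh_adjust",
    "run_de",
    "compare_contrasts",
    "replicate_qc",
    "QCResult",
    "load_published_contrast",
]

_MAX_R = 1e8  # size parameter cap; beyond this NB is numerically Poisson


@dataclass
class NormalizationState:
    """TMM scaling factors and the effective library sizes they imply."""

    factors: pd.Series
    lib_sizes: pd.Series

    @property
    def effective_sizes(self) -> pd.Series:
        return self.lib_sizes * self.factors


def _tmm_pair(
    obs: np.ndarray,
    ref: np.ndarray,
    n_obs: float,
    n_ref: float,
    logratio_trim: float,
    sum_trim: float,
) -> float:
    keep = (obs > 0) & (ref > 0)
    obs, ref = obs[keep].astype(float), ref[keep].astype(float)
    if obs.size == 0:
        return 1.0
    log_r = np.log2((obs / n_obs) / (ref / n_ref))
    abs_e = 0.5 * (np.log2(obs / n_obs) + np.log2(ref / n_ref))
    v = (n_obs - obs) / (n_obs * obs) + (n_ref - ref) / (n_ref * ref)
    if np.max(np.abs(log_r)) < 1e-6:
        return 1.0
    n = log_r.size
    lo_l = np.floor(n * logratio_trim) + 1
    hi_l = n + 1 - lo_l
    lo_s = np.floor(n * sum_trim) + 1
    hi_s = n + 1 - lo_s
    rank_r = stats.rankdata(log_r)
    rank_e = stats.rankdata(abs_e)
    keep = (rank_r >= lo_l) & (rank_r <= hi_l) & (rank_e >= lo_s) & (rank_e <= hi_s)
    if not keep.any():
        return 1.0
    f = np.sum(log_r[keep] / v[keep]) / np.sum(1.0 / v[keep])
    return float(2.0 ** f)


def tmm_factors(
    counts: pd.DataFrame,
    logratio_trim: float = 0.3,
    sum_trim: float = 0.05,
) -> NormalizationState:
    """Robinson–Oshlack TMM scaling factors.

    The reference library is the one whose 75th count-fraction percentile
    is closest to the across-library mean; factors are re-centred so
    their geometric mean is 1.
    """
    if counts.shape[1] < 2:
        raise ValueError("TMM needs at least two libraries")
    lib_sizes = counts.sum(axis=0).astype(float)
    if (lib_sizes <= 0).any():
        bad = lib_sizes.index[lib_sizes <= 0].tolist()
        raise ValueError(f"libraries with zero total counts: {bad}")
    y = counts.to_numpy(dtype=float)
    f75 = np.array(
        [np.quantile(y[:, j] / lib_sizes.iloc[j], 0.75) for j in range(y.shape[1])]
    )
    ref_idx = int(np.argmin(np.abs(f75 - f75.mean())))
    factors = np.array(
        [
            _tmm_pair(
                y[:, j],
                y[:, ref_idx],
                lib_sizes.iloc[j],
                lib_sizes.iloc[ref_idx],
                logratio_trim,
                sum_trim,
            )
            for j in range(y.shape[1])
        ]
    )
    factors = factors / np.exp(np.mean(np.log(factors)))
    return NormalizationState(
        factors=pd.Series(factors, index=counts.columns),
        lib_sizes=lib_sizes,
    )


@dataclass
class DispersionEstimate:
    """Common and per-miRNA NB dispersion (BCV^2)."""

    common: float
    per_feature: pd.Series
    prior_weight: float

    @property
    def bcv(self) -> float:
        return float(np.sqrt(self.common))


def _pseudo_counts(
    counts: pd.DataFrame, state: NormalizationState | None
) -> np.ndarray:
    """Counts rescaled (and rounded) to a common effective library size."""
    if state is None:
        state = tmm_factors(counts)
    eff = state.effective_sizes.reindex(counts.columns).to_numpy()
    common = np.exp(np.mean(np.log(eff)))
    return np.rint(counts.to_numpy(dtype=float) * (common / eff))


def _cond_loglik(
    pseudo: np.ndarray, group_cols: Sequence[np.ndarray], phi: float
) -> np.ndarray:
    """Per-feature NB conditional log-likelihood at dispersion ``phi``,
    summed over groups, assuming equal library sizes."""
    r = min(1.0 / max(phi, 1e-12), _MAX_R)
    out = np.zeros(pseudo.shape[0])
    for cols in group_cols:
        y = pseudo[:, cols]
        n = y.shape[1]
        z = y.sum(axis=1)
        out += (
            gammaln(y + r).sum(axis=1)
            - n * gammaln(r)
            + gammaln(n * r)
            - gammaln(z + n * r)
        )
    return out


def estimate_dispersion(
    counts: pd.DataFrame,
    groups: Mapping[str, str],
    state: NormalizationState | None = None,
    prior_df: float = 10.0,
    grid_size: int = 80,
) -> DispersionEstimate:
    """Conditional-likelihood dispersion with empirical-Bayes shrinkage.

    The common dispersion maximises the summed conditional likelihood on
    library-size-equalised counts; per-miRNA values maximise a weighted
    combination of the feature's own likelihood and the average across
    features, with weight ``prior_df / residual_df``.  All-zero features
    carry no information and inherit the common value.
    """
    labels = pd.Series({c: groups[c] for c in counts.columns})
    if (labels.value_counts() < 2).any():
        raise ValueError("each group needs >= 2 replicates")
    pseudo = _pseudo_counts(counts, state)
    col_idx = {c: j for j, c in enumerate(counts.columns)}
    group_cols = [
        np.array([col_idx[c] for c in labels.index[labels == g]])
        for g in labels.unique()
    ]
    informative = pseudo.sum(axis=1) > 0
    pseudo_i = pseudo[informative]

    grid = np.concatenate([[1e-8], np.logspace(-4, np.log10(5.0), grid_size - 1)])
    ll = np.stack(
        [_cond_loglik(pseudo_i, group_cols, phi) for phi in grid], axis=1
    )  # features x grid
    total = ll.sum(axis=0)
    common = float(grid[int(np.argmax(total))])

    resid_df = len(labels) - labels.nunique()
    prior_n = prior_df / max(resid_df, 1)
    weighted = ll + prior_n * ll.mean(axis=0, keepdims=True)
    tagwise_i = grid[np.argmax(weighted, axis=1)]
    tagwise = np.full(counts.shape[0], common)
    tagwise[informative] = tagwise_i
    return DispersionEstimate(
        common=common,
        per_feature=pd.Series(tagwise, index=counts.index),
        prior_weight=prior_n,
    )


def _exact_nb_pvalue(s_a: float, s_b: float, n_a: int, n_b: int, phi: float) -> float:
    """Exact two-sided NB test on equalised group sums.

    Conditional on the total, compares the observed split of the summed
    pseudo-counts between groups against its null distribution; the
    p-value accumulates all splits no more probable than the observed
    one.
    """
    s_a, s_b = int(round(s_a)), int(round(s_b))
    s = s_a + s_b
    if s == 0:
        return 1.0
    mu = s / (n_a + n_b)
    r_a = min(n_a / max(phi, 1e-12), _MAX_R)
    r_b = min(n_b / max(phi, 1e-12), _MAX_R)
    k = np.arange(s + 1)
    logp_a = stats.nbinom.logpmf(k, r_a, r_a / (r_a + n_a * mu))
    logp_b = stats.nbinom.logpmf(k, r_b, r_b / (r_b + n_b * mu))
    joint = logp_a + logp_b[::-1]
    joint -= joint.max()
    prob = np.exp(joint)
    obs = prob[s_a]
    return float(prob[prob <= obs * (1.0 + 1e-12)].sum() / prob.sum())


def nb_test(
    counts: pd.DataFrame,
    state: NormalizationState,
    dispersion: DispersionEstimate,
    group_a: Sequence[str],
    group_b: Sequence[str],
    prior_count: float = 0.125,
) -> pd.DataFrame:
    """Two-group exact NB test of ``group_b`` (treatment) vs ``group_a``.

    log2FC is computed from TMM-normalised group means with a prior
    count of ``prior_count`` scaled by relative library size, which keeps
    fold changes finite when one group is all zeros.  Returns a frame
    with columns ``log2FC`` and ``pvalue`` indexed by miRNA id.
    """
    group_a, group_b = list(group_a), list(group_b)
    if set(group_a) & set(group_b):
        raise ValueError("groups must be disjoint")
    if min(len(group_a), len(group_b)) < 1:
        raise ValueError("both groups need at least one library")
    sub = counts[group_a + group_b]
    eff = state.effective_sizes.reindex(sub.columns).to_numpy()
    prior = prior_count * eff / eff.mean()
    norm = (sub.to_numpy(dtype=float) + prior) / (eff + 2 * prior)
    mean_a = norm[:, : len(group_a)].mean(axis=1)
    mean_b = norm[:, len(group_a):].mean(axis=1)
    log2fc = np.log2(mean_b / mean_a)

    pseudo = _pseudo_counts(sub, NormalizationState(
        factors=state.factors[sub.columns], lib_sizes=state.lib_sizes[sub.columns]
    ))
    s_a = pseudo[:, : len(group_a)].sum(axis=1)
    s_b = pseudo[:, len(group_a):].sum(axis=1)
    phis = dispersion.per_feature.reindex(counts.index).to_numpy()
    pvals = np.array(
        [
            _exact_nb_pvalue(sa, sb, len(group_a), len(group_b), ph)
            for sa, sb, ph in zip(s_a, s_b, phis)
        ]
    )
    return pd.DataFrame(
        {"log2FC": log2fc, "pvalue": np.clip(pvals, 0.0, 1.0)}, index=counts.index
    )


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (FDR)."""
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ValueError("pvalues must be one-dimensional")
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adjusted, 1.0)
    return out


def run_de(
    counts: pd.DataFrame,
    groups: Mapping[str, str],
    control: str,
    treatment: str,
    state: NormalizationState | None = None,
    dispersion: DispersionEstimate | None = None,
    prior_count: float = 0.125,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """TMM -> dispersion -> exact test -> BH, for one contrast.

    Returns a frame with columns log2FC, pvalue, FDR, significant
    (FDR < ``alpha``), indexed by miRNA id.
    """
    labels = pd.Series({c: groups[c] for c in counts.columns})
    if state is None:
        state = tmm_factors(counts)
    if dispersion is None:
        dispersion = estimate_dispersion(counts, groups, state)
    libs_a = labels.index[labels == control].tolist()
    libs_b = labels.index[labels == treatment].tolist()
    res = nb_test(counts, state, dispersion, libs_a, libs_b, prior_count)
    res["FDR"] = bh_adjust(res["pvalue"].to_numpy())
    res["significant"] = res["FDR"] < alpha
    res.index.name = "mirna_id"
    return res


def compare_contrasts(
    de_mild: pd.DataFrame, de_severe: pd.DataFrame, alpha: float = 0.05
) -> dict:
    """Set algebra over two contrasts' significant miRNAs.

    Expects frames with ``FDR`` and ``log2FC`` columns indexed by miRNA
    id.  Returns the shared/mild-only/severe-only partition at
    FDR < ``alpha`` plus the count of shared ids whose fold changes
    disagree in sign between the two stress levels.
    """
    sig_mild = set(de_mild.index[de_mild["FDR"] < alpha])
    sig_severe = set(de_severe.index[de_severe["FDR"] < alpha])
    shared = sig_mild & sig_severe
    discordant = {
        i
        for i in shared
        if np.sign(de_mild.loc[i, "log2FC"]) != np.sign(de_severe.loc[i, "log2FC"])
    }
    return {
        "mild_only": sorted(sig_mild - sig_severe),
        "severe_only": sorted(sig_severe - sig_mild),
        "shared": sorted(shared),
        "discordant": sorted(discordant),
        "union_count": len(sig_mild | sig_severe),
        "shared_count": len(shared),
        "mild_only_count": len(sig_mild - sig_severe),
        "severe_only_count": len(sig_severe - sig_mild),
        "discordant_sign_count": len(discordant),
    }


@dataclass
class QCResult:
    """Replicate QC summary: BCV, 2-D ordination, outlier flags."""

    bcv: float
    coordinates: pd.DataFrame  # library x (dim1, dim2)
    outliers: list[str]
    distances: pd.DataFrame


def replicate_qc(
    counts: pd.DataFrame,
    groups: Mapping[str, str],
    top_n: int = 100,
    k: float = 3.0,
    n_mds_features: int = 500,
) -> QCResult:
    """Replicate agreement diagnostics on non-normalised counts.

    BCV is sqrt(common dispersion) over the ``top_n`` highest-count
    miRNAs.  Libraries are ordinated in 2-D by classical scaling of
    pairwise leading log-fold-change distances (root-mean-square of the
    ``n_mds_features`` largest absolute log2 ratios per pair).  A library
    is flagged as an outlier when its median distance to its own group's
    other members exceeds median + ``k`` x MAD of those within-group
    distances across all libraries.
    """
    if counts.shape[1] < 3:
        raise ValueError("replicate QC needs >= 3 libraries")
    labels = pd.Series({c: groups[c] for c in counts.columns})
    top = counts.loc[counts.mean(axis=1).sort_values(ascending=False).index[:top_n]]
    disp = estimate_dispersion(top, groups)
    bcv = float(np.sqrt(disp.common))

    lib_sizes = counts.sum(axis=0).to_numpy(dtype=float)
    logcpm = np.log2((counts.to_numpy(dtype=float) + 0.5) / (lib_sizes + 1.0) * 1e6)
    n = counts.shape[1]
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = np.abs(logcpm[:, i] - logcpm[:, j])
            lead = np.sort(d)[::-1][: min(n_mds_features, d.size)]
            dist[i, j] = dist[j, i] = np.sqrt(np.mean(lead ** 2))
    # classical MDS on the distance matrix
    j_mat = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j_mat @ (dist ** 2) @ j_mat
    vals, vecs = np.linalg.eigh(b)
    idx = np.argsort(vals)[::-1][:2]
    coords = vecs[:, idx] * np.sqrt(np.maximum(vals[idx], 0.0))
    coordinates = pd.DataFrame(
        coords, index=counts.columns, columns=["dim1", "dim2"]
    )

    within = {}
    for lib in counts.columns:
        mates = labels.index[(labels == labels[lib]) & (labels.index != lib)]
        if len(mates) == 0:
            within[lib] = 0.0
            continue
        i = counts.columns.get_loc(lib)
        within[lib] = float(
            np.median([dist[i, counts.columns.get_loc(m)] for m in mates])
        )
    w = pd.Series(within)
    med = w.median()
    # floor the MAD at 10% of the median so near-identical replicate
    # distances do not make the threshold degenerate
    mad = max(1.4826 * (w - med).abs().median(), 0.1 * med, 1e-9)
    outliers = w.index[w > med + k * mad].tolist()
    return QCResult(
        bcv=bcv,
        coordinates=coordinates,
        outliers=outliers,
        distances=pd.DataFrame(dist, index=counts.columns, columns=counts.columns),
    )


def load_published_contrast(which: str) -> pd.DataFrame:
    """Load the packaged published DE summary for ``"mild"`` or
    ``"severe"`` water-deficit stress (vs well-watered).

    These tables carry the significant miRNAs (FDR < 0.05) of the maize
    primary-root growth-zone study with their log2 fold change, p-value
    and FDR, and drive the worked set-logic example.
    """
    if which not in ("mild", "severe"):
        raise ValueError("which must be 'mild' or 'severe'")
    ref = resources.files("rootmir.data") / f"de_summary_{which}.tsv"
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t", index_col="mirna_id")
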