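"""Two-group negative-binomial differential expression on count tables.

This stage provides a documented, self-contained count-based test in the
mold of the standard NB tools: median-of-ratios size factors, gene-wise
method-of-moments dispersions shrunk toward a mean-dispersion trend, group
means fitted by NB maximum likelihood with size-factor offsets, a Wald test
on the log2 fold change with a standard error from the NB Fisher
information, and Benjamini-Hochberg adjustment. It does not claim
bit-for-bit equivalence with any external package; precomputed differential
tables can be supplied instead (``load_external_de``).

The NB parameterization throughout is variance = mu + alpha * mu**2, with
alpha called the dispersion.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.stats.multitest import multipletests

from .data_model import CountMatrix, ValidationError

logger = logging.getLogger(__name__)

DISPERSION_FLOOR = 1e-8

DE_COLUMNS = [
    "gene_id", "base_mean", "fold_change", "log2fc", "p_value", "q_value", "direction",
]


def estimate_size_factors(counts: CountMatrix) -> pd.Series:
    """Median-of-ratios size factors, normalized to geometric mean 1.

    Ratios are taken against the per-gene geometric mean over samples,
    using only genes with positive counts in every sample. If no such gene
    exists the estimator falls back to total-count ratios (logged warning).
    """
    k = counts.counts.to_numpy(dtype=float)
    all_pos = np.all(k > 0, axis=1)
    if all_pos.any():
        kp = k[all_pos]
        ref = np.exp(np.mean(np.log(kp), axis=1))  # per-gene geometric mean
        sf = np.median(kp / ref[:, None], axis=0)
    else:
        logger.warning(
            "no gene with positive counts in all samples; "
            "falling back to total-count size factors"
        )
        totals = k.sum(axis=0)
        if np.any(totals == 0):
            raise ValidationError("sample with zero total counts")
        sf = totals / totals.mean()
    sf = sf / np.exp(np.mean(np.log(sf)))
    return pd.Series(sf, index=counts.sample_ids, name="size_factor")


@dataclass
class DispersionFit:
    """Per-gene raw, trend and final (shrunken) dispersion estimates."""

    table: pd.DataFrame  # columns: mean, raw, trend, final
    trend_coef: tuple[float, float]  # alpha(mu) = a0 + a1 / mu

    @property
    def final(self) -> pd.Series:
        return self.table["final"]


def _groups_to_arrays(counts: CountMatrix, groups) -> dict[str, list[str]]:
    by_group: dict[str, list[str]] = {}
    for sid in counts.sample_ids:
        if sid not in groups:
            raise ValidationError(f"sample {sid!r} missing from group labels")
        by_group.setdefault(groups[sid], []).append(sid)
    extra = set(groups) - set(counts.sample_ids)
    if extra:
        raise ValidationError(f"group labels for unknown sample(s): {sorted(extra)}")
    return by_group


def _fit_dispersion_trend(mean: np.ndarray, raw: np.ndarray) -> tuple[float, float]:
    """Fit alpha(mu) = a0 + a1/mu by non-negative least squares, one
    trimming pass to resist outliers."""
    use = (mean > 0) & (raw > 10 * DISPERSION_FLOOR)
    if use.sum() < 10:
        med = float(np.median(raw[mean > 0])) if (mean > 0).any() else DISPERSION_FLOOR
        return (max(med, DISPERSION_FLOOR), 0.0)
    for _ in range(2):
        A = np.column_stack([np.ones(use.sum()), 1.0 / mean[use]])
        coef, _ = optimize.nnls(A, raw[use])
        fit = coef[0] + coef[1] / mean[use]
        ratio = raw[use] / np.maximum(fit, DISPERSION_FLOOR)
        keep = (ratio < 10) & (ratio > 0.01)
        if keep.all():
            break
        idx = np.flatnonzero(use)
        use = np.zeros_like(use)
        use[idx[keep]] = True
        if use.sum() < 10:
            break
    return (max(float(coef[0]), DISPERSION_FLOOR), max(float(coef[1]), 0.0))


def estimate_dispersions(
    counts: CountMatrix,
    groups: dict[str, str],
    size_factors: pd.Series,
    shrink_weight: float = 0.5,
) -> DispersionFit:
    """Method-of-moments dispersions with trend shrinkage.

    Raw gene-wise dispersion pools the within-group moment estimates
    alpha_hat = (s^2 - m) / m^2 on normalized counts, floored at 1e-8; the
    trend alpha(mu) = a0 + a1/mu is fitted across genes; the final value
    shrinks raw toward trend on the log scale with ``shrink_weight`` on the
    trend. Genes with no data (all zero) get the trend value at their mean.
    """
    by_group = _groups_to_arrays(counts, groups)
    for g, ids in by_group.items():
        if len(ids) < 2:
            raise ValidationError(
                f"group {g!r} has {len(ids)} sample(s); at least 2 are needed "
                "for dispersion estimation — supply an external DE table instead"
            )
    k = counts.counts.to_numpy(dtype=float)
    sf = size_factors.reindex(counts.sample_ids).to_numpy()
    y = k / sf
    num = np.zeros(k.shape[0])
    den = 0.0
    for ids in by_group.values():
        cols = [counts.sample_ids.index(s) for s in ids]
        yg = y[:, cols]
        m = yg.mean(axis=1)
        s2 = yg.var(axis=1, ddof=1)
        # moment estimator with the E[m^2] = mu^2 + var(m)/1 correction:
        # denominator m^2 - s^2/n is an unbiased estimate of mu^2
        mu2 = np.maximum(m ** 2 - s2 / len(ids), (0.5 * m) ** 2)
        with np.errstate(divide="ignore", invalid="ignore"):
            a = np.where(m > 0, (s2 - m) / np.maximum(mu2, 1e-300), np.nan)
        w = len(ids) - 1
        num += np.nan_to_num(a, nan=0.0) * w
        den += w
    raw = np.maximum(num / den, DISPERSION_FLOOR)
    mean = y.mean(axis=1)
    a0, a1 = _fit_dispersion_trend(mean, raw)
    with np.errstate(divide="ignore"):
        trend = a0 + a1 / np.maximum(mean, 1e-300)
    trend = np.where(mean > 0, trend, a0)
    trend = np.maximum(trend, DISPERSION_FLOOR)
    final = np.exp(
        (1.0 - shrink_weight) * np.log(raw) + shrink_weight * np.log(trend)
    )
    final = np.where(mean > 0, final, trend)
    table = pd.DataFrame(
        {"mean": mean, "raw": raw, "trend": trend, "final": final},
        index=counts.gene_ids,
    )
    return DispersionFit(table, (a0, a1))


def _fit_group_mean(
    k: np.ndarray, sf: np.ndarray, alpha: np.ndarray, n_iter: int = 50
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized NB maximum-likelihood group mean with size-factor offsets.

    Fisher scoring on theta = log(q), where sample means are mu_s = sf_s*q.
    Returns (q_hat, information at q_hat).
    """
    q = np.maximum((k / sf).mean(axis=1), 1e-8)
    a = alpha[:, None]
    for _ in range(n_iter):
        mu = q[:, None] * sf[None, :]
        denom = 1.0 + a * mu
        score = (k - mu * (1.0 + a * k) / denom).sum(axis=1)
        info = (mu / denom).sum(axis=1)
        step = np.clip(score / np.maximum(info, 1e-12), -3.0, 3.0)
        q = np.maximum(q * np.exp(step), 1e-12)
        if np.max(np.abs(step)) < 1e-10:
            break
    mu = q[:, None] * sf[None, :]
    info = (mu / (1.0 + a * mu)).sum(axis=1)
    return q, info


def nb_wald_test(
    counts: CountMatrix,
    groups: dict[str, str],
    size_factors: pd.Series | None = None,
    dispersions: DispersionFit | None = None,
    reference: str | None = None,
    fc_min: float = 2.0,
    q_max: float = 0.05,
    lfc_pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Per-gene NB Wald test between exactly two groups.

    Fold changes are oriented treatment/reference; the reference defaults
    to ``wild_type`` when present, else the lexicographically first label.
    log2fc uses pseudocounted (+0.5) normalized group means; the Wald
    standard error comes from the NB Fisher information, evaluated at the
    pseudocounted means so it stays finite for all-zero groups; p values
    are two-sided normal; q values are Benjamini-Hochberg over tested genes
    (genes with zero counts in every sample are excluded from testing and
    from the BH denominator).
    """
    by_group = _groups_to_arrays(counts, groups)
    if len(by_group) != 2:
        raise ValidationError(f"need exactly 2 groups, got {sorted(by_group)}")
    labels = sorted(by_group)
    if reference is None:
        reference = "wild_type" if "wild_type" in labels else labels[0]
    if reference not in by_group:
        raise ValidationError(f"reference group {reference!r} not among {labels}")
    treatment = next(g for g in labels if g != reference)
    if size_factors is None:
        size_factors = estimate_size_factors(counts)
    if dispersions is None:
        dispersions = estimate_dispersions(counts, groups, size_factors)

    k = counts.counts.to_numpy(dtype=float)
    sf_all = size_factors.reindex(counts.sample_ids).to_numpy()
    alpha = dispersions.table["final"].reindex(counts.gene_ids).to_numpy()
    tested = k.sum(axis=1) > 0

    cols = {g: [counts.sample_ids.index(s) for s in ids] for g, ids in by_group.items()}
    q_hat, info = {}, {}
    for g in labels:
        qg, _ = _fit_group_mean(k[:, cols[g]], sf_all[cols[g]], alpha)
        q_hat[g] = qg
        # information at pseudocounted means keeps the SE finite for zero groups
        mu_t = (qg + lfc_pseudocount)[:, None] * sf_all[cols[g]][None, :]
        info[g] = (mu_t / (1.0 + alpha[:, None] * mu_t)).sum(axis=1)

    lfc = np.log2(
        (q_hat[treatment] + lfc_pseudocount) / (q_hat[reference] + lfc_pseudocount)
    )
    # small-sample variance inflation: the two fitted group means consume
    # 2 of the n_total degrees of freedom the plug-in information ignores
    n_total = sum(len(ids) for ids in by_group.values())
    df_corr = np.sqrt(n_total / max(n_total - 2, 1))
    se = df_corr * np.sqrt(1.0 / info[reference] + 1.0 / info[treatment]) / np.log(2.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, lfc / se, 0.0)
    p = 2.0 * stats.norm.sf(np.abs(z))

    q_adj = np.full(len(p), np.nan)
    if tested.any():
        q_adj[tested] = multipletests(p[tested], method="fdr_bh")[1]
    p = np.where(tested, p, np.nan)

    fold = 2.0 ** lfc
    direction = np.full(len(p), "ns", dtype=object)
    with np.errstate(invalid="ignore"):
        sig = tested & (q_adj < q_max)
        direction[sig & (fold > fc_min)] = "up"
        direction[sig & (fold < 1.0 / fc_min)] = "down"

    return pd.DataFrame(
        {
            "gene_id": counts.gene_ids,
            "base_mean": (k / sf_all).mean(axis=1),
            "fold_change": fold,
            "log2fc": lfc,
            "p_value": p,
            "q_value": q_adj,
            "direction": direction,
        }
    )


def filter_de(
    result: pd.DataFrame,
    fc_min: float = 2.0,
    q_max: float = 0.05,
    use_raw_p: bool = False,
) -> tuple[list[str], list[str]]:
    """Split a differential result into (up, down) gene lists.

    up: fold_change strictly > fc_min and significance strictly < q_max;
    down: fold_change strictly < 1/fc_min, same significance rule. The
    significance column is the BH q value by default, the raw p value with
    ``use_raw_p``.
    """
    sig_col = "p_value" if use_raw_p else "q_value"
    sig = result[sig_col] < q_max
    up = result.loc[sig & (result["fold_change"] > fc_min), "gene_id"]
    down = result.loc[sig & (result["fold_change"] < 1.0 / fc_min), "gene_id"]
    return sorted(up.tolist()), sorted(down.tolist())


def load_external_de(path_or_frame) -> pd.DataFrame:
    """Ingest a precomputed differential table (gene_id, fold_change, and
    p_value and/or q_value); missing q defaults to BH over the given p."""
    df = path_or_frame if isinstance(path_or_frame, pd.DataFrame) else pd.read_csv(
        path_or_frame, sep="\t"
    )
    required = {"gene_id", "fold_change"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"external DE table lacks column(s): {sorted(missing)}")
    if "p_value" not in df.columns and "q_value" not in df.columns:
        raise ValidationError("external DE table needs p_value and/or q_value")
    out = df.copy()
    out["gene_id"] = out["gene_id"].astype(str)
    if "q_value" not in out.columns:
        out["q_value"] = multipletests(out["p_value"].to_numpy(), method="fdr_bh")[1]
    if "p_value" not in out.columns:
        out["p_value"] = out["q_value"]
    out["log2fc"] = np.log2(out["fold_change"].astype(float))
    return out
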