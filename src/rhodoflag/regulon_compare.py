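"""Differential expression and cross-species core-regulon intersection.

Per-gene negative binomial models with a log link and library-size
offsets are fitted per contrast (mutant vs wild type); significance
comes from a likelihood-ratio test against chi-square(1), with the
dispersion held fixed at a moderated per-gene estimate. A gene is
significantly differentially expressed when |log2 fold change| > 1 and
the Benjamini-Hochberg FDR < 0.05 (fold change > 2 and FDR < 0.05 are
the same gate).

The moderated dispersion is a pragmatic stand-in for full empirical
Bayes machinery: a common dispersion maximizing the exact NB conditional
likelihood (given per-group totals, on normalized pseudo-counts), and
per-gene method-of-moments estimates shrunk toward it with weight
w = 20 / (20 + residual df).

The cross-species step maps genes by bidirectional best hit (e-value
cutoff 1e-10) and classifies each ortholog pair per corresponding
contrast: ``strict`` (significant in both species, same direction),
``relaxed`` (same direction, significant in at least one),
``discordant`` (significant in both, opposite directions) or
``species_specific``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.special import gammaln
from scipy.stats import chi2
from statsmodels.stats.multitest import multipletests

from .errors import DataError
from .io_formats import GeneRecord
from .orthology import AlignParams, HitThresholds, best_hits

PHI_FLOOR = 1e-8
SHRINKAGE_PRIOR_DF = 20.0
LFC_THRESHOLD = 1.0
FDR_THRESHOLD = 0.05
ORTHOLOG_EVALUE = 1e-10
#: Fraction of the fold-change gate a near-miss must reach for ``relaxed``.
RELAXED_GATE_FRACTION = 0.75


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios library-size factors, geometric mean 1.

    Falls back to total-count ratios (with a warning) when no gene is
    nonzero in every sample.
    """
    mat = counts.to_numpy(dtype=float)
    all_nonzero = (mat > 0).all(axis=1)
    if all_nonzero.any():
        logref = np.log(mat[all_nonzero]).mean(axis=1)
        ratios = np.log(mat[all_nonzero]) - logref[:, None]
        logf = np.median(ratios, axis=0)
    else:
        warnings.warn(
            "no gene is nonzero in all samples; falling back to total-count factors",
            stacklevel=2,
        )
        totals = mat.sum(axis=0)
        if (totals == 0).any():
            raise DataError("a sample has zero total counts")
        logf = np.log(totals)
    logf = logf - logf.mean()
    return pd.Series(np.exp(logf), index=counts.columns, name="size_factor")


@dataclass
class DispersionEstimate:
    common: float
    per_gene: pd.Series
    shrinkage_weight: float


def _conditional_loglik(counts_pseudo: np.ndarray, groups: list[np.ndarray], log_r: float) -> float:
    """Exact NB conditional log-likelihood given per-group totals.

    Valid for equal library sizes; applied to size-factor-normalized,
    rounded pseudo-counts as an approximation otherwise.
    """
    r = np.exp(log_r)
    total = 0.0
    for cols in groups:
        y = counts_pseudo[:, cols]
        n = y.shape[1]
        if n < 2:
            continue
        z = y.sum(axis=1)
        total += float(
            (gammaln(y + r).sum(axis=1) - n * gammaln(r) + gammaln(n * r) - gammaln(n * r + z)).sum()
        )
    return total


def estimate_dispersion(
    counts: pd.DataFrame,
    groups: pd.Series,
    factors: pd.Series | None = None,
) -> DispersionEstimate:
    """Common + moderated per-gene NB dispersion.

    Common dispersion maximizes the conditional likelihood pooled over
    genes and groups; per-gene raw estimates are method-of-moments
    within groups, shrunk toward the common value with weight
    w = 20 / (20 + residual df). All values floored at 1e-8.
    """
    groups = groups.loc[list(counts.columns)]
    group_cols = [
        np.array([counts.columns.get_loc(s) for s in groups.index[groups == g]])
        for g in sorted(groups.unique())
    ]
    resid_df = sum(max(0, len(c) - 1) for c in group_cols)
    if not any(len(c) >= 2 for c in group_cols):
        raise DataError("dispersion estimation needs a group with >= 2 replicates")

    if factors is None:
        factors = size_factors(counts)
    mat = counts.to_numpy(dtype=float) / factors.to_numpy()[None, :]
    pseudo = np.rint(mat)
    nz = pseudo.sum(axis=1) > 0
    res = minimize_scalar(
        lambda lr: -_conditional_loglik(pseudo[nz], group_cols, lr),
        bounds=(np.log(1.0 / 50.0), np.log(1e8)),  # r = 1/phi, phi in [1e-8, 50]
        method="bounded",
        options={"xatol": 1e-6},
    )
    common = max(1.0 / np.exp(res.x), PHI_FLOOR)

    num = np.zeros(counts.shape[0])
    den = 0.0
    for cols in group_cols:
        if len(cols) < 2:
            continue
        y = mat[:, cols]
        m = y.mean(axis=1)
        v = y.var(axis=1, ddof=1)
        df = len(cols) - 1
        # moments with the finite-sample denominator correction:
        # E[v - m] = phi*mu^2 and E[m^2 - v/n] = mu^2
        denom = np.square(m) - v / len(cols)
        with np.errstate(divide="ignore", invalid="ignore"):
            phi_grp = np.where(denom > 0, (v - m) / denom, 0.0)
        num += df * np.clip(phi_grp, 0.0, None)
        den += df
    raw = num / den
    w = SHRINKAGE_PRIOR_DF / (SHRINKAGE_PRIOR_DF + resid_df)
    per_gene = np.maximum(w * common + (1 - w) * raw, PHI_FLOOR)
    return DispersionEstimate(
        common=float(common),
        per_gene=pd.Series(per_gene, index=counts.index, name="dispersion"),
        shrinkage_weight=float(w),
    )


def _nb_loglik(y: np.ndarray, mu: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Per-gene NB log-likelihood summed over samples (constants included)."""
    mu = np.clip(mu, 1e-300, None)
    r = 1.0 / phi[:, None]
    return (
        gammaln(y + r) - gammaln(r) - gammaln(y + 1)
        + r * np.log(r / (r + mu))
        + y * np.log(mu / (r + mu))
    ).sum(axis=1)


def _fit_group_mean(
    y: np.ndarray, s: np.ndarray, phi: np.ndarray, n_iter: int = 50
) -> np.ndarray:
    """MLE of a per-gene constant mean m with offsets: mu_ij = s_j * m_i.

    Fisher scoring on eta = log m; closed-form start at sum(y)/sum(s).
    Genes with all-zero counts get m = 0.
    """
    tot = y.sum(axis=1)
    m = tot / s.sum()
    pos = m > 0
    eta = np.where(pos, np.log(np.clip(m, 1e-300, None)), -np.inf)
    for _ in range(n_iter):
        mu = s[None, :] * np.exp(eta)[:, None]
        denom = 1.0 + phi[:, None] * mu
        score = ((y - mu) / denom).sum(axis=1)
        info = (mu / denom).sum(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            step = np.where(pos & (info > 0), score / np.clip(info, 1e-12, None), 0.0)
        step = np.clip(step, -5.0, 5.0)
        eta = eta + step
        if np.max(np.abs(step)) < 1e-12:
            break
    return np.where(pos, np.exp(eta), 0.0)


def nb_lrt_test(
    counts: pd.DataFrame,
    groups: pd.Series,
    reference: str,
    treatment: str,
    dispersion: pd.Series,
    factors: pd.Series | None = None,
) -> pd.DataFrame:
    """Likelihood-ratio test of treatment vs reference, per gene.

    Dispersion is held fixed; the statistic 2*(logL_alt - logL_null) is
    referred to chi-square(1). log2fc = log2(m_treat / m_ref) from the
    fitted group means, with a 0.5 pseudo-mean floor for all-zero groups
    (reporting only, never inside the likelihood).
    """
    samples = [s for s in counts.columns if groups[s] in (reference, treatment)]
    if not samples:
        raise DataError(f"no samples for contrast {treatment} vs {reference}")
    sub = counts[samples]
    lab = groups.loc[samples]
    for g in (reference, treatment):
        if (lab == g).sum() < 2:
            raise DataError(f"group {g} needs >= 2 samples")
    if factors is None:
        factors = size_factors(counts)
    s = factors.loc[samples].to_numpy()
    y = sub.to_numpy(dtype=float)
    phi = np.maximum(dispersion.loc[counts.index].to_numpy(), PHI_FLOOR)

    ref_cols = np.array([i for i, smp in enumerate(samples) if lab[smp] == reference])
    trt_cols = np.array([i for i, smp in enumerate(samples) if lab[smp] == treatment])

    m_null = _fit_group_mean(y, s, phi)
    ll_null = _nb_loglik(y, s[None, :] * m_null[:, None], phi)

    m_ref = _fit_group_mean(y[:, ref_cols], s[ref_cols], phi)
    m_trt = _fit_group_mean(y[:, trt_cols], s[trt_cols], phi)
    mu_alt = np.empty_like(y)
    mu_alt[:, ref_cols] = s[ref_cols][None, :] * m_ref[:, None]
    mu_alt[:, trt_cols] = s[trt_cols][None, :] * m_trt[:, None]
    ll_alt = _nb_loglik(y, mu_alt, phi)

    stat = np.clip(2.0 * (ll_alt - ll_null), 0.0, None)
    pvalue = chi2.sf(stat, df=1)
    log2fc = np.log2(np.maximum(m_trt, 0.5) / np.maximum(m_ref, 0.5))
    return pd.DataFrame(
        {"log2fc": log2fc, "stat": stat, "pvalue": pvalue}, index=counts.index
    )


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up FDR values (order-preserving, capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise DataError("p-values must be in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_significant(
    results: pd.DataFrame,
    lfc_threshold: float = LFC_THRESHOLD,
    fdr_threshold: float = FDR_THRESHOLD,
) -> pd.DataFrame:
    """Apply the joint gate |log2fc| > 1 and FDR < 0.05; set direction."""
    out = results.copy()
    out["fdr"] = bh_adjust(out["pvalue"].to_numpy())
    out["significant"] = (np.abs(out["log2fc"]) > lfc_threshold) & (
        out["fdr"] < fdr_threshold
    )
    out["direction"] = np.where(
        out["significant"], np.where(out["log2fc"] > 0, "up", "down"), "none"
    )
    return out


def de_contrasts(
    counts: pd.DataFrame,
    conditions: pd.Series,
    reference: str = "wt",
    contrasts: list[str] | None = None,
) -> dict[str, pd.DataFrame]:
    """Full DE pipeline per contrast: normalize, moderate, test, gate.

    BH adjustment is applied within each contrast (per-mutant families).
    """
    if contrasts is None:
        contrasts = sorted(c for c in conditions.unique() if c != reference)
    factors = size_factors(counts)
    disp = estimate_dispersion(counts, conditions, factors)
    out = {}
    for contrast in contrasts:
        res = nb_lrt_test(counts, conditions, reference, contrast, disp.per_gene, factors)
        out[contrast] = call_significant(res)
    return out


def cross_species_orthologs(
    proteome_a: list[GeneRecord],
    proteome_b: list[GeneRecord],
    max_evalue: float = ORTHOLOG_EVALUE,
    params: AlignParams = AlignParams(),
) -> list[tuple[str, str]]:
    """Bidirectional best hits at the regulon e-value cutoff (1e-10).

    Coverage/identity gates are disabled for this mapping; only the
    reciprocal best-hit requirement and the e-value cutoff apply.
    """
    thr = HitThresholds(min_coverage_pct=0.0, min_identity_pct=0.0, max_evalue=max_evalue)
    fwd = best_hits(proteome_a, proteome_b, thr, params)
    rev = best_hits(proteome_b, proteome_a, thr, params)
    pairs = []
    for ga, hit in sorted(fwd.items()):
        back = rev.get(hit.gene_b)
        if back is not None and back.gene_b == ga:
            pairs.append((ga, hit.gene_b))
    return pairs


def _classify_pair(
    row_a: pd.Series | None,
    row_b: pd.Series | None,
    lfc_threshold: float = LFC_THRESHOLD,
) -> str | None:
    """One class per ortholog pair and contrast.

    ``relaxed`` requires a near-miss on the non-significant side: the
    same direction with at least three quarters of the fold-change gate
    (e.g. a 1.9-fold change alongside a significant call in the other
    species). Same-signed noise around zero stays ``species_specific``.
    """
    sig_a = bool(row_a is not None and row_a["significant"])
    sig_b = bool(row_b is not None and row_b["significant"])
    if not (sig_a or sig_b):
        return None
    lfc_a = float(row_a["log2fc"]) if row_a is not None else 0.0
    lfc_b = float(row_b["log2fc"]) if row_b is not None else 0.0
    same_dir = lfc_a * lfc_b > 0
    if sig_a and sig_b:
        return "strict" if same_dir else "discordant"
    other = abs(lfc_b) if sig_a else abs(lfc_a)
    if same_dir and other > RELAXED_GATE_FRACTION * lfc_threshold:
        return "relaxed"
    return "species_specific"


def core_regulon(
    de_a: dict[str, pd.DataFrame],
    de_b: dict[str, pd.DataFrame],
    pairs: list[tuple[str, str]],
    contrast_map: dict[str, str] | None = None,
) -> dict[str, pd.DataFrame]:
    """Classify ortholog pairs per corresponding contrast; overlap tables.

    Returns ``entries`` (one row per pair x contrast with at least one
    significant call), ``overlap`` (shared/unique up/down counts per
    contrast pair) and per-species mutant-overlap tables (membership
    patterns of the per-mutant significant gene lists).
    """
    if contrast_map is None:
        contrast_map = {c: c for c in de_a}
    for ca, cb in contrast_map.items():
        if ca not in de_a:
            raise DataError(f"contrast {ca} missing from species A results")
        if cb not in de_b:
            raise DataError(f"contrast {cb} missing from species B results")

    rows = []
    overlap_rows = []
    for ca, cb in sorted(contrast_map.items()):
        ta, tb = de_a[ca], de_b[cb]
        n = {"shared_up": 0, "shared_down": 0, "unique_a": 0, "unique_b": 0}
        for ga, gb in pairs:
            row_a = ta.loc[ga] if ga in ta.index else None
            row_b = tb.loc[gb] if gb in tb.index else None
            cls = _classify_pair(row_a, row_b)
            if cls is None:
                continue
            rows.append(
                {
                    "contrast_a": ca,
                    "contrast_b": cb,
                    "gene_a": ga,
                    "gene_b": gb,
                    "log2fc_a": float(row_a["log2fc"]) if row_a is not None else np.nan,
                    "log2fc_b": float(row_b["log2fc"]) if row_b is not None else np.nan,
                    "significant_a": bool(row_a is not None and row_a["significant"]),
                    "significant_b": bool(row_b is not None and row_b["significant"]),
                    "class": cls,
                }
            )
            if cls == "strict":
                key = "shared_up" if float(row_a["log2fc"]) > 0 else "shared_down"
                n[key] += 1
            elif rows[-1]["significant_a"] and not rows[-1]["significant_b"]:
                n["unique_a"] += 1
            elif rows[-1]["significant_b"] and not rows[-1]["significant_a"]:
                n["unique_b"] += 1
        overlap_rows.append({"contrast_a": ca, "contrast_b": cb, **n})

    entries = pd.DataFrame(
        rows,
        columns=[
            "contrast_a", "contrast_b", "gene_a", "gene_b",
            "log2fc_a", "log2fc_b", "significant_a", "significant_b", "class",
        ],
    )
    overlap = pd.DataFrame(
        overlap_rows,
        columns=["contrast_a", "contrast_b", "shared_up", "shared_down", "unique_a", "unique_b"],
    )

    def mutant_overlap(de: dict[str, pd.DataFrame]) -> pd.DataFrame:
        contrasts = sorted(de)
        sig = {
            c: {
                (g, de[c].loc[g, "direction"])
                for g in de[c].index[de[c]["significant"]]
            }
            for c in contrasts
        }
        genes = {g for s in sig.values() for (g, _) in s}
        pat_counts: dict[tuple, int] = {}
        for g in sorted(genes):
            pattern = tuple(
                next((d for (gg, d) in sig[c] if gg == g), "none") for c in contrasts
            )
            pat_counts[pattern] = pat_counts.get(pattern, 0) + 1
        recs = [
            {**{c: p[i] for i, c in enumerate(contrasts)}, "n_genes": cnt}
            for p, cnt in sorted(pat_counts.items())
        ]
        return pd.DataFrame(recs, columns=contrasts + ["n_genes"])

    return {
        "entries": entries,
        "overlap": overlap,
        "mutant_overlap_a": mutant_overlap(de_a),
        "mutant_overlap_b": mutant_overlap(de_b),
    }
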