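"""TMM normalization and exact-test differential expression for count data.

Between-sample normalization uses the trimmed mean of M-values (TMM):
per-library scaling factors are computed from gene-wise log count ratios
against a reference library, doubly trimmed by log-ratio (M) and average
log abundance (A) and combined with inverse-variance (delta-method)
weights, then rescaled so their geometric mean is one.

Differential expression is a self-contained exact conditional test under a
negative-binomial model with a single common dispersion ``phi``
(variance = m + phi * m^2).  Counts are scaled to a common effective
library size, summed per group, and the treatment pseudo-sum is tested
against its conditional distribution given the total; with phi = 0 and
equal effective sizes this reduces to a binomial test.  The test is
two-sided by summing the probability of all outcomes at most as likely as
the observed one.  It trades edgeR's quantile adjustment and dispersion
shrinkage for transparency; directional agreement on strong effects is the
design contract, not numeric identity with edgeR.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from coexhub.data_model import CountMatrix, DataModelError, PipelineConfig

DE_COLUMNS = ["gene_id", "contrast_id", "timepoint_h", "log2fc", "pvalue", "qvalue", "call"]

#: Above this conditional-support size the exact convolution is replaced by
#: a Gaussian approximation (memory/time guard; negligible error at that scale).
_EXACT_TOTAL_CAP = 1_000_000


@dataclass
class NormalizationResult:
    """Per-sample library sizes and TMM scaling factors."""

    sample_ids: list[str]
    library_sizes: np.ndarray
    tmm_factors: np.ndarray
    reference_sample: str

    @property
    def effective_library_sizes(self) -> np.ndarray:
        return self.library_sizes * self.tmm_factors

    def factor_of(self, sample_id: str) -> float:
        return float(self.tmm_factors[self.sample_ids.index(sample_id)])


@dataclass(frozen=True)
class DEResult:
    """One gene in one contrast: effect size, significance and call."""

    gene_id: str
    contrast_id: str
    log2fc: float
    pvalue: float
    qvalue: float = float("nan")
    call: str = "ns"


# -- TMM ----------------------------------------------------------------------

def _tmm_pair_factor(obs: np.ndarray, ref: np.ndarray, n_obs: float, n_ref: float,
                     trim_m: float, trim_a: float) -> float:
    """log2 TMM factor of one library against the reference library."""
    keep = (obs > 0) & (ref > 0)
    if not np.any(keep):
        return 0.0
    o = obs[keep].astype(float)
    r = ref[keep].astype(float)
    m = np.log2((o / n_obs) / (r / n_ref))
    a = 0.5 * np.log2((o / n_obs) * (r / n_ref))
    w = (n_obs - o) / (n_obs * o) + (n_ref - r) / (n_ref * r)
    fin = np.isfinite(m) & np.isfinite(a) & np.isfinite(w)
    m, a, w = m[fin], a[fin], w[fin]
    n = m.size
    if n == 0:
        return 0.0
    # rank-based double trim, ties averaged
    rm = stats.rankdata(m)
    ra = stats.rankdata(a)
    lo_m = np.floor(n * trim_m) + 1
    hi_m = n + 1 - lo_m
    lo_a = np.floor(n * trim_a) + 1
    hi_a = n + 1 - lo_a
    keep2 = (rm >= lo_m) & (rm <= hi_m) & (ra >= lo_a) & (ra <= hi_a)
    if not np.any(keep2) or np.sum(w[keep2]) == 0:
        return 0.0
    f = float(np.sum(w[keep2] * m[keep2]) / np.sum(w[keep2]))
    if abs(f) < 1e-6:
        f = 0.0
    return f


def tmm_factors(counts: CountMatrix, reference: str | None = None,
                trim_m: float = 0.30, trim_a: float = 0.05) -> NormalizationResult:
    """Compute TMM normalization factors for every library.

    The reference defaults to the sample whose upper-quartile CPM is
    closest to the mean upper-quartile across samples.  Factors are
    rescaled so their geometric mean is exactly 1.

    Raises on matrices with fewer than two samples or any all-zero library.
    """
    if counts.n_samples < 2:
        raise DataModelError("TMM requires at least two samples")
    y = counts.counts.astype(float)
    lib = y.sum(axis=0)
    if np.any(lib == 0):
        bad = counts.sample_ids[int(np.argmin(lib))]
        raise DataModelError(f"sample {bad!r} has all-zero counts")

    if reference is None:
        uq = np.quantile(y / lib, 0.75, axis=0)
        ref_idx = int(np.argmin(np.abs(uq - uq.mean())))
    else:
        if reference not in counts.sample_ids:
            raise DataModelError(f"unknown reference sample {reference!r}")
        ref_idx = counts.sample_ids.index(reference)

    log_factors = np.array([
        _tmm_pair_factor(y[:, k], y[:, ref_idx], lib[k], lib[ref_idx], trim_m, trim_a)
        for k in range(counts.n_samples)
    ])
    factors = 2.0 ** log_factors
    factors = factors / np.exp(np.mean(np.log(factors)))
    return NormalizationResult(
        sample_ids=list(counts.sample_ids),
        library_sizes=lib.astype(np.int64),
        tmm_factors=factors,
        reference_sample=counts.sample_ids[ref_idx],
    )


def cpm_matrix(counts: CountMatrix, norm: NormalizationResult,
               log: bool = False, prior_count: float = 0.5) -> pd.DataFrame:
    """Counts per million on effective (TMM-scaled) library sizes.

    With ``log=True`` returns ``log2(CPM + prior_count)``; the prior keeps
    zero counts finite.
    """
    if list(norm.sample_ids) != list(counts.sample_ids):
        raise DataModelError("normalization result does not match counts samples")
    eff = norm.effective_library_sizes
    cpm = counts.counts / eff * 1e6
    if log:
        cpm = np.log2(cpm + prior_count)
    return pd.DataFrame(cpm, index=counts.gene_ids, columns=counts.sample_ids)


# -- dispersion ---------------------------------------------------------------

def estimate_common_dispersion(counts: CountMatrix, groups: Sequence[str],
                               norm: NormalizationResult | None = None) -> float:
    """Method-of-moments common NB dispersion.

    Counts are scaled to a common effective library size.  For every gene
    the within-group (pooled) variance ``v`` and mean ``m`` give a
    gene-wise ``phi_g = max(0, (v - m) / m^2)``; the common dispersion is
    the median of ``phi_g`` over genes with positive mean.  Only groups
    with at least two replicates contribute variance.

    Because the median of a chi-square-distributed variance estimate sits
    below its mean, the raw median of ``phi_g`` is biased downward; the
    pooled variance is therefore rescaled by ``df / median(chi2_df)``
    (about 1.19 at 4 degrees of freedom), which makes the median
    approximately unbiased for the planted dispersion.
    """
    groups = np.asarray([str(g) for g in groups])
    if len(groups) != counts.n_samples:
        raise DataModelError("groups length must equal the number of samples")
    eff = (norm.effective_library_sizes if norm is not None
           else counts.library_sizes().astype(float))
    target = np.exp(np.mean(np.log(eff)))
    scaled = counts.counts / eff * target

    labels = np.unique(groups)
    usable = [g for g in labels if np.sum(groups == g) >= 2]
    if not usable:
        raise DataModelError("need at least one group with >= 2 replicates")

    ss = np.zeros(counts.n_genes)
    df_total = 0
    weighted_mean = np.zeros(counts.n_genes)
    n_total = 0
    for g in usable:
        cols = groups == g
        n = int(cols.sum())
        sub = scaled[:, cols]
        mu = sub.mean(axis=1)
        ss += ((sub - mu[:, None]) ** 2).sum(axis=1)
        weighted_mean += mu * n
        df_total += n - 1
        n_total += n
    v = ss / df_total * (df_total / stats.chi2.median(df_total))
    m = weighted_mean / n_total
    pos = m > 0
    if not np.any(pos):
        raise DataModelError("no gene has a positive mean")
    phi_g = np.maximum(0.0, (v[pos] - m[pos]) / m[pos] ** 2)
    return float(np.median(phi_g))


# -- exact test ---------------------------------------------------------------

def _conditional_pmf(total: int, n_a: int, n_b: int, phi: float) -> np.ndarray:
    """PMF of the group-A pseudo-sum given the two-group total.

    Group sums of iid NB(mu, phi) replicates are NB(n*mu, phi/n); the
    conditional law of the A-sum given the total follows from their joint
    pmf, with the shared per-replicate mean estimated as total/(nA+nB).
    With phi=0 this is exactly Binomial(total, nA/(nA+nB)).
    """
    s = np.arange(total + 1)
    if phi == 0.0:
        return stats.binom.pmf(s, total, n_a / (n_a + n_b))
    mu = total / (n_a + n_b)
    mean_a, disp_a = n_a * mu, phi / n_a
    mean_b, disp_b = n_b * mu, phi / n_b
    r_a = 1.0 / disp_a
    r_b = 1.0 / disp_b
    log_a = stats.nbinom.logpmf(s, r_a, r_a / (r_a + mean_a))
    log_b = stats.nbinom.logpmf(total - s, r_b, r_b / (r_b + mean_b))
    log_joint = log_a + log_b
    log_joint -= log_joint.max()
    pmf = np.exp(log_joint)
    return pmf / pmf.sum()


def _exact_pvalue(s_a: int, total: int, n_a: int, n_b: int, phi: float) -> float:
    if total == 0:
        return 1.0
    if total > _EXACT_TOTAL_CAP:
        # Gaussian fallback on the conditional mean/variance scale
        w = n_a / (n_a + n_b)
        mean = total * w
        mu = total / (n_a + n_b)
        v_a = n_a * mu + (phi / n_a) * (n_a * mu) ** 2
        v_b = n_b * mu + (phi / n_b) * (n_b * mu) ** 2
        var = v_a * v_b / (v_a + v_b)
        z = (s_a - mean) / np.sqrt(var)
        return float(min(1.0, 2.0 * stats.norm.sf(abs(z))))
    pmf = _conditional_pmf(total, n_a, n_b, phi)
    p_obs = pmf[s_a]
    return float(min(1.0, pmf[pmf <= p_obs * (1.0 + 1e-7)].sum()))


def nb_exact_test(counts: CountMatrix, norm: NormalizationResult,
                  treatment: Sequence[str], control: Sequence[str],
                  phi: float, contrast_id: str = "contrast",
                  timepoint_h: float = float("nan"),
                  prior_count: float = 0.5) -> pd.DataFrame:
    """Exact conditional NB test of a treatment group against a control group.

    Returns a DataFrame with ``gene_id``, ``contrast_id``, ``timepoint_h``,
    ``log2fc`` (prior-moderated log2 ratio of group mean CPMs) and
    ``pvalue``; q-values and DEG calls are filled by :func:`bh_adjust` /
    :func:`call_degs`.
    """
    if len(treatment) == 0 or len(control) == 0:
        raise DataModelError("both contrast groups must be non-empty")
    if phi < 0:
        raise DataModelError("dispersion phi must be >= 0")
    ids = counts.sample_ids
    for s in list(treatment) + list(control):
        if s not in ids:
            raise DataModelError(f"contrast sample {s!r} not in count matrix")
    idx_a = [ids.index(s) for s in treatment]
    idx_b = [ids.index(s) for s in control]
    eff = norm.effective_library_sizes
    target = np.exp(np.mean(np.log(eff[idx_a + idx_b])))
    pseudo = counts.counts[:, idx_a + idx_b] / eff[idx_a + idx_b] * target
    n_a, n_b = len(idx_a), len(idx_b)
    s_a = np.rint(pseudo[:, :n_a].sum(axis=1)).astype(np.int64)
    s_b = np.rint(pseudo[:, n_a:].sum(axis=1)).astype(np.int64)

    cpm = counts.counts / eff * 1e6
    mean_a = cpm[:, idx_a].mean(axis=1)
    mean_b = cpm[:, idx_b].mean(axis=1)
    log2fc = np.log2((mean_a + prior_count) / (mean_b + prior_count))

    pvals = np.array([
        _exact_pvalue(int(a), int(a + b), n_a, n_b, phi)
        for a, b in zip(s_a, s_b)
    ])
    return pd.DataFrame({
        "gene_id": counts.gene_ids,
        "contrast_id": contrast_id,
        "timepoint_h": timepoint_h,
        "log2fc": log2fc,
        "pvalue": pvals,
        "qvalue": np.nan,
        "call": "ns",
    })


# -- multiple testing and calling ---------------------------------------------

def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, input order preserved."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise DataModelError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_degs(de: pd.DataFrame, config: PipelineConfig | None = None,
              per_family: bool = True) -> pd.DataFrame:
    """Fill q-values (BH within each contrast family) and up/down/ns calls.

    Calls use strict inequalities: up iff ``log2fc > lfc_threshold`` and
    ``q < fdr_threshold``; down symmetric; everything else ``ns``.
    """
    config = config or PipelineConfig()
    de = de.copy()
    if per_family:
        for cid in de["contrast_id"].unique():
            mask = de["contrast_id"] == cid
            de.loc[mask, "qvalue"] = bh_adjust(de.loc[mask, "pvalue"].to_numpy())
    else:
        de["qvalue"] = bh_adjust(de["pvalue"].to_numpy())
    up = (de["log2fc"] > config.lfc_threshold) & (de["qvalue"] < config.fdr_threshold)
    down = (de["log2fc"] < -config.lfc_threshold) & (de["qvalue"] < config.fdr_threshold)
    de["call"] = np.where(up, "up", np.where(down, "down", "ns"))
    return de


# -- contrast plumbing --------------------------------------------------------

def timepoint_contrasts(counts: CountMatrix, strain: str | None = None
                        ) -> list[tuple[str, float, list[str], list[str]]]:
    """Treatment-vs-control contrasts, one per timepoint.

    Returns ``(contrast_id, timepoint_h, treatment_ids, control_ids)``
    tuples for every timepoint that has samples in both conditions,
    optionally restricted to one strain.
    """
    samples = counts.samples
    if strain is not None:
        samples = [s for s in samples if s.strain == strain]
    tps = sorted({s.timepoint_h for s in samples})
    out = []
    for tp in tps:
        treat = [s.sample_id for s in samples
                 if s.timepoint_h == tp and s.condition == "treatment"]
        ctrl = [s.sample_id for s in samples
                if s.timepoint_h == tp and s.condition == "control"]
        if treat and ctrl:
            label = f"{int(tp) if float(tp).is_integer() else tp}hpi"
            out.append((f"treatment_vs_control_{label}", tp, treat, ctrl))
    return out


def strain_contrasts(counts: CountMatrix, mutant: str, wildtype: str = "WT",
                     condition: str = "treatment"
                     ) -> list[tuple[str, float, list[str], list[str]]]:
    """Mutant-vs-wild-type contrasts, one per timepoint, within one condition."""
    samples = [s for s in counts.samples if s.condition == condition]
    tps = sorted({s.timepoint_h for s in samples})
    out = []
    for tp in tps:
        mut = [s.sample_id for s in samples
               if s.timepoint_h == tp and s.strain == mutant]
        wt = [s.sample_id for s in samples
              if s.timepoint_h == tp and s.strain == wildtype]
        if mut and wt:
            label = f"{int(tp) if float(tp).is_integer() else tp}hpi"
            out.append((f"{mutant}_vs_{wildtype}_{label}", tp, mut, wt))
    return out


def run_de(counts: CountMatrix, norm: NormalizationResult,
           contrasts: Sequence[tuple[str, float, list[str], list[str]]],
           phi: float, config: PipelineConfig | None = None) -> pd.DataFrame:
    """Exact test over a list of contrasts, BH per contrast, calls filled."""
    config = config or PipelineConfig()
    tables = [
        nb_exact_test(counts, norm, treat, ctrl, phi,
                      contrast_id=cid, timepoint_h=tp,
                      prior_count=config.prior_count)
        for cid, tp, treat, ctrl in contrasts
    ]
    if not tables:
        raise DataModelError("no valid contrasts found in the design")
    de = pd.concat(tables, ignore_index=True)
    return call_degs(de, config)


def write_de_table(de: pd.DataFrame, path: str | Path) -> None:
    de.to_csv(path, sep="\t", index=False, columns=DE_COLUMNS)


def read_de_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"gene_id": str, "contrast_id": str,
                                              "call": str})
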