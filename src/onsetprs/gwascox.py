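"""Variant QC, exit-age population splits, and per-variant Cox scans.

The scan fits, for every variant, a Cox proportional-hazards model of the
event on effect-allele dosage plus adjustment covariates on the age
timescale (risk interval ``(entry_age, exit_age]``), and collects the
per-variant log hazard ratio, its standard error and a two-sided Wald
p-value into the shared sumstats schema.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logsumexp

from .containers import (GenotypeMatrix, SurvivalCohort, SUMSTATS_COLUMNS)
from .coxph import fit_cox
from .exceptions import (ConvergenceError, EmptyInputError, NoEventsError,
                         ValidationError)

__all__ = ["hwe_exact_p", "variant_qc", "split_population", "split_by_bins",
           "split_case_control", "cox_scan"]


def hwe_exact_p(n_het: int, n_hom_minor: int, n_hom_major: int) -> float:
    """Two-sided exact Hardy–Weinberg test p-value.

    Conditional on the observed allele counts, sums the probabilities of
    all heterozygote counts whose probability does not exceed that of the
    observed count (point-probability summation). Computed with a stable
    recurrence over heterozygote counts.
    """
    n_het, n_hom_minor, n_hom_major = int(n_het), int(n_hom_minor), int(n_hom_major)
    n = n_het + n_hom_minor + n_hom_major
    if n == 0:
        return 1.0
    minor = 2 * n_hom_minor + n_het
    if minor > n:  # ensure 'minor' really is the rarer allele
        minor = 2 * n - minor
    if minor == 0:
        return 1.0

    # heterozygote counts share parity with the minor-allele count;
    # work with log probabilities (the unnormalised pmf overflows for
    # biobank-scale counts)
    h_min = minor % 2
    h_max = minor if minor <= n else 2 * n - minor  # = min(minor, major)
    hs = [h_min]
    logp = [0.0]
    h = h_min
    lp = 0.0
    while h + 2 <= h_max:
        hom_min = (minor - h) // 2
        hom_maj = n - h - hom_min
        # log P(h+2) - log P(h) from the hypergeometric-style pmf
        lp += np.log(4.0 * hom_min * hom_maj) - np.log((h + 2.0) * (h + 1.0))
        h += 2
        hs.append(h)
        logp.append(lp)
    logp = np.array(logp)
    logp -= logsumexp(logp)
    try:
        i_obs = hs.index(n_het)
    except ValueError:
        return 0.0  # impossible heterozygote count for these allele totals
    lp_obs = logp[i_obs]
    mask = logp <= lp_obs + 1e-12
    return float(min(1.0, np.exp(logsumexp(logp[mask]))))


def variant_qc(g: GenotypeMatrix,
               maf_min: float = 0.01,
               hwe_p_min: float = 1e-6,
               call_rate_min: float = 0.95) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Remove variants failing MAF, HWE-exact or call-rate criteria.

    Retention requires minor-allele frequency >= ``maf_min``, exact
    Hardy–Weinberg p-value >= ``hwe_p_min`` and call rate > ``call_rate_min``
    (strict, matching the 'call rate > 95%' convention). The report lists
    every variant with its metrics and, for removals, the failing criteria.
    """
    if g.n_variants == 0 or g.n_samples == 0:
        raise EmptyInputError("empty genotype matrix")
    for name, val, lo, hi in [("maf_min", maf_min, 0, 0.5),
                              ("hwe_p_min", hwe_p_min, 0, 1),
                              ("call_rate_min", call_rate_min, 0, 1)]:
        if not (lo <= val <= hi):
            raise ValidationError(f"{name}={val} outside [{lo}, {hi}]")

    eaf = g.eaf()
    maf = np.minimum(eaf, 1 - eaf)
    call_rate = g.call_rate()
    hwe_p = np.empty(g.n_variants)
    for j in range(g.n_variants):
        d = g.dosages[:, j]
        d = d[~np.isnan(d)]
        if d.size == 0:
            hwe_p[j] = 1.0
            continue
        n_het = int((d == 1).sum())
        n_alt = int((d == 2).sum())
        n_ref = int((d == 0).sum())
        hwe_p[j] = hwe_exact_p(n_het, n_alt, n_ref)

    with np.errstate(invalid="ignore"):
        fail_maf = ~(maf >= maf_min)        # NaN maf (all-missing) fails too
    fail_hwe = hwe_p < hwe_p_min
    fail_cr = ~(call_rate > call_rate_min)

    reasons = []
    for fm, fh, fc in zip(fail_maf, fail_hwe, fail_cr):
        rs = ([r for r, f in (("maf", fm), ("hwe", fh), ("call_rate", fc)) if f])
        reasons.append(",".join(rs))
    report = pd.DataFrame({
        "variant_id": g.variants["variant_id"],
        "maf": maf, "call_rate": call_rate, "hwe_p": hwe_p,
        "removed": fail_maf | fail_hwe | fail_cr,
        "reason": reasons,
    })
    kept = g.subset_variants(~report["removed"].to_numpy())
    return kept, report


def split_population(c: SurvivalCohort,
                     age_cut: float = 55.0) -> tuple[SurvivalCohort, SurvivalCohort]:
    """Split a follow-up cohort at the exit age: EO (<= cut) vs LO (> cut)."""
    if age_cut <= 0:
        raise ValidationError("age_cut must be positive")
    exit_age = c.table["exit_age"].to_numpy()
    eo = c.subset(exit_age <= age_cut, label="EO")
    lo = c.subset(exit_age > age_cut, label="LO")
    return eo, lo


def split_by_bins(c: SurvivalCohort, bin_edges) -> list[SurvivalCohort]:
    """Partition by exit age into left-open, right-closed bins.

    ``bin_edges`` are interior cut ages; the outer bins are unbounded, so
    ``bin_edges=[55]`` reproduces the EO/LO split and a longer list yields
    the piecewise age-group analysis.
    """
    edges = [-np.inf] + sorted(bin_edges) + [np.inf]
    exit_age = c.table["exit_age"].to_numpy()
    out = []
    for lo_e, hi_e in zip(edges[:-1], edges[1:]):
        mask = (exit_age > lo_e) & (exit_age <= hi_e)
        out.append(c.subset(mask, label=f"({lo_e},{hi_e}]"))
    return out


def split_case_control(table: pd.DataFrame,
                       age_cut: float = 55.0) -> dict[str, pd.DataFrame]:
    """Group a case–control table by reference age (diagnosis or censoring).

    Returns ``{"General": all rows, "EO": reference_age <= cut,
    "LO": reference_age > cut}`` with the same closed-left boundary as the
    follow-up split.
    """
    if "reference_age" not in table:
        raise ValidationError("case-control table lacks 'reference_age'")
    if table["reference_age"].isna().any():
        bad = int(table["reference_age"].isna().sum())
        raise ValidationError(f"{bad} rows with missing reference_age")
    ref = table["reference_age"].to_numpy()
    return {
        "General": table.reset_index(drop=True),
        "EO": table.loc[ref <= age_cut].reset_index(drop=True),
        "LO": table.loc[ref > age_cut].reset_index(drop=True),
    }


def cox_scan(g: GenotypeMatrix,
             c: SurvivalCohort,
             covariate_names: list[str] | None = None,
             weights: np.ndarray | None = None) -> pd.DataFrame:
    """Per-variant Cox association scan; returns a sumstats table.

    Samples with a missing dosage are dropped for that variant only
    (complete-case per variant). Rows with missing covariates are dropped
    for all variants and counted in the table's ``n``. When ``weights`` are
    given the weighted partial likelihood is maximised and the sandwich
    (robust) standard error is reported.
    """
    covariate_names = list(covariate_names or [])
    if g.n_samples != len(c):
        raise ValidationError(
            f"genotypes ({g.n_samples}) and cohort ({len(c)}) misaligned")
    if c.n_events == 0:
        raise NoEventsError("cohort has zero events")
    unknown = [x for x in covariate_names if x not in c.table]
    if unknown:
        raise ValidationError(f"unknown covariates {unknown}")

    cov = c.table[covariate_names].to_numpy(dtype=float) if covariate_names \
        else np.empty((len(c), 0))
    complete = ~np.isnan(cov).any(axis=1)
    entry = c.table["entry_age"].to_numpy(dtype=float)
    exit_age = c.table["exit_age"].to_numpy(dtype=float)
    event = c.table["event"].to_numpy(dtype=int)
    w_all = np.ones(len(c)) if weights is None else np.asarray(weights, float)
    robust = weights is not None

    eaf = g.eaf()
    rows = []
    for j in range(g.n_variants):
        dos = g.dosages[:, j]
        ok = complete & ~np.isnan(dos)
        meta = g.variants.iloc[j]
        base = {
            "variant_id": meta["variant_id"], "chr": meta["chr"],
            "pos": meta["pos"], "ea": meta["ea"], "oa": meta["oa"],
            "eaf": eaf[j], "n": int(ok.sum()),
        }
        d = dos[ok]
        if ok.sum() < 2 or np.all(d == d[0]) or event[ok].sum() == 0:
            rows.append({**base, "beta": np.nan, "se": np.nan,
                         "p": np.nan, "converged": False})
            continue
        X = np.column_stack([d, cov[ok]])
        try:
            fit = fit_cox(X, exit_age[ok], event[ok], entry_age=entry[ok],
                          weights=w_all[ok], robust=robust)
        except (ConvergenceError, np.linalg.LinAlgError):
            rows.append({**base, "beta": np.nan, "se": np.nan,
                         "p": np.nan, "converged": False})
            continue
        se = (fit.robust_se if robust else fit.se)[0]
        beta = fit.beta[0]
        zval = beta / se if se > 0 else np.nan
        rows.append({**base, "beta": beta, "se": se,
                     "p": float(np.clip(2 * stats.norm.sf(abs(zval)),
                                        1e-300, 1.0)),
                     "converged": bool(fit.converged)})
    return pd.DataFrame(rows, columns=SUMSTATS_COLUMNS)
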