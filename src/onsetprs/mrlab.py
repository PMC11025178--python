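"""Two-sample Mendelian randomization screen.

Instruments are genome-wide-significant, LD-independent exposure variants
(clumping at p < 5e-8, 10 Mb window, r² < 0.001 against a reference
panel). After allele harmonization between the exposure and outcome tables,
:class:`TwoSampleMR` estimates the causal effect by fixed-effect
inverse-variance weighting of per-variant Wald ratios, by the weighted
median (robust to up to 50% invalid weight), and by MR-Egger regression
whose intercept indexes directional pleiotropy; Cochran's Q over the Wald
ratios tests instrument heterogeneity.

A trait passes the high-confidence filter when the IVW and weighted-median
estimates are directionally concordant and both nominally significant
(p < 0.05) while the heterogeneity and Egger-intercept p-values are both
>= 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .containers import GenotypeMatrix
from .exceptions import (InsufficientInstrumentsError, ValidationError)
from .prslab import clump

__all__ = ["MRDataset", "MRResult", "select_instruments", "harmonize",
           "harmonize_tables", "ivw", "weighted_median", "mr_egger",
           "heterogeneity_q", "high_confidence_filter", "TwoSampleMR",
           "TwoSampleMRResults"]

PALINDROMIC = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}
COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


@dataclass
class MRDataset:
    """Harmonized instrument table for one exposure-outcome pair."""
    instruments: pd.DataFrame   # variant_id, beta_exp, se_exp, beta_out,
    #                             se_out, ea, oa, eaf_exp, eaf_out, palindromic
    exposure_id: str = "exposure"
    outcome_id: str = "outcome"

    def __post_init__(self):
        need = {"variant_id", "beta_exp", "se_exp", "beta_out", "se_out"}
        if not need.issubset(self.instruments.columns):
            raise ValidationError(f"instrument table needs {sorted(need)}")
        t = self.instruments
        if t["variant_id"].duplicated().any():
            raise ValidationError("duplicate instrument ids")
        if ((t["se_exp"] <= 0) | (t["se_out"] <= 0)).any():
            raise ValidationError("non-positive instrument SE")

    @property
    def n_iv(self) -> int:
        return len(self.instruments)

    def wald_ratios(self) -> tuple[np.ndarray, np.ndarray]:
        """First-order Wald ratios and their SEs; drops beta_exp == 0."""
        t = self.instruments
        be = t["beta_exp"].to_numpy(dtype=float)
        keep = be != 0
        ratio = t["beta_out"].to_numpy(float)[keep] / be[keep]
        se = t["se_out"].to_numpy(float)[keep] / np.abs(be[keep])
        return ratio, se


def select_instruments(exposure_stats: pd.DataFrame,
                       reference: GenotypeMatrix,
                       p_max: float = 5e-8,
                       r2_max: float = 0.001,
                       window_kb: float = 10_000.0) -> list[str]:
    """Index variants of the exposure after stringent clumping."""
    result = clump(exposure_stats, reference, p_index=p_max,
                   r2_max=r2_max, window_kb=window_kb)
    return result.index_variants


def harmonize(exposure_row: pd.Series, outcome_row: pd.Series,
              palindromic_eaf_max: float = 0.42) -> dict | None:
    """Align one outcome record to the exposure's effect allele.

    Returns the harmonized instrument dict, or ``None`` with the drop
    reason recorded under key ``'reason'`` being absent (callers inspect
    the return value). Matching alleles pass unchanged; swapped alleles
    flip the outcome beta (and frequency); a strand flip (complement) is
    resolved first; palindromic variants are aligned by allele frequency
    unless the frequency is too close to 0.5 to call
    (min(eaf, 1-eaf) > ``palindromic_eaf_max``), in which case they drop.
    """
    ea_e, oa_e = str(exposure_row["ea"]), str(exposure_row["oa"])
    ea_o, oa_o = str(outcome_row["ea"]), str(outcome_row["oa"])
    beta_out = float(outcome_row["beta"])
    eaf_out = float(outcome_row.get("eaf", np.nan))
    eaf_exp = float(exposure_row.get("eaf", np.nan))
    palindromic = (ea_e, oa_e) in PALINDROMIC

    def entry(beta_out, eaf_out, action):
        return {
            "variant_id": exposure_row["variant_id"],
            "beta_exp": float(exposure_row["beta"]),
            "se_exp": float(exposure_row["se"]),
            "beta_out": beta_out, "se_out": float(outcome_row["se"]),
            "ea": ea_e, "oa": oa_e,
            "eaf_exp": eaf_exp, "eaf_out": eaf_out,
            "palindromic": palindromic, "action": action,
        }

    if palindromic:
        if not np.isnan(eaf_exp) and min(eaf_exp, 1 - eaf_exp) > palindromic_eaf_max:
            return None  # ambiguous: frequency too close to 0.5
        if (ea_o, oa_o) not in PALINDROMIC:
            return None  # irreconcilable coding
        # align by frequency: same-side frequencies mean same allele
        if np.isnan(eaf_exp) or np.isnan(eaf_out):
            return None
        same = (eaf_exp - 0.5) * (eaf_out - 0.5) >= 0
        if same:
            return entry(beta_out, eaf_out, "kept")
        return entry(-beta_out, 1 - eaf_out, "flipped")

    if (ea_o, oa_o) == (ea_e, oa_e):
        return entry(beta_out, eaf_out, "kept")
    if (ea_o, oa_o) == (oa_e, ea_e):
        return entry(-beta_out, 1 - eaf_out, "flipped")
    # try strand flip
    ea_c = COMPLEMENT.get(ea_o)
    oa_c = COMPLEMENT.get(oa_o)
    if (ea_c, oa_c) == (ea_e, oa_e):
        return entry(beta_out, eaf_out, "strand")
    if (ea_c, oa_c) == (oa_e, ea_e):
        return entry(-beta_out, 1 - eaf_out, "strand+flipped")
    return None


def harmonize_tables(exposure: pd.DataFrame, outcome: pd.DataFrame,
                     exposure_id: str = "exposure",
                     outcome_id: str = "outcome",
                     palindromic_eaf_max: float = 0.42) -> MRDataset:
    """Harmonize full exposure/outcome tables on shared variant ids."""
    out_ix = outcome.set_index("variant_id")
    rows = []
    for _, erow in exposure.iterrows():
        v = erow["variant_id"]
        if v not in out_ix.index:
            continue
        orow = out_ix.loc[v]
        orow = orow.copy()
        orow["variant_id"] = v
        h = harmonize(erow, orow, palindromic_eaf_max)
        if h is not None:
            rows.append(h)
    cols = ["variant_id", "beta_exp", "se_exp", "beta_out", "se_out",
            "ea", "oa", "eaf_exp", "eaf_out", "palindromic", "action"]
    return MRDataset(pd.DataFrame(rows, columns=cols),
                     exposure_id=exposure_id, outcome_id=outcome_id)


def ivw(d: MRDataset, method: str = "fixed"
        ) -> tuple[float, float, float, pd.DataFrame]:
    """Inverse-variance-weighted estimate over Wald ratios.

    ``method='fixed'`` is the classic fixed-effect estimator;
    ``method='mre'`` inflates the SE by the multiplicative residual error
    (sqrt(Q/df), floored at 1) as in random-effect IVW.
    """
    ratio, se = d.wald_ratios()
    if len(ratio) < 1:
        raise InsufficientInstrumentsError("IVW needs >= 1 valid instrument")
    w = 1.0 / se ** 2
    est = float((w * ratio).sum() / w.sum())
    est_se = float(np.sqrt(1.0 / w.sum()))
    if method == "mre" and len(ratio) > 2:
        q = float((w * (ratio - est) ** 2).sum())
        est_se *= max(1.0, np.sqrt(q / (len(ratio) - 1)))
    elif method not in ("fixed", "mre"):
        raise ValidationError(f"unknown IVW method {method!r}")
    p = float(np.clip(2 * stats.norm.sf(abs(est / est_se)), 1e-300, 1.0))
    per_iv = pd.DataFrame({"variant_id": d.instruments.loc[
        d.instruments["beta_exp"] != 0, "variant_id"].to_numpy(),
        "wald_ratio": ratio, "wald_se": se})
    return est, est_se, p, per_iv


def _weighted_median_point(ratio: np.ndarray, w: np.ndarray) -> float:
    order = np.argsort(ratio)
    r = ratio[order]
    ww = w[order]
    cum = np.cumsum(ww) - ww / 2.0
    cum = cum / ww.sum()
    if cum[0] >= 0.5:
        return float(r[0])
    if cum[-1] < 0.5:
        return float(r[-1])
    below = int(np.searchsorted(cum, 0.5, side="left")) - 1
    frac = (0.5 - cum[below]) / (cum[below + 1] - cum[below])
    return float(r[below] + frac * (r[below + 1] - r[below]))


def weighted_median(d: MRDataset, n_boot: int = 1000,
                    seed: int = 0) -> tuple[float, float, float]:
    """Weighted-median estimate with seeded parametric-bootstrap SE."""
    if d.n_iv < 3:
        raise InsufficientInstrumentsError("weighted median needs >= 3 IVs")
    ratio, se = d.wald_ratios()
    if len(ratio) < 3:
        raise InsufficientInstrumentsError(
            "weighted median needs >= 3 usable IVs")
    w = 1.0 / se ** 2
    est = _weighted_median_point(ratio, w)

    t = d.instruments.loc[d.instruments["beta_exp"] != 0]
    be = t["beta_exp"].to_numpy(float)
    bo = t["beta_out"].to_numpy(float)
    se_e = t["se_exp"].to_numpy(float)
    se_o = t["se_out"].to_numpy(float)
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for i in range(n_boot):
        be_b = be + rng.normal(0.0, se_e)
        bo_b = bo + rng.normal(0.0, se_o)
        ok = be_b != 0
        r_b = bo_b[ok] / be_b[ok]
        w_b = (np.abs(be_b[ok]) / se_o[ok]) ** 2
        boots[i] = _weighted_median_point(r_b, w_b)
    est_se = float(boots.std(ddof=1))
    if est_se == 0:
        p = 0.0 if est != 0 else 1.0
    else:
        p = float(np.clip(2 * stats.norm.sf(abs(est / est_se)), 1e-300, 1.0))
    return est, est_se, p


def mr_egger(d: MRDataset) -> dict:
    """MR-Egger weighted regression with intercept.

    Outcome effects are sign-oriented so exposure effects are positive,
    then regressed on |beta_exp| with weights 1/se_out²; the intercept
    two-sided t-test (n_iv - 2 df) indexes directional pleiotropy.
    """
    if d.n_iv < 3:
        raise InsufficientInstrumentsError("MR-Egger needs >= 3 IVs")
    t = d.instruments.loc[d.instruments["beta_exp"] != 0]
    if len(t) < 3:
        raise InsufficientInstrumentsError("MR-Egger needs >= 3 usable IVs")
    sign = np.sign(t["beta_exp"].to_numpy(float))
    x = np.abs(t["beta_exp"].to_numpy(float))
    y = t["beta_out"].to_numpy(float) * sign
    w = 1.0 / t["se_out"].to_numpy(float) ** 2

    import statsmodels.api as sm
    X = sm.add_constant(x)
    res = sm.WLS(y, X, weights=w).fit()
    intercept, slope = float(res.params[0]), float(res.params[1])
    int_se, slope_se = float(res.bse[0]), float(res.bse[1])
    df = len(t) - 2
    int_p = float(np.clip(2 * stats.t.sf(abs(intercept / int_se), df),
                          1e-300, 1.0)) if int_se > 0 else (1.0 if intercept == 0 else 0.0)
    slope_p = float(np.clip(2 * stats.t.sf(abs(slope / slope_se), df),
                            1e-300, 1.0)) if slope_se > 0 else (1.0 if slope == 0 else 0.0)
    return {"slope": slope, "slope_se": slope_se, "slope_p": slope_p,
            "intercept": intercept, "intercept_se": int_se,
            "intercept_p": int_p, "df": df}


def heterogeneity_q(d: MRDataset) -> tuple[float, int, float]:
    """Cochran's Q of Wald ratios about the IVW estimate."""
    ratio, se = d.wald_ratios()
    if len(ratio) < 2:
        raise InsufficientInstrumentsError("Q needs >= 2 usable IVs")
    w = 1.0 / se ** 2
    est = (w * ratio).sum() / w.sum()
    q = float((w * (ratio - est) ** 2).sum())
    df = len(ratio) - 1
    p = float(stats.chi2.sf(q, df))
    return q, df, p


@dataclass
class MRResult:
    """All estimator outputs for one exposure-outcome pair."""
    exposure_id: str
    outcome_id: str
    n_iv: int
    ivw: tuple[float, float, float]              # (estimate, se, p)
    weighted_median: tuple[float, float, float]
    egger: dict
    q: tuple[float, int, float]                  # (Q, df, p)
    high_confidence: bool = False
    reasons: list[str] = field(default_factory=list)

    def as_row(self) -> dict:
        return {
            "exposure": self.exposure_id, "outcome": self.outcome_id,
            "n_iv": self.n_iv,
            "ivw_beta": self.ivw[0], "ivw_se": self.ivw[1], "ivw_p": self.ivw[2],
            "wm_beta": self.weighted_median[0],
            "wm_se": self.weighted_median[1], "wm_p": self.weighted_median[2],
            "egger_slope": self.egger["slope"],
            "egger_intercept": self.egger["intercept"],
            "egger_intercept_p": self.egger["intercept_p"],
            "q": self.q[0], "q_df": self.q[1], "q_p": self.q[2],
            "high_confidence": self.high_confidence,
            "reasons": ";".join(self.reasons),
        }


def high_confidence_filter(r: MRResult) -> tuple[bool, list[str]]:
    """Apply the high-confidence trait criteria.

    Pass requires: directionally concordant IVW and weighted-median
    estimates, both with p < 0.05; heterogeneity p >= 0.05; Egger
    intercept p >= 0.05. Failing criteria are listed by name.
    """
    for name, val in [("ivw", r.ivw), ("weighted_median", r.weighted_median),
                      ("egger", r.egger), ("q", r.q)]:
        if val is None:
            raise ValidationError(f"missing component result: {name}")
    reasons = []
    if np.sign(r.ivw[0]) != np.sign(r.weighted_median[0]):
        reasons.append("directional discordance")
    if not (r.ivw[2] < 0.05):
        reasons.append("ivw not significant")
    if not (r.weighted_median[2] < 0.05):
        reasons.append("weighted median not significant")
    if not (r.q[2] >= 0.05):
        reasons.append("heterogeneity")
    if not (r.egger["intercept_p"] >= 0.05):
        reasons.append("pleiotropy")
    return len(reasons) == 0, reasons


class TwoSampleMR:
    """Two-sample MR model over a harmonized instrument set.

    ``fit()`` runs IVW, weighted median, MR-Egger and Cochran's Q, applies
    the high-confidence filter, and returns a results object.
    """

    def __init__(self, dataset: MRDataset, ivw_method: str = "fixed"):
        self.dataset = dataset
        self.ivw_method = ivw_method

    def fit(self, n_boot: int = 1000, seed: int = 0) -> "TwoSampleMRResults":
        d = self.dataset
        ivw_est = ivw(d, method=self.ivw_method)[:3]
        wm = weighted_median(d, n_boot=n_boot, seed=seed)
        egger = mr_egger(d)
        q = heterogeneity_q(d)
        result = MRResult(
            exposure_id=d.exposure_id, outcome_id=d.outcome_id,
            n_iv=d.n_iv, ivw=ivw_est, weighted_median=wm, egger=egger, q=q)
        result.high_confidence, result.reasons = high_confidence_filter(result)
        return TwoSampleMRResults(self, result)


class TwoSampleMRResults:
    def __init__(self, model: TwoSampleMR, result: MRResult):
        self.model = model
        self.result = result

    def __getattr__(self, name):
        return getattr(self.result, name)

    def summary(self) -> str:
        r = self.result
        lines = [
            f"Two-sample MR: {r.exposure_id} -> {r.outcome_id} "
            f"({r.n_iv} instruments)",
            f"{'method':<18}{'beta':>9}{'se':>9}{'p':>11}",
            f"{'IVW':<18}{r.ivw[0]:>9.4f}{r.ivw[1]:>9.4f}{r.ivw[2]:>11.3g}",
            f"{'weighted median':<18}{r.weighted_median[0]:>9.4f}"
            f"{r.weighted_median[1]:>9.4f}{r.weighted_median[2]:>11.3g}",
            f"{'Egger slope':<18}{r.egger['slope']:>9.4f}"
            f"{r.egger['slope_se']:>9.4f}{r.egger['slope_p']:>11.3g}",
            f"Egger intercept = {r.egger['intercept']:.4f} "
            f"(p = {r.egger['intercept_p']:.3g})",
            f"Cochran Q = {r.q[0]:.3f} on {r.q[1]} df (p = {r.q[2]:.3g})",
            f"high confidence: {r.high_confidence}"
            + (f" [{'; '.join(r.reasons)}]" if r.reasons else ""),
        ]
        return "\n".join(lines)
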