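"""LD computation, greedy clumping, PRS construction and merging.

Clumping follows the classic greedy scheme: repeatedly promote the
unassigned variant with the smallest p-value (below the index threshold) to
clump index, then absorb every unassigned variant on the same chromosome
within the window whose dosage r² with the index reaches the threshold.
For score construction the clump members are discarded and the indices kept
("independent variants"); the full membership is preserved in the result.

PRS_j = sum_i w_i * dosage_ij after aligning each entry's effect allele to
the genotype matrix; a missing call contributes 2 x effect-allele frequency.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import GenotypeMatrix, PRSModel
from .exceptions import (InsufficientDataError, InsufficientVariationError,
                         MissingVariantError, ValidationError)

__all__ = ["ld_r2", "clump", "ClumpResult", "compute_prs",
           "standardize_and_quintile", "merge_prs"]


def ld_r2(g: GenotypeMatrix, v1: str, v2: str) -> float:
    """Squared Pearson correlation of two dosage vectors.

    Computed over pairwise-complete samples (composite LD from unphased
    dosages).
    """
    d1 = g.dosage_vector(v1)
    d2 = g.dosage_vector(v2)
    return _r2_vec(d1, d2)


def _r2_vec(d1: np.ndarray, d2: np.ndarray) -> float:
    ok = ~np.isnan(d1) & ~np.isnan(d2)
    if ok.sum() < 2:
        raise InsufficientDataError(
            f"only {int(ok.sum())} pairwise-complete samples")
    a, b = d1[ok], d2[ok]
    if np.all(a == a[0]) or np.all(b == b[0]):
        raise InsufficientVariationError("constant dosage vector")
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


@dataclass
class ClumpResult:
    """Clump membership plus the thresholds that produced it."""
    clumps: list[tuple[str, list[str]]]
    p_index: float
    r2_max: float
    window_kb: float

    @property
    def index_variants(self) -> list[str]:
        return [idx for idx, _ in self.clumps]

    def membership(self) -> pd.DataFrame:
        rows = []
        for idx, members in self.clumps:
            rows.append({"index_variant": idx, "variant_id": idx, "role": "index"})
            for m in members:
                rows.append({"index_variant": idx, "variant_id": m,
                             "role": "member"})
        return pd.DataFrame(rows,
                            columns=["index_variant", "variant_id", "role"])


def clump(stats: pd.DataFrame,
          g: GenotypeMatrix,
          p_index: float = 1e-5,
          r2_max: float = 0.8,
          window_kb: float = 10_000.0) -> ClumpResult:
    """Greedy LD clumping of an association table.

    Only variants with ``p < p_index`` participate. Ties on p are broken by
    smaller (chr, pos), which makes the output invariant to input row
    order. Variants whose r² with the current index cannot be computed
    (constant dosage) are left unassigned.
    """
    need = {"variant_id", "chr", "pos", "p"}
    if not need.issubset(stats.columns):
        raise ValidationError(f"stats table needs columns {sorted(need)}")
    cand = stats.loc[stats["p"].notna() & (stats["p"] < p_index),
                     ["variant_id", "chr", "pos", "p"]].copy()
    cand = cand.sort_values(["p", "chr", "pos"], kind="stable")
    ids = set(g.variants["variant_id"])
    missing = [v for v in cand["variant_id"] if v not in ids]
    if missing:
        raise ValidationError(
            f"{len(missing)} clump candidates absent from genotypes "
            f"(e.g. {missing[:3]})")

    unassigned = dict.fromkeys(cand["variant_id"])  # ordered set
    info = cand.set_index("variant_id")
    clumps: list[tuple[str, list[str]]] = []
    while unassigned:
        index_v = next(iter(unassigned))
        del unassigned[index_v]
        chrom = info.at[index_v, "chr"]
        pos = info.at[index_v, "pos"]
        d_index = g.dosage_vector(index_v)
        members = []
        for v in list(unassigned):
            if info.at[v, "chr"] != chrom:
                continue
            if abs(info.at[v, "pos"] - pos) > window_kb * 1000.0:
                continue
            try:
                r2 = _r2_vec(d_index, g.dosage_vector(v))
            except InsufficientDataError:
                continue
            if r2 >= r2_max:
                members.append(v)
                del unassigned[v]
        clumps.append((index_v, members))
    return ClumpResult(clumps, p_index, r2_max, window_kb)


def compute_prs(g: GenotypeMatrix,
                model: PRSModel,
                max_missing_fraction: float = 0.2) -> pd.DataFrame:
    """Score each sample under a PRS model.

    Effect alleles are aligned to the matrix (an allele swap flips the
    dosage to ``2 - dosage``); a missing call is imputed as twice the
    effect-allele frequency observed in the matrix. Returns columns
    ``sample_id, score, n_imputed`` plus the list of model variants absent
    from the matrix in ``DataFrame.attrs['missing_variants']``.
    """
    ids = {v: i for i, v in enumerate(g.variants["variant_id"])}
    eaf = g.eaf()
    score = np.zeros(g.n_samples)
    n_imputed = np.zeros(g.n_samples, dtype=int)
    absent = []
    for row in model.entries.itertuples(index=False):
        j = ids.get(row.variant_id)
        if j is None:
            absent.append(row.variant_id)
            continue
        mat_ea = g.variants.at[j, "ea"]
        mat_oa = g.variants.at[j, "oa"]
        dos = g.dosages[:, j]
        f = eaf[j]
        if row.effect_allele == mat_ea:
            pass
        elif row.effect_allele == mat_oa:
            dos = 2.0 - dos
            f = 1.0 - f
        else:
            absent.append(row.variant_id)
            continue
        miss = np.isnan(dos)
        filled = np.where(miss, 2.0 * f, dos)
        score += row.weight * filled
        n_imputed += miss.astype(int)
    if len(model) and len(absent) / len(model) > max_missing_fraction:
        raise MissingVariantError(
            f"{len(absent)}/{len(model)} model variants unusable "
            f"(> {max_missing_fraction:.0%})")
    out = pd.DataFrame({"sample_id": g.samples, "score": score,
                        "n_imputed": n_imputed})
    out.attrs["missing_variants"] = absent
    return out


def standardize_and_quintile(scores: np.ndarray,
                             reference_scores: np.ndarray
                             ) -> tuple[np.ndarray, np.ndarray]:
    """Z-scores and quintile labels against a reference distribution.

    Cut points are the reference 20/40/60/80 percentiles; intervals are
    left-open, right-closed except the lowest (a score equal to a cut point
    falls in the lower quintile; anything below the minimum is quintile 1).
    """
    reference_scores = np.asarray(reference_scores, dtype=float)
    scores = np.asarray(scores, dtype=float)
    if reference_scores.size == 0:
        raise ValidationError("empty reference for standardization")
    mu = reference_scores.mean()
    sd = reference_scores.std(ddof=1) if reference_scores.size > 1 else 0.0
    if sd == 0:
        raise ValidationError("zero reference variance; cannot standardize")
    z = (scores - mu) / sd
    cuts = np.percentile(reference_scores, [20, 40, 60, 80])
    quintile = 1 + (scores[:, None] > cuts[None, :]).sum(axis=1)
    return z, quintile.astype(int)


def merge_prs(reported: PRSModel,
              gwas_hits: pd.DataFrame,
              g: GenotypeMatrix,
              r2_replace: float = 0.8,
              name: str = "merged") -> PRSModel:
    """Union of a reported score with scan hits not in LD with it.

    Every reported entry is kept with its reported weight. A scan hit whose
    r² with any reported variant reaches ``r2_replace`` is dropped (it is
    'replaced by' the reported variant); the remaining hits enter with
    their scanned beta. When either variant of a pair is absent from the
    reference genotypes the pair's LD is unknowable and treated as
    independent.
    """
    if not (0.0 < r2_replace <= 1.0):
        raise ValidationError("r2_replace must be in (0, 1]")
    ids = set(g.variants["variant_id"])
    rep = reported.entries.copy()
    rep["provenance"] = "reported"
    reported_present = [v for v in rep["variant_id"] if v in ids]
    rep_dos = {v: g.dosage_vector(v) for v in reported_present}

    kept_hits = []
    for row in gwas_hits.itertuples(index=False):
        if row.variant_id in set(rep["variant_id"]):
            continue  # identical variant: reported weight wins
        replaced = False
        if row.variant_id in ids:
            d = g.dosage_vector(row.variant_id)
            for v in reported_present:
                try:
                    if _r2_vec(d, rep_dos[v]) >= r2_replace:
                        replaced = True
                        break
                except InsufficientDataError:
                    continue
        if not replaced:
            kept_hits.append({
                "variant_id": row.variant_id, "chr": row.chr, "pos": row.pos,
                "effect_allele": row.ea, "other_allele": row.oa,
                "weight": row.beta, "provenance": "gwas",
            })
    cols = ["variant_id", "chr", "pos", "effect_allele", "other_allele",
            "weight", "provenance"]
    rep = rep.reindex(columns=cols)
    if kept_hits:
        merged = pd.concat([rep, pd.DataFrame(kept_hits, columns=cols)],
                           ignore_index=True)
    else:
        merged = rep
    return PRSModel(merged, name=name)
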