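"""Statistical layer: ANOVA with compact letter display, proportions, 2^-ΔΔCt.

These are the three quantitative summaries the phenotyping pipeline needs:

* one-way ANOVA across genotype groups with a post-hoc test (Tukey HSD by
  default, Fisher LSD optionally) converted to a compact letter display —
  groups that share a letter are not significantly different at ``alpha``;
* binomial proportion scoring with a Wilson confidence interval (stable at
  the small counts a mininuclei screen produces);
* relative expression by the 2^-ΔΔCt method: per sample
  ΔCt = Ct_target − Ct_reference, ΔΔCt = ΔCt − mean calibrator ΔCt, and
  relative expression 2^(−ΔΔCt).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.proportion import proportion_confint

from .errors import ValidationError


# ---------------------------------------------------------------------------
# ANOVA + compact letter display


@dataclass
class AnovaGroups:
    """One-way ANOVA result with per-group significance letters."""

    f_statistic: float
    p_value: float
    alpha: float
    posthoc: str
    table: pd.DataFrame          # group, n, mean, letters (sorted by mean desc)
    pairwise_p: pd.DataFrame     # symmetric matrix of post-hoc p-values

    def letters(self) -> dict[str, str]:
        return dict(zip(self.table["group"], self.table["letters"]))


def _compact_letter_display(groups: list[str], nonsig: set[frozenset]) -> dict[str, str]:
    """Letters from maximal cliques of the non-significance graph.

    Every maximal clique receives one letter, so two groups share a letter
    iff their pairwise comparison is non-significant — valid in both
    directions by construction.
    """
    g = nx.Graph()
    g.add_nodes_from(groups)
    g.add_edges_from(tuple(p) for p in nonsig)
    rank = {grp: i for i, grp in enumerate(groups)}
    cliques = sorted(nx.find_cliques(g), key=lambda c: min(rank[m] for m in c))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    if len(cliques) > len(alphabet):
        raise ValidationError("more letter groups than letters; too many groups")
    out = {grp: "" for grp in groups}
    for letter, clique in zip(alphabet, cliques):
        for member in clique:
            out[member] += letter
    return {grp: "".join(sorted(s)) for grp, s in out.items()}


def _lsd_pairwise(samples: dict[str, np.ndarray]) -> pd.DataFrame:
    """Unadjusted pairwise t-tests on the pooled within-group variance."""
    names = list(samples)
    n_tot = sum(len(v) for v in samples.values())
    k = len(names)
    mse = sum(((v - v.mean()) ** 2).sum() for v in samples.values()) / (n_tot - k)
    p = pd.DataFrame(np.ones((k, k)), index=names, columns=names)
    for i, a in enumerate(names):
        for j in range(i + 1, k):
            b = names[j]
            va, vb = samples[a], samples[b]
            se = np.sqrt(mse * (1 / len(va) + 1 / len(vb)))
            tstat = (va.mean() - vb.mean()) / se
            pval = 2 * sps.t.sf(abs(tstat), n_tot - k)
            p.iloc[i, j] = p.iloc[j, i] = pval
    return p


def anova_letters(values, groups, alpha: float = 0.05,
                  posthoc: str = "tukey") -> AnovaGroups:
    """One-way ANOVA with post-hoc compact letter groups.

    ``posthoc`` is ``"tukey"`` (HSD) or ``"lsd"`` (Fisher's unprotected
    LSD, the agricolae default).  Requires ≥2 groups with ≥2 observations
    each.
    """
    df = pd.DataFrame({"value": np.asarray(values, dtype=float),
                       "group": np.asarray(groups)})
    if df["value"].isna().any():
        raise ValidationError("values contain NaN")
    samples = {g: sub["value"].to_numpy() for g, sub in df.groupby("group", sort=False)}
    if len(samples) < 2:
        raise ValidationError("need at least two groups")
    for g, v in samples.items():
        if len(v) < 2:
            raise ValidationError(f"group {g!r} has fewer than 2 observations")

    f_stat, p_val = sps.f_oneway(*samples.values())

    names = sorted(samples, key=lambda g: -samples[g].mean())
    if posthoc == "tukey":
        res = sps.tukey_hsd(*(samples[g] for g in names))
        pmat = pd.DataFrame(res.pvalue, index=names, columns=names)
    elif posthoc == "lsd":
        pmat = _lsd_pairwise({g: samples[g] for g in names})
    else:
        raise ValidationError(f"unknown post-hoc method {posthoc!r}")

    nonsig = {
        frozenset((a, b))
        for i, a in enumerate(names)
        for b in names[i + 1:]
        if pmat.loc[a, b] > alpha
    }
    letters = _compact_letter_display(names, nonsig)
    table = pd.DataFrame({
        "group": names,
        "n": [len(samples[g]) for g in names],
        "mean": [samples[g].mean() for g in names],
        "letters": [letters[g] for g in names],
    })
    return AnovaGroups(f_statistic=float(f_stat), p_value=float(p_val),
                       alpha=alpha, posthoc=posthoc, table=table,
                       pairwise_p=pmat)


# ---------------------------------------------------------------------------
# proportions


@dataclass
class ProportionResult:
    """A scored proportion with its Wilson binomial confidence interval."""

    n_positive: int
    n_scored: int
    percent: float
    ci_low: float   # percent scale
    ci_high: float  # percent scale
    ci_level: float


def proportion(n_positive: int, n_scored: int,
               ci_level: float = 0.95) -> ProportionResult:
    """Percentage positive with a Wilson score interval (percent scale)."""
    if n_scored <= 0:
        raise ValidationError("n_scored must be positive")
    if not 0 <= n_positive <= n_scored:
        raise ValidationError("need 0 <= n_positive <= n_scored")
    lo, hi = proportion_confint(n_positive, n_scored, alpha=1 - ci_level,
                                method="wilson")
    return ProportionResult(
        n_positive=int(n_positive), n_scored=int(n_scored),
        percent=100.0 * n_positive / n_scored,
        ci_low=100.0 * float(lo), ci_high=100.0 * float(hi),
        ci_level=ci_level)


# ---------------------------------------------------------------------------
# 2^-ΔΔCt relative expression


@dataclass
class ExpressionResult:
    """Per-sample and per-genotype relative expression (2^-ΔΔCt)."""

    per_sample: pd.DataFrame    # sample_id, genotype, dct, ddct, relative_expression
    per_genotype: pd.DataFrame  # genotype, n, relative_expression, ci_low, ci_high
    calibrator: str
    excluded: list[str] = field(default_factory=list)


def ddct(ct_table: pd.DataFrame, calibrator_genotype: str,
         ci_level: float = 0.95) -> ExpressionResult:
    """Relative expression by the 2^-ΔΔCt method.

    ``ct_table`` is tidy with columns ``sample_id, genotype, gene
    ("target"/"reference"), ct``.  Per sample, ΔCt averages target Ct minus
    average reference Ct; ΔΔCt is taken against the mean calibrator ΔCt.
    Genotype summaries are computed on the ΔΔCt scale (so the point
    estimate is the geometric mean of 2^-ΔΔCt) with a t-based CI.  Samples
    missing either gene are excluded and reported, not fatal.
    """
    required = {"sample_id", "genotype", "gene", "ct"}
    missing = required - set(ct_table.columns)
    if missing:
        raise ValidationError(f"ct_table missing columns {sorted(missing)}")
    if (ct_table["ct"] <= 0).any():
        raise ValidationError("Ct values must be positive")

    rows, excluded = [], []
    for (sample, genotype), sub in ct_table.groupby(["sample_id", "genotype"], sort=False):
        target = sub.loc[sub["gene"] == "target", "ct"]
        ref = sub.loc[sub["gene"] == "reference", "ct"]
        if target.empty or ref.empty:
            excluded.append(str(sample))
            continue
        rows.append((sample, genotype, float(target.mean() - ref.mean())))
    per_sample = pd.DataFrame(rows, columns=["sample_id", "genotype", "dct"])
    if per_sample.empty:
        raise ValidationError("no sample has both target and reference Ct")
    cal = per_sample[per_sample["genotype"] == calibrator_genotype]
    if cal.empty:
        raise ValidationError(f"calibrator genotype {calibrator_genotype!r} absent")
    per_sample["ddct"] = per_sample["dct"] - cal["dct"].mean()
    per_sample["relative_expression"] = 2.0 ** (-per_sample["ddct"])

    geno_rows = []
    for genotype, sub in per_sample.groupby("genotype", sort=False):
        dd = sub["ddct"].to_numpy()
        n = len(dd)
        mean_dd = dd.mean()
        if n > 1:
            half = sps.t.ppf(0.5 + ci_level / 2, n - 1) * dd.std(ddof=1) / np.sqrt(n)
        else:
            half = 0.0
        geno_rows.append((genotype, n, 2.0 ** (-mean_dd),
                          2.0 ** (-(mean_dd + half)), 2.0 ** (-(mean_dd - half))))
    per_genotype = pd.DataFrame(
        geno_rows,
        columns=["genotype", "n", "relative_expression", "ci_low", "ci_high"])
    return ExpressionResult(per_sample=per_sample, per_genotype=per_genotype,
                            calibrator=calibrator_genotype, excluded=excluded)
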