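"""Mixed-model genetics on the pattern trait: BLUP, heritability, haplotype tests.

The phenotype (genotype x year pattern-axis score) is modelled as

    y = X beta + Z u + e,

with year a categorical fixed effect (first year as reference), genotype a
random effect u ~ N(0, sigma_g^2 I) and residual e ~ N(0, sigma_r^2 I).
Variance components are estimated by REML with the likelihood profiled
down to a 1-D search over the variance ratio lambda = sigma_g^2 /
sigma_r^2; because genotype is the single grouping factor the matrix
algebra collapses to per-genotype sums (Woodbury identity), so fits are
exact and fast at any population size.  Genotype BLUPs are the shrunken
genotype means at the REML estimates, and broad-sense heritability is the
intra-class correlation h2 = sigma_g^2 / (sigma_g^2 + sigma_r^2).

Haplotype effects at a locus are assessed on the BLUPs by one-way ANOVA
and Tukey's HSD across diplotype groups and across presence/absence of a
focal haplotype, with a compact letter display at alpha = 0.05.
"""

from __future__ import annotations

import warnings as _warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "VarianceComponents",
    "NoGeneticContrastError",
    "fit_blup",
    "heritability",
    "haplotype_effect_test",
    "HaplotypeTestReport",
    "GroupComparison",
    "canonical_diplotype",
    "compact_letter_display",
]


class NoGeneticContrastError(ValueError):
    """Fewer than two genotypes: no genetic variance is estimable."""


@dataclass
class VarianceComponents:
    """REML variance components, fixed effects, BLUPs and heritability."""

    sigma_g2: float
    sigma_r2: float
    beta: pd.Series  # intercept + year effects (treatment coding)
    blups: pd.Series  # per-genotype predicted random effect
    h2: float
    convergence: dict


def _design(pheno: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, list, list]:
    genotypes = sorted(pheno["genotype"].unique())
    years = sorted(pheno["year"].unique())
    gidx = pheno["genotype"].map({g: i for i, g in enumerate(genotypes)}).to_numpy()
    n = len(pheno)
    x = np.ones((n, len(years)))
    names = ["intercept"]
    for j, yr in enumerate(years[1:], start=1):
        x[:, j] = (pheno["year"] == yr).to_numpy(float)
        names.append(f"year[{yr}]")
    return x, gidx, names, genotypes


def _profile_reml(lam: float, y, x, gidx, n_groups):
    """REML pieces at variance ratio lam, via per-genotype sums.

    H = I + lam Z Z'; H^{-1} v = v - Z d Z' v with d_i = lam/(1 + lam n_i).
    Returns (deviance, beta, sigma_r2, u).
    """
    n, p = x.shape
    n_i = np.bincount(gidx, minlength=n_groups).astype(float)
    d = lam / (1.0 + lam * n_i)

    def hinv(v):
        gs = np.zeros((n_groups,) + v.shape[1:])
        np.add.at(gs, gidx, v)
        return v - (d.reshape((-1,) + (1,) * (v.ndim - 1)) * gs)[gidx]

    hx = hinv(x)
    hy = hinv(y)
    a = x.T @ hx
    b = x.T @ hy
    beta = np.linalg.solve(a, b)
    quad = float(y @ hy - b @ beta)
    quad = max(quad, 0.0)
    sigma_r2 = quad / (n - p)
    logdet_h = float(np.log1p(lam * n_i).sum())
    sign, logdet_a = np.linalg.slogdet(a)
    if sigma_r2 <= 0.0:
        dev = -np.inf  # degenerate: perfect fit
    else:
        dev = (n - p) * np.log(sigma_r2) + logdet_h + logdet_a
    resid = y - x @ beta
    gs = np.zeros(n_groups)
    np.add.at(gs, gidx, hinv(resid))
    u = lam * gs
    return dev, beta, sigma_r2, u


def fit_blup(pheno: pd.DataFrame, response: str = "score") -> VarianceComponents:
    """REML fit of the year-fixed, genotype-random mixed model.

    ``pheno`` needs columns genotype, year and the response.  Duplicated
    (genotype, year) pairs are rejected.  If the REML optimum lies on the
    boundary the fit is returned with sigma_g2 = 0 and a convergence
    flag.  For balanced designs the estimates agree with the closed-form
    ANOVA solution.
    """
    for col in ("genotype", "year", response):
        if col not in pheno.columns:
            raise ValueError(f"phenotype table lacks the {col!r} column")
    if pheno.duplicated(subset=["genotype", "year"]).any():
        raise ValueError("duplicated (genotype, year) pair in phenotype table")
    if pheno["genotype"].nunique() < 2:
        raise NoGeneticContrastError("no genetic contrast: need >= 2 genotypes")
    y = pheno[response].to_numpy(dtype=np.float64)
    x, gidx, beta_names, genotypes = _design(pheno)
    q = len(genotypes)

    def objective(log_lam: float) -> float:
        dev = _profile_reml(np.exp(log_lam), y, x, gidx, q)[0]
        return dev if np.isfinite(dev) else -1e30

    lo, hi = -16.0, 16.0
    res = optimize.minimize_scalar(objective, bounds=(lo, hi), method="bounded")
    lam_hat = float(np.exp(res.x))
    dev_hat = float(res.fun)
    boundary = False
    # compare against the sigma_g2 = 0 boundary (lam -> 0)
    dev0 = _profile_reml(0.0, y, x, gidx, q)[0]
    if dev0 <= dev_hat or res.x < lo + 1e-6:
        lam_hat = 0.0
        boundary = True
    dev, beta, sigma_r2, u = _profile_reml(lam_hat, y, x, gidx, q)
    sigma_g2 = lam_hat * sigma_r2
    h2 = 0.0 if sigma_g2 == 0.0 else sigma_g2 / (sigma_g2 + sigma_r2)
    return VarianceComponents(
        sigma_g2=float(sigma_g2),
        sigma_r2=float(sigma_r2),
        beta=pd.Series(beta, index=beta_names),
        blups=pd.Series(u, index=genotypes, name="blup"),
        h2=float(h2),
        convergence={
            "iterations": int(res.nfev),
            "criterion": float(dev),
            "boundary": boundary,
        },
    )


def heritability(sigma_g2: float, sigma_r2: float) -> float:
    """Broad-sense heritability h2 = sigma_g2 / (sigma_g2 + sigma_r2)."""
    if sigma_g2 < 0 or sigma_r2 < 0:
        raise ValueError("variance components must be non-negative")
    total = sigma_g2 + sigma_r2
    if total == 0.0:
        raise ValueError("heritability undefined: both variance components are zero")
    return sigma_g2 / total


# ---------------------------------------------------------------------------
# haplotype / diplotype effect testing on BLUPs
# ---------------------------------------------------------------------------


def canonical_diplotype(hap1: str, hap2: str) -> str:
    """Unordered pair label, e.g. ('H2', 'H1') -> 'H1/H2'."""
    return "/".join(sorted([str(hap1), str(hap2)]))


@dataclass
class GroupComparison:
    """ANOVA + Tukey HSD + letters for one grouping of the BLUPs."""

    grouping: str
    descriptives: pd.DataFrame  # group, n, mean, sd, letter
    f_statistic: float
    df_between: int
    df_within: int
    p_value: float
    tukey: pd.DataFrame  # group1, group2, diff, p_adj, reject
    warnings: list = field(default_factory=list)


@dataclass
class HaplotypeTestReport:
    focal: str
    diplotype: GroupComparison
    presence: GroupComparison


def _anova(groups: list[np.ndarray]) -> tuple[float, int, int, float]:
    """One-way ANOVA with explicit handling of zero-variance degeneracies."""
    k = len(groups)
    n = sum(len(g) for g in groups)
    grand = np.concatenate(groups).mean()
    ssb = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df_b, df_w = k - 1, n - k
    if ssb <= 1e-12 * max(ssw, 1.0):
        return 0.0, df_b, df_w, 1.0
    if ssw == 0.0:
        return np.inf, df_b, df_w, 0.0
    f = (ssb / df_b) / (ssw / df_w)
    return float(f), df_b, df_w, float(stats.f.sf(f, df_b, df_w))


def _tukey(groups: dict[str, np.ndarray], df_w: int, msw: float) -> pd.DataFrame:
    """Tukey–Kramer adjusted pairwise p-values via the studentized range."""
    names = list(groups)
    k = len(names)
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            gi, gj = groups[names[i]], groups[names[j]]
            diff = gj.mean() - gi.mean()
            if msw == 0.0:
                p = 1.0 if diff == 0.0 else 0.0
            else:
                se = np.sqrt(msw / 2.0 * (1.0 / len(gi) + 1.0 / len(gj)))
                qstat = abs(diff) / se
                p = float(stats.studentized_range.sf(qstat, k, df_w))
            rows.append((names[i], names[j], float(diff), min(max(p, 0.0), 1.0)))
    out = pd.DataFrame(rows, columns=["group1", "group2", "diff", "p_adj"])
    out["reject"] = out["p_adj"] < 0.05
    return out


def compact_letter_display(
    names: list[str], tukey: pd.DataFrame, alpha: float = 0.05
) -> dict[str, str]:
    """Insert-and-absorb letter assignment.

    Groups sharing no letter differ significantly (adjusted p < alpha);
    any non-significant pair shares at least one letter.
    """
    columns: list[set] = [set(names)]
    sig_pairs = [
        (r.group1, r.group2) for r in tukey.itertuples() if r.p_adj < alpha
    ]
    for a, b in sig_pairs:
        new_cols = []
        for col in columns:
            if a in col and b in col:
                new_cols.append(col - {a})
                new_cols.append(col - {b})
            else:
                new_cols.append(col)
        # absorb columns that are subsets of another
        columns = [
            c
            for i, c in enumerate(new_cols)
            if c and not any(i != j and c < d or (c == d and i > j) for j, d in enumerate(new_cols))
        ]
    letters = {g: "" for g in names}
    for i, col in enumerate(columns):
        ch = chr(ord("a") + i)
        for g in names:
            if g in col:
                letters[g] += ch
    return letters


def _compare_groups(
    values: pd.Series, labels: pd.Series, grouping: str, alpha: float = 0.05
) -> GroupComparison:
    warn = []
    by = {
        str(name): grp.to_numpy(dtype=float)
        for name, grp in values.groupby(labels, sort=True)
    }
    desc = pd.DataFrame(
        [
            (name, len(v), v.mean(), v.std(ddof=1) if len(v) > 1 else np.nan)
            for name, v in by.items()
        ],
        columns=["group", "n", "mean", "sd"],
    )
    testable = {k: v for k, v in by.items() if len(v) >= 2}
    dropped = sorted(set(by) - set(testable))
    if dropped:
        warn.append(f"groups with < 2 members dropped from testing: {dropped}")
    if len(testable) < 2:
        raise ValueError(f"need >= 2 groups with >= 2 observations for {grouping!r}")
    arrays = list(testable.values())
    f, df_b, df_w, p = _anova(arrays)
    msw = sum(((g - g.mean()) ** 2).sum() for g in arrays) / df_w
    tukey = _tukey(testable, df_w, msw)
    letters = compact_letter_display(list(testable), tukey, alpha)
    desc["letter"] = desc["group"].map(lambda g: letters.get(g, ""))
    return GroupComparison(
        grouping=grouping,
        descriptives=desc,
        f_statistic=f,
        df_between=df_b,
        df_within=df_w,
        p_value=p,
        tukey=tukey,
        warnings=warn,
    )


def haplotype_effect_test(
    blups: pd.Series, assignment: pd.DataFrame, focal: str, alpha: float = 0.05
) -> HaplotypeTestReport:
    """Test haplotype effects on genotype BLUPs.

    ``assignment`` has columns genotype, hap1, hap2.  Two groupings are
    compared: the canonical diplotype (unordered haplotype pair), and the
    presence/absence of the ``focal`` haplotype.
    """
    asg = assignment.set_index("genotype")
    common = [g for g in blups.index if g in asg.index]
    if len(common) < len(blups):
        _warnings.warn(
            f"{len(blups) - len(common)} genotypes lack haplotype assignments", stacklevel=2
        )
    vals = blups.loc[common]
    dip = pd.Series(
        [canonical_diplotype(asg.loc[g, "hap1"], asg.loc[g, "hap2"]) for g in common],
        index=common,
    )
    pres = pd.Series(
        [
            "present" if focal in (str(asg.loc[g, "hap1"]), str(asg.loc[g, "hap2"])) else "absent"
            for g in common
        ],
        index=common,
    )
    return HaplotypeTestReport(
        focal=focal,
        diplotype=_compare_groups(vals, dip, "diplotype", alpha),
        presence=_compare_groups(vals, pres, f"{focal} presence", alpha),
    )
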