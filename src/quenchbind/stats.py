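"""Gated parametric group comparison with compact letter display.

Replicated assay data (typically triplicates) are compared the way the
food-chemistry literature reports them: Levene's test for homogeneity of
variance and a Kolmogorov-Smirnov (Lilliefors) normality check gate a
one-way ANOVA; pairwise Tukey HSD differences are then summarised as
compact letters, where two groups share a letter iff their difference is
non-significant at alpha.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from statsmodels.stats.diagnostic import lilliefors

__all__ = [
    "GroupedData",
    "LetterReport",
    "GateFailure",
    "levene",
    "ks_normality",
    "anova_cld",
    "compact_letters",
]


class GateFailure(RuntimeError):
    """A pre-test gate (Levene or K-S) failed and override was not set."""


@dataclass(frozen=True)
class GroupedData:
    groups: tuple[str, ...]
    values: tuple[np.ndarray, ...]

    def __post_init__(self):
        if len(self.groups) < 2:
            raise ValueError("need at least 2 groups")
        if len(self.groups) != len(self.values):
            raise ValueError("groups and values must align")
        vals = tuple(np.asarray(v, dtype=float) for v in self.values)
        if any(v.size < 2 for v in vals):
            raise ValueError("each group needs at least 2 replicate values")
        object.__setattr__(self, "groups", tuple(self.groups))
        object.__setattr__(self, "values", vals)

    @classmethod
    def from_frame(cls, df, group: str, value: str) -> "GroupedData":
        names, arrays = [], []
        for name, sub in df.groupby(group, sort=False):
            names.append(str(name))
            arrays.append(sub[value].to_numpy(dtype=float))
        return cls(groups=tuple(names), values=tuple(arrays))


@dataclass(frozen=True)
class LetterReport:
    groups: tuple[str, ...]
    means: tuple[float, ...]
    sds: tuple[float, ...]
    letters: tuple[str, ...]  # e.g. "A", "AB"
    alpha: float


def levene(g: GroupedData) -> tuple[float, float]:
    """Levene's test with center = mean (the classical form)."""
    if all(np.ptp(v) == 0 for v in g.values):
        # identical spread everywhere: homogeneous by definition
        return 0.0, 1.0
    stat, p = sps.levene(*g.values, center="mean")
    return float(stat), float(p)


def ks_normality(
    values,
    pvalue_method: str = "table",
    n_mc: int = 2000,
    seed: int | None = None,
) -> tuple[float, float]:
    """One-sample K-S statistic against a normal with estimated parameters.

    D = sup |ECDF - Phi((x - mean)/sd)|.  Because the parameters are
    estimated from the data, p-values use Lilliefors' correction: the
    statsmodels table/approximation by default, or Monte Carlo
    (``pvalue_method='mc'``), which is the defensible choice at very small n.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 values for a normality check")
    if np.ptp(x) == 0:
        raise ValueError("degenerate constant sample: normality undefined")
    if pvalue_method == "mc":
        d = _lilliefors_d(x)
        rng = np.random.default_rng(seed)
        sims = np.array(
            [_lilliefors_d(rng.standard_normal(x.size)) for _ in range(n_mc)]
        )
        p = float((np.sum(sims >= d) + 1) / (n_mc + 1))
        return float(d), p
    d, p = lilliefors(x, dist="norm", pvalmethod=pvalue_method)
    return float(d), float(p)


def _lilliefors_d(x: np.ndarray) -> float:
    z = np.sort((x - x.mean()) / x.std(ddof=1))
    cdf = sps.norm.cdf(z)
    n = z.size
    ecdf_hi = np.arange(1, n + 1) / n
    ecdf_lo = np.arange(0, n) / n
    return float(max(np.max(ecdf_hi - cdf), np.max(cdf - ecdf_lo)))


def compact_letters(
    groups: tuple[str, ...],
    means: np.ndarray,
    significant: np.ndarray,
) -> tuple[str, ...]:
    """Insert-absorb compact letter display.

    ``significant[i, j]`` marks pairs whose means differ at alpha.  Columns
    (letter classes) start as one all-group class; every significant pair
    splits each class containing both; subset classes are absorbed.  Letters
    are ordered so that 'A' contains the largest mean (ties by group order).
    """
    k = len(groups)
    classes: list[set[int]] = [set(range(k))]
    for i in range(k):
        for j in range(i + 1, k):
            if not significant[i, j]:
                continue
            for cls in [c for c in classes if i in c and j in c]:
                classes.remove(cls)
                a, b = cls - {i}, cls - {j}
                for new in (a, b):
                    if new and not any(new <= c for c in classes):
                        classes.append(new)
            classes = [c for c in classes if not any(c < d for d in classes)]
    # order classes by the largest mean they contain, descending
    order = np.argsort([-means[i] for i in range(k)], kind="stable")
    rank = {int(g): r for r, g in enumerate(order)}
    classes.sort(key=lambda c: min(rank[i] for i in c))
    alphabet = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"
    letters = ["" for _ in range(k)]
    for li, cls in enumerate(classes):
        for i in cls:
            letters[i] += alphabet[li % 26]
    return tuple("".join(sorted(s)) for s in letters)


def anova_cld(
    g: GroupedData,
    alpha: float = 0.05,
    override_gates: bool = False,
    gate_alpha: float = 0.05,
    ks_pvalue_method: str = "table",
) -> tuple[float, float, LetterReport, dict]:
    """One-way ANOVA with Tukey HSD letters, gated on Levene and K-S checks.

    The normality gate runs on pooled group-centered residuals, since per-
    group triplicates carry no information about distribution shape.  A
    failed gate raises :class:`GateFailure` naming the gate, unless
    ``override_gates`` is set; the gate outcomes are always returned.
    """
    lv_stat, lv_p = levene(g)
    resid = np.concatenate([v - v.mean() for v in g.values])
    ks_stat, ks_p = ks_normality(resid, pvalue_method=ks_pvalue_method)
    gates = {
        "levene": {"statistic": lv_stat, "p": lv_p, "passed": lv_p >= gate_alpha},
        "ks": {"statistic": ks_stat, "p": ks_p, "passed": ks_p >= gate_alpha},
    }
    for name, res in gates.items():
        if not res["passed"] and not override_gates:
            raise GateFailure(
                f"{name} gate failed (p = {res['p']:.4g} < {gate_alpha}); "
                "parametric ANOVA not applicable without override_gates=True"
            )

    if all(np.ptp(v) == 0 for v in g.values) and len({float(v[0]) for v in g.values}) == 1:
        f_stat, p = 0.0, 1.0
        sig = np.zeros((len(g.groups),) * 2, dtype=bool)
    else:
        f_stat, p = sps.f_oneway(*g.values)
        tukey = sps.tukey_hsd(*g.values)
        sig = tukey.pvalue < alpha
        np.fill_diagonal(sig, False)

    means = np.array([float(v.mean()) for v in g.values])
    sds = np.array([float(v.std(ddof=1)) for v in g.values])
    letters = compact_letters(g.groups, means, sig)
    report = LetterReport(
        groups=g.groups,
        means=tuple(means),
        sds=tuple(sds),
        letters=letters,
        alpha=alpha,
    )
    return float(f_stat), float(p), report, gates
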