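"""Replicate-level statistics for critical areal strains.

The factorial design crosses bilayer composition (pure DPPC vs DPPC + 40
mol% cholesterol) with stretching speed, with unequal replicate counts per
cell.  The procedure: a two-way ANOVA on eps_c (Type III sums of squares
with sum-to-zero contrasts, suited to interaction-first testing of
unbalanced designs); when the interaction is significant, simple main
effects of each factor within levels of the other against the pooled
residual of the full model; and Ryan's step-down multiple comparison over
the speed groups.  Also provides the cube-root reference-area scaling that
maps simulation-box critical strains to cell-scale membrane areas.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

ALPHA_DEFAULT = 0.05


class StatsError(ValueError):
    pass


@dataclass
class ReplicateGroup:
    """Critical-strain replicates for one (composition, speed) cell."""

    composition: str
    speed: float  # m/s
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.values) < 1:
            raise StatsError("each cell needs at least one replicate")
        if np.any(self.values <= -1):
            raise StatsError("areal strains must exceed -1")

    @property
    def n(self) -> int:
        return len(self.values)

    @property
    def mean(self) -> float:
        return float(self.values.mean())

    @property
    def sd(self) -> float:
        return float(self.values.std(ddof=1)) if self.n > 1 else float("nan")


@dataclass
class AnovaTable:
    """Two-way ANOVA summary: rows composition, speed, interaction, residual."""

    table: pd.DataFrame  # columns: source, sum_sq, df, F, p
    typ: str = "III"

    def row(self, source: str) -> pd.Series:
        hit = self.table[self.table["source"] == source]
        if hit.empty:
            raise StatsError(f"no ANOVA row {source!r}")
        return hit.iloc[0]

    @property
    def interaction_p(self) -> float:
        return float(self.row("interaction")["p"])

    @property
    def residual_ms(self) -> float:
        r = self.row("residual")
        return float(r["sum_sq"] / r["df"])

    @property
    def residual_df(self) -> float:
        return float(self.row("residual")["df"])


def _groups_to_frame(groups: list[ReplicateGroup]) -> pd.DataFrame:
    rows = []
    for g in groups:
        for v in g.values:
            rows.append({"composition": g.composition, "speed": g.speed, "eps_c": v})
    return pd.DataFrame(rows)


def _check_design(df: pd.DataFrame) -> None:
    comps = df["composition"].unique()
    speeds = df["speed"].unique()
    if len(comps) < 2 or len(speeds) < 2:
        raise StatsError("need at least two levels of each factor")
    cells = df.groupby(["composition", "speed"]).size()
    if len(cells) != len(comps) * len(speeds):
        raise StatsError("factorial design has empty cells")
    n = len(df)
    if n - len(comps) * len(speeds) <= 0:
        raise StatsError("no residual degrees of freedom")


def two_way_anova(groups: list[ReplicateGroup], typ: str = "III") -> AnovaTable:
    """Unbalanced two-way ANOVA of eps_c on composition x speed.

    Type III (default) uses sum-to-zero contrasts so each effect is tested
    adjusting for all others including the interaction; Type II is available
    for comparison.
    """
    import statsmodels.formula.api as smf
    from statsmodels.stats.anova import anova_lm

    if typ not in ("II", "III"):
        raise StatsError("typ must be 'II' or 'III'")
    df = _groups_to_frame(groups)
    _check_design(df)
    df = df.copy()
    df["speed"] = df["speed"].astype(str)  # categorical factor
    fit = smf.ols("eps_c ~ C(composition, Sum) * C(speed, Sum)", data=df).fit()
    raw = anova_lm(fit, typ=3 if typ == "III" else 2)
    name_map = {
        "C(composition, Sum)": "composition",
        "C(speed, Sum)": "speed",
        "C(composition, Sum):C(speed, Sum)": "interaction",
        "Residual": "residual",
    }
    rows = []
    for src, label in name_map.items():
        if src not in raw.index:
            continue
        r = raw.loc[src]
        rows.append({"source": label, "sum_sq": float(r["sum_sq"]),
                     "df": float(r["df"]),
                     "F": float(r.get("F", np.nan)),
                     "p": float(r.get("PR(>F)", np.nan))})
    return AnovaTable(pd.DataFrame(rows), typ=typ)


def synthetic_cell(n: int, mean: float, sd: float) -> np.ndarray:
    """n values with exactly the given sample mean and SD (ddof=1).

    The ANOVA depends on the raw data only through the cell means and
    within-cell sums of squares, so any such reconstruction reproduces the
    table computed from the original data exactly.
    """
    if n < 1:
        raise StatsError("n must be >= 1")
    if n == 1:
        return np.array([mean])
    base = np.arange(n, dtype=float)
    base -= base.mean()
    base /= base.std(ddof=1)
    return mean + sd * base


def anova_from_summary(cells: pd.DataFrame, typ: str = "III") -> AnovaTable:
    """Two-way ANOVA from per-cell sufficient statistics.

    ``cells`` columns: composition, speed, n, mean, sd.  Identical to
    :func:`two_way_anova` on any raw data having exactly those summaries.
    """
    groups = []
    for row in cells.itertuples(index=False):
        if row.n >= 2 and not np.isfinite(row.sd):
            raise StatsError(
                f"cell ({row.composition}, {row.speed}): SD required for n >= 2")
        groups.append(ReplicateGroup(row.composition, float(row.speed),
                                     synthetic_cell(int(row.n), row.mean,
                                                    row.sd if row.n > 1 else 0.0)))
    return two_way_anova(groups, typ=typ)


def simple_main_effects(groups: list[ReplicateGroup], which_factor: str,
                        full_table: AnovaTable | None = None) -> pd.DataFrame:
    """Effect of ``which_factor`` within each level of the other factor.

    Each slice's between-cell sum of squares is tested against the pooled
    residual mean square of the full two-way model.  Callers should test the
    interaction first; this function does not gate on it.
    """
    if which_factor not in ("composition", "speed"):
        raise StatsError("which_factor must be 'composition' or 'speed'")
    other = "speed" if which_factor == "composition" else "composition"
    if full_table is None:
        full_table = two_way_anova(groups)
    mse = full_table.residual_ms
    df_res = full_table.residual_df
    df = _groups_to_frame(groups)
    levels = sorted(df[other].unique())
    out = []
    for lev in levels:
        sl = df[df[other] == lev]
        cell_means = sl.groupby(which_factor)["eps_c"].agg(["mean", "size"])
        if len(cell_means) < 2:
            raise StatsError(f"level {lev!r}: factor {which_factor} not varied")
        grand = np.average(cell_means["mean"], weights=cell_means["size"])
        ss = float(np.sum(cell_means["size"] * (cell_means["mean"] - grand) ** 2))
        df_effect = len(cell_means) - 1
        f = (ss / df_effect) / mse
        p = float(sps.f.sf(f, df_effect, df_res))
        out.append({other: lev, "sum_sq": ss, "df": df_effect, "F": f, "p": p})
    return pd.DataFrame(out)


@dataclass
class PosthocPair:
    """One Ryan step-down comparison between two group means."""

    group_i: str
    group_j: str
    span: int        # ordered means covered, inclusive
    alpha_nominal: float
    p: float
    significant: bool


def ryan_posthoc(groups: list[ReplicateGroup], alpha: float = ALPHA_DEFAULT,
                 variant: str = "linear", mse: float | None = None,
                 df_resid: float | None = None,
                 label_by: str = "speed") -> list[PosthocPair]:
    """Ryan's step-down multiple comparison over k group means.

    Groups are ordered by mean; the pair spanning r ordered means is tested
    at the adjusted level alpha'(r), with the step-down constraint that a
    pair nested inside any non-significant span is not declared significant.

    ``linear`` (default): alpha'(r) = alpha * r / k and two-sided t p-values
    on the pooled residual variance.  This variant tracks published
    significance patterns from factorial stretching studies, but because the
    step-down gate tests the *selected* extreme pair with an unadjusted t
    statistic its familywise error under a complete null is controlled only
    loosely (see the methods note).

    ``regw``: alpha'(r) = 1 - (1 - alpha)^(r/k) for r <= k - 2 (alpha
    otherwise) and studentized-range p-values with the span's group count as
    the range parameter (Tukey-Kramer standard error for unequal n).  The
    full-span gate is then an exact range test, so the familywise error
    under a complete null is held at alpha.  For k = 2 both variants reduce
    to the ordinary two-sample t test (q with 2 means equals sqrt(2)|t|).

    ``mse``/``df_resid`` override the pooled within-group variance, e.g.
    with the residual mean square of the full factorial model.
    """
    k = len(groups)
    if k < 2:
        raise StatsError("need at least two groups")
    if variant not in ("linear", "regw"):
        raise StatsError("variant must be 'linear' or 'regw'")
    if (mse is None) != (df_resid is None):
        raise StatsError("mse and df_resid must be supplied together")
    if mse is None:
        num = sum((g.n - 1) * g.sd ** 2 for g in groups if g.n > 1)
        df_resid = sum(g.n - 1 for g in groups)
        if df_resid <= 0:
            raise StatsError("no within-group degrees of freedom")
        mse = num / df_resid

    order = sorted(range(k), key=lambda i: groups[i].mean)

    def label(g: ReplicateGroup) -> str:
        return str(getattr(g, label_by))

    def pair_p(a: int, b: int, r: int) -> float:
        ga, gb = groups[a], groups[b]
        if variant == "linear":
            se = np.sqrt(mse * (1.0 / ga.n + 1.0 / gb.n))
            t = abs(ga.mean - gb.mean) / se
            return float(2.0 * sps.t.sf(t, df_resid))
        se = np.sqrt(mse / 2.0 * (1.0 / ga.n + 1.0 / gb.n))
        q = abs(ga.mean - gb.mean) / se
        return float(sps.studentized_range.sf(q, r, df_resid))

    def alpha_adj(r: int) -> float:
        if variant == "linear":
            return alpha * r / k
        return alpha if r >= k - 1 else 1.0 - (1.0 - alpha) ** (r / k)

    # step-down over spans of ordered means, largest first; a span is tested
    # via its extreme pair, and failure retains every nested span
    significant: dict[tuple[int, int], bool] = {}
    retained: set[tuple[int, int]] = set()
    results = []
    for r in range(k, 1, -1):
        for a in range(0, k - r + 1):
            b = a + r - 1
            nested_in_retained = any(a >= ra and b <= rb for ra, rb in retained)
            p = pair_p(order[a], order[b], r)
            a_nom = alpha_adj(r)
            sig = (p <= a_nom) and not nested_in_retained
            if not sig:
                retained.add((a, b))
            significant[(a, b)] = sig
            results.append(PosthocPair(label(groups[order[a]]),
                                       label(groups[order[b]]),
                                       r, a_nom, p, sig))
    return results


def significant_pairs(pairs: list[PosthocPair]) -> set[frozenset]:
    return {frozenset((p.group_i, p.group_j)) for p in pairs if p.significant}


def scaled_critical_strain(epsilon_c: float, a_sim_nm2: float,
                           a_ref_um2: float) -> float:
    """Cube-root area scaling: eps_scaled = eps_c * (A_sim / A_ref)^(1/3).

    The critical areal strain of a membrane patch scales inversely with the
    cube root of its reference area, which maps simulation-box values
    (~42 nm^2) onto cell-scale membranes (~100-1000 um^2); 1 um^2 = 1e6 nm^2.
    """
    if a_sim_nm2 <= 0 or a_ref_um2 <= 0:
        raise StatsError("areas must be > 0")
    return epsilon_c * (a_sim_nm2 / (a_ref_um2 * 1e6)) ** (1.0 / 3.0)


# ---------------------------------------------------------------------------
# I/O helpers
# ---------------------------------------------------------------------------

def groups_from_dataframe(df: pd.DataFrame) -> list[ReplicateGroup]:
    """ReplicateGroups from a replicate table (composition, speed_m_per_s or
    speed, epsilon_c)."""
    speed_col = "speed_m_per_s" if "speed_m_per_s" in df.columns else "speed"
    out = []
    for (comp, speed), sub in df.groupby(["composition", speed_col], sort=True):
        out.append(ReplicateGroup(str(comp), float(speed),
                                  sub["epsilon_c"].to_numpy()))
    return out


def read_replicates_csv(path: str) -> list[ReplicateGroup]:
    return groups_from_dataframe(pd.read_csv(path))


def summary_table(groups: list[ReplicateGroup],
                  multipore: dict | None = None) -> pd.DataFrame:
    """Condition-level summary: n, speed, mean, SD of eps_c, multi-pore rate."""
    rows = []
    for g in sorted(groups, key=lambda g: (g.composition, g.speed)):
        row = {"composition": g.composition, "speed_m_per_s": g.speed,
               "replicates": g.n, "eps_c_mean": g.mean, "eps_c_sd": g.sd}
        if multipore is not None:
            row["multipore_rate"] = multipore.get((g.composition, g.speed), np.nan)
        rows.append(row)
    return pd.DataFrame(rows)
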