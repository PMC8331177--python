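"""Group-level statistics for mixed within-between discounting designs.

Implements the classical univariate repeated-measures decomposition for
a design with one between-subject factor (group) and up to two
within-subject factors (condition, reward magnitude), plus the
accompanying post hoc (Fisher LSD), summary-statistic t and chi-square
tests, and the default-prior (JZS) Bayes factor for two-sample t-tests.

The mixed ANOVA works on a long-format table and returns one row per
effect with its own error term: the between effect is tested against
subjects-within-groups; each within effect and its interaction with
group against the corresponding effect-by-subject interaction.  With
unequal group sizes, main effects of within factors are tested on the
unweighted mean of group means (the Type-III convention of mainstream
ANOVA software), which reproduces the 1-and-51 degrees of freedom of a
12-vs-41 two-group study.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import integrate, linalg, stats

__all__ = [
    "AnovaTable",
    "BayesResult",
    "DesignError",
    "GroupSummary",
    "LsdResult",
    "NumericalError",
    "TTestResult",
    "chi_square_2x2",
    "fisher_lsd",
    "jzs_bf_from_t",
    "jzs_bf_ttest",
    "mixed_anova",
    "pooled_t",
]

DEFAULT_PRIOR_SCALE = math.sqrt(2.0) / 2.0  # Cauchy scale 0.707

AnovaTable = pd.DataFrame  # rows: effect, df_effect, df_error, ss_effect, ss_error, F, p, partial_eta_sq


class DesignError(ValueError):
    """The data table does not realize the requested crossed design."""


class NumericalError(RuntimeError):
    """A quadrature failed to converge to acceptable accuracy."""


@dataclass(frozen=True)
class GroupSummary:
    """Summary statistics (n, mean, sd) of one group's measurements."""

    n: int
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("group summaries need n >= 2")
        if self.sd < 0:
            raise ValueError("sd must be nonnegative")


class TTestResult(NamedTuple):
    t: float
    df: int
    p: float


class LsdResult(NamedTuple):
    t: float
    df: int
    p: float


@dataclass(frozen=True)
class BayesResult:
    bf10: float
    prior_scale: float


# --------------------------------------------------------------------------
# Mixed ANOVA
# --------------------------------------------------------------------------


def _wide_scores(
    data: pd.DataFrame,
    dv: str,
    between: str,
    within: Sequence[str],
    subject: str,
) -> tuple[np.ndarray, np.ndarray, list[tuple], list[str]]:
    """Pivot to one row per subject, one column per within cell.

    Returns (scores, group codes per subject, cell index, group levels).
    Raises :class:`DesignError` naming the first incomplete subject/cell.
    """
    for col in (dv, between, subject, *within):
        if col not in data.columns:
            raise DesignError(f"column {col!r} missing from table")
    gmap = data.groupby(subject)[between].nunique()
    if (gmap > 1).any():
        bad = gmap[gmap > 1].index[0]
        raise DesignError(f"participant {bad!r} appears in more than one group")
    levels = [sorted(data[w].unique()) for w in within]
    cells = list(itertools.product(*levels))
    try:
        wide = data.pivot(index=subject, columns=list(within), values=dv)
    except ValueError as err:  # duplicated subject/cell observations
        raise DesignError(f"duplicate observations in design: {err}") from None
    wide = wide.reindex(columns=pd.MultiIndex.from_tuples(cells) if len(within) > 1
                        else [c[0] for c in cells])
    if wide.isna().any().any():
        sub = wide.index[wide.isna().any(axis=1)][0]
        cell = wide.columns[wide.loc[sub].isna()][0]
        raise DesignError(f"participant {sub!r} is missing cell {cell!r}")
    groups = data.drop_duplicates(subject).set_index(subject)[between].reindex(wide.index)
    glevels = sorted(groups.unique())
    if len(glevels) < 2:
        raise DesignError("need at least two groups")
    counts = groups.value_counts()
    if (counts < 2).any():
        raise DesignError("need at least two participants per group")
    gcodes = groups.map({g: i for i, g in enumerate(glevels)}).to_numpy()
    return wide.to_numpy(dtype=float), gcodes, cells, glevels


def _orthonormal_contrasts(n_levels: int) -> np.ndarray:
    """(n_levels, n_levels-1) orthonormal columns, each orthogonal to 1."""
    return linalg.helmert(n_levels).T


def _within_effect_columns(
    within: Sequence[str], levels_per_factor: Sequence[int]
) -> dict[tuple[str, ...], np.ndarray]:
    """Orthonormal transform columns for each within effect.

    For factors W1 (p levels) and W2 (q levels) over cells ordered as
    the cartesian product, the W1 main-effect columns are U_p kron
    1_q/sqrt(q), W2's are 1_p/sqrt(p) kron U_q, and the interaction's
    U_p kron U_q, where U_r is an orthonormal contrast basis.
    """
    parts = []
    for p in levels_per_factor:
        parts.append((_orthonormal_contrasts(p), np.full((p, 1), 1 / math.sqrt(p))))
    effects: dict[tuple[str, ...], np.ndarray] = {}
    n = len(within)
    for mask in range(1, 2**n):
        names = tuple(within[i] for i in range(n) if mask & (1 << i))
        mat = np.ones((1, 1))
        for i in range(n):
            mat = np.kron(mat, parts[i][0] if mask & (1 << i) else parts[i][1])
        effects[names] = mat
    return effects


def _between_ss_per_column(
    z: np.ndarray, gcodes: np.ndarray, n_groups: int
) -> tuple[float, float, float]:
    """(SS for unweighted grand mean, SS between groups, SS residual).

    ``z`` is an (n_subjects, df) block of transformed scores; all three
    sums pool over the block's columns.
    """
    ns = np.array([(gcodes == g).sum() for g in range(n_groups)], dtype=float)
    gmeans = np.vstack([z[gcodes == g].mean(axis=0) for g in range(n_groups)])
    mu = gmeans.mean(axis=0)  # unweighted mean of group means
    ss_mu = float(np.sum(mu**2) / (np.sum(1.0 / ns) / n_groups**2))
    grand_w = (ns[:, None] * gmeans).sum(axis=0) / ns.sum()
    ss_between = float(np.sum(ns[:, None] * (gmeans - grand_w) ** 2))
    resid = z - gmeans[gcodes]
    ss_resid = float(np.sum(resid**2))
    return ss_mu, ss_between, ss_resid


def _row(effect, df1, df2, ss_e, ss_err):
    ms_e, ms_err = ss_e / df1, ss_err / df2
    f = ms_e / ms_err if ms_err > 0 else (0.0 if ms_e == 0 else math.inf)
    p = float(stats.f.sf(f, df1, df2)) if math.isfinite(f) else 0.0
    pes = ss_e / (ss_e + ss_err) if (ss_e + ss_err) > 0 else 0.0
    return {
        "effect": effect,
        "df_effect": df1,
        "df_error": df2,
        "ss_effect": ss_e,
        "ss_error": ss_err,
        "F": f,
        "p": p,
        "partial_eta_sq": pes,
    }


def mixed_anova(
    data: pd.DataFrame,
    dv: str,
    between: str,
    within: Sequence[str],
    subject: str = "participant_id",
) -> AnovaTable:
    """Mixed within-between ANOVA with partial eta squared.

    Parameters
    ----------
    data
        Long-format table: one row per subject x within-cell.
    dv, between, within, subject
        Column names of the measurement, the between-subject factor,
        the one or two within-subject factors, and the subject id.

    Returns
    -------
    DataFrame with one row per effect (between; each within effect; each
    within-by-between interaction) and columns ``effect, df_effect,
    df_error, ss_effect, ss_error, F, p, partial_eta_sq``.  No
    sphericity correction is applied (all within factors in the target
    design have two levels, where sphericity holds trivially).
    """
    within = list(within)
    Y, gcodes, cells, glevels = _wide_scores(data, dv, between, within, subject)
    n_subj, m_cells = Y.shape
    g = len(glevels)
    levels_per_factor = []
    for i, w in enumerate(within):
        levels_per_factor.append(len({c[i] for c in cells}))

    rows = []
    # Between effect: classical one-way ANOVA on subject means, scaled by
    # the number of within cells so sums of squares live on the
    # per-observation scale.
    smeans = Y.mean(axis=1, keepdims=True)
    _, ss_b, ss_sg = _between_ss_per_column(smeans, gcodes, g)
    rows.append(_row(between, g - 1, n_subj - g, m_cells * ss_b, m_cells * ss_sg))

    for names, C in _within_effect_columns(within, levels_per_factor).items():
        z = Y @ C
        df_e = C.shape[1]
        ss_mu, ss_int, ss_err = _between_ss_per_column(z, gcodes, g)
        label = " * ".join(names)
        rows.append(_row(label, df_e, df_e * (n_subj - g), ss_mu, ss_err))
        rows.append(
            _row(f"{between} * {label}", df_e * (g - 1), df_e * (n_subj - g), ss_int, ss_err)
        )
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# Fisher LSD post hoc
# --------------------------------------------------------------------------


def _cell_scores(
    wide: np.ndarray, cells: list[tuple], within: Sequence[str], spec: Mapping[str, object]
) -> np.ndarray:
    """Per-subject mean over the within cells selected by ``spec``."""
    idx = []
    for j, cell in enumerate(cells):
        cell_levels = dict(zip(within, cell if isinstance(cell, tuple) else (cell,)))
        if all(cell_levels[w] == v for w, v in spec.items() if w in within):
            idx.append(j)
    if not idx:
        raise DesignError(f"no cells match {dict(spec)!r}")
    return wide[:, idx].mean(axis=1)


def fisher_lsd(
    data: pd.DataFrame,
    dv: str,
    between: str,
    within: Sequence[str],
    cell_a: Mapping[str, object],
    cell_b: Mapping[str, object],
    subject: str = "participant_id",
) -> LsdResult:
    """Fisher LSD comparison of two design-cell means.

    Cells are given as factor -> level mappings; within factors left out
    of a mapping are collapsed by averaging within subject.  The test is
    a two-tailed t on the pooled error of the corresponding contrast
    scores across all groups (df = N - g), with no multiplicity
    correction — the classical least-significant-difference test.
    """
    within = list(within)
    Y, gcodes, cells, glevels = _wide_scores(data, dv, between, within, subject)
    g = len(glevels)
    n_subj = Y.shape[0]
    df = n_subj - g
    ns = np.array([(gcodes == gi).sum() for gi in range(g)], dtype=float)

    if dict(cell_a) == dict(cell_b):
        return LsdResult(t=0.0, df=df, p=1.0)

    ga = glevels.index(cell_a[between]) if between in cell_a else None
    gb = glevels.index(cell_b[between]) if between in cell_b else None

    if ga == gb:
        # Same (or unspecified) group: per-subject difference scores,
        # error pooled within groups across the whole sample.
        z = _cell_scores(Y, cells, within, cell_a) - _cell_scores(Y, cells, within, cell_b)
        gmeans = np.array([z[gcodes == gi].mean() for gi in range(g)])
        s2 = float(np.sum((z - gmeans[gcodes]) ** 2)) / df
        if ga is None:
            est = float(gmeans.mean())
            var = s2 * float(np.sum(1.0 / ns)) / g**2
        else:
            est = float(gmeans[ga])
            var = s2 / ns[ga]
    else:
        if ga is None or gb is None:
            raise DesignError("a between-group comparison must name both groups")
        # Each subject contributes its own group's cell score; error is
        # pooled over the two compared groups' scores.
        za = _cell_scores(Y, cells, within, cell_a)
        zb = _cell_scores(Y, cells, within, cell_b)
        resid_sq = 0.0
        for gi, zz in ((ga, za), (gb, zb)):
            sel = zz[gcodes == gi]
            resid_sq += float(np.sum((sel - sel.mean()) ** 2))
        df = int(ns[ga] + ns[gb] - 2)
        s2 = resid_sq / df
        est = float(za[gcodes == ga].mean()) - float(zb[gcodes == gb].mean())
        var = s2 * (1.0 / ns[ga] + 1.0 / ns[gb])

    if var == 0:
        t = 0.0 if est == 0 else math.copysign(math.inf, est)
    else:
        t = est / math.sqrt(var)
    p = float(2 * stats.t.sf(abs(t), df)) if math.isfinite(t) else 0.0
    return LsdResult(t=float(t), df=df, p=p)


# --------------------------------------------------------------------------
# Summary-statistic tests
# --------------------------------------------------------------------------


def pooled_t(a: GroupSummary, b: GroupSummary) -> TTestResult:
    """Student's pooled-variance two-sample t-test from summaries.

    df = n_a + n_b - 2; two-tailed p.  Degenerate inputs (both sds zero
    with equal means) return t = 0, p = 1 by convention.
    """
    df = a.n + b.n - 2
    if a.sd == 0 and b.sd == 0:
        if a.mean == b.mean:
            return TTestResult(t=0.0, df=df, p=1.0)
        return TTestResult(t=math.copysign(math.inf, a.mean - b.mean), df=df, p=0.0)
    t, p = stats.ttest_ind_from_stats(
        a.mean, a.sd, a.n, b.mean, b.sd, b.n, equal_var=True
    )
    return TTestResult(t=float(t), df=df, p=float(p))


def chi_square_2x2(counts: Sequence[Sequence[int]]) -> tuple[float, float]:
    """Pearson chi-square on a 2x2 table, df = 1, no continuity correction."""
    table = np.asarray(counts)
    if table.shape != (2, 2):
        raise ValueError(f"expected a 2x2 table, got shape {table.shape}")
    if (table < 0).any() or not np.issubdtype(table.dtype, np.integer):
        raise ValueError("counts must be nonnegative integers")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("chi-square undefined: a marginal total is zero")
    res = stats.chi2_contingency(table, correction=False)
    return float(res.statistic), float(res.pvalue)


# --------------------------------------------------------------------------
# JZS Bayes factor
# --------------------------------------------------------------------------


def jzs_bf_from_t(
    t: float, n1: int, n2: int | None = None, prior_scale: float = DEFAULT_PRIOR_SCALE
) -> float:
    """Default-prior (JZS) Bayes factor BF10 from a t statistic.

    The alternative places a Cauchy(0, prior_scale) prior on the
    standardized effect size; marginalizing analytically over the
    variance leaves a one-dimensional integral over the scale mixture
    variable g ~ InverseGamma(1/2, prior_scale^2/2), evaluated by
    adaptive quadrature.  ``n2=None`` gives the one-sample test.
    """
    if prior_scale <= 0:
        raise ValueError("prior_scale must be positive")
    if n2 is None:
        neff, nu = float(n1), n1 - 1
    else:
        neff, nu = n1 * n2 / (n1 + n2), n1 + n2 - 2
    t2 = t * t
    r2 = prior_scale * prior_scale

    def log_kernel(g: float) -> float:
        shrink = 1.0 + neff * g
        return (
            -0.5 * math.log(shrink)
            - 0.5 * (nu + 1) * math.log1p(t2 / (shrink * nu))
        )

    log_null = -0.5 * (nu + 1) * math.log1p(t2 / nu)

    def integrand(g: float) -> float:
        # g ~ InverseGamma(1/2, r2/2); scale out the null kernel for
        # numerical headroom at large |t|.
        if g <= 0:
            return 0.0
        log_prior = (
            0.5 * math.log(r2 / 2.0)
            - math.lgamma(0.5)
            - 1.5 * math.log(g)
            - r2 / (2.0 * g)
        )
        return math.exp(log_kernel(g) - log_null + log_prior)

    val, err = integrate.quad(integrand, 0.0, np.inf, limit=400)
    if not math.isfinite(val) or val <= 0 or err > 1e-6 * max(val, 1e-12):
        raise NumericalError(
            f"JZS quadrature did not converge (value={val}, abserr={err})"
        )
    return float(val)


def jzs_bf_ttest(
    a: GroupSummary, b: GroupSummary, prior_scale: float = DEFAULT_PRIOR_SCALE
) -> BayesResult:
    """Two-sample JZS Bayes factor (BF10) from group summaries.

    Computes the pooled-variance t statistic and converts it with
    :func:`jzs_bf_from_t`; with the default Cauchy scale 0.707 this
    reproduces the default two-sided Bayesian t-test of standard
    Bayes-factor software.
    """
    t, _, _ = pooled_t(a, b)
    return BayesResult(
        bf10=jzs_bf_from_t(t, a.n, b.n, prior_scale=prior_scale),
        prior_scale=prior_scale,
    )
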