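"""Interplay classification by intersection-union testing.

Each AS01 DEG is assigned, per time point, to one of ten interplay
categories describing how the two immunostimulants jointly shape its
response.  Writing M, Q, A for the effect scores of MPL, QS-21 and AS01
over PBS and D = A - M - Q for the deviation from additivity, the default
category definitions are:

======================  =====================================================
irrelevance_of_MPL      M ~ 0 and A ~ Q
irrelevance_of_QS21     Q ~ 0 and A ~ M
additivity              M != 0, Q != 0, A ~ M + Q
synergy                 M != 0, Q != 0, D != 0 with sign(D) = sign(A)
antagonism              M != 0, Q != 0, D != 0 with sign(D) = -sign(M + Q)
potentiation_by_MPL     M ~ 0, Q != 0, A - Q != 0 with sign = sign(Q)
potentiation_by_QS21    Q ~ 0, M != 0, A - M != 0 with sign = sign(M)
inhibition_by_MPL       M ~ 0, Q != 0, A - Q != 0 with sign = -sign(Q)
inhibition_by_QS21      Q ~ 0, M != 0, A - M != 0 with sign = -sign(M)
emergence               M ~ 0, Q ~ 0, A != 0
======================  =====================================================

"!= 0" statements are moderated two-sided difference tests; "~" statements
are TOST equivalence tests within a [-margin, margin] log2 interval
(margin 1.0 by default).  A category's intersection-union test (IUT)
p-value is the maximum of its component p-values; the category is assigned
only when that maximum is below alpha AND the listed sign conditions hold
on the point estimates.  This three-state logic (active / demonstrably
null / indeterminate) is exactly what the equivalence machinery buys: a
merely non-significant contrast never counts as null, so indeterminate
genes fall to ``unclassified``.

When several categories pass, the one with the smallest IUT p wins, ties
broken by the fixed order of the table above.  The definitions are a
declarative data structure and can be edited without touching the engine.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .linear_model import (
    ContrastSpec,
    EBPrior,
    ModelFit,
    _contrast_moments,
    _t_sf,
    effect_contrast,
)

CATEGORY_NAMES = (
    "irrelevance_of_MPL",
    "irrelevance_of_QS21",
    "additivity",
    "synergy",
    "antagonism",
    "potentiation_by_MPL",
    "potentiation_by_QS21",
    "inhibition_by_MPL",
    "inhibition_by_QS21",
    "emergence",
)

UNCLASSIFIED = "unclassified"


@dataclass(frozen=True)
class Statement:
    """One elementary condition of a category definition.

    kind
        ``difference`` (two-sided moderated t of the contrast against 0),
        ``equivalence`` (TOST within the margin interval), or
        ``any_difference`` (a disjunction over several contrasts; its
        contribution to the IUT p is the minimum of the difference p's).
    contrasts
        Named contrasts (see :func:`adjinterplay.linear_model.effect_contrast`).
    """

    kind: str
    contrasts: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.kind not in {"difference", "equivalence", "any_difference"}:
            raise ValueError(f"unknown statement kind {self.kind!r}")
        if self.kind != "any_difference" and len(self.contrasts) != 1:
            raise ValueError(
                f"{self.kind} statement takes exactly one contrast"
            )


@dataclass(frozen=True)
class SignRule:
    """Require sign(est[target]) = (-)sign(sum of est[reference])."""

    target: str
    reference: tuple[str, ...]
    opposite: bool = False


@dataclass(frozen=True)
class CategoryDefinition:
    """A named conjunction of elementary statements plus sign rules."""

    name: str
    statements: tuple[Statement, ...]
    sign_rules: tuple[SignRule, ...] = ()

    def contrast_names(self) -> set[str]:
        names = {c for s in self.statements for c in s.contrasts}
        for rule in self.sign_rules:
            names.add(rule.target)
            names.update(rule.reference)
        return names


def _diff(*contrasts: str) -> Statement:
    kind = "difference" if len(contrasts) == 1 else "any_difference"
    return Statement(kind=kind, contrasts=tuple(contrasts))


def _eq(contrast: str) -> Statement:
    return Statement(kind="equivalence", contrasts=(contrast,))


DEFAULT_CATEGORIES: tuple[CategoryDefinition, ...] = (
    CategoryDefinition(
        "irrelevance_of_MPL", (_eq("M"), _eq("A_minus_Q"))
    ),
    CategoryDefinition(
        "irrelevance_of_QS21", (_eq("Q"), _eq("A_minus_M"))
    ),
    CategoryDefinition(
        "additivity", (_diff("M"), _diff("Q"), _eq("D"))
    ),
    CategoryDefinition(
        "synergy",
        (_diff("M"), _diff("Q"), _diff("D")),
        (SignRule("D", ("A",)),),
    ),
    CategoryDefinition(
        "antagonism",
        (_diff("M"), _diff("Q"), _diff("D")),
        (SignRule("D", ("M", "Q"), opposite=True),),
    ),
    CategoryDefinition(
        "potentiation_by_MPL",
        (_eq("M"), _diff("Q"), _diff("A_minus_Q")),
        (SignRule("A_minus_Q", ("Q",)),),
    ),
    CategoryDefinition(
        "potentiation_by_QS21",
        (_eq("Q"), _diff("M"), _diff("A_minus_M")),
        (SignRule("A_minus_M", ("M",)),),
    ),
    CategoryDefinition(
        "inhibition_by_MPL",
        (_eq("M"), _diff("Q"), _diff("A_minus_Q")),
        (SignRule("A_minus_Q", ("Q",), opposite=True),),
    ),
    CategoryDefinition(
        "inhibition_by_QS21",
        (_eq("Q"), _diff("M"), _diff("A_minus_M")),
        (SignRule("A_minus_M", ("M",), opposite=True),),
    ),
    CategoryDefinition(
        "emergence", (_eq("M"), _eq("Q"), _diff("A"))
    ),
)

#: Categories whose statements assert at least one nonzero effect; for an
#: all-null gene these are the only possible false assignments (the two
#: irrelevance categories consist solely of equivalence statements that a
#: null gene genuinely satisfies).
EFFECT_ASSERTING_CATEGORIES = tuple(
    c.name for c in DEFAULT_CATEGORIES
    if any(s.kind != "equivalence" for s in c.statements)
)

#: Mirror map under exchange of the MPL and QS-21 labels.
MIRROR_MAP = {
    "irrelevance_of_MPL": "irrelevance_of_QS21",
    "irrelevance_of_QS21": "irrelevance_of_MPL",
    "potentiation_by_MPL": "potentiation_by_QS21",
    "potentiation_by_QS21": "potentiation_by_MPL",
    "inhibition_by_MPL": "inhibition_by_QS21",
    "inhibition_by_QS21": "inhibition_by_MPL",
    "additivity": "additivity",
    "synergy": "synergy",
    "antagonism": "antagonism",
    "emergence": "emergence",
    UNCLASSIFIED: UNCLASSIFIED,
}


@dataclass
class InterplayCall:
    """Classification of one gene at one time point."""

    gene: str
    time: str
    category: str
    iut_p: float
    theta_M: float
    theta_Q: float
    theta_A: float
    components: dict[str, float] = field(default_factory=dict)


def compute_effect_scores(fit: ModelFit, time: str) -> pd.DataFrame:
    """Per-gene effect scores over PBS at one time point.

    theta_M = mean(MPL) - mean(PBS), theta_Q = mean(QS21) - mean(PBS),
    theta_A = mean(AS01) - mean(PBS), all in log2 units.
    """
    for cond in ("PBS", "MPL", "QS21", "AS01"):
        if (cond, time) not in set(fit.cells):
            raise ValueError(f"cell ({cond!r}, {time!r}) absent from fit")
    out = {}
    for label, name in (("theta_M", "M"), ("theta_Q", "Q"), ("theta_A", "A")):
        est, _ = _contrast_moments(fit, effect_contrast(name, time))
        out[label] = est
    return pd.DataFrame(out, index=fit.coef.index)


def test_equivalence(
    fit: ModelFit,
    prior: EBPrior,
    contrast: ContrastSpec,
    margin: float = 1.0,
) -> pd.DataFrame:
    """TOST equivalence test of a contrast within [-margin, margin].

    p = max[ P(T <= (est - margin)/SE), P(T >= (est + margin)/SE) ] with
    T Student t on d0 + d_g degrees of freedom (normal when d0 = inf).
    Equivalence (the effect confidently inside the interval) is declared
    at p < alpha.
    """
    if not margin > 0:
        raise ValueError("margin must be positive")
    est, unscaled = _contrast_moments(fit, contrast)
    se = np.sqrt(prior.posterior_var(fit).to_numpy()) * unscaled
    df_total = prior.total_df(fit)
    with np.errstate(divide="ignore", invalid="ignore"):
        safe_se = np.where(se > 0, se, 1.0)
        p_upper = _t_sf((margin - est) / safe_se, df_total)   # P(T <= (est-margin)/SE)
        p_lower = _t_sf((est + margin) / safe_se, df_total)   # P(T >= (est+margin)/SE)
    p = np.maximum(p_upper, p_lower)
    degenerate = se == 0
    if degenerate.any():
        p = np.where(
            degenerate, np.where(np.abs(est) < margin, 0.0, 1.0), p
        )
    return pd.DataFrame(
        {"estimate": est, "se": se, "df_total": df_total, "p": p},
        index=fit.coef.index,
    )


def _elementary_tables(
    fit: ModelFit,
    prior: EBPrior,
    time: str,
    definitions: tuple[CategoryDefinition, ...],
    margin: float,
) -> tuple[dict[str, np.ndarray], dict[str, np.ndarray], dict[str, np.ndarray]]:
    """All elementary estimates and p-values needed by the definitions."""
    from .linear_model import test_contrast

    needed = set()
    for d in definitions:
        needed |= d.contrast_names()
    est: dict[str, np.ndarray] = {}
    p_diff: dict[str, np.ndarray] = {}
    p_eq: dict[str, np.ndarray] = {}
    kinds_needed: dict[str, set[str]] = {n: set() for n in needed}
    for d in definitions:
        for s in d.statements:
            for c in s.contrasts:
                kinds_needed[c].add(
                    "difference" if s.kind != "equivalence" else "equivalence"
                )
    for name in sorted(needed):
        spec = effect_contrast(name, time)
        res = test_contrast(fit, prior, spec)
        est[name] = res["estimate"].to_numpy()
        if "difference" in kinds_needed[name] or not kinds_needed[name]:
            p_diff[name] = res["p"].to_numpy()
        if "equivalence" in kinds_needed[name]:
            p_eq[name] = test_equivalence(fit, prior, spec, margin)["p"].to_numpy()
    return est, p_diff, p_eq


def _category_iut(
    definition: CategoryDefinition,
    est: dict[str, np.ndarray],
    p_diff: dict[str, np.ndarray],
    p_eq: dict[str, np.ndarray],
    alpha: float,
) -> tuple[np.ndarray, np.ndarray]:
    """IUT p-value and pass mask (p < alpha and sign rules) per gene."""
    n = len(next(iter(est.values())))
    iut_p = np.zeros(n)
    ok = np.ones(n, dtype=bool)
    for s in definition.statements:
        if s.kind == "difference":
            comp = p_diff[s.contrasts[0]]
        elif s.kind == "equivalence":
            comp = p_eq[s.contrasts[0]]
        else:  # any_difference: the disjunction holds if any member rejects
            comp = np.minimum.reduce([p_diff[c] for c in s.contrasts])
        iut_p = np.maximum(iut_p, comp)
    for rule in definition.sign_rules:
        target = est[rule.target]
        ref = np.sum([est[c] for c in rule.reference], axis=0)
        agree = np.sign(target) == np.sign(ref)
        if rule.opposite:
            agree = (np.sign(target) == -np.sign(ref))
        ok &= agree & (np.sign(target) != 0) & (np.sign(ref) != 0)
    ok &= iut_p < alpha
    return iut_p, ok


def classify_table(
    fit: ModelFit,
    prior: EBPrior,
    time: str,
    genes: list[str] | pd.Index | None = None,
    alpha: float = 0.05,
    margin: float = 1.0,
    definitions: tuple[CategoryDefinition, ...] = DEFAULT_CATEGORIES,
) -> pd.DataFrame:
    """Classify genes at one time point (vectorised over genes).

    Parameters
    ----------
    genes
        Classification universe, normally the AS01 DEGs at this time
        point; ``None`` classifies every gene in the fit.

    Returns a DataFrame with columns gene, time, category, iut_p,
    theta_M/Q/A, plus one ``p_<category>`` column with each category's IUT
    p-value and the elementary ``p_diff_*`` / ``p_eq_*`` columns.
    """
    est, p_diff, p_eq = _elementary_tables(fit, prior, time, definitions,
                                           margin)
    scores = compute_effect_scores(fit, time)
    all_genes = fit.coef.index
    n = len(all_genes)
    cat_p = np.full((len(definitions), n), np.nan)
    cat_ok = np.zeros((len(definitions), n), dtype=bool)
    for i, d in enumerate(definitions):
        cat_p[i], cat_ok[i] = _category_iut(d, est, p_diff, p_eq, alpha)
    # smallest passing IUT p wins; ties resolved by fixed definition order
    masked = np.where(cat_ok, cat_p, np.inf)
    best = masked.argmin(axis=0)
    any_pass = cat_ok.any(axis=0)
    names = np.array([d.name for d in definitions])
    category = np.where(any_pass, names[best], UNCLASSIFIED)
    iut_p = np.where(any_pass, masked[best, np.arange(n)], np.nan)
    out = pd.DataFrame(
        {
            "gene": all_genes,
            "time": time,
            "category": category,
            "iut_p": iut_p,
            "theta_M": scores["theta_M"].to_numpy(),
            "theta_Q": scores["theta_Q"].to_numpy(),
            "theta_A": scores["theta_A"].to_numpy(),
        }
    )
    for i, d in enumerate(definitions):
        out[f"p_{d.name}"] = cat_p[i]
    for name, arr in sorted(p_diff.items()):
        out[f"p_diff_{name}"] = arr
    for name, arr in sorted(p_eq.items()):
        out[f"p_eq_{name}"] = arr
    if genes is not None:
        missing = set(genes) - set(all_genes)
        if missing:
            raise KeyError(f"genes absent from fit: {sorted(missing)[:5]}")
        out = out.set_index("gene").loc[list(genes)].reset_index()
    return out


def classify_gene(
    gene: str,
    time: str,
    fit: ModelFit,
    prior: EBPrior,
    alpha: float = 0.05,
    margin: float = 1.0,
    definitions: tuple[CategoryDefinition, ...] = DEFAULT_CATEGORIES,
) -> InterplayCall:
    """Classify a single gene; see :func:`classify_table`."""
    if gene not in set(fit.coef.index):
        raise KeyError(f"gene {gene!r} absent from fit")
    row = classify_table(
        fit, prior, time, genes=[gene], alpha=alpha, margin=margin,
        definitions=definitions,
    ).iloc[0]
    components = {
        k: float(row[k]) for k in row.index
        if k.startswith(("p_diff_", "p_eq_", "p_"))
    }
    return InterplayCall(
        gene=gene,
        time=time,
        category=str(row["category"]),
        iut_p=float(row["iut_p"]) if pd.notna(row["iut_p"]) else math.nan,
        theta_M=float(row["theta_M"]),
        theta_Q=float(row["theta_Q"]),
        theta_A=float(row["theta_A"]),
        components=components,
    )


def summarize_categories(
    calls: pd.DataFrame,
    deg_table: pd.DataFrame | None = None,
    definitions: tuple[CategoryDefinition, ...] = DEFAULT_CATEGORIES,
) -> pd.DataFrame:
    """Per-time category counts and fractions over the DEG universe.

    ``fraction`` is relative to all DEGs (unclassified included in the
    denominator); ``fraction_of_classified`` excludes the unclassified
    remainder.  Both are emitted because published category distributions
    do not always state which denominator they use.
    """
    names = [d.name for d in definitions] + [UNCLASSIFIED]
    rows = []
    times = (
        list(dict.fromkeys(calls["time"])) if len(calls) else
        (list(dict.fromkeys(deg_table["time"])) if deg_table is not None
         and len(deg_table) else [])
    )
    for time in times:
        sub = calls[calls["time"] == time]
        total = len(sub)
        classified = int((sub["category"] != UNCLASSIFIED).sum())
        for name in names:
            count = int((sub["category"] == name).sum())
            rows.append(
                {
                    "time": time,
                    "category": name,
                    "count": count,
                    "total_degs": total,
                    "fraction": count / total if total else np.nan,
                    "fraction_of_classified": (
                        count / classified
                        if classified and name != UNCLASSIFIED
                        else np.nan
                    ),
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "time", "category", "count", "total_degs", "fraction",
            "fraction_of_classified",
        ],
    )


def mirror_category(name: str) -> str:
    """Category label after exchanging the MPL and QS-21 input labels."""
    return MIRROR_MAP[name]
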