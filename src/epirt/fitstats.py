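"""Item-fit chi-square diagnostics and nested-model comparison.

Item fit uses an interval likelihood-ratio statistic: for each item,
patients are grouped into quantile intervals of their *leave-one-out* EAP
trait score (the posterior mean over the quadrature grid given every other
item's response), observed endorsement counts per interval are compared
with the counts expected under the leave-one-out posterior,
``E[x_si | rest] = sum_k post^(-i)_sk P_i(node_k)``, and the statistic

    G2 = 2 * sum_g [ r ln(r/E) + (n - r) ln((n - r)/(n - E)) ]

is referred to a chi-square with (number of intervals after merging) minus
(number of item parameters) degrees of freedom.  Leaving the item itself
out of both the grouping and the expectation is what keeps the statistic
calibrated: trait scores estimated *with* the item condition on the very
response being tested, which inflates the statistic severely even when the
model is correct (the classic trait-estimation-error problem with
interval fit statistics).  Adjacent intervals are merged until every
expected endorsement count reaches a minimum (default 5).  Because many
items are tested at once, a Benjamini-Hochberg adjusted p-value column is
emitted alongside the raw one.

Nested models (1PL within 2PL within 3PL) are compared with the usual
likelihood-ratio chi-square on the difference in free-parameter counts:
for m items, 2PL versus common-slope 1PL has m - 1 degrees of freedom.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy.stats import chi2
from statsmodels.stats.multitest import multipletests

from .irt import MODELS, CodeIRT, CodeIRTResults, _pattern_loglik, _probs, irf

__all__ = [
    "ItemFitStat",
    "ModelComparison",
    "lr_chisq",
    "item_fit_chisq",
    "item_fit_table",
    "compare_models",
    "fit_nested_pair",
    "item_fit_reference",
]


@dataclasses.dataclass
class ItemFitStat:
    code: str
    chisq: float
    df: int
    p_value: float
    intervals: pd.DataFrame
    reason: str | None = None  # set when the statistic is not computable


@dataclasses.dataclass(frozen=True)
class ModelComparison:
    model_a: str  # restricted
    model_b: str  # general
    chisq: float
    df: int
    p_value: float


def lr_chisq(r: np.ndarray, n: np.ndarray, e: np.ndarray) -> float:
    """Interval likelihood-ratio statistic with the 0*ln(0/E)=0 convention."""
    r = np.asarray(r, dtype=float)
    n = np.asarray(n, dtype=float)
    e = np.clip(np.asarray(e, dtype=float), 1e-9, n - 1e-9)
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = np.where(r > 0, r * np.log(r / e), 0.0)
        t0 = np.where(n - r > 0, (n - r) * np.log((n - r) / (n - e)), 0.0)
    return float(2.0 * (t1 + t0).sum())


def _quantile_bins(eap: np.ndarray, n_intervals: int) -> np.ndarray:
    """Equal-mass intervals that never split tied trait scores.

    Sparse endorsement matrices produce heavy ties (identical response
    patterns get identical EAPs); plain quantile edges then collapse.
    Each tied value is assigned the bin its cumulative rank starts in, so
    a dominant tie group occupies a single interval while the rest of the
    distribution is still split into roughly equal-mass intervals.
    """
    u, inverse, counts = np.unique(eap, return_inverse=True, return_counts=True)
    start = np.concatenate([[0], np.cumsum(counts)[:-1]])
    width = len(eap) / n_intervals
    bin_of_value = np.minimum((start / width).astype(int), n_intervals - 1)
    # renumber to consecutive bins
    _, bin_of_value = np.unique(bin_of_value, return_inverse=True)
    return bin_of_value[inverse]


def _merge_intervals(r, n, e, min_expected):
    """Merge adjacent intervals until every expected count >= min_expected."""
    r, n, e = list(r), list(n), list(e)
    while len(e) > 2 and min(e) < min_expected:
        g = int(np.argmin(e))
        if g == 0:
            nb = 1
        elif g == len(e) - 1:
            nb = g - 1
        else:
            nb = g - 1 if e[g - 1] <= e[g + 1] else g + 1
        lo, hi = min(g, nb), max(g, nb)
        r[lo] += r.pop(hi)
        n[lo] += n.pop(hi)
        e[lo] += e.pop(hi)
    return np.asarray(r), np.asarray(n), np.asarray(e)


def item_fit_chisq(
    results: CodeIRTResults, n_intervals: int = 10, min_expected: float = 5.0
) -> list[ItemFitStat]:
    """Interval LR chi-square for every calibrated item.

    For item ``i``, both the quantile grouping and the expected
    endorsement counts are built from the leave-one-out posterior over the
    quadrature grid (all items except ``i``); see the module docstring.
    Items left with fewer than 2 usable intervals get a missing statistic
    with a reason instead of a number.
    """
    X = results.X
    grid = results.grid
    n_params = {"1pl": 1, "2pl": 2, "3pl": 3}[results.model]
    alpha = results.items["alpha"].to_numpy()
    beta = results.items["beta"].to_numpy()
    gamma = results.items["gamma"].to_numpy()
    P = _probs(alpha, beta, gamma, grid.nodes)  # (m, K)
    ll = _pattern_loglik(X, P) + np.log(grid.weights)[None, :]  # (n, K)
    logP = np.log(P)
    log1mP = np.log1p(-P)
    out = []
    for j, code in enumerate(results.items["code"]):
        x = X[:, j].astype(float)
        ll_j = ll - (x[:, None] * logP[j][None, :] + (1.0 - x)[:, None] * log1mP[j][None, :])
        ll_j -= ll_j.max(axis=1, keepdims=True)
        post_j = np.exp(ll_j)
        post_j /= post_j.sum(axis=1, keepdims=True)
        expected_s = post_j @ P[j]
        # round so patients with identical rest-patterns are exact ties:
        # the subtraction above leaves ulp-level noise that differs with
        # the patient's own response, which would leak it into the grouping
        eap_j = np.round(post_j @ grid.nodes, 8)
        bins = _quantile_bins(eap_j, n_intervals)
        n_bins = bins.max() + 1
        r = np.bincount(bins, weights=x, minlength=n_bins)
        n = np.bincount(bins, minlength=n_bins).astype(float)
        e = np.bincount(bins, weights=expected_s, minlength=n_bins)
        r, n, e = _merge_intervals(r, n, e, min_expected)
        table = pd.DataFrame({"n": n, "observed": r, "expected": e})
        df = len(e) - n_params
        if len(e) < 2 or df < 1:
            out.append(
                ItemFitStat(str(code), np.nan, max(df, 0), np.nan, table,
                            reason="fewer than 2 usable intervals")
            )
            continue
        stat = lr_chisq(r, n, e)
        out.append(ItemFitStat(str(code), stat, df, float(chi2.sf(stat, df)), table))
    return out


def item_fit_table(
    results: CodeIRTResults, n_intervals: int = 10, min_expected: float = 5.0
) -> pd.DataFrame:
    """Item-fit statistics as a table with BH-adjusted p-values."""
    stats = item_fit_chisq(results, n_intervals, min_expected)
    df = pd.DataFrame(
        {
            "code": [s.code for s in stats],
            "chisq": [s.chisq for s in stats],
            "df": [s.df for s in stats],
            "p_value": [s.p_value for s in stats],
            "reason": [s.reason or "" for s in stats],
        }
    )
    ok = df["p_value"].notna()
    adj = np.full(len(df), np.nan)
    if ok.any():
        adj[ok.to_numpy()] = multipletests(df.loc[ok, "p_value"], method="fdr_bh")[1]
    df["p_adjusted"] = adj
    return df


def compare_models(restricted: CodeIRTResults, general: CodeIRTResults) -> ModelComparison:
    """Likelihood-ratio comparison of two nested fits on the same matrix."""
    order = {m: i for i, m in enumerate(MODELS)}
    if order[restricted.model] >= order[general.model]:
        raise ValueError(
            f"{restricted.model} is not nested in {general.model}; "
            "pass the restricted fit first"
        )
    if restricted.n_patients != general.n_patients or list(restricted.items["code"]) != list(
        general.items["code"]
    ):
        raise ValueError("fits must use the same matrix and the same kept items")
    chisq = restricted.minus2_loglik - general.minus2_loglik
    df = general.n_free_parameters - restricted.n_free_parameters
    p = float(chi2.sf(max(chisq, 0.0), df)) if chisq > 0 else 1.0
    return ModelComparison(restricted.model, general.model, float(chisq), int(df), p)


def fit_nested_pair(
    data,
    models: tuple[str, str] = ("1pl", "2pl"),
    fit_options: dict | None = None,
    **model_kwargs,
) -> tuple[CodeIRTResults, CodeIRTResults, ModelComparison]:
    """Fit a restricted and a general model, warm-starting the general one.

    Warm-starting the general fit from the restricted solution guarantees a
    non-negative likelihood-ratio statistic.
    """
    fit_options = fit_options or {}
    res_a = CodeIRT(data, model=models[0], **model_kwargs).fit(**fit_options)
    start = (
        res_a.items["alpha"].to_numpy(),
        res_a.items["beta"].to_numpy(),
    )
    res_b = CodeIRT(data, model=models[1], **model_kwargs).fit(start=start, **fit_options)
    return res_a, res_b, compare_models(res_a, res_b)


def item_fit_reference(
    results: CodeIRTResults,
    n_reps: int = 200,
    seed: int = 0,
    n_intervals: int = 10,
    min_expected: float = 5.0,
    fit_options: dict | None = None,
) -> pd.DataFrame:
    """Parametric-bootstrap reference distribution of the item-fit statistic.

    Each replicate draws traits from the standard-normal prior and
    responses from the fitted item parameters, refits the same model
    (screening off: the replicate is correctly specified by construction)
    and recomputes the statistic.  Returns a long table
    (rep, code, chisq, df) for calibration checks and empirical critical
    values.
    """
    rng = np.random.default_rng(seed)
    fit_options = dict(fit_options or {})
    fit_options.setdefault("compute_se", False)
    alpha = results.items["alpha"].to_numpy()
    beta = results.items["beta"].to_numpy()
    gamma = results.items["gamma"].to_numpy()
    n = results.n_patients
    rows = []
    for rep in range(n_reps):
        theta = rng.standard_normal(n)
        prob = irf(theta[:, None], alpha[None, :], beta[None, :], gamma[None, :])
        Xb = (rng.random(prob.shape) < prob).astype(np.uint8)
        model = CodeIRT(
            Xb,
            model=results.model,
            code_ids=results.items["code"].to_numpy(),
            grid=results.grid,
            screen=False,
        )
        res_b = model.fit(**fit_options)
        for s in item_fit_chisq(res_b, n_intervals, min_expected):
            rows.append({"rep": rep, "code": s.code, "chisq": s.chisq, "df": s.df})
    return pd.DataFrame(rows)
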